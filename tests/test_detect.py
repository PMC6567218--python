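"""Centroid distances, GEV thresholds, run extraction, widening geometry
and channel-group fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from uar import (
    EstimationError,
    Span,
    SynthScenario,
    EventSpec,
    UARConfig,
    ValidationError,
    build_seeg,
    centroid_distances,
    detect_grouped,
    detect_runs,
    fit_gev,
    merge_spans,
    threshold_T1,
    threshold_T2,
    widen_and_layout,
)
from uar.detect import ArtifactDetector, DistanceProfile
from uar.features import IntervalFeatures


def profile_from(distances, Lw=155, d=32):
    distances = np.asarray(distances, dtype=float)
    starts = np.arange(distances.size) * d
    return DistanceProfile(
        distances=distances, centroid=np.zeros(2), starts=starts, Lw=Lw, d=d
    )


def feats_from(vectors):
    vectors = np.asarray(vectors, dtype=float)
    return IntervalFeatures(
        vectors=vectors, starts=np.arange(len(vectors)) * 32, Lw=155, d=32
    )


class TestCentroidDistances:
    def test_identical_rows_zero(self):
        prof = centroid_distances(feats_from(np.ones((5, 4))))
        np.testing.assert_allclose(prof.distances, 0.0)

    def test_antipodal_rows(self):
        v = np.array([3.0, 4.0])
        prof = centroid_distances(feats_from([v, -v]))
        np.testing.assert_allclose(prof.centroid, 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.distances, [5.0, 5.0])

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        rows = rng.standard_normal((5, 6))
        prof = centroid_distances(feats_from(rows))
        centroid = sum(rows) / 5
        for i, row in enumerate(rows):
            expected = np.sqrt(sum((a - b) ** 2 for a, b in zip(row, centroid)))
            assert prof.distances[i] == pytest.approx(expected, abs=1e-12)

    def test_single_interval_rejected(self):
        with pytest.raises(ValidationError):
            centroid_distances(feats_from(np.ones((1, 4))))


class TestGEV:
    def test_parameter_recovery(self):
        # xi convention: scipy's c = -xi
        sample = stats.genextreme.rvs(
            -0.1, loc=1.0, scale=0.3, size=100_000, random_state=1
        )
        shape, loc, scale = fit_gev(sample)
        assert shape == pytest.approx(0.1, abs=0.05)
        assert loc == pytest.approx(1.0, abs=0.05)
        assert scale == pytest.approx(0.3, abs=0.05)

    def test_constant_sample_degenerate(self):
        with pytest.raises(EstimationError):
            fit_gev(np.full(100, 2.0))

    def test_too_few(self):
        with pytest.raises(ValidationError):
            fit_gev(np.arange(10.0))

    def test_shift_equivariance(self):
        sample = stats.genextreme.rvs(
            -0.1, loc=1.0, scale=0.3, size=20_000, random_state=2
        )
        s0, l0, sc0 = fit_gev(sample)
        s1, l1, sc1 = fit_gev(sample + 5.0)
        assert l1 - l0 == pytest.approx(5.0, abs=0.02)
        assert s1 == pytest.approx(s0, abs=0.02)
        assert sc1 == pytest.approx(sc0, abs=0.02)


class TestThresholds:
    def test_fixed_echoes_value(self):
        assert threshold_T1(np.arange(100.0), "fixed", 1.33) == 1.33

    def test_gev_quantile_matches_closed_form(self):
        sample = stats.genextreme.rvs(
            -0.15, loc=1.0, scale=0.25, size=50_000, random_state=3
        )
        xi, loc, scale = fit_gev(sample)
        # closed-form GEV quantile: loc + scale * ((-ln p)^(-xi) - 1) / xi
        p = 0.5
        expected = loc + scale * ((-np.log(p)) ** (-xi) - 1.0) / xi
        got = threshold_T1(sample, "gev_quantile", p)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_gev_quantile_bad_probability(self):
        with pytest.raises(ValidationError):
            threshold_T1(np.arange(100.0), "gev_quantile", 1.0)

    def test_t2_even_tail(self):
        d = np.array([0.1, 0.2, 2.0, 3.0, 4.0, 5.0])
        assert threshold_T2(d, 2.0) == 3.5
        assert np.sum(d >= 3.5) == np.sum((d >= 2.0) & (d < 3.5)) == 2

    def test_t2_odd_tail_imbalance_at_most_one(self):
        d = np.array([0.1, 2.0, 3.0, 4.0])
        t2 = threshold_T2(d, 2.0)
        assert t2 == 3.0
        assert abs(np.sum(d >= t2) - np.sum((d >= 2.0) & (d < t2))) <= 1

    def test_t2_small_tail_rejected(self):
        with pytest.raises(ValidationError):
            threshold_T2(np.array([0.1, 0.2, 5.0]), 2.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_t2_balance_property(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.gamma(2.0, 1.0, size=rng.integers(10, 300))
        t1 = np.quantile(d, 0.8)
        if np.sum(d >= t1) < 2:
            return
        t2 = threshold_T2(d, t1)
        assert abs(np.sum(d >= t2) - np.sum((d >= t1) & (d < t2))) <= 1


class TestDetectRuns:
    def test_hand_mapped_example(self):
        prof = profile_from([0.5, 2.0, 2.0, 0.5])
        assert detect_runs(prof, 1.0) == [Span(32, 219)]

    def test_all_below_threshold(self):
        assert detect_runs(profile_from([0.1, 0.2, 0.3]), 1.0) == []

    def test_min_run_filters_short_runs(self):
        prof = profile_from([2.0, 0.1, 2.0, 2.0, 0.1])
        assert detect_runs(prof, 1.0, min_run=2) == [Span(64, 251)]

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 2, size=rng.integers(2, 60))
        prof = profile_from(d)
        got = detect_runs(prof, 1.0)
        # brute-force scan over the boolean pattern
        expected = []
        i = 0
        flags = d >= 1.0
        while i < len(flags):
            if flags[i]:
                j = i
                while j + 1 < len(flags) and flags[j + 1]:
                    j += 1
                expected.append(Span(int(prof.starts[i]), int(prof.starts[j]) + 155))
                i = j + 1
            else:
                i += 1
        assert got == expected

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        prof = profile_from(rng.uniform(0, 3, size=50))
        low = detect_runs(prof, 1.0)
        high = detect_runs(prof, 1.8)
        for s in high:
            assert any(t.contains(s) for t in low)


class TestWidenAndLayout:
    CFG = UARConfig()

    def test_single_artefact_geometry(self):
        portions = widen_and_layout([Span(5000, 6000)], self.CFG, 256.0, 30_000)
        (p,) = portions
        assert p.art == Span(4744, 6256)
        # 26 s window would start at 6256 - 6656 < 0: clipped to the origin
        assert p.icap == Span(0, 6256)
        assert p.ref == Span(4744 - len(p.art), 4744)
        assert not p.truncated_at2

    def test_truncation_when_next_starts_inside_at2(self):
        portions = widen_and_layout(
            [Span(5000, 6000), Span(6100, 6500)], self.CFG, 256.0, 30_000
        )
        a, b = portions
        assert a.art.end == 6100 and a.truncated_at2
        assert b.art.start == 6100  # AT1 of the follower collapses
        assert b.at == Span(6100, 6500)

    def test_clipped_at_recording_start(self):
        (p,) = widen_and_layout([Span(0, 300)], self.CFG, 256.0, 30_000)
        assert p.art.start == 0
        assert p.icap.start == 0

    def test_overlapping_inputs_rejected(self):
        with pytest.raises(ValidationError):
            widen_and_layout([Span(0, 300), Span(200, 400)], self.CFG, 256.0, 30_000)

    @given(st.integers(0, 5_000))
    @settings(max_examples=50, deadline=None)
    def test_layout_invariants(self, seed):
        rng = np.random.default_rng(seed)
        total = 200_000
        n = rng.integers(1, 6)
        cuts = np.sort(rng.choice(np.arange(8000, total - 8000), 2 * n, replace=False))
        spans = [Span(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n)]
        portions = widen_and_layout(spans, self.CFG, 256.0, total)
        for p in portions:
            assert p.art.contains(p.at)
            assert p.icap.contains(p.art)
            assert p.ref.end <= p.art.start
        for a, b in zip(portions, portions[1:]):
            assert a.art.end <= b.art.start  # non-overlapping, sorted


class TestGroupedDetection:
    def _group_rec(self, seed=0):
        # muscle artefact confined to channel 9 (one-hot topography)
        sc = SynthScenario(
            n_channels=12,
            fs=256.0,
            duration_seconds=16.0,
            clean_prefix_seconds=8.0,
            seed=seed,
            events=[EventSpec("emg", 4.0, 1.0, 50.0, focus_channel=9, decay=50.0)],
        )
        return build_seeg(sc)

    def test_merge_spans_examples(self):
        assert merge_spans([Span(0, 100), Span(50, 150)]) == [Span(0, 150)]
        assert merge_spans([Span(0, 100), Span(100, 150)]) == [Span(0, 150)]
        assert merge_spans([Span(0, 10), Span(20, 30)]) == [Span(0, 10), Span(20, 30)]
        assert merge_spans([]) == []

    def test_single_group_identity(self):
        clean, cont, _ = self._group_rec()
        cfg = UARConfig(T=0.7)
        det = ArtifactDetector(T=0.7, fs=256.0).fit(cont.data.T)
        fused = detect_grouped(cont, [list(range(12))], cfg)
        assert fused == det.at_spans_

    def test_focal_artefact_found_by_fusion(self):
        clean, cont, events = self._group_rec()
        cfg = UARConfig(T=0.7)
        groups = [list(range(0, 6)), list(range(6, 12))]
        fused = detect_grouped(cont, groups, cfg)
        ev = events[0].span
        assert any(s.overlap(ev) > 0 for s in fused)

    def test_empty_groups_rejected(self):
        clean, cont, _ = self._group_rec()
        with pytest.raises(ValidationError):
            detect_grouped(cont, [], UARConfig())
        with pytest.raises(ValidationError):
            detect_grouped(cont, [[0], []], UARConfig())


class TestDetectorEstimator:
    def test_fit_attributes(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4000, 4)) * 10
        det = ArtifactDetector(T=5.0, fs=256.0).fit(X)
        assert det.distances_.ndim == 1
        assert det.threshold_ == 5.0
        assert det.at_spans_ == []
        assert det.portions_ == []

    def test_get_set_params_roundtrip(self):
        det = ArtifactDetector(T=2.0)
        params = det.get_params()
        assert params["T"] == 2.0
        det.set_params(T=1.0, min_run=3)
        assert det.T == 1.0 and det.min_run == 3
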