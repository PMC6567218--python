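"""Unsupervised artefact detection from interval-feature centroid distances.

Every sliding interval is a point in AR(2)-coefficient space; artefact-free
cognitive activity forms one dense cluster while artefacts land far from
its centroid.  The Euclidean distance of each interval to the centroid of
all intervals is therefore the detection statistic.  The distance histogram
is well modelled by a Generalized Extreme Value distribution; the default
threshold T = 1.33 marks the beginning of its extreme tail for 64-electrode
recordings and travels across recordings because AR coefficients are scale-
and location-invariant.  A second threshold T2 (the median of the tail
beyond T1) is computed for diagnostics: beyond T2 the number of intervals
equals the number inside [T1, T2).

Detected runs of supra-threshold intervals are widened on both sides
("Option B") to correct late/early detections, and the geometry needed by
the removal stage (ART = AT1 + AT + AT2, the ICA window, the reference
span) is laid out here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .core import (
    EstimationError,
    Recording,
    Span,
    UARConfig,
    ValidationError,
    seconds_to_samples,
)
from .features import ARFeatureExtractor, IntervalFeatures, feature_matrix


@dataclass
class DistanceProfile:
    """Distance of every interval's feature vector to the common centroid."""

    distances: np.ndarray
    centroid: np.ndarray
    starts: np.ndarray
    Lw: int
    d: int


@dataclass
class Thresholds:
    T1: float
    T2: float | None = None
    gev_params: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.T2 is not None and self.T1 > self.T2:
            raise ValidationError(f"T1={self.T1} exceeds T2={self.T2}")


@dataclass
class ArtefactPortion:
    """Sample-coordinate geometry of one detected artefact.

    ``at`` is the detected span, ``art = AT1 + AT + AT2`` the span actually
    filtered, ``icap`` the local ICA window ending with ``art``, ``ref`` the
    provisional equal-length reference immediately preceding ``art`` (the
    removal stage re-selects it against a clean-history mask).
    """

    at: Span
    art: Span
    icap: Span
    ref: Span
    truncated_at2: bool = False

    def __post_init__(self) -> None:
        if not self.art.contains(self.at):
            raise ValidationError("ART must contain AT")
        if not self.icap.contains(self.art):
            raise ValidationError("ICA_P must contain ART")


def centroid_distances(feats: IntervalFeatures) -> DistanceProfile:
    """Euclidean distance of each feature row to the mean of all rows."""
    v = np.asarray(feats.vectors, dtype=np.float64)
    if v.shape[0] < 2:
        raise ValidationError("need at least 2 intervals to form a centroid")
    centroid = v.mean(axis=0)
    distances = np.linalg.norm(v - centroid, axis=1)
    return DistanceProfile(
        distances=distances,
        centroid=centroid,
        starts=np.asarray(feats.starts),
        Lw=feats.Lw,
        d=feats.d,
    )


def fit_gev(distances: np.ndarray) -> tuple[float, float, float]:
    """Maximum-likelihood GEV fit of the distance sample.

    Returns ``(shape, location, scale)`` with the shape parameter in the
    extreme-value xi convention (xi > 0: heavy Frechet tail).  scipy's
    ``genextreme`` uses c = -xi internally.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.size < 50:
        raise ValidationError(f"need >= 50 distances for a GEV fit, got {d.size}")
    if np.ptp(d) == 0:
        raise EstimationError("distances are constant; GEV fit is degenerate")
    c, loc, scale = stats.genextreme.fit(d)
    if not (np.isfinite(c) and np.isfinite(loc) and scale > 0):
        raise EstimationError(
            f"GEV fit did not converge: c={c}, loc={loc}, scale={scale}"
        )
    return float(-c), float(loc), float(scale)


def threshold_T1(
    distances: np.ndarray,
    mode: str = "fixed",
    value: float = 1.33,
) -> float:
    """Detection threshold: a fixed value or a GEV quantile.

    The fixed default 1.33 is the portable tail-onset threshold for
    64-electrode recordings; ``gev_quantile`` mode fits the distance sample
    and returns the inverse CDF at probability ``value``.
    """
    if mode == "fixed":
        return float(value)
    if mode == "gev_quantile":
        if not (0 < value < 1):
            raise ValidationError(f"quantile probability must be in (0, 1), got {value}")
        xi, loc, scale = fit_gev(distances)
        return float(stats.genextreme.ppf(value, -xi, loc=loc, scale=scale))
    raise ValidationError(f"unknown threshold mode {mode!r}")


def threshold_T2(distances: np.ndarray, T1: float) -> float:
    """Median of the tail ``{d : d >= T1}``.

    Guarantees that the number of intervals beyond T2 differs from the
    number inside [T1, T2) by at most one.
    """
    d = np.asarray(distances, dtype=np.float64)
    tail = d[d >= T1]
    if tail.size < 2:
        raise ValidationError(
            f"tail beyond T1={T1} has {tail.size} distances; need >= 2"
        )
    return float(np.median(tail))


def detect_runs(
    profile: DistanceProfile,
    T: float,
    min_run: int = 1,
    Lw: int | None = None,
    d: int | None = None,
) -> list[Span]:
    """Maximal runs of intervals with distance >= T, as sample spans.

    A run of member intervals i..j maps to the union of their windows,
    ``[starts[i], starts[j] + Lw)``; runs shorter than ``min_run`` intervals
    are dropped.
    """
    if not T > 0:
        raise ValidationError("threshold T must be positive")
    Lw = profile.Lw if Lw is None else Lw
    flags = profile.distances >= T
    spans = []
    for i0, i1 in _runs(flags):
        if i1 - i0 >= min_run:
            spans.append(Span(int(profile.starts[i0]), int(profile.starts[i1 - 1]) + Lw))
    return spans


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.r_[0, flags.astype(np.int8), 0]))
    return [(int(idx[k]), int(idx[k + 1])) for k in range(0, len(idx), 2)]


def widen_and_layout(
    at_spans: list[Span],
    cfg: UARConfig,
    fs: float,
    total_samples: int,
) -> list[ArtefactPortion]:
    """Widen detections and lay out the removal geometry.

    ART extends AT by ``at1_seconds`` before and ``at2_seconds`` after,
    clipped to the recording.  When the next detection starts inside the
    AT2 margin, the current ART is truncated at that start and the next
    ART begins exactly there (its AT1 margin collapses).  The ICA window
    is the trailing ``icap_seconds`` ending with ART; the provisional
    reference is the equal-length span immediately before ART.
    """
    at1 = seconds_to_samples(cfg.at1_seconds, fs)
    at2 = seconds_to_samples(cfg.at2_seconds, fs)
    icap_len = seconds_to_samples(cfg.icap_seconds, fs)
    for a, b in zip(at_spans, at_spans[1:]):
        if b.start < a.end:
            raise ValidationError(f"AT spans overlap: {a} and {b}")
    portions: list[ArtefactPortion] = []
    prev_end: int | None = None
    for k, at in enumerate(at_spans):
        art_start = max(at.start - at1, 0)
        if prev_end is not None:
            art_start = max(art_start, prev_end)
        art_end = min(at.end + at2, total_samples)
        truncated = False
        if k + 1 < len(at_spans) and at_spans[k + 1].start < at.end + at2:
            art_end = at_spans[k + 1].start
            truncated = True
        art = Span(art_start, art_end)
        icap = Span(max(art.end - icap_len, 0), art.end)
        if icap.start > art.start:  # ART longer than the ICA window: extend
            icap = Span(art.start, art.end)
        ref = Span(max(art.start - len(art), 0), art.start)
        portions.append(
            ArtefactPortion(at=at, art=art, icap=icap, ref=ref, truncated_at2=truncated)
        )
        prev_end = art_end
    return portions


def merge_spans(spans: list[Span]) -> list[Span]:
    """Union of sample spans, merged into maximal non-overlapping spans."""
    if not spans:
        return []
    spans = sorted(spans)
    merged = [spans[0]]
    for s in spans[1:]:
        if s.start <= merged[-1].end:
            merged[-1] = Span(merged[-1].start, max(merged[-1].end, s.end))
        else:
            merged.append(s)
    return merged


def detect_grouped(
    rec: Recording,
    groups: list[list[int]],
    cfg: UARConfig,
) -> list[Span]:
    """Per-group detection fused by union.

    Running detection on small electrode groups makes the centroid distance
    sensitive to artefacts confined to few channels; the per-group span
    lists are merged into maximal spans.
    """
    if not groups or any(not g for g in groups):
        raise ValidationError("groups must be a non-empty list of non-empty subsets")
    cfg.validate(rec.fs)
    all_spans: list[Span] = []
    for g in groups:
        feats = feature_matrix(rec, channels=g, Lw=cfg.Lw, d=cfg.d)
        profile = centroid_distances(feats)
        all_spans.extend(detect_runs(profile, cfg.T, cfg.min_run))
    return merge_spans(all_spans)


class ArtifactDetector(BaseEstimator):
    """Centroid-distance artefact detector over sliding AR(2) features.

    Parameters mirror :class:`~uar.core.UARConfig`.  ``fit`` takes ``X`` of
    shape ``(n_samples, n_channels)`` and exposes:

    ``distances_`` : per-interval centroid distances
    ``centroid_`` : feature-space centroid
    ``threshold_`` : the detection threshold used (T1)
    ``t2_`` : diagnostic tail-median threshold (None if the tail is empty)
    ``at_spans_`` : detected spans in sample coordinates
    ``portions_`` : widened :class:`ArtefactPortion` layout
    """

    def __init__(
        self,
        Lw: int = 155,
        d: int = 32,
        T: float = 1.33,
        threshold_mode: str = "fixed",
        gev_quantile: float = 0.90,
        min_run: int = 1,
        at1_seconds: float = 1.0,
        at2_seconds: float = 1.0,
        icap_seconds: float = 26.0,
        channels: list[int] | None = None,
        fs: float = 256.0,
    ):
        self.Lw = Lw
        self.d = d
        self.T = T
        self.threshold_mode = threshold_mode
        self.gev_quantile = gev_quantile
        self.min_run = min_run
        self.at1_seconds = at1_seconds
        self.at2_seconds = at2_seconds
        self.icap_seconds = icap_seconds
        self.channels = channels
        self.fs = fs

    def _config(self) -> UARConfig:
        return UARConfig(
            Lw=self.Lw,
            d=self.d,
            T=self.T,
            min_run=self.min_run,
            at1_seconds=self.at1_seconds,
            at2_seconds=self.at2_seconds,
            icap_seconds=self.icap_seconds,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_samples, n_channels)")
        cfg = self._config().validate(self.fs)
        ext = ARFeatureExtractor(Lw=self.Lw, d=self.d, channels=self.channels)
        vectors = ext.fit_transform(X)
        feats = IntervalFeatures(vectors, ext.starts_, self.Lw, self.d)
        profile = centroid_distances(feats)
        if self.threshold_mode == "fixed":
            t1 = threshold_T1(profile.distances, "fixed", self.T)
        else:
            t1 = threshold_T1(profile.distances, "gev_quantile", self.gev_quantile)
        try:
            t2 = threshold_T2(profile.distances, t1)
        except ValidationError:
            t2 = None
        self.n_features_in_ = X.shape[1]
        self.profile_ = profile
        self.distances_ = profile.distances
        self.centroid_ = profile.centroid
        self.threshold_ = t1
        self.t2_ = t2
        # nearby runs whose window unions overlap are one artefact portion
        self.at_spans_ = merge_spans(detect_runs(profile, t1, self.min_run))
        self.portions_ = widen_and_layout(self.at_spans_, cfg, self.fs, X.shape[0])
        return self

    def detect(self, rec: Recording) -> list[Span]:
        """Convenience wrapper: fit on a :class:`Recording`, return spans."""
        self.fs = rec.fs
        self.fit(rec.data.T)
        return self.at_spans_
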