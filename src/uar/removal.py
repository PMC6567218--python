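"""Iterative per-electrode artefact subtraction with a variance stopping test.

For each detected artefact, the components of the local ICA decomposition
are subtracted from the artefact span (ART) of every electrode, one
projection at a time, in descending order of influence.  After each
subtraction the residual span is compared against an equal-length
artefact-free reference span (REF) with a two-sample F-test for equal
variances.  The subtraction stops when the residual variance has dropped
significantly below the reference variance; if that significant drop was
preceded by a plateau of non-rejections (the residual statistically
indistinguishable from clean background), the output rolls back to the
first state of that plateau, so the algorithm neither under- nor
over-filters.  Samples outside ART spans are never modified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .core import (
    Recording,
    ReferenceUnavailableError,
    Span,
    UARConfig,
    ValidationError,
    notch_filter,
)
from .decompose import (
    ICADecomposition,
    OrderedComponents,
    order_components,
    project_component,
    run_fastica,
)
from .detect import (
    ArtefactPortion,
    centroid_distances,
    detect_grouped,
    detect_runs,
    widen_and_layout,
)
from .features import feature_matrix


@dataclass
class VarianceTestResult:
    """Two-sided two-sample F-test for equal variances."""

    F: float
    p: float
    reject: bool
    v1: float = 0.0
    v2: float = 0.0


@dataclass
class ElectrodeFilterTrace:
    """What happened while filtering one electrode's ART span."""

    n_components_subtracted: int
    stop_reason: str  # significant_drop | rollback_to_plateau | exhausted_unchanged
    tests: list[tuple[float, float, bool]] = field(default_factory=list)


@dataclass
class ArtefactRecord:
    """Per-artefact entry of a filter report."""

    portion: ArtefactPortion
    ref: Span | None
    ref_short: bool
    converged: bool
    traces: list[ElectrodeFilterTrace] = field(default_factory=list)
    skipped: bool = False
    skip_reason: str | None = None


@dataclass
class FilterReport:
    """One entry per detected portion, in detection order."""

    records: list[ArtefactRecord] = field(default_factory=list)
    threshold: float = 0.0
    t2: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold_T1": self.threshold,
            "threshold_T2": self.t2,
            "warnings": list(self.warnings),
            "artefacts": [
                {
                    "at": list(r.portion.at),
                    "art": list(r.portion.art),
                    "icap": list(r.portion.icap),
                    "ref": list(r.ref) if r.ref is not None else None,
                    "ref_short": r.ref_short,
                    "truncated_at2": r.portion.truncated_at2,
                    "ica_converged": r.converged,
                    "skipped": r.skipped,
                    "skip_reason": r.skip_reason,
                    "electrodes": [
                        {
                            "components_subtracted": t.n_components_subtracted,
                            "stop_reason": t.stop_reason,
                            "tests": [
                                {"F": F, "p": p, "reject": rej}
                                for F, p, rej in t.tests
                            ],
                        }
                        for t in r.traces
                    ],
                }
                for r in self.records
            ],
        }


def variance_test(x1: np.ndarray, x2: np.ndarray, alpha: float = 0.01) -> VarianceTestResult:
    """Two-sample F-test of equal variances, two-sided.

    F = var(x1)/var(x2) with unbiased variances;
    p = 2 * min(P(F' <= F), P(F' >= F)) under F(n1-1, n2-1).
    A zero-variance ``x2`` against non-degenerate ``x1`` rejects by
    convention with F = +inf (and symmetrically F = 0).
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("variance test needs at least 2 samples per side")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    v1 = float(x1.var(ddof=1))
    v2 = float(x2.var(ddof=1))
    if v1 == 0.0 and v2 == 0.0:
        return VarianceTestResult(F=1.0, p=1.0, reject=False, v1=v1, v2=v2)
    if v2 == 0.0:
        return VarianceTestResult(F=float("inf"), p=0.0, reject=True, v1=v1, v2=v2)
    if v1 == 0.0:
        return VarianceTestResult(F=0.0, p=0.0, reject=True, v1=v1, v2=v2)
    F = v1 / v2
    dist = stats.f(x1.size - 1, x2.size - 1)
    p = float(min(1.0, 2.0 * min(dist.cdf(F), dist.sf(F))))
    return VarianceTestResult(F=F, p=p, reject=p < alpha, v1=v1, v2=v2)


def select_reference(
    art: ArtefactPortion,
    clean_mask: np.ndarray,
    signal_length: int,
    Lw: int = 155,
) -> tuple[Span, bool]:
    """Most recent all-clean span of length len(ART) ending at or before ART.

    Previously filtered artefact spans count as clean.  If no full-length
    clean span exists anywhere in the history, the longest clean span
    ending exactly at ART's start is returned flagged short, provided it
    has at least ``Lw`` samples; otherwise the artefact cannot be filtered.
    """
    clean = np.asarray(clean_mask, dtype=bool)
    if clean.size != signal_length:
        raise ValidationError("clean_mask length must equal signal_length")
    L = len(art.art)
    limit = art.art.start
    if limit >= L:
        cums = np.concatenate([[0], np.cumsum(clean[:limit])])
        ends = np.arange(L, limit + 1)
        ok = (cums[ends] - cums[ends - L]) == L
        hits = np.flatnonzero(ok)
        if hits.size:
            end = int(ends[hits[-1]])
            return Span(end - L, end), False
    # fall back: longest clean run ending exactly at ART's start
    k = 0
    while k < limit and clean[limit - 1 - k]:
        k += 1
    if k >= Lw:
        return Span(limit - k, limit), True
    raise ReferenceUnavailableError(
        f"no clean reference of at least {Lw} samples before sample {limit}"
    )


def filter_electrode(
    electrode_signal: np.ndarray,
    electrode: int,
    art: Span,
    ref: Span,
    dec: ICADecomposition,
    order: OrderedComponents,
    alpha: float = 0.01,
) -> tuple[np.ndarray, ElectrodeFilterTrace]:
    """Iterative component subtraction on one electrode's ART span.

    Subtracts ordered component projections from the ART samples one at a
    time.  After each subtraction the reference span is tested against the
    residual: the process stops when var(REF) > var(residual) *and* the
    two-sided F-test rejects equality.  If the stop was preceded by a run
    of consecutive non-rejections, the output rolls back to the first
    state of that run; if all components are exhausted without a stop, the
    output is that first-plateau state if one was recorded, else the
    original ART unchanged.
    """
    x = np.asarray(electrode_signal, dtype=np.float64)
    for s in (art, ref):
        if not (0 <= s.start < s.end <= x.size):
            raise ValidationError(f"span {s} outside electrode signal")
    if order.order.size != dec.n_components or set(order.order.tolist()) != set(
        range(dec.n_components)
    ):
        raise ValidationError("ordering must be a permutation of all components")
    ref_samples = x[ref.start : ref.end]
    var_ref = float(ref_samples.var(ddof=1))
    n_art = x[art.start : art.end].copy()
    old_art: np.ndarray | None = None
    old_count = 0
    first = False
    before = False
    tests: list[tuple[float, float, bool]] = []
    for i, comp in enumerate(order.order, start=1):
        n_art = n_art - project_component(dec, electrode, int(comp), art)
        res = variance_test(ref_samples, n_art, alpha)
        tests.append((res.F, res.p, res.reject))
        if var_ref > res.v2 and res.reject:
            if before:
                return old_art, ElectrodeFilterTrace(old_count, "rollback_to_plateau", tests)
            return n_art, ElectrodeFilterTrace(i, "significant_drop", tests)
        if not res.reject:  # R0: start or extend a plateau
            if not first:
                old_art = n_art.copy()
                old_count = i
            first = True
            before = True
        else:
            first = False
            before = False
    original = x[art.start : art.end].copy()
    if old_art is not None and not np.array_equal(old_art, original):
        return old_art, ElectrodeFilterTrace(old_count, "rollback_to_plateau", tests)
    return original, ElectrodeFilterTrace(0, "exhausted_unchanged", tests)


def _detect(data: np.ndarray, fs: float, cfg: UARConfig,
            groups: list[list[int]] | None):
    """Detection step shared by the pipeline: spans + distance profile."""
    from .detect import merge_spans, threshold_T2

    channels = None
    if cfg.n_detect is not None:
        channels = list(range(min(cfg.n_detect, data.shape[0])))
    rec = Recording(data, fs=fs)
    feats = feature_matrix(rec, channels=channels, Lw=cfg.Lw, d=cfg.d)
    profile = centroid_distances(feats)
    if groups is None:
        # nearby runs whose window unions overlap are one artefact portion
        spans = merge_spans(detect_runs(profile, cfg.T, cfg.min_run))
    else:
        spans = detect_grouped(rec, groups, cfg)
    try:
        t2 = threshold_T2(profile.distances, cfg.T)
    except ValidationError:
        t2 = None
    return spans, profile, t2


def uar_filter(
    rec: Recording,
    cfg: UARConfig | None = None,
    groups: list[list[int]] | None = None,
) -> tuple[Recording, FilterReport]:
    """Detect and remove artefacts from a whole recording.

    Runs detection, lays out the widened artefact geometry, then processes
    each artefact in order: local FastICA on the current (partially
    filtered) signal, component ordering, and per-electrode iterative
    subtraction of the ART span.  Earlier filtered spans count as clean
    history for later reference selection.  Samples outside every ART span
    are returned bit-identical to the input.
    """
    cfg = (cfg or UARConfig()).validate(rec.fs)
    if cfg.notch_hz is not None:
        rec = notch_filter(rec, cfg.notch_hz)
    flt = UARFilter(**_cfg_to_params(cfg), fs=rec.fs, groups=groups)
    out = flt.fit(rec.data.T).transform(rec.data.T)
    return replace(rec, data=out.T, labels=list(rec.labels)), flt.report_


def _cfg_to_params(cfg: UARConfig) -> dict:
    return dict(
        Lw=cfg.Lw,
        d=cfg.d,
        T=cfg.T,
        min_run=cfg.min_run,
        n_detect=cfg.n_detect,
        at1_seconds=cfg.at1_seconds,
        at2_seconds=cfg.at2_seconds,
        icap_seconds=cfg.icap_seconds,
        alpha=cfg.alpha,
        ordering_mode=cfg.ordering_mode,
        max_restarts=cfg.max_restarts,
        random_state=cfg.seed,
    )


class UARFilter(TransformerMixin, BaseEstimator):
    """Unsupervised artefact-removal transformer.

    ``X`` is ``(n_samples, n_channels)`` in microvolts (time on the first
    axis, as in scikit-learn); the sampling rate comes from the ``fs``
    parameter.  ``transform`` returns the filtered signal and stores a
    :class:`FilterReport` in ``report_`` along with the detection
    attributes ``at_spans_`` and ``portions_``.

    Note that the transformation is per-recording: statistics are estimated
    from, and applied to, the array passed to ``transform``.
    """

    def __init__(
        self,
        Lw: int = 155,
        d: int = 32,
        T: float = 1.33,
        min_run: int = 1,
        n_detect: int | None = None,
        at1_seconds: float = 1.0,
        at2_seconds: float = 1.0,
        icap_seconds: float = 26.0,
        alpha: float = 0.01,
        ordering_mode: str = "max_abs",
        max_restarts: int = 3,
        notch_hz: float | None = None,
        groups: list[list[int]] | None = None,
        fs: float = 256.0,
        random_state: int = 0,
    ):
        self.Lw = Lw
        self.d = d
        self.T = T
        self.min_run = min_run
        self.n_detect = n_detect
        self.at1_seconds = at1_seconds
        self.at2_seconds = at2_seconds
        self.icap_seconds = icap_seconds
        self.alpha = alpha
        self.ordering_mode = ordering_mode
        self.max_restarts = max_restarts
        self.notch_hz = notch_hz
        self.groups = groups
        self.fs = fs
        self.random_state = random_state

    def _config(self) -> UARConfig:
        return UARConfig(
            Lw=self.Lw,
            d=self.d,
            T=self.T,
            min_run=self.min_run,
            n_detect=self.n_detect,
            at1_seconds=self.at1_seconds,
            at2_seconds=self.at2_seconds,
            icap_seconds=self.icap_seconds,
            alpha=self.alpha,
            ordering_mode=self.ordering_mode,
            max_restarts=self.max_restarts,
            notch_hz=self.notch_hz,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_samples, n_channels)")
        self._config().validate(self.fs)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_samples, n_channels)")
        cfg = self._config().validate(self.fs)
        data = X.T.copy()  # channels x samples
        if cfg.notch_hz is not None:
            data = notch_filter(Recording(data, fs=self.fs), cfg.notch_hz).data
        filtered, report, spans, portions = _run_pipeline(
            data, self.fs, cfg, self.groups
        )
        self.report_ = report
        self.at_spans_ = spans
        self.portions_ = portions
        return filtered.T

    def filter_recording(self, rec: Recording) -> tuple[Recording, FilterReport]:
        """Convenience wrapper operating on a :class:`Recording`."""
        self.fs = rec.fs
        out = self.fit(rec.data.T).transform(rec.data.T)
        return replace(rec, data=out.T, labels=list(rec.labels)), self.report_


def _run_pipeline(
    data: np.ndarray,
    fs: float,
    cfg: UARConfig,
    groups: list[list[int]] | None,
):
    n_ch, n_samples = data.shape
    spans, profile, t2 = _detect(data, fs, cfg, groups)
    portions = widen_and_layout(spans, cfg, fs, n_samples)
    report = FilterReport(threshold=cfg.T, t2=t2)
    working = data.copy()
    clean_mask = np.ones(n_samples, dtype=bool)
    for p in portions:
        clean_mask[p.art.start : p.art.end] = False
    for k, portion in enumerate(portions):
        seed = (cfg.seed + 7919 * k) % (2**31 - 1)
        try:
            ref, short = select_reference(portion, clean_mask, n_samples, cfg.Lw)
        except ReferenceUnavailableError as exc:
            msg = f"artefact at {tuple(portion.at)} skipped: {exc}"
            warnings.warn(msg, stacklevel=2)
            report.warnings.append(msg)
            report.records.append(
                ArtefactRecord(
                    portion=portion,
                    ref=None,
                    ref_short=False,
                    converged=False,
                    skipped=True,
                    skip_reason=str(exc),
                )
            )
            continue
        dec = run_fastica(
            working, portion.icap, seed=seed, max_restarts=cfg.max_restarts
        )
        order = order_components(dec, portion.art, cfg.ordering_mode)
        record = ArtefactRecord(
            portion=portion, ref=ref, ref_short=short, converged=dec.converged
        )
        for e in range(n_ch):
            filtered_art, trace = filter_electrode(
                working[e], e, portion.art, ref, dec, order, cfg.alpha
            )
            working[e, portion.art.start : portion.art.end] = filtered_art
            record.traces.append(trace)
        clean_mask[portion.art.start : portion.art.end] = True
        report.records.append(record)
    return working, report, spans, portions
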