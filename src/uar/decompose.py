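"""Local FastICA decomposition of the window around each artefact.

For an N-electrode recording, FastICA on the ICA window yields N
independent components with mixing matrix A (N x N) and unit-variance
sources S (N x samples), so that for every electrode E the windowed signal
is the channel mean plus the sum over components of the projection
A[E, c] * S[c, :].  The components are then ordered by how strongly their
projections influence the artefact span: descending peak absolute value
(default) or descending variance, maximised over electrodes.

FastICA is run with symmetric (parallel) orthogonalisation and the cube
nonlinearity, whitening to all N dimensions.  FastICA is somewhat unstable
(reruns can produce different components); that does not matter here
because the stopping test in the removal stage judges projections by their
effect, not their identity.  Non-converged runs are retried with fresh
seeds and the best attempt is kept, flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import DecompositionError, Span, ValidationError, validate_span


@dataclass
class ICADecomposition:
    """Mixing matrix and sources for one ICA window.

    ``A`` is electrodes x components, ``S`` components x window samples
    (unit variance rows); ``channel_means`` holds the per-electrode mean
    over the window so that ``channel_means[:, None] + A @ S`` reconstructs
    the windowed data.
    """

    A: np.ndarray
    S: np.ndarray
    channel_means: np.ndarray
    icap: Span
    converged: bool
    seed_used: int

    @property
    def n_components(self) -> int:
        return self.A.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.channel_means[:, None] + self.A @ self.S


@dataclass
class OrderedComponents:
    """Permutation of component indices, sorted by descending influence."""

    order: np.ndarray
    scores: np.ndarray
    mode: str


def run_fastica(
    data: np.ndarray,
    icap: Span,
    seed: int = 0,
    max_restarts: int = 3,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> ICADecomposition:
    """FastICA on ``data[:, icap]`` (channels x samples), N components.

    Retries with fresh seeds on non-convergence, keeping the first
    converged attempt; after ``max_restarts`` failures the last attempt is
    returned with ``converged=False``.
    """
    data = np.asarray(data, dtype=np.float64)
    validate_span(icap, data.shape[1])
    window = data[:, icap.start : icap.end]
    n_ch, n_samp = window.shape
    if n_samp < n_ch:
        raise ValidationError(
            f"ICA window of {n_samp} samples is shorter than {n_ch} channels"
        )
    if n_samp < 10 * n_ch:
        warnings.warn(
            f"ICA window has only {n_samp} samples for {n_ch} channels; "
            "component quality may be poor",
            stacklevel=2,
        )
    centered = window - window.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(centered) < n_ch:
        raise DecompositionError(
            "ICA window is rank deficient (e.g. duplicated or flat channels)"
        )
    attempt_seed = int(seed)
    last = None
    for attempt in range(max_restarts + 1):
        ica = FastICA(
            n_components=n_ch,
            algorithm="parallel",
            whiten="unit-variance",
            fun="cube",
            tol=tol,
            max_iter=max_iter,
            random_state=attempt_seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(window.T)  # (n_samp, n_comp)
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        dec = ICADecomposition(
            A=ica.mixing_.copy(),
            S=sources.T.copy(),
            channel_means=ica.mean_.copy(),
            icap=icap,
            converged=converged,
            seed_used=attempt_seed,
        )
        if converged:
            return dec
        last = dec
        attempt_seed = (attempt_seed + 1_000_003) % (2**31 - 1)
    return last


def project_component(
    dec: ICADecomposition,
    electrode: int,
    component: int,
    span: Span,
) -> np.ndarray:
    """One component's additive contribution to one electrode over ``span``.

    ``span`` is in recording coordinates and must lie inside the ICA
    window.  The projection is zero-mean by construction: channel means
    live in ``channel_means`` and are never subtracted from the recording.
    """
    if not dec.icap.contains(span):
        raise ValidationError(f"span {span} outside ICA window {dec.icap}")
    lo = span.start - dec.icap.start
    hi = span.end - dec.icap.start
    return dec.A[electrode, component] * dec.S[component, lo:hi]


def order_components(
    dec: ICADecomposition,
    art: Span,
    mode: str = "max_abs",
) -> OrderedComponents:
    """Sort components by descending influence on the artefact span.

    The score of a component is the maximum over electrodes of either the
    peak absolute value (``max_abs``) or the variance (``max_var``) of its
    projection restricted to ``art``.  Ties break by ascending component
    index.
    """
    if len(art) <= 0:
        raise ValidationError("empty artefact span")
    if not dec.icap.contains(art):
        raise ValidationError(f"artefact span {art} outside ICA window {dec.icap}")
    lo = art.start - dec.icap.start
    hi = art.end - dec.icap.start
    seg = dec.S[:, lo:hi]  # (n_comp, len(art))
    absA = np.abs(dec.A)  # (n_el, n_comp)
    if mode == "max_abs":
        # max_e max_t |A[e,c] S[c,t]| = (max_e |A[e,c]|) * (max_t |S[c,t]|)
        scores = absA.max(axis=0) * np.abs(seg).max(axis=1)
    elif mode == "max_var":
        # var of A[e,c] S[c,t] over t = A[e,c]^2 var(S[c, art])
        scores = (absA.max(axis=0) ** 2) * seg.var(axis=1)
    else:
        raise ValidationError(f"unknown ordering mode {mode!r}")
    order = np.lexsort((np.arange(scores.size), -scores))
    return OrderedComponents(order=order, scores=scores, mode=mode)
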