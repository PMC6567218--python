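"""Sliding-interval segmentation and AR(2) coefficient features.

Each interval of ``Lw`` samples (slid by ``d``) is summarised, per channel,
by the two coefficients of a second-order autoregression fitted to the
mean-centred window with Burg's method.  AR coefficients are scale- and
location-invariant, which is what makes a single detection threshold
portable across recordings and subjects.

The Burg recursion is vectorised over the stacked (interval, channel)
window array; a typical minute of 64-channel EEG yields tens of thousands
of windows, so the per-window estimators in general-purpose statistics
packages are the bottleneck here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .core import Recording, Span, ValidationError


@dataclass
class IntervalFeatures:
    """Per-interval AR(2) feature vectors.

    ``vectors`` is ``n_intervals x (2 * n_channels)``; row *i* concatenates
    the (a1, a2) pairs of every selected channel, in channel order, for the
    window starting at ``starts[i]``.
    """

    vectors: np.ndarray
    starts: np.ndarray
    Lw: int
    d: int

    @property
    def n_intervals(self) -> int:
        return self.vectors.shape[0]


def make_intervals(samples: int, Lw: int, d: int) -> list[Span]:
    """Sliding-window spans ``[i*d, i*d + Lw)`` covering ``samples``."""
    if samples < Lw:
        raise ValidationError(f"signal of {samples} samples is shorter than Lw={Lw}")
    if not (0 < d <= Lw):
        raise ValidationError("need 0 < d <= Lw")
    n = (samples - Lw) // d + 1
    return [Span(i * d, i * d + Lw) for i in range(n)]


def _burg2(windows: np.ndarray) -> np.ndarray:
    """Burg AR(2) over the last axis of a stack of windows.

    Returns an array ``windows.shape[:-1] + (2,)`` of (a1, a2) in the
    ``x_t = a1 x_{t-1} + a2 x_{t-2} + e_t`` convention.  Zero-variance
    windows map to (0, 0).
    """
    w = windows - windows.mean(axis=-1, keepdims=True)
    f = w[..., 1:]
    b = w[..., :-1]
    den1 = np.sum(f * f, -1) + np.sum(b * b, -1)
    safe1 = np.where(den1 > 0, den1, 1.0)
    k1 = np.where(den1 > 0, -2.0 * np.sum(f * b, -1) / safe1, 0.0)
    ff = f[..., 1:] + k1[..., None] * b[..., 1:]
    bb = b[..., :-1] + k1[..., None] * f[..., :-1]
    den2 = np.sum(ff * ff, -1) + np.sum(bb * bb, -1)
    safe2 = np.where(den2 > 0, den2, 1.0)
    k2 = np.where(den2 > 0, -2.0 * np.sum(ff * bb, -1) / safe2, 0.0)
    a1 = -(k1 + k2 * k1)
    a2 = -k2
    return np.stack([a1, a2], axis=-1)


def ar2_window(x: np.ndarray) -> tuple[float, float]:
    """AR(2) coefficients of one mean-centred window.

    A zero-variance (flat) window returns (0, 0) by convention so that
    flat-lined channels do not abort detection.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise ValidationError("ar2_window needs a 1-D window of length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValidationError("window contains non-finite samples")
    a = _burg2(x)
    return float(a[0]), float(a[1])


def feature_matrix(
    rec: Recording,
    channels: list[int] | None = None,
    Lw: int = 155,
    d: int = 32,
) -> IntervalFeatures:
    """AR(2) feature vectors for every sliding interval of a recording."""
    ext = ARFeatureExtractor(Lw=Lw, d=d, channels=channels)
    vectors = ext.fit_transform(rec.data.T)
    return IntervalFeatures(vectors=vectors, starts=ext.starts_, Lw=Lw, d=d)


class ARFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sliding-window AR(2) feature transformer.

    Parameters
    ----------
    Lw : int
        Window length in samples.
    d : int
        Sliding distance in samples.
    channels : list of int, optional
        Column subset to use; default all.

    ``transform`` takes ``X`` of shape ``(n_samples, n_channels)`` (time on
    the first axis, as in scikit-learn) and returns the
    ``(n_intervals, 2 * n_used_channels)`` feature matrix.  The window start
    indices of the last transform are stored in ``starts_``.
    """

    def __init__(self, Lw: int = 155, d: int = 32, channels: list[int] | None = None):
        self.Lw = Lw
        self.d = d
        self.channels = channels

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_samples, n_channels)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_samples, n_channels)")
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains non-finite samples")
        if self.Lw <= 2:
            raise ValidationError("Lw must exceed 2 so AR(2) is estimable")
        n_samples, n_ch = X.shape
        channels = list(range(n_ch)) if self.channels is None else list(self.channels)
        if not channels:
            raise ValidationError("empty channel subset")
        if any(c < 0 or c >= n_ch for c in channels):
            raise ValidationError(f"channel subset {channels} out of range 0..{n_ch - 1}")
        spans = make_intervals(n_samples, self.Lw, self.d)
        data = X.T[channels]  # (n_used, n_samples)
        # (n_used, n_positions, Lw) strided view, then subsample by d
        win = sliding_window_view(data, self.Lw, axis=-1)[:, :: self.d, :]
        coeffs = _burg2(win)  # (n_used, n_intervals, 2)
        # rows: per-channel (a1, a2) blocks concatenated in channel order
        vectors = np.transpose(coeffs, (1, 0, 2)).reshape(len(spans), -1)
        self.starts_ = np.array([s.start for s in spans], dtype=np.intp)
        self.n_intervals_ = len(spans)
        return vectors
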