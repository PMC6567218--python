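"""Domain types, recording I/O and sample-coordinate conventions.

A :class:`Recording` holds a multichannel EEG as a ``channels x samples``
float array in microvolts, together with the sampling rate and channel
labels.  All sample coordinates in this package are 0-based and half-open
(``[start, end)``); seconds are converted to samples with ``floor(t * fs)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal


class ValidationError(ValueError):
    """Invalid argument or inconsistent domain object."""


class FormatError(RuntimeError):
    """A file does not parse under the named standard."""


class EstimationError(RuntimeError):
    """A statistical fit failed (degenerate data or non-convergence)."""


class DecompositionError(RuntimeError):
    """ICA cannot be computed on the requested window."""


class ReferenceUnavailableError(RuntimeError):
    """No artefact-free reference span of sufficient length exists."""


class Span(NamedTuple):
    """Half-open sample interval ``[start, end)``, 0-based."""

    start: int
    end: int

    def __len__(self) -> int:  # length in samples
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlap(self, other: "Span") -> int:
        """Number of samples shared with *other*."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shift(self, offset: int) -> "Span":
        return Span(self.start + offset, self.end + offset)


def validate_span(span: Span, total: int | None = None) -> Span:
    if not (0 <= span.start < span.end):
        raise ValidationError(f"invalid span {span!r}: need 0 <= start < end")
    if total is not None and span.end > total:
        raise ValidationError(f"span {span!r} exceeds signal length {total}")
    return span


def seconds_to_samples(t: float, fs: float) -> int:
    """Convert a duration/instant in seconds to samples: ``floor(t * fs)``."""
    return int(math.floor(t * fs))


@dataclass
class Recording:
    """Multichannel signal: ``data`` is channels x samples, in microvolts."""

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("Recording data must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise ValidationError("Recording needs at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("Recording contains non-finite samples")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not self.labels:
            self.labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), labels=list(self.labels))


@dataclass
class UARConfig:
    """Tunable parameters of the detection/removal pipeline.

    Defaults follow the published operating point for 64-electrode EEG at
    256 Hz: sliding window ``Lw`` = 155 samples, slide ``d`` = 32 samples,
    detection threshold ``T`` = 1.33, ICA window 26 s, 1 s widening margins
    on each side of a detection, and a 1% significance level for the
    variance-equality stopping test.
    """

    Lw: int = 155
    d: int = 32
    n_detect: int | None = None  # channels used for detection (None = all)
    T: float = 1.33
    at1_seconds: float = 1.0
    at2_seconds: float = 1.0
    icap_seconds: float = 26.0
    alpha: float = 0.01
    ordering_mode: str = "max_abs"
    min_run: int = 1
    max_restarts: int = 3
    notch_hz: float | None = None
    seed: int = 0

    def validate(self, fs: float | None = None) -> "UARConfig":
        if self.Lw <= 2:
            raise ValidationError("Lw must exceed 2 so AR(2) is estimable")
        if not (0 < self.d <= self.Lw):
            raise ValidationError("need 0 < d <= Lw")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.ordering_mode not in ("max_abs", "max_var"):
            raise ValidationError(f"unknown ordering_mode {self.ordering_mode!r}")
        if self.min_run < 1:
            raise ValidationError("min_run must be >= 1")
        if self.at1_seconds < 0 or self.at2_seconds < 0:
            raise ValidationError("widening lengths must be non-negative")
        if fs is not None and seconds_to_samples(self.icap_seconds, fs) < self.Lw:
            raise ValidationError("icap_seconds * fs must be at least Lw")
        return self


# ---------------------------------------------------------------------------
# Recording I/O
#
# Formats: EDF/BDF (headers honoured; BDF read-only), CSV with one row per
# channel, and a raw .npy array with a JSON sidecar carrying fs and labels.
# Matrix formats carry no sampling rate: fs is a required argument there.
# ---------------------------------------------------------------------------

_FORMATS = ("edf", "bdf", "csv", "npy")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValidationError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise ValidationError(f"cannot infer format from {path.name!r}; pass format=")


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    labels: Sequence[str] | None = None,
) -> Recording:
    """Read a multichannel recording.

    EDF/BDF headers supply ``fs`` and labels; for CSV/npy they must come
    from the caller (``fs`` is mandatory there).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt in ("edf", "bdf"):
        return _read_edf_bdf(path, fmt)
    if fmt == "npy":
        return _read_npy(path, fs, labels)
    if fs is None:
        raise ValidationError(f"{fmt} files carry no sampling rate; fs is required")
    if fmt == "csv":
        try:
            data = np.loadtxt(path, delimiter=",", ndmin=2)
        except Exception as exc:  # empty / malformed file
            raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
        if data.size == 0:
            raise FormatError(f"{path} is empty")
        return Recording(data, fs=fs, labels=list(labels) if labels else [])
    raise ValidationError(f"unhandled format {fmt!r}")  # pragma: no cover


def _read_npy(path: Path, fs: float | None, labels: Sequence[str] | None) -> Recording:
    """Raw binary array with a JSON sidecar carrying fs and labels."""
    try:
        data = np.load(path)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as npy: {exc}") from exc
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
        if labels is None:
            labels = meta.get("labels")
        if fs is None and "fs" in meta:
            fs = float(meta["fs"])
    if fs is None:
        raise ValidationError("npy input needs fs (argument or sidecar)")
    return Recording(np.atleast_2d(data), fs=fs, labels=list(labels) if labels else [])


def _read_edf_bdf(path: Path, fmt: str) -> Recording:
    import mne  # deferred: mne import is heavy

    reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as {fmt.upper()}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne returns volts for EEG-dimensioned channels
    return Recording(data, fs=float(raw.info["sfreq"]), labels=list(raw.ch_names))


def write_recording(
    rec: Recording, path: str | Path, format: str | None = None
) -> None:
    """Write a recording; ``read_recording`` round-trips the result.

    CSV and npy are lossless for float64; EDF quantises to 16 bits over the
    per-channel physical range. BDF writing is not supported.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "bdf":
        raise ValidationError("BDF writing is not supported (read-only format)")
    if fmt == "csv":
        np.savetxt(path, rec.data, delimiter=",", fmt="%.17g")
    elif fmt == "npy":
        np.save(path, rec.data)
        side = path.with_suffix(path.suffix + ".json")
        side.write_text(json.dumps({"fs": rec.fs, "labels": rec.labels}))
    else:
        _write_edf(rec, path)


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _edf_num(value: float, width: int) -> bytes:
    """Format a number into an EDF ASCII field, keeping maximal precision."""
    for digits in range(width, 0, -1):
        s = (f"%.{digits}g" % value).replace("e+0", "e").replace("e-0", "e-")
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise FormatError(f"cannot encode {value} in {width} EDF header chars")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: one data record holding the whole signal, 16-bit.

    Physical min/max are written per channel, re-parsed from their own ASCII
    header fields before quantisation so the round-trip error is bounded by
    one quantisation step of the written range.
    """
    n_ch, n_samp = rec.data.shape
    dig_min, dig_max = -32768, 32767
    pmins, pmaxs = [], []
    for ch in rec.data:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:  # constant channel: widen artificially
            lo, hi = lo - 1.0, hi + 1.0
        pmins.append(_edf_num(lo, 8))
        pmaxs.append(_edf_num(hi, 8))
    header_bytes = 256 + 256 * n_ch
    duration = n_samp / rec.fs
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))  # patient id
        fh.write(_edf_field("Startdate X X X X", 80))  # recording id
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(header_bytes, 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(1, 8))  # one data record
        fh.write(_edf_num(duration, 8))
        fh.write(_edf_field(n_ch, 4))
        for lab in rec.labels:
            fh.write(_edf_field(lab, 16))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))  # transducer
        for _ in range(n_ch):
            fh.write(_edf_field("uV", 8))
        for b in pmins:
            fh.write(b)
        for b in pmaxs:
            fh.write(b)
        for _ in range(n_ch):
            fh.write(_edf_field(dig_min, 8))
        for _ in range(n_ch):
            fh.write(_edf_field(dig_max, 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_edf_field(n_samp, 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 32))
        for i, ch in enumerate(rec.data):
            lo = float(pmins[i].decode())
            hi = float(pmaxs[i].decode())
            scale = (hi - lo) / (dig_max - dig_min)
            dig = np.round((ch - lo) / scale + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes())


def notch_filter(rec: Recording, mains_hz: float, q: float = 35.0) -> Recording:
    """Suppress mains interference with a narrow band-stop (notch) filter.

    Zero-phase second-order IIR notch; attenuation at ``mains_hz`` exceeds
    20 dB while the passband outside a +/-2 Hz neighbourhood stays within
    about 1 dB.
    """
    if not (0 < mains_hz < rec.fs / 2):
        raise ValidationError(
            f"mains frequency {mains_hz} Hz must lie below Nyquist ({rec.fs / 2} Hz)"
        )
    b, a = signal.iirnotch(mains_hz, q, fs=rec.fs)
    data = signal.filtfilt(b, a, rec.data, axis=-1)
    return replace(rec, data=data, labels=list(rec.labels))
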