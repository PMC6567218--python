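"""Seeded generator of clean EEG background and contaminated test signals.

The background is a statistical stand-in for resting EEG: per-source 1/f
(pink) noise whose amplitude is slowly modulated by a positive envelope
(real EEG is burst-like rather than stationary Gaussian, and a purely
Gaussian background would also be a degenerate input for ICA), mixed
across channels by an exponential channel-distance correlation, plus a
shared 10 Hz oscillation.  Per-channel RMS lands in the 10-30 microvolt
range typical of scalp EEG.

Artefact templates: a raised-cosine pulse for blinks, a smoothed-plateau
pulse for eye movements, and band-pass filtered (20-60 Hz) noise for EMG
bursts, each projected over channels with an exponentially decaying
topography.  The contaminated signal is exactly clean + sum of projected
templates, so ground truth is available sample by sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import Recording, Span, ValidationError, seconds_to_samples


@dataclass
class ArtefactEvent:
    """One injected artefact: kind, sample span, amplitude, topography."""

    kind: str  # blink | eye_move | emg
    span: Span
    amplitude: float
    topography: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("blink", "eye_move", "emg"):
            raise ValidationError(f"unknown artefact kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be non-negative")
        self.topography = np.asarray(self.topography, dtype=np.float64)
        if not np.all(np.isfinite(self.topography)):
            raise ValidationError("topography weights must be finite")


@dataclass
class EventSpec:
    """Declarative artefact specification used by :class:`SynthScenario`."""

    kind: str
    onset_seconds: float  # relative to the end of the clean prefix
    duration_seconds: float
    amplitude: float
    focus_channel: int = 0
    decay: float = 0.03


@dataclass
class SynthScenario:
    """Parameters of one simulated contaminated recording."""

    n_channels: int = 64
    fs: float = 256.0
    duration_seconds: float = 60.0
    clean_prefix_seconds: float = 30.0
    events: list[EventSpec] = field(default_factory=list)
    background_rms: float = 15.0
    seed: int = 0

    def validate(self) -> "SynthScenario":
        if self.n_channels < 2:
            raise ValidationError("need at least 2 channels")
        if self.fs <= 120:
            raise ValidationError("fs must exceed 120 Hz so the EMG band fits")
        if self.duration_seconds <= 0 or self.clean_prefix_seconds < 0:
            raise ValidationError("durations must be positive")
        return self


def default_scenario(seed: int = 0) -> SynthScenario:
    """The standard test bed: 64 channels at 256 Hz, 60 s of signal after a
    30 s clean prefix, six artefacts (two blinks, two eye movements, two
    EMG bursts) with frontal/temporal topographies."""
    return SynthScenario(
        n_channels=64,
        fs=256.0,
        duration_seconds=60.0,
        clean_prefix_seconds=30.0,
        seed=seed,
        events=[
            EventSpec("blink", 4.0, 0.35, 150.0, focus_channel=0, decay=0.03),
            EventSpec("eye_move", 12.0, 1.2, 120.0, focus_channel=1, decay=0.03),
            EventSpec("emg", 21.0, 2.0, 70.0, focus_channel=40, decay=0.02),
            EventSpec("blink", 32.0, 0.35, 150.0, focus_channel=1, decay=0.03),
            EventSpec("eye_move", 40.0, 1.2, 120.0, focus_channel=0, decay=0.03),
            EventSpec("emg", 50.0, 2.0, 70.0, focus_channel=20, decay=0.02),
        ],
    )


def _pink(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """1/f-power noise, flat below 1 Hz, unit-variance rows."""
    n = shape[-1]
    w = rng.standard_normal(shape)
    spec = np.fft.rfft(w, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec *= 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def gen_background(
    n_channels: int,
    fs: float,
    duration: float,
    seed: int = 0,
    rms: float = 15.0,
) -> Recording:
    """Clean multichannel EEG background, deterministic given ``seed``.

    Spatially correlated, slow-envelope-modulated pink noise plus a shared
    10 Hz oscillation; per-channel RMS spread around ``rms`` within the
    10-30 microvolt range.
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = seconds_to_samples(duration, fs)
    pad = seconds_to_samples(2.0, fs)  # trimmed: keeps filter edge transients out
    x = _pink(rng, (n_channels, n + 2 * pad), fs)
    # slow positive envelope: burst-like amplitude modulation.  The cutoff is
    # well below 1/Lw-window rates so the envelope is nearly constant within
    # a detection window (AR features are scale-invariant, so slow amplitude
    # modulation does not masquerade as an artefact).
    sos = signal.butter(2, min(0.4, 0.45 * fs / 2), "low", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, rng.standard_normal((n_channels, n + 2 * pad)), axis=-1)
    sd = env.std(axis=-1, keepdims=True)
    env = 0.4 + np.abs(env) / np.where(sd > 0, sd, 1.0)
    x = (x * env)[:, pad : pad + n]
    # spatial correlation by channel-index distance
    idx = np.arange(n_channels)
    corr = np.exp(-np.abs(idx[:, None] - idx[None, :]) / 8.0)
    x = np.linalg.cholesky(corr) @ x
    # shared 10 Hz oscillation with per-channel gain and a common phase
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    gains = rng.uniform(0.2, 0.5, size=n_channels)
    x += gains[:, None] * np.sin(2 * np.pi * 10.0 * t + phase)[None, :]
    sd = x.std(axis=-1, keepdims=True)
    x = x / np.where(sd > 0, sd, 1.0)
    targets = rng.uniform(0.8 * rms, 1.3 * rms, size=(n_channels, 1))
    return Recording(x * targets, fs=fs)


def gen_emg(
    duration_s: float,
    fs: float,
    amplitude: float,
    seed: int = 0,
) -> np.ndarray:
    """EMG burst: white noise band-passed to 20-60 Hz, edge-tapered, with
    RMS scaled exactly to ``amplitude``."""
    if fs <= 120:
        raise ValidationError("fs must exceed 120 Hz for a 20-60 Hz band")
    if duration_s <= 0:
        raise ValidationError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = seconds_to_samples(duration_s, fs)
    sos = signal.butter(4, [20.0, 60.0], "bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    x *= signal.windows.tukey(n, alpha=0.2)
    r = np.sqrt(np.mean(x**2))
    if amplitude == 0 or r == 0:
        return np.zeros(n)
    return x * (amplitude / r)


def gen_blink(duration_s: float, fs: float, amplitude: float) -> np.ndarray:
    """Blink: smooth unimodal raised-cosine pulse, peak exactly at
    ``amplitude``, zero at both ends, symmetric about its midpoint."""
    if not (0.1 <= duration_s <= 1.0):
        raise ValidationError("blink duration must lie in [0.1, 1.0] s")
    n = seconds_to_samples(duration_s, fs)
    u = np.arange(n) / (n - 1)
    pulse = 0.5 * (1.0 - np.cos(2 * np.pi * u))
    return amplitude * pulse / pulse.max()


def gen_eye_move(
    duration_s: float,
    fs: float,
    amplitude: float,
    ramp_fraction: float = 0.7,
) -> np.ndarray:
    """Eye movement: smoothed-plateau pulse (raised-cosine ramps up to a
    sustained deflection and back), peak ``amplitude``."""
    if duration_s <= 0:
        raise ValidationError("duration must be positive")
    n = seconds_to_samples(duration_s, fs)
    return amplitude * signal.windows.tukey(n, alpha=ramp_fraction)


def frontal_topography(
    n_channels: int,
    focus_channel: int,
    decay: float,
) -> np.ndarray:
    """Exponentially decaying channel weights, 1 at the focus channel.

    Channel-index distance stands in for scalp distance; supply an
    explicit weight vector for realistic montages.
    """
    if not (0 <= focus_channel < n_channels):
        raise ValidationError(f"focus channel {focus_channel} out of range")
    if decay <= 0:
        raise ValidationError("decay must be positive")
    d = np.abs(np.arange(n_channels) - focus_channel)
    return np.exp(-decay * d)


_TEMPLATES = {
    "blink": lambda spec, fs, seed: gen_blink(spec.duration_seconds, fs, spec.amplitude),
    "eye_move": lambda spec, fs, seed: gen_eye_move(
        spec.duration_seconds, fs, spec.amplitude
    ),
    "emg": lambda spec, fs, seed: gen_emg(
        spec.duration_seconds, fs, spec.amplitude, seed=seed
    ),
}


def build_seeg(
    scenario: SynthScenario,
) -> tuple[Recording, Recording, list[ArtefactEvent]]:
    """Build (clean, contaminated, events) for a scenario.

    contaminated = clean + sum over events of topography (x) template, with
    exact additivity; the clean prefix carries no events.
    """
    scenario.validate()
    fs = scenario.fs
    total_s = scenario.clean_prefix_seconds + scenario.duration_seconds
    clean = gen_background(
        scenario.n_channels, fs, total_s, seed=scenario.seed, rms=scenario.background_rms
    )
    n_total = clean.n_samples
    prefix = seconds_to_samples(scenario.clean_prefix_seconds, fs)
    contaminated = clean.data.copy()
    events: list[ArtefactEvent] = []
    for i, spec in enumerate(scenario.events):
        if spec.kind not in _TEMPLATES:
            raise ValidationError(f"unknown artefact kind {spec.kind!r}")
        start = prefix + seconds_to_samples(spec.onset_seconds, fs)
        template = _TEMPLATES[spec.kind](spec, fs, scenario.seed * 1009 + i)
        span = Span(start, start + template.size)
        if span.start < prefix or span.end > n_total:
            raise ValidationError(
                f"event {i} ({spec.kind}) at {tuple(span)} outside the usable range"
            )
        topo = frontal_topography(scenario.n_channels, spec.focus_channel, spec.decay)
        events.append(
            ArtefactEvent(spec.kind, span, spec.amplitude, topo)
        )
        contaminated[:, span.start : span.end] += topo[:, None] * template[None, :]
    ordered = sorted(events, key=lambda e: e.span.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.span.start < a.span.end:
            raise ValidationError(f"events overlap: {tuple(a.span)} and {tuple(b.span)}")
    return clean, Recording(contaminated, fs=fs, labels=list(clean.labels)), events
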