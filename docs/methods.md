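# Methods

This note documents the models, parameters and numerical choices behind
the package, what the synthetic test bed does and does not emulate, and
the design decisions taken where the procedure left room.

## Coordinates and units

All sample coordinates are 0-based, half-open `[start, end)`. Seconds
convert to samples as `floor(t * fs)`. Signals are `channels x samples`
float64 arrays in microvolts; the scikit-learn estimators take the
transposed `(n_samples, n_channels)` orientation, as is conventional
there. Matrix file formats (CSV, npy) carry no sampling rate, so `fs`
must be supplied when reading them; EDF/BDF headers are honoured, and the
EDF physical dimension is assumed to be microvolts.

## Detection

Each sliding window of `Lw` samples (default 155, slide `d` = 32) is
summarised per channel by the two coefficients of a second-order
autoregression, `x_t = a1 x_{t-1} + a2 x_{t-2} + e_t`, estimated with
Burg's method on the mean-centred window. Burg is preferred for short
windows because it cannot produce the unstable estimates that
direct least squares can and has lower variance than Yule-Walker at this
length; the Yule-Walker solution of the sample autocovariances serves as
an independent oracle in the tests, together with the per-window Burg
implementation in statsmodels. The recursion is vectorised over all
(window, channel) pairs, since one minute of 64-channel EEG already
yields ~45,000 window fits. Zero-variance windows map to (0, 0) by
convention so a flat-lined channel degrades detection instead of aborting
it. Windows are mean-centred but not detrended further; AR coefficients
are invariant to amplitude scaling and offsets, which is what makes a
fixed threshold portable across recordings.

The detection statistic is the Euclidean distance of each window's
concatenated coefficient vector (channel blocks in recording order) to
the centroid of all windows. Distances are computed on raw coefficients,
not standardised ones: the coefficient scale is already dimensionless and
comparable across channels. The default threshold `T = 1.33` is the
extreme-tail onset for 64-electrode montages. Because the distance is a
norm over `2 x n_channels` coordinates, its scale grows with the montage;
smaller test montages in this repository use proportionally smaller
thresholds (0.55-0.7 for 8-16 channels). A GEV-quantile mode
(`threshold_mode="gev_quantile"`, default probability 0.90) fits the
distance sample by maximum likelihood and thresholds at the inverse CDF;
it is opt-in because "tail onset" has no unique operational definition.
The diagnostic threshold `T2` is the median of the tail beyond `T1`,
which balances the interval counts on either side to within one; it is
reported but never used for detection (detection always uses `T = T1`, so
borderline portions are probed and the stopping test decides).

Runs of consecutive supra-threshold windows (minimum length `min_run`,
default 1) map to the union of their windows — biased wide, consistent
with the widening philosophy below. Window unions of nearby runs can
overlap; overlapping or touching spans are merged into one portion.
Per-group detection (`detect_grouped`, `--group-size`) runs the same
procedure on channel subsets and fuses the span lists by plain union,
which restores sensitivity to artefacts confined to few channels.

## Geometry around an artefact

Each detected span `AT` is widened by `at1_seconds` before and
`at2_seconds` after (1 s each by default) into `ART`, the span actually
filtered, clipped to the recording. If the next detection starts inside
the trailing margin, the current `ART` is truncated exactly at that start
and the next `ART` begins there, so consecutive artefacts tile without
overlap. The ICA window `ICA_P` is the trailing `icap_seconds` (26 s)
ending with `ART`, clipped at the recording start and extended if `ART`
itself is longer. The reference `REF` is the most recent span of length
`len(ART)`, ending at or before `ART`, whose samples are all clean —
where "clean" means outside every not-yet-filtered `ART`; spans already
filtered count as clean history, which is what makes closely spaced
artefacts processable in order. If no full-length clean span exists, the
longest clean span ending at `ART` is used, flagged short, provided it
has at least `Lw` samples; otherwise the artefact is skipped with a
warning (a fully contaminated recording has no usable reference).

## Decomposition and ordering

FastICA: symmetric (parallel) orthogonalisation, cube nonlinearity,
whitening to all `N` dimensions with unit-variance sources, tolerance
1e-4, at most 500 iterations. Rank-deficient windows (duplicated or flat
channels) are rejected before the solver runs. FastICA restarts with a
fresh seed on non-convergence (default 3 restarts) and otherwise returns
the last attempt flagged `converged=False`; run-to-run instability of the
components is harmless here because the stopping test judges projections
by their effect on the residual, not by their identity. Channel means
over `ICA_P` are stored separately and never subtracted from the
recording, so filtering leaves the local baseline intact. Components are
ordered by descending influence over `ART`: the default score is the peak
absolute value of the projection, maximised over electrodes
(`max_abs`), with projection variance (`max_var`) as the alternative;
ties break by component index.

## Stopping rule

The two-sample F-test uses unbiased variances, `F = v1/v2` with
`(n1-1, n2-1)` degrees of freedom and two-sided p-value
`2 * min(P(F' <= F), P(F' >= F))`, rejecting at `alpha` (default 0.01).
Degenerate inputs follow the convention: zero variance on one side
rejects (F = +inf or 0), zero on both sides fails to reject with F = 1.
The per-electrode loop subtracts ordered projections from `ART`; it stops
at the first iteration where the residual variance is *below* the
reference variance *and* the test rejects. A preceding run of consecutive
non-rejections means the residual had already reached statistical
equality with clean background, so the output rolls back to the first
state of that run; the state is re-recorded whenever a new non-rejection
run begins. If all `N` components are exhausted without a stop, the
plateau state is returned when one was recorded and differs from the
original, otherwise the original `ART` is returned unchanged — this is
the path taken on false-positive detections, which is how the detector
can afford a permissive threshold. The reference variance is recomputed
per electrode and per artefact from the current (partially filtered)
signal.

Processing is strictly sequential in detection order, each artefact
decomposed on the partially filtered signal, and every sample outside all
`ART` spans is bit-identical in the output — both properties are asserted
in the tests.

## Synthetic test bed

The generator emulates the statistical features the pipeline depends on,
not scalp physics:

- **Background**: per-source 1/f-power noise (flat below 1 Hz), amplitude-
  modulated by a slow positive envelope (second-order low-pass at 0.4 Hz,
  floor 0.4), spatially mixed by an exponential channel-distance
  correlation (length 8 channels), plus a shared 10 Hz oscillation with
  per-channel gain; per-channel RMS drawn in 12-20 µV. The amplitude
  modulation matters twice: real EEG is burst-like rather than stationary
  Gaussian, and a strictly Gaussian background would make ICA ill-posed
  (FastICA cannot converge on it even in principle). Two seconds of
  padding are generated and trimmed on each side so filter edge
  transients never enter the signal.
- **Templates**: blink = raised-cosine pulse (0.1-1 s, peak = amplitude,
  zero endpoints); eye movement = smoothed-plateau pulse (raised-cosine
  ramps over 70% of the duration); EMG = white noise band-passed to
  20-60 Hz, edge-tapered, RMS scaled exactly to the requested amplitude.
- **Topography**: weight `exp(-decay * |channel - focus|)`, a stand-in
  for scalp distance; montage-accurate weight vectors can be supplied per
  event instead.
- **Standard scenario** (`default_scenario`): 64 channels, 256 Hz, 60 s
  of signal after a 30 s artefact-free prefix (so early artefacts have
  clean ICA and reference history), six events — two blinks (150 µV,
  0.35 s), two eye movements (120 µV, 1.2 s), two EMG bursts (70 µV RMS,
  2 s) — with frontal/temporal topographies (decay 0.02-0.03, so every
  channel carries a measurable share). Amplitudes sit 5-10x above the
  background RMS, the regime the detector is designed for.

Contamination is exactly additive (`contaminated = clean + injected`),
events may not overlap, and everything is deterministic given the
scenario seed. What passing tests on this bed demonstrate: correct
geometry, calibrated statistics, and that the subtract-until-equal-
variance loop recovers a known ground truth through a genuine ICA. What
they cannot demonstrate: performance under real head-volume conduction,
non-additive artefacts (electrode pops, drift), or montage-specific
topographies.

## Evaluation

`mse` is the plain mean squared difference of equal-length portions.
Detection precision/recall counts an event as hit when one predicted span
covers at least `min_overlap_fraction` (default 0.5) of it; with no
predictions, precision is reported as 1.0 with an explicit
`precision_defined=False` flag. The ICA-window sweep rebuilds the same
scenario per seed, filters with each window length, and reports the
whole-channel MSE against the clean signal; quality saturates once the
window comfortably exceeds the artefact span, and shrinks noticeably
below ~20 s at 64 channels, where the sample-per-component ratio
deteriorates.

## Problem sizes used in the checked properties

The acceptance-style tests scale the recordings to what their property
needs rather than always running the full scenario: stopping-test
calibration uses 20,000 pairs of 512 samples; preservation is checked on
ten seeded 16-channel recordings; end-to-end recovery and detection
recall run the full 64-channel standard scenario over five seeds; the
ICA-window trend uses 64 channels with a 28 s contaminated section and
three seeds. The 16-channel fixtures use `T = 0.7` per the
dimension-scaling argument above.

## Known limitations

- The fixed default threshold is calibrated for 64-electrode montages;
  other montages need the GEV-quantile mode or a hand-set threshold.
- The F-test assumes approximately normal, independent samples; EEG is
  autocorrelated, so the nominal level is approximate in practice (the
  calibration test uses white Gaussian pairs by design).
- Artefacts near the start of a recording with insufficient clean history
  are skipped, not filtered; prepending a clean portion is the intended
  operating procedure.
- Filtering quality depends on the number of electrodes: with few
  channels, ICA has too few components to isolate artefact sources
  cleanly.
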