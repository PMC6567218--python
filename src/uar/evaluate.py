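"""Evaluation metrics: mean squared error against ground truth, detection
precision/recall on injected events, and the ICA-window-length sweep."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import Recording, Span, UARConfig, ValidationError
from .synth import ArtefactEvent, SynthScenario, build_seeg


def mse(filtered: np.ndarray, reference: np.ndarray) -> float:
    """Mean of squared sample differences between two equal-length portions."""
    a = np.asarray(filtered, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    if a.shape != b.shape or a.size < 1:
        raise ValidationError(f"portions must match in length, got {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


@dataclass
class DetectionScores:
    precision: float
    recall: float
    n_predicted: int
    n_truth: int
    precision_defined: bool = True


def detection_scores(
    predicted: list[Span],
    truth: list[ArtefactEvent],
    min_overlap_fraction: float = 0.5,
) -> DetectionScores:
    """Event-level precision/recall.

    An event is hit when some predicted span overlaps at least
    ``min_overlap_fraction`` of it; a predicted span is a true positive
    when it hits some event.  With no predictions, precision is reported
    as 1.0 with ``precision_defined=False``.
    """
    if any(predicted[i].start > predicted[i + 1].start for i in range(len(predicted) - 1)):
        raise ValidationError("predicted spans must be sorted by start")
    hits = 0
    for ev in truth:
        need = min_overlap_fraction * len(ev.span)
        if any(p.overlap(ev.span) >= need for p in predicted):
            hits += 1
    tp_pred = sum(
        1
        for p in predicted
        if any(p.overlap(ev.span) >= min_overlap_fraction * len(ev.span) for ev in truth)
    )
    recall = hits / len(truth) if truth else 1.0
    if not predicted:
        return DetectionScores(1.0, recall, 0, len(truth), precision_defined=False)
    return DetectionScores(tp_pred / len(predicted), recall, len(predicted), len(truth))


def whole_channel_mse(filtered: Recording, clean: Recording) -> float:
    """MSE between two recordings over all samples, averaged over channels."""
    return mse(filtered.data, clean.data)


def icap_sweep(
    scenario: SynthScenario,
    icap_values: list[float],
    seeds: list[int],
    cfg: UARConfig | None = None,
) -> pd.DataFrame:
    """Filter the same simulated recording with different ICA-window sizes.

    For every (icap_seconds, seed) pair the scenario is rebuilt with that
    seed, filtered, and the whole-channel MSE against the clean signal is
    recorded.  Returns a tidy frame with columns ``icap_seconds``, ``seed``,
    ``mse``; aggregate with ``df.groupby("icap_seconds")["mse"].mean()``.
    """
    from .removal import uar_filter

    base = cfg or UARConfig()
    for icap in icap_values:
        if icap * scenario.fs < base.Lw:
            raise ValidationError(f"icap={icap}s is shorter than Lw at fs={scenario.fs}")
    rows = []
    for icap in icap_values:
        for seed in seeds:
            sc = replace(scenario, seed=seed)
            clean, contaminated, _ = build_seeg(sc)
            run_cfg = replace(base, icap_seconds=float(icap), seed=seed)
            filtered, _ = uar_filter(contaminated, run_cfg)
            rows.append(
                {"icap_seconds": float(icap), "seed": seed,
                 "mse": whole_channel_mse(filtered, clean)}
            )
    return pd.DataFrame(rows)
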