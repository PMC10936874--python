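"""Treated-water locomotion analysis and light/dark-cycle activity.

Fish traces are sampled at a fixed frame rate (0.1 s by default); per-frame
displacements below the noise threshold (0.1 mm) are treated as tracker
noise and zeroed before distances are summed. Treatment groups are compared
with one-tailed Student's t tests whose direction is declared a priori,
with Benjamini-Hochberg FDR correction across the declared pairs.

For light/dark experiments, the recording starts with an acclimation
period (15 min) followed by alternating light and dark epochs (3 cycles of
30 min light + 30 min dark); activity is the total filtered distance per
epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .arena import Track
from . import stats as assay_stats

__all__ = [
    "DEFAULT_NOISE_THRESHOLD_MM",
    "LightDarkDesign",
    "filter_noise",
    "total_distance",
    "compare_treatments",
    "epoch_activity",
]

DEFAULT_NOISE_THRESHOLD_MM = 0.1


@dataclass(frozen=True)
class LightDarkDesign:
    """Acclimation followed by alternating light/dark epochs."""

    acclimation: float = 900.0
    light_duration: float = 1800.0
    dark_duration: float = 1800.0
    n_cycles: int = 3
    first_epoch: str = "light"

    def __post_init__(self) -> None:
        if self.light_duration <= 0 or self.dark_duration <= 0:
            raise ValueError("epoch durations must be positive")
        if self.first_epoch not in ("light", "dark"):
            raise ValueError("first_epoch must be 'light' or 'dark'")

    def epochs(self) -> list[tuple[str, float, float]]:
        """(label, start, end) of each epoch, seconds from recording start."""
        order = ("light", "dark") if self.first_epoch == "light" else ("dark", "light")
        durations = {
            "light": self.light_duration,
            "dark": self.dark_duration,
        }
        out = []
        t = self.acclimation
        for _ in range(self.n_cycles):
            for label in order:
                out.append((label, t, t + durations[label]))
                t += durations[label]
        return out

    @classmethod
    def from_yaml(cls, path) -> "LightDarkDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def filter_noise(
    trace: Track, noise_threshold: float = DEFAULT_NOISE_THRESHOLD_MM
) -> np.ndarray:
    """Per-frame displacements with sub-threshold movement zeroed.

    A displacement strictly below ``noise_threshold`` mm is considered
    tracker noise and replaced by 0; a step of exactly the threshold is
    kept (the removal rule is a strict inequality).
    """
    if noise_threshold < 0:
        raise ValueError("noise_threshold must be non-negative")
    steps = trace.displacements()  # raises on <2 frames
    return np.where(steps < noise_threshold, 0.0, steps)


def total_distance(
    trace: Track, noise_threshold: float = DEFAULT_NOISE_THRESHOLD_MM
) -> float:
    """Total distance moved (mm) after noise filtering."""
    return float(filter_noise(trace, noise_threshold).sum())


def compare_treatments(
    distances: Mapping[str, Sequence[float]],
    alternatives: Sequence[tuple[str, str, str]],
    correction: str = "bh",
    welch: bool = False,
) -> pd.DataFrame:
    """One-tailed t tests between declared treatment pairs, FDR-corrected.

    ``alternatives`` is a sequence of (treatment_a, treatment_b, direction)
    where direction "greater" declares the a-priori alternative
    mean(a) > mean(b) (and "less" the reverse). Every tested pair must be
    declared — the direction is never inferred from the data. Adjusted
    p-values use Benjamini-Hochberg across the declared pairs.
    """
    if correction not in ("bh", "none"):
        raise ValueError("correction must be 'bh' or 'none'")
    if not alternatives:
        raise ValueError("declare at least one (pair, direction) to test")
    rows = []
    for a, b, direction in alternatives:
        if direction not in ("greater", "less"):
            raise ValueError(f"pair ({a}, {b}) lacks a declared direction")
        if a not in distances or b not in distances:
            raise ValueError(f"unknown treatment in pair ({a}, {b})")
        res = assay_stats.students_t(
            distances[a], distances[b], tails=1, alternative=direction,
            welch=welch, label_a=a, label_b=b,
        )
        rows.append(
            {
                "treatment_a": a,
                "treatment_b": b,
                "alternative": direction,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "mean_difference": res.mean_difference,
                "method": res.method,
            }
        )
    table = pd.DataFrame(rows)
    if correction == "bh":
        table["adjusted_p"] = assay_stats.bh_fdr(table["p_value"].to_numpy())
    else:
        table["adjusted_p"] = table["p_value"]
    return table


def epoch_activity(
    trace: Track,
    design: LightDarkDesign,
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD_MM,
    normalize_truncated: bool = False,
) -> pd.DataFrame:
    """Total filtered activity per light/dark epoch.

    Drops the acclimation period, partitions the remaining recording into
    the designed epochs, and sums filtered displacement per epoch. Epochs
    extending past the end of the recording are truncated with a warning;
    with ``normalize_truncated`` activity is reported per second of
    covered epoch time instead of as a raw total.
    """
    t_end = float(trace.times[-1])
    if t_end < design.acclimation:
        raise ValueError("trace is shorter than the acclimation period")
    steps = filter_noise(trace, noise_threshold)
    # Displacement i spans (times[i], times[i+1]]; attribute it to the epoch
    # containing the end of the step.
    step_t = trace.times[1:]
    rows = []
    for idx, (label, start, end) in enumerate(design.epochs()):
        if start >= t_end:
            warnings.warn(f"epoch {idx} ({label}) lies beyond the recording; dropped")
            continue
        covered_end = min(end, t_end)
        if covered_end < end:
            warnings.warn(f"epoch {idx} ({label}) truncated at {covered_end:.1f} s")
        mask = (step_t > start) & (step_t <= covered_end)
        activity = float(steps[mask].sum())
        covered = covered_end - start
        rows.append(
            {
                "epoch": idx,
                "condition": label,
                "start_s": start,
                "end_s": covered_end,
                "covered_s": covered,
                "activity_mm": activity / covered if normalize_truncated else activity,
            }
        )
    return pd.DataFrame(rows)
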