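"""Grid-based weighted proximity scoring of predator behavior.

At fixed intervals (every 10 s by default) the predator's position is
classified relative to the focal anemone and given a weight:

* 0.6 — touching the anemone (within ``touch_radius``),
* 0.3 — within a single grid cell (Chebyshev cell distance <= 1; the
  anemone's own cell counts when not touching),
* 0.1 — anywhere else.

The per-trial statistic is the arithmetic mean of the interval weights; a
high mean score means the predator spent its time close to the anemone,
i.e. the anemone defended itself poorly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaSpec, Track, cell_of
from . import stats as assay_stats

__all__ = [
    "WEIGHT_TOUCH",
    "WEIGHT_ADJACENT",
    "WEIGHT_DISTANT",
    "ScoreResult",
    "score_interval",
    "score_track",
    "compare_scores",
    "score_tracks_to_frame",
]

WEIGHT_TOUCH = 0.6
WEIGHT_ADJACENT = 0.3
WEIGHT_DISTANT = 0.1


@dataclass(frozen=True)
class ScoreResult:
    """Weighted proximity scores for one trial."""

    interval_scores: np.ndarray
    weights: tuple[float, float, float] = (WEIGHT_TOUCH, WEIGHT_ADJACENT, WEIGHT_DISTANT)

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.interval_scores))

    @property
    def counts(self) -> dict[str, int]:
        s = np.asarray(self.interval_scores)
        w_touch, w_adj, w_far = self.weights
        return {
            "touch": int(np.sum(s == w_touch)),
            "adjacent": int(np.sum(s == w_adj)),
            "distant": int(np.sum(s == w_far)),
        }

    @property
    def n_intervals(self) -> int:
        return int(len(self.interval_scores))


def score_interval(predator_pos: tuple[float, float], arena: ArenaSpec) -> float:
    """Weight for a single scored instant given the predator position."""
    if not arena.contains(predator_pos):
        raise ValueError(f"predator position {predator_pos} outside arena")
    ax, ay = arena.anemone_position
    dist = math.hypot(predator_pos[0] - ax, predator_pos[1] - ay)
    if dist <= arena.touch_radius:
        return WEIGHT_TOUCH
    prow, pcol = cell_of(predator_pos, arena)
    arow, acol = arena.anemone_cell
    if max(abs(prow - arow), abs(pcol - acol)) <= 1:
        return WEIGHT_ADJACENT
    return WEIGHT_DISTANT


def scoring_instants(arena: ArenaSpec) -> np.ndarray:
    """Scored instants t = k * scoring_interval, k = 1..floor(duration/interval).

    The release instant t=0 is excluded: the animal is placed into the
    arena at recording start.
    """
    n = int(math.floor(arena.duration / arena.scoring_interval + 1e-9))
    return arena.scoring_interval * np.arange(1, n + 1)


def score_track(track: Track, arena: ArenaSpec) -> ScoreResult:
    """Score a whole trial track at every scoring instant.

    Samples the position at the frame nearest each instant; instants past
    the end of the recording are dropped (a short recording is scored over
    what it covers). At least one instant must be covered.
    """
    instants = scoring_instants(arena)
    t_end = float(track.times[-1]) + track.frame_dt / 2 + 1e-9
    instants = instants[instants <= t_end]
    if instants.size == 0:
        raise ValueError("track does not cover a single scoring instant")
    scores = np.array(
        [score_interval(track.position_at(t), arena) for t in instants], dtype=float
    )
    return ScoreResult(interval_scores=scores)


def score_tracks_to_frame(
    results: Mapping[str, ScoreResult] | Sequence[tuple[str, ScoreResult]],
) -> pd.DataFrame:
    """Tidy per-trial table (trial, n_intervals, touch/adjacent/distant, mean_score)."""
    items = results.items() if isinstance(results, Mapping) else results
    rows = []
    for trial, res in items:
        counts = res.counts
        rows.append(
            {
                "trial": trial,
                "n_intervals": res.n_intervals,
                "n_touch": counts["touch"],
                "n_adjacent": counts["adjacent"],
                "n_distant": counts["distant"],
                "mean_score": res.mean_score,
            }
        )
    return pd.DataFrame(rows)


def compare_scores(
    groups: Mapping[str, Sequence[float]],
    design: str = "anova_tukey",
) -> pd.DataFrame:
    """Compare per-trial mean scores between lines/populations.

    ``design`` selects the test used in the corresponding assay: one-way
    ANOVA with Tukey HSD pairwise comparisons (multi-line experiments) or
    a two-tailed Student's t test (two-population comparisons). Returns a
    tidy table of pairwise p-values and 95% confidence intervals on the
    mean difference.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for label, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 trials")
    if design == "anova_tukey":
        return assay_stats.oneway_anova_tukey(groups)
    if design in ("t_two_tailed", "t"):
        rows = []
        labels = list(groups)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                res = assay_stats.students_t(groups[a], groups[b], tails=2)
                rows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "mean_difference": res.mean_difference,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "method": res.method,
                    }
                )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown design {design!r}")


def write_comparison(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")
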