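"""Shared statistics layer for the behavioral, qPCR, and fitness assays.

Implements the small set of procedures every assay in the pipeline needs:
one-way ANOVA with Tukey HSD pairwise comparisons, Student's t tests
(one/two-tailed, paired/unpaired, equal-variance by default with Welch
behind a flag), Benjamini-Hochberg FDR adjustment, and Gardner-Altman
style bootstrap estimation of a mean difference.

Degenerate inputs (zero variance) return typed flags rather than NaN so
that limit cases — e.g. two identical groups — stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "EstimationResult",
    "oneway_anova_tukey",
    "students_t",
    "bh_fdr",
    "bootstrap_mean_difference",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise comparison: statistic, p, and mean difference with 95% CI."""

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    mean_difference: float
    ci_low: float
    ci_high: float
    method: str
    adjusted_p: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.degenerate or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class EstimationResult:
    """Bootstrap estimation of a mean difference (Gardner-Altman style)."""

    mean_difference: float
    ci_low: float
    ci_high: float
    n_resamples: int
    ci_method: str
    seed: int
    bootstrap_distribution: np.ndarray = field(repr=False, default=None)


def _as_array(x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence of values")
    return arr


def _mean_diff_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Pooled-variance 95% CI on mean(x) - mean(y)."""
    nx, ny = len(x), len(y)
    diff = x.mean() - y.mean()
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1 / nx + 1 / ny))
    if se == 0:
        return diff, diff
    half = sps.t.ppf(1 - alpha / 2, df) * se
    return diff - half, diff + half


def oneway_anova_tukey(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """One-way ANOVA omnibus test plus all-pairs Tukey HSD.

    Returns a tidy table with one row per pair; the omnibus F statistic and
    p-value are repeated in ``anova_F`` / ``anova_p`` columns. Pairwise
    p-values come from the studentized-range distribution.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [_as_array(groups[g]) for g in labels]
    for lab, arr in zip(labels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")

    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        f_stat, f_p = 0.0, 1.0
        rows = []
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                rows.append(
                    {
                        "group_a": a,
                        "group_b": labels[j],
                        "statistic": 0.0,
                        "p_value": 1.0,
                        "mean_difference": 0.0,
                        "ci_low": 0.0,
                        "ci_high": 0.0,
                        "method": "tukey_hsd",
                        "anova_F": f_stat,
                        "anova_p": f_p,
                    }
                )
        return pd.DataFrame(rows)

    f_stat, f_p = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)
    ci = tukey.confidence_interval(confidence_level=0.95)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "statistic": float(tukey.statistic[i, j]),
                    "p_value": float(tukey.pvalue[i, j]),
                    "mean_difference": float(arrays[i].mean() - arrays[j].mean()),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "method": "tukey_hsd",
                    "anova_F": float(f_stat),
                    "anova_p": float(f_p),
                }
            )
    return pd.DataFrame(rows)


def students_t(
    x: Sequence[float],
    y: Sequence[float],
    tails: int = 2,
    paired: bool = False,
    alternative: str = "greater",
    welch: bool = False,
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Student's t test between two samples.

    ``tails=1`` gives a one-tailed test on the side declared by
    ``alternative`` ("greater": mean(x) > mean(y); "less": mean(x) <
    mean(y)); the direction is always an explicit argument, never inferred
    from the data. Equal-variance (classic Student) by default; ``welch``
    switches to the unequal-variance form.
    """
    xa, ya = _as_array(x), _as_array(y)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if tails == 1 and alternative not in ("greater", "less"):
        raise ValueError("one-tailed tests need alternative 'greater' or 'less'")

    if paired:
        if len(xa) != len(ya):
            raise ValueError("paired samples must have equal length")
        diffs = xa - ya
        mean_diff = float(diffs.mean())
        if np.allclose(diffs, diffs[0]):
            # Zero variance in the differences: exact outcome.
            p = 1.0 if mean_diff == 0 else 0.0
            if tails == 1 and mean_diff != 0:
                on_side = (mean_diff > 0) == (alternative == "greater")
                p = 0.0 if on_side else 1.0
            return ComparisonResult(
                label_a, label_b, float("inf") if mean_diff else 0.0, p,
                mean_diff, mean_diff, mean_diff,
                method="t_paired", degenerate=True,
            )
        alt = "two-sided" if tails == 2 else alternative
        res = sps.ttest_rel(xa, ya, alternative=alt)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        half = sps.t.ppf(0.975, len(diffs) - 1) * se
        return ComparisonResult(
            label_a, label_b, float(res.statistic), float(res.pvalue),
            mean_diff, mean_diff - half, mean_diff + half, method="t_paired",
        )

    mean_diff = float(xa.mean() - ya.mean())
    pooled_var = xa.var(ddof=1) + ya.var(ddof=1)
    if pooled_var == 0:
        p = 1.0 if mean_diff == 0 else 0.0
        if tails == 1 and mean_diff != 0:
            on_side = (mean_diff > 0) == (alternative == "greater")
            p = 0.0 if on_side else 1.0
        return ComparisonResult(
            label_a, label_b, float("inf") if mean_diff else 0.0, p,
            mean_diff, mean_diff, mean_diff,
            method="t_welch" if welch else "t_student", degenerate=True,
        )
    alt = "two-sided" if tails == 2 else alternative
    res = sps.ttest_ind(xa, ya, equal_var=not welch, alternative=alt)
    lo, hi = _mean_diff_ci(xa, ya)
    return ComparisonResult(
        label_a, label_b, float(res.statistic), float(res.pvalue),
        mean_diff, lo, hi, method="t_welch" if welch else "t_student",
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = _as_array(p_values)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def bootstrap_mean_difference(
    x: Sequence[float],
    y: Sequence[float],
    n_resamples: int = 5000,
    ci: str = "percentile",
    seed: int = 0,
) -> EstimationResult:
    """Bootstrap estimation of mean(x) - mean(y) with a 95% interval.

    The default mirrors estimation-statistics practice: 5000 resamples and
    a percentile interval ("bca" selects bias-corrected-and-accelerated).
    Resampling is independent within each group; the result is
    deterministic under ``seed``.
    """
    xa, ya = _as_array(x), _as_array(y)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if ci not in ("percentile", "bca"):
        raise ValueError("ci must be 'percentile' or 'bca'")
    rng = np.random.default_rng(seed)
    observed = float(xa.mean() - ya.mean())
    bx = rng.integers(0, len(xa), size=(n_resamples, len(xa)))
    by = rng.integers(0, len(ya), size=(n_resamples, len(ya)))
    dist = xa[bx].mean(axis=1) - ya[by].mean(axis=1)

    if np.allclose(dist, dist[0]):
        lo = hi = float(dist[0])
    elif ci == "percentile":
        lo, hi = np.percentile(dist, [2.5, 97.5])
    else:
        lo, hi = _bca_interval(xa, ya, dist, observed)
    return EstimationResult(
        mean_difference=observed,
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=int(n_resamples),
        ci_method=ci,
        seed=int(seed),
        bootstrap_distribution=dist,
    )


def _bca_interval(
    x: np.ndarray, y: np.ndarray, dist: np.ndarray, observed: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval via jackknife."""
    z0 = sps.norm.ppf(np.clip(np.mean(dist < observed), 1e-9, 1 - 1e-9))
    jack = []
    for i in range(len(x)):
        jack.append(np.delete(x, i).mean() - y.mean())
    for i in range(len(y)):
        jack.append(x.mean() - np.delete(y, i).mean())
    jack = np.asarray(jack)
    dev = jack.mean() - jack
    denom = 6.0 * (dev**2).sum() ** 1.5
    a = (dev**3).sum() / denom if denom > 0 else 0.0
    z = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = sps.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(dist, adj)
    return float(lo), float(hi)


def estimation_plot(result: EstimationResult, labels: tuple[str, str] = ("a", "b"), path=None):
    """Minimal Gardner-Altman panel: bootstrap distribution + 95% interval.

    matplotlib is imported lazily so analysis-only use never needs a
    display backend.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.hist(result.bootstrap_distribution, bins=50, color="0.7")
    ax.axvline(result.mean_difference, color="k", lw=1.5, label="mean difference")
    ax.axvline(result.ci_low, color="k", ls="--", lw=1)
    ax.axvline(result.ci_high, color="k", ls="--", lw=1)
    ax.set_xlabel(f"mean({labels[0]}) - mean({labels[1]})")
    ax.set_ylabel("bootstrap resamples")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
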