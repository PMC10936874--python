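"""ΔΔCt relative quantification and diploid gene copy-number estimation.

Replicate Ct values per (sample, gene) are averaged first, then differenced
against a reference gene:

    ΔCt = mean Ct(reference gene) - mean Ct(target gene)

so that higher target expression (lower Ct) gives a larger ΔCt. Relative
expression against a calibrator sample is 2^(ΔCt_sample - ΔCt_calibrator),
assuming amplification efficiency exactly 2 per cycle. Diploid copy number
uses the same arithmetic with a single-copy control gene as reference and a
reference sample of known copy number (1 by default).

"Undetected" (no amplification) is a typed state — an empty ``ct`` field on
disk, NaN in memory — never a large Ct placeholder: zero copies is a
legitimate biological outcome for the target gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as assay_stats

__all__ = [
    "CtPlate",
    "CopyNumberEstimate",
    "delta_ct",
    "relative_expression",
    "estimate_copy_number",
    "paired_delta_ct_test",
]


class UndetectedReferenceError(ValueError):
    """The reference gene failed to amplify — the assay is invalid."""


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    diploid_copies: float
    delta_ct: float | None
    delta_delta_ct: float | None
    flag: str  # "detected" | "undetected"

    @property
    def rounded_copies(self) -> int:
        """Integer display value, rounded half-up."""
        return int(math.floor(self.diploid_copies + 0.5))


@dataclass
class CtPlate:
    """Replicate Ct measurements plus reference designations.

    ``data`` columns: sample, gene, replicate, ct (float; NaN = undetected).
    ``reference_gene`` is the normalizer for the analysis at hand
    (expression: a stably expressed housekeeping gene; copy number: a
    single-copy control gene). ``reference_sample`` with
    ``known_copy_number`` anchors copy-number estimates.
    """

    data: pd.DataFrame
    reference_gene: str
    reference_sample: str | None = None
    known_copy_number: float = 1.0

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        self.data = self.data.copy()
        self.data["ct"] = pd.to_numeric(self.data["ct"], errors="coerce")
        if self.reference_gene not in set(self.data["gene"]):
            raise ValueError(f"reference gene {self.reference_gene!r} not on plate")
        if (
            self.reference_sample is not None
            and self.reference_sample not in set(self.data["sample"])
        ):
            raise ValueError(f"reference sample {self.reference_sample!r} not on plate")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene"]))

    def replicate_cts(self, sample: str, gene: str) -> np.ndarray:
        sel = self.data[(self.data["sample"] == sample) & (self.data["gene"] == gene)]
        if sel.empty:
            raise KeyError(f"no wells for sample {sample!r}, gene {gene!r}")
        return sel["ct"].to_numpy(float)

    def mean_ct(self, sample: str, gene: str) -> float:
        """Mean replicate Ct; NaN if the gene is undetected in the sample."""
        cts = self.replicate_cts(sample, gene)
        detected = cts[np.isfinite(cts)]
        if detected.size == 0:
            return float("nan")
        return float(detected.mean())

    def is_detected(self, sample: str, gene: str) -> bool:
        return bool(np.isfinite(self.replicate_cts(sample, gene)).any())

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        reference_gene: str | None = None,
        reference_sample: str | None = None,
        known_copy_number: float = 1.0,
    ) -> "CtPlate":
        """Read a plate CSV (sample, gene, replicate, ct[, is_reference_gene,
        is_reference_sample]); empty ct means undetected. Explicit arguments
        override flag columns."""
        df = pd.read_csv(path)
        if reference_gene is None and "is_reference_gene" in df.columns:
            flagged = df.loc[df["is_reference_gene"].astype(bool), "gene"].unique()
            if len(flagged) == 1:
                reference_gene = str(flagged[0])
        if reference_sample is None and "is_reference_sample" in df.columns:
            flagged = df.loc[df["is_reference_sample"].astype(bool), "sample"].unique()
            if len(flagged) == 1:
                reference_sample = str(flagged[0])
        if reference_gene is None:
            raise ValueError("reference gene neither flagged in file nor supplied")
        return cls(
            data=df[["sample", "gene", "replicate", "ct"]],
            reference_gene=reference_gene,
            reference_sample=reference_sample,
            known_copy_number=known_copy_number,
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.data.copy()
        df["is_reference_gene"] = df["gene"] == self.reference_gene
        df["is_reference_sample"] = (
            df["sample"] == self.reference_sample if self.reference_sample else False
        )
        df.to_csv(path, index=False, float_format="%.6f")


def delta_ct(plate: CtPlate, sample: str, target_gene: str) -> float:
    """ΔCt = mean Ct(reference gene) - mean Ct(target gene) for one sample.

    Returns NaN when the target gene is undetected (the flag propagates to
    downstream quantities); an undetected reference gene raises, because a
    plate with no reference amplification cannot be normalized.
    """
    if not plate.is_detected(sample, plate.reference_gene):
        raise UndetectedReferenceError(
            f"reference gene {plate.reference_gene!r} undetected in sample {sample!r}"
        )
    if not plate.is_detected(sample, target_gene):
        return float("nan")
    return plate.mean_ct(sample, plate.reference_gene) - plate.mean_ct(sample, target_gene)


def relative_expression(
    plate: CtPlate, sample: str, calibrator_sample: str, target_gene: str
) -> float:
    """Fold change of ``target_gene`` in ``sample`` relative to the calibrator.

    2^(ΔCt_sample - ΔCt_calibrator); the calibrator itself maps to 1.
    Undetected target in the sample gives 0 (no expression); undetected in
    the calibrator makes the ratio undefined (NaN).
    """
    d_cal = delta_ct(plate, calibrator_sample, target_gene)
    if math.isnan(d_cal):
        return float("nan")
    d_s = delta_ct(plate, sample, target_gene)
    if math.isnan(d_s):
        return 0.0
    return float(2.0 ** (d_s - d_cal))


def estimate_copy_number(
    plate: CtPlate, sample: str, target_gene: str = "Nv1"
) -> CopyNumberEstimate:
    """Diploid copy number of ``target_gene`` by ΔΔCt against the plate's
    single-copy control gene and reference sample of known copy number.

    copies = known_copy_number * 2^(ΔCt_sample - ΔCt_reference_sample).
    An undetected target maps to 0 copies with an "undetected" flag.
    """
    if plate.reference_sample is None:
        raise ValueError("plate has no designated reference sample")
    d_ref = delta_ct(plate, plate.reference_sample, target_gene)
    if math.isnan(d_ref):
        raise UndetectedReferenceError(
            f"target undetected in reference sample {plate.reference_sample!r}"
        )
    d_s = delta_ct(plate, sample, target_gene)
    if math.isnan(d_s):
        return CopyNumberEstimate(sample, 0.0, None, None, flag="undetected")
    ddct = d_s - d_ref
    copies = plate.known_copy_number * 2.0**ddct
    return CopyNumberEstimate(sample, float(copies), float(d_s), float(ddct), flag="detected")


def paired_delta_ct_test(
    plate: CtPlate,
    group_a_samples: Sequence[str],
    group_b_samples: Sequence[str],
    target_gene: str,
) -> dict:
    """Paired two-tailed Student's t test on ΔCt values between two groups.

    Samples are paired by position (replicate i of group a with replicate i
    of group b). Reports the t statistic and p-value on the ΔCt scale, the
    mean ΔΔCt, and the implied fold change 2^(mean ΔΔCt).
    """
    if len(group_a_samples) != len(group_b_samples):
        raise ValueError("paired groups must have equal length")
    if len(group_a_samples) < 2:
        raise ValueError("need at least 2 pairs")
    da = np.array([delta_ct(plate, s, target_gene) for s in group_a_samples])
    db = np.array([delta_ct(plate, s, target_gene) for s in group_b_samples])
    if np.isnan(da).any() or np.isnan(db).any():
        raise ValueError("undetected target in a tested sample; pairing undefined")
    res = assay_stats.students_t(da, db, tails=2, paired=True)
    mean_ddct = float(np.mean(da - db))
    return {
        "n_pairs": len(da),
        "t_statistic": res.statistic,
        "p_value": res.p_value,
        "mean_delta_delta_ct": mean_ddct,
        "implied_fold_change": float(2.0**mean_ddct),
        "degenerate": res.degenerate,
    }


def copy_number_table(
    plate: CtPlate, target_gene: str = "Nv1", samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Copy-number estimates for every (or the given) sample, tidy."""
    rows = []
    for s in samples if samples is not None else plate.samples:
        est = estimate_copy_number(plate, s, target_gene)
        rows.append(
            {
                "sample": est.sample_id,
                "diploid_copies": est.diploid_copies,
                "rounded_copies": est.rounded_copies,
                "delta_ct": est.delta_ct,
                "delta_delta_ct": est.delta_delta_ct,
                "flag": est.flag,
            }
        )
    return pd.DataFrame(rows)
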