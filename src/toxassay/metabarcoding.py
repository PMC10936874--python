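"""CO1 gut-content metabarcoding: merge, dereplicate, assign, summarize.

The diet of a generalist marine invertebrate is profiled by amplicon
sequencing of the mitochondrial CO1 locus from gut contents. This module
reimplements the bespoke tail of that pipeline:

* :func:`merge_pairs` — join overlapping read pairs into full amplicons,
* :func:`dereplicate` — exact-duplicate counting,
* :func:`assign_taxon` — top-hit assignment against a taxon-annotated CO1
  reference database (k-mer-seeded, ungapped semi-global scan; a
  precomputed BLAST outfmt-6 hit table can substitute for the internal
  search with identical top-hit logic),
* :func:`summarize_diet` — per-site/per-month abundance, per-individual
  shares, zero-sequence individuals, and phylum (arthropod) fractions.

Reference FASTA headers carry the taxon and its lineage as
``>taxonID|k__...;p__...;...`` (ranks down to phylum at minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "DBEntry",
    "ReferenceDB",
    "AmpliconSet",
    "Assignment",
    "MergeResult",
    "merge_pairs",
    "dereplicate",
    "assign_taxon",
    "assign_all",
    "load_blast_hits",
    "summarize_diet",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_SEED_K = 12


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DBEntry:
    taxon_id: str
    lineage: str
    sequence: str

    def rank(self, prefix: str) -> str | None:
        """Lineage name at a rank given its prefix, e.g. 'p' -> phylum."""
        for part in self.lineage.split(";"):
            part = part.strip()
            if part.startswith(prefix + "__"):
                return part[len(prefix) + 2 :] or None
        return None

    @property
    def phylum(self) -> str | None:
        return self.rank("p")


class ReferenceDB:
    """Taxon-annotated CO1 reference sequences with a k-mer seed index."""

    def __init__(self, entries: Sequence[DBEntry], seed_k: int = DEFAULT_SEED_K):
        ids = [e.taxon_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("taxon_ids must be unique")
        for e in entries:
            if not e.sequence:
                raise ValueError(f"empty sequence for taxon {e.taxon_id!r}")
        self.entries = list(entries)
        self.seed_k = int(seed_k)
        self._encoded: dict[int, np.ndarray] = {}
        self._index: dict[str, set[int]] = {}
        for i, e in enumerate(self.entries):
            seq = e.sequence.upper()
            for pos in range(len(seq) - self.seed_k + 1):
                self._index.setdefault(seq[pos : pos + self.seed_k], set()).add(i)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, taxon_id: str) -> DBEntry:
        for e in self.entries:
            if e.taxon_id == taxon_id:
                return e
        raise KeyError(taxon_id)

    def encoded(self, index: int) -> np.ndarray:
        """Integer-coded reference sequence (cached; ambiguity code 5)."""
        if index not in self._encoded:
            self._encoded[index] = _encode(self.entries[index].sequence, ambiguous_code=5)
        return self._encoded[index]

    def candidate_indices(self, sequence: str) -> set[int]:
        """Indices of references sharing at least one seed k-mer with the read."""
        seq = sequence.upper()
        hits: set[int] = set()
        for pos in range(len(seq) - self.seed_k + 1):
            hits |= self._index.get(seq[pos : pos + self.seed_k], set())
        return hits

    @classmethod
    def from_fasta(cls, path: str | Path, seed_k: int = DEFAULT_SEED_K) -> "ReferenceDB":
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.description
            taxon_id, _, lineage = header.partition("|")
            entries.append(DBEntry(taxon_id.strip(), lineage.strip(), str(rec.seq).upper()))
        return cls(entries, seed_k=seed_k)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.taxon_id}|{e.lineage}\n{e.sequence}\n")


@dataclass(frozen=True)
class MergeResult:
    merged: str | None
    overlap: int
    mismatches: int

    @property
    def status(self) -> str:
        return "merged" if self.merged is not None else "unmerged"


def merge_pairs(
    r1: str,
    r2: str,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.05,
) -> MergeResult:
    """Join a read pair into one amplicon by their 3' overlap.

    ``r2`` is supplied in sequencing orientation and reverse-complemented
    internally. All overlap lengths >= ``min_overlap`` are scanned and the
    longest overlap whose mismatch rate is <= ``max_mismatch_rate`` is
    accepted; at disagreeing overlap positions the consensus takes r1's
    base. Failure to find a qualifying overlap returns an unmerged result,
    never an exception.
    """
    r1 = r1.upper()
    r2rc = reverse_complement(r2.upper())
    max_ov = min(len(r1), len(r2rc))
    for ov in range(max_ov, min_overlap - 1, -1):
        tail = r1[-ov:]
        head = r2rc[:ov]
        mism = sum(a != b for a, b in zip(tail, head))
        if mism / ov <= max_mismatch_rate:
            return MergeResult(merged=r1 + r2rc[ov:], overlap=ov, mismatches=mism)
    return MergeResult(merged=None, overlap=0, mismatches=0)


@dataclass(frozen=True)
class AmpliconSet:
    """Dereplicated sequences with counts, plus optional provenance.

    ``table`` columns: sequence, count — ordered by count descending then
    sequence lexicographic, so output is deterministic. ``provenance``
    optionally records (site, month, individual_id) for the read group the
    set came from.
    """

    table: pd.DataFrame
    provenance: tuple[str, str, str] | None = None

    @property
    def total_reads(self) -> int:
        return int(self.table["count"].sum()) if len(self.table) else 0

    def __len__(self) -> int:
        return len(self.table)


def dereplicate(
    reads: Iterable[str], provenance: tuple[str, str, str] | None = None
) -> AmpliconSet:
    """Exact-string dereplication with duplicate counting."""
    counts: dict[str, int] = {}
    for seq in reads:
        s = str(seq).upper()
        counts[s] = counts.get(s, 0) + 1
    if not counts:
        return AmpliconSet(pd.DataFrame(columns=["sequence", "count"]), provenance)
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(items, columns=["sequence", "count"])
    return AmpliconSet(table=table, provenance=provenance)


@dataclass(frozen=True)
class Assignment:
    sequence: str
    taxon_id: str | None
    identity: float
    aligned_length: int
    strand: str = "+"
    reason: str | None = None

    @property
    def assigned(self) -> bool:
        return self.taxon_id is not None


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str, ambiguous_code: int = 4) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (incl. N) -> ``ambiguous_code``.

    Reads use code 4 and references code 5 for ambiguity characters, so an
    N never matches anything — not even another N (conservative identity).
    """
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    arr = np.full(len(seq), ambiguous_code, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        arr[raw == ord(base)] = code
    return arr


def _best_ungapped(read_arr: np.ndarray, ref_arr: np.ndarray) -> tuple[int, int]:
    """Best (matches, aligned_length) sliding the shorter sequence fully
    inside the longer one (ungapped semi-global containment)."""
    short, long_ = (read_arr, ref_arr) if len(read_arr) <= len(ref_arr) else (ref_arr, read_arr)
    m, L = len(short), len(long_)
    windows = np.lib.stride_tricks.sliding_window_view(long_, m)
    matches = (windows == short).sum(axis=1)
    return int(matches.max()), m


def _scan_entry(read_f: np.ndarray, read_r: np.ndarray, ref: np.ndarray):
    mf, length = _best_ungapped(read_f, ref)
    mr, _ = _best_ungapped(read_r, ref)
    if mr > mf:
        return mr, length, "-"
    return mf, length, "+"


def assign_taxon(
    sequence: str,
    db: ReferenceDB,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    exhaustive: bool = False,
) -> Assignment:
    """Top-hit taxonomic assignment of one amplicon against the database.

    Candidate references are gathered by shared seed k-mers and each is
    scored by the best ungapped semi-global placement (Hamming identity
    over the contained length; N never matches). Both strands are tried and
    the better one wins. The top hit is the highest identity, ties broken
    by longer aligned length, then lexicographic taxon_id. Identity below
    ``min_identity`` (percent) leaves the read unassigned; 0 retains every
    top hit. ``exhaustive`` skips seeding and scans the whole database
    (the seed index is purely a performance device).
    """
    seq = str(sequence).upper()
    if len(seq) < db.seed_k:
        return Assignment(seq, None, 0.0, 0, reason="shorter than seed k-mer")
    rc = reverse_complement(seq)
    if exhaustive:
        candidates = set(range(len(db.entries)))
    else:
        candidates = db.candidate_indices(seq) | db.candidate_indices(rc)
        if not candidates:
            candidates = set(range(len(db.entries)))  # conservative fallback
    read_f = _encode(seq)
    read_r = _encode(rc)
    best: tuple[float, int, str, str] | None = None  # (identity, length, taxon, strand)
    for i in sorted(candidates):
        entry = db.entries[i]
        matches, length, strand = _scan_entry(read_f, read_r, db.encoded(i))
        identity = 100.0 * matches / length
        key = (identity, length)
        if (
            best is None
            or key > (best[0], best[1])
            or (key == (best[0], best[1]) and entry.taxon_id < best[2])
        ):
            best = (identity, length, entry.taxon_id, strand)
    assert best is not None
    identity, length, taxon, strand = best
    if identity < min_identity:
        return Assignment(seq, None, identity, length, strand, reason="below min_identity")
    return Assignment(seq, taxon, identity, length, strand)


def assign_all(
    amplicons: AmpliconSet,
    db: ReferenceDB,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> pd.DataFrame:
    """Assign every dereplicated sequence; returns the set's table with
    taxon, identity, and aligned_length columns appended."""
    out = amplicons.table.copy()
    results = [assign_taxon(s, db, min_identity=min_identity) for s in out["sequence"]]
    out["taxon"] = [r.taxon_id if r.assigned else "unassigned" for r in results]
    out["identity"] = [r.identity for r in results]
    out["aligned_length"] = [r.aligned_length for r in results]
    return out


def load_blast_hits(
    path: str | Path, min_identity: float = DEFAULT_MIN_IDENTITY
) -> pd.DataFrame:
    """Top hit per query from a BLAST outfmt-6 tabular file.

    Columns follow the standard 12-field layout (qseqid sseqid pident
    length mismatch gapopen qstart qend sstart send evalue bitscore). The
    top hit per query is the highest pident, ties broken by longer aligned
    length then lexicographic sseqid — the same logic as the internal
    classifier. Hits below ``min_identity`` leave the query unassigned.
    """
    names = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    df = df.sort_values(
        ["qseqid", "pident", "length", "sseqid"],
        ascending=[True, False, False, True],
    )
    top = df.groupby("qseqid", sort=True).first().reset_index()
    top["taxon"] = np.where(top["pident"] >= min_identity, top["sseqid"], "unassigned")
    return top[["qseqid", "taxon", "pident", "length"]].rename(
        columns={"pident": "identity", "length": "aligned_length"}
    )


def summarize_diet(
    assigned: pd.DataFrame,
    db: ReferenceDB | None = None,
    exclude_taxa: Sequence[str] = (),
    focal_phylum: str = "Arthropoda",
) -> dict[str, pd.DataFrame]:
    """Diet summaries across sites, months, and individuals.

    ``assigned`` is a tidy table with columns site, month, individual,
    taxon ("unassigned" allowed), count. A reference database adds phylum
    labels for the phylum-level tables. ``exclude_taxa`` drops hits to the
    listed taxa (e.g. host self-hits) before summarizing; nothing is
    excluded by default.

    Returns tables:

    * ``per_taxon`` — reads per (site, month, taxon),
    * ``per_phylum`` — reads and fraction per (site, month, phylum),
    * ``per_individual`` — assigned totals and each individual's share of
      its (site, month) total,
    * ``site_summary`` — per (site, month): totals, individuals lacking
      any assigned sequence, the maximum individual share, and the focal
      phylum's read fraction.
    """
    required = {"site", "month", "individual", "taxon", "count"}
    missing = required - set(assigned.columns)
    if missing:
        raise ValueError(f"assigned table missing columns: {sorted(missing)}")
    df = assigned.copy()
    if exclude_taxa:
        df = df[~df["taxon"].isin(set(exclude_taxa))]

    assigned_only = df[df["taxon"] != "unassigned"]
    per_taxon = (
        assigned_only.groupby(["site", "month", "taxon"], as_index=False)["count"]
        .sum()
        .sort_values(["site", "month", "count", "taxon"], ascending=[True, True, False, True])
        .reset_index(drop=True)
    )

    if db is not None:
        phylum_of = {e.taxon_id: (e.phylum or "unknown") for e in db}
        assigned_only = assigned_only.assign(
            phylum=assigned_only["taxon"].map(lambda t: phylum_of.get(t, "unknown"))
        )
    else:
        assigned_only = assigned_only.assign(phylum="unknown")
    per_phylum = (
        assigned_only.groupby(["site", "month", "phylum"], as_index=False)["count"].sum()
    )
    totals = per_phylum.groupby(["site", "month"])["count"].transform("sum")
    per_phylum["fraction"] = np.where(totals > 0, per_phylum["count"] / totals, 0.0)
    per_phylum = per_phylum.sort_values(["site", "month", "phylum"]).reset_index(drop=True)

    # Per-individual assigned totals; individuals with only unassigned (or
    # no) reads still appear, with total 0.
    ind_all = df.groupby(["site", "month", "individual"], as_index=False)["count"].sum(
        numeric_only=True
    )[["site", "month", "individual"]]
    ind_assigned = assigned_only.groupby(
        ["site", "month", "individual"], as_index=False
    )["count"].sum()
    per_individual = ind_all.merge(
        ind_assigned, on=["site", "month", "individual"], how="left"
    ).fillna({"count": 0})
    per_individual["count"] = per_individual["count"].astype(int)
    site_totals = per_individual.groupby(["site", "month"])["count"].transform("sum")
    per_individual["share"] = np.where(
        site_totals > 0, per_individual["count"] / site_totals, 0.0
    )
    per_individual = per_individual.sort_values(
        ["site", "month", "individual"]
    ).reset_index(drop=True)

    rows = []
    for (site, month), grp in per_individual.groupby(["site", "month"]):
        total = int(grp["count"].sum())
        focal = per_phylum[
            (per_phylum["site"] == site)
            & (per_phylum["month"] == month)
            & (per_phylum["phylum"] == focal_phylum)
        ]
        focal_fraction = float(focal["fraction"].iloc[0]) if len(focal) else 0.0
        rows.append(
            {
                "site": site,
                "month": month,
                "n_individuals": int(len(grp)),
                "total_reads": total,
                "zero_sequence_individuals": int((grp["count"] == 0).sum()),
                "max_individual_share": float(grp["share"].max()) if total else 0.0,
                f"{focal_phylum.lower()}_fraction": focal_fraction,
            }
        )
    site_summary = pd.DataFrame(rows).sort_values(["site", "month"]).reset_index(drop=True)
    return {
        "per_taxon": per_taxon,
        "per_phylum": per_phylum,
        "per_individual": per_individual,
        "site_summary": site_summary,
    }


def write_fasta(sequences: Mapping[str, str] | Sequence[tuple[str, str]], path: str | Path):
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
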