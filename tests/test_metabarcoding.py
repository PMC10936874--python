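import numpy as np
import pandas as pd
import pytest

from toxassay.metabarcoding import (
    ReferenceDB,
    assign_all,
    assign_taxon,
    dereplicate,
    load_blast_hits,
    merge_pairs,
    read_fasta,
    reverse_complement,
    summarize_diet,
    write_fasta,
)
from toxassay.simulate import CommunitySimParams, simulate_amplicons

from conftest import random_reference_db


def hamming_oracle(read: str, db: ReferenceDB) -> tuple[str, float, int]:
    """Exhaustive ungapped scan over all offsets of all references, both
    strands; identical scoring and tie-break rules, written independently.

    N (or any non-ACGT character) matches nothing, including another N.
    """
    def matches_at(r: str, ref: str, off: int) -> int:
        return sum(
            1
            for a, b in zip(r, ref[off : off + len(r)])
            if a == b and a in "ACGT"
        )

    best = None  # (identity, length, taxon)
    for entry in db:
        ref = entry.sequence
        for r in (read, reverse_complement(read)):
            short, long_ = (r, ref) if len(r) <= len(ref) else (ref, r)
            length = len(short)
            top = max(
                matches_at(short, long_, off)
                for off in range(len(long_) - length + 1)
            )
            identity = 100.0 * top / length
            key = (identity, length)
            if (
                best is None
                or key > (best[0], best[1])
                or (key == (best[0], best[1]) and entry.taxon_id < best[2])
            ):
                best = (identity, length, entry.taxon_id)
    return best[2], best[0], best[1]


class TestMergePairs:
    def template(self, n=250, seed=0):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=n))

    def split(self, template, read_length=150):
        r1 = template[:read_length]
        r2 = reverse_complement(template[-read_length:])
        return r1, r2

    def test_perfect_overlap_reconstructs_template(self):
        template = self.template()
        r1, r2 = self.split(template)
        res = merge_pairs(r1, r2, min_overlap=20)
        assert res.merged == template
        assert res.overlap == 50 and res.mismatches == 0

    def test_no_qualifying_overlap_returns_unmerged(self):
        res = merge_pairs("A" * 100, "C" * 100, min_overlap=20)
        # r2 revcomp is G*100; no overlap of A against G qualifies.
        assert res.merged is None and res.status == "unmerged"

    def test_one_mismatch_within_rate_still_merges(self):
        template = self.template(seed=1)
        r1, r2 = self.split(template)
        # Plant one disagreement inside the 50-bp overlap on the r2 side.
        r2rc = reverse_complement(r2)
        pos = 10  # within the first 50 bases of r2rc
        flipped = "A" if r2rc[pos] != "A" else "C"
        r2rc = r2rc[:pos] + flipped + r2rc[pos + 1 :]
        res = merge_pairs(r1, reverse_complement(r2rc), min_overlap=20,
                          max_mismatch_rate=0.05)
        assert res.merged is not None and len(res.merged) == 250
        assert res.mismatches == 1
        assert res.merged == template  # consensus takes r1's base

    def test_mismatch_rate_above_cap_rejected(self):
        template = self.template(seed=2)
        r1, r2 = self.split(template)
        r2rc = list(reverse_complement(r2))
        for pos in range(0, 50, 5):  # 10 mismatches in the 50-bp overlap
            r2rc[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r2rc[pos]]
        res = merge_pairs(r1, reverse_complement("".join(r2rc)),
                          min_overlap=20, max_mismatch_rate=0.05)
        assert res.merged is None


class TestDereplicate:
    def test_counts_duplicates(self):
        amp = dereplicate(["AAA", "AAA", "AAA", "CCC"])
        assert amp.table["sequence"].tolist() == ["AAA", "CCC"]
        assert amp.table["count"].tolist() == [3, 1]
        assert amp.total_reads == 4

    def test_empty_input(self):
        amp = dereplicate([])
        assert len(amp) == 0 and amp.total_reads == 0

    def test_deterministic_order_count_then_lexicographic(self):
        amp = dereplicate(["TTT", "GGG", "TTT", "GGG", "AAA"])
        assert amp.table["sequence"].tolist() == ["GGG", "TTT", "AAA"]

    def test_error_free_simulated_community_collapses_to_templates(self, toy_db):
        reads = simulate_amplicons(
            CommunitySimParams(
                abundance={"taxon_00": 400, "taxon_01": 300, "taxon_02": 300},
                error_rate=0.0,
                read_length=600,  # whole reference per read
                overlap=0,
                seed=9,
            ),
            toy_db,
        )
        amp = dereplicate(r.sequence for r in reads)
        assert len(amp) == 3
        assert amp.total_reads == len(reads)


class TestAssignTaxon:
    def test_exact_reference_sequence_hits_at_100(self, toy_db):
        entry = toy_db.entries[2]
        res = assign_taxon(entry.sequence[50:350], toy_db)
        assert res.taxon_id == entry.taxon_id
        assert res.identity == pytest.approx(100.0)

    def test_reverse_complement_reads_assigned(self, toy_db):
        entry = toy_db.entries[1]
        res = assign_taxon(reverse_complement(entry.sequence[100:400]), toy_db)
        assert res.taxon_id == entry.taxon_id
        assert res.identity == pytest.approx(100.0)
        assert res.strand == "-"

    def test_closer_reference_wins(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), size=100))

        def mutate(seq, k, seed):
            r = np.random.default_rng(seed)
            out = list(seq)
            for pos in r.choice(len(seq), size=k, replace=False):
                out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
            return "".join(out)

        from toxassay.metabarcoding import DBEntry

        db = ReferenceDB(
            [
                DBEntry("A", "k__x;p__y", mutate(base, 2, 1)),
                DBEntry("B", "k__x;p__y", mutate(base, 5, 2)),
            ]
        )
        res = assign_taxon(base, db)
        assert res.taxon_id == "A"
        assert res.identity == pytest.approx(98.0)

    def test_below_min_identity_unassigned(self, toy_db):
        rng = np.random.default_rng(5)
        junk = "".join(rng.choice(list("ACGT"), size=200))
        res = assign_taxon(junk, toy_db, min_identity=80.0)
        assert not res.assigned and res.reason == "below min_identity"
        # Threshold 0 retains every top hit.
        assert assign_taxon(junk, toy_db, min_identity=0.0).assigned

    def test_read_shorter_than_seed_unassigned_with_reason(self, toy_db):
        res = assign_taxon("ACGT", toy_db)
        assert not res.assigned and "seed" in res.reason

    def test_n_bases_count_as_mismatch(self, toy_db):
        entry = toy_db.entries[0]
        read = "N" * 10 + entry.sequence[10:110]
        res = assign_taxon(read, toy_db)
        assert res.taxon_id == entry.taxon_id
        assert res.identity == pytest.approx(100.0 * 100 / 110)

    @pytest.mark.parametrize("error_rate", [0.0, 0.02, 0.1])
    def test_agrees_with_exhaustive_hamming_oracle(self, error_rate):
        """Seeded classifier output equals the brute-force scan, identity
        and top taxon alike, on simulated error-bearing reads."""
        db = random_reference_db(12, length=400, seed=21)
        reads = simulate_amplicons(
            CommunitySimParams(
                abundance={f"taxon_{i:02d}": 10 for i in range(12)},
                error_rate=error_rate,
                read_length=150,
                seed=13,
            ),
            db,
        )
        for r in reads[:60]:
            got = assign_taxon(r.sequence, db, min_identity=0.0)
            taxon, identity, length = hamming_oracle(r.sequence, db)
            assert got.taxon_id == taxon
            assert got.identity == pytest.approx(identity, abs=1e-9)
            assert got.aligned_length == length


class TestBlastImport:
    def test_top_hit_per_query_with_threshold(self, tmp_path):
        rows = [
            "q1\ttaxA\t98.0\t300\t6\t0\t1\t300\t1\t300\t1e-50\t500",
            "q1\ttaxB\t95.0\t300\t15\t0\t1\t300\t1\t300\t1e-40\t450",
            "q2\ttaxC\t70.0\t250\t75\t0\t1\t250\t1\t250\t1e-10\t100",
            "q3\ttaxA\t90.0\t200\t20\t0\t1\t200\t1\t200\t1e-30\t300",
            "q3\ttaxB\t90.0\t300\t30\t0\t1\t300\t1\t300\t1e-30\t300",
        ]
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(rows) + "\n")
        top = load_blast_hits(path, min_identity=80.0)
        by_query = top.set_index("qseqid")
        assert by_query.loc["q1", "taxon"] == "taxA"  # higher identity
        assert by_query.loc["q2", "taxon"] == "unassigned"  # below threshold
        assert by_query.loc["q3", "taxon"] == "taxB"  # tie broken by length


class TestSummarizeDiet:
    def tidy(self):
        return pd.DataFrame(
            [
                ("MA", "March", "ind1", "copepod", 10),
                ("MA", "March", "ind2", "unassigned", 4),
                ("MA", "March", "ind3", "copepod", 20),
                ("MA", "March", "ind3", "worm", 10),
                ("NS", "March", "ind4", "worm", 8),
            ],
            columns=["site", "month", "individual", "taxon", "count"],
        )

    def test_individual_shares_and_zero_counts(self):
        tables = summarize_diet(self.tidy())
        ma = tables["site_summary"].set_index("site").loc["MA"]
        assert ma["total_reads"] == 40
        assert ma["zero_sequence_individuals"] == 1  # ind2 has only unassigned
        assert ma["max_individual_share"] == pytest.approx(0.75)  # ind3: 30/40

    def test_single_phylum_site_has_fraction_one(self, toy_db):
        # toy_db taxa 0 and 3 share phylum Arthropoda (index pattern of the
        # synthetic db); build a site with only one taxon instead.
        tidy = pd.DataFrame(
            [("X", "June", "i1", "taxon_00", 7), ("X", "June", "i2", "taxon_00", 3)],
            columns=["site", "month", "individual", "taxon", "count"],
        )
        tables = summarize_diet(tidy, db=toy_db)
        assert tables["per_phylum"]["fraction"].tolist() == [1.0]

    def test_share_sums_to_one_per_site(self):
        tables = summarize_diet(self.tidy())
        for _, grp in tables["per_individual"].groupby(["site", "month"]):
            if grp["count"].sum() > 0:
                assert grp["share"].sum() == pytest.approx(1.0)

    def test_exclude_taxon_filter(self):
        tables = summarize_diet(self.tidy(), exclude_taxa=["worm"])
        assert "worm" not in set(tables["per_taxon"]["taxon"])
        ma = tables["site_summary"].set_index("site").loc["MA"]
        assert ma["total_reads"] == 30

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            summarize_diet(pd.DataFrame({"taxon": ["a"], "count": [1]}))


class TestPipelineConservation:
    def test_read_counts_conserved_through_stages(self, toy_db):
        reads = simulate_amplicons(
            CommunitySimParams(
                abundance={"taxon_00": 120, "taxon_01": 80, "taxon_03": 50},
                error_rate=0.01,
                read_length=150,
                overlap=50,
                seed=31,
            ),
            toy_db,
            paired=True,
        )
        merged, unmerged = [], 0
        for r in reads:
            res = merge_pairs(r.r1, r.r2, min_overlap=20)
            if res.merged is None:
                unmerged += 1
            else:
                merged.append(res.merged)
        assert len(merged) + unmerged == len(reads)
        amp = dereplicate(merged)
        assert amp.total_reads == len(merged)
        assigned = assign_all(amp, toy_db, min_identity=80.0)
        assert assigned["count"].sum() == len(merged)

    def test_fasta_round_trip(self, tmp_path):
        seqs = [("r1", "ACGTACGT"), ("r2", "TTTTGGGG")]
        path = tmp_path / "reads.fasta"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs
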