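import numpy as np
import pytest

from toxassay.arena import ArenaSpec
from toxassay.locomotion import total_distance
from toxassay.proximity import score_track
from toxassay.qpcr import estimate_copy_number, relative_expression
from toxassay.simulate import (
    CommunitySimParams,
    LocomotionSimParams,
    QpcrSimParams,
    WalkParams,
    simulate_amplicons,
    simulate_ct_plate,
    simulate_locomotion,
    simulate_predator_track,
)


class TestPredatorWalk:
    def test_zero_steps_stays_at_start(self, arena):
        track = simulate_predator_track(
            WalkParams(n_steps=0, start_position=(50.0, 40.0)), arena
        )
        assert len(track) == 1
        assert tuple(track.positions[0]) == (50.0, 40.0)

    def test_seed_determinism(self, arena):
        p = WalkParams(bias=2.0, n_steps=300, seed=17)
        t1 = simulate_predator_track(p, arena)
        t2 = simulate_predator_track(p, arena)
        assert np.array_equal(t1.positions, t2.positions)

    def test_different_seeds_differ(self, arena):
        t1 = simulate_predator_track(WalkParams(n_steps=100, seed=1), arena)
        t2 = simulate_predator_track(WalkParams(n_steps=100, seed=2), arena)
        assert not np.array_equal(t1.positions, t2.positions)

    def test_start_outside_rejected(self, arena):
        with pytest.raises(ValueError):
            simulate_predator_track(
                WalkParams(start_position=(-5.0, 0.0), n_steps=10), arena
            )

    def test_reflective_boundaries_keep_walk_inside(self, arena):
        track = simulate_predator_track(
            WalkParams(bias=-4.0, step_scale=30.0, n_steps=500, seed=3), arena
        )
        assert np.all(track.positions[:, 0] >= 0) and np.all(
            track.positions[:, 0] <= arena.width
        )
        assert np.all(track.positions[:, 1] >= 0) and np.all(
            track.positions[:, 1] <= arena.height
        )

    def test_strong_attraction_ends_near_anemone(self):
        """Monte-Carlo regression: with bias +5 and large steps the walker
        ends within a 20 mm touch radius in >= 95% of 200 seeded runs
        (194/200 when frozen)."""
        arena = ArenaSpec(touch_radius=20.0)
        hits = 0
        for seed in range(200):
            track = simulate_predator_track(
                WalkParams(bias=5.0, step_scale=12.0, n_steps=500, seed=seed), arena
            )
            hits += track.distance_to(arena.anemone_position)[-1] <= arena.touch_radius
        assert hits >= 190  # 0.95 * 200

    def test_mean_score_increases_with_bias(self, arena):
        """Parameter recovery: mean weighted proximity score is strictly
        ordered in the attraction coefficient."""
        means = []
        for bias in (-3.0, 0.0, 3.0):
            scores = [
                score_track(
                    simulate_predator_track(
                        WalkParams(bias=bias, n_steps=900, seed=500 + k), arena
                    ),
                    arena,
                ).mean_score
                for k in range(60)
            ]
            means.append(np.mean(scores))
        assert means[0] < means[1] < means[2]


class TestCtPlateSimulation:
    def test_noiseless_fold_change_of_one_gives_zero_ddct(self):
        plate = simulate_ct_plate(
            QpcrSimParams(true_fold_change={"cal": 1.0, "s": 1.0}, replicate_sd=0.0)
        )
        assert relative_expression(plate, "s", "cal", "Nv1") == pytest.approx(1.0)

    def test_noiseless_copy_number_inverts_exactly(self):
        plate = simulate_ct_plate(
            QpcrSimParams(
                true_copy_number={"ref": 1.0, "s": 8.0},
                reference_sample="ref",
                replicate_sd=0.0,
            )
        )
        assert estimate_copy_number(plate, "s").diploid_copies == pytest.approx(8.0)

    def test_zero_copies_emit_undetected_sentinels(self):
        plate = simulate_ct_plate(
            QpcrSimParams(
                true_copy_number={"ref": 1.0, "fl": 0.0},
                reference_sample="ref",
            )
        )
        assert not plate.is_detected("fl", "Nv1")
        assert plate.is_detected("fl", "Catalase")
        est = estimate_copy_number(plate, "fl")
        assert est.diploid_copies == 0.0 and est.flag == "undetected"

    def test_replicate_structure_and_determinism(self):
        params = QpcrSimParams(
            true_fold_change={"a": 2.0, "b": 0.5}, replicate_sd=0.3, seed=9
        )
        p1, p2 = simulate_ct_plate(params), simulate_ct_plate(params)
        assert p1.data.equals(p2.data)
        assert len(p1.replicate_cts("a", "Nv1")) == 3

    def test_requires_exactly_one_truth_map(self):
        with pytest.raises(ValueError):
            QpcrSimParams(
                true_copy_number={"a": 1.0}, true_fold_change={"a": 1.0}
            )
        with pytest.raises(ValueError):
            QpcrSimParams()


class TestAmpliconSimulation:
    def test_error_free_reads_are_reference_substrings(self, toy_db):
        reads = simulate_amplicons(
            CommunitySimParams(abundance={"taxon_00": 50}, error_rate=0.0, seed=1),
            toy_db,
        )
        ref = toy_db["taxon_00"].sequence
        assert reads and all(r.sequence in ref for r in reads)

    def test_unknown_taxon_rejected(self, toy_db):
        with pytest.raises(ValueError, match="not in reference"):
            simulate_amplicons(
                CommunitySimParams(abundance={"nope": 5}), toy_db
            )

    def test_zero_abundance_emits_nothing(self, toy_db):
        reads = simulate_amplicons(
            CommunitySimParams(
                abundance={"taxon_00": 60, "taxon_01": 0}, error_rate=0.0, seed=2
            ),
            toy_db,
        )
        assert {r.taxon_id for r in reads} == {"taxon_00"}

    def test_mean_mismatch_count_matches_binomial_expectation(self, toy_db):
        """error_rate 0.01 on 300 bp reads plants ~3 substitutions per read."""
        reads = simulate_amplicons(
            CommunitySimParams(
                abundance={"taxon_02": 1000}, error_rate=0.01, read_length=300, seed=4
            ),
            toy_db,
        )
        ref = np.frombuffer(toy_db["taxon_02"].sequence.encode(), dtype=np.uint8)
        mm = []
        for r in reads:
            arr = np.frombuffer(r.sequence.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(ref, len(arr))
            mm.append(len(arr) - int((windows == arr).sum(axis=1).max()))
        assert np.mean(mm) == pytest.approx(3.0, abs=0.5)

    def test_paired_reads_share_exact_overlap(self, toy_db):
        reads = simulate_amplicons(
            CommunitySimParams(
                abundance={"taxon_03": 30},
                error_rate=0.0,
                read_length=150,
                overlap=50,
                seed=5,
            ),
            toy_db,
            paired=True,
        )
        from toxassay.metabarcoding import reverse_complement

        for r in reads:
            assert len(r.sequence) == 250
            assert r.r1 == r.sequence[:150]
            assert reverse_complement(r.r2) == r.sequence[-150:]


class TestLocomotionSimulation:
    def test_stationary_when_mean_step_zero(self):
        trace = simulate_locomotion(
            LocomotionSimParams(mean_step=0.0, jitter_below_threshold=0.0, seed=1)
        )
        assert total_distance(trace) == 0.0

    def test_all_jitter_filters_to_zero_but_moves(self):
        trace = simulate_locomotion(
            LocomotionSimParams(mean_step=0.5, jitter_below_threshold=1.0, seed=2)
        )
        assert total_distance(trace) == 0.0
        assert trace.displacements().sum() > 0.0

    def test_deterministic_sum_without_noise(self):
        trace = simulate_locomotion(
            LocomotionSimParams(
                mean_step=0.5, step_sd=0.0, jitter_below_threshold=0.0, duration=60.0
            )
        )
        assert len(trace) == 601
        assert total_distance(trace) == pytest.approx(300.0)

    def test_seed_determinism(self):
        p = LocomotionSimParams(mean_step=0.4, jitter_below_threshold=0.2, seed=6)
        assert np.array_equal(
            simulate_locomotion(p).positions, simulate_locomotion(p).positions
        )
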