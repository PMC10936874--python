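"""Synthetic inputs with the statistical structure the assays assume.

Every downstream stage of the pipeline is testable without animals or a
sequencer: this module generates predator tracks from a biased random walk
with tunable attraction/avoidance toward the focal anemone, qPCR Ct plates
by inverting the ΔΔCt model with programmed copy numbers and fold changes,
amplicon communities as error-bearing windows of reference sequences, and
locomotion traces with programmed per-treatment displacement plus planted
sub-threshold jitter.

All generators are pure functions of (params, seed): the same parameters
and seed reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .arena import ArenaSpec, Track
from .locomotion import DEFAULT_NOISE_THRESHOLD_MM
from .metabarcoding import ReferenceDB, reverse_complement
from .qpcr import CtPlate

__all__ = [
    "WalkParams",
    "QpcrSimParams",
    "CommunitySimParams",
    "LocomotionSimParams",
    "SimulatedRead",
    "simulate_predator_track",
    "simulate_ct_plate",
    "simulate_amplicons",
    "simulate_locomotion",
]

# Concentration of the von Mises heading component. Higher values make the
# biased fraction of steps point more sharply along (or against) the bearing
# to the anemone; 4.0 gives a clearly directional but noisy walk.
WALK_KAPPA = 4.0


@dataclass(frozen=True)
class WalkParams:
    """Biased random walk standing in for a live predator trial.

    ``bias`` is a signed attraction coefficient: positive values tilt step
    headings toward the anemone, negative away, zero is an unbiased walk.
    The mixture weight of the directed component is |bias| / (1 + |bias|),
    so the walk interpolates smoothly between uniform headings (bias 0) and
    near-deterministic approach/avoidance (|bias| large).
    """

    step_scale: float = 8.0
    bias: float = 0.0
    n_steps: int = 900
    frame_dt: float = 1.0
    seed: int = 0
    start_position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.step_scale <= 0:
            raise ValueError("step_scale must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")


def _reflect(value: float, upper: float) -> float:
    """Fold a coordinate back into [0, upper] (reflective boundary)."""
    while value < 0.0 or value > upper:
        if value < 0.0:
            value = -value
        if value > upper:
            value = 2.0 * upper - value
    return value


def simulate_predator_track(params: WalkParams, arena: ArenaSpec) -> Track:
    """Simulate a predator track inside the arena.

    Each step has fixed length ``step_scale``; its heading is, with
    probability |bias|/(1+|bias|), a von Mises draw centred on the bearing
    to the anemone (bias > 0) or directly away from it (bias < 0), and
    otherwise uniform. Walls reflect. The default start is the arena
    corner quarter-point farthest from release bias — the point
    (width/10, height/2), mimicking introduction at one end of the vessel.
    """
    start = params.start_position or (arena.width / 10.0, arena.height / 2.0)
    if not arena.contains(start):
        raise ValueError(f"start position {start} outside arena")
    rng = np.random.default_rng(params.seed)
    n = params.n_steps
    w = abs(params.bias) / (1.0 + abs(params.bias))
    use_biased = rng.random(n) < w
    vm_offsets = rng.vonmises(0.0, WALK_KAPPA, n)
    uniform_headings = rng.uniform(-math.pi, math.pi, n)

    ax, ay = arena.anemone_position
    x, y = float(start[0]), float(start[1])
    xs = [x]
    ys = [y]
    step = params.step_scale
    flip = math.pi if params.bias < 0 else 0.0
    for i in range(n):
        if use_biased[i] and params.bias != 0.0:
            theta = math.atan2(ay - y, ax - x) + flip + vm_offsets[i]
        else:
            theta = uniform_headings[i]
        x = _reflect(x + step * math.cos(theta), arena.width)
        y = _reflect(y + step * math.sin(theta), arena.height)
        xs.append(x)
        ys.append(y)
    positions = np.column_stack([xs, ys])
    times = np.arange(n + 1) * params.frame_dt
    return Track(times=times, positions=positions, frame_dt=params.frame_dt)


@dataclass(frozen=True)
class QpcrSimParams:
    """Programmed truth for a simulated Ct plate.

    Exactly one of ``true_copy_number`` / ``true_fold_change`` maps each
    sample to its target-gene signal relative to the single-copy control
    (copy-number mode) or to the housekeeping reference (expression mode).
    The generator inverts the ΔΔCt model: with per-cycle efficiency exactly
    2, Ct = base_ct - log2(signal) + Normal(0, replicate_sd) per replicate;
    signal 0 emits undetected sentinels for every target replicate.
    """

    true_copy_number: Mapping[str, float] | None = None
    true_fold_change: Mapping[str, float] | None = None
    reference_sample: str | None = None
    base_ct: float = 20.0
    replicate_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    target_gene: str = "Nv1"
    reference_gene: str = "Catalase"

    def __post_init__(self) -> None:
        if (self.true_copy_number is None) == (self.true_fold_change is None):
            raise ValueError("give exactly one of true_copy_number / true_fold_change")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        signals = self.true_copy_number or self.true_fold_change
        if any(v < 0 for v in signals.values()):
            raise ValueError("signals must be non-negative")
        if self.true_fold_change is not None and any(
            v <= 0 for v in self.true_fold_change.values()
        ):
            raise ValueError("fold changes must be positive")


def simulate_ct_plate(params: QpcrSimParams) -> CtPlate:
    """Simulate a Ct plate carrying the programmed copy numbers/fold changes.

    The reference gene amplifies at ``base_ct`` in every sample; the target
    gene at ``base_ct - log2(signal)``. Replicate noise is iid Normal with
    sd ``replicate_sd`` on every well. Signal 0 gives undetected (NaN)
    target wells — the explicit no-amplification sentinel.
    """
    signals = dict(params.true_copy_number or params.true_fold_change)
    copy_mode = params.true_copy_number is not None
    rng = np.random.default_rng(params.seed)
    ref_sample = params.reference_sample
    if copy_mode and ref_sample is None:
        raise ValueError("copy-number mode needs a designated reference_sample")
    if ref_sample is not None and ref_sample not in signals:
        raise ValueError("reference_sample must appear in the signal map")

    rows = []
    for sample, signal in signals.items():
        for gene, gene_signal in ((params.reference_gene, 1.0), (params.target_gene, signal)):
            for rep in range(1, params.n_replicates + 1):
                if gene_signal == 0.0:
                    ct = float("nan")
                else:
                    ct = params.base_ct - math.log2(gene_signal)
                    if params.replicate_sd > 0:
                        ct += rng.normal(0.0, params.replicate_sd)
                rows.append(
                    {"sample": sample, "gene": gene, "replicate": rep, "ct": ct}
                )
    data = pd.DataFrame(rows)
    known = signals[ref_sample] if (copy_mode and ref_sample is not None) else 1.0
    return CtPlate(
        data=data,
        reference_gene=params.reference_gene,
        reference_sample=ref_sample,
        known_copy_number=float(known),
    )


@dataclass(frozen=True)
class CommunitySimParams:
    """Programmed amplicon community for the metabarcoding pipeline.

    ``abundance`` maps taxon ids (present in the reference database) to
    expected read counts; realized counts are Poisson. Reads are windows of
    the source reference with iid substitutions at ``error_rate``; paired
    emission splits a fragment of length 2*read_length - overlap into two
    reads sharing exactly ``overlap`` bp, r2 in sequencing orientation.
    """

    abundance: Mapping[str, float]
    error_rate: float = 0.0
    read_length: int = 150
    overlap: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError("abundances must be non-negative")
        if not (0.0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must lie in [0, 0.25)")
        if self.overlap > self.read_length:
            raise ValueError("overlap cannot exceed read_length")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    taxon_id: str  # ground truth
    r1: str | None = None
    r2: str | None = None


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_amplicons(
    params: CommunitySimParams, db: ReferenceDB, paired: bool = False
) -> list[SimulatedRead]:
    """Emit reads from the programmed community.

    Single-read mode emits one window of length ``read_length`` per read
    (the whole reference when it is shorter). Paired mode emits fragments
    of length 2*read_length - overlap and splits them into (r1, r2) with r2
    reverse-complemented; ``sequence`` then holds the true fragment so the
    merger can be validated against ground truth.
    """
    unknown = set(params.abundance) - {e.taxon_id for e in db}
    if unknown:
        raise ValueError(f"taxa not in reference database: {sorted(unknown)}")
    rng = np.random.default_rng(params.seed)
    frag_len = 2 * params.read_length - params.overlap if paired else params.read_length
    reads: list[SimulatedRead] = []
    serial = 0
    for taxon in sorted(params.abundance):
        lam = params.abundance[taxon]
        count = int(rng.poisson(lam)) if lam > 0 else 0
        ref_seq = db[taxon].sequence
        span = max(len(ref_seq) - frag_len, 0)
        for _ in range(count):
            start = int(rng.integers(0, span + 1))
            window = ref_seq[start : start + frag_len]
            fragment = _mutate(window, params.error_rate, rng)
            serial += 1
            rid = f"read_{serial:06d}"
            if paired:
                r1 = fragment[: params.read_length]
                r2 = reverse_complement(fragment[-params.read_length :])
                reads.append(SimulatedRead(rid, fragment, taxon, r1=r1, r2=r2))
            else:
                reads.append(SimulatedRead(rid, fragment, taxon))
    return reads


@dataclass(frozen=True)
class LocomotionSimParams:
    """Programmed locomotion trace for the treated-water assay.

    A fraction ``jitter_below_threshold`` of frames get a displacement
    drawn strictly below the tracker noise threshold (planting frames the
    noise filter must remove); the rest move with half-normal displacements
    around ``mean_step`` (|Normal(mean_step, step_sd)|) in a uniformly
    random direction.
    """

    mean_step: float = 0.5
    step_sd: float = 0.05
    jitter_below_threshold: float = 0.0
    frame_dt: float = 0.1
    duration: float = 60.0
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD_MM
    seed: int = 0
    start_position: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mean_step < 0:
            raise ValueError("mean_step must be non-negative")
        if not (0.0 <= self.jitter_below_threshold <= 1.0):
            raise ValueError("jitter fraction must lie in [0, 1]")
        if self.frame_dt <= 0 or self.duration < 0:
            raise ValueError("frame_dt must be positive and duration non-negative")


def simulate_locomotion(params: LocomotionSimParams) -> Track:
    """Simulate a fish trace sampled every ``frame_dt`` seconds."""
    n = int(round(params.duration / params.frame_dt))
    rng = np.random.default_rng(params.seed)
    jitter_mask = rng.random(n) < params.jitter_below_threshold
    if params.mean_step == 0.0:
        # A programmed mean displacement of zero means a stationary animal,
        # not symmetric noise around zero.
        steps = np.zeros(n)
    else:
        steps = np.abs(rng.normal(params.mean_step, params.step_sd, n))
    # Planted sub-threshold frames: strictly below the noise threshold.
    steps[jitter_mask] = rng.uniform(0.0, params.noise_threshold, jitter_mask.sum()) * (
        1.0 - 1e-9
    )
    headings = rng.uniform(-math.pi, math.pi, n)
    dx = steps * np.cos(headings)
    dy = steps * np.sin(headings)
    positions = np.empty((n + 1, 2))
    positions[0] = params.start_position
    positions[1:, 0] = params.start_position[0] + np.cumsum(dx)
    positions[1:, 1] = params.start_position[1] + np.cumsum(dy)
    times = np.arange(n + 1) * params.frame_dt
    return Track(times=times, positions=positions, frame_dt=params.frame_dt)
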