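"""End-to-end synthetic run: simulators -> assays -> statistics.

``run_demo`` chains every stage of the pipeline on generated data — predator
tracks for avoiding / neutral / attracted predators, Ct plates for a control
vs knockdown comparison and a copy-number panel, a gut-content amplicon
community, and treated-water locomotion traces — writes all result tables
under one output directory, and records a manifest with parameters, seeds,
and artifact checksums. Rerunning with the same configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .arena import ArenaSpec
from .locomotion import compare_treatments, total_distance
from .metabarcoding import ReferenceDB, assign_all, dereplicate, summarize_diet
from .proximity import compare_scores, score_track, score_tracks_to_frame
from .qpcr import copy_number_table, paired_delta_ct_test, relative_expression
from .simulate import (
    CommunitySimParams,
    LocomotionSimParams,
    QpcrSimParams,
    WalkParams,
    simulate_amplicons,
    simulate_ct_plate,
    simulate_locomotion,
    simulate_predator_track,
)

__all__ = ["default_config", "load_config", "run_demo", "toy_reference_db"]

REQUIRED_BLOCKS = ("proximity", "qpcr", "community", "locomotion")


def default_config(seed: int = 0) -> dict:
    """Default demo configuration (all blocks present, seeds derived)."""
    return {
        "seed": int(seed),
        "proximity": {
            "groups": {"avoid": -3.0, "neutral": 0.0, "attract": 3.0},
            "n_trials": 50,
            "step_scale": 8.0,
            "arena": {},
        },
        "qpcr": {
            "copy_numbers": {"reference_fl": 1.0, "fl_a": 0.0, "fl_b": 2.0, "nc_a": 13.0, "md_a": 12.0},
            "expression_fold_changes": {"control_1": 1.0, "control_2": 1.0, "control_3": 1.0,
                                        "kd_1": 0.1, "kd_2": 0.1, "kd_3": 0.1},
            "replicate_sd": 0.15,
            "n_replicates": 3,
        },
        "community": {
            "abundance": {
                "copepod_a": 300, "copepod_b": 150, "amphipod_a": 90,
                "polychaete_a": 160, "gastropod_a": 100,
            },
            "error_rate": 0.01,
            "read_length": 150,
            "overlap": 50,
            "site": "MA",
            "month": "March",
        },
        "locomotion": {
            "treatments": {"control_water": 0.5, "kd_water": 0.35, "asw": 0.35},
            "n_fish": 9,
            "duration": 60.0,
            "jitter_below_threshold": 0.1,
            "alternatives": [
                ["control_water", "kd_water", "greater"],
                ["control_water", "asw", "greater"],
            ],
        },
    }


def load_config(path: str | Path) -> dict:
    """Load a run configuration from YAML, filling defaults per block."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config(seed=raw.get("seed", 0))
    for block in REQUIRED_BLOCKS:
        if block in raw:
            cfg[block].update(raw[block])
    return cfg


def toy_reference_db() -> ReferenceDB:
    """Small deterministic CO1-like reference database for synthetic runs.

    Sequences are generated (not real CO1 loci) but carry realistic lineage
    annotations down to phylum, covering arthropod and non-arthropod prey.
    """
    import numpy as np

    taxa = [
        ("copepod_a", "k__Animalia;p__Arthropoda;c__Copepoda"),
        ("copepod_b", "k__Animalia;p__Arthropoda;c__Copepoda"),
        ("amphipod_a", "k__Animalia;p__Arthropoda;c__Malacostraca"),
        ("polychaete_a", "k__Animalia;p__Annelida;c__Polychaeta"),
        ("gastropod_a", "k__Animalia;p__Mollusca;c__Gastropoda"),
    ]
    rng = np.random.default_rng(20160301)
    from .metabarcoding import DBEntry

    entries = []
    for taxon, lineage in taxa:
        seq = "".join(rng.choice(list("ACGT"), size=650))
        entries.append(DBEntry(taxon, lineage, seq))
    return ReferenceDB(entries)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_demo(config: dict, out_dir: str | Path, overwrite: bool = False) -> dict:
    """Run the full synthetic pipeline and write results under ``out_dir``.

    ``out_dir`` must be empty (or absent) unless ``overwrite`` is set; the
    check happens before any file is written, so a violated precondition
    leaves no partial output. Returns the manifest (also written as
    ``manifest.json``).
    """
    for block in REQUIRED_BLOCKS:
        if block not in config:
            raise ValueError(
                f"configuration is missing the {block!r} block; "
                f"expected blocks: {', '.join(REQUIRED_BLOCKS)}"
            )
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty")
    out.mkdir(parents=True, exist_ok=True)
    cfg = copy.deepcopy(config)
    seed = int(cfg.get("seed", 0))

    # --- proximity assay on simulated predator trials -----------------
    prox = cfg["proximity"]
    arena = ArenaSpec(**prox.get("arena", {}))
    group_scores: dict[str, list[float]] = {}
    per_trial = []
    trial_seed = seed * 10_000
    for label, bias in prox["groups"].items():
        scores = []
        for k in range(int(prox["n_trials"])):
            trial_seed += 1
            params = WalkParams(
                step_scale=float(prox.get("step_scale", 8.0)),
                bias=float(bias),
                n_steps=int(arena.duration / 1.0),
                frame_dt=1.0,
                seed=trial_seed % (2**31),
            )
            track = simulate_predator_track(params, arena)
            if k == 0:
                track.to_csv(out / f"track_{label}_example.csv")
            result = score_track(track, arena)
            scores.append(result.mean_score)
            per_trial.append((f"{label}_{k:03d}", result))
        group_scores[label] = scores
    _write_csv(score_tracks_to_frame(per_trial), out / "proximity_scores.csv")
    _write_csv(compare_scores(group_scores, "anova_tukey"), out / "proximity_comparison.csv")

    # --- qPCR: copy-number panel and control-vs-knockdown expression --
    qp = cfg["qpcr"]
    copy_plate = simulate_ct_plate(
        QpcrSimParams(
            true_copy_number=qp["copy_numbers"],
            reference_sample="reference_fl",
            replicate_sd=float(qp.get("replicate_sd", 0.15)),
            n_replicates=int(qp.get("n_replicates", 3)),
            seed=(seed * 7 + 1) % (2**31),
        )
    )
    copy_plate.to_csv(out / "ct_plate_copy_number.csv")
    _write_csv(copy_number_table(copy_plate), out / "copy_number_estimates.csv")

    expr_plate = simulate_ct_plate(
        QpcrSimParams(
            true_fold_change=qp["expression_fold_changes"],
            replicate_sd=float(qp.get("replicate_sd", 0.15)),
            n_replicates=int(qp.get("n_replicates", 3)),
            seed=(seed * 7 + 2) % (2**31),
            reference_gene="NVE5273",
        )
    )
    expr_plate.to_csv(out / "ct_plate_expression.csv")
    controls = sorted(s for s in expr_plate.samples if s.startswith("control"))
    kds = sorted(s for s in expr_plate.samples if s.startswith("kd"))
    expr_rows = [
        {
            "sample": s,
            "fold_change_vs_control_1": relative_expression(expr_plate, s, controls[0], "Nv1"),
        }
        for s in expr_plate.samples
    ]
    _write_csv(pd.DataFrame(expr_rows), out / "relative_expression.csv")
    paired = paired_delta_ct_test(expr_plate, controls, kds, "Nv1")
    (out / "knockdown_test.json").write_text(json.dumps(paired, indent=2, sort_keys=True))

    # --- gut-content metabarcoding ------------------------------------
    comm = cfg["community"]
    db = toy_reference_db()
    db.to_fasta(out / "reference_db.fasta")
    reads = simulate_amplicons(
        CommunitySimParams(
            abundance=comm["abundance"],
            error_rate=float(comm.get("error_rate", 0.01)),
            read_length=int(comm.get("read_length", 150)),
            overlap=int(comm.get("overlap", 50)),
            seed=(seed * 7 + 3) % (2**31),
        ),
        db,
    )
    with open(out / "amplicons.fasta", "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")
    derep = dereplicate([r.sequence for r in reads])
    assigned = assign_all(derep, db, min_identity=80.0)
    _write_csv(assigned.drop(columns=["sequence"]), out / "assignments.csv")
    tidy = assigned.assign(
        site=comm.get("site", "MA"), month=comm.get("month", "March"), individual="ind_01"
    )[["site", "month", "individual", "taxon", "count"]]
    tables = summarize_diet(tidy, db=db)
    for name, table in tables.items():
        _write_csv(table, out / f"diet_{name}.csv")

    # --- treated-water locomotion -------------------------------------
    loc = cfg["locomotion"]
    distances: dict[str, list[float]] = {}
    fish_seed = (seed * 7 + 4) % (2**31)
    dist_rows = []
    for treatment, mean_step in loc["treatments"].items():
        values = []
        for k in range(int(loc["n_fish"])):
            fish_seed += 1
            trace = simulate_locomotion(
                LocomotionSimParams(
                    mean_step=float(mean_step),
                    jitter_below_threshold=float(loc.get("jitter_below_threshold", 0.1)),
                    duration=float(loc.get("duration", 60.0)),
                    seed=fish_seed % (2**31),
                )
            )
            d = total_distance(trace)
            values.append(d)
            dist_rows.append({"treatment": treatment, "fish": k, "distance_mm": d})
        distances[treatment] = values
    _write_csv(pd.DataFrame(dist_rows), out / "locomotion_distances.csv")
    alternatives = [tuple(a) for a in loc["alternatives"]]
    _write_csv(
        compare_treatments(distances, alternatives), out / "locomotion_comparison.csv"
    )

    # --- manifest ------------------------------------------------------
    artifacts = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package": "toxassay",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
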