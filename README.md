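# toxassay

Quantitative assays for toxin-genotype ecology in the sea anemone
*Nematostella vectensis*. The package implements, as a tested and reusable
pipeline, the measurements used to connect variation in the neurotoxin Nv1
— its gene copy number and expression level — to predator–prey
interactions and fitness: grid-based weighted proximity scoring of
predator behavior, treated-water fish locomotion analysis, ΔΔCt-based
copy-number and expression quantification, CO1 gut-content metabarcoding
summaries, and the shared statistics behind all of them. A synthetic-data
generator stands in for the animals and the sequencer, so every stage can
be exercised and validated without lab data.

It is intended for behavioral ecologists and molecular biologists who have
exported tracking tables, qPCR Ct plates, or amplicon FASTA files and want
the downstream quantification to be scripted, deterministic, and tested.

## The measurements

**Weighted proximity score.** A trial arena (27.5 × 8 cm by default) is
partitioned by a 15-cell grid (3 rows × 5 columns) with a focal anemone at
a fixed position. Every 10 s the predator's position is classified and
weighted:

    w(t) = 0.6  if d(predator, anemone) ≤ r_touch
           0.3  if the predator's grid cell is within Chebyshev distance 1
                of the anemone's cell
           0.1  otherwise

and the per-trial statistic is the mean of the interval weights over the
recording (90 intervals for a 15-min shrimp trial, 60 for a 10-min fish
trial). High scores mean the predator stayed close — poor defense by the
anemone. Lines or populations are compared by one-way ANOVA with Tukey HSD
(multi-line designs) or a two-tailed Student's *t* test (two populations).

**Locomotion in treated water.** Fish positions sampled every 0.1 s;
per-frame displacements `d_i < 0.1 mm` are tracker noise and zeroed, then
distance is the sum of the filtered displacements. Treatments are compared
with one-tailed Student's *t* tests whose direction is declared a priori,
Benjamini–Hochberg corrected across the declared pairs. A light/dark
module partitions a recording (15-min acclimation, then 3 cycles of 30 min
light + 30 min dark) into epochs and totals activity per epoch.

**ΔΔCt quantification.** Replicate Ct values are averaged per
(sample, gene), then

    ΔCt   = mean Ct(reference gene) − mean Ct(target gene)
    fold  = 2^(ΔCt_sample − ΔCt_calibrator)
    copies = known_copies(reference sample) × 2^(ΔCt_sample − ΔCt_ref-sample)

assuming amplification efficiency exactly 2 per cycle. Copy number uses a
single-copy control gene (*Catalase*) and a reference individual of known
diploid copy number (1 by default); expression uses a stable housekeeping
gene. "Undetected" is a typed state (empty field / NaN), never a large Ct
placeholder — zero copies is a real biological outcome. Knockdown
comparisons use a paired two-tailed *t* test on ΔCt values.

**CO1 metabarcoding.** Read pairs are merged on their best qualifying 3'
overlap, exact duplicates counted, and each unique amplicon assigned the
top hit against a taxon-annotated CO1 reference database (k-mer-seeded
ungapped scan, Hamming identity, both strands, fully specified tie-breaks;
a precomputed BLAST outfmt-6 table can substitute for the internal
search). Summaries report reads per taxon and phylum, per-individual
shares of each site's total, individuals lacking any assigned sequence,
and the arthropod read fraction per site.

**Estimation statistics.** Mean differences are also reported
Gardner–Altman style: a seeded bootstrap (5000 resamples, percentile 95%
interval by default, BCa optional) of the difference in group means.

## Worked example

```python
from toxassay import (
    ArenaSpec, WalkParams, QpcrSimParams,
    simulate_predator_track, simulate_ct_plate,
    score_track, estimate_copy_number, bootstrap_mean_difference,
)

arena = ArenaSpec()  # 275 x 80 mm, 3 x 5 grid, anemone centred
track = simulate_predator_track(WalkParams(bias=3.0, n_steps=900, seed=7), arena)
res = score_track(track, arena)
print(round(res.mean_score, 4), res.counts)

plate = simulate_ct_plate(QpcrSimParams(
    true_copy_number={"fl_ref": 1.0, "fl_new": 0.0, "nc_01": 13.0},
    reference_sample="fl_ref", replicate_sd=0.2, seed=7))
for s in plate.samples:
    e = estimate_copy_number(plate, s)
    print(s, round(e.diploid_copies, 3), e.flag)

boot = bootstrap_mean_difference(
    [3.1, 2.8, 3.4, 3.0, 2.9, 3.3], [1.9, 2.2, 2.0, 2.4, 2.1, 1.8], seed=1)
print(round(boot.mean_difference, 4), (round(boot.ci_low, 4), round(boot.ci_high, 4)))
```

prints

```
0.4311 {'touch': 40, 'adjacent': 49, 'distant': 1}
fl_ref 1.0 detected
fl_new 0.0 undetected
nc_01 12.252 detected
1.0167 (0.7833, 1.2333)
```

A strongly attracted simulated predator (bias +3) touches or neighbors the
anemone at 89 of 90 scored instants, giving a mean weighted score of 0.43;
the noisy Ct plate recovers the programmed copy numbers (a true-13-copy
sample estimated at 12.25 with replicate sd 0.2 cycles; the zero-copy
sample flagged undetected rather than given a spurious estimate); and the
bootstrap puts the mean group difference at 1.02 with 95% interval
(0.78, 1.23).

## Command line

The `toxassay` executable exposes the same operations:

```
toxassay simulate tracks|qpcr|amplicons|locomotion --seed N --out ...
toxassay proximity score --tracks 'runs/*.csv' --arena arena.yaml --out scores.csv
toxassay proximity compare --scores scores.csv --design anova_tukey
toxassay locomotion distance|compare|lightdark ...
toxassay qpcr expression --calibrator control_1 / copynumber --reference-copies 1
toxassay diet merge|derep|assign|summarize ...
toxassay stats anova|t|fdr|estimate ...
toxassay demo --seed 0 --out results/
```

`toxassay demo` chains the full synthetic pipeline (behavioral trials at
three attraction settings, copy-number and knockdown plates, an amplicon
community, locomotion treatments) and writes every table plus a
`manifest.json` recording parameters, seeds, and artifact checksums;
rerunning with the same seed reproduces byte-identical files.

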