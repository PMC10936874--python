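# Methods

This note records the models, parameter choices, numerical conventions,
and known limitations behind each module. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Proximity scoring

The arena is a rectangle partitioned into `grid_rows × grid_cols` equal
cells (default 3 × 5 = 15, matching the aspect ratio of a 27.5 × 8 cm
vessel; both counts are configurable). Scored instants are
`t = k·scoring_interval` for `k = 1 … ⌊duration/interval⌋`; the release
instant `t = 0` is excluded because the animal is introduced at recording
start. The position at an instant is the nearest recorded frame, required
to lie within half a frame interval — tracks and the scoring clock need
not be phase-aligned, but an instant must actually be covered. Instants
past the end of a short recording are dropped rather than invented.

Category definitions:

* *touching* — Euclidean distance to the anemone ≤ `touch_radius`
  (default 5 mm). Manual scoring used visual contact; a distance
  threshold is the reproducible operationalization, and it is
  configurable.
* *adjacent* — Chebyshev distance ≤ 1 between the predator's and the
  anemone's grid cells, diagonals included; the anemone's own cell counts
  as adjacent when the animal is not touching. Visual adjacency on a grid
  overlay naturally includes diagonals, hence Chebyshev rather than
  Manhattan.
* *distant* — everything else.

The per-trial statistic is the arithmetic mean of interval weights
(0.6/0.3/0.1), so it always lies in [0.1, 0.6]. An alternative reading —
total score divided by duration in other units — differs only by a
constant factor and would not change any comparison; the mean per interval
is what the package reports.

Degenerate geometry behaves sensibly: with `touch_radius → ∞` every
instant scores 0.6; with a 1 × 1 grid and a vanishing touch radius every
instant scores 0.3, since adjacency degenerates to "same cell".

## Predator walk simulator

No movement model exists for the real predators; the simulator's job is
parameter recovery, not realism. Each step has fixed length `step_scale`
(default 8 mm at 1 Hz). Its heading is a two-component mixture: with
probability `|β|/(1+|β|)` a von Mises draw (κ = 4) centred on the bearing
to the anemone (β > 0) or directly away from it (β < 0), otherwise
uniform. A single signed coefficient β therefore spans avoidance through
indifference to attraction, and the mixture weight — not a potential
field — makes the expected proximity score monotone in β, which is the
property the pipeline's recovery tests rely on. Walls reflect (the
animals are confined to a vessel; reflection avoids absorbing states).
The default start is (width/10, height/2), mimicking introduction at one
end of the vessel.

## Locomotion analysis

Displacements below the noise threshold are **zeroed**, not deleted: for
summed distance the two are identical, but zeroing preserves the time
base for the light/dark epoch partition. The removal rule is a strict
inequality (`< 0.1 mm` removed), so a step of exactly 0.1 mm is movement.
Raising the threshold can only decrease total distance, and total
distance is invariant under rigid rotation/translation of the trace —
both are tested properties.

One-tailed tests require the direction as an explicit argument for every
pair; the package never infers sidedness from the data (the direction in
the motivating assay came from prior knowledge that fish move more when
exposed to the toxin). The FDR correction is Benjamini–Hochberg, the
standard step-up procedure. Tests are classic equal-variance Student's
*t* by default, with Welch behind a flag.

Light/dark epochs beyond the end of a recording are truncated with a
warning; activity is reported as a raw total by default, or per second of
covered epoch time with `normalize_truncated` (a truncated raw total is
not comparable across epochs, so the warning is always emitted). Each
displacement is attributed to the epoch containing the end of its frame
interval, which makes epoch activities sum exactly to the
post-acclimation total.

## ΔΔCt quantification

Replicate Cts are averaged before differencing — standard ΔΔCt practice;
the sign convention `ΔCt = Ct(reference) − Ct(target)` means higher
expression gives larger ΔCt. Amplification efficiency is fixed at 2 per
cycle (plain `2^ΔΔCt`, no standard-curve correction). Plate-wide additive
Ct shifts cancel exactly, and copy-number estimates are monotone in
target Ct — both tested invariants.

"Undetected" is a typed state: empty `ct` field on disk, NaN in memory,
an `undetected` flag on estimates. It is never encoded as Ct 40 or
another large number, because zero target copies is a legitimate outcome
that must survive arithmetic (an undetected target yields copy number 0
with the flag; an undetected reference gene invalidates the assay and
raises). Reported copy numbers are raw reals; an integer display value
rounds half-up.

The qPCR simulator inverts this model exactly:
`Ct = base_ct − log2(signal) + N(0, replicate_sd)` per replicate, with
three technical replicates per (sample, gene) by default. With
`replicate_sd = 0` the estimator is the identity on programmed copy
numbers and fold changes, the package's round-trip test. With the
replicate noise used in the acceptance run (sd 0.2 cycles, triplicates),
the ΔΔCt estimate carries noise from four replicate means — two genes in
the sample and two in the shared reference sample — giving an analytic
relative error sd of about 16% per sample, so the realized RMSE of a
200-sample panel fluctuates by seed around 14% and is reported as a
stochastic quantity, not a constant.

## Metabarcoding

Pair merging reverse-complements R2, scans all overlap lengths from the
longest down to `min_overlap` (default 20 bp), and accepts the first
(longest) overlap whose mismatch rate is ≤ `max_mismatch_rate` (default
0.05); the consensus takes R1's base at disagreements. Failure is a
status, not an exception, so unmerged pairs remain countable —
read-count conservation through every stage is a tested invariant.

Dereplication is exact string grouping, ordered by count descending then
sequence lexicographically, so outputs are deterministic.

The classifier is an ungapped semi-global scan: candidate references are
gathered by shared k-mers (k = 12, purely a performance device — the
oracle tests run it against an exhaustive scan), each candidate is scored
at its best placement of the shorter sequence inside the longer, identity
is Hamming matches over the contained length, both strands are tried, and
ties break by longer aligned length then lexicographic taxon id. `N`
matches nothing, including another `N` — conservative identity. Gapped
alignment is out of scope because fixed-locus CO1 amplicons are
length-matched to their references; where indels matter, a precomputed
BLAST outfmt-6 table can be imported and the identical top-hit/threshold
logic applied. The default `min_identity` of 80% is deliberately
conservative; a threshold of 0 retains every top hit, reproducing plain
top-hit assignment. Per-read top hits are used; no per-locality reduction
is applied. No taxa are excluded by default (host self-hits can be
dropped with `exclude_taxa`).

The community simulator emits reads as windows of reference sequences
with iid substitutions; per-taxon counts are Poisson around the expected
abundances, so realized totals fluctuate and fraction-recovery tests use
binomial bounds. Quality scores, chimeras, and primer artifacts are not
modeled — passing tests validate the arithmetic of the pipeline, not its
robustness to those real-data failure modes.

## Statistics layer

ANOVA/Tukey and the t tests delegate to scipy's implementations behind
the module's own interface; the Tukey pairwise p-values come from the
studentized-range distribution and are cross-checked in the tests against
statsmodels' independent implementation. Degenerate inputs return typed
flags: all-identical data gives F = 0, p = 1; zero pooled variance with
unequal means gives p = 0 with `degenerate=True`, never NaN.

The bootstrap estimator resamples each group independently (5000
resamples by default) from a single seeded generator recorded in the
result. The percentile interval is the default; BCa (jackknife
acceleration) is available. With n = 30 per group the percentile
interval's null coverage measures 0.946 over 500 simulated datasets in
the test suite; at smaller n (≈15) percentile intervals are known to
undercover slightly, a limitation to weigh when trials are few.

## Synthetic runs and problem sizes

The end-to-end demo and the acceptance script run at the assays' own
design points: 15-min trials scored every 10 s (90 intervals), 200
simulated trials per attraction setting for parameter recovery, Ct
triplicates, 200-sample copy-number panels at replicate sd 0.2, ~1000-read
communities with a programmed 60% arthropod fraction and 1–2%
substitution error, and 0.1-s locomotion traces with planted
sub-threshold jitter. Locomotion traces in the demo are 60 s rather than
15 min — the filter and the tests are per-frame operations, so trace
length only scales the totals. All randomness flows from one user-visible
seed; every generator is a pure function of (params, seed).
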