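# Methods

## Clone growth model

Each engrafted marked cell founds one clone, labeled by its lentiviral
integration site (chromosome, 1-based position, strand).  Within a clone
every cell divides at the same constant rate λ — a Yule linear birth
process with no death.  Starting from one cell, the clone size after time
*T* is geometric on {1, 2, ...}:

    P(Z = k) = q (1 − q)^(k−1),   q = exp(−λT),   E[Z] = 1/q.

Only the product λT is identifiable from a single harvest, so all
inference is parameterized by q.  Time units are arbitrary.  Two samplers
are provided: the direct geometric draw and an event-by-event Gillespie
simulation (exponential waiting times with total rate λ·size), the latter
serving as an independent distributional oracle in the test suite.
Engraftment times are taken as simultaneous; there is no latency, death
or differentiation term.

## Detection model

A fraction *f* of a dissociated tumor of N cells is used for IS analysis;
each cell enters the aliquot independently (binomial thinning; an exact
multivariate-hypergeometric aliquot is available as a switchable
strategy, indistinguishable when N greatly exceeds the aliquot).  An IS
is *called* when its share of the sample reaches the relative-abundance
cutoff c (default 0.06% of total sequence counts).  Modeling read share
as sampled-cell share, a clone is detected iff its sampled cell count S
satisfies S ≥ m with m = max(1, ⌈c·f·N⌉).  The per-clone detection
probability

    p_det(q, f) = 1 − Σ_k P(Z = k) · P(Binomial(k, f) ≤ m − 1)

is computed by series summation truncated when the geometric tail bound
falls below 10⁻¹².  Note that p_det is provably nonincreasing in c but
*not* monotone in f once c > 0 (the threshold m scales with f); the
nuisance-supremum machinery therefore never assumes a corner extremum.
Read-depth multinomial noise is applied only in the synthetic-data
generator, keeping the analytic p_det separate from sequencing noise.

## Synthetic serial-transplantation experiments

The generator emulates the experimental design: `n_cells_transplanted`
(default 10⁵) cells at `transduction_efficiency` (default 0.6, study
range 0.355–0.975) yield ⌊n·eff⌋ uniquely labeled founders (IS positions
uniform over GRCh37 chromosome lengths; no integration-preference model).
Founders engraft with `seeding_prob` (default 0.005, putting the
engrafted clone number near the inferred-hundreds scale); each tumor is
assayed (fraction `f` = 0.1 of cells, study range 0.03–0.30; two enzyme
replicates with independent dropout, default 0.1; `read_depth` = 50,000
reads each, multinomially allocated) and split per clone into the IS
aliquot, `mice_per_generation` (default 2) re-transplantation inocula of
`fraction_retransplanted` (default 0.4, study range 0.33–0.50) each, and
a remainder — cells are conserved exactly.  Three generations by default.

**Cell-state model.**  TIC-competent cells engraft and may proliferate;
non-tumorigenic progeny (the bulk tumor mass) die on re-transplantation.
This is what makes formerly dominant clones invisible in daughter tumors
despite their progeny dominating the inoculum — the central observation
the succession scenario reproduces.

**Growth to harvest size.**  Because all active cells share one division
rate, the joint composition of a tumor grown until it reaches the harvest
size (default 2×10⁶ cells) is exactly a Pólya urn started from the active
founder counts, i.e. Dirichlet-multinomial.  The generator uses this
exact representation by default (`growth_mode="fixed_size"`): it keeps
serial passages at a realistic, stable tumor size, whereas fixed-duration
growth compounds across generations and explodes once inocula are large.
A fixed-duration mode (independent per-clone negative-binomial Yule
growth with the configured λ, T) remains available.

**Scenarios.**
* *succession*: dormant engrafted clones are recruited with `p_activate`
  (default 0.04) per tumor they enter; at harvest each active clone's TIC
  lineage is exhausted with `p_inactivate` (default 0.75), decided once
  per burst — surviving clones retain a single TIC-competent cell (so a
  persisting clone continues in at most one daughter).  Exhaustion at
  harvest, rather than per daughter, is what makes dominant-clone
  persistence ≈ (1 − p_inactivate) × (total re-transplant fraction) per
  generation step.
* *hierarchy*: a fixed `ltic_fraction` (default 0.04) of clones
  self-renews indefinitely (TIC reservoir refreshed to 50 cells per
  passage, so LT-TIC clones reach every daughter); all other clones never
  activate.
* *stochastic*: every clone is equally likely active in each tumor,
  independent of history.

**Calibration.**  No activation/inactivation rates are published; the
defaults were chosen once so that succession-scenario summary statistics
fall in the reported ranges: median detected IS per primary tumor ≈ 12
(reported 4–16), dominant-clone nonpersistence ≈ 0.8 (reported 75%),
sibling-tumor overlap ≈ 0–13%.  Known mismatches, accepted rather than
re-tuned: the generation-exclusive fraction runs ≈ 0.90 (reported 78%)
and the detected-once fraction ≈ 0.90 (reported 49%) — with at most one
TIC-competent cell transplanted per dormant clone, the generator rarely
detects the same clone in two tumors of the same generation, which is the
main source of non-once detections in the real data.  The prior-
generation fraction (≈ 0.07–0.15 vs reported 14–39%) is low for the same
reason.  Passing simulation-based tests therefore demonstrates internal
consistency of the pipeline and separability of the competing scenarios,
not quantitative agreement of every statistic with the real dataset.

## IS-table filtering

Fixed pipeline order: merge enzyme replicates (union; counts summed) →
relative-abundance cutoff (shares against the tumor's pre-filter total;
share ≥ c retained) → collision removal → contribution matrix
(renormalized per tumor; IS ordered by genomic coordinate; tumors with no
surviving IS retained as flagged all-undetected columns).  Merging before
thresholding maximizes sensitivity (the point of the dual-enzyme design)
and is part of the contract — a regression fixture pins a case where the
orders differ.  A *collision* is the same IS coordinate in more than one
independent experiment lineage; only its below-cutoff occurrences are
removed (cross-contamination signature), never at-or-above-cutoff
occurrences in their own lineage.  In the fixed order the cutoff step has
already removed every below-cutoff row, so the collision pass is a
verified no-op safety net there; it acts when applied to pre-cutoff
tables.  IS identity is the exact coordinate triple — no fuzzy windows.

## Succession metrics

All metrics operate on the detection matrix plus per-tumor annotations
(patient, experiment, generation 1–3, parent).  Definitions:
generation-exclusive = all detections of an IS in one generation;
detected-once = detected in exactly one tumor (per-generation variant:
among IS detected in generation g, those whose only detection anywhere is
a single generation-g tumor); dominant-nonpersistent = among IS reaching
≥ 50% of some tumor's reads, those whose detections are confined to a
single generation; prior-generation fraction = share of serial-tumor IS
already present in the experiment's primary; sibling overlap = Jaccard
index over tumors transplanted from the same donor (the denominator is a
flag: `union` or `smaller`; the published range does not state one, and
Jaccard is the default).

## Clone-number bound and homogeneity tests

Detected IS counts are K ~ Binomial(n, p_det(q, f)) with unknown n and
nuisance pair (q, f).  The identity of the "two nuisance parameters" with
(q, f) — growth and effective sampling — is this package's construction.
Given a confidence rectangle for (q, f), the upper bound on n at
confidence 1−α inverts the exact binomial CDF (largest n with
P(K ≤ k | n, p) ≥ α_bin) at every node of a 25×25 grid over the
rectangle and reports the supremum; α is split Bonferroni-style between
rectangle and inversion (default 0.5/0.5, configurable).  One doubling
refinement pass must leave the p_det extremum unchanged to 10⁻³ or the
construction refuses.  The bound is conservative by design; at p_det = 1
it returns n_upper = k exactly.  Seeding efficiency is the bound interval
divided by the number of transplanted marked cells, in percent.

The three homogeneity tests report supremum p-values over the nuisance
grid *and* over reconstructions of the unobservable per-clone cell counts
(read share × scale, rounded half-to-even, floored at 1, with the scale
scanned over a caller-supplied interval).  Null distributions are seeded
parametric Monte Carlo at each node with add-one p-values
(1 + #{T* ≥ T}) / (B + 1), so every p-value is bit-reproducible and the
supremum is conservative:

* **H0,P1 (equal proliferation within a tumor)** — under the null the
  reconstructed counts of detected clones are i.i.d. geometric; the
  statistic is the log-likelihood ratio of the saturated per-clone
  geometric model against the common-q fit.
* **H0,P2 (constant growth across a transplantation step)** — parent
  shares are propagated through binomial transplant thinning and common
  Yule growth; the statistic is the multinomial deviance between observed
  and propagated daughter counts over the parent-detected clones plus an
  explicit "rest" bucket (undetected parent mass and new clones), which
  is what makes the disappearance of formerly dominant clones visible.
* **H0,S (equal seeding)** — clone-level engraftment is Bernoulli with
  p_i = 1 − (1−r)^{s_i} under a common per-cell rate r (fitted by MLE per
  node); the statistic Σ e_i log s_i is referred to its conditional null
  distribution given the number of engrafting clones, drawn by rejection
  from the fitted Bernoulli law (unconditional fallback flagged if
  acceptance is poor); two-sided Monte-Carlo p.

Degenerate inputs return p = 1 with a flag (single clone; all clones
engrafting; no clone shared between parent and daughter).  Monte-Carlo
replicates default to 2,000; child seeds derive from the root seed via
`SeedSequence.spawn`.  The published per-tumor inputs behind the
"hundreds of clones present" bounds are in an appendix not shipped with
the package, so the procedure is validated by empirical coverage
(≥ 99% across true n ∈ {10, 100, 300} and a nuisance grid) rather than by
reproducing those endpoints.

## Limiting dilution

Single-hit Poisson likelihood

    ℓ(θ) = Σ_i [ k_i log(1 − e^{−θ d_i}) − (n_i − k_i) θ d_i ]

maximized over log θ (bounded scalar optimization, tolerance 10⁻¹²).  The
95% CI uses the expected Fisher information on the log-θ (complementary
log-log) scale, the convention of the standard LDA fitting tools; the
frequency is reported as 1 in round(1/θ̂), rounding half away from zero.
No continuity correction is applied — the exact MLE reproduces all eight
published tables to ±1 of the printed denominator.  All-negative tables
report an infinite denominator; all-positive tables a boundary estimate
with a warning.  Group comparison is a 1-df likelihood-ratio test of
common versus separate θ.  Published tables are taken at face value
(mice lost before endpoint are assumed already excluded from the counts).

## Problem sizes and numerical choices

Test-suite simulation sizes are chosen for a laptop-scale run: 10⁵ draws
for distributional agreement (total-variation tolerance 0.01), 500 null
experiments per homogeneity test (level checked against α + 2 Monte-Carlo
standard errors), 1,000 replicates per cell of the coverage grid, 50
replicates per scenario for the succession/hierarchy contrast
(Mann-Whitney, α = 0.01).  Bootstrap sizes inside the calibration loops
use B = 199 with 3×3 nuisance grids; production defaults are B = 2,000
with 5×5 grids.  Ties in Monte-Carlo p-values are broken conservatively
(≥ with a 10⁻¹² slack).  The series summation, binomial inversion and
urn growth all carry explicit guards against runaway sizes.

## Known limitations

* The generator's activity-transition model is an operationalization; its
  rates are calibrated, not measured (see Calibration above).
* Integration-site placement is uniform; real lentiviral integration
  prefers transcription units.
* No cell death, differentiation hierarchy within clones, spatial
  structure, or microenvironment effects.
* The H0,P2 null treats the non-detected parent mass as a single pooled
  bucket of independent founders, slightly understating its variance.
* Collision removal assumes lineage labels are correct; it cannot detect
  contamination within a lineage.
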