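# Methods

This note records the statistical procedures the package implements, the
design choices that were genuinely open, and what the synthetic cohorts do
and do not establish.

## Stage 1 — the extreme-expressor burden screen

**Burden statistic.** For subject *j*, the burden in channel *c* is a gene
count over the discrete GISTIC 2.0 call matrix: total = #{*g* : call ≠ 0},
amp = #{call > 0}, del = #{call < 0}.  Missing calls are excluded from both
the counts and the per-subject denominator `n_evaluated`.  The default
counts *any* nonzero call: the high-level restriction (|call| = 2) belongs
to the altered/unaltered definition of the survival stage, not to the
burden response.  `min_magnitude=2` is exposed for sensitivity analysis.
Burden is a gene count, not a segment- or base-pair measure, because the
pipeline operates entirely on the gene × sample call matrix.

**Group selection.** Per gene, subjects are ordered by (expression value,
subject id) and the bottom and top *k* = 10 form the comparison groups.
The secondary sort key makes boundary ties deterministic and auditable;
with z-scored expression, exact ties are rare in real data but must not
depend on input row order.  Genes with fewer than 2*k* non-missing values
are excluded with a recorded reason (all-missing genes are the extreme
case); the 2*k* threshold is the weakest precondition under which both
groups can be filled.

**Test.** A classical pooled-variance Student *t*-test (two-sided) compares
group burdens.  Welch would be the textbook-robust choice, but the screen's
groups are equal-sized (which largely neutralizes variance imbalance) and
the pooled test is the screen's defining statistic; Welch is available via
`student_t_test` callers that pass unequal groups if needed.  Degenerate
inputs follow fixed conventions rather than propagating NaN: both groups
constant and equal → *t* = 0, *p* = 1; constant but unequal → flagged
degenerate (*p* = 0 path) and barred from the significant lists; fewer than
two usable values per group → the gene is excluded.

**Multiplicity.** q-values are computed *within each channel's family*
(three families), because the six lists are reported per channel; a
`pool_channels` flag merges the families for users who prefer one.  The
default estimator is Storey's: π̂₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ = 0.05…0.95, smoothed by a cubic polynomial and read off at λ = 0.95,
clamped to (0, 1]; q(i) = min over larger p of π̂₀·m·p(i)/rank.  For
families under 100 tests the smoother is unstable and the estimator falls
back to π̂₀ = 1, i.e. Benjamini–Hochberg, which is also available
explicitly (`method="bh"`).  Calibration at m = 20,000 uniform p-values
puts π̂₀ within [0.9, 1.1].

**Classification.** A significant gene is a facilitator in a channel when
its high-expressor group shows the larger mean burden, a suppressor when
smaller.  By construction a gene cannot occupy both directions of one
channel; it may legitimately appear in several channels.

## Covariate balance check

For each screened gene, the 2*k* extreme subjects are compared with the
remaining cohort on three covariates: 4-level tumor stage with the
Fisher–Freeman–Halton exact test on the 2 × 4 table, gender with the
Pearson chi-squared test *without* continuity correction, and age with the
two-sample Student *t*-test.  The plain chi-squared is kept even when cell
expectations fall below 5 (a warning is logged) — fidelity to the named
test over optimality.  The exact 2 × c p-value is the total null
probability of tables no more probable than the one observed, computed by
full enumeration of the margin-constrained grid (always feasible here: the
included margin is 2*k* = 20, ≤ 21³ tables); a seeded Monte-Carlo fallback
(10⁵ multivariate-hypergeometric draws) covers tables beyond the
enumeration budget.  q-adjustment is per covariate family across genes.
Subjects missing a covariate are dropped from that covariate's test only.

## Stage 2 — the survival screen

**Altered status.** altered ⇔ GISTIC call = ±2 or ≥1 mutation record for
the gene; ±1 calls never confer altered status, and a missing call
contributes nothing.  Either source alone suffices (the union rule, as in
cBioPortal's oncoprint convention).

**Subjects.** The survival stage runs on the intersection of the CNA,
clinical and mutation sample universes; a MAF-like table only lists mutated
samples, so its universe is taken as the distinct sample barcodes present
(complete in practice at the generator's default mutation rate, and a
conservative choice on real files where a barcode absent from the MAF
usually was not sequenced).

**Covariate pre-selection.** Each of age (continuous years), race
(White/Other) and stage (categorical, indicator-coded with stage 1 as
reference) is screened by a univariate Cox fit on complete cases: Wald *p*
for the single-coefficient terms, a 3-df likelihood-ratio *p* for the stage
block.  Covariates with *p* < 0.05 enter every per-gene model.
Zero-variance covariates are unselectable; at least 10 events are required
for the stage to run at all.

**Per-gene model.** lifelines' Cox partial-likelihood maximization with
Efron tie handling (ties are common at month resolution).  Degenerate
situations — no altered or no unaltered subjects, all events on one side
(monotone likelihood), non-convergence, |β| > 15 — yield a flagged result
that can never pass the screen, rather than an exception or a wild
estimate.  Complete-case analysis per model.  Scale invariance (time
rescaling leaves HR and *p* unchanged) and agreement with an independent
proportional-hazards implementation (coefficients to 10⁻⁴ relative on
random datasets) are enforced by tests.

**Expression gate.** Wilcoxon rank-sum on altered vs unaltered expression,
exact null when both groups have ≤ 25 tie-free values, otherwise the normal
approximation with tie correction; direction = `over` when the altered
group's median (mean on median ties) is higher.

**Pass rule.** `passes_screen` ⇔ Cox Wald *p* < 0.05 AND Wilcoxon
*p* < 0.05 AND non-degenerate fit.  The conjunction is this package's
reading of a two-test survival screen; candidates default to the union of
all six stage-1 lists, with `all_cna` (total-channel lists only) as the
alternative, and `adjust="bh"` optionally replaces both raw gates with
BH-adjusted ones.  No multiplicity adjustment is applied by default in this
stage — it reports raw *p* gates, which is the appropriate reading for a
hypothesis-generating second screen over an already-filtered list.

## Over-representation analysis

One-sided hypergeometric test per GMT set: p = P(X ≥ k) for X ~
Hypergeom(M, K, n), BH-adjusted across sets.  The universe defaults to the
genes that entered stage 1 (post all-missing exclusion) — conditioning on
testability, not the whole genome.  The module is a generic open
replacement for proprietary pathway tools: on real data its p-values
characterize over-representation against the user's own collections, not
any vendor knowledge base.

## The synthetic cohort generator

The generator emulates the *structure* of a PanCancer-Atlas download, not
its biology.  Per subject and channel c ∈ {amp, del}, a latent instability
score z ~ N(0,1) sets a negative-binomial burden count with mean
`base_rate·exp(σz − σ²/2)` (normalized so the mean burden equals the base
rate; σ = 0.5, dispersion 8 give the heavy right tail real CNA burdens
show).  Calls land on uniformly chosen genes, magnitude 2 with probability
0.2.  Planted gene expression is `±β·standardized(burden) + √(1−β²)·noise`,
so `effect_beta` (default 0.6, sign = direction) is exactly the
expression-burden correlation; null genes are standard normal, and 1% of
genes are all-missing.  Mutations are Bernoulli(0.01) per gene × subject.

Survival-effect genes are drawn round-robin from the planted screen-positive
roles (so the two-stage funnel has nonempty truth), receive extra
alterations in a Bernoulli(0.2) subject subset (mutation or ±2 call with
equal probability), and shift those subjects' expression by 1.5 z-units in
the alteration's direction — amplified genes overexpress, deleted genes
underexpress.  Without that coupling the Wilcoxon gate would have only
α-level power on genes whose hazard effect is real, which would misrepresent
the biology the screen targets (high-level amplification drives expression).
The death hazard is `h₀·exp(Σ log HR·altered + 0.02·(age−65) +
0.3·(stage−1))` with exponential event times and independent exponential
censoring whose rate is solved (Brent) so the expected censored fraction
matches `censoring_rate` (0.35).  Defaults: 2,000 genes × 200 subjects,
20 planted genes per role, burden base rate 80 per channel, six survival
genes at HR 2.5 (×4) and 0.4 (×2), baseline hazard 0.01/month, age
N(65, 10²) clipped to [30, 90], stage probabilities (0.45, 0.25, 0.2, 0.1).
Everything is drawn from one seeded generator, so a config reproduces its
cohort bit-for-bit.

**What the generator does not emulate** — and hence what passing tests do
not establish about real cohorts: genomic coordinates, segment and arm
structure (calls are independent across genes given the burden count),
realistic driver-gene spectra, co-occurrence/mutual-exclusivity of
alterations, batch effects in the z-scores, sample-vs-patient id
discrepancies, and any nonlinearity in the expression-burden relationship.
Recovery rates measured here are statements about the screen's statistical
machinery under a known linear coupling, not about biological sensitivity.

## Validation-study problem sizes

The calibration and recovery studies (`gecna.validation`, driven by the
test suite and `scripts/acceptance.py`) use: 10,000 replicates for t-test
type-I error (normal and negative-binomial burdens); 10 seeds of the
2,000 × 200 global-null and planted-recovery screens; 50 cohorts of
*n* = 500 for Cox ln-HR recovery (tolerance ±0.35 around ln 2); 20 random
datasets for the independent-reference cross-check; and 10 seeds of the
full two-stage funnel at *n* = 500, HR 2.5, altered fraction 0.2.  These
sizes put Monte-Carlo error comfortably inside each study's stated band
while keeping a full run in the minutes range on one CPU.

## Known limitations

* The Storey smoother uses a cubic-polynomial fit rather than a smoothing
  spline; at genome scale the two agree closely, and small families fall
  back to BH regardless.
* The screen has no continuous (correlation/regression) variant: it is an
  extreme-group design by definition, and a gene whose coupling is confined
  to mid-distribution expression will be missed.
* Stage-2 power depends on the altered fraction; genes altered in a handful
  of subjects yield wide, often degenerate fits and are reported as such
  rather than suppressed.
* One sample per patient is assumed; no barcode truncation or
  sample-to-patient reconciliation is attempted (exact id matching only,
  to avoid silent mis-joins).
* Enrichment results on real data are relative to the user-supplied GMT
  collection and the screened universe; they are not comparable to
  proprietary pathway-tool outputs.
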