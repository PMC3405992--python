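# Methods

## The crossover model

Each bivalent receives crossovers from two independent point processes on
its genetic map (cM scale):

* **Class I (interfering).** A stationary renewal process whose
  inter-event spacings are Gamma(ν, θ) with shape ν =
  `interference_shape` and mean spacing 1/λ₁ (θ = 1/(λ₁ν)). ν = 1 is a
  homogeneous Poisson process (no interference); larger ν spaces events
  more regularly. The first event is drawn from the length-biased
  equilibrium (forward-recurrence) distribution, whose CDF
  F_e(x) = (x·S_ν(x) + μ·F_{ν+1}(x))/μ is inverted on a dense grid, so
  that the expected count in any window is exactly λ₁ × window length —
  no edge artefacts at the chromosome ends.
* **Class II (non-interfering).** A homogeneous Poisson process with
  intensity λ₂.

All simulation is on the genetic scale; physical (bp) coordinates of the
fluorescent inserts are metadata only, because every estimation target is
in cM.

**Chromatid assignment.** Each crossover joins the two homologs: it picks,
uniformly and independently, one strand currently carrying each parental
allele at its position and exchanges their distal continuations. This is
the standard no-chromatid-interference convention and yields the classical
tetrad-type chain — PD → TT; TT → (¼ PD, ½ TT, ¼ NPD); NPD → TT — whose
low-order consequences (one CO ⇒ TT always; two COs ⇒ 1 : 2 : 1) the test
suite checks against exhaustive 4ᵏ enumeration. An earlier formulation
that exchanged fixed physical chromatids regardless of local allele
content was rejected because it violates these invariants (a CO between
two strands locally carrying the same parental allele would be
genetically silent).

**Obligate crossover.** When `obligate_co` is set, whole-bivalent draws
are rejection-sampled until at least one event exists. Rejection
conditioning inflates the expected interval CO count by 1/(1 − p₀), where
p₀ is the empty-bivalent probability (3–4 % under wild-type intensities on
a 110 cM chromosome) — a distortion of the same order as the estimation
SEs at realistic sample sizes. Parameter-recovery and independence-null
simulations therefore run unconditioned (`obligate_co=False`); obligate
mode is intended for cytology-level simulation, where it guarantees zero
univalents. In the analysis drivers the obligate guarantee is applied only
to genotypes with an intact class I pathway, reflecting its mechanistic
basis; with all pathways ablated (*spo11*) the constraint is vacuous and
the simulator emits univalent-only cells.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| total intensity λ₁+λ₂ | 0.02 | CO/bivalent/cM | 2 CO per Morgan: each CO involves 2 of 4 chromatids, so map length = 100 × E[CO]/2 |
| class I : class II split | 0.85 : 0.15 | — | class-I-null mutants retain ~10–15 % of COs genome-wide |
| `interference_shape` ν | 5 | — | free calibration knob; no measured value exists for these intervals. ν = 5 gives interval-level interference ratios ≈ 0.4, in the observed range |
| genome | 5 chromosomes, 80–120 cM | cM | ~500 cM total male map, ~10 CO/meiosis |
| markers | R 60, Y 82.84, C 95.69 on Chr5 | cM | interval lengths equal the measured wild-type I5a/I5b distances |
| `mer3`/`mlh1` class I multipliers | 0.3 / 0.45 | — | placeholders for partial class I loss; fit to your own data before quantitative use |

## Calibration for parameter recovery

The Perkins estimator d = 100(TT/2 + 3 NPD)/n is unbiased only up to two
COs per interval; for k ≥ 3 the expected contribution E[TT/2 + 3 NPD | k]
falls below k/2 (¾ instead of 1.5 at k = 3), giving a downward bias of
~0.2 cM at a 22.84 cM interval under the default model. Recovery studies
therefore rescale the total intensity so that the *expected Perkins
distance* — computed analytically from the stationary-renewal count
distribution (numerical convolution of the equilibrium first-interval law
with gamma sums), the Poisson class II counts, and the type chain —
equals the generating truth (`calibrate_to_distance`; a ~0.4 % intensity
increase at default parameters). The analytic expectation is cross-checked
against simulation in the tests.

## Estimation stages

* **Classification** restricts each spore to the two markers of an
  interval; any marker not segregating 2 : 2 excludes the tetrad (counted,
  never imputed — the FTL assay scores only clean quartets). Results are
  invariant to spore order; relabelling one marker's alleles swaps
  PD ↔ NPD and fixes TT (asserted exactly in tests).
* **Perkins SE** uses the multinomial delta method,
  Var(d) = (100²/n)[p_TT/4 + 9p_NPD − (p_TT/2 + 3p_NPD)²].
* **Interference** conditions on a recombination event (TT or NPD) in the
  adjacent interval. The primary independence test is a G-test of
  homogeneity on the 2 × 3 stratum-by-type table (zero columns dropped;
  degenerate tables return p = 1); a percentile bootstrap CI on the ratio
  (default 10,000 resamples) resamples the 9-cell joint classification,
  which is equivalent to resampling whole tetrads. Empty strata or a zero
  denominator yield a flagged, NaN ratio rather than an exception.
* **SNK grouping** uses the step-down studentized-range procedure on
  sorted means with harmonic-mean group size for unbalanced designs;
  exact mean ties are never declared different. When the pooled
  within-group variance is zero, any mean difference separates groups.
* **Welch tests** are computed from (mean, SD, n) summaries with
  Satterthwaite degrees of freedom; both-degenerate SDs with equal means
  return p = 1 by convention. Welch is the default (pooled-variance
  results differ negligibly at the reported group sizes).

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the estimators assume:
2 : 2 segregation, the tetrad-type chain, stationary interval counts,
pathway-specific interference, rod/ring chiasma scoring capped at 2 per
bivalent, and per-genotype pathway ablation. It does **not** model gene
conversion or NCO tracts, aberrant (non-2 : 2) tetrads (real FTL datasets
contain a few; the I/O layer flags them on read), viability selection
against unbalanced spores (which biases real mutant tetrad data relative
to chiasma counts), sex differences, intra-genome intensity variation, or
physical-distance effects. Passing tests therefore demonstrate the
correctness of the estimation machinery under the model, not the fidelity
of the model to any particular organism.

Two known quantitative gaps follow from the fixed genome-wide 0.85 : 0.15
split: simulated wild-type cells average ≈ 7.6 chiasmata (measured Col-0:
9.2 — the default 500 cM genome is shorter than the effective Col-0 male
map), and simulated class-I-null interval distances (≈ 3.8 cM for I5a) are
below the measured 7.76 cM, because the residual class II share in these
particular intervals exceeds the genome-wide average. Neither quantity is
an estimation target; both are documented rather than tuned away.

## Numerical choices

* Equilibrium sampling by inverse transform on an 8192-point grid covering
  1 − 10⁻¹² of the mass; renewal count CDFs by trapezoidal convolution on
  4001-point grids (errors ≪ 10⁻⁶, far below Monte-Carlo noise).
* The batch simulator processes events rank-by-rank, fully vectorised over
  meioses; it is distribution-identical to the per-bivalent object path
  (checked by a frequency-comparison test).
* Reproducibility: one master seed per run; per-chromosome streams are
  spawned from a `SeedSequence`, so outputs are byte-identical across
  repeats of the same configuration.
* Reported precision follows print convention (2 decimals for cM and
  ratios, nearest integer for residual percentages, 1 decimal for folds);
  all internal computation is full precision.

## Problem sizes

The shipped analyses use 11,672 wild-type and 3,127 mutant tetrads (the
experimental sample sizes), 100,000 tetrads for the independence null,
100 × 11,672 tetrads for recovery coverage, and 150–2,000 cells for
cytology summaries — the scale at which the estimators' SEs match the
published precision.

## Known limitations

* The interference ratio is a conditional-distance summary, not a full
  interference model fit; ν is not estimable from it alone.
* The aggregate Ws-background arithmetic (n-weighted mean of four allele
  means: 0.6387 chiasma/cell, 11.6-fold, 8.6 % residual) is reported as
  computed; aggregates obtained with other weightings round differently.
* SNK letter displays can be non-transitive in pathological mean
  configurations (a property of the procedure, not of this
  implementation).
* With `obligate_co` on and only a very weak pathway active, rejection
  sampling is exact but slow (acceptance ≈ 1 − e^{−λL}); the guard raises
  after 10⁶ rejections.
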