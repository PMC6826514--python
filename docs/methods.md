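# Methods

This note documents the statistical model behind `genefabric`, the
conventions chosen where the methodology admits more than one reading, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Design assumptions

The analysis targets a replicated, redundant-probe expression design:
each condition profiled in *n* biological replicates (default 4), each
transcript probed by *R* = 1..28 spots per array.  Biological replicates
are treated as the same system under slightly different micro-environments;
coordination is therefore always computed *within* a condition, across its
replicates, never across conditions.

## Spot filtering

A spot is disqualified from **all** samples if it (in rule order)
is a control spot, is flagged corrupted in any sample, or has foreground
fluorescence strictly less than `snr_factor` (default 2.0) times the local
background in any sample or channel.  The strict inequality matters at the
boundary: foreground exactly twice the background survives.  Filtering is
idempotent, and a ragged design (a spot present in only some samples) is a
structural error rather than a silent drop.

Two channels collapse into one expression value as background-subtracted
foreground, clipped at a small positive floor (default 1e-6), combined by a
configurable rule — channel 1 only (default), channel ratio, or geometric
mean.  The combination rule is a dialect option because scanner
conventions differ; nothing downstream depends on it.

## Iterative median normalization

Each iteration applies (i) an inter-array step — every array is divided by
the median of its spot-wise ratios to the per-spot cross-array median
reference — then (ii) an intra-array step — every array is divided by its
median of valid spots, so converged output always has unit array medians
exactly.  Iteration stops when the maximum absolute relative change of any
value between successive iterations ("overall maximum error of estimate",
implemented as max |v_new − v_old| / v_old) falls below the tolerance
(default 0.05).  Because the inter-array step is scale-free and the
intra-array step removes any global factor, the result is exactly invariant
under global positive rescaling of the input.  Non-convergence raises with
the full error trace attached.

**Regime note.**  Median normalization assumes the array median is
dominated by many uncoordinated spots (real arrays: tens of thousands).
In small simulations (≲ a few hundred spots) the median itself fluctuates
with the latent-factor draws, injecting a shared per-replicate component
that attenuates — in extreme cases inverts — negative pair correlations.
Tests and examples that exercise coordination after normalization therefore
use enough background genes and a moderate spread of base levels; the
recovery experiments that probe the estimators themselves (REV calibration,
sign recovery) run on the generator's output directly.

## REV

REV_i = C(R_i) · 100 · sqrt((1/R_i) Σ_k (s_ik/μ_ik)²): the pooled per-spot
CV (sample SD, n−1 denominator, divided by the spot's replicate mean)
multiplied by the mid chi-square interval factor for ν = 4R_i − 1 degrees
of freedom at significance level ε (default 0.05).

The default convention for C(R) is the midpoint of the confidence interval
for a standard deviation,

    C(R) = ½ ( sqrt(ν/χ²(ν; 1−ε/2)) + sqrt(ν/χ²(ν; ε/2)) ),

giving C(1) ≈ 2.148 and C(28) ≈ 1.018; a variance-interval variant (no
square roots) is also supported.  Both are positive and monotone
non-increasing in R, so redundant probing always tightens REV.  Endpoint
values quoted in parts of the methodology literature (1.566 at R = 1, 0.960
at R = 28) do not correspond to either standard convention; rather than
absorb the discrepancy silently, the convention in force is recorded in the
pipeline manifest, and no code path calibrates to those endpoints.

## Coordination

Per gene and condition, the replicate profile is the mean over its
redundant spots of the normalized value in each replicate, log₂-transformed
by default (configurable; the package's own worked example uses raw values,
where the printed correlations reproduce exactly).  Pearson ρ between two
profiles is tested two-tailed against Student's t with

    df = n_replicates · R − 2,

R being the common redundancy, or min(R_i, R_j) when they differ (an
all-pairings rule, df = n·R_i·R_j − 2, is available but off by default —
it overstates the information).  The critical threshold is
t*/sqrt(t*² + df).  Classification: POS if ρ > threshold, NEG if
ρ < −threshold, IND if |ρ| < 0.05 (the "significantly uncorrelated" class,
operationalized as a configurable near-zero band because no closed-form
criterion exists for it), otherwise UNCLASSIFIED.  Undefined correlations
(constant profiles, missing genes) surface as UNCLASSIFIED records — the
record count always equals the enumerated pair count.

No multiple-testing correction is applied across distinct pairs; the only
Bonferroni-style correction in the package is within a transcript's
redundancy group (see regulation calls).  Note that the df rule credits
redundant spots with independent information; when spot-level noise is
small relative to replicate-level variation the effective sample size
remains the number of replicates, so nominal significance at high R is
optimistic.  This is a property of the method, reproduced faithfully.

A coordination reversal is a pair classified POS in one condition and NEG
in another; pairs merely losing significance are not reversals.

## Regulation calls (surrogate)

Differential-expression calling is not this package's contribution; a
simple, clearly-labeled surrogate is provided so networks can be annotated:
fold change = ratio of combined means (negative-reciprocal convention below
1), p-value from a heteroscedastic (Welch) t-test on the pooled
spot × replicate values, corrected p = min(1, R·p) — Bonferroni over the
redundancy group only — and status UP/DOWN iff |fold| ≥ 1.5 and corrected
p < 0.05 (both configurable).  Outputs carry a `method` field marking them
as surrogate.

## PWR

PWR_ij = (μ_i μ_j/μ̄²) · ρ_ij² · (REV̄²/(REV_i REV_j)), with μ̄ and REV̄
arithmetic means over **all** N quantified unigenes of the condition, not
over the analyzed subset — this choice changes absolute scores and is fixed
by the definition of the fabric means.  ρ enters squared and ungated: a
pair's PWR does not depend on whether its correlation cleared the
significance bar.  The score is symmetric, invariant under global
rescaling of expression levels and of REVs, and bounded by its
expression × control factors since ρ² ≤ 1.  Zero REV is a domain error in
direct scoring; in batch scoring such genes yield flagged NaN records.
Ranking ties break lexicographically by pair key, making top-k extraction
deterministic.

## Networks

One node per gene-set member (isolates retained, annotated UP/DOWN/NC,
defaulting to NC), one edge per POS/NEG record with sign and ρ as
attributes.  IND and UNCLASSIFIED pairs contribute no edge.  GraphML
export round-trips losslessly (ρ to float precision); TSV and DOT writers
are provided for interchange and quick rendering.

## Synthetic data

The generator emulates the target study design — 5 conditions
(unstimulated, two stimulation patterns × two durations) × 4 replicates,
truncated-geometric redundancy over 1..28 (most genes single-spot),
log-normal base levels (default sd 1.5 log₂ units ≈ a 3-decade dynamic
range), replicate CVs of order 5–15%, scanner-scale foreground counts over
a gamma-distributed background — and injects configurable fractions
(default 2% each) of control, corrupted and low-signal spots for filter
testing.

Noise is log-additive: on the log₂ scale a replicate value is base +
factor + idiosyncratic noise, with one standard-normal factor draw per
(module, replicate) shared by all member genes.  A module's `strength` is
the variance fraction explained at unit loading, so two members with
loadings l_g, l_h have true replicate correlation l_g·l_h·strength;
claiming more variance than the total is a config error.  The log-normal
σ for a programmed CV is sqrt(ln(1 + cv²)), divided by the Gaussian
small-sample factor c₄(n) so that the *expected measured* sample CV at the
design's replicate count equals the programmed value (the raw σ would make
the n = 4 sample CV read ~8% low on average — an estimator-bias artifact,
not a property of the data).  Spot-level noise is independent across a
gene's spots, which is precisely the structure that motivates the
redundancy-based df gain.

Not emulated: spatial array artifacts, dye bias, probe-sequence effects,
intensity-dependent (loess-type) trends, and background that bleeds into
the signal (background subtraction is exact by construction).  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise model, not robustness to scanner pathologies.

## Problem sizes

The test suite and the reproduction script run simulations of 500 genes
(REV calibration), 30 designated pairs at redundancy 2 (sign recovery), and
60–120-gene two-condition studies (pipeline, reversals); these sizes put
the estimators in their intended regime while keeping any run under a few
seconds.  Transcriptome-scale pair enumeration (~10⁸ pairs) is supported
combinatorially and via iterators; dense all-pairs correlation at that
scale is deliberately not the default and sits behind an explicit pipeline
flag.

## Numerical choices

* Sample SDs everywhere use the n−1 denominator.
* Correlation of constant profiles is NaN, never ±1; p-values for |ρ| = 1
  are exactly 0.
* Normalization tolerance is a relative change (unitless fraction);
  convergence in one iteration means the input was already a fixed point.
* Pair keys are canonical (lexicographic), so unordered pairs cannot be
  double-counted and reversal detection is order-independent.
* All simulation randomness flows from one integer seed through one
  `numpy` generator; identical config + seed is bit-identical output.
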