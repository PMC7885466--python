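# Methods

## Poisson quantification of droplet counts

Each ddPCR well partitions the reaction into `n` droplets (default
volume 0.85 nL, the QX200 standard; overridable per well). Target
molecules load independently, so occupancy is Poisson and the mean
copies per droplet is estimated from the positive fraction `p̂` as
`λ̂ = −ln(1 − p̂)`; concentration in copies/µL is `λ̂ / v_nL × 1000`.
The 95% CI is a normal approximation with the asymptotic variance
`(e^λ̂ − 1)/n`, the common choice in ddPCR software; we do not invert an
exact binomial interval, and the CI method name is recorded in every
estimate so downstream records are auditable. One numerical special
case: at zero positive droplets the asymptotic variance collapses to
zero, so the upper bound falls back to the rule-of-three limit
`−ln(1 − 3/n)`, giving blank wells a non-degenerate detection bound. A
fully positive channel raises a saturation error rather than returning
infinity — the estimate is unbounded and the assay must be diluted.

Replicate wells are pooled by summing their 2×2 droplet tables before
Poisson correction (the maximum-likelihood treatment); averaging
per-well λ̂ values is biased at high occupancy and is deliberately not
offered.

Duplex wells treat double-positive droplets as positive on both
channels: the two targets occupy droplets independently (independent
amplicons, no probe competition — competitive duplex designs are out of
scope). Allele fractions `λ₁/(λ₁+λ₂)` and copy-number ratios
`k·λ_t/λ_ref` carry first-order (delta-method) CIs derived from the
stored λ CIs; a seeded parametric-bootstrap CI is available behind a
flag for the fraction, mainly as a cross-check, and agrees with the
delta interval to ~0.01 at typical depths. The delta method treats the
two channels as uncorrelated; for independent targets the droplet
cross-category covariance is exactly zero (verified empirically in the
test suite at the level of CI coverage: 94–95% observed for λ, MAF and
CN at 20,000 droplets).

## Clone models and cell-fraction arithmetic

A clone model is an ordered list of populations: the first is healthy
and carries the germline genotype at every locus; each later clone
descends from its parent (the previous population by default, i.e. a
linear chain — the only topology the case study requires; branching is
representable by naming parents but is never inferred automatically).
Populations list allele copy numbers only for loci where they differ
from the parent; inheritance fills in the rest. Loci are declared with
their germline allele copies (`{"mut": 0, "wt": 2}` for a somatic
mutation, `{"A": 1, "B": 1}` for a heterozygous SNP), so "somatic
allele" and "germline copies" are derivable rather than redundant
fields.

Aberrations are modelled as single-copy events: a loss in a fraction
`f` of cells moves the bulk copy number to `2 − f` and a gain to
`2 + f`, so `f` is read off affinely from the CN estimate (CI mapped
through the same transform, clipped to [0, 1]); a direction
inconsistent with the CN interval raises an error rather than returning
a clipped zero. At a heterozygous SNP the same fractions come from the
allele ratio `r = λ_affected/λ_retained` via `f = 1 − r` (loss) or
`r − 1` (gain). Multi-copy events must be written explicitly into the
clone model's copy numbers.

The copy-number-corrected mutant cell fraction uses the chain-model
identities

    MCF = 2·MAF,   MAF·(2 − L),   MAF·(2 + G) − G

for the diploid, wild-type-loss and mutant-gain cases, with first-order
variance propagation of both inputs. A result outside [0, 1] beyond its
CI raises an inconsistent-measurements error (the MAF and CNA estimates
cannot both be right); small overshoots within the CI are clipped.

## Deconvolution

Every supported observation is linear in the mixing proportions `w`:
copy number is `(2/g)·t·w` with `t` the per-population locus totals;
aberrant-cell fractions weight populations by the magnitude of their
deviation from germline in the stated direction; mutation-positive cell
fractions are indicators of carrying ≥1 mutant copy; and an allele
fraction `v` becomes the homogeneous row `(c − v·t)·w = 0`. The system
is solved on the simplex by weighted least squares (weights = inverse
CI-derived variances; the homogeneous MAF row is weighted by
`1/Var(v)`, which ignores a `(t·w)²` factor — immaterial for determined
systems, an approximation for overdetermined ones). The sum-to-one
constraint is eliminated through a null-space parameterisation and the
reduced system solved by minimal-norm least squares, which returns the
exact solution whenever the observations determine `w` and breaks
rank-deficient ties minimally; only if a proportion comes out negative
does the solver fall back to non-negative least squares with a heavily
weighted sum-to-one row. Negativity beyond 0.05 in the unconstrained
solution is treated as model mismatch and raised, not silently clipped.
Identifiability is checked up front by the rank of the stacked design;
the error names the confounded populations from the null-space vector.

Per-population CIs come from a parametric bootstrap (default 200 draws,
explicit seed recorded in the result): each observation is resampled
from a normal with its CI-derived SE, the design rebuilt (MAF rows
depend on the resampled value), and percentile intervals taken. On
simulated 20,000-droplet tumours this yields ~94–95% per-proportion
coverage; the joint event that all three proportions of a
healthy/clone I/clone II mixture are covered at once runs near 91%,
which the acceptance-level recovery test checks with 500 bootstrap
draws (quantile Monte-Carlo noise at 200 draws costs about a point of
joint coverage).

## Event ordering

Events are grouped by pairwise two-sided two-proportion z-tests on
CI-derived standard errors at α = 0.05 (the study reports only
"significantly smaller", so the test is this package's choice);
non-significant pairs are merged transitively (connected components),
making the grouping permutation invariant. Groups are sorted by
descending mean cell fraction; the top group is labelled clonal, the
rest subclonal. With one event the result is a trivial clonal group,
not an error.

## Allelic expression

Count-based allele fractions use Wilson score intervals (better
small-count behaviour than Wald; λ-based fractions keep delta intervals
and the two sources are labelled by `ci_method`). The RNA-vs-DNA test
is a two-proportion z-test on the raw counts, except under a known
copy-number change where the proportional-expression null is a fixed
expected RNA fraction tested by an exact two-sided binomial test.
Identical count pairs short-circuit to p = 1 regardless of depth.
Samples are tested independently by default, matching per-tumour
reporting; Benjamini–Hochberg correction is available behind a flag.
Measured type-I error of the z-test route is 4.4% at α = 0.05 over
5,000 null replicates at depth 2,000.

## Synthetic data

The simulator is the package's source of ground-truthed data, since raw
per-well droplet counts are not published for the motivating
experiments. Droplet generation draws the 2×2 classification table from
a multinomial with cell probabilities `p_i = 1 − e^{−λ_i}` multiplied
independently across channels — exactly the model the estimators
assume. Tumour simulation scales forward-model allele averages so that
a diploid locus loads `input_copies_per_assay` copies per well (default
15,000 copies in 20,000 droplets, λ ≈ 0.75 for a diploid locus — the
assay sweet spot, consistent with "thousands of alleles per target");
it emits one duplex well per two-allele locus and one copy-number well
(target vs an in-well diploid reference) per locus. DNA allele counts
are binomial on the average allele copy fractions; RNA counts are
binomial at a fixed depth with a per-copy expression weight `s` for
allele 1 (`p_RNA = s·c₁/(s·c₁ + (1−s)·c₂)`), so `s = 0.5` is
proportional expression and `s = 1` monoallelic. An optional
multiplicative lognormal pipetting factor (default off) is the only
extra noise source; pre-PCR degradation, amplification efficiency
differences, droplet "rain" and misclassification are *not* modelled.
Passing tests therefore show the estimators are correct and calibrated
under Poisson partitioning noise — not that they are robust to gating
artefacts or FFPE damage, which upstream droplet classification must
handle.

All simulators take explicit integer seeds and are bit-reproducible;
property tests on random chain models use one mutation locus plus one
private CNA locus per clone, which always yields an identifiable
design. Random test compositions are Dirichlet(1, …, 1) squeezed so
every population keeps ≥5% — mirroring the case study's range of
healthy fractions while avoiding the simplex boundary, where
"recovery" is ill-posed for an absent population.

## Problem sizes and determinism

Worked-example checks are closed-form and instantaneous. Calibration
tests use 2,000 wells (λ coverage), 200 random models (inversion
identity), 500 simulated tumours × 500 bootstrap draws (recovery), and
5,000 replicates (type-I error); all run from fixed seeds and complete
in about a minute together. Reports round percentages to whole numbers
for display only; JSON output keeps full precision, and re-running any
pipeline with the same inputs and seed is byte-identical.
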