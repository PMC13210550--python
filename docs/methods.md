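# Methods

This note documents the statistical models behind `bromeval`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Synthetic trial generator

`synthetic_data.generate_trial` draws a balanced factorial table

    y_{gybj} = μ_j + α_{gj} + τ_{yj} + (ατ)_{gyj} + b_{bj} + ε_{gybj}

for genotype g, year y, block b and indicator j, with
ε ~ N(0, σ_j²) i.i.d. and block effects b_{bj} ~ N(0, (c·σ_j)²).  The
block SD multiplier c (`block_sd`) is expressed in units of the indicator's
residual SD because the 15 indicators span four orders of magnitude (leaf
width in cm versus fresh yield in tens of thousands of kg·hm⁻²); a single
absolute block SD would be meaningless across them.  All effects are
additive shifts specified directly — interaction cells are not derived from
marginals and no sum-to-zero constraint is imposed; the ANOVA handles
coding (irrelevant in the balanced case).  Records are plot-level means,
the grain at which such trials are analyzed.

The default spec emulates a 5-genotype × 3-year × 4-block trial with
realistic baselines (plant height ≈ 100 cm, hay yield ≈ 15,000 kg·hm⁻²,
ADF ≈ 45 % DM), genotype contrasts of ±0.8–1.8 residual SDs with one
dominant and one weak entry, a peaked middle-year effect, and G×Y wobble up
to 2 residual SDs concentrated in a few cells (the dominant genotype gains
extra in the peak year; one entry swings between years).  Those magnitudes
make genotype, year and interaction terms detectable at the trial's size in
most replicates, matching the qualitative outcome of real multi-year
cultivar trials.  Draw order is fixed (block effects first, then residuals
in row order) so outputs are bit-reproducible across versions.  Generated
values must be strictly positive — the generator raises rather than
truncating, because the TOPSIS stage requires positive inputs; choose
baselines well above the noise scale.

What the generator does **not** emulate: skewed or heteroscedastic residuals,
spatial block structure, missing plots, measurement rounding, and
mechanistic weather-driven year effects.  Passing tests therefore
demonstrate correctness of the estimators under the Gaussian additive
model, not robustness to real-data pathologies.

`generate_sem_dataset` simulates a linear-Gaussian DAG in topological
order.  Exogenous variables are standard normal; each endogenous variable
is the coefficient-weighted sum of its parents plus Gaussian noise whose SD
is, by default, solved from the model-implied covariance so the variable
has unit variance in expectation.  Planted coefficients are then directly
standardized path coefficients, and fitted β may be compared to them
without rescaling.  The genotype, year and G×Y inputs are represented as
continuous unit-variance scores in this generator (they act as generic
exogenous drivers); the reference yield-pathway model
(`yield_pathway_truth`) carries the seven standardized coefficients
(−0.52, 0.70, −0.24, 0.54, 0.29, −0.29, 0.79) of the G×Y-mediated
yield-formation structure.

## Quality indices

DDM, DMI, RFV and CP are the standard hay-evaluation formulas, applied to
percentages on the 0–100 scale.  Full precision is kept everywhere;
rounding to reporting precision (1 dp) happens only at the report layer —
e.g. `rfv(22.0, 42.0)` is 158.94, printed as 158.9.  Domain guards: ADF in
[0, 100), NDF > 0 (divisor), N ≥ 0.  "CF" is treated as an opaque
benefit-type indicator (field usage is ambiguous between crude fat and
crude fiber) and never computed.

## Trial statistics

*Normality.* The Lilliefors statistic is the KS distance to a normal with
estimated mean/SD.  Its p-value is Monte-Carlo: a null table of the
statistic is simulated once per sample size (fixed internal seed, 10,000
replicates by default, memoized) and p = (#{null ≥ obs} + 1)/(N + 1).  The
p therefore carries ≈ ±0.01 simulation noise at the default size.  A group
"passes" when p ≥ 0.05, or marginally (0.01 < p < 0.05) with |skew| < 2 and
|excess kurtosis| < 7.

*Variance homogeneity.* Median-centred Levene (Brown-Forsythe), delegated
to scipy.  It is conservative for very small groups (measured type-I rate
≈ 0.037 at n = 20/group, ≈ 0.043 at n = 30); calibration checks use
n = 30 per group, the smallest size at which it runs near nominal level.

*ANOVA.* The one- and two-way tables are computed directly from cell means
under an explicit balanced-complete contract (equal replication in every
cell); unbalanced input raises.  In the balanced case all classical SS
types coincide, so no coding choice is needed.  Effect sizes are partial
η² = SS_term/(SS_term + SS_error).  Block is treated as replication, not
modeled — the generator's block variance simply inflates the residual.

*Protected LSD.* LSD = t_{1−α/2,df_e}·√(2·MSE/n) from the one-way fit;
pairs are declared different only when the omnibus F is itself significant.
Compact letters exploit the equal-n structure: with a common threshold,
significance depends only on the gap between sorted means, so letter
groups are the maximal windows of sorted means spanning ≤ 1 LSD.  Ties in
mean break by ascending group label, making output deterministic.

*t-tests.* Pooled-variance Student t by default (consistent with the
balanced design and the LSD machinery); Welch available via a flag.

## Clustering and association

Genotype profiles are indicator means over all years and blocks, z-scored
per column (n−1 SD); constant columns are dropped with a warning.  K-means
uses k-means++ initialization, ≤ 300 Lloyd iterations and 25 restarts, each
run separately so the per-restart WSS trace is real and the returned
solution provably minimizes WSS among restarts.  k is selected by maximum
mean silhouette (ties to the smaller k) with the WSS elbow curve reported
for inspection; silhouette on fewer than 2k points triggers a warning
rather than an error, since genotype panels are tiny by nature.  PCA signs
are fixed by making each component's largest-magnitude loading positive.

The Mantel test correlates the strictly-lower triangles of two distance
matrices (Euclidean on z-scored trait subsets by default) and permutes the
objects of the second matrix; p = (#{r_perm ≥ r} + 1)/(n_perm + 1),
one-tailed "greater" by default because trait–yield associations are
directional hypotheses; a two-sided option exists.

## Entropy-TOPSIS

Implemented exactly as the four-stage scheme in the README.  Choices:

- **Positivity.** Proportion normalization and ln are undefined otherwise,
  so strict positivity is enforced; non-positive inputs must pass through
  the explicit `rescale_to_positive` min-max map to [0.05, 1].  Making the
  rescale a visible, loggable step (rather than silent) is deliberate.
- **Aggregation.** The decision matrix is the genotype × indicator table of
  means over all years and blocks; per-year matrices are equally valid
  inputs.
- **Cost indicators** (ADF, NDF, ash) are handled by direction at the
  ideal-solution stage, not by transforming the data.
- **Ties** in closeness share a dense rank.  Weights are reported at full
  precision; printed 2-dp weights may visibly sum to ≠ 1.
- Under entropy weighting, duplicating an indicator column changes the
  weights (information counted twice); column-scale invariance, by
  contrast, holds exactly because proportions are quotients.

Degenerate cases raise: all-uniform columns (no dispersion anywhere) and
fully identical alternatives (D⁺ = D⁻ = 0).

## Random-forest importance

The forest is bagged sklearn regression trees with the conventional
regression protocol (1000 trees, mtry = ⌊m/3⌋, node size 5, seed 123 by
default).  Bagging is done in the wrapper so each tree's out-of-bag indices
are explicit; the backend contract (fit, per-tree OOB prediction) is thin
and swappable.

%IncMSE permutes a predictor among each tree's OOB samples and reports
100 × (mean per-tree MSE increase)/(mean per-tree OOB MSE) — the percentage
by which scrambling the predictor inflates out-of-bag error.  Model fit is
pseudo-R² = 1 − OOB-MSE/Var(y), and "variance explained" is exactly
100 × pseudo-R².  A normalized importance vector (clipped at 0, rescaled to
sum to 100) is reported separately as per-trait contribution percentages.

Significance is by permutation with add-one correction.  The variable-level
null permutes one predictor's training values and refits, collecting that
predictor's %IncMSE.  The model-level null permutes the response and
refits, collecting pseudo-R².  A desk-scale mode (`scaled_down`: 200 trees,
199 permutations, 25-tree null refits) keeps the estimator identical while
bounding cost.  One subtlety: OOB R² rises systematically with tree count,
so the model-level test computes the observed statistic at the *null* tree
count whenever the null refits are reduced — mixing tree counts across the
comparison would be anticonservative (measured ≈ 23 % false-positive rate
at nominal 5 %).  The variable-level statistic is centred at zero under the
null regardless of tree count, so its one-sided reduction is merely
conservative.

## Piecewise SEM

The basis set contains one claim per non-adjacent variable pair,
conditioned on the union of both variables' parents (the standard union
basis set; other constructions exist).  The regression response for a
claim is the topologically later variable, ties broken lexicographically,
which also makes the set invariant to declaration order.  Pairs of
exogenous variables are claimed independent given the empty set.

Component models are OLS.  Continuous parents report
β = b·SD(parent)/SD(child) (sample SDs) and the coefficient-t p;
categorical parents enter as dummy blocks, with the partial-F p of the
block and no single β (NaN).  An interaction such as genotype × year can
instead be supplied as its own derived column when a single path
coefficient is wanted.  Fisher's C = −2 Σ ln p_i is referred to χ²(2k);
an empty basis set (saturated model) returns C = 0, df = 0, p = 1 with a
warning, and p_i underflowing to zero are floored at 1e-300 with a
warning.  Rank-deficient designs raise, naming the collinear parents.

Effects are decomposed over all directed paths: indirect = Σ over paths of
length ≥ 2 of the product of β along the path; total = direct + indirect.
Paths through categorical edges propagate NaN (no defined product).

## Pipeline

Stages run in a fixed order (validate → assumptions → ANOVA → clustering →
TOPSIS → importance → SEM), each writing CSV artifacts; a failure aborts
naming the stage.  Input validation is strict: required columns, numeric
indicator cells (a stray thousands separator is an error, not a coercion),
and unique (genotype, year, block) keys.  Reports contain no timestamps,
so a rerun with the same config and seed reproduces every artifact byte
for byte.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to give the assertions
comfortable statistical margins: path-coefficient recovery averages 50
replicates of n = 10,000; Fisher's-C calibration uses 100 replicates of
n = 400; forest protocol checks use 100 replicates of 60-record tables
with the desk-scale forest config; type-I calibrations use 1000 null
replicates; Monte-Carlo normality tables use 4000 null samples.  All seeds
are fixed in the tests.

## Known limitations

- ANOVA is fixed-effects and balanced-only; no mixed models, no missing
  plots, no multiple-testing correction beyond protected LSD.
- The SEM is linear-Gaussian per component; no latent variables, no
  covariance-structure (global ML) fitting, no non-Gaussian families.
- Entropy weights are the only weighting scheme (no expert/AHP weights).
- Clustering metrics on 5-genotype panels are fragile by construction; the
  package warns but does not refuse.
- The quality indices are the printed prediction equations; no wet-chemistry
  corrections (ash-free NDF, lignin).
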