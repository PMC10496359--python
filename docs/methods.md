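# Methods

## The selection test

The test asks, pair by pair, whether the correlation of two traits across
diverging lineages (COR_E) is compatible with the correlation produced by
mutation alone (COR_M).

COR_M is the Pearson correlation of standardized trait values across a
mutant panel. Standardization is the natural log of the ratio to a
reference phenotype (wild type for deletion panels, the progenitor for
mutation-accumulation panels), which makes morphological ratios
approximately normal. Rows with any missing value among the analyzed
traits are dropped listwise (with a logged count) rather than handled
pairwise, so that every pairwise correlation shares a single sample size
n_M — the quantity the Z-test needs.

COR_E is computed on phylogenetically independent contrasts. At each
internal node of the (binarized) rooted tree with child values x₁, x₂ on
adjusted branch lengths v₁, v₂, the contrast is (x₁ − x₂)/√(v₁ + v₂), the
ancestral value is the branch-length-weighted mean, and the parent branch
is extended by v₁v₂/(v₁ + v₂). Under Brownian motion the n − 1 contrasts
are independent with mean zero, so the evolutionary covariance is taken
**through the origin** (mean of cᵢcⱼ over contrasts); a `center=True`
switch provides the ordinary mean-centered covariance for sensitivity
analysis, since upstream implementations do not document their convention.
Multifurcations are resolved into zero-length binary splits (this leaves
the induced covariance unchanged); zero-length terminal branches are
floored at 1e-8 × tree height (configurable) to avoid division by zero;
trees with a basal polytomy are rejected as effectively unrooted.

Both correlations are Fisher-transformed and compared with
Z = (Z_E − Z_M)/√(1/(n_E − 3) + 1/(n_M − 3)), where n_E is the contrast
count (tips − 1) and n_M the mutant count. Two-sided normal P-values are
Benjamini–Hochberg adjusted across all pairs (default FDR 5%). Significant
pairs are classified:

* **strengthened** — same sign with |COR_E| > |COR_M|, or opposite signs
  with only COR_E significantly nonzero;
* **weakened** — the mirror image;
* **reversed** — opposite signs with both correlations significantly
  nonzero.

The per-correlation nonzero test is the Fisher-z test
z = arctanh(r)·√(n − 3), with n = n_M or n_E respectively, keeping the
whole machinery on one footing. Significant pairs matching none of the
three rule sets (e.g. opposite signs with neither correlation nonzero at
the nominal 5%) are reported as `unclassified` rather than forced into a
category; empirical datasets may never produce them, but synthetic data
can, and silently mislabeling them would corrupt counts.

Two controls accompany the scan: a random non-overlapping pairing control
(each trait used exactly once per repeat, removing the concern that reusing
every trait in many pairs biases the significant fraction) and a
random-draw overlap expectation for comparing significant-pair sets from
two different mutant panels (null mean k²/N for equal-size sets).

### Known calibration detail

n_E − 3 in the Z denominator is the variance appropriate for a correlation
that estimates two means. A through-origin correlation of n_E i.i.d.
contrasts has the slightly smaller Fisher variance 1/(n_E − 2), so the
test as specified is marginally conservative: on fully neutral synthetic
data the raw rejection rate at α = 0.05 measures ≈ 0.040–0.043 rather than
0.050. The convention n_E = tips − 1 with the −3 denominator is kept as
the method's definition.

## Neutral Brownian-motion null

To ask whether an observed number of significant pairs could arise without
selection, tip phenotypes are simulated along the same tree with the full
estimated mutational covariance matrix M as input (sampled jointly, so the
simulated matrices inherit realistic cross-pair dependence), COR_E is
re-estimated per dataset, and the scan is repeated against the fixed
COR_M. Two branch-length scalings are available for the per-branch
multivariate-normal increment:

* `as_printed` — increment = deviate × l (tip variance grows with Σl²);
* `standard` — increment = deviate × √l (canonical Brownian motion,
  variance ∝ Σl).

Every branch contributes covariance proportional to M under either rule,
so the pairwise correlations the test consumes are identical in
distribution up to branch weighting; `as_printed` is the default for the
count null. Note that under `as_printed` the contrasts of an asymmetric
tree are no longer exactly independent (the pruning variances assume
variance ∝ l), which can shift the null rejection rate slightly; on a
symmetric (balanced) tree the two scalings coincide exactly by symmetry.
The synthetic-data generator uses `standard` as its default so that
contrasts are exactly i.i.d. and injected ground truth is sharp.

## Integration and modularity

V_eigen is the population (divide-by-n) variance of the eigenvalues of a
correlation matrix: 0 for uncorrelated traits, n − 1 when all |r| = 1, so
V_eigen/(n − 1) is a relative integration index on [0, 1]. The
divide-by-n convention is what makes the relative index reach exactly 1.

CR contrasts between-module covariances (numerator trace(M₁₂M₂₁), the
squared Frobenius norm of the between block) with within-module
off-diagonal covariances. Two denominator variants are implemented and
always named in output: `as_printed` takes √(trace(M*₁₁M*₁₁) +
trace(M*₂₂M*₂₂)) (a sum inside the inner root), while
`product_denominator` takes the product, the form used in the
morphometrics CR literature. The product variant is scale-invariant;
the sum variant scales as c^(1/2) when the covariance matrix is scaled by
c. Printed sources are ambiguous between the two, so neither is asserted
as correct; with more than two modules the unweighted mean over module
pairs is reported.

Because a correlation matrix estimated from k samples has at most k − 1
positive eigenvalues, comparing V_eigen or CR between matrices estimated
at very different sample sizes is confounded. The rank-matched null
therefore subsamples k mutant lines (k chosen by the user to match the
rank of the evolutionary matrix) n_subsets times and recomputes the
statistic, and the observed value is located in that null with a
two-tailed empirical P: p = 2·min(q, 1 − q) with q the fraction of null
values strictly below the observed one, reported as the band "< 2/n_null"
when the observed value lies beyond every null value. (A centered Pearson
matrix from k samples has rank k − 1, not k; descriptions that equate the
two differ by one, which is why k is left to the user rather than derived.)

## Origin–fixation simulation of two coevolving traits

Evolution acts on the population mean phenotype of independent lineages,
starting at (0, 0). Per unit time, Poisson(1) pleiotropic mutations are
drawn from the bivariate normal with covariance
M = [[V_M, V_M·COR_M], [V_M·COR_M, V_M]], V_M = 0.01. Fitness is Gaussian,
f = exp(−D²/2), with D the Euclidean distance to a point optimum or the
shortest distance |y − kx|/√(1 + k²) to a ridge y = kx. The selection
coefficient is s = f_mut/f_wt − 1 and a mutation fixes with probability
min(1, N_e·P_f), P_f = (1 − e^(−2s))/(1 − e^(−2N_e·s)) for a haploid
population with N_e = 10⁴ (the neutral limit 1/N_e at s = 0, so without
selection every mutation fixes). Mutations within a time unit are
evaluated **sequentially**, the mean moving after each acceptance; s is
computed in log-fitness space, exp((D²_cur − D²_new)/2) − 1, which is
exact and avoids underflow far from the optimum.

Per cell, 50 lineages evolve for 1,000 time units and the Pearson
correlation of their final means is recorded; 200 repetitions give the
COR_E distribution. A significant COR_E vs COR_M difference is called when
COR_M falls in either 2.5% tail. The duration is not dictated by the
regimes themselves having a stated timescale: with ~1 fixation opportunity
per unit and mutational steps of s.d. 0.1, lineages cross the N(0,1)
optimum scale within tens of units, so 1,000 units is comfortably at
steady state; `check_steady_state=True` re-runs a cell at double duration
and warns if the median COR_E moves by more than 0.05. The verdict for a
cell calls a reversal only when the COR_E distribution itself excludes
zero (central 95%); a near-zero median of either sign under stabilizing
selection is a weakening, not a reversal.

Implementation note: lineages are vectorized across repetitions, with
mutations within a time unit processed in "slots" so that sequential
within-unit updates are preserved; in the no-selection case the final
displacement is drawn directly as a Poisson(T)-scaled normal, which is
distributionally identical to the stepwise process. The full 21-cell grid
runs in about half a minute on one CPU.

Under the random-optima regime each lineage's optimum is an independent
standard-normal draw, redrawn (logged) if the two coordinates correlate at
|r| ≥ 0.3 across a repetition's lineages. Because every repetition redraws
its optima, the distribution of COR_E is centered at ~0; a single fixed
set of optima shared by all repetitions would instead center COR_E on that
set's sampling correlation (≈ ±1/√n_lineages), which is worth keeping in
mind when comparing to studies that drew optima once.

Mutational bias is modeled by rescaling each mutation by B (both
components multiplied by B when the effect on trait 1 is positive, divided
by B when negative; the measure-zero m₁ = 0 case passes unchanged). This
preserves each mutation's direction exactly. The accompanying diagnostic
draws 5,000 effects, rescales, and re-estimates the correlation, 200
times. The rescaling keeps a zero correlation at zero and leaves the ratio
m₂/m₁ untouched, but because the two sign-classes are scaled differently
the mixture correlation shifts slightly — about −0.02 at B = 1.5 and
COR_M = 0.5, detectable at this replication (the preset value sits near
the 92nd percentile of the estimates rather than the center). The shift is
small relative to the effects the selection test targets.

## Synthetic data

The generators emulate the study designs the pipeline targets: mutant
panels of thousands of deletion lines (default 4,817) or ~150 MA lines
phenotyped for many traits, ~16 strains (or ~110 species) on a rooted
ultrametric tree, and three-module block covariance structure. Panels are
i.i.d. multivariate-normal draws — they model line means, not within-line
measurement error, cell-to-cell variation, or the heavy tails of real
deletion phenotypes. Trees are pure-birth; real strain trees have
clade-concentrated branch lengths that reduce the effective number of
contrasts. Passing tests therefore demonstrate correctness of the
machinery under its own model assumptions, not robustness to those
real-data features.

Selection distortions are injected in contrast space: for a target pair,
i.i.d. contrast rows E with the target correlation are drawn and mapped to
tip space through the pseudo-inverse of the tree's contrast operator
(U @ pinv(U) = I), so the contrasts the estimator computes are exactly E
and the realized COR_E is the target up to its own sampling noise.
Injecting in tip space would confound the target with tree structure.
Injections replace the pair's tip values wholesale, so an injected trait's
correlations with third traits are scrambled — expected, and visible as
collateral "weakened" calls in scans of injected datasets. Injections
sharing a trait are rejected as jointly unsatisfiable.

## Numerical choices

* Covariance/correlation containers enforce symmetry to 1e-10, PSD to an
  eigenvalue floor of −1e-8, unit diagonals, and clip correlations into
  [−1, 1] only within round-off.
* Matrix square roots for sampling use the symmetric eigendecomposition
  with negative round-off eigenvalues clipped to zero, so rank-deficient
  targets (|COR_M| = 1) sample correctly.
* A trait whose contrasts are all zero yields NaN correlations with a
  warning (its variance falls below 1e-24 of the largest, absorbing float
  residue), never a crash or silent zero.
* The fixation probability is computed with `expm1` and explicit limits,
  accurate to <1e-9 relative error against arbitrary-precision evaluation
  and exactly 1/N_e at s = 0.
* Fisher z rejects |r| ≥ 1 in user-facing scans; the count-null inner loop
  clips simulated correlations at 1 − 1e-12, a measure-zero safeguard.

## Problem sizes used in checks

The packaged studies run at the scales the method is described at: grid
cells of 200 × 50 lineages × 1,000 units; calibration on 2,000 neutral
pairs with n_M = 4,817 and a 16-tip tree; power on 200 replicates with
n_M = 5,000; count nulls of 1,000 datasets. These complete in a few
minutes total on one CPU; panel sizes and tree sizes in unit tests are
smaller where the property under test does not depend on scale.
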