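# Methods

This note documents the statistical procedures implemented in `covnet`, the
defaults and why they were chosen, and what the synthetic studies used by the
test suite do and do not establish.

## Decomposition with respect to a covariable of interest

Each metabolite is modelled by ordinary least squares on the saturated
interaction expansion of the covariables: intercept, the target covariable's
main effect (indicator-coded against a reference level), every product of
non-target covariables (the γ terms, indexed by the non-empty 0/1 vectors δ
over the non-target set), and every interaction of the target with such a
product (the η terms).  Categorical covariables expand to reference-coded
indicators; interaction columns are elementwise products of the constituent
columns.  The covariable-relevant part Ỹ is the fitted contribution of the
target main effect plus all η terms; intercept and γ terms are excluded, so
Ỹ is exactly zero when every target-involving coefficient is zero, and for
the full model Ỹ + (non-target fitted part) + residuals reconstructs the data
to numerical precision.

**Term selection.** Group significance uses partial F-tests (the model with
and without the whole term group), since multi-level factors and
interactions occupy several columns.  Selection is hierarchical and
backward: the highest-order η group is tested first; when non-significant it
is removed and the next order is tested; at the first significant order all
remaining terms are retained.  γ terms are never removed — they model
nuisance structure whose removal would bias the target part.

**Keep/discard decision.** Whether a metabolite enters the
covariable-specific network at all is decided by one joint partial F-test of
*all* target-involving terms at level α (default 0.05).  A sequential
any-stage-significant rule would inflate the discard error to roughly
1 − (1 − α)^k over k stages; the single gate keeps the probability of
retaining a null metabolite at exactly α, which the test suite verifies by
Monte Carlo.  When the gate rejects but no individual stage reaches
significance, the minimal model with the target main effect is retained and
the selection trace records it.  No across-metabolite multiplicity
correction is applied by default.

Degenerate designs (empty cells) make high-order terms unestimable; the
largest estimable hierarchical submodel is used, dropping terms from the
highest order down, and the drops are recorded in the selection trace.

Because Ỹ depends on the indicator coding, the reference level of every
categorical covariable is either declared or fixed deterministically (first
level in sorted order), and the CLI prints the coding used.

**Auxiliary operations.** Nuisance adjustment replaces each metabolite by
its OLS residual on intercept + declared nuisance columns (constant columns
degrade to mean-centering; collinear adjusters raise).  Continuous
covariables can be categorized into k equally sized ordered classes with
boundaries at the i/k empirical quantiles (linear interpolation — the
standard, reproducible convention); ties that empty a class raise rather
than silently merging.

## Weighted correlation networks

Edge weights are |Pearson correlation|^γ (unsigned network), diagonal zero.
The power γ is restricted to integers ≥ 1 and chosen as the smallest integer
with P(P−1)/(2·√N^γ) < 1: the magnitude of a noise correlation between two
Gaussian variables on N samples is ≈ 1/√N, and the rule keeps the *summed*
noise weight over all P(P−1)/2 pairs below one edge-equivalent.  The search
is capped at γ ≤ 12 by default; beyond that the error reports the power that
would be required.  This rule, not a scale-free fit, governs the power,
because small metabolomics datasets frequently fail the scale-free
criterion; a diagnostic is still provided: node strengths are binned
(equal-width, zero bins dropped, ≥ 3 bins required) and log10 frequency is
regressed on log10 bin center.  Strength (weighted degree) replaces integer
degree in this diagnostic because the weighted network has no integer
degrees.

Sparse views keep the top fraction q of edges: the threshold is the
nearest-rank upper quantile of the upper-triangle weights, every edge with
weight ≥ threshold is kept (tie groups kept whole), q = 0 gives the empty
edge set and q = 1 all positive-weight edges.

## Gaussian graphical model with StARS

With column-centered data, S = YᵀY/N (divide by N; the maximum-likelihood
convention).  The precision matrix maximizes
log det Θ − tr(SΘ) − λ·Σ_{i≠j}|Θ_ij|.  Only off-diagonal entries are
penalized by default: the edge set is the estimand and a diagonal penalty
merely shrinks variances; `penalize_diagonal=True` solves the fully
penalized problem via the exact equivalence with the off-diagonal problem on
S + λI.  The convex solver is scikit-learn's coordinate-descent graphical
lasso; when its dual gap stalls (an oscillation seen on some subsample
correlation matrices) the exact LARS path is used instead, and genuine
non-convergence raises with the final gap.  By default the model is fitted
on the correlation-scaled covariance, which makes λ comparable across
metabolites with different variances; raw covariance is a switch.

**Penalty selection.** StARS draws B subsamples of size b without
replacement (defaults B = 100; b = ⌊10√N⌋ capped below N, with presets
matching small-study practice), refits the model over a decreasing λ grid
(30 log-spaced values from λ_max = max off-diagonal |S| down to 0.05·λ_max),
and computes per-edge selection frequencies θ̂_ij(λ).  Total instability
D(λ) = mean over pairs of 2θ̂(1−θ̂) is monotonized by its running supremum
from the largest λ downward, and λ\* is the smallest λ whose monotonized
instability stays within the disagreement allowance β (default 0.05).  If no
grid point qualifies, the largest λ is returned with a fallback flag and a
warning rather than an error, so exploratory runs on weakly structured data
still produce output.  All subsampling uses one seeded generator; the
subsample indices are kept in the result, and identical seeds reproduce the
result bit-exactly.

The frequency matrix at λ\* serves directly as an edge-weight matrix for
module detection and network concepts — the same data structure as the
correlation weights, so all downstream code is agnostic to the weights'
origin.  Partial correlations are computed as −Θ_ij/√(Θ_ii·Θ_jj) and are
zero exactly where the precision entries are.

## Module detection

Nodes are clustered on the dissimilarity 1 − |w_ij| (for stability networks:
one minus the edge's subsampling stability) with unweighted average linkage
(UPGMA, via scipy).  The two-step hybrid cut is a deliberately simplified
re-implementation of the dynamic hybrid tree-cut idea, not a line-for-line
port of the reference algorithm: (1) a static cut at the
`cut_height_quantile` (default 0.99) quantile of the *distinct* merge
heights defines candidate branches, and branches below `min_module_size`
(default 3) are dissolved; (2) each dissolved node joins the module with the
smallest average dissimilarity to it when that average lies below the cut
height, and otherwise stays unassigned (module 0, reported as "grey").
Taking the quantile over distinct heights makes the cut robust to ties:
several equal-height top merges (equidistant blocks) all land above the cut,
while a completely flat tree — no structure to split — collapses into a
single module.  Modules are relabelled by decreasing size and mapped to a
fixed color-name palette for reporting.  The reference hybrid algorithm's
tuning (deepSplit, cut height) is not published for this workflow, so exact
module membership is not an anchored quantity; the implementation is instead
validated on planted-block dissimilarities (exact recovery, minimum-size
enforcement, permutation invariance).

## Network concepts

For a weight matrix M with strengths s_i = Σ_{j≠i} w_ij:
density = s̄/(P−1); centralization = P/((P−1)(P−2))·(max s − s̄) — the exact
form, not the ≈1/P approximation — and heterogeneity = √var(s)/s̄ with the
population (divide-by-P) variance, matching the network-concepts literature;
a sample-variance switch exists.  A unit-weight star yields centralization
exactly 1 and density 2/P; regular networks yield 0 for both centralization
and heterogeneity.  Summaries are produced per module (restricted
submatrix), ordered by decreasing density, plus a "complete" row; modules
with fewer than 3 nodes report centralization as NaN.  Top-connected tables
rank nodes by degree of a thresholded adjacency, ties broken by node id.

## Synthetic studies

The generator emulates the two study designs the pipeline targets.  The
factorial scenario reproduces an unbalanced 2×2×2 genotype × PEG × ABA
experiment (wild type: 6 control + 3 per treated cell; mutant: 3 per cell;
N = 27).  The observational scenario draws sex ~ Bernoulli(0.5),
age ~ Uniform(25, 74) and an adiposity score ~ Normal(26.5, 4.2), the latter
categorized into thirtiles as the 3-level target covariable (N = 419 by
default).  Metabolites follow the same interaction model the decomposition
fits: each module shares one template of target coefficients (defaults: two
modules of 12, |η| = 5 residual sd, near-orthogonal response patterns),
per-metabolite nuisance (γ) coefficients are drawn independently with sd
`nuisance_sd` (default 0) — they create covariable-independent correlation
"noise" that masks module structure in the raw values but vanishes in Ỹ —
and residuals are multivariate Gaussian with exchangeable correlation ρ
(default 0.3) within modules and independence between modules, the simplest
structure consistent with a joint Gaussian model.  Coefficients on columns
involving continuous covariables are rescaled by the covariable's sd so that
template values remain interpretable in residual-sd units.  All randomness
flows from a single seeded generator per scenario.

What passing tests on these simulations establish: correct algebra
(coefficient recovery within 3 standard errors at large N), correct error
control (null keep-rate ≈ α), and correct qualitative behaviour (planted
modules recovered from Ỹ-based networks with ARI ≥ 0.8 at 5-sd effects;
Ỹ-based networks denser than raw-value networks when nuisance variation
masks the target structure, in ≥ 80% of seeded replicates).  What they do
not establish: behaviour under non-Gaussian concentrations, heteroscedastic
measurement error, block-Toeplitz or long-range residual correlation,
repeated measures, or missing data — none of which the generator emulates.

## Problem sizes and numerical choices

The test suite and examples run at desk scale — P ≤ 30 metabolites, N ≤ 419
samples, StARS with ≤ 30 subsamples over ≤ 10-point grids — chosen so the
whole suite completes in about a minute while still exercising every code
path; the defaults for real analyses (B = 100, 30-point grid) are the
conventional ones.  Matrix rank is checked before every fit and
rank-deficient expansions name the offending columns via pivoted QR.
Quantiles use linear interpolation throughout.  Edge presence in a precision
matrix uses a relative tolerance of 1e-10 on the partial-correlation scale
(the solver returns exact zeros; the tolerance only guards against
floating-point dust).  F-test p-values on saturated (zero-residual) fits
degrade to 0/1 by the sign of the sum-of-squares reduction.

## Known limitations

* The keep/discard gate controls the per-metabolite error rate, not a
  false-discovery rate across metabolites; a Benjamini–Hochberg flag would
  be a natural extension.
* The hybrid tree cut is a simplification; on dendrograms with gradual
  height profiles it can split differently from the reference dynamic
  algorithm.
* StARS instability is the Liu-style total instability bound; if
  "disagreement allowance" is interpreted as a raw edge-disagreement
  fraction the selected λ can differ.
* The λ values reported by other software are not comparable unless the
  covariance scaling (correlation vs raw) and diagonal-penalty conventions
  match.
* Unpenalized estimation requires a nonsingular covariance, hence N > P.
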