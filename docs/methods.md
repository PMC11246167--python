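# Methods

## Model and assumptions

The quantity of interest is the association between within-sample (alpha)
diversity of a TCR repertoire and a phenotype or covariate, free of the
technical dependence of observed diversity on sequencing depth. The
multi-bin procedure stratifies the cohort into K library-size bins defined by
cut points `c_1 < … < c_{K−1}` (with `c_0` the minimum retained library size
and `c_K` the maximum, assignment `c_{k−1} ≤ L_i < c_k`, top bin closed),
rarefies every sample in bin k to the bin's lower bound `L*_k = c_{k−1}`,
fits a univariate OLS of alpha on the covariate within each bin
(slope `τ̂_k`, variance `V_k`), and pools across bins under a fixed-effect
meta-analysis:

    τ̂ = Σ ω_k τ̂_k / Σ ω_k,     W = (Σ ω_k τ̂_k)² / Σ ω_k² V_k ~ χ²(1) under H0.

The fixed-effect assumption — one common true effect τ across bins — is
appropriate because binning is on a technical artifact: depth should not
change the underlying biology–diversity relationship. Weightings: `equal`
(ω_k = 1), `ssw` (ω_k = n_k), `ivw` (ω_k = 1/V_k; most powerful under
homogeneity and the recommended default). Random-effects pooling is out of
scope.

Note the per-bin slopes are estimated at different rarefying depths, so under
depth-dependent measures (richness in particular) the per-bin `τ̂_k` are on
different effective scales; the fixed-effect model treats them as estimates
of one τ regardless. This is inherent to the method, which trades that
approximation for the removal of depth confounding.

## Diversity measures

Richness `S_obs`, Shannon `H = −Σ p_i ln p_i` (natural log; the base only
rescales H and cancels in Pielou), Pielou `J = H / ln S_obs` (NaN when
`S_obs = 1`, propagated and dropped pairwise from regressions with a
warning), bias-corrected Chao1 `S_obs + f1(f1−1)/(2(f2+1))`. Bray-Curtis
dissimilarity `1 − 2Σmin(x_i,y_i)/(N_x+N_y)` is provided for checking pool
overlap in the simulations.

## Rarefaction

Subsampling without replacement is a multivariate-hypergeometric draw,
generated category-by-category (numpy's `multivariate_hypergeometric`,
"marginals" method) so memory is O(#clonotypes) even at library sizes of
4×10⁷. Determinism: a draw depends only on `(counts, depth, seed)`.
Multiple-rarefying averaging (`n_rep > 1`) uses counter-based sub-seeds
`seed + j`, making replicate j reproducible in isolation; the default is a
single replicate, with averaging opt-in. Cohort-level operations derive
per-sample seeds from the sorted sample-id order, so results are invariant
to input order, and overall rarefying at the cohort minimum is exactly the
K = 1 multi-bin analysis at the same seed.

`expected_richness` implements the closed-form expectation
`E[S(m)] = Σ_i (1 − C(N−n_i, m)/C(N, m))`, evaluated in log-space
(`gammaln`) to avoid overflow; it serves as an independent oracle for the
stochastic subsampler and for locating the saturation elbow of rarefaction
curves.

## Degenerate inputs and numerical choices

- Bins with fewer than 3 complete observations, a constant covariate, or a
  zero-variance slope estimate are excluded from the meta-analysis with a
  warning rather than aborting; `bins_used` records what entered the pool.
- Empty bins (cut points outside the observed depth range) are dropped with
  a warning; remaining bins keep their interval edges.
- `min_depth` optionally excludes failed/ultra-shallow runs before binning —
  without it a single failed sample drags the bottom rarefying level to a
  useless depth. Default: no exclusion.
- Ties: samples with equal `L_i` always land in the same bin; Spearman
  diagnostics use average ranks.
- p-values are two-sided throughout; no multiple-testing adjustment is
  applied across metrics or covariates.
- Within-bin OLS is computed in closed form (slope, `V_k = SE²`, t-test with
  n−2 df); the test suite cross-checks it against statsmodels OLS and the
  equal-variance t-test.

## Baselines

No rarefying (raw counts); overall rarefying at a single level L* (samples
with `L_i < L*`, strict inequality, are discarded); LOESS residualization —
a local-linear tricube smoother (statsmodels lowess) of raw alpha on
log₁₀(L) at span 0.5, residuals carried into the association test. The
log₁₀ predictor is used because depths span orders of magnitude and local
windows on the raw scale would be badly unbalanced; the raw-scale predictor
remains available via `log10_predictor=False`.

## Simulation framework

**Simulation B (two-pool generative model).** Two sequence pools emulate two
near-disjoint source repertoires. The synthetic generator draws
1000 clonotypes per pool (0 shared by default), weights from a discretized
log-normal (μ=0.5, σ=1.5 on the log scale) capped at 1000 — mimicking the
heavy-tailed clone-size distribution after removing dominant clones — and
fixes a random pool order once, seeded. Pool A is the first source; Pool B
is Pool A plus `round(p·1000)` clonotypes of the second source, so p controls
the true diversity difference and p = 0 is an exact null (Pool B *is*
Pool A, same object and order). Each replicate simulates 400 samples, half
cases (Pool A) and half controls (Pool B); library sizes are `round(10^U)`,
`U ~ Uniform(3, 5)`; a sample's `L_i` reads are drawn with replacement from
its pool, each read choosing a clonotype with probability proportional to
its weight.

In the confounded scenario, labels are tied to depth — `round(0.7·n/2)`
cases are placed uniformly among samples at or below the median library
size, the rest above, controls mirrored — and depth is tied to diversity by
the gamma truncation rule over four fixed depth intervals
([1000,3000), [3000,10000), [10000,30000), [30000,100000]): a sample may
only draw from the first `floor(γ_i·|pool|)` clonotypes of the pool order,
with γ linearly spaced 0.80–0.85, 0.95–0.98, 0.98–0.99, and 1 by depth rank
within the interval. Because truncation is along one fixed order, larger γ
always gives a superset sampling space and hence weakly higher expected
diversity.

Design choices where the generative recipe was open, recorded here as the
package's conventions: reads are drawn weight-proportionally (pools retain
their read counts; a uniform-over-clonotypes variant would discard them);
the mixing proportion p operates on clonotypes, not reads; the truncation
order is a single seeded permutation fixed at pool construction.

**Simulation A (label permutation).** On a fixed cohort, case/control labels
are permuted half/half per replicate; alpha values per normalization depend
only on the fixed repertoires and are computed once, so each replicate only
re-runs the association tests. Rejection rates are reported within strata of
increasing |Spearman ρ(label, L)| — chance label–depth correlation is what
turns the depth–diversity artifact into false positives. The default cohort
is synthetic (`synthesize_cohort`): one pool, depths `10^U`, the gamma rule
coupling depth to diversity; it emulates a real cohort's depth spread at
desk scale.

## What the synthetic generator does and does not emulate

It reproduces the features that drive the confounding phenomenon — heavy-
tailed clone sizes, near-disjoint pools, depths spanning two orders of
magnitude, and a monotone depth–diversity coupling. It does not emulate
V/J-gene usage structure, the full 10⁵–10⁶ clonotype richness of deep real
repertoires, depths up to 4×10⁷, or covariate structure beyond a single
binary label. Passing simulations therefore demonstrate statistical
calibration and power of the machinery under controlled confounding, not
performance claims about any particular real cohort.

## Problem sizes

Default study conditions are 400 samples per replicate with 1000-clonotype
pools and depths 10³–10⁵. Headline checks use 500 replicates (type-I error)
and 300 per power point; package defaults keep replicate counts at this
desk scale, and larger runs (e.g. 5000 replicates) are a config field away
(`SimBConfig.n_replicates`). One caution discovered in development: shrinking
the pool far below 1000 clonotypes while keeping depths 10³–10⁵ saturates
richness at the deeper rarefying levels, collapsing within-bin variance and
destabilising the t-tests — reduced-scale experiments should scale depths
and pool size together.

## Known limitations

- Only univariate within-bin models (OLS / equal-variance t-test); no
  survival or mixed models, no covariate adjustment within bins.
- Fixed-effect pooling only; heterogeneous per-bin effects (possible for
  strongly depth-dependent measures) are not modelled.
- Cut points are user-chosen; `bin_diagnostics` supports the choice (little
  within-bin alpha–depth correlation, adequate bin sizes) but no automatic
  optimisation is attempted.
- The Wald reference is the asymptotic χ²(1); very small bins rely on the
  minimum-bin-size guard rather than exact small-sample corrections.
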