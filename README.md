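# multibin-alpha

Multi-bin rarefying for alpha-diversity association tests in T-cell receptor
(TCR) repertoire sequencing data.

## The problem

Sequencing depth ("library size", `L_i`) in AIRR-seq experiments spans orders
of magnitude across samples, and observed alpha diversity — richness, Shannon
index, Pielou's evenness, Chao1 — grows with depth as a purely technical
artifact. When library size is also associated with the phenotype under
study, diversity–phenotype association tests pick up the artifact as signal.
The common remedy, rarefying every sample to one shared depth, discards most
reads from deep samples and still leaves a residual depth–diversity
correlation.

## The method

`multibin-alpha` implements a stratified alternative:

1. **Bin** samples by library size using cut points
   `min(L_i) = c_0 ≤ c_1 < … < c_{K−1} ≤ c_K = max(L_i)`; sample *i* joins
   bin *k* when `c_{k−1} ≤ L_i < c_k` (top bin closed).
2. **Rarefy within bins**: every sample in bin *k* is subsampled without
   replacement to the bin's lower bound `L*_k = c_{k−1}`, so diversity is
   compared at equal effort *within* each narrow depth range while deep
   samples keep (most of) their reads.
3. **Test within bins**: alpha diversity is regressed on the covariate by
   univariate OLS in each bin, giving a slope `τ̂_k` with variance `V_k`
   (for a 0/1 covariate this is the equal-variance two-sample t-test).
4. **Pool by fixed-effect meta-analysis** with weights `ω_k` — equal,
   sample-size (`n_k`), or inverse-variance (`1/V_k`) — and test
   `H0: τ = 0` with the Wald statistic

   ```
   τ̂ = Σ ω_k τ̂_k / Σ ω_k ,   W = (Σ ω_k τ̂_k)² / Σ ω_k² V_k  ~  χ²(1)
   ```

The package also ships the baseline normalizations used for comparison (no
rarefying, overall rarefying, LOESS residualization), the four diversity
measures, an exact expected-richness oracle, and a simulation framework that
measures type-I error and power under depth confounding.

## Worked example

Simulate a 120-sample cohort in which controls draw their reads from a more
diverse sequence pool than cases, then fit the model:

```python
import numpy as np, pandas as pd
from multibin_alpha import MultibinAlphaModel, CohortTable
from multibin_alpha.simulation import (
    synthesize_pools, mix_pool_b, draw_library_sizes, simulate_sample)

rng = np.random.default_rng(42)
src_a, src_b = synthesize_pools(1000, 0, seed=rng)       # two disjoint pools
pool_b = mix_pool_b(src_a, src_b, 0.3, seed=rng)          # controls: +30%
L = draw_library_sizes(120, seed=rng)                     # 10^U, U~Unif(3,5)
labels = np.r_[np.ones(60, int), np.zeros(60, int)]
reps = [simulate_sample(src_a if labels[i] else pool_b, int(L[i]), 1.0,
                        seed=int(rng.integers(2**31)), sample_id=f"S{i:03d}")
        for i in range(120)]
cohort = CohortTable(pd.DataFrame({
    "sample_id": [r.sample_id for r in reps],
    "library_size": [r.library_size for r in reps],
    "case": labels}))
model = MultibinAlphaModel(reps, cohort, "case", metric="richness",
                           cut_points=(3000, 10000, 30000))
print(model.fit(weighting="ivw", seed=0).summary())
```

```
Multi-bin rarefying alpha-diversity association
===============================================================
Metric: richness   Covariate: case   Weighting: ivw
Samples: 120 retained, 0 excluded; K = 4 bins
---------------------------------------------------------------
Per-bin estimates (rarefied to the bin lower bound L*_k):
      n  level  tau_hat     se    pvalue  degenerate
bin
1    28   1020   -54.41  4.615  6.19e-12       False
2    40   3000   -111.8  3.653 2.217e-28       False
3    27  1e+04   -225.6  3.286 5.382e-30       False
4    25  3e+04   -294.5 0.7566 2.002e-45       False
---------------------------------------------------------------
Fixed-effect meta-analysis (W ~ chi2, df=1):
           tau_hat         W  pvalue  bins_used    se
weighting
equal       -171.6 1.023e+04       0          4 1.696
ssw         -162.1      8171       0          4 1.793
ivw         -278.5 1.521e+05       0          4 0.714
===============================================================
```

Each bin rarefies to its own lower bound, so the per-bin slopes are on the
bin's own depth scale: cases are 54 unique clonotypes poorer than controls
when both are compared at ~1000 reads, and 295 poorer at 30 000 reads. All
bins agree on the direction, and the pooled Wald test rejects decisively
under every weighting. `results.diagnostics()` reports the within-bin
Spearman correlations between diversity and depth used to vet the cut
points.

A command-line interface mirrors the library
(`multibin-alpha multibin --reps reps.tsv --meta meta.tsv --covariate case
--metric richness --cuts 3000,10000,30000 --weighting ivw --out result.tsv`;
see `multibin-alpha --help` for the `diversity`, `rarefy`, `baseline` and
`simulate` subcommands).

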