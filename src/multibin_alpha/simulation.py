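"""Type-I-error and power simulations for library-size-confounded cohorts.

Two validation designs are provided.

Simulation A (label permutation): given a fixed cohort of repertoires,
case/control labels are repeatedly permuted half/half, so the null holds by
construction; chance correlation between labels and library size still arises
replicate to replicate, and rejection rates are summarised within strata of
increasing |Spearman rho(label, library size)| to expose depth confounding.

Simulation B (two-pool generative model): two near-disjoint sequence pools of
~1000 clonotypes each stand in for two source repertoires.  Pool A is the
first source; Pool B is Pool A plus a proportion ``p`` of the second source's
clonotypes, so ``p`` controls the true diversity difference (``p = 0`` is the
null).  Each replicate simulates 400 samples (cases from Pool A, controls
from Pool B): library sizes are drawn as ``10^U`` with U ~ Uniform(3, 5), and
each sample's reads are drawn with replacement from its pool, weighted by
clonotype counts.  In the confounded scenario, labels are tied to depth (70%
of cases at or below the median library size, mirrored for controls) and a
depth-diversity coupling is induced by the gamma truncation rule: a sample
may only draw from the first ``gamma_i`` fraction of its pool's (fixed,
seeded) clonotype order, with

    gamma_i = 0.80 + 0.05 (i)/n1   for L_i in [ 1000,   3000)
              0.95 + 0.03 (i)/n2   for L_i in [ 3000,  10000)
              0.98 + 0.01 (i)/n3   for L_i in [10000,  30000)
              1                    for L_i in [30000, 100000]

where (i) is the sample's depth rank within its interval.  Shallow samples
thus see a truncated pool and genuinely lower diversity, making library size
a confounder even under the null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import as_rng, child_seeds
from .baselines import loess_residual_alpha
from .diversity import bray_curtis, resolve_metric
from .io import Clonotype, Repertoire
from .multibin import (
    BinResult,
    DegenerateBinError,
    _assign_bins_array,
    _ols_slope,
    wald_test,
)

__all__ = [
    "SequencePool",
    "SimBConfig",
    "GAMMA_EDGES",
    "build_pools_from_repertoires",
    "synthesize_pools",
    "mix_pool_b",
    "draw_library_sizes",
    "confounded_label_assignment",
    "gamma_of",
    "simulate_sample",
    "synthesize_cohort",
    "run_simulation_B",
    "run_simulation_A",
    "pool_bray_curtis",
    "METHODS",
]

METHODS = (
    "multibin-equal",
    "multibin-ssw",
    "multibin-ivw",
    "none",
    "overall",
    "loess",
)

#: Library-size interval edges of the gamma truncation rule.
GAMMA_EDGES = (1_000.0, 3_000.0, 10_000.0, 30_000.0, 100_000.0)
#: (intercept, slope) of gamma within each interval: base + slope * (i)/n_k.
GAMMA_RULES = ((0.80, 0.05), (0.95, 0.03), (0.98, 0.01), (1.00, 0.00))


# ---------------------------------------------------------------------------
# sequence pools
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequencePool:
    """An ordered list of (clonotype, weight) pairs.

    The order is fixed at construction (randomised once, seeded); gamma
    truncation takes the first ``floor(gamma * size)`` entries of this order,
    so a larger gamma always yields a superset sampling space.
    """

    name: str
    clonotypes: tuple
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.int64)
        if len(self.clonotypes) != w.size or w.size == 0:
            raise ValueError("pool needs matching, non-empty clonotypes/weights")
        if np.any(w < 1):
            raise ValueError("pool weights must be >= 1")
        object.__setattr__(self, "weights", w)

    @property
    def size(self) -> int:
        return len(self.clonotypes)

    def truncated(self, gamma: float) -> int:
        """Sampling-space size at truncation fraction gamma (minimum 1)."""
        if not 0 < gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        return max(1, math.floor(gamma * self.size))


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _cdr3_tag(prefix: str, idx: int) -> str:
    """Deterministic unique CDR3-like string encoding an index."""
    body = []
    i = idx
    for _ in range(6):
        body.append(_AA[i % 20])
        i //= 20
    return f"CASS{prefix}{''.join(body)}EQYF"


def _default_weight_law(rng: np.random.Generator, n: int) -> np.ndarray:
    # discretized log-normal capped at 1000, matching the <=1000-read filter
    w = np.rint(rng.lognormal(mean=0.5, sigma=1.5, size=n))
    return np.clip(w, 1, 1000).astype(np.int64)


def synthesize_pools(n_per_pool: int, n_shared: int = 0, weight_law=None, seed=0):
    """Two synthetic pools of ``n_per_pool`` clonotypes sharing ``n_shared``.

    Download-free stand-in for two filtered source repertoires: heavy-tailed
    weights (discretized log-normal, capped at 1000) and a seeded random
    order.  ``n_shared = 0`` gives Bray-Curtis dissimilarity exactly 1.
    """
    if not 0 <= n_shared <= n_per_pool:
        raise ValueError("need 0 <= n_shared <= n_per_pool")
    if n_per_pool < 1:
        raise ValueError("n_per_pool must be >= 1")
    rng = as_rng(seed)
    law = weight_law or _default_weight_law
    shared = [
        Clonotype("TRBV9", _cdr3_tag("S", i), "TRBJ2-5") for i in range(n_shared)
    ]
    n_own = n_per_pool - n_shared
    pools = []
    for tag, name in (("A", "A-source"), ("B", "B-source")):
        own = [
            Clonotype("TRBV5-1", _cdr3_tag(tag, i), "TRBJ1-2") for i in range(n_own)
        ]
        cts = shared + own
        order = rng.permutation(len(cts))
        weights = law(rng, len(cts))
        pools.append(
            SequencePool(
                name=name,
                clonotypes=tuple(cts[i] for i in order),
                weights=weights[order],
            )
        )
    return pools[0], pools[1]


def build_pools_from_repertoires(
    rep1: Repertoire, rep2: Repertoire, max_count: int = 1000,
    n_select: int = 1000, seed=0,
):
    """Source pools from two real repertoires, per the filtering protocol.

    Clonotypes with more than ``max_count`` reads are removed (they would
    dominate subsampling), then ``n_select`` clonotypes are drawn uniformly
    without replacement from each; weights are the retained read counts and
    the pool order is randomised once by the seed.
    """
    rng = as_rng(seed)
    pools = []
    for rep, name in ((rep1, "A-source"), (rep2, "B-source")):
        items = [(ct, c) for ct, c in rep.counts.items() if c <= max_count]
        if len(items) < n_select:
            raise ValueError(
                f"{rep.sample_id}: only {len(items)} clonotypes with count <= "
                f"{max_count}, need {n_select}"
            )
        items.sort(key=lambda t: (t[0].v_gene, t[0].cdr3_aa, t[0].j_gene))
        chosen = rng.choice(len(items), size=n_select, replace=False)
        order = rng.permutation(n_select)
        picked = [items[i] for i in chosen[order]]
        pools.append(
            SequencePool(
                name=name,
                clonotypes=tuple(ct for ct, _ in picked),
                weights=np.array([c for _, c in picked], dtype=np.int64),
            )
        )
    return pools[0], pools[1]


def mix_pool_b(source_a: SequencePool, source_b: SequencePool, p: float, seed=0) -> SequencePool:
    """Pool B: all of Pool A plus a proportion ``p`` of the second source.

    ``round(p * |source_b|)`` clonotypes are drawn uniformly without
    replacement from ``source_b`` and appended; the combined order is
    reshuffled once.  At ``p = 0`` Pool A itself is returned unchanged, so
    the null scenario uses byte-identical pools for both groups.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    n_add = int(round(p * source_b.size))
    if n_add == 0:
        return source_a
    rng = as_rng(seed)
    idx = rng.choice(source_b.size, size=n_add, replace=False)
    combined: dict[Clonotype, int] = dict(zip(source_a.clonotypes, source_a.weights))
    for i in idx:
        ct = source_b.clonotypes[i]
        combined[ct] = combined.get(ct, 0) + int(source_b.weights[i])
    cts = list(combined)
    order = rng.permutation(len(cts))
    return SequencePool(
        name="B",
        clonotypes=tuple(cts[i] for i in order),
        weights=np.array([combined[cts[i]] for i in order], dtype=np.int64),
    )


def pool_bray_curtis(pool_x: SequencePool, pool_y: SequencePool) -> float:
    """Bray-Curtis dissimilarity of two pools' weight profiles."""
    union = list(dict.fromkeys(list(pool_x.clonotypes) + list(pool_y.clonotypes)))
    wx = dict(zip(pool_x.clonotypes, pool_x.weights))
    wy = dict(zip(pool_y.clonotypes, pool_y.weights))
    x = np.array([wx.get(ct, 0) for ct in union], dtype=np.int64)
    y = np.array([wy.get(ct, 0) for ct in union], dtype=np.int64)
    return bray_curtis(x, y)


# ---------------------------------------------------------------------------
# generative ingredients
# ---------------------------------------------------------------------------

def draw_library_sizes(n: int, lo_exp: float = 3.0, hi_exp: float = 5.0, seed=0) -> np.ndarray:
    """Library sizes ``L_i = round(10^U)`` with U ~ Uniform(lo_exp, hi_exp)."""
    if lo_exp >= hi_exp:
        raise ValueError("lo_exp must be < hi_exp")
    rng = as_rng(seed)
    u = rng.uniform(lo_exp, hi_exp, size=int(n))
    return np.rint(10.0 ** u).astype(np.int64)


def confounded_label_assignment(library_sizes, case_frac_low: float = 0.7, seed=0) -> np.ndarray:
    """Depth-confounded case/control labels (1 = case), half cases.

    ``round(case_frac_low * n/2)`` cases are placed uniformly at random among
    samples with library size at or below the median, the remaining cases
    above it; controls receive the mirror-image allocation.
    """
    L = np.asarray(library_sizes)
    n = L.size
    if n % 2:
        raise ValueError("need an even number of samples")
    if not 0 <= case_frac_low <= 1:
        raise ValueError("case_frac_low must be in [0, 1]")
    rng = as_rng(seed)
    n_case = n // 2
    low = np.flatnonzero(L <= np.median(L))
    high = np.flatnonzero(L > np.median(L))
    n_case_low = int(round(case_frac_low * n_case))
    n_case_high = n_case - n_case_low
    if n_case_low > low.size or n_case_high > high.size:
        raise ValueError(
            f"depth strata too small for the {case_frac_low:.0%} split "
            f"(low={low.size}, high={high.size})"
        )
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.choice(low, size=n_case_low, replace=False)] = 1
    labels[rng.choice(high, size=n_case_high, replace=False)] = 1
    return labels


def gamma_of(L_i: int, rank_in_bin: int, n_bin: int) -> float:
    """Truncation fraction gamma for one sample (piecewise-linear in rank).

    ``rank_in_bin`` is the sample's 1-based depth order within its interval
    of ``n_bin`` samples.  The deepest sample of the first interval gets
    0.85; the entire last interval gets 1.
    """
    if not 1 <= rank_in_bin <= n_bin:
        raise ValueError("rank_in_bin must be in 1..n_bin")
    L = float(L_i)
    if not GAMMA_EDGES[0] <= L <= GAMMA_EDGES[-1]:
        raise ValueError(
            f"library size {L_i} outside [{GAMMA_EDGES[0]:.0f}, {GAMMA_EDGES[-1]:.0f}]"
        )
    for (lo, hi), (base, slope) in zip(
        zip(GAMMA_EDGES, GAMMA_EDGES[1:]), GAMMA_RULES
    ):
        if lo <= L < hi or (hi == GAMMA_EDGES[-1] and L == hi):
            return base + slope * rank_in_bin / n_bin
    raise AssertionError("unreachable")


def _gammas(L: np.ndarray) -> np.ndarray:
    """Vectorised gamma_of over a cohort (ranks computed per interval)."""
    L = np.asarray(L, dtype=float)
    gam = np.ones(L.size)
    edges = np.asarray(GAMMA_EDGES)
    which = np.searchsorted(edges[1:-1], L, side="right")  # 0..3
    for b, (base, slope) in enumerate(GAMMA_RULES):
        members = np.flatnonzero(which == b)
        if members.size == 0:
            continue
        ranks = np.empty(members.size)
        ranks[np.argsort(L[members], kind="stable")] = np.arange(1, members.size + 1)
        gam[members] = base + slope * ranks / members.size
    return gam


def _draw_counts(pool: SequencePool, L_i: int, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Counts over the truncated pool: L_i weighted draws with replacement."""
    m = pool.truncated(gamma)
    w = pool.weights[:m].astype(float)
    return rng.multinomial(int(L_i), w / w.sum())


def simulate_sample(pool: SequencePool, L_i: int, gamma: float, seed=0,
                    sample_id: str = "sim") -> Repertoire:
    """Simulate one repertoire of exactly ``L_i`` reads from a pool.

    Reads are drawn with replacement, each choosing a clonotype with
    probability proportional to its weight within the first
    ``floor(gamma * pool.size)`` clonotypes of the pool's fixed order.
    """
    rng = as_rng(seed)
    counts = _draw_counts(pool, L_i, gamma, rng)
    m = counts.size
    cmap = {
        pool.clonotypes[i]: int(counts[i]) for i in range(m) if counts[i] > 0
    }
    return Repertoire(sample_id, cmap)


def synthesize_cohort(n: int = 400, seed: int = 0, lo_exp: float = 3.0,
                      hi_exp: float = 5.0, pool_size: int = 1000,
                      depth_coupled: bool = True):
    """A synthetic cohort with a depth-diversity coupling, for Simulation A.

    One pool; library sizes ``10^U``; the gamma truncation rule (when
    ``depth_coupled``) makes shallow samples genuinely less diverse,
    emulating the depth spread of a real TCR cohort at desk scale.
    Returns a list of Repertoires.
    """
    seeds = child_seeds(seed, 3 + n, key=101)
    pool, _ = synthesize_pools(pool_size, 0, seed=int(seeds[0]))
    L = draw_library_sizes(n, lo_exp, hi_exp, seed=int(seeds[1]))
    gam = _gammas(L) if depth_coupled else np.ones(n)
    return [
        simulate_sample(pool, int(L[i]), float(gam[i]), seed=int(seeds[3 + i]),
                        sample_id=f"S{i:04d}")
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# per-replicate analysis engine (arrays, shared by both simulations)
# ---------------------------------------------------------------------------

def _rarefied_alpha_arrays(counts_list, L, bins, levels, metric_fn, rng):
    """Alpha at each sample's own bin level, via hypergeometric subsampling."""
    alphas = np.empty(len(counts_list))
    for i, x in enumerate(counts_list):
        k = bins[i]
        if k < 0:
            alphas[i] = np.nan
            continue
        depth = int(levels[k])
        if L[i] == depth:
            sub = x
        else:
            sub = rng.multivariate_hypergeometric(x, depth)
        alphas[i] = metric_fn(sub)
    return alphas


def _multibin_pvalues(alphas, bins, levels, labels, weightings):
    """Within-bin OLS + Wald pooling; p-value per requested weighting."""
    results = []
    for k in range(len(levels)):
        members = np.flatnonzero(bins == k)
        if members.size < 3:
            continue
        try:
            slope, var, p, n = _ols_slope(
                alphas[members], labels[members].astype(float)
            )
        except DegenerateBinError:
            continue
        if var <= 0:
            continue
        results.append(
            BinResult(k=k + 1, tau_hat=slope, var=var, n=n, pvalue=p,
                      level=float(levels[k]))
        )
    out = {}
    for w in weightings:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[w] = wald_test(results, w).pvalue if results else float("nan")
    return out


def _analyse_replicate(counts_list, L, labels, methods, cut_points, metric_fn,
                       rng, overall_level, loess_span=0.5):
    """P-value of every requested method on one simulated cohort."""
    pvals = {}
    mb = [m for m in methods if m.startswith("multibin-")]
    if mb:
        bins, levels, _, _ = _assign_bins_array(L, cut_points)
        alphas = _rarefied_alpha_arrays(counts_list, L, bins, levels, metric_fn, rng)
        weightings = [m.split("-", 1)[1] for m in mb]
        mp = _multibin_pvalues(alphas, bins, levels, labels, weightings)
        for m in mb:
            pvals[m] = mp[m.split("-", 1)[1]]
    raw = None
    if "none" in methods or "loess" in methods:
        raw = np.array([metric_fn(x) for x in counts_list], dtype=float)
    if "none" in methods:
        _, _, p, _ = _ols_slope(raw, labels.astype(float))
        pvals["none"] = p
    if "loess" in methods:
        resid = loess_residual_alpha(
            pd.Series(raw), pd.Series(L.astype(float)), span=loess_span
        )
        _, _, p, _ = _ols_slope(resid.to_numpy(), labels.astype(float))
        pvals["loess"] = p
    if "overall" in methods:
        keep = np.flatnonzero(L >= overall_level)
        sub_labels = labels[keep].astype(float)
        if keep.size < 3 or len(set(sub_labels)) < 2:
            pvals["overall"] = float("nan")
        else:
            vals = np.empty(keep.size)
            for j, i in enumerate(keep):
                if L[i] == overall_level:
                    sub = counts_list[i]
                else:
                    sub = rng.multivariate_hypergeometric(
                        counts_list[i], int(overall_level)
                    )
                vals[j] = metric_fn(sub)
            _, _, p, _ = _ols_slope(vals, sub_labels)
            pvals["overall"] = p
    return pvals


# ---------------------------------------------------------------------------
# Simulation B
# ---------------------------------------------------------------------------

@dataclass
class SimBConfig:
    """Generative settings of the two-pool simulation.

    Defaults are the study conditions: 400 samples split evenly, library
    sizes ``10^U`` with U ~ Uniform(3, 5), 1000-clonotype pools with no
    shared clonotypes, a 70/30 depth split for cases in the confounded
    scenario, and the gamma rule anchored at 0.8-0.85 / 0.95-0.98 /
    0.98-0.99 / 1 over the four depth intervals.
    """

    p: float = 0.0
    scenario: str = "no_confounding"  # or "confounded"
    n_samples: int = 400
    n_replicates: int = 500
    lo_exp: float = 3.0
    hi_exp: float = 5.0
    case_frac_low: float = 0.7
    pool_size: int = 1000
    n_shared: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples % 2:
            raise ValueError("n_samples must be even (half cases, half controls)")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.scenario not in ("no_confounding", "confounded"):
            raise ValueError("scenario must be 'no_confounding' or 'confounded'")


def _simulate_b_replicate(config: SimBConfig, rep_seed: int):
    """One replicate: pools, labels, depths, gammas, per-sample counts."""
    rng = np.random.default_rng(int(rep_seed))
    src_a, src_b = synthesize_pools(config.pool_size, config.n_shared, seed=rng)
    pool_a = src_a
    pool_b = mix_pool_b(src_a, src_b, config.p, seed=rng)
    n = config.n_samples
    L = draw_library_sizes(n, config.lo_exp, config.hi_exp, seed=rng)
    if config.scenario == "confounded":
        labels = confounded_label_assignment(L, config.case_frac_low, seed=rng)
        gam = _gammas(L)
    else:
        labels = np.zeros(n, dtype=np.int64)
        labels[rng.choice(n, size=n // 2, replace=False)] = 1
        gam = np.ones(n)
    counts_list = [
        _draw_counts(pool_a if labels[i] else pool_b, int(L[i]), float(gam[i]), rng)
        for i in range(n)
    ]
    return counts_list, L, labels, rng


def run_simulation_B(config: SimBConfig, methods=("multibin-ivw",),
                     cut_points=(3_000, 10_000, 30_000), metric="richness",
                     alpha_level: float = 0.05, overall_level=None,
                     return_pvalues: bool = False):
    """Monte-Carlo rejection rates of the requested methods.

    Returns a DataFrame with one row per method (columns ``method``,
    ``scenario``, ``p``, ``rejection_rate``, ``n_reps``, ``mc_se``); with
    ``return_pvalues=True`` also the per-replicate p-value arrays.  Fully
    deterministic given ``config.seed``.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}; choose from {METHODS}")
    metric_fn = resolve_metric(metric)
    if overall_level is None:
        overall_level = int(cut_points[0]) if len(cut_points) else 10 ** config.lo_exp
    rep_seeds = child_seeds(config.seed, config.n_replicates, key=7)
    pvals = {m: np.empty(config.n_replicates) for m in methods}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(config.n_replicates):
            counts_list, L, labels, rng = _simulate_b_replicate(
                config, int(rep_seeds[r])
            )
            res = _analyse_replicate(
                counts_list, L, labels, methods, cut_points, metric_fn, rng,
                overall_level,
            )
            for m in methods:
                pvals[m][r] = res[m]
    rows = []
    for m in methods:
        pv = pvals[m]
        ok = ~np.isnan(pv)
        rate = float((pv[ok] <= alpha_level).mean()) if ok.any() else float("nan")
        n_ok = int(ok.sum())
        rows.append(
            {
                "method": m,
                "scenario": config.scenario,
                "p": config.p,
                "rejection_rate": rate,
                "n_reps": n_ok,
                "mc_se": float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else float("nan"),
            }
        )
    summary = pd.DataFrame(rows)
    if return_pvalues:
        return summary, pvals
    return summary


# ---------------------------------------------------------------------------
# Simulation A
# ---------------------------------------------------------------------------

def run_simulation_A(reps, n_reps: int = 500, seed: int = 0,
                     methods=("multibin-ivw", "none"),
                     rho_thresholds=(0.0, 0.02, 0.05, 0.1),
                     cut_points=(3_000, 10_000, 30_000), metric="richness",
                     alpha_level: float = 0.05, overall_level=None,
                     return_details: bool = False):
    """Permutation-null type-I error stratified by |rho(label, depth)|.

    Alpha values per normalization depend only on the fixed cohort, so they
    are computed once; each replicate permutes half/half labels, records the
    Spearman correlation between labels and library sizes, and re-runs the
    association tests.  Rejection rates are reported within each
    ``|rho| > threshold`` stratum (NaN when a stratum is empty).
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}; choose from {METHODS}")
    reps = list(reps)
    n = len(reps)
    if n % 2:
        raise ValueError("need an even number of samples")
    metric_fn = resolve_metric(metric)
    if overall_level is None:
        overall_level = int(cut_points[0]) if len(cut_points) else min(
            r.library_size for r in reps
        )
    L = np.array([r.library_size for r in reps], dtype=float)
    counts_list = [r.abundance() for r in reps]
    rng = np.random.default_rng(int(child_seeds(seed, 1, key=11)[0]))

    # fixed per-method alpha vectors (labels do not enter normalization)
    alpha_by_method = {}
    mb = [m for m in methods if m.startswith("multibin-")]
    bins = levels = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if mb:
            bins, levels, _, _ = _assign_bins_array(L, cut_points)
            alpha_by_method["_multibin"] = _rarefied_alpha_arrays(
                counts_list, L, bins, levels, metric_fn, rng
            )
        raw = None
        if "none" in methods or "loess" in methods:
            raw = np.array([metric_fn(x) for x in counts_list], dtype=float)
        if "none" in methods:
            alpha_by_method["none"] = raw
        if "loess" in methods:
            alpha_by_method["loess"] = loess_residual_alpha(
                pd.Series(raw), pd.Series(L), span=0.5
            ).to_numpy()
        if "overall" in methods:
            keep = np.flatnonzero(L >= overall_level)
            vals = np.full(n, np.nan)
            for i in keep:
                sub = (
                    counts_list[i]
                    if L[i] == overall_level
                    else rng.multivariate_hypergeometric(
                        counts_list[i], int(overall_level)
                    )
                )
                vals[i] = metric_fn(sub)
            alpha_by_method["overall"] = vals

    base_labels = np.zeros(n, dtype=np.int64)
    base_labels[: n // 2] = 1
    rhos = np.empty(n_reps)
    pv = {m: np.empty(n_reps) for m in methods}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            labels = rng.permutation(base_labels)
            rhos[r] = stats.spearmanr(labels, L).statistic
            for m in methods:
                if m.startswith("multibin-"):
                    mp = _multibin_pvalues(
                        alpha_by_method["_multibin"], bins, levels, labels,
                        [m.split("-", 1)[1]],
                    )
                    pv[m][r] = mp[m.split("-", 1)[1]]
                else:
                    vals = alpha_by_method[m]
                    ok = ~np.isnan(vals)
                    try:
                        _, _, p, _ = _ols_slope(vals[ok], labels[ok].astype(float))
                    except DegenerateBinError:
                        p = float("nan")
                    pv[m][r] = p
    rows = []
    for thr in rho_thresholds:
        stratum = np.flatnonzero(np.abs(rhos) > thr)
        for m in methods:
            if stratum.size == 0:
                rows.append((m, thr, float("nan"), 0, float("nan")))
                continue
            pvs = pv[m][stratum]
            ok = ~np.isnan(pvs)
            rate = float((pvs[ok] <= alpha_level).mean()) if ok.any() else float("nan")
            n_ok = int(ok.sum())
            rows.append(
                (m, thr, rate, n_ok,
                 float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else float("nan"))
            )
    table = pd.DataFrame(
        rows, columns=["method", "rho_threshold", "rejection_rate", "n_reps", "mc_se"]
    )
    if return_details:
        return table, rhos, pv
    return table
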