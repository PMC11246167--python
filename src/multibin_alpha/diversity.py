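"""Alpha-diversity measures for clonotype abundance vectors.

Four within-sample measures are supported, spanning richness and evenness:

- ``richness``: the observed number of unique clonotypes, :math:`S_{obs}`.
  Takes no account of clonotype frequencies.
- ``shannon``: :math:`H = -\\sum_i p_i \\ln p_i` with :math:`p_i = x_i / N`,
  in nats.  Sensitive to both richness and evenness.
- ``pielou``: Pielou's evenness :math:`J = H / \\ln S_{obs} \\in [0, 1]`;
  undefined for a single-clonotype sample, where NaN (the missing sentinel)
  is returned and propagated — silent substitution of 0 or 1 would bias
  downstream association tests.
- ``chao1_bc``: bias-corrected Chao1 richness estimator
  :math:`S_{obs} + f_1 (f_1 - 1) / (2 (f_2 + 1))`, where :math:`f_1`/:math:`f_2`
  are the singleton/doubleton counts.  The ``f2 + 1`` denominator handles
  :math:`f_2 = 0` without a special case.  Equals ``richness`` whenever
  :math:`f_1 \\le 1` — in deep TCR repertoires with no singletons the two
  measures coincide.

Plus Bray-Curtis dissimilarity, used to verify near-disjointness of the
simulation sequence pools.

An abundance vector is any 1-d array of nonnegative integer counts; zeros are
allowed (entries simply do not contribute).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "richness",
    "shannon",
    "pielou",
    "chao1_bc",
    "bray_curtis",
    "alpha_diversity",
    "ALPHA_METRICS",
]


def _as_counts(x, allow_empty: bool = True) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError("abundance vector must be 1-dimensional")
    if arr.size and not np.issubdtype(arr.dtype, np.number):
        raise ValueError("abundance vector must be numeric")
    arr = np.asarray(arr, dtype=np.int64)
    if np.any(arr < 0):
        raise ValueError("abundance vector must be nonnegative")
    if not allow_empty and (arr.size == 0 or arr.sum() == 0):
        raise ValueError("abundance vector has no reads (all zero)")
    return arr


def richness(x) -> int:
    """Number of clonotypes with a strictly positive count (``S_obs``)."""
    return int(np.count_nonzero(_as_counts(x)))


def shannon(x) -> float:
    """Shannon index in nats; 0 iff a single clonotype is present."""
    arr = _as_counts(x, allow_empty=False)
    pos = arr[arr > 0]
    p = pos / pos.sum()
    return float(-(p * np.log(p)).sum())


def pielou(x) -> float:
    """Pielou's evenness ``H / ln(S_obs)``; NaN when ``S_obs == 1``."""
    arr = _as_counts(x, allow_empty=False)
    s = int(np.count_nonzero(arr))
    if s == 1:
        return float("nan")
    return shannon(arr) / float(np.log(s))


def chao1_bc(x) -> float:
    """Bias-corrected Chao1: ``S_obs + f1*(f1-1) / (2*(f2+1))``."""
    arr = _as_counts(x, allow_empty=False)
    s = int(np.count_nonzero(arr))
    f1 = int(np.count_nonzero(arr == 1))
    f2 = int(np.count_nonzero(arr == 2))
    return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity ``1 - 2*sum(min(x,y)) / (Nx + Ny)``.

    Both vectors must be indexed on the same (union) clonotype set.  0 for
    identical vectors, 1 for disjoint supports.
    """
    ax = _as_counts(x, allow_empty=False)
    ay = _as_counts(y, allow_empty=False)
    if ax.shape != ay.shape:
        raise ValueError(
            "Bray-Curtis requires both vectors on the union clonotype index "
            f"(got lengths {ax.size} and {ay.size})"
        )
    shared = np.minimum(ax, ay).sum()
    return float(1.0 - 2.0 * shared / (ax.sum() + ay.sum()))


ALPHA_METRICS = {
    "richness": richness,
    "chao1_bc": chao1_bc,
    "shannon": shannon,
    "pielou": pielou,
}


def resolve_metric(metric):
    """Turn a metric name (or callable) into the metric function."""
    if callable(metric):
        return metric
    try:
        return ALPHA_METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown alpha-diversity metric {metric!r}; "
            f"choose from {sorted(ALPHA_METRICS)}"
        ) from None


def alpha_diversity(x, metric) -> float:
    """Dispatch to one of :data:`ALPHA_METRICS` by name."""
    return float(resolve_metric(metric)(x))
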