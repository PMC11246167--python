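"""Rarefaction: subsampling repertoires to a common depth without replacement.

A rarefied sample is a multivariate-hypergeometric draw: ``depth`` reads taken
uniformly without replacement from the multiset of ``N`` observed reads.  The
draw is generated category-by-category (conditional hypergeometric draws), so
memory stays O(#clonotypes) even at library sizes of 4e7.

``expected_richness`` provides the classical closed-form expectation of
observed richness under rarefaction (Hurlbert's formula),

    E[S(m)] = sum_i [ 1 - C(N - n_i, m) / C(N, m) ],

used as an independent oracle for the stochastic subsampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .diversity import resolve_metric

__all__ = [
    "RarefyResult",
    "rarefy",
    "mean_rarefied_alpha",
    "expected_richness",
    "rarefaction_curve",
]


@dataclass(frozen=True)
class RarefyResult:
    """A single rarefying draw: counts sum to ``depth`` exactly."""

    depth: int
    counts: np.ndarray
    replicate_seed: int


def _check_depth(total: int, depth: int) -> int:
    depth = int(depth)
    if depth < 1:
        raise ValueError("rarefying depth must be a positive integer")
    if depth > total:
        raise ValueError(
            f"cannot rarefy to depth {depth}: sample has only {total} reads"
        )
    return depth


def rarefy(x, depth: int, seed: int) -> RarefyResult:
    """Subsample ``depth`` reads without replacement from abundance vector x.

    Deterministic given ``(x, depth, seed)``: the draw uses numpy's PCG64
    generator seeded with ``seed``.
    """
    arr = np.asarray(x, dtype=np.int64)
    if np.any(arr < 0):
        raise ValueError("abundance vector must be nonnegative")
    total = int(arr.sum())
    depth = _check_depth(total, depth)
    if depth == total:
        counts = arr.copy()
    else:
        rng = np.random.default_rng(int(seed))
        counts = rng.multivariate_hypergeometric(arr, depth)
    return RarefyResult(depth=depth, counts=counts, replicate_seed=int(seed))


def mean_rarefied_alpha(x, depth: int, metric, n_rep: int = 1, seed: int = 0) -> float:
    """Average an alpha-diversity metric over ``n_rep`` rarefying draws.

    Replicate ``j`` uses sub-seed ``seed + j`` (counter-based), so each
    replicate is reproducible independently and ``n_rep=1`` coincides with
    ``metric(rarefy(x, depth, seed).counts)``.  Replicates where the metric is
    undefined (NaN, e.g. Pielou on a single-clonotype draw) are excluded from
    the mean with a warning.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    fn = resolve_metric(metric)
    vals = np.array(
        [fn(rarefy(x, depth, int(seed) + j).counts) for j in range(int(n_rep))],
        dtype=float,
    )
    ok = ~np.isnan(vals)
    if not ok.any():
        warnings.warn(
            f"metric undefined in all {n_rep} rarefying replicates; returning NaN",
            stacklevel=2,
        )
        return float("nan")
    if not ok.all():
        warnings.warn(
            f"metric undefined in {int((~ok).sum())}/{n_rep} rarefying replicates; "
            "excluded from the mean",
            stacklevel=2,
        )
    return float(vals[ok].mean())


def expected_richness(x, depth: int) -> float:
    """Exact expected richness of a without-replacement draw at ``depth``."""
    arr = np.asarray(x, dtype=np.int64)
    pos = arr[arr > 0]
    total = int(pos.sum())
    m = _check_depth(total, depth)
    # log C(N - n_i, m) - log C(N, m), with the term 0 when N - n_i < m
    rem = total - pos
    with np.errstate(invalid="ignore"):
        logp = (
            gammaln(rem + 1)
            - gammaln(rem - m + 1)
            + gammaln(total - m + 1)
            - gammaln(total + 1)
        )
    p_absent = np.where(rem >= m, np.exp(logp), 0.0)
    return float(np.sum(1.0 - p_absent))


def rarefaction_curve(x, depths, n_rep: int = 1, seed: int = 0, expected: bool = False):
    """Mean observed richness at each of a set of increasing depths.

    With ``expected=True`` the exact expectation (:func:`expected_richness`)
    replaces Monte-Carlo averaging; that curve is exactly nondecreasing and is
    how the saturation "elbow" is best located.
    """
    depths = [int(d) for d in depths]
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing")
    out = []
    for i, d in enumerate(depths):
        if expected:
            val = expected_richness(x, d)
        else:
            val = mean_rarefied_alpha(x, d, "richness", n_rep=n_rep, seed=int(seed) + 1000 * i)
        out.append((d, float(val)))
    return out
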