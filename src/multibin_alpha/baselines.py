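"""Baseline library-size normalizations for alpha-diversity association tests.

Three comparison strategies:

- no rarefying: alpha diversity straight from the raw counts;
- overall rarefying: pick one level ``L*``, discard every sample shallower
  than ``L*`` (strict inequality), subsample the rest to exactly ``L*``;
- LOESS residualization: fit a locally weighted regression of raw alpha on
  library size (log10 scale by default, span 0.5) and use the residuals in
  downstream tests.

Association testing is univariate OLS with the normalized alpha as the
outcome, identical to the within-bin model of the multi-bin method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._seeds import per_sample_seeds
from .diversity import resolve_metric
from .multibin import DegenerateBinError, _ols_slope
from .rarefaction import mean_rarefied_alpha

__all__ = [
    "BaselineResult",
    "no_rarefy_alpha",
    "overall_rarefy_alpha",
    "loess_residual_alpha",
    "baseline_association",
]


@dataclass(frozen=True)
class BaselineResult:
    """A baseline normalization plus its association test for one covariate."""

    method: str
    values: pd.Series
    retained: tuple
    estimate: float
    se: float
    pvalue: float


def no_rarefy_alpha(reps, metric) -> pd.Series:
    """Alpha diversity of the raw, non-rarefied counts."""
    fn = resolve_metric(metric)
    vals = {r.sample_id: float(fn(r.abundance())) for r in reps}
    out = pd.Series(vals, name="alpha", dtype=float)
    out.index.name = "sample_id"
    return out.sort_index()


def overall_rarefy_alpha(reps, metric, level: int, n_rep: int = 1, seed: int = 0):
    """Rarefy all sufficiently deep samples to a single common level.

    Samples with library size strictly below ``level`` are discarded and
    returned as the second element.  Per-sample seeds use the same derivation
    as the multi-bin pipeline, so at ``level = min(L_i)`` this reproduces the
    K=1 multi-bin alpha values exactly (same seed).
    """
    level = int(level)
    if level < 1:
        raise ValueError("rarefying level must be a positive integer")
    keep = [r for r in reps if r.library_size >= level]
    excluded = sorted(r.sample_id for r in reps if r.library_size < level)
    if not keep:
        raise ValueError(f"all samples have library size below {level}")
    seeds = per_sample_seeds([r.sample_id for r in keep], seed)
    vals = {
        r.sample_id: mean_rarefied_alpha(
            r.abundance(), level, metric, n_rep=n_rep, seed=seeds[r.sample_id]
        )
        for r in keep
    }
    out = pd.Series(vals, name="alpha", dtype=float)
    out.index.name = "sample_id"
    return out.sort_index(), excluded


def loess_residual_alpha(
    alpha: pd.Series,
    library_sizes: pd.Series,
    span: float = 0.5,
    log10_predictor: bool = True,
) -> pd.Series:
    """Residuals of a LOESS fit of alpha on library size.

    Local-linear smoother with tricube weights (statsmodels lowess) at the
    given span.  The predictor is log10(library size) by default — depths
    span orders of magnitude — with the raw scale behind the flag.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    alpha = alpha.dropna()
    x = library_sizes.reindex(alpha.index).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("library size missing for some samples")
    if len(alpha) < 10:
        raise ValueError(f"LOESS needs >= 10 samples, got {len(alpha)}")
    pred = np.log10(x) if log10_predictor else x
    fitted = lowess(alpha.to_numpy(dtype=float), pred, frac=span, return_sorted=False)
    resid = pd.Series(alpha.to_numpy() - fitted, index=alpha.index, name="alpha")
    resid.index.name = "sample_id"
    return resid


def baseline_association(values, covariate):
    """Univariate OLS of normalized alpha on a covariate: (slope, SE, p)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("values and covariate must have equal length")
    slope, var, p, _ = _ols_slope(y, x)
    if var == 0.0:
        raise DegenerateBinError("response is constant (zero residual variance)")
    return float(slope), float(np.sqrt(var)), float(p)
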