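"""Multi-bin rarefying with fixed-effect meta-analysis.

The method addresses library-size confounding in alpha-diversity association
tests.  Samples are partitioned into K bins by library size using user-chosen
cut points ``c_1 < ... < c_{K-1}`` (with ``c_0`` the minimum retained library
size and ``c_K`` the maximum); sample i joins bin k when
``c_{k-1} <= L_i < c_k`` (top bin closed).  Every sample in bin k is rarefied
to the bin's lower bound ``L*_k = c_{k-1}``, alpha diversity is computed at
that common depth, and the diversity-phenotype association is tested within
each bin by ordinary least squares (for a 0/1 covariate this is the
equal-variance two-sample t-test).  Per-bin slopes ``tau_k`` with variances
``V_k`` are pooled by fixed-effect meta-analysis,

    tau_hat = sum_k w_k tau_k / sum_k w_k,
    W       = (sum_k w_k tau_k)^2 / sum_k w_k^2 V_k  ~  chi2(1) under H0,

with weights ``w_k`` equal (1), sample-size (``n_k``), or inverse-variance
(``1/V_k``).

The statsmodels-style entry point is :class:`MultibinAlphaModel` /
:class:`MultibinAlphaResults`; the individual steps are exposed as functions
(:func:`assign_bins`, :func:`within_bin_alpha`, :func:`within_bin_association`,
:func:`pooled_effect`, :func:`wald_test`, :func:`multibin_alpha_test`,
:func:`bin_diagnostics`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import per_sample_seeds
from .diversity import resolve_metric
from .io import CohortTable
from .rarefaction import mean_rarefied_alpha

__all__ = [
    "DegenerateBinError",
    "BinPartition",
    "BinResult",
    "MetaResult",
    "assign_bins",
    "within_bin_alpha",
    "within_bin_association",
    "pooled_effect",
    "wald_test",
    "multibin_alpha_test",
    "bin_diagnostics",
    "MultibinAlphaModel",
    "MultibinAlphaResults",
    "WEIGHTINGS",
]

WEIGHTINGS = ("equal", "ssw", "ivw")

#: Bins below this size are dropped from the meta-analysis with a warning.
MIN_BIN_SIZE = 3


class DegenerateBinError(ValueError):
    """A bin cannot support a within-bin association test."""


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _assign_bins_array(L: np.ndarray, cut_points, min_depth=None):
    """Vectorised bin assignment.

    Returns ``(bins, lower, upper, retained)`` where ``bins`` holds 0-based
    bin indices (-1 = excluded), ``lower``/``upper`` the interval edges of
    the kept (non-empty) bins, and ``retained`` the boolean retention mask.
    """
    L = np.asarray(L, dtype=float)
    cuts = np.asarray(cut_points, dtype=float)
    if cuts.size and (np.any(np.diff(cuts) <= 0) or np.any(cuts <= 0)):
        raise ValueError("cut_points must be positive and strictly increasing")
    retained = np.ones(L.size, dtype=bool)
    if min_depth is not None:
        retained = L >= float(min_depth)
    if not retained.any():
        raise ValueError("all samples excluded by min_depth")
    c0 = float(L[retained].min())
    cK = float(L[retained].max())
    raw = np.searchsorted(cuts, L, side="right")  # c_{k-1} <= L < c_k
    raw[~retained] = -1
    kept = np.unique(raw[raw >= 0])
    n_possible = cuts.size + 1
    if kept.size < n_possible:
        warnings.warn(
            f"dropping {n_possible - kept.size} empty library-size bin(s)",
            stacklevel=3,
        )
    remap = -np.ones(n_possible, dtype=int)
    remap[kept] = np.arange(kept.size)
    bins = np.where(raw >= 0, remap[np.maximum(raw, 0)], -1)
    lower = np.array([c0 if k == 0 else cuts[k - 1] for k in kept])
    upper = np.array([cK if k == cuts.size else cuts[k] for k in kept])
    return bins, lower, upper, retained


@dataclass(frozen=True)
class BinPartition:
    """Library-size bins: membership, interval edges, rarefying levels."""

    assignments: pd.Series  # sample_id -> bin index (1-based)
    lower: np.ndarray       # per-bin lower edge = rarefying level L*_k
    upper: np.ndarray       # per-bin upper edge (top bin closed)
    excluded: tuple         # sample ids dropped by min_depth

    @property
    def K(self) -> int:
        return len(self.lower)

    @property
    def levels(self) -> np.ndarray:
        """Per-bin rarefying level ``L*_k`` (the bin's lower bound)."""
        return self.lower

    @property
    def bin_sizes(self) -> np.ndarray:
        counts = self.assignments.value_counts()
        return np.array([int(counts.get(k + 1, 0)) for k in range(self.K)])

    def level_of(self, sample_id) -> float:
        return float(self.lower[int(self.assignments.loc[sample_id]) - 1])


def _library_sizes_of(cohort) -> pd.Series:
    if isinstance(cohort, CohortTable):
        return cohort.library_sizes
    if isinstance(cohort, pd.DataFrame):
        return CohortTable(cohort).library_sizes
    if isinstance(cohort, pd.Series):
        return cohort
    # mapping sample_id -> L
    return pd.Series(dict(cohort), name="library_size")


def assign_bins(cohort, cut_points, min_depth=None) -> BinPartition:
    """Partition samples into library-size bins ``[c_{k-1}, c_k)``.

    ``cohort`` may be a :class:`CohortTable`, a DataFrame, or a Series/mapping
    of sample_id -> library size.  Samples with ``L_i < min_depth`` (if given)
    are excluded and reported on the partition; empty bins are dropped with a
    warning.  The rarefying level of each kept bin is its lower edge, with the
    bottom bin's edge equal to the minimum retained library size.
    """
    sizes = _library_sizes_of(cohort)
    bins, lower, upper, retained = _assign_bins_array(
        sizes.to_numpy(dtype=float), cut_points, min_depth
    )
    assignments = pd.Series(bins + 1, index=sizes.index, name="bin")
    excluded = tuple(sizes.index[~retained])
    assignments = assignments[retained]
    return BinPartition(
        assignments=assignments, lower=lower, upper=upper, excluded=excluded
    )


# ---------------------------------------------------------------------------
# within-bin alpha and association
# ---------------------------------------------------------------------------

def within_bin_alpha(
    reps, partition: BinPartition, metric, n_rep: int = 1, seed: int = 0
) -> pd.DataFrame:
    """Rarefy every sample to its own bin's level and compute alpha diversity.

    Returns a DataFrame indexed by sample_id with columns ``alpha``, ``bin``
    and ``level``.  Per-sample rarefying seeds are derived from ``seed`` by
    position in the sorted retained sample ids.
    """
    rep_map = {r.sample_id: r for r in reps}
    ids = list(partition.assignments.index)
    missing = [i for i in ids if i not in rep_map]
    if missing:
        raise KeyError(f"no repertoire for sample(s): {missing[:5]}")
    seeds = per_sample_seeds(ids, seed)
    rows = {}
    for sid in ids:
        k = int(partition.assignments.loc[sid])
        level = int(partition.lower[k - 1])
        x = rep_map[sid].abundance()
        val = mean_rarefied_alpha(x, level, metric, n_rep=n_rep, seed=seeds[sid])
        rows[sid] = (val, k, level)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["alpha", "bin", "level"]
    )
    out.index.name = "sample_id"
    return out


def _ols_slope(y: np.ndarray, x: np.ndarray):
    """Univariate OLS of y on x with intercept: (slope, var(slope), p, n).

    Raises DegenerateBinError for a constant covariate; a constant (or
    perfectly fitted) response yields variance 0, flagged by the caller.
    """
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    n = y.size
    if n < 3:
        raise DegenerateBinError(f"need >= 3 complete observations, got {n}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DegenerateBinError("covariate is constant")
    slope = float(xc @ y) / sxx
    resid = y - y.mean() - slope * xc
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    var = sigma2 / sxx
    if var > 0.0:
        t = slope / np.sqrt(var)
        p = 2.0 * stats.t.sf(abs(t), dof)
    else:
        p = float("nan") if slope == 0.0 else 0.0
    return slope, var, float(p), n


@dataclass(frozen=True)
class BinResult:
    """Within-bin association: slope ``tau_k``, variance ``V_k``, p-value."""

    k: int
    tau_hat: float
    var: float
    n: int
    pvalue: float
    level: float = float("nan")
    degenerate: bool = False


def within_bin_association(alpha, covariate, bin: int = 1, min_n: int = MIN_BIN_SIZE) -> BinResult:
    """OLS of alpha diversity on one covariate within a single bin.

    ``tau_hat`` is the slope, ``var`` the squared standard error; for a 0/1
    covariate this reproduces the equal-variance two-sample t-test.  Missing
    alpha values are dropped pairwise.  A constant covariate or an
    undersized bin raises :class:`DegenerateBinError`; a constant response
    returns a result flagged ``degenerate`` (tau 0, variance 0).
    """
    y = np.asarray(alpha, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("alpha and covariate must have equal length")
    n_complete = int((~(np.isnan(y) | np.isnan(x))).sum())
    if n_complete < min_n:
        raise DegenerateBinError(
            f"bin {bin}: {n_complete} complete observations < minimum {min_n}"
        )
    slope, var, p, n = _ols_slope(y, x)
    degenerate = var == 0.0
    return BinResult(
        k=int(bin), tau_hat=slope, var=var, n=n, pvalue=p, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# fixed-effect meta-analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaResult:
    """Pooled effect and Wald test under a named weighting scheme."""

    weighting: str
    tau_hat: float
    wald: float
    pvalue: float
    weights: np.ndarray = field(repr=False)
    bins_used: tuple = ()
    se: float = float("nan")


def _usable_bins(bins) -> list:
    usable = []
    for b in bins:
        if b.degenerate or not np.isfinite(b.var) or b.var <= 0.0:
            warnings.warn(
                f"bin {b.k} excluded from meta-analysis (degenerate or "
                "zero-variance estimate)",
                stacklevel=3,
            )
            continue
        usable.append(b)
    if not usable:
        raise ValueError("no usable bins for meta-analysis")
    return usable


def _weights_for(bins, weighting: str) -> np.ndarray:
    if weighting == "equal":
        return np.ones(len(bins))
    if weighting == "ssw":
        return np.array([b.n for b in bins], dtype=float)
    if weighting == "ivw":
        return np.array([1.0 / b.var for b in bins])
    raise ValueError(f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}")


def pooled_effect(bins, weighting: str = "ivw") -> MetaResult:
    """Weighted average of per-bin effects (no test statistic)."""
    usable = _usable_bins(bins)
    w = _weights_for(usable, weighting)
    tau = np.array([b.tau_hat for b in usable])
    pooled = float((w * tau).sum() / w.sum())
    return MetaResult(
        weighting=weighting,
        tau_hat=pooled,
        wald=float("nan"),
        pvalue=float("nan"),
        weights=w,
        bins_used=tuple(b.k for b in usable),
    )


def wald_test(bins, weighting: str = "ivw") -> MetaResult:
    """Pooled Wald test ``W = (sum w tau)^2 / sum w^2 V`` against chi2(1)."""
    usable = _usable_bins(bins)
    w = _weights_for(usable, weighting)
    tau = np.array([b.tau_hat for b in usable])
    V = np.array([b.var for b in usable])
    num = float((w * tau).sum())
    denom = float((w * w * V).sum())
    W = num * num / denom
    p = float(stats.chi2.sf(W, df=1))
    return MetaResult(
        weighting=weighting,
        tau_hat=num / float(w.sum()),
        wald=W,
        pvalue=p,
        weights=w,
        bins_used=tuple(b.k for b in usable),
        se=float(np.sqrt(denom) / w.sum()),
    )


def _associations_by_bin(alpha_df: pd.DataFrame, covariate: pd.Series, levels: np.ndarray):
    """Run within-bin OLS for every bin, flagging degenerate ones."""
    results = []
    for k, grp in alpha_df.groupby("bin", sort=True):
        cov = covariate.reindex(grp.index).to_numpy(dtype=float)
        level = float(levels[int(k) - 1])
        try:
            res = within_bin_association(grp["alpha"].to_numpy(), cov, bin=int(k))
            res = BinResult(
                k=res.k, tau_hat=res.tau_hat, var=res.var, n=res.n,
                pvalue=res.pvalue, level=level, degenerate=res.degenerate,
            )
        except DegenerateBinError as err:
            warnings.warn(f"degenerate bin: {err}", stacklevel=3)
            res = BinResult(
                k=int(k), tau_hat=float("nan"), var=float("nan"),
                n=len(grp), pvalue=float("nan"), level=level, degenerate=True,
            )
        results.append(res)
    return results


def multibin_alpha_test(
    reps,
    cohort,
    covariate_name: str,
    metric="richness",
    cut_points=(),
    weighting: str = "ivw",
    n_rep: int = 1,
    seed: int = 0,
    min_depth=None,
):
    """Full pipeline: bin, rarefy within bins, test within bins, pool.

    Returns ``(partition, bin_results, meta)`` where ``meta`` is the
    :class:`MetaResult` for the requested weighting.  With no interior cut
    points (K=1) this reduces exactly to overall rarefying at the minimum
    retained library size, and all weightings coincide.
    """
    model = MultibinAlphaModel(
        reps, cohort, covariate_name, metric=metric,
        cut_points=cut_points, min_depth=min_depth,
    )
    res = model.fit(weighting=weighting, n_rep=n_rep, seed=seed)
    return res.partition, res.bin_results, res.meta[weighting]


def bin_diagnostics(alpha_df: pd.DataFrame, cohort) -> pd.DataFrame:
    """Spearman correlation of alpha vs library size, per bin and overall.

    Intended for cut-point selection: a well-chosen partition shows no or
    little within-bin correlation.  Bins with fewer than 3 samples, or with
    constant alpha, report NaN.  Ties use average ranks.
    """
    sizes = _library_sizes_of(cohort).reindex(alpha_df.index)
    rows = []

    def _spear(sub_alpha, sub_L):
        a = np.asarray(sub_alpha, dtype=float)
        l = np.asarray(sub_L, dtype=float)
        ok = ~np.isnan(a)
        a, l = a[ok], l[ok]
        if a.size < 3 or np.all(a == a[0]) or np.all(l == l[0]):
            return float("nan"), float("nan")
        rho, p = stats.spearmanr(a, l)
        return float(rho), float(p)

    for k, grp in alpha_df.groupby("bin", sort=True):
        rho, p = _spear(grp["alpha"], sizes.loc[grp.index])
        rows.append(("bin", int(k), len(grp), rho, p))
    rho, p = _spear(alpha_df["alpha"], sizes)
    rows.append(("overall", 0, len(alpha_df), rho, p))
    return pd.DataFrame(
        rows, columns=["scope", "bin", "n", "spearman_rho", "pvalue"]
    )


# ---------------------------------------------------------------------------
# model / results front end
# ---------------------------------------------------------------------------

class MultibinAlphaModel:
    """Multi-bin alpha-diversity association model for a repertoire cohort.

    Parameters
    ----------
    reps : list of Repertoire
        Clonotype count data, one per sample.
    cohort : CohortTable or DataFrame
        Sample metadata holding the covariate; library sizes are taken from
        the repertoires.
    covariate : str
        Name of the phenotype/covariate column (numeric or two-level).
    metric : str
        One of ``richness``, ``chao1_bc``, ``shannon``, ``pielou``.
    cut_points : sequence of float
        Interior library-size thresholds ``c_1 < ... < c_{K-1}``; empty for a
        single bin (overall rarefying at the minimum).
    min_depth : float, optional
        Exclude samples shallower than this before binning (e.g. failed
        sequencing runs, which would otherwise drag the bottom rarefying
        level to a useless depth).
    """

    def __init__(self, reps, cohort, covariate, metric="richness",
                 cut_points=(), min_depth=None):
        self.reps = list(reps)
        if not self.reps:
            raise ValueError("no repertoires")
        if not isinstance(cohort, CohortTable):
            cohort = CohortTable(cohort)
        self.cohort = cohort
        self.covariate_name = covariate
        self.metric = metric
        resolve_metric(metric)  # fail fast on unknown metric
        self.cut_points = tuple(float(c) for c in cut_points)
        self.min_depth = min_depth
        ids = {r.sample_id for r in self.reps}
        missing = [s for s in ids if s not in cohort.df.index]
        if missing:
            raise KeyError(f"samples missing from cohort table: {sorted(missing)[:5]}")

    @classmethod
    def from_files(cls, reps_path, meta_path, covariate, column_map=None, **kwargs):
        from .io import read_cohort_table, read_repertoire_table

        reps = read_repertoire_table(reps_path, column_map=column_map)
        cohort = read_cohort_table(meta_path)
        return cls(reps, cohort, covariate, **kwargs)

    def fit(self, weighting: str = "ivw", n_rep: int = 1, seed: int = 0) -> "MultibinAlphaResults":
        """Run the pipeline; returns results with all three weightings."""
        if weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}")
        sizes = pd.Series(
            {r.sample_id: r.library_size for r in self.reps}, name="library_size"
        ).loc[lambda s: s.index.isin(self.cohort.df.index)]
        partition = assign_bins(sizes, self.cut_points, min_depth=self.min_depth)
        alpha_df = within_bin_alpha(
            self.reps, partition, self.metric, n_rep=n_rep, seed=seed
        )
        cov = self.cohort.covariate(self.covariate_name)
        bin_results = _associations_by_bin(alpha_df, cov, partition.levels)
        meta = {w: wald_test(bin_results, w) for w in WEIGHTINGS}
        return MultibinAlphaResults(
            model=self, partition=partition, alpha=alpha_df,
            bin_results=bin_results, meta=meta, weighting=weighting,
            n_rep=n_rep, seed=seed,
        )


@dataclass
class MultibinAlphaResults:
    """Fitted multi-bin analysis: per-bin estimates plus pooled tests."""

    model: MultibinAlphaModel
    partition: BinPartition
    alpha: pd.DataFrame = field(repr=False)
    bin_results: list = field(repr=False)
    meta: dict = field(repr=False)
    weighting: str = "ivw"
    n_rep: int = 1
    seed: int = 0

    @property
    def tau_hat(self) -> float:
        return self.meta[self.weighting].tau_hat

    @property
    def wald_stat(self) -> float:
        return self.meta[self.weighting].wald

    @property
    def pvalue(self) -> float:
        return self.meta[self.weighting].pvalue

    def bin_table(self) -> pd.DataFrame:
        rows = [
            {
                "bin": b.k, "n": b.n, "level": b.level, "tau_hat": b.tau_hat,
                "se": float(np.sqrt(b.var)) if b.var >= 0 else float("nan"),
                "pvalue": b.pvalue, "degenerate": b.degenerate,
            }
            for b in self.bin_results
        ]
        return pd.DataFrame(rows).set_index("bin")

    def meta_table(self) -> pd.DataFrame:
        rows = [
            {
                "weighting": w, "tau_hat": m.tau_hat, "W": m.wald,
                "pvalue": m.pvalue, "bins_used": len(m.bins_used), "se": m.se,
            }
            for w, m in self.meta.items()
        ]
        return pd.DataFrame(rows).set_index("weighting")

    def diagnostics(self) -> pd.DataFrame:
        sizes = pd.Series(
            {r.sample_id: r.library_size for r in self.model.reps}
        )
        return bin_diagnostics(self.alpha, sizes)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Multi-bin rarefying alpha-diversity association",
            "=" * 63,
            f"Metric: {m.metric}   Covariate: {m.covariate_name}   "
            f"Weighting: {self.weighting}",
            f"Samples: {len(self.partition.assignments)} retained, "
            f"{len(self.partition.excluded)} excluded; K = {self.partition.K} bins",
            "-" * 63,
            "Per-bin estimates (rarefied to the bin lower bound L*_k):",
            self.bin_table().to_string(float_format=lambda v: f"{v:.4g}"),
            "-" * 63,
            "Fixed-effect meta-analysis (W ~ chi2, df=1):",
            self.meta_table().to_string(float_format=lambda v: f"{v:.4g}"),
            "=" * 63,
        ]
        return "\n".join(lines)

    def plot_bins(self, ax=None):
        """Scatter of alpha vs log10 library size, coloured by bin."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sizes = pd.Series({r.sample_id: r.library_size for r in self.model.reps})
        for k, grp in self.alpha.groupby("bin"):
            ax.scatter(
                np.log10(sizes.loc[grp.index]), grp["alpha"], s=12,
                label=f"bin {k}",
            )
        ax.set_xlabel("log10 library size")
        ax.set_ylabel(f"alpha ({self.model.metric})")
        ax.legend(fontsize=8)
        return ax
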