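import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_cohort, make_repertoire
from multibin_alpha.baselines import overall_rarefy_alpha
from multibin_alpha.multibin import (
    BinResult,
    DegenerateBinError,
    MultibinAlphaModel,
    assign_bins,
    bin_diagnostics,
    multibin_alpha_test,
    pooled_effect,
    wald_test,
    within_bin_alpha,
    within_bin_association,
)


# ---------------------------------------------------------------- binning

def test_boundary_sample_goes_to_the_upper_bin():
    part = assign_bins({"a": 5, "b": 10, "c": 25}, (10, 20))
    assert part.assignments.to_dict() == {"a": 1, "b": 2, "c": 3}
    assert part.levels.tolist() == [5, 10, 20]
    assert part.upper.tolist() == [10, 20, 25]


def test_six_bins_from_five_cut_points():
    rng = np.random.default_rng(0)
    L = np.concatenate([
        rng.integers(lo, hi, size=20)
        for lo, hi in [(1e5, 1e6), (1e6, 2e6), (2e6, 4e6), (4e6, 8e6),
                       (8e6, 1e7), (1e7, 4e7)]
    ])
    part = assign_bins(dict(enumerate(L)), (1e6, 2e6, 4e6, 8e6, 1e7))
    assert part.K == 6
    assert np.all(part.bin_sizes == 20)


def test_nonincreasing_cut_points_rejected():
    with pytest.raises(ValueError, match="increasing"):
        assign_bins({"a": 5, "b": 30}, (20, 10))


def test_min_depth_excludes_and_reports():
    part = assign_bins({"a": 50, "b": 500, "c": 5000}, (1000,), min_depth=100)
    assert part.excluded == ("a",)
    assert part.levels[0] == 500  # bottom level is the minimum retained size
    with pytest.raises(ValueError, match="excluded"):
        assign_bins({"a": 50}, (), min_depth=100)


def test_empty_bins_are_dropped_with_warning():
    with pytest.warns(UserWarning, match="empty"):
        part = assign_bins({"a": 5, "b": 6, "c": 50}, (10, 20, 30))
    assert part.K == 2  # [5,10) and [30,50]; [10,20),[20,30) empty
    assert part.assignments.to_dict() == {"a": 1, "b": 1, "c": 2}


def test_partition_covers_retained_samples_exactly_once():
    rng = np.random.default_rng(3)
    L = {f"s{i}": int(v) for i, v in enumerate(rng.integers(100, 10_000, 200))}
    part = assign_bins(L, (500, 2000, 5000))
    assert sorted(part.assignments.index) == sorted(L)
    sizes = np.array([L[s] for s in part.assignments.index])
    levels = part.levels[part.assignments.to_numpy() - 1]
    assert np.all(levels <= sizes)  # rarefying always feasible


# ------------------------------------------------- within-bin association

def test_ols_slope_matches_closed_form_two_group_example():
    res = within_bin_association([1, 2, 3, 4], [0, 0, 1, 1])
    assert res.tau_hat == pytest.approx(2.0)
    assert res.var == pytest.approx(0.5)


def test_ols_matches_statsmodels_and_ttest():
    import statsmodels.api as sm
    from scipy import stats

    rng = np.random.default_rng(5)
    y = rng.normal(size=40)
    x = rng.normal(size=40)
    res = within_bin_association(y, x)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    assert res.tau_hat == pytest.approx(fit.params[1])
    assert np.sqrt(res.var) == pytest.approx(fit.bse[1])
    assert res.pvalue == pytest.approx(fit.pvalues[1])
    # binary covariate: identical to the equal-variance two-sample t-test
    g = np.repeat([0.0, 1.0], 20)
    res2 = within_bin_association(y, g)
    t, p = stats.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
    assert res2.pvalue == pytest.approx(p)
    assert res2.tau_hat == pytest.approx(y[g == 1].mean() - y[g == 0].mean())


def test_degenerate_bins_raise_or_flag():
    with pytest.raises(DegenerateBinError, match="constant"):
        within_bin_association([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
    with pytest.raises(DegenerateBinError, match="minimum"):
        within_bin_association([1.0, 2.0], [0.0, 1.0])
    res = within_bin_association([2.0, 2.0, 2.0, 2.0], [0, 0, 1, 1])
    assert res.degenerate and res.tau_hat == 0.0 and res.var == 0.0


def test_missing_alpha_dropped_pairwise():
    res = within_bin_association([1, 2, np.nan, 3, 4], [0, 0, 0, 1, 1])
    assert res.n == 4
    assert res.tau_hat == pytest.approx(2.0)


# ------------------------------------------------------- meta-analysis

def _bins(taus, Vs, ns=None):
    ns = ns or [10] * len(taus)
    return [
        BinResult(k=i + 1, tau_hat=t, var=v, n=n, pvalue=0.5)
        for i, (t, v, n) in enumerate(zip(taus, Vs, ns))
    ]


def test_pooled_effect_examples():
    assert pooled_effect(_bins([1, 3], [1, 1]), "equal").tau_hat == pytest.approx(2.0)
    assert pooled_effect(_bins([0, 2], [1, 3]), "ivw").tau_hat == pytest.approx(0.5)
    for w in ("equal", "ssw", "ivw"):
        assert pooled_effect(_bins([3], [2]), w).tau_hat == pytest.approx(3.0)


def test_wald_statistic_and_pvalue():
    from scipy import stats

    meta = wald_test(_bins([2, 2], [1, 1]), "equal")
    assert meta.wald == pytest.approx(8.0)
    assert meta.pvalue == pytest.approx(stats.chi2.sf(8.0, 1))
    assert meta.pvalue == pytest.approx(0.004677, abs=1e-6)
    single = wald_test(_bins([3], [1]), "ssw")
    assert single.wald == pytest.approx(9.0)  # squared z-score


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(-5, 5), min_size=1, max_size=6),
    st.lists(st.floats(0.01, 10), min_size=6, max_size=6),
    st.floats(0.1, 100),
)
def test_weight_scaling_invariance_and_ivw_identity(taus, Vs, scale):
    bins = _bins(taus, Vs[: len(taus)])
    meta = wald_test(bins, "ivw")
    # scaling all weights leaves tau, W unchanged: compare ivw to manually
    # scaled weights via the generic formula
    w = np.array([1.0 / b.var for b in bins]) * scale
    tau = np.array([b.tau_hat for b in bins])
    V = np.array([b.var for b in bins])
    W_scaled = (w @ tau) ** 2 / (w**2 @ V)
    assert meta.wald == pytest.approx(W_scaled, rel=1e-9)
    # IVW identity: W = tau_pooled^2 * sum(1/V)
    assert meta.wald == pytest.approx(meta.tau_hat**2 * (1.0 / V).sum(), rel=1e-9)
    assert meta.se == pytest.approx(np.sqrt(1.0 / (1.0 / V).sum()), rel=1e-9)


def test_meta_requires_a_usable_bin():
    bad = [BinResult(k=1, tau_hat=0.0, var=0.0, n=5, pvalue=np.nan, degenerate=True)]
    with pytest.raises(ValueError, match="no usable bins"), pytest.warns(UserWarning):
        wald_test(bad, "equal")


# ------------------------------------------------------- full pipeline

def _toy_cohort(n=60, seed=0):
    rng = np.random.default_rng(seed)
    L = rng.integers(200, 5000, size=n)
    reps = [
        make_repertoire(f"S{i:03d}", rng.multinomial(L[i], np.full(50, 0.02)))
        for i in range(n)
    ]
    sizes = [r.library_size for r in reps]
    group = rng.integers(0, 2, size=n)
    return reps, make_cohort(sizes, covariate=group)


def test_k1_reduces_to_overall_rarefying_at_the_minimum():
    reps, cohort = _toy_cohort()
    part, bins, meta = multibin_alpha_test(
        reps, cohort, "group", metric="shannon", cut_points=(), seed=9
    )
    assert part.K == 1
    overall, excluded = overall_rarefy_alpha(
        reps, "shannon", level=int(min(cohort.library_sizes)), seed=9
    )
    mb = within_bin_alpha(reps, part, "shannon", seed=9)["alpha"].sort_index()
    assert excluded == []
    pd.testing.assert_series_equal(mb, overall, check_names=False)
    # all weightings coincide for a single bin
    model = MultibinAlphaModel(reps, cohort, "group", metric="shannon")
    res = model.fit(seed=9)
    metas = [res.meta[w] for w in ("equal", "ssw", "ivw")]
    assert len({round(m.pvalue, 12) for m in metas}) == 1
    assert len({round(m.tau_hat, 12) for m in metas}) == 1


def test_per_bin_rarefying_levels_are_the_bin_lower_bounds():
    reps, cohort = _toy_cohort()
    part, bins, _ = multibin_alpha_test(
        reps, cohort, "group", metric="richness", cut_points=(1000, 2500), seed=2
    )
    levels = {b.k: b.level for b in bins}
    assert levels[2] == 1000 and levels[3] == 2500
    alpha = within_bin_alpha(reps, part, "richness", seed=2)
    deep = alpha[alpha["bin"] == 3]
    assert (deep["level"] == 2500).all()  # deep samples keep their own level


def test_sample_at_its_level_is_not_subsampled():
    reps, cohort = _toy_cohort()
    part = assign_bins(cohort.library_sizes, ())
    alpha = within_bin_alpha(reps, part, "richness", seed=0)
    smallest = cohort.library_sizes.idxmin()
    rep = next(r for r in reps if r.sample_id == smallest)
    assert alpha.loc[smallest, "alpha"] == len(rep.counts)


def test_degenerate_bin_is_excluded_from_meta():
    reps, cohort = _toy_cohort(n=40, seed=4)
    # force one tiny bin: cut just below the maximum library size
    cuts = (int(cohort.library_sizes.max()) - 1,)
    with pytest.warns(UserWarning):
        part, bins, meta = multibin_alpha_test(
            reps, cohort, "group", metric="richness", cut_points=cuts, seed=1
        )
    assert len(meta.bins_used) < part.K


def test_results_summary_and_tables():
    reps, cohort = _toy_cohort()
    model = MultibinAlphaModel(
        reps, cohort, "group", metric="shannon", cut_points=(1000, 2500)
    )
    res = model.fit(weighting="ivw", seed=0)
    text = res.summary()
    assert "Fixed-effect meta-analysis" in text and "ivw" in text
    assert set(res.meta_table().index) == {"equal", "ssw", "ivw"}
    assert res.pvalue == res.meta["ivw"].pvalue
    assert 0 < res.pvalue <= 1
    assert np.isfinite(res.tau_hat) and res.wald_stat >= 0


def test_fit_is_deterministic_given_seed():
    reps, cohort = _toy_cohort()
    model = MultibinAlphaModel(reps, cohort, "group", metric="richness",
                               cut_points=(1000, 2500))
    r1 = model.fit(seed=5)
    r2 = model.fit(seed=5)
    r3 = model.fit(seed=6)
    pd.testing.assert_frame_equal(r1.alpha, r2.alpha)
    assert r1.pvalue == r2.pvalue
    assert r1.alpha["alpha"].tolist() != r3.alpha["alpha"].tolist()


# ------------------------------------------------------- diagnostics

def test_bin_diagnostics_signs_and_missing():
    ids = [f"S{i}" for i in range(12)]
    alpha = pd.DataFrame(
        {
            "alpha": np.r_[np.arange(6, dtype=float), np.full(6, 2.0)],
            "bin": np.r_[np.ones(6, int), np.full(6, 2, int)],
        },
        index=ids,
    )
    sizes = pd.Series(np.arange(12, dtype=float) * 100 + 100, index=ids)
    diag = bin_diagnostics(alpha, sizes)
    b1 = diag[(diag.scope == "bin") & (diag.bin == 1)].iloc[0]
    b2 = diag[(diag.scope == "bin") & (diag.bin == 2)].iloc[0]
    assert b1.spearman_rho == pytest.approx(1.0)   # alpha increasing in L
    assert np.isnan(b2.spearman_rho)               # constant alpha: undefined
    assert (diag.scope == "overall").sum() == 1
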