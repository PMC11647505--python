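"""Size factors, dispersion, NB Wald testing, BH, overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trfseq.differential import (
    DiffParams,
    bh_adjust,
    estimate_dispersion,
    nb_wald_test,
    overlap_analysis,
    pooled_dispersion,
    size_factors,
)


def frame(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=samples)


def conditions(n_wt, n_ko):
    return pd.Series(
        ["WT"] * n_wt + ["KO"] * n_ko,
        index=[f"s{i}" for i in range(n_wt + n_ko)],
    )


# ---------------------------------------------------------------- size factors


def test_identical_samples_unit_factors():
    counts = frame([[10, 10], [7, 7], [100, 100]])
    assert np.allclose(size_factors(counts), [1.0, 1.0])


def test_doubled_sample_sqrt2_factors():
    """sample2 = 2 x sample1 -> factors (1/sqrt2, sqrt2) by hand
    evaluation of median-of-ratios with a geometric-mean reference."""
    counts = frame([[10, 20], [50, 100], [7, 14]])
    sf = size_factors(counts)
    assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])


def test_single_sample_unit_factor():
    assert np.allclose(size_factors(frame([[5], [9]])), [1.0])


def test_no_common_nonzero_feature_errors():
    with pytest.raises(ValueError, match="nonzero"):
        size_factors(frame([[0, 5], [5, 0]]))


def test_scale_equivariance():
    """Multiplying one sample by c multiplies its factor by c relative
    to the others (median-of-ratios property)."""
    rng = np.random.default_rng(0)
    counts = frame(rng.poisson(100, size=(50, 3)))
    sf = size_factors(counts)
    scaled = counts.copy()
    scaled["s1"] *= 4
    sf2 = size_factors(scaled)
    assert sf2["s1"] / sf2["s0"] == pytest.approx(4 * sf["s1"] / sf["s0"], rel=1e-9)


# ----------------------------------------------------------------- dispersion


def test_constant_counts_floor_dispersion():
    counts = frame(np.full((3, 6), 50))
    disp = estimate_dispersion(counts, size_factors(counts), conditions(3, 3))
    assert np.allclose(disp, 1e-8)


def test_poisson_dispersion_near_zero():
    """True alpha=0: per-feature MoM pooled over many replicates stays
    near zero (consistency at large n)."""
    rng = np.random.default_rng(2)
    counts = frame(rng.poisson(200, size=(5, 2000)))
    cond = pd.Series(["WT"] * 1000 + ["KO"] * 1000, index=counts.columns)
    disp = estimate_dispersion(counts, size_factors(counts), cond)
    # SE of MoM alpha-hat at mu=200, n=1000 is ~ sqrt(2/n)(1/mu+alpha) ~ 2e-4
    assert (disp < 3 * np.sqrt(2 / 1000) * (1 / 200)).all() or (disp == 1e-8).any()
    assert disp.max() < 2e-3


def test_nb_dispersion_recovered():
    """alpha=0.1 at n=500/condition recovered within [0.07, 0.13]."""
    rng = np.random.default_rng(3)
    r = 10.0
    counts = frame(rng.negative_binomial(r, r / (r + 200.0), size=(20, 1000)))
    cond = pd.Series(["WT"] * 500 + ["KO"] * 500, index=counts.columns)
    disp = estimate_dispersion(counts, size_factors(counts), cond)
    assert ((disp > 0.07) & (disp < 0.13)).all()
    pooled = pooled_dispersion(counts, size_factors(counts), cond)
    assert 0.09 < pooled < 0.11


def test_dispersion_requires_replicates():
    counts = frame([[1, 2], [3, 4]])
    with pytest.raises(ValueError, match="replicates"):
        estimate_dispersion(counts, size_factors(counts), conditions(1, 1))


# ------------------------------------------------------------------------- BH


def test_bh_hand_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust([0.2]), [0.2])
    assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
@settings(max_examples=200, deadline=None)
def test_bh_monotone_and_dominating(pvals):
    padj = bh_adjust(pvals)
    assert (padj >= np.asarray(pvals) - 1e-12).all()
    assert (padj <= 1.0).all()
    order = np.argsort(pvals)
    assert (np.diff(padj[order]) >= -1e-12).all()


# ------------------------------------------------------------------ Wald test


def test_identical_groups_null_result():
    counts = frame([[30, 30, 30, 30, 30, 30], [7, 7, 7, 7, 7, 7]])
    res = nb_wald_test(counts, conditions(3, 3))
    assert np.allclose(res["log2FC"], 0.0)
    assert np.allclose(res["pvalue"], 1.0)
    assert not res["significant"].any()


def test_all_zero_feature_na_and_excluded_from_m():
    arr = np.vstack([np.zeros(6), [[10, 12, 9, 50, 55, 40]], [[5, 6, 7, 5, 6, 7]]])
    res = nb_wald_test(frame(arr), conditions(3, 3))
    assert res.loc["g0", ["log2FC", "pvalue", "padj"]].isna().all()
    testable_p = res.loc[["g1", "g2"], "pvalue"].to_numpy()
    assert np.allclose(
        res.loc[["g1", "g2"], "padj"].to_numpy(), bh_adjust(testable_p)
    )


def test_zero_group_pseudocount_finite_lfc():
    arr = np.array([[0, 0, 0, 40, 44, 36], [20, 22, 18, 20, 22, 18]])
    res = nb_wald_test(frame(arr), conditions(3, 3))
    assert np.isfinite(res.loc["g0", "log2FC"])
    assert res.loc["g0", "log2FC"] > 4  # strong induction, bounded by pseudo


def test_lfc_invariant_to_sample_rescaling():
    rng = np.random.default_rng(4)
    counts = frame(rng.poisson(100, size=(60, 6)))
    res = nb_wald_test(counts, conditions(3, 3))
    scaled = counts.copy()
    scaled["s0"] *= 3
    res2 = nb_wald_test(scaled, conditions(3, 3))
    assert np.allclose(res["log2FC"], res2["log2FC"], atol=1e-9)


def test_detects_large_depletion():
    rng = np.random.default_rng(5)
    null = rng.poisson(200, size=(80, 6))
    de_wt = rng.poisson(400, size=(8, 3))
    de_ko = rng.poisson(50, size=(8, 3))
    counts = frame(np.vstack([null, np.hstack([de_wt, de_ko])]))
    res = nb_wald_test(counts, conditions(3, 3))
    de_index = [f"g{i}" for i in range(80, 88)]
    assert res.loc[de_index, "significant"].mean() >= 0.9
    assert res.loc[de_index, "log2FC"].mean() == pytest.approx(-3, abs=0.5)
    null_index = [f"g{i}" for i in range(80)]
    assert res.loc[null_index, "significant"].mean() <= 0.05


def test_null_pvalues_roughly_uniform_smoke():
    """Fast single-draw check; the calibration study lives in the
    acceptance suite."""
    rng = np.random.default_rng(6)
    r = 10.0
    counts = frame(rng.negative_binomial(r, r / (r + 200.0), size=(400, 6)))
    res = nb_wald_test(counts, conditions(3, 3))
    assert stats.kstest(res["pvalue"], "uniform").statistic < 0.08
    assert (res["pvalue"] < 0.05).mean() < 0.10


def test_reference_condition_orientation():
    """log2FC is second condition over the named reference."""
    arr = np.array([[10, 10, 10, 40, 40, 40]])
    cond = conditions(3, 3)
    # unit size factors: with one feature, median-of-ratios would
    # otherwise absorb the group difference entirely
    unit = pd.Series(1.0, index=cond.index)
    res = nb_wald_test(frame(arr), cond, reference="WT", sf=unit)
    assert res["log2FC"].iloc[0] == pytest.approx(2.0, abs=0.1)
    flipped = nb_wald_test(frame(arr), cond, reference="KO", sf=unit)
    assert flipped["log2FC"].iloc[0] == pytest.approx(-2.0, abs=0.1)


# -------------------------------------------------------------------- overlap


def result_frame(sig_features, lfc, all_features):
    padj = pd.Series(1.0, index=all_features)
    padj[sig_features] = 0.01
    return pd.DataFrame({"padj": padj, "log2FC": lfc})


def test_overlap_examples():
    space = list("xyzw")
    a = result_frame(["x", "y", "z"], -2.0, space)
    b = result_frame(["y", "z", "w"], -2.0, space)
    out = overlap_analysis(a, b)
    assert (out["n_shared"], out["n_sig_a"], out["n_sig_b"]) == (2, 3, 3)
    assert out["frac_of_a"] == pytest.approx(2 / 3)
    assert out["n_shared_down"] == 2

    same = overlap_analysis(a, a)
    assert same["frac_of_a"] == 1.0

    empty = overlap_analysis(a, result_frame([], -2.0, space))
    assert empty["n_shared"] == 0


def test_overlap_disjoint_namespaces_warns():
    a = result_frame(["x"], -1.0, ["x"])
    b = result_frame(["q"], -1.0, ["q"])
    with pytest.warns(UserWarning):
        out = overlap_analysis(a, b)
    assert out["n_shared"] == 0


def test_overlap_lfc_rule():
    space = list("xy")
    a = result_frame(["x", "y"], pd.Series([-2.0, -0.5], index=space), space)
    b = result_frame(["x", "y"], pd.Series([-2.0, -0.5], index=space), space)
    out = overlap_analysis(a, b, require_lfc=True)
    assert out["n_sig_a"] == 1  # y fails |lfc|>1
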