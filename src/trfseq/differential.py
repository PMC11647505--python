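"""Negative-binomial differential abundance between two conditions.

The procedure is a self-contained, fully specified analogue of the
count-based differential testing used for small-RNA features:

1. median-of-ratios size factors (per-sample count over the feature's
   geometric-mean reference, median over features nonzero everywhere);
2. a negative-binomial dispersion (Var = mu + alpha * mu^2).  By
   default one alpha is pooled across features by matching the Pearson
   chi-square of within-condition residuals to its degrees of freedom;
   a per-feature method-of-moments estimator is also provided.  Pooling
   matters: with 2-3 replicates a per-feature variance estimate is so
   noisy that a normal-reference Wald test is strongly anti-conservative,
   while sharing one dispersion across features (the generator's own
   regime) gives calibrated p-values without any shrinkage machinery;
3. a Wald test on log2 of the ratio of normalized group means, with a
   delta-method standard error and a two-sided normal reference;
4. Benjamini-Hochberg adjustment (all-zero features excluded from m);
   a feature is called significant when |log2FC| exceeds ``lfc_cutoff``
   and padj < ``alpha``.

No dispersion or fold-change shrinkage, outlier handling, or
independent filtering is attempted; this is deliberately simpler than
full GLM machinery and its outputs on real data will differ from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

LN2_SQ = np.log(2.0) ** 2


@dataclass(frozen=True)
class DiffParams:
    lfc_cutoff: float = 1.0
    alpha: float = 0.05
    dispersion_floor: float = 1e-8
    zero_group_pseudo: float = 0.5  # added to a group mean only when all-zero
    dispersion_method: str = "pooled"  # pooled | per_feature

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over features g (nonzero in every sample) of
    counts_gj / geomean_g.  An all-equal table yields factors of 1.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ValueError("counts must be a feature x sample table")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; supply a "
            "pseudo-reference or filter samples"
        )
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    conditions: pd.Series,
    floor: float = 1e-8,
) -> pd.Series:
    """Per-feature method-of-moments NB dispersion.

    Within each condition, alpha = (s^2 - mean)/mean^2 on normalized
    counts; the per-condition values are averaged and clipped at
    ``floor``.  Requires >= 2 replicates per condition.  Noisy at small
    n — see :func:`pooled_dispersion` for the default used in testing.
    """
    groups = _group_columns(counts, conditions)
    for cond, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has <2 replicates")
    normed = counts / sf
    per_cond = []
    for cond, cols in groups.items():
        sub = normed[cols].to_numpy(dtype=float)
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (var - mean) / mean**2
        per_cond.append(np.where(np.isfinite(alpha), alpha, 0.0))
    pooled = np.mean(per_cond, axis=0)
    return pd.Series(
        np.maximum(floor, pooled), index=counts.index, name="dispersion"
    )


def pooled_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    conditions: pd.Series,
    floor: float = 1e-8,
    upper: float = 100.0,
) -> float:
    """One NB dispersion shared across features, by Pearson-chi-square
    moment matching on within-condition residuals.

    Solves sum_gj (c_gj - mu_gj)^2 / (mu_gj + a mu_gj^2) = residual df,
    with mu_gj = (group mean of normalized counts) * sf_j.
    """
    groups = _group_columns(counts, conditions)
    mat = counts.to_numpy(dtype=float)
    sf_arr = sf[counts.columns].to_numpy(dtype=float)
    normed = mat / sf_arr
    blocks = []  # (obs, mu0) per group with nonzero mean
    df = 0
    for cols in groups.values():
        idx = [counts.columns.get_loc(c) for c in cols]
        sub = mat[:, idx]
        q = normed[:, idx].mean(axis=1)
        ok = q > 0
        if not ok.any():
            continue
        mu = q[ok, None] * sf_arr[idx][None, :]
        blocks.append((sub[ok], mu))
        df += ok.sum() * (len(idx) - 1)
    if df <= 0:
        return floor

    def excess(a: float) -> float:
        total = 0.0
        for obs, mu in blocks:
            total += (((obs - mu) ** 2) / (mu + a * mu**2)).sum()
        return total - df

    if excess(0.0) <= 0:
        return floor
    if excess(upper) > 0:
        return upper
    return max(floor, optimize.brentq(excess, 0.0, upper))


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(counts: pd.DataFrame, conditions: pd.Series) -> dict[str, list]:
    missing = [c for c in counts.columns if c not in conditions.index]
    if missing:
        raise ValueError(f"samples without condition label: {missing}")
    groups: dict[str, list] = {}
    for col in counts.columns:
        groups.setdefault(conditions[col], []).append(col)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 conditions, got {sorted(groups)}")
    return groups


def nb_wald_test(
    counts: pd.DataFrame,
    conditions: pd.Series,
    params: DiffParams = DiffParams(),
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-feature Wald test of KO-vs-WT (second-vs-reference) means.

    ``reference`` names the baseline condition (defaults to the first
    condition label in ``conditions``'s order of appearance).  Features
    with zero counts everywhere get NA statistics and do not count
    toward the BH m.  Returns a frame with baseMean, log2FC, se, stat,
    pvalue, padj and significant.
    """
    groups = _group_columns(counts, conditions)
    labels = list(groups)
    if reference is None:
        reference = labels[0]
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not among conditions")
    other = next(c for c in labels if c != reference)
    if sf is None:
        sf = size_factors(counts)
    normed = counts / sf
    ref_mat = normed[groups[reference]].to_numpy(dtype=float)
    alt_mat = normed[groups[other]].to_numpy(dtype=float)
    n_ref, n_alt = ref_mat.shape[1], alt_mat.shape[1]
    mu_ref = ref_mat.mean(axis=1)
    mu_alt = alt_mat.mean(axis=1)
    base_mean = normed.to_numpy(dtype=float).mean(axis=1)

    if dispersions is not None:
        alpha_arr = dispersions.reindex(counts.index).to_numpy(dtype=float)
    elif params.dispersion_method == "per_feature":
        alpha_arr = estimate_dispersion(
            counts, sf, conditions, params.dispersion_floor
        ).to_numpy()
    else:
        alpha_arr = np.full(
            len(counts),
            max(
                params.dispersion_floor,
                pooled_dispersion(counts, sf, conditions, params.dispersion_floor),
            ),
        )

    all_zero = (counts.to_numpy() == 0).all(axis=1)
    mu_ref_adj = np.where(mu_ref == 0, params.zero_group_pseudo, mu_ref)
    mu_alt_adj = np.where(mu_alt == 0, params.zero_group_pseudo, mu_alt)
    log2fc = np.log2(mu_alt_adj / mu_ref_adj)
    se = np.sqrt(
        ((1.0 / mu_alt_adj + alpha_arr) / n_alt + (1.0 / mu_ref_adj + alpha_arr) / n_ref)
        / LN2_SQ
    )
    wald = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))

    padj = np.full(len(counts), np.nan)
    testable = ~all_zero
    if testable.any():
        padj[testable] = bh_adjust(pvalue[testable])
    result = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "se": se,
            "stat": wald,
            "pvalue": pvalue,
            "padj": padj,
            "dispersion": alpha_arr,
        },
        index=counts.index,
    )
    result.loc[all_zero, ["log2FC", "se", "stat", "pvalue", "padj"]] = np.nan
    result["significant"] = (
        (result["log2FC"].abs() > params.lfc_cutoff)
        & (result["padj"] < params.alpha)
    ).fillna(False)
    return result


def overlap_analysis(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    alpha: float = 0.05,
    require_lfc: bool = False,
    lfc_cutoff: float = 1.0,
) -> dict:
    """Shared significant features between two comparisons.

    By default significance is padj < alpha alone (the overlap rule);
    with ``require_lfc`` the volcano rule (|log2FC| > cutoff as well) is
    applied.  Reports the intersection, the direction-concordant
    (both-down) subset and overlap fractions.
    """
    def sig_set(res: pd.DataFrame) -> set:
        mask = res["padj"] < alpha
        if require_lfc:
            mask &= res["log2FC"].abs() > lfc_cutoff
        return set(res.index[mask.fillna(False)])

    shared_space = set(results_a.index) & set(results_b.index)
    if not shared_space:
        import warnings

        warnings.warn("disjoint feature namespaces; empty overlap")
    sig_a, sig_b = sig_set(results_a), sig_set(results_b)
    inter = sig_a & sig_b
    both_down = {
        k
        for k in inter
        if results_a.loc[k, "log2FC"] < 0 and results_b.loc[k, "log2FC"] < 0
    }
    return {
        "n_sig_a": len(sig_a),
        "n_sig_b": len(sig_b),
        "n_shared": len(inter),
        "n_shared_down": len(both_down),
        "frac_of_a": len(inter) / len(sig_a) if sig_a else 0.0,
        "frac_of_b": len(inter) / len(sig_b) if sig_b else 0.0,
        "shared": sorted(inter),
    }
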