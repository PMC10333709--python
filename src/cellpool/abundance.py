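"""Differential cluster-abundance testing before/after allergen challenge.

Per-sample cluster counts are normalized to each sample's total (CD45+
cells, or mononuclear cells when granulocytes are excluded from the
denominator) to correct for varying biopsy yields. For each cluster and
each subject group separately, the challenge effect on the cluster's
frequency is estimated with the overdispersed binomial mixed model of
:mod:`cellpool.glmm`; the estimated-marginal-means contrast after-before
for the single two-level fixed factor equals the challenge coefficient b1
with its Wald standard error. P values are corrected across clusters by
Benjamini-Hochberg, with adjusted P < 0.1 flagged significant.

Wilcoxon matched-pairs signed-rank and Mann-Whitney tests are provided
for the frequency panels analyzed nonparametrically (exact null
distributions at small n, tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .glmm import GLMMFit, SeparationError, fit_overdispersed_binomial_glmm

__all__ = [
    "normalize_frequencies",
    "ContrastResult",
    "contrast_challenge",
    "adjust_bh",
    "RankTestResult",
    "paired_rank_test",
    "unpaired_rank_test",
    "test_all_clusters",
]

_EXACT_N_MAX = 25
_EXACT_ENUM_N_MAX = 13  # 2^13 sign patterns enumerated when ranks are tied


def normalize_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-sample cluster proportions (count / total).

    Raises ValueError when any count exceeds its total or a total is not
    positive. For an exhaustive, mutually exclusive cluster set the
    proportions within a sample sum to 1.
    """
    for col in ("sample_id", "cluster_id", "count", "total"):
        if col not in table.columns:
            raise ValueError(f"table lacks column {col!r}")
    if len(table) and (table["total"] <= 0).any():
        raise ValueError("totals must be positive")
    if len(table) and (table["count"] > table["total"]).any():
        bad = table.loc[table["count"] > table["total"], "sample_id"].tolist()
        raise ValueError(f"count exceeds total for sample(s) {bad[:5]}")
    dup = table.duplicated(subset=["sample_id", "cluster_id"])
    if dup.any():
        raise ValueError("one row per (sample, cluster) required")
    out = table.copy()
    out["proportion"] = out["count"] / out["total"]
    return out


@dataclass
class ContrastResult:
    """After-before challenge contrast on the log-odds scale."""

    cluster_id: str
    group: str
    estimate: float
    se: float
    z: float
    p_raw: float
    p_adj: float | None = None
    significant: bool | None = None


def contrast_challenge(fit: GLMMFit, reference: str = "t") -> ContrastResult:
    """Estimated-marginal-means contrast for the challenge factor.

    With a single two-level fixed factor the EMM contrast after-before
    equals the challenge coefficient b1 with its Wald SE; the statistic is
    z = b1/se. By default the two-sided p value uses a t reference with
    df = (paired donors - 1), which keeps the Wald test close to nominal
    at realistic donor counts; ``reference="normal"`` gives the asymptotic
    normal p. A non-converged fit propagates without a p value (NaN).
    """
    if reference not in ("t", "normal"):
        raise ValueError("reference must be 't' or 'normal'")
    if not fit.converged or not np.isfinite(fit.se_beta1) or fit.se_beta1 <= 0:
        return ContrastResult(fit.cluster_id, fit.group, fit.beta1,
                              fit.se_beta1, float("nan"), float("nan"))
    z = fit.beta1 / fit.se_beta1
    if reference == "t" and fit.df >= 1:
        p = float(2.0 * stats.t.sf(abs(z), fit.df))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return ContrastResult(fit.cluster_id, fit.group, float(fit.beta1),
                          float(fit.se_beta1), float(z), p)


def adjust_bh(p_values, alpha: float = 0.1) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment with significance at ``alpha``.

    Returns a DataFrame (p_raw, p_adj, significant); adjusted values are
    monotone in rank and clipped at 1, and ``significant`` implements
    p_adj < alpha exactly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return pd.DataFrame(columns=["p_raw", "p_adj", "significant"])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "p_raw": p,
        "p_adj": p_adj,
        "significant": p_adj < alpha,
    })


@dataclass
class RankTestResult:
    p: float
    statistic: float
    n_effective: int
    method: str  # "exact" or "approx"
    defined: bool = True


def paired_rank_test(before, after) -> RankTestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are discarded (Wilcoxon's original treatment). The
    exact null distribution is used when the number of nonzero differences
    is at most 25 and their magnitudes are untied; otherwise the
    tie-corrected normal approximation. All differences zero yields an
    undefined result (``defined=False``; p is NaN).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired vectors must have equal length")
    d = after - before
    d = d[d != 0]
    n_eff = len(d)
    if n_eff == 0:
        return RankTestResult(float("nan"), float("nan"), 0, "exact", False)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    ties = len(np.unique(np.abs(d))) < n_eff
    if not ties and n_eff <= _EXACT_N_MAX:
        res = stats.wilcoxon(d, zero_method="wilcox",
                             alternative="two-sided", method="exact")
        return RankTestResult(float(res.pvalue), float(res.statistic),
                              n_eff, "exact")
    if ties and n_eff <= _EXACT_ENUM_N_MAX:
        # tied magnitudes defeat the tabulated null; enumerate all 2^n sign
        # patterns of the observed (mid-)ranks instead
        signs = (np.arange(2**n_eff)[:, None] >> np.arange(n_eff)) & 1
        w = signs @ ranks
        ew = n_eff * (n_eff + 1) / 4.0
        p = float(np.mean(np.abs(w - ew) >= abs(w_plus - ew) - 1e-12))
        return RankTestResult(p, w_plus, n_eff, "exact")
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method="approx", correction=False)
    return RankTestResult(float(res.pvalue), float(res.statistic),
                          n_eff, "approx")


def unpaired_rank_test(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both samples are small (n, m <= 25) and
    the pooled values are untied; tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    small = len(x) <= _EXACT_N_MAX and len(y) <= _EXACT_N_MAX
    method = "exact" if (small and not ties) else "approx"
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if method == "exact"
                             else "asymptotic", use_continuity=False)
    return RankTestResult(float(res.pvalue), float(res.statistic),
                          len(x) + len(y), method)


def test_all_clusters(
    table: pd.DataFrame,
    group: str,
    alpha: float = 0.1,
    min_donors: int = 4,
    **glmm_kwargs,
) -> pd.DataFrame:
    """Fit the GLMM per cluster within one subject group and adjust by BH.

    BH is applied across clusters within the group (one p per cluster).
    Clusters whose fit fails (separation, too few paired donors,
    non-convergence) are reported with NaN p values and excluded from the
    adjustment family.

    Returns one row per cluster: beta0, beta1, sigma_u, sigma_e, se, z,
    p_raw, p_adj, significant, converged, note.
    """
    sub = table[table["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"no rows for group {group!r}")
    rows = []
    for cid, rows_c in sub.groupby("cluster_id", sort=True):
        note = ""
        try:
            fit = fit_overdispersed_binomial_glmm(
                rows_c, cluster_id=str(cid), group=group,
                min_donors=min_donors, **glmm_kwargs)
            ctr = contrast_challenge(fit)
            rows.append({
                "cluster_id": str(cid), "group": group,
                "beta0": fit.beta0, "beta1": fit.beta1,
                "sigma_u": fit.sigma_u, "sigma_e": fit.sigma_e,
                "se": ctr.se, "z": ctr.z, "p_raw": ctr.p_raw,
                "converged": fit.converged, "note": note,
            })
        except (SeparationError, ValueError) as exc:
            rows.append({
                "cluster_id": str(cid), "group": group,
                "beta0": np.nan, "beta1": np.nan,
                "sigma_u": np.nan, "sigma_e": np.nan,
                "se": np.nan, "z": np.nan, "p_raw": np.nan,
                "converged": False, "note": str(exc),
            })
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_adj"] = np.nan
    out["significant"] = False
    if ok.any():
        adj = adjust_bh(out.loc[ok, "p_raw"].to_numpy(), alpha=alpha)
        out.loc[ok, "p_adj"] = adj["p_adj"].to_numpy()
        out.loc[ok, "significant"] = adj["significant"].to_numpy()
    return out
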