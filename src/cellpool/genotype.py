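"""SNP-based donor deconvolution of pooled single-cell runs.

Works from per-cell per-SNP reference/alternative transcript counts
(alignment and pileup are upstream; counts are the interface):

1. :func:`select_informative_snps` keeps positions that are polymorphic in
   the pooled pileup — adequate depth and an intermediate pooled
   alt-allele fraction — i.e. positions likely to differ between donors.
2. :func:`aggregate_counts_by_sample` cumulates cell counts per
   provisionally assigned sample; :func:`call_genotypes` calls each
   sample's per-SNP alt dosage g in {0, 1, 2} by maximum binomial
   likelihood with alt-read probabilities q_0 = eps, q_1 = 0.5,
   q_2 = 1 - eps (base-miscall rate eps).
3. :func:`genotype_concordance` scores sample pairs by the fraction of
   co-called SNPs with equal genotype; same-donor pairs across runs should
   separate completely from different-donor pairs.
4. :func:`pool_donor_genotypes` cumulates counts of samples linked to the
   same donor across runs and recalls the donor genotypes.
5. :func:`assign_by_genotype` assigns each cell to the donor genotype that
   maximizes the summed per-SNP binomial log-likelihood, requiring a
   log-likelihood margin over the runner-up and a minimum number of
   informative SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "select_informative_snps",
    "aggregate_counts_by_sample",
    "call_genotypes",
    "genotype_concordance",
    "concordance_table",
    "pool_donor_genotypes",
    "assign_by_genotype",
    "GenotypeLinkageWarning",
    "MISSING",
]

#: Sentinel for an uncalled genotype (depth below min_call_depth).
MISSING = -1


class GenotypeLinkageWarning(UserWarning):
    """A run->donor link's concordance is below the cross-donor ceiling."""


def _check_allele_columns(counts: pd.DataFrame) -> None:
    for col in ("cell_id", "snp_id", "ref_count", "alt_count"):
        if col not in counts.columns:
            raise ValueError(f"allele counts lack column {col!r}")
    if len(counts) and ((counts["ref_count"] < 0) | (counts["alt_count"] < 0)).any():
        raise ValueError("allele counts must be nonnegative")


def select_informative_snps(
    pooled: pd.DataFrame,
    min_depth: int = 50,
    af_low: float = 0.05,
    af_high: float = 0.95,
) -> pd.DataFrame:
    """Filter pooled per-position counts to donor-discriminating SNPs.

    Retains positions with pooled depth >= ``min_depth`` and pooled
    alt-allele fraction within [af_low, af_high]; monomorphic positions
    (fraction 0 or 1) cannot distinguish donors and drop out.

    Parameters
    ----------
    pooled
        One row per candidate position with columns ``snp_id``,
        ``pooled_ref``, ``pooled_alt`` (and optionally chrom/pos/ref/alt).

    Returns the retained rows with ``pooled_alt_fraction`` added.
    """
    for col in ("snp_id", "pooled_ref", "pooled_alt"):
        if col not in pooled.columns:
            raise ValueError(f"pooled counts lack column {col!r}")
    depth = (pooled["pooled_ref"] + pooled["pooled_alt"]).astype(float)
    af = (pooled["pooled_alt"] / depth.where(depth > 0)).astype(float)
    keep = (depth >= min_depth) & (af >= af_low) & (af <= af_high)
    keep = keep.fillna(False)
    out = pooled.loc[keep].copy()
    out["pooled_alt_fraction"] = af[keep]
    return out.reset_index(drop=True)


def pool_allele_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Cumulate per-cell allele counts into pooled per-SNP totals."""
    _check_allele_columns(counts)
    g = counts.groupby("snp_id", sort=True)[["ref_count", "alt_count"]].sum()
    g = g.rename(columns={"ref_count": "pooled_ref", "alt_count": "pooled_alt"})
    return g.reset_index()


def aggregate_counts_by_sample(
    counts: pd.DataFrame,
    assignment: dict[str, str] | pd.Series,
) -> pd.DataFrame:
    """Cumulate cell-level allele counts per (sample, SNP).

    Cells absent from ``assignment`` (or mapped to null) are ignored. Total
    ref/alt are conserved over the mapped cells.

    Returns a long DataFrame (sample_id, snp_id, ref_count, alt_count).
    """
    _check_allele_columns(counts)
    if isinstance(assignment, dict):
        assignment = pd.Series(assignment)
    mapped = counts["cell_id"].map(assignment)
    sub = counts.loc[mapped.notna()].copy()
    sub["sample_id"] = mapped[mapped.notna()]
    agg = (sub.groupby(["sample_id", "snp_id"], sort=True)
              [["ref_count", "alt_count"]].sum().reset_index())
    return agg


def _dosage_log_likelihoods(
    ref: np.ndarray, alt: np.ndarray, error_rate: float
) -> np.ndarray:
    """Log-likelihood of each dosage g in {0,1,2}; shape (..., 3).

    Binomial coefficients are omitted (constant across g).
    """
    q = np.array([error_rate, 0.5, 1.0 - error_rate])
    alt = np.asarray(alt, dtype=float)[..., None]
    ref = np.asarray(ref, dtype=float)[..., None]
    return xlogy(alt, q) + xlogy(ref, 1.0 - q)


def call_genotypes(
    sample_counts: pd.DataFrame,
    error_rate: float = 0.01,
    min_call_depth: int = 5,
) -> pd.DataFrame:
    """Call per-sample per-SNP alt dosages by maximum binomial likelihood.

    For each (sample, SNP) with depth >= ``min_call_depth`` the call is
    argmax over g in {0,1,2} of Binomial(alt; depth, q_g); exact likelihood
    ties break toward heterozygous. Shallower entries are missing.

    Parameters
    ----------
    sample_counts
        Long DataFrame (sample_id, snp_id, ref_count, alt_count).

    Returns a samples x SNPs DataFrame of dosages with missing as
    :data:`MISSING` (-1), plus matching ``.attrs["depth"]`` DataFrame.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    for col in ("sample_id", "snp_id", "ref_count", "alt_count"):
        if col not in sample_counts.columns:
            raise ValueError(f"sample counts lack column {col!r}")

    ref = sample_counts.pivot_table(index="sample_id", columns="snp_id",
                                    values="ref_count", aggfunc="sum",
                                    fill_value=0)
    alt = sample_counts.pivot_table(index="sample_id", columns="snp_id",
                                    values="alt_count", aggfunc="sum",
                                    fill_value=0)
    alt = alt.reindex_like(ref).fillna(0)
    depth = ref.to_numpy() + alt.to_numpy()

    ll = _dosage_log_likelihoods(ref.to_numpy(), alt.to_numpy(), error_rate)
    # break exact ties toward het: give g=1 an infinitesimal bonus
    best = np.argmax(ll + np.array([0.0, 1e-12, 0.0]), axis=-1)
    geno = np.where(depth >= min_call_depth, best, MISSING)
    out = pd.DataFrame(geno, index=ref.index, columns=ref.columns)
    out.attrs["depth"] = pd.DataFrame(depth, index=ref.index,
                                      columns=ref.columns)
    return out


def genotype_concordance(
    a: pd.Series | np.ndarray,
    b: pd.Series | np.ndarray,
) -> tuple[float, int]:
    """Fraction of co-called SNPs with equal genotype, and their number.

    Returns (nan, 0) when no SNP is called in both samples.
    """
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        common = a.index.intersection(b.index)
        a, b = a[common].to_numpy(), b[common].to_numpy()
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must share a SNP universe")
    called = (a != MISSING) & (b != MISSING)
    n_shared = int(called.sum())
    if n_shared == 0:
        return float("nan"), 0
    return float((a[called] == b[called]).mean()), n_shared


def concordance_table(
    genotypes: pd.DataFrame,
    same_donor: dict[str, str] | None = None,
) -> pd.DataFrame:
    """All-pairs genotype concordance for a samples x SNPs dosage matrix.

    ``same_donor`` optionally maps sample_id -> donor_id, in which case the
    output flags pairs expected to belong to the same donor (e.g. the same
    individual pooled into multiple runs).
    """
    rows = []
    for sa, sb in combinations(genotypes.index, 2):
        c, n = genotype_concordance(genotypes.loc[sa], genotypes.loc[sb])
        row = {"sample_a": sa, "sample_b": sb, "concordance": c,
               "n_shared": n}
        if same_donor is not None:
            row["same_donor_expected"] = same_donor.get(sa) == same_donor.get(sb)
        rows.append(row)
    return pd.DataFrame(rows)


def pool_donor_genotypes(
    sample_counts: pd.DataFrame,
    links: dict[str, str] | pd.Series,
    error_rate: float = 0.01,
    min_call_depth: int = 5,
    validate_with: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cumulate linked samples' counts across runs and call donor genotypes.

    Parameters
    ----------
    sample_counts
        Long per-sample counts as accepted by :func:`call_genotypes`.
    links
        sample_id -> donor_id map (samples of the same donor across runs).
    validate_with
        Optional per-sample genotype matrix; when given, each same-donor
        pair's concordance is compared against the maximum different-donor
        concordance and a :class:`GenotypeLinkageWarning` is emitted for
        links below that ceiling.

    Returns a donors x SNPs dosage matrix (missing as -1).
    """
    if isinstance(links, dict):
        links = pd.Series(links)
    if validate_with is not None:
        tab = concordance_table(validate_with,
                                same_donor=dict(links))
        tab = tab.dropna(subset=["concordance"])
        diff = tab.loc[~tab["same_donor_expected"], "concordance"]
        ceiling = diff.max() if len(diff) else -np.inf
        bad = tab[tab["same_donor_expected"] & (tab["concordance"] < ceiling)]
        for _, r in bad.iterrows():
            warnings.warn(
                f"linked samples {r['sample_a']}/{r['sample_b']} have "
                f"concordance {r['concordance']:.3f} below the "
                f"different-donor maximum {ceiling:.3f}",
                GenotypeLinkageWarning, stacklevel=2)

    mapped = sample_counts["sample_id"].map(links)
    sub = sample_counts.loc[mapped.notna()].copy()
    sub["sample_id"] = mapped[mapped.notna()]
    pooled = (sub.groupby(["sample_id", "snp_id"], sort=True)
                 [["ref_count", "alt_count"]].sum().reset_index())
    geno = call_genotypes(pooled, error_rate=error_rate,
                          min_call_depth=min_call_depth)
    geno.index.name = "donor_id"
    return geno


@dataclass
class GenotypeAssignmentParams:
    error_rate: float = 0.01
    min_margin: float = 2.0  # natural-log units between best and runner-up
    min_informative: int = 3


def assign_by_genotype(
    counts: pd.DataFrame,
    donor_genotypes: pd.DataFrame,
    error_rate: float = 0.01,
    min_margin: float = 2.0,
    min_informative: int = 3,
) -> pd.DataFrame:
    """Assign each cell to its most likely donor genotype.

    Per donor d the cell's score is the sum over covered SNPs of
    log Binomial(alt; depth, q_g(d)); SNPs missing in any donor are
    excluded so all donors are scored on the same loci. The best donor is
    called only when its log-likelihood exceeds the runner-up by
    ``min_margin`` and at least ``min_informative`` informative SNPs were
    used; otherwise the call is null.

    Returns a DataFrame (cell_id, donor_call, best_donor, margin,
    n_informative, log_likelihood).
    """
    if donor_genotypes.shape[0] == 0:
        raise ValueError("empty donor genotype set")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    _check_allele_columns(counts)

    geno = donor_genotypes
    usable = (geno.to_numpy() != MISSING).all(axis=0)
    usable_snps = geno.columns[usable]
    G = geno.loc[:, usable_snps].to_numpy()  # donors x snps
    q = np.array([error_rate, 0.5, 1.0 - error_rate])[G]  # donors x snps
    with np.errstate(divide="ignore"):
        logq = np.where(q > 0, np.log(q), -np.inf)
        log1mq = np.where(q < 1, np.log1p(-q), -np.inf)
    # replace -inf by a very negative finite value so 0 * (-inf) never occurs
    logq = np.nan_to_num(logq, neginf=-745.0)
    log1mq = np.nan_to_num(log1mq, neginf=-745.0)

    sub = counts[counts["snp_id"].isin(usable_snps)]
    ref = sub.pivot_table(index="cell_id", columns="snp_id",
                          values="ref_count", aggfunc="sum", fill_value=0)
    alt = sub.pivot_table(index="cell_id", columns="snp_id",
                          values="alt_count", aggfunc="sum", fill_value=0)
    ref = ref.reindex(columns=usable_snps, fill_value=0)
    alt = alt.reindex(columns=usable_snps, fill_value=0)
    A = alt.to_numpy(dtype=float)
    R = ref.to_numpy(dtype=float)

    # cells x donors log-likelihood (binomial coefficient constant per cell)
    L = A @ logq.T + R @ log1mq.T
    n_inf = ((A + R) > 0).sum(axis=1)

    all_cells = pd.Index(pd.unique(counts["cell_id"]))
    order = np.argsort(L, axis=1)
    best_idx = order[:, -1]
    donors = geno.index.to_numpy(dtype=object)
    best = donors[best_idx]
    best_ll = L[np.arange(len(L)), best_idx]
    if L.shape[1] >= 2:
        second_ll = L[np.arange(len(L)), order[:, -2]]
        margin = best_ll - second_ll
    else:
        margin = np.full(len(L), np.inf)

    ok = (margin >= min_margin) & (n_inf >= min_informative)
    out = pd.DataFrame({
        "cell_id": ref.index.astype(str),
        "donor_call": np.where(ok, best, None),
        "best_donor": best,
        "margin": margin,
        "n_informative": n_inf,
        "log_likelihood": best_ll,
    })
    # cells whose covered SNPs were all unusable still deserve a null row
    uncovered = all_cells.difference(ref.index)
    if len(uncovered):
        out = pd.concat([out, pd.DataFrame({
            "cell_id": uncovered.astype(str),
            "donor_call": None,
            "best_donor": None,
            "margin": 0.0,
            "n_informative": 0,
            "log_likelihood": np.nan,
        })], ignore_index=True)
    return out.sort_values("cell_id", ignore_index=True)
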