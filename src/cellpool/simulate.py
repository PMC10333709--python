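"""Synthetic multiplexed single-cell runs with ground truth.

Generates the four inputs the pipeline consumes — hashtag (antibody-barcode)
count matrices, per-cell per-SNP allele counts, per-cell QC metrics, and
per-sample cluster count tables — with the statistical structure the
downstream stages assume, alongside a :class:`SimulationTruth` record
sufficient to score any assignment.

Model summary
-------------
* Each pooled run carries ``donors_per_run`` barcoded donors (default 15).
  For a cell of donor *d*, the count of hashtag *d* is a "signal" draw and
  every other hashtag a "noise" draw; on the log10(count+1) scale signal and
  noise are Normal(mu_hi, sigma_hi) and Normal(mu_lo, sigma_lo), producing
  the bimodal per-hashtag log-count histograms the demultiplexer fits.
  A fraction ``doublet_rate`` of droplets contain two distinct donors and
  receive signal draws on both hashtags.
* Donor genotypes at biallelic SNPs are alt-allele dosages g in {0, 1, 2},
  drawn Binomial(2, f) with the allele frequency f uniform per SNP in
  [maf_low, maf_high].
* Per cell and SNP, sequencing depth is Poisson(depth_mean) and the alt
  count Binomial(depth, q_g) with q_0 = eps, q_1 = 0.5, q_2 = 1 - eps for
  base-miscall rate eps; doublets mix the two donors' q with equal weight.
* Cluster counts per sample follow an overdispersed binomial: count ~
  Binomial(total, logistic(beta0 + beta1*challenge + u_donor + e_sample))
  with u ~ N(0, sigma_u^2) shared across a donor's samples and a
  sample-level e ~ N(0, sigma_e^2) absorbing extra-binomial variation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import substream

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_hashtag_run",
    "simulate_allele_counts",
    "simulate_qc_metrics",
    "simulate_cluster_counts",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the pooled-run design the pipeline targets: 15 barcoded
    donors per run with well-separated bimodal hashtag log-counts, a modest
    two-donor doublet rate, and a panel of biallelic SNPs read at
    Poisson(depth_mean) per cell and SNP.
    """

    n_runs: int = 2
    donors_per_run: int = 15
    cells_per_donor: int = 1000
    doublet_rate: float = 0.05
    # log10(count+1) scale
    mu_hi: float = 2.5
    sigma_hi: float = 0.2
    mu_lo: float = 1.0
    sigma_lo: float = 0.2
    n_snps: int = 200
    maf_low: float = 0.1
    maf_high: float = 0.5
    depth_mean: float = 20.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_hi <= self.mu_lo:
            raise ValueError("mu_hi must exceed mu_lo")
        if self.sigma_hi <= 0 or self.sigma_lo <= 0:
            raise ValueError("sigmas must be positive")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ValueError("doublet_rate must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not 0.0 <= self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")
        for name in ("n_runs", "donors_per_run", "n_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cells_per_donor < 0:
            raise ValueError("cells_per_donor must be >= 0")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth emitted with every synthetic dataset.

    Attributes
    ----------
    cell_to_donor
        One row per simulated cell: ``cell_id``, ``run_id``, ``donor_a``,
        ``donor_b`` (empty string for singlets) and ``is_doublet``.
    genotype_matrix
        donors x SNPs alt-allele dosages in {0, 1, 2}.
    abundance_params
        Per-cluster generating parameters (beta0, beta1, sigma_u, sigma_e)
        plus the realized random effects, when cluster counts were simulated.
    """

    cell_to_donor: pd.DataFrame
    genotype_matrix: pd.DataFrame | None = None
    abundance_params: pd.DataFrame | None = None
    random_effects: pd.DataFrame | None = None

    def donor_of(self, cell_id: str) -> tuple[str, ...]:
        row = self.cell_to_donor.set_index("cell_id").loc[cell_id]
        if row["is_doublet"]:
            return (row["donor_a"], row["donor_b"])
        return (row["donor_a"],)


def simulate_genotypes(
    n_donors: int,
    n_snps: int,
    maf_low: float,
    maf_high: float,
    seed: int,
    donor_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw alt-allele dosages for unrelated donors at independent SNPs.

    Per SNP a population alt-allele frequency f ~ Uniform(maf_low, maf_high)
    is drawn and each donor's dosage is Binomial(2, f) (Hardy-Weinberg).

    Returns a donors x SNPs DataFrame of dosages in {0, 1, 2}.
    """
    if n_donors < 1 or n_snps < 1:
        raise ValueError("n_donors and n_snps must be >= 1")
    if not 0.0 <= maf_low <= maf_high <= 0.5:
        raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")
    rng = substream(seed, "genotypes")
    freqs = rng.uniform(maf_low, maf_high, size=n_snps)
    dosages = rng.binomial(2, freqs[None, :], size=(n_donors, n_snps))
    if donor_ids is None:
        donor_ids = [f"donor{d:02d}" for d in range(1, n_donors + 1)]
    snp_ids = [f"snp{s:04d}" for s in range(1, n_snps + 1)]
    return pd.DataFrame(dosages, index=pd.Index(donor_ids, name="donor_id"),
                        columns=pd.Index(snp_ids, name="snp_id"))


def _log10_counts_to_ints(x: np.ndarray) -> np.ndarray:
    """Map log10(count+1) draws back to nonnegative integer counts."""
    return np.maximum(np.rint(10.0 ** x - 1.0), 0).astype(np.int64)


def simulate_hashtag_run(
    config: SimulationConfig,
    run_id: str,
    donor_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate one pooled run's hashtag count matrix with truth labels.

    Every droplet draws its own hashtag(s) from the signal component
    (round(10^x - 1), x ~ Normal(mu_hi, sigma_hi)) and all remaining
    hashtags from the noise component. Doublets (fraction
    ``config.doublet_rate``) carry two distinct donors and receive signal
    draws on both of their hashtags.

    Returns
    -------
    counts : DataFrame
        cells x hashtags integer counts; hashtag columns are named after the
        pooled donors.
    truth : SimulationTruth
        Per-cell donor labels for this run.
    """
    cfg = config
    if donor_ids is None:
        donor_ids = [f"donor{d:02d}" for d in range(1, cfg.donors_per_run + 1)]
    if len(donor_ids) != cfg.donors_per_run:
        raise ValueError("donor_ids length must equal donors_per_run")
    n_cells = cfg.donors_per_run * cfg.cells_per_donor
    rng = substream(cfg.seed, "hashtag", run_id)

    if n_cells == 0:
        counts = pd.DataFrame(
            np.zeros((0, cfg.donors_per_run), dtype=np.int64),
            columns=pd.Index(donor_ids, name="hashtag_id"),
            index=pd.Index([], name="cell_id"),
        )
        truth = SimulationTruth(cell_to_donor=pd.DataFrame(
            columns=["cell_id", "run_id", "donor_a", "donor_b", "is_doublet"]))
        return counts, truth

    donor_a = np.repeat(np.arange(cfg.donors_per_run), cfg.cells_per_donor)
    if cfg.donors_per_run > 1:
        is_doublet = rng.random(n_cells) < cfg.doublet_rate
        # the second donor of a doublet is uniform over the other pooled donors
        offset = rng.integers(1, cfg.donors_per_run, size=n_cells)
        donor_b = (donor_a + offset) % cfg.donors_per_run
        donor_b = np.where(is_doublet, donor_b, -1)
    else:  # a single-donor pool cannot form cross-donor doublets
        is_doublet = np.zeros(n_cells, dtype=bool)
        donor_b = np.full(n_cells, -1)

    log_noise = rng.normal(cfg.mu_lo, cfg.sigma_lo,
                           size=(n_cells, cfg.donors_per_run))
    log_sig_a = rng.normal(cfg.mu_hi, cfg.sigma_hi, size=n_cells)
    log_sig_b = rng.normal(cfg.mu_hi, cfg.sigma_hi, size=n_cells)
    logc = log_noise
    rows = np.arange(n_cells)
    logc[rows, donor_a] = log_sig_a
    dbl = np.where(is_doublet)[0]
    logc[dbl, donor_b[dbl]] = log_sig_b[dbl]

    counts = _log10_counts_to_ints(logc)
    cell_ids = [f"{run_id}:cell{i:05d}" for i in range(n_cells)]
    counts_df = pd.DataFrame(counts,
                             index=pd.Index(cell_ids, name="cell_id"),
                             columns=pd.Index(donor_ids, name="hashtag_id"))
    donors = np.asarray(donor_ids, dtype=object)
    truth_df = pd.DataFrame({
        "cell_id": cell_ids,
        "run_id": run_id,
        "donor_a": donors[donor_a],
        "donor_b": np.where(is_doublet, donors[np.maximum(donor_b, 0)], ""),
        "is_doublet": is_doublet,
    })
    return counts_df, SimulationTruth(cell_to_donor=truth_df)


def simulate_allele_counts(
    truth: SimulationTruth | pd.DataFrame,
    genotypes: pd.DataFrame,
    depth_mean: float,
    error_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate per-cell per-SNP (ref, alt) transcript counts.

    Depth per cell and SNP is Poisson(depth_mean); the alt count is
    Binomial(depth, q_g) with q_0 = eps, q_1 = 0.5, q_2 = 1 - eps for the
    cell's true dosage g. Doublet cells use the equal-weight mixture of
    their two donors' q.

    Returns a long DataFrame (cell_id, snp_id, ref_count, alt_count)
    restricted to entries with depth > 0.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if depth_mean < 0:
        raise ValueError("depth_mean must be >= 0")
    cells = truth.cell_to_donor if isinstance(truth, SimulationTruth) else truth
    missing = set(cells["donor_a"]) - set(genotypes.index)
    missing |= set(cells.loc[cells["is_doublet"], "donor_b"]) - set(genotypes.index)
    if missing:
        raise ValueError(f"donors absent from genotype matrix: {sorted(missing)}")

    rng = substream(seed, "allele_counts")
    n_cells = len(cells)
    n_snps = genotypes.shape[1]
    if n_cells == 0 or n_snps == 0:
        return pd.DataFrame(columns=["cell_id", "snp_id", "ref_count", "alt_count"])

    q_of = np.array([error_rate, 0.5, 1.0 - error_rate])
    geno = genotypes.to_numpy()
    donor_pos = {d: i for i, d in enumerate(genotypes.index)}
    ia = cells["donor_a"].map(donor_pos).to_numpy()
    q = q_of[geno[ia]]  # cells x snps
    is_dbl = cells["is_doublet"].to_numpy()
    if is_dbl.any():
        ib = cells.loc[is_dbl, "donor_b"].map(donor_pos).to_numpy()
        q[is_dbl] = 0.5 * (q[is_dbl] + q_of[geno[ib]])

    depth = rng.poisson(depth_mean, size=(n_cells, n_snps))
    alt = rng.binomial(depth, q)
    ref = depth - alt

    ci, si = np.nonzero(depth)
    return pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy()[ci],
        "snp_id": genotypes.columns.to_numpy()[si],
        "ref_count": ref[ci, si],
        "alt_count": alt[ci, si],
    })


def simulate_qc_metrics(
    cell_ids: list[str],
    seed: int,
    umi_log10_mean: float = 3.1,
    umi_log10_sd: float = 0.25,
    mito_alpha: float = 2.0,
    mito_beta: float = 25.0,
    fail_fraction: float = 0.05,
) -> pd.DataFrame:
    """Simulate per-cell UMI counts and mitochondrial fractions.

    Healthy cells draw UMI counts log-normally (log10 scale) and
    mitochondrial fractions Beta(mito_alpha, mito_beta); a ``fail_fraction``
    of cells emulate dead or degraded droplets with very low UMI counts and
    elevated mitochondrial content, so the downstream QC filter has
    something to remove.
    """
    rng = substream(seed, "qc_metrics")
    n = len(cell_ids)
    umi = np.rint(10.0 ** rng.normal(umi_log10_mean, umi_log10_sd, n)).astype(int)
    mito = rng.beta(mito_alpha, mito_beta, n)
    bad = rng.random(n) < fail_fraction
    umi[bad] = np.rint(10.0 ** rng.normal(2.0, 0.3, bad.sum())).astype(int)
    mito[bad] = rng.beta(10.0, 12.0, bad.sum())
    return pd.DataFrame({
        "cell_id": cell_ids,
        "umi_count": np.maximum(umi, 0),
        "mito_fraction": np.clip(mito, 0.0, 1.0),
    })


def simulate_cluster_counts(
    design: pd.DataFrame,
    params: pd.DataFrame,
    total_sampler: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-sample cluster counts under the overdispersed binomial.

    Parameters
    ----------
    design
        One row per sample with columns ``donor_id``, ``group`` and
        ``timepoint`` (levels "before"/"after"); each donor appears at most
        once per timepoint.
    params
        One row per cluster: ``cluster_id``, ``beta0`` (baseline log-odds),
        ``beta1`` (challenge effect on log-odds), ``sigma_u`` (donor
        random-effect sd), ``sigma_e`` (sample random-effect sd).
    total_sampler
        Mean of the Poisson draw for per-sample totals, truncated >= 1.

    Returns
    -------
    table
        Long ClusterFrequencyTable rows (sample_id, donor_id, group,
        timepoint, cluster_id, count, total, denominator_kind).
    params
        Echo of the generating fixed effects and sds (the truth).
    effects
        Realized random effects u_donor and e_sample per cluster.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    dup = design.duplicated(subset=["donor_id", "timepoint"])
    if dup.any():
        raise ValueError("each donor may appear only once per timepoint")
    for col in ("donor_id", "group", "timepoint"):
        if col not in design.columns:
            raise ValueError(f"design lacks column {col!r}")
    rng = substream(seed, "cluster_counts")

    design = design.reset_index(drop=True).copy()
    if "sample_id" not in design.columns:
        design["sample_id"] = [
            f"{d}_{t}" for d, t in zip(design["donor_id"], design["timepoint"])
        ]
    donors = design["donor_id"].unique()
    challenge = (design["timepoint"] == "after").to_numpy(dtype=float)

    totals = rng.poisson(total_sampler, size=len(design))
    totals = np.maximum(totals, 1)

    rows, effects = [], []
    for _, p in params.iterrows():
        u = rng.normal(0.0, p["sigma_u"], size=len(donors))
        u_of = dict(zip(donors, u))
        e = rng.normal(0.0, p["sigma_e"], size=len(design))
        eta = (p["beta0"] + p["beta1"] * challenge
               + design["donor_id"].map(u_of).to_numpy() + e)
        counts = rng.binomial(totals, expit(eta))
        for i, r in design.iterrows():
            rows.append((r["sample_id"], r["donor_id"], r["group"],
                         r["timepoint"], p["cluster_id"], counts[i], totals[i],
                         "CD45"))
            effects.append((p["cluster_id"], r["sample_id"], r["donor_id"],
                            u_of[r["donor_id"]], e[i]))
    table = pd.DataFrame(rows, columns=[
        "sample_id", "donor_id", "group", "timepoint", "cluster_id",
        "count", "total", "denominator_kind"])
    eff = pd.DataFrame(effects, columns=[
        "cluster_id", "sample_id", "donor_id", "u_donor", "e_sample"])
    return table, params.reset_index(drop=True), eff


def simulate_study(config: SimulationConfig) -> dict:
    """Simulate a complete multi-run study.

    Runs share one donor cohort: run *r* pools donors, the hashtag matrix,
    allele counts and QC metrics are generated per run, and the truth tables
    are concatenated. Returns a dict with keys ``hashtag_counts`` (per-run
    dict), ``allele_counts`` (per-run dict), ``qc_metrics`` (per-run dict),
    ``genotypes`` and ``truth``.
    """
    cfg = config
    donor_ids = [f"donor{d:02d}" for d in range(1, cfg.donors_per_run + 1)]
    genotypes = simulate_genotypes(cfg.donors_per_run, cfg.n_snps,
                                   cfg.maf_low, cfg.maf_high, cfg.seed,
                                   donor_ids=donor_ids)
    hashtag, alleles, qc, truths = {}, {}, {}, []
    for r in range(1, cfg.n_runs + 1):
        run_id = f"run{r}"
        counts, truth = simulate_hashtag_run(cfg, run_id, donor_ids=donor_ids)
        hashtag[run_id] = counts
        alleles[run_id] = simulate_allele_counts(
            truth, genotypes, cfg.depth_mean, cfg.error_rate,
            seed=cfg.seed + r)
        qc[run_id] = simulate_qc_metrics(list(counts.index), seed=cfg.seed + r)
        truths.append(truth.cell_to_donor)
    truth = SimulationTruth(
        cell_to_donor=pd.concat(truths, ignore_index=True),
        genotype_matrix=genotypes,
    )
    return {"hashtag_counts": hashtag, "allele_counts": alleles,
            "qc_metrics": qc, "genotypes": genotypes, "truth": truth,
            "config": asdict(cfg)}
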