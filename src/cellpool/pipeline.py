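"""End-to-end pipeline driver.

Orders the stages simulate (optional) -> qc -> hashtag demux -> genotype
demux -> consensus -> abundance, writes every stage's outputs as TSV, and
returns a machine-readable run report (per-stage record counts, the
parameter values actually used, output paths, warnings). Identical config
and seed reproduce byte-identical outputs: all randomness flows from the
single seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as cio
from .abundance import normalize_frequencies, test_all_clusters
from .consensus import consensus_assign
from .genotype import (aggregate_counts_by_sample, assign_by_genotype,
                       call_genotypes, concordance_table,
                       pool_allele_counts, pool_donor_genotypes,
                       select_informative_snps)
from .hashtag import assign_by_hashtag, fit_all_hashtags
from .qc import filter_cells
from .simulate import SimulationConfig, simulate_cluster_counts, simulate_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


@dataclass
class PipelineConfig:
    """All stage parameters plus the output directory and the seed."""

    out_dir: str = "cellpool_out"
    seed: int = 0

    # stage toggles
    do_simulate: bool = True
    do_qc: bool = True
    do_hashtag: bool = True
    do_genotype: bool = True
    do_consensus: bool = True
    do_abundance: bool = True

    # simulation
    sim: SimulationConfig | None = None

    # qc thresholds
    min_umi: int = 200
    max_umi: int = 4000
    max_mito: float = 0.25

    # hashtag demux
    ratio_threshold: float = 3.0
    gmm_tol: float = 1e-6
    gmm_max_iter: int = 500

    # genotype demux
    error_rate: float = 0.01
    min_call_depth: int = 5
    min_margin: float = 2.0
    min_informative: int = 3
    snp_min_depth: int = 50
    snp_af_low: float = 0.05
    snp_af_high: float = 0.95

    # abundance
    abundance_groups: tuple[str, ...] = ("non-allergic", "allergic")
    bh_alpha: float = 0.1
    n_cluster_sim: int = 5
    total_mean: float = 2000.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = cio.read_yaml_config(path)
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["abundance_groups"] = list(self.abundance_groups)
        return d


def _write(df: pd.DataFrame, path: Path, index: bool = False,
           index_label=None) -> str:
    df.to_csv(path, sep="\t", index=index, index_label=index_label)
    return str(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and return the run report."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "outputs": {}, "warnings": [],
                    "parameters": cfg.to_dict()}

    if cfg.do_consensus and not (cfg.do_hashtag and cfg.do_genotype):
        raise PipelineError(
            "stage consensus: requires both the hashtag and the genotype "
            "demultiplexing stages to be enabled")

    if not cfg.do_simulate:
        raise PipelineError(
            "stage simulate: this driver runs on simulated studies; "
            "disable downstream stages instead or call the library "
            "functions on your own data")

    sim_cfg = cfg.sim if cfg.sim is not None else SimulationConfig(seed=cfg.seed)
    try:
        study = simulate_study(sim_cfg)
    except Exception as exc:  # pragma: no cover - config errors
        raise PipelineError(f"stage simulate: {exc}") from exc
    truth = study["truth"]
    run_ids = sorted(study["hashtag_counts"])
    report["stages"]["simulate"] = {
        "runs": len(run_ids),
        "cells": int(len(truth.cell_to_donor)),
        "snps": int(study["genotypes"].shape[1]),
    }
    report["outputs"]["truth"] = _write(
        truth.cell_to_donor, out / "truth_cells.tsv")
    report["outputs"]["genotype_truth"] = _write(
        study["genotypes"], out / "truth_genotypes.tsv", index=True)
    for rid in run_ids:
        report["outputs"][f"hashtag_{rid}"] = _write(
            study["hashtag_counts"][rid], out / f"hashtag_{rid}.tsv",
            index=True, index_label="cell_id")
        report["outputs"][f"alleles_{rid}"] = _write(
            study["allele_counts"][rid], out / f"alleles_{rid}.tsv")
        report["outputs"][f"qc_{rid}"] = _write(
            study["qc_metrics"][rid], out / f"qc_{rid}.tsv")

    # ------------------------------------------------------------------ QC
    retained_by_run: dict[str, set] = {}
    if cfg.do_qc:
        qc_tables = []
        total_kept = 0
        for rid in run_ids:
            try:
                res = filter_cells(study["qc_metrics"][rid],
                                   min_umi=cfg.min_umi, max_umi=cfg.max_umi,
                                   max_mito=cfg.max_mito)
            except ValueError as exc:
                raise PipelineError(f"stage qc ({rid}): {exc}") from exc
            retained_by_run[rid] = set(res.retained)
            total_kept += res.n_retained
            qc_tables.append(res.table.assign(run_id=rid))
        qc_all = pd.concat(qc_tables, ignore_index=True)
        report["outputs"]["qc_calls"] = _write(qc_all, out / "qc_calls.tsv")
        report["stages"]["qc"] = {
            "cells_in": int(len(qc_all)),
            "cells_retained": int(total_kept),
        }
    else:
        for rid in run_ids:
            retained_by_run[rid] = set(study["hashtag_counts"][rid].index)

    # -------------------------------------------------------- hashtag demux
    hashtag_calls = None
    if cfg.do_hashtag:
        per_run = []
        for rid in run_ids:
            counts = study["hashtag_counts"][rid]
            counts = counts.loc[counts.index.isin(retained_by_run[rid])]
            try:
                fits = fit_all_hashtags(counts, tol=cfg.gmm_tol,
                                        max_iter=cfg.gmm_max_iter)
                calls = assign_by_hashtag(counts, fits,
                                          ratio_threshold=cfg.ratio_threshold)
            except ValueError as exc:
                raise PipelineError(f"stage hashtag_demux ({rid}): {exc}") from exc
            calls["run_id"] = rid
            per_run.append(calls)
        hashtag_calls = pd.concat(per_run, ignore_index=True)
        report["outputs"]["hashtag_calls"] = _write(
            hashtag_calls, out / "hashtag_calls.tsv")
        report["stages"]["hashtag_demux"] = {
            "cells": int(len(hashtag_calls)),
            "called": int(hashtag_calls["donor_call"].notna().sum()),
            "multiplets": int((hashtag_calls["status"] == "multiplet").sum()),
        }

    # ------------------------------------------------------- genotype demux
    genotype_calls = None
    if cfg.do_genotype:
        if hashtag_calls is None:
            raise PipelineError(
                "stage genotype_demux: the provisional per-sample grouping "
                "comes from the hashtag stage; enable do_hashtag")
        all_counts = pd.concat(
            [study["allele_counts"][rid] for rid in run_ids],
            ignore_index=True)
        keep_cells = set().union(*retained_by_run.values())
        all_counts = all_counts[all_counts["cell_id"].isin(keep_cells)]

        pooled = pool_allele_counts(all_counts)
        panel = select_informative_snps(pooled, min_depth=cfg.snp_min_depth,
                                        af_low=cfg.snp_af_low,
                                        af_high=cfg.snp_af_high)
        panel_counts = all_counts[all_counts["snp_id"].isin(panel["snp_id"])]

        # provisional per-run samples from the hashtag calls
        ht = hashtag_calls[hashtag_calls["donor_call"].notna()]
        sample_of = pd.Series(
            (ht["run_id"] + "/" + ht["donor_call"].astype(str)).to_numpy(),
            index=ht["cell_id"].to_numpy())
        sample_counts = aggregate_counts_by_sample(panel_counts, sample_of)
        sample_geno = call_genotypes(sample_counts,
                                     error_rate=cfg.error_rate,
                                     min_call_depth=cfg.min_call_depth)
        links = {s: s.split("/", 1)[1] for s in sample_geno.index}
        conc = concordance_table(sample_geno, same_donor=links)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            donor_geno = pool_donor_genotypes(
                sample_counts, links, error_rate=cfg.error_rate,
                min_call_depth=cfg.min_call_depth,
                validate_with=sample_geno)
        report["warnings"] += [str(w.message) for w in caught]
        genotype_calls = assign_by_genotype(
            panel_counts, donor_geno, error_rate=cfg.error_rate,
            min_margin=cfg.min_margin, min_informative=cfg.min_informative)
        report["outputs"]["snp_panel"] = _write(panel, out / "snp_panel.tsv")
        report["outputs"]["sample_genotypes"] = _write(
            sample_geno, out / "sample_genotypes.tsv", index=True)
        report["outputs"]["concordance"] = _write(
            conc, out / "concordance.tsv")
        report["outputs"]["donor_genotypes"] = _write(
            donor_geno, out / "donor_genotypes.tsv", index=True)
        report["outputs"]["genotype_calls"] = _write(
            genotype_calls, out / "genotype_calls.tsv")
        report["stages"]["genotype_demux"] = {
            "snps_selected": int(len(panel)),
            "cells": int(len(genotype_calls)),
            "called": int(genotype_calls["donor_call"].notna().sum()),
        }

    # ------------------------------------------------------------ consensus
    if cfg.do_consensus:
        assignments, crosstab = consensus_assign(
            hashtag_calls[["cell_id", "donor_call"]],
            genotype_calls[["cell_id", "donor_call"]])
        report["outputs"]["assignments"] = _write(
            assignments, out / "assignments.tsv")
        report["outputs"]["crosstab"] = _write(
            crosstab, out / "crosstab.tsv", index=True)
        n_cons = int((assignments["status"] == "consistent").sum())
        report["stages"]["consensus"] = {
            "cells": int(len(assignments)),
            "consistent": n_cons,
            "conflict": int((assignments["status"] == "conflict").sum()),
        }
        if (n_cons > report["stages"].get("hashtag_demux", {}).get("called", n_cons)
                or n_cons > report["stages"].get("genotype_demux", {}).get("called", n_cons)):
            raise PipelineError(
                "stage consensus: consensus count exceeds a modality's "
                "call count (internal inconsistency)")

    # ------------------------------------------------------------ abundance
    if cfg.do_abundance:
        donors = sorted(truth.cell_to_donor["donor_a"].unique())
        half = len(donors) // 2
        design = pd.DataFrame([
            {"donor_id": d,
             "group": cfg.abundance_groups[0] if i < half else cfg.abundance_groups[-1],
             "timepoint": tp}
            for i, d in enumerate(donors) for tp in ("before", "after")])
        params = pd.DataFrame({
            "cluster_id": [f"cluster{c}" for c in range(1, cfg.n_cluster_sim + 1)],
            "beta0": [-2.0] * cfg.n_cluster_sim,
            "beta1": [0.0, 0.4, 0.8, -0.4, 1.2][:cfg.n_cluster_sim]
                     + [0.0] * max(0, cfg.n_cluster_sim - 5),
            "sigma_u": [0.5] * cfg.n_cluster_sim,
            "sigma_e": [0.3] * cfg.n_cluster_sim,
        })
        table, _, _ = simulate_cluster_counts(design, params,
                                              total_sampler=cfg.total_mean,
                                              seed=cfg.seed)
        table = normalize_frequencies(table)
        results = []
        for grp in dict.fromkeys(design["group"]):
            try:
                results.append(test_all_clusters(table, grp,
                                                 alpha=cfg.bh_alpha))
            except ValueError as exc:
                raise PipelineError(f"stage abundance ({grp}): {exc}") from exc
        res = pd.concat(results, ignore_index=True)
        report["outputs"]["cluster_table"] = _write(
            table, out / "cluster_table.tsv")
        report["outputs"]["abundance_results"] = _write(
            res, out / "abundance_results.tsv")
        report["stages"]["abundance"] = {
            "clusters": int(res["cluster_id"].nunique()),
            "fits": int(len(res)),
            "significant": int(res["significant"].sum()),
        }

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["outputs"]["run_report"] = str(out / "run_report.json")
    return report
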