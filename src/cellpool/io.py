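"""Readers and writers for the pipeline's interchange formats.

TSV is the canonical interchange (inspectable, diff-able); hashtag count
matrices are also supported as MatrixMarket (MTX) triplets with cell and
feature label files, and SNP panels as a minimal biallelic VCF. All
readers validate shape and value constraints and name the offending line
where possible; round-trips are record-exact.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "read_hashtag_tsv", "write_hashtag_tsv",
    "read_hashtag_mtx", "write_hashtag_mtx",
    "read_allele_counts_tsv", "write_allele_counts_tsv",
    "read_cluster_table_tsv", "write_cluster_table_tsv",
    "read_qc_metrics_tsv",
    "read_vcf_panel", "write_vcf_panel",
    "read_yaml_config", "write_yaml_config",
]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------- hashtags

def read_hashtag_tsv(path: str | Path) -> pd.DataFrame:
    """Read a wide cells x hashtags TSV (first column cell_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "cell_id"
    df.columns.name = "hashtag_id"
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate cell ids")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate hashtag ids")
    arr = df.to_numpy()
    if arr.size and (arr < 0).any():
        row = int(np.argwhere(arr < 0)[0, 0])
        raise ValueError(f"{path}: negative count at data line {row + 2}")
    return df.astype(np.int64)


def write_hashtag_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="cell_id")


def read_hashtag_mtx(
    mtx_path: str | Path,
    cells_path: str | Path | None = None,
    features_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read an MTX triplet (matrix + cell/feature label files).

    The matrix is cells x hashtags. Label files are single-column,
    headerless text files; by default ``<stem>.cells.tsv`` and
    ``<stem>.features.tsv`` next to the matrix.
    """
    mtx_path = Path(mtx_path)
    stem = mtx_path.with_suffix("")
    cells_path = Path(cells_path) if cells_path else stem.with_suffix(".cells.tsv")
    features_path = (Path(features_path) if features_path
                     else stem.with_suffix(".features.tsv"))
    mat = scipy.io.mmread(os.fspath(mtx_path))
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str)
    feats = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if dense.shape != (len(cells), len(feats)):
        raise ValueError(
            f"{mtx_path}: matrix is {dense.shape} but labels give "
            f"({len(cells)}, {len(feats)})")
    if dense.size and (dense < 0).any():
        raise ValueError(f"{mtx_path}: negative count")
    if cells.duplicated().any() or feats.duplicated().any():
        raise ValueError(f"{mtx_path}: duplicate cell or feature ids")
    return pd.DataFrame(dense.astype(np.int64),
                        index=pd.Index(cells, name="cell_id"),
                        columns=pd.Index(feats, name="hashtag_id"))


def write_hashtag_mtx(
    counts: pd.DataFrame,
    mtx_path: str | Path,
    cells_path: str | Path | None = None,
    features_path: str | Path | None = None,
) -> None:
    mtx_path = Path(mtx_path)
    stem = mtx_path.with_suffix("")
    cells_path = Path(cells_path) if cells_path else stem.with_suffix(".cells.tsv")
    features_path = (Path(features_path) if features_path
                     else stem.with_suffix(".features.tsv"))
    scipy.io.mmwrite(os.fspath(mtx_path),
                     scipy.sparse.coo_matrix(counts.to_numpy()))
    pd.Series(counts.index.astype(str)).to_csv(cells_path, sep="\t",
                                               index=False, header=False)
    pd.Series(counts.columns.astype(str)).to_csv(features_path, sep="\t",
                                                 index=False, header=False)


# ---------------------------------------------------------- allele counts

def read_allele_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read long allele counts (cell_id, snp_id, ref_count, alt_count)."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"cell_id": str, "snp_id": str})
    _require_columns(df, ("cell_id", "snp_id", "ref_count", "alt_count"), path)
    neg = (df["ref_count"] < 0) | (df["alt_count"] < 0)
    if neg.any():
        line = int(np.flatnonzero(neg)[0]) + 2  # 1-based, after header
        raise ValueError(f"{path}: negative count at line {line}")
    dup = df.duplicated(subset=["cell_id", "snp_id"])
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise ValueError(f"{path}: duplicate (cell, snp) pair at line {line}")
    return df


def write_allele_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- cluster table

CLUSTER_COLUMNS = ("sample_id", "donor_id", "group", "timepoint",
                   "cluster_id", "count", "total", "denominator_kind")


def read_cluster_table_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={
        "sample_id": str, "donor_id": str, "cluster_id": str})
    _require_columns(df, CLUSTER_COLUMNS[:7], path)
    bad = (df["count"] < 0) | (df["count"] > df["total"]) | (df["total"] <= 0)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: invalid count/total at line {line}")
    return df


def write_cluster_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- QC metrics

def read_qc_metrics_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    _require_columns(df, ("cell_id", "umi_count", "mito_fraction"), path)
    bad = ((df["umi_count"] < 0) | (df["mito_fraction"] < 0)
           | (df["mito_fraction"] > 1))
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: invalid QC metric at line {line}")
    return df


# -------------------------------------------------------------------- VCF

VCF_HEADER = "\t".join(
    ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"])


def write_vcf_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a minimal biallelic SNP panel VCF (sites only)."""
    _require_columns(panel, ("snp_id", "chrom", "pos", "ref", "alt"), path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cellpool\n")
        fh.write(VCF_HEADER + "\n")
        for _, r in panel.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t{r['snp_id']}\t"
                     f"{r['ref']}\t{r['alt']}\t.\t.\t.\n")


def read_vcf_panel(path: str | Path) -> pd.DataFrame:
    """Read a sites-only SNP panel VCF; multi-allelic records are rejected."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}: malformed VCF record at line {lineno}")
            chrom, pos, vid, ref, alt = parts[:5]
            if "," in alt:
                raise ValueError(
                    f"{path}: multi-allelic ALT at line {lineno} "
                    f"(biallelic panel required)")
            if len(ref) != 1 or len(alt) != 1 or alt == ".":
                raise ValueError(
                    f"{path}: non-SNP record at line {lineno}")
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-integer POS at line {lineno}") from exc
            rows.append((vid, chrom, pos_i, ref, alt))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])


# ------------------------------------------------------------------- YAML

def read_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_yaml_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
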