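"""Cell-level quality filtering on UMI counts and mitochondrial fraction.

Cells with fewer than ``min_umi`` or more than ``max_umi`` unique molecular
identifiers, or with a mitochondrial read fraction above ``max_mito``, are
removed; the boundaries themselves are retained (removal inequalities are
strict). The defaults (200, 4000, 0.25) target dead cells, residual
doublets and cell clumps in droplet scRNA-seq data.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["QCResult", "filter_cells"]

REQUIRED_COLUMNS = ("cell_id", "umi_count", "mito_fraction")


@dataclass
class QCResult:
    """Outcome of :func:`filter_cells`.

    ``table`` carries one row per input cell with boolean ``retained`` and a
    semicolon-joined ``reason`` for removed cells; ``removal_counts`` tallies
    cells per reason (a cell may count toward several reasons).
    """

    retained: list[str]
    removal_counts: dict[str, int]
    table: pd.DataFrame

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def filter_cells(
    metrics: pd.DataFrame,
    min_umi: int = 200,
    max_umi: int = 4000,
    max_mito: float = 0.25,
) -> QCResult:
    """Apply the UMI-range and mitochondrial-fraction filter.

    A cell is retained iff ``min_umi <= umi_count <= max_umi`` and
    ``mito_fraction <= max_mito``.

    Parameters
    ----------
    metrics
        DataFrame with columns cell_id, umi_count, mito_fraction.

    Raises
    ------
    ValueError
        On invalid thresholds, missing columns, duplicate cell ids, or
        mito_fraction outside [0, 1].
    """
    if min_umi <= 0 or max_umi <= 0 or max_mito <= 0:
        raise ValueError("thresholds must be positive")
    if min_umi > max_umi:
        raise ValueError("min_umi must not exceed max_umi")
    for col in REQUIRED_COLUMNS:
        if col not in metrics.columns:
            raise ValueError(f"metrics lacks column {col!r}")
    if metrics["cell_id"].duplicated().any():
        dups = metrics.loc[metrics["cell_id"].duplicated(), "cell_id"]
        raise ValueError(f"duplicate cell ids: {sorted(set(dups))[:5]}")
    mito = metrics["mito_fraction"]
    if len(metrics) and ((mito < 0) | (mito > 1)).any():
        raise ValueError("mito_fraction must lie in [0, 1]")

    umi = metrics["umi_count"]
    low = umi < min_umi
    high = umi > max_umi
    mito_bad = mito > max_mito
    keep = ~(low | high | mito_bad)

    reasons = pd.Series([""] * len(metrics), index=metrics.index, dtype=object)
    for mask, tag in ((low, "low_umi"), (high, "high_umi"),
                      (mito_bad, "high_mito")):
        sel = reasons[mask]
        reasons[mask] = [tag if r == "" else f"{r};{tag}" for r in sel]

    table = metrics[list(REQUIRED_COLUMNS)].copy()
    table["retained"] = keep.to_numpy()
    table["reason"] = reasons.to_numpy()
    return QCResult(
        retained=metrics.loc[keep, "cell_id"].tolist(),
        removal_counts={
            "low_umi": int(low.sum()),
            "high_umi": int(high.sum()),
            "high_mito": int(mito_bad.sum()),
        },
        table=table,
    )
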