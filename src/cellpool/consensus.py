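"""Cross-validation of hashtag and genotype donor calls.

A cell enters the final analysis set only when the hashtag-based and the
genotype-based demultiplexers agree on its donor ("consistent"). Cells
called by a single modality, called to different donors ("conflict"), or
called by neither are reported with distinct statuses; the cross-tabulation
of hashtag donor x genotype donor exposes the diagonal (consensus), the
edges (single-modality calls) and the off-diagonal disagreements.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["consensus_assign", "UNCALLED"]

#: Cross-tab label for cells without a call in a modality.
UNCALLED = "(none)"


def _calls_series(calls: pd.DataFrame, what: str) -> pd.Series:
    if "cell_id" not in calls.columns or "donor_call" not in calls.columns:
        raise ValueError(f"{what} calls need columns cell_id and donor_call")
    if calls["cell_id"].duplicated().any():
        dups = calls.loc[calls["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell ids in {what} calls: {dups[:5]}")
    return calls.set_index("cell_id")["donor_call"]


def consensus_assign(
    hashtag_calls: pd.DataFrame,
    genotype_calls: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine per-cell donor calls from the two modalities.

    Cells missing from either input are treated as uncalled in that
    modality. Statuses: ``consistent`` (both modalities, same donor; the
    only status with a non-null final_donor), ``conflict`` (both, different
    donors), ``hashtag_only``, ``genotype_only``, ``unassigned``.

    Returns
    -------
    assignments : DataFrame
        cell_id, hashtag_donor, genotype_donor, final_donor, status.
    crosstab : DataFrame
        hashtag donor (rows) x genotype donor (columns) cell counts, with
        uncalled cells under the :data:`UNCALLED` label; marginals equal the
        per-modality call counts.
    """
    ht = _calls_series(hashtag_calls, "hashtag")
    gt = _calls_series(genotype_calls, "genotype")
    cells = ht.index.union(gt.index)
    ht = ht.reindex(cells)
    gt = gt.reindex(cells)

    both = ht.notna() & gt.notna()
    consistent = both & (ht == gt)
    status = pd.Series("unassigned", index=cells, dtype=object)
    status[ht.notna() & gt.isna()] = "hashtag_only"
    status[ht.isna() & gt.notna()] = "genotype_only"
    status[both & ~consistent] = "conflict"
    status[consistent] = "consistent"

    final = ht.where(consistent)
    assignments = pd.DataFrame({
        "cell_id": cells.astype(str),
        "hashtag_donor": ht.astype(object).where(ht.notna(), None).to_numpy(),
        "genotype_donor": gt.astype(object).where(gt.notna(), None).to_numpy(),
        "final_donor": final.astype(object).where(final.notna(), None).to_numpy(),
        "status": status.to_numpy(),
    }).sort_values("cell_id", ignore_index=True)

    crosstab = pd.crosstab(
        ht.fillna(UNCALLED), gt.fillna(UNCALLED),
        rownames=["hashtag_donor"], colnames=["genotype_donor"],
    )
    return assignments, crosstab
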