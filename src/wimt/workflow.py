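"""End-to-end convenience pipelines built from the core stages."""

from __future__ import annotations

from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .align import (
    LinkResult,
    estimate_rt_warp,
    link_features,
    rollup_protein_intensity,
    transfer_identifications,
)
from .io import TransferConfig

__all__ = ["split_runs", "align_and_link", "transfer_quantify", "per_dilution_log2"]


def split_runs(features: pd.DataFrame) -> dict:
    return {run_id: df.reset_index(drop=True) for run_id, df in features.groupby("run_id")}


def align_and_link(runs: Mapping[str, pd.DataFrame], cfg: TransferConfig,
                   reference: Optional[str] = None) -> LinkResult:
    """Warp every run onto the reference and link features across runs."""
    if reference is None:
        reference = max(sorted(runs), key=lambda r: len(runs[r]))
    warps = {
        run_id: estimate_rt_warp(df, runs[reference], cfg)
        for run_id, df in runs.items()
        if run_id != reference
    }
    return link_features(runs, warps, cfg, reference=reference)


def transfer_quantify(features: pd.DataFrame, ids: pd.DataFrame, run_levels,
                      cfg: TransferConfig,
                      reference: Optional[str] = None) -> Tuple[pd.DataFrame, pd.DataFrame, LinkResult]:
    """Full MS1 transfer: align, link, transfer identities, roll up proteins.

    Returns ``(protein_matrix, records, link)`` where ``protein_matrix`` is
    proteins x runs (linear intensities from both native and transferred
    peptides) and ``records`` is the per-peptide transfer/native table.
    """
    runs = split_runs(features)
    if reference is None and len(ids):
        reference = ids["run_id"].mode().iloc[0]
    link = align_and_link(runs, cfg, reference=reference)
    records = transfer_identifications(link, ids, run_levels, runs, cfg)
    if len(records) == 0:
        raise ValueError("no identities could be transferred or matched")
    matrix = rollup_protein_intensity(
        records.rename(columns={"protein": "protein"})[["run_id", "peptide", "protein", "intensity"]]
    )
    return matrix, records, link


def per_dilution_log2(matrix: pd.DataFrame, run_amounts: Mapping[str, float]) -> pd.DataFrame:
    """Average log2 intensity per dilution point (mean over replicates).

    ``run_amounts`` maps run_id -> loaded amount (ng); output columns are
    the distinct amounts in descending order.
    """
    log2 = np.log2(matrix)
    amounts = sorted({float(a) for a in run_amounts.values()}, reverse=True)
    cols = {}
    for a in amounts:
        runs = [r for r in matrix.columns if float(run_amounts[r]) == a]
        cols[a] = log2[runs].mean(axis=1)
    return pd.DataFrame(cols)
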