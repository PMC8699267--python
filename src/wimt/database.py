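"""The multilevel plasma database: per-depletion-level identification sets,
minimal-level categorization, and the normalization used for comparisons.

Plasma runs are acquired at four depletion levels (undepleted, top-7,
top-14, SuperMix). Identifications from technical replicates of a level
are merged by union (a protein identified in at least one replicate counts
as identified at that level); each protein's ``min_level`` is the least
depleted level at which it was ever MS2-identified, which categorizes
undepleted-run intensities by the depletion depth needed to see the
protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .align import _match_ids_to_features, rollup_protein_intensity
from .io import DepletionLevel, TransferConfig

__all__ = [
    "MultiLevelDatabase",
    "build_database",
    "normalize_for_comparison",
    "level_abundance_contrast",
]


@dataclass
class MultiLevelDatabase:
    """Four-layer identification database.

    ``table`` has one row per protein: ``min_level``, per-level mean
    intensities (``intensity_L1..L4``, NaN where unidentified) and
    ``unique_to_level`` (the only level identifying the protein, else NA).
    ``peptides`` maps (protein, level) -> set of peptide sequences.
    """

    table: pd.DataFrame
    peptides: dict = field(default_factory=dict)

    def proteins_at(self, level: DepletionLevel) -> set:
        col = f"identified_L{int(level)}"
        if col not in self.table.columns:
            return set()
        return set(self.table.index[self.table[col]])

    @property
    def levels(self) -> list:
        return [
            lv for lv in DepletionLevel
            if f"identified_L{int(lv)}" in self.table.columns
        ]


def build_database(
    per_level_ids: Mapping[DepletionLevel, pd.DataFrame],
    per_level_features: Mapping[DepletionLevel, pd.DataFrame],
    cfg: TransferConfig = TransferConfig(),
) -> MultiLevelDatabase:
    """Build the multilevel database from per-level ID and feature tables.

    Each level's table may contain several technical-replicate runs
    (distinct ``run_id``); replicates merge by union. Per-level protein
    intensity is the label-free rollup of the level's identified features
    (peptide intensity = matched feature intensity, summed per protein per
    run, averaged over the level's runs).
    """
    levels = sorted(per_level_ids, key=int)
    if len(set(int(lv) for lv in levels)) != len(levels):
        raise ValueError("duplicate level inputs")
    if DepletionLevel.UNDEPLETED not in [DepletionLevel(int(lv)) for lv in levels]:
        raise ValueError("the UNDEPLETED level is required")

    rows_by_protein: dict[str, dict] = {}
    peptides: dict[tuple, set] = {}
    level_intensity: dict[DepletionLevel, pd.Series] = {}
    for lv in levels:
        lv = DepletionLevel(int(lv))
        ids = per_level_ids[lv]
        feats = per_level_features[lv]
        pep_rows = []
        for run_id, run_ids in ids.groupby("run_id"):
            run_feats = feats[feats["run_id"] == run_id]
            matched = _match_ids_to_features(run_ids, run_feats, cfg.align_ppm, 0.5)
            fint = dict(zip(run_feats["feature_id"], run_feats["intensity"]))
            for idx, fid in matched.items():
                row = ids.loc[idx]
                pep_rows.append(
                    (run_id, row["peptide"], row["proteins"], fint[fid])
                )
        pep_df = pd.DataFrame(pep_rows, columns=["run_id", "peptide", "proteins", "intensity"])
        if len(pep_df):
            rolled = rollup_protein_intensity(pep_df)
            level_intensity[lv] = rolled.mean(axis=1)
        else:
            level_intensity[lv] = pd.Series(dtype=float)
        for accs, pep in zip(ids["proteins"], ids["peptide"]):
            p = accs[0] if not isinstance(accs, str) else accs
            rows_by_protein.setdefault(p, {})[lv] = True
            peptides.setdefault((p, lv), set()).add(pep)

    proteins = sorted(rows_by_protein)
    data = {}
    for lv in levels:
        lv = DepletionLevel(int(lv))
        data[f"identified_L{int(lv)}"] = [
            rows_by_protein[p].get(lv, False) for p in proteins
        ]
        data[f"intensity_L{int(lv)}"] = [
            level_intensity[lv].get(p, np.nan) for p in proteins
        ]
    table = pd.DataFrame(data, index=pd.Index(proteins, name="protein"))
    min_level = []
    unique_to = []
    for p in proteins:
        lvs = [lv for lv in levels if rows_by_protein[p].get(DepletionLevel(int(lv)), False)]
        min_level.append(int(min(lvs, key=int)))
        unique_to.append(int(lvs[0]) if len(lvs) == 1 else pd.NA)
    table["min_level"] = min_level
    table["unique_to_level"] = unique_to
    return MultiLevelDatabase(table=table, peptides=peptides)


def normalize_for_comparison(
    matrix: pd.DataFrame, groups: Optional[Mapping[str, object]] = None
) -> pd.DataFrame:
    """Log2-transform, median-center each run, filter by group validity.

    ``matrix`` is proteins x runs on the linear scale (NaN = missing).
    After log2 and per-run median subtraction, a protein is kept only if it
    has at least one valid value in every declared group (``groups`` maps
    run -> group label; default: every run in one group). Missing values
    are never imputed.
    """
    mat = matrix.to_numpy(dtype=float)
    if np.any(mat[np.isfinite(mat)] <= 0):
        raise ValueError("intensities must be positive (or missing)")
    log2 = np.log2(mat)
    all_missing = ~np.isfinite(log2)
    if np.any(all_missing.all(axis=0)):
        bad = matrix.columns[all_missing.all(axis=0)].tolist()
        raise ValueError(f"run(s) with no valid values: {bad}")
    centered = log2 - np.nanmedian(log2, axis=0, keepdims=True)
    out = pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)
    if groups is None:
        groups = {c: "all" for c in matrix.columns}
    keep = pd.Series(True, index=matrix.index)
    for g in sorted(set(map(str, groups.values()))):
        cols = [c for c in matrix.columns if str(groups[c]) == g]
        keep &= out[cols].notna().any(axis=1)
    return out[keep]


@dataclass
class LevelContrast:
    summary: pd.DataFrame
    anova_f: float
    anova_p: float
    pairwise: Optional[pd.DataFrame]
    excluded: list


def level_abundance_contrast(
    db: MultiLevelDatabase, undepleted_intensities: pd.Series
) -> LevelContrast:
    """Compare undepleted-run abundances across min-level categories.

    Groups proteins by the depletion level first identifying them, reports
    the median and 5th-95th percentile of log2 intensity per category, and
    runs a one-way ANOVA with Tukey-HSD pairwise comparisons (reporting
    convenience, not part of the transfer method). Categories with fewer
    than two proteins are excluded from testing and listed.
    """
    cats = db.table["min_level"]
    log2 = np.log2(undepleted_intensities.dropna())
    shared = log2.index.intersection(cats.index)
    log2 = log2[shared]
    cat = cats[shared]

    rows, samples, labels, excluded = [], [], [], []
    for lv in sorted(cat.unique()):
        vals = log2[cat == lv].to_numpy()
        rows.append(
            {
                "min_level": int(lv),
                "n": len(vals),
                "median_log2": float(np.median(vals)) if len(vals) else np.nan,
                "p5_log2": float(np.percentile(vals, 5)) if len(vals) else np.nan,
                "p95_log2": float(np.percentile(vals, 95)) if len(vals) else np.nan,
            }
        )
        if len(vals) >= 2:
            samples.append(vals)
            labels.append(int(lv))
        else:
            excluded.append(int(lv))
    summary = pd.DataFrame(rows).set_index("min_level")

    if len(samples) >= 2:
        f, p = stats.f_oneway(*samples)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(samples)
        grp = np.concatenate([[lab] * len(s) for lab, s in zip(labels, samples)])
        tk = pairwise_tukeyhsd(values, grp)
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    else:
        f, p, pairwise = float("nan"), float("nan"), None
    return LevelContrast(summary=summary, anova_f=float(f), anova_p=float(p),
                         pairwise=pairwise, excluded=excluded)
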