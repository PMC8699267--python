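"""MS1 transfer core: RT alignment, cross-run feature linking, identity
transfer, and label-free protein rollup.

The workflow mirrors a feature-mapper stage: one run is designated the
reference; every other run is aligned to it by a robust monotone RT warp
fitted on mutually-nearest high-S/N anchor features (within a ppm mass
window and a maximum RT shift, 10 ppm / 3 min by default). Features are
then linked across runs into consensus features by greedy nearest-neighbour
matching, lexicographic in (ppm distance, warped-RT distance), and peptide
identities propagate along each consensus from identified runs to runs
where the feature was detected but never fragmented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import DepletionLevel, TransferConfig

__all__ = [
    "InsufficientAnchorsError",
    "ConflictingIdentityError",
    "RTAligner",
    "IdentityWarp",
    "FeatureLinker",
    "LinkResult",
    "estimate_rt_warp",
    "link_features",
    "transfer_identifications",
    "rollup_protein_intensity",
    "transfer_ratio",
]

RECORD_COLUMNS = (
    "protein", "peptide", "run_id", "source_level", "intensity",
    "rank1", "pdi", "score", "qvalue", "accepted", "native",
)


class InsufficientAnchorsError(RuntimeError):
    def __init__(self, n_anchors: int, minimum: int):
        self.n_anchors = n_anchors
        super().__init__(f"insufficient anchors: found {n_anchors}, need >= {minimum}")


class ConflictingIdentityError(RuntimeError):
    """A consensus feature carries two or more distinct peptide identities."""

    def __init__(self, consensus_id, peptides):
        self.consensus_id = consensus_id
        self.peptides = sorted(peptides)
        super().__init__(
            f"consensus {consensus_id} carries conflicting peptide identities: {self.peptides}"
        )


def _best_match(mz_q, rt_q, mz_s, rt_s, ppm_tol, rt_tol):
    """Index in the *sorted* arrays of the lexicographically nearest candidate
    (ppm first, RT second) within both tolerances, or -1."""
    lo = np.searchsorted(mz_s, mz_q * (1.0 - ppm_tol * 1e-6), side="left")
    hi = np.searchsorted(mz_s, mz_q * (1.0 + ppm_tol * 1e-6), side="right")
    if lo == hi:
        return -1
    cand = np.arange(lo, hi)
    d_rt = np.abs(rt_s[cand] - rt_q)
    ok = d_rt <= rt_tol
    if not ok.any():
        return -1
    cand, d_rt = cand[ok], d_rt[ok]
    d_ppm = np.abs(mz_s[cand] - mz_q) / mz_q * 1e6
    best = np.lexsort((d_rt, d_ppm))[0]
    return cand[best]


def _mutual_pairs(tgt, ref, ppm_tol, rt_tol, min_snr):
    """Mutually-nearest (target_idx, ref_idx) pairs within tolerances."""
    t = tgt[tgt["snr"] >= min_snr]
    r = ref[ref["snr"] >= min_snr]
    if len(t) == 0 or len(r) == 0:
        return np.empty((0, 2), dtype=int)
    t_mz, t_rt, t_idx = t["mz"].to_numpy(), t["rt_min"].to_numpy(), t.index.to_numpy()
    r_order = np.argsort(r["mz"].to_numpy(), kind="stable")
    r_mz = r["mz"].to_numpy()[r_order]
    r_rt = r["rt_min"].to_numpy()[r_order]
    r_idx = r.index.to_numpy()[r_order]
    t_order = np.argsort(t_mz, kind="stable")
    ts_mz, ts_rt, ts_idx = t_mz[t_order], t_rt[t_order], t_idx[t_order]

    fwd = {}
    for i in range(len(t_mz)):
        j = _best_match(t_mz[i], t_rt[i], r_mz, r_rt, ppm_tol, rt_tol)
        if j >= 0:
            fwd[t_idx[i]] = r_idx[j]
    pairs = []
    for j in range(len(r_mz)):
        i = _best_match(r_mz[j], r_rt[j], ts_mz, ts_rt, ppm_tol, rt_tol)
        if i >= 0 and fwd.get(ts_idx[i]) == r_idx[j]:
            pairs.append((ts_idx[i], r_idx[j]))
    return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


class RTAligner(BaseEstimator, TransformerMixin):
    """Monotone retention-time warp of a target run onto a reference run.

    Anchors are mutually-nearest feature pairs within ``ppm`` in m/z and
    ``max_rt_shift`` in RT, with S/N >= ``min_snr`` on both sides. The warp
    is a robust local-linear (LOWESS) smooth of the anchor RT offsets,
    clipped to ``max_rt_shift``, forced monotone, and tapering to identity
    away from the anchor range.

    Attributes
    ----------
    anchor_pairs_ : (n, 2) array of (rt_target, rt_reference) minutes
    rt_residuals_ : post-warp anchor RT residuals (minutes)
    ppm_residuals_ : anchor mass residuals (ppm)
    """

    def __init__(self, max_rt_shift: float = 3.0, ppm: float = 10.0,
                 min_snr: float = 5.0, min_anchors: int = 5, lowess_frac="auto"):
        self.max_rt_shift = max_rt_shift
        self.ppm = ppm
        self.min_snr = min_snr
        self.min_anchors = min_anchors
        self.lowess_frac = lowess_frac

    def fit(self, X: pd.DataFrame, reference: pd.DataFrame):
        """Fit the warp from target features ``X`` to ``reference`` features."""
        if len(X) == 0 or len(reference) == 0:
            raise ValueError("both runs must be non-empty")
        pairs = _mutual_pairs(X, reference, self.ppm, self.max_rt_shift, self.min_snr)
        if len(pairs) < self.min_anchors:
            raise InsufficientAnchorsError(len(pairs), self.min_anchors)
        rt_t = X.loc[pairs[:, 0], "rt_min"].to_numpy()
        rt_r = reference.loc[pairs[:, 1], "rt_min"].to_numpy()
        mz_t = X.loc[pairs[:, 0], "mz"].to_numpy()
        mz_r = reference.loc[pairs[:, 1], "mz"].to_numpy()
        self.anchor_pairs_ = np.column_stack([rt_t, rt_r])
        self.ppm_residuals_ = (mz_t - mz_r) / mz_r * 1e6

        offset = rt_r - rt_t
        span = rt_t.max() - rt_t.min()
        # adaptive span: ~20 anchors per window tracks smooth drift with low
        # bias while staying robust to stray mismatched anchors
        frac = (
            float(np.clip(20.0 / len(pairs), 0.03, 0.67))
            if self.lowess_frac == "auto" else float(self.lowess_frac)
        )
        sm = lowess(offset, rt_t, frac=frac, it=2,
                    delta=0.005 * max(span, 1e-9), return_sorted=True)
        lo, hi = rt_t.min(), rt_t.max()
        margin = 2.0 * self.max_rt_shift
        grid = np.linspace(lo - margin, hi + margin, 512)
        off = np.interp(grid, sm[:, 0], sm[:, 1])
        # taper to identity outside the anchor range
        off = np.where(grid < lo, sm[0, 1] * np.clip(1 - (lo - grid) / margin, 0, 1), off)
        off = np.where(grid > hi, sm[-1, 1] * np.clip(1 - (grid - hi) / margin, 0, 1), off)
        off = np.clip(off, -self.max_rt_shift, self.max_rt_shift)
        w = grid + off
        w = np.maximum.accumulate(w)
        w = np.minimum(w, grid + self.max_rt_shift)
        w = w + np.arange(len(w)) * 1e-9  # strict monotonicity
        self._grid, self._warped = grid, w
        self.rt_residuals_ = rt_r - self.transform(rt_t)
        return self

    def transform(self, rt) -> np.ndarray:
        """Map target-run RTs into the reference frame (identity far outside)."""
        rt = np.asarray(rt, dtype=float)
        inside = np.interp(rt, self._grid, self._warped)
        out = np.where(
            (rt < self._grid[0]) | (rt > self._grid[-1]), rt, inside
        )
        return out

    __call__ = transform


class IdentityWarp:
    """No-op warp (reference frame)."""

    anchor_pairs_ = np.empty((0, 2))
    rt_residuals_ = np.empty(0)
    ppm_residuals_ = np.empty(0)

    def transform(self, rt):
        return np.asarray(rt, dtype=float)

    __call__ = transform


def estimate_rt_warp(target: pd.DataFrame, reference: pd.DataFrame,
                     cfg: TransferConfig = TransferConfig()) -> RTAligner:
    """Spec-level wrapper: fit an :class:`RTAligner` under ``cfg`` tolerances."""
    return RTAligner(
        max_rt_shift=cfg.max_rt_shift, ppm=cfg.align_ppm, min_snr=cfg.min_snr
    ).fit(target, reference)


@dataclass
class LinkResult:
    """Outcome of cross-run feature linking.

    ``consensus`` has one row per consensus feature (intensity-weighted
    consensus m/z, reference-frame consensus RT); ``members`` is long-form
    with one row per linked feature.
    """

    consensus: pd.DataFrame
    members: pd.DataFrame
    tol_ppm: float
    tol_rt: float
    reference_run: str


class FeatureLinker(BaseEstimator):
    """Greedy cross-run feature linking against a reference run.

    Consensus features are seeded by reference-run features with
    S/N >= ``min_snr``. For every other run, candidate (feature, seed)
    pairs within the effective tolerances are accepted greedily in
    lexicographic (ppm distance, warped-RT distance) order, so each
    feature joins at most one consensus and each consensus holds at most
    one member per run. Tolerances given as ``"auto"`` resolve to the 95th
    percentile of post-alignment anchor residuals, floored at 5 ppm and
    0.2 min.
    """

    PPM_FLOOR = 5.0
    RT_FLOOR = 0.2

    def __init__(self, ppm="auto", rt_tol="auto", min_snr: float = 5.0):
        self.ppm = ppm
        self.rt_tol = rt_tol
        self.min_snr = min_snr

    def _resolve_tolerances(self, warps):
        ppm_res = np.concatenate(
            [np.abs(w.ppm_residuals_) for w in warps.values()] or [np.empty(0)]
        )
        rt_res = np.concatenate(
            [np.abs(w.rt_residuals_) for w in warps.values()] or [np.empty(0)]
        )
        tol_ppm = (
            float(self.ppm) if self.ppm != "auto"
            else max(self.PPM_FLOOR, float(np.percentile(ppm_res, 95)) if len(ppm_res) else 0.0)
        )
        tol_rt = (
            float(self.rt_tol) if self.rt_tol != "auto"
            else max(self.RT_FLOOR, float(np.percentile(rt_res, 95)) if len(rt_res) else 0.0)
        )
        return tol_ppm, tol_rt

    def fit(self, runs: Mapping[str, pd.DataFrame], reference: str,
            warps: Optional[Mapping[str, RTAligner]] = None):
        warps = dict(warps or {})
        for run_id in runs:
            if run_id != reference and run_id not in warps:
                raise ValueError(f"missing RT warp for non-reference run {run_id!r}")
        warps[reference] = IdentityWarp()
        tol_ppm, tol_rt = self._resolve_tolerances(
            {k: v for k, v in warps.items() if k != reference}
        )

        ref = runs[reference].reset_index(drop=True)
        seed_ok = ref["snr"].to_numpy() >= self.min_snr
        seeds = ref[seed_ok].reset_index(drop=True)
        n_seeds = len(seeds)
        seed_mz = seeds["mz"].to_numpy()
        seed_rt = seeds["rt_min"].to_numpy()
        seed_sorted = np.argsort(seed_mz, kind="stable")
        smz, srt = seed_mz[seed_sorted], seed_rt[seed_sorted]

        member_rows = []
        for i in range(n_seeds):
            member_rows.append((
                i, reference, seeds["feature_id"].iloc[i], seed_mz[i],
                seeds["rt_min"].iloc[i], seed_rt[i],
                seeds["intensity"].iloc[i], seeds["snr"].iloc[i],
            ))

        for run_id in sorted(runs):
            if run_id == reference:
                continue
            run = runs[run_id].reset_index(drop=True)
            wrt = warps[run_id].transform(run["rt_min"].to_numpy())
            f_mz = run["mz"].to_numpy()
            # candidate pairs within tolerance, greedy by (ppm, rt) distance
            cand_f, cand_s, cand_dppm, cand_drt = [], [], [], []
            for fi in range(len(run)):
                lo = np.searchsorted(smz, f_mz[fi] * (1.0 - tol_ppm * 1e-6), "left")
                hi = np.searchsorted(smz, f_mz[fi] * (1.0 + tol_ppm * 1e-6), "right")
                for jj in range(lo, hi):
                    drt = abs(wrt[fi] - srt[jj])
                    if drt <= tol_rt:
                        cand_f.append(fi)
                        cand_s.append(seed_sorted[jj])
                        cand_dppm.append(abs(f_mz[fi] - smz[jj]) / smz[jj] * 1e6)
                        cand_drt.append(drt)
            if not cand_f:
                continue
            order = np.lexsort((np.array(cand_drt), np.array(cand_dppm)))
            used_f, used_s = set(), set()
            for k in order:
                fi, sj = cand_f[k], cand_s[k]
                if fi in used_f or sj in used_s:
                    continue
                used_f.add(fi)
                used_s.add(sj)
                member_rows.append((
                    sj, run_id, run["feature_id"].iloc[fi], f_mz[fi],
                    run["rt_min"].iloc[fi], wrt[fi],
                    run["intensity"].iloc[fi], run["snr"].iloc[fi],
                ))

        members = pd.DataFrame(
            member_rows,
            columns=["seed", "run_id", "feature_id", "mz", "rt_min", "rt_ref", "intensity", "snr"],
        )
        members["consensus_id"] = [f"c{int(s):06d}" for s in members["seed"]]
        members = members.drop(columns="seed").sort_values(
            ["consensus_id", "run_id"], kind="mergesort"
        ).reset_index(drop=True)

        g = members.groupby("consensus_id")
        wsum = g.apply(
            lambda d: pd.Series({
                "mz_consensus": np.average(d["mz"], weights=d["intensity"]),
                "rt_consensus": np.average(d["rt_ref"], weights=d["intensity"]),
                "n_members": len(d),
            }),
            include_groups=False,
        ).reset_index()
        self.consensus_ = wsum
        self.members_ = members
        self.tol_ppm_ = tol_ppm
        self.tol_rt_ = tol_rt
        self.reference_run_ = reference
        return self

    @property
    def result_(self) -> LinkResult:
        return LinkResult(self.consensus_, self.members_, self.tol_ppm_,
                          self.tol_rt_, self.reference_run_)


def link_features(runs: Mapping[str, pd.DataFrame],
                  warps: Optional[Mapping[str, RTAligner]],
                  cfg: TransferConfig = TransferConfig(),
                  reference: Optional[str] = None) -> LinkResult:
    """Link features across runs into consensus features.

    The reference run defaults to the run with the most features (ties by
    run_id). ``warps`` must cover every non-reference run.
    """
    if reference is None:
        reference = max(sorted(runs), key=lambda r: len(runs[r]))
    linker = FeatureLinker(ppm=cfg.link_ppm, rt_tol=cfg.link_rt_tol, min_snr=cfg.min_snr)
    return linker.fit(runs, reference, warps).result_


def _match_ids_to_features(ids: pd.DataFrame, run: pd.DataFrame,
                           tol_ppm: float, tol_rt: float) -> dict:
    """psm index -> feature_id, by nearest (ppm, RT) within tolerance."""
    order = np.argsort(run["mz"].to_numpy(), kind="stable")
    mz = run["mz"].to_numpy()[order]
    rt = run["rt_min"].to_numpy()[order]
    fid = run["feature_id"].to_numpy()[order]
    out = {}
    for idx, row in ids.iterrows():
        j = _best_match(row["mz"], row["rt_min"], mz, rt, tol_ppm, tol_rt)
        if j >= 0:
            out[idx] = fid[j]
    return out


def transfer_identifications(link: LinkResult, ids: pd.DataFrame,
                             run_levels: Mapping[str, DepletionLevel],
                             runs: Mapping[str, pd.DataFrame],
                             cfg: TransferConfig = TransferConfig()) -> pd.DataFrame:
    """Propagate peptide identities along consensus features.

    Returns one row per (consensus member x identity): rows with
    ``native=True`` were MS2-identified in their own run; rows with
    ``native=False`` are transfers, carrying ``source_level`` = the minimal
    depletion level among the identified members of the consensus. A
    consensus with two conflicting peptide identities raises
    :class:`ConflictingIdentityError` rather than voting.
    """
    members = link.members
    feat_to_cons = {
        (r, f): c for r, f, c in zip(members["run_id"], members["feature_id"], members["consensus_id"])
    }
    # attach each PSM to its run's nearest feature, then to its consensus
    cons_ids: dict[str, list] = {}
    for run_id, run_ids in ids.groupby("run_id"):
        if run_id not in runs:
            continue
        matched = _match_ids_to_features(run_ids, runs[run_id], link.tol_ppm, link.tol_rt)
        for idx, feature_id in matched.items():
            cons = feat_to_cons.get((run_id, feature_id))
            if cons is not None:
                cons_ids.setdefault(cons, []).append(ids.loc[idx])

    members_by_cons: dict[str, list] = {}
    for m in members.itertuples():
        members_by_cons.setdefault(m.consensus_id, []).append(m)

    rows = []
    for cons, id_rows in cons_ids.items():
        peptides = {r["peptide"] for r in id_rows}
        if len(peptides) > 1:
            raise ConflictingIdentityError(cons, peptides)
        id_row = id_rows[0]
        identified_runs = {r["run_id"] for r in id_rows}
        source_level = DepletionLevel(
            min(int(run_levels[r]) for r in identified_runs)
        )
        protein = id_row["proteins"][0] if not isinstance(id_row["proteins"], str) else id_row["proteins"]
        for m in members_by_cons[cons]:
            native = m.run_id in identified_runs
            rows.append((
                protein, id_row["peptide"], m.run_id,
                int(run_levels[m.run_id]) if native else int(source_level),
                m.intensity, np.nan, np.nan, np.nan, np.nan, False, native,
            ))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records.sort_values(["protein", "peptide", "run_id"], kind="mergesort").reset_index(drop=True)


def rollup_protein_intensity(peptides: pd.DataFrame) -> pd.DataFrame:
    """Sum peptide intensities to protein intensities (linear scale).

    Input needs columns ``run_id``, ``peptide``, ``intensity`` and either
    ``protein`` or an accession-tuple column ``proteins``. Shared (razor)
    peptides are assigned wholly to the protein with the larger total
    unique-peptide intensity, ties broken by accession order. Returns a
    proteins x runs wide table; total intensity is conserved exactly.
    """
    if len(peptides) == 0:
        raise ValueError("empty peptide group")
    df = peptides.copy()
    if "protein" not in df.columns:
        accs = df["proteins"]
        unique_mask = accs.map(len) == 1
        unique_tot = (
            df[unique_mask]
            .assign(protein=[a[0] for a in accs[unique_mask]])
            .groupby("protein")["intensity"].sum()
        )

        def razor(acc_tuple):
            return sorted(acc_tuple, key=lambda a: (-unique_tot.get(a, 0.0), a))[0]

        df["protein"] = [a[0] if len(a) == 1 else razor(a) for a in accs]
    out = df.pivot_table(index="protein", columns="run_id", values="intensity",
                         aggfunc="sum")
    return out.sort_index()


def transfer_ratio(db, records: pd.DataFrame,
                   run_levels: Mapping[str, DepletionLevel]) -> dict:
    """Per-depleted-level fraction of identified proteins recovered in
    undepleted runs (by accepted transfer or native identification).

    ``db`` is either a mapping level -> protein set or an object exposing
    ``proteins_at(level)``. Levels with no identified proteins report NaN.
    """
    def proteins_at(level):
        if hasattr(db, "proteins_at"):
            return set(db.proteins_at(level))
        return set(db.get(level, set()))

    undep_runs = {r for r, lv in run_levels.items() if DepletionLevel(int(lv)) == DepletionLevel.UNDEPLETED}
    in_undep = records["run_id"].isin(undep_runs)
    recovered = set(
        records.loc[in_undep & (records["native"] | records["accepted"]), "protein"]
    )
    out = {}
    for level in (DepletionLevel.LOW_DEP, DepletionLevel.MID_DEP, DepletionLevel.DEEP_DEP):
        identified = proteins_at(level)
        out[level] = (
            float("nan") if not identified
            else len(identified & recovered) / len(identified)
        )
    return out
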