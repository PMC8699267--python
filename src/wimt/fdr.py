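"""Target-decoy false-discovery-rate control for MS1-transferred identities.

Two branches validate transfers:

* **Dilution-linearity branch** -- per-protein ordinary least squares of
  log2 intensity on log2 loaded amount across a dilution series; R² is the
  score. Decoys are built by permuting intensities across proteins within
  each dilution column (preserving per-column intensity multisets while
  destroying each protein's dilution profile).
* **Empirical plasma branch** -- each transferred protein is scored from
  its MS1 intensity Ii through its ascending-intensity rank Rank1 within
  the run and its plasma probability PDi (a Laplace-smoothed empirical CDF
  of known plasma-protein reference intensities):

      score = w * Rank1/N + (1 - w) * PDi,        w = 0.5 by default.

  The exact functional form combining the three ingredients is a declared
  surrogate (see docs/methods.md): it is monotone in each ingredient and
  uses nothing else. Decoys draw log2 intensities from a Gaussian fitted
  to the target log2 intensities and pass through the same scoring path.

Both branches estimate FDR at cutoff s as #{decoy >= s} / #{target >= s},
convert to q-values by the running minimum over decreasing cutoffs, and
accept q <= 0.05 by default.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ReferenceIntensities

__all__ = [
    "fit_linearity",
    "make_shuffle_decoys",
    "target_decoy_fdr",
    "plasma_probability",
    "empirical_score",
    "make_simulated_decoys",
    "ReferenceCDF",
    "LinearityFDR",
    "EmpiricalTransferFDR",
]


# ---------------------------------------------------------------------------
# linearity branch


def _ols_rows(Y: np.ndarray, x: np.ndarray):
    """Row-wise OLS of Y (n_rows x n_points, may contain NaN) on x.

    Returns (slope, intercept, r2, n_points). Rows with fewer than 3
    finite points get NaN. R² is clipped to [0, 1]; a zero-variance
    response is scored 0 (no linear signal).
    """
    if np.ptp(x[np.isfinite(x)]) == 0:
        raise ValueError("zero-variance regressor")
    n_rows = Y.shape[0]
    slope = np.full(n_rows, np.nan)
    intercept = np.full(n_rows, np.nan)
    r2 = np.full(n_rows, np.nan)
    npts = np.isfinite(Y).sum(axis=1)
    for i in range(n_rows):
        m = np.isfinite(Y[i])
        if m.sum() < 3 or np.ptp(x[m]) == 0:
            continue
        xi, yi = x[m], Y[i, m]
        xc = xi - xi.mean()
        yc = yi - yi.mean()
        sxx = (xc * xc).sum()
        b = (xc * yc).sum() / sxx
        a = yi.mean() - b * xi.mean()
        sst = (yc * yc).sum()
        sse = ((yi - a - b * xi) ** 2).sum()
        slope[i], intercept[i] = b, a
        r2[i] = 0.0 if sst == 0 else np.clip(1.0 - sse / sst, 0.0, 1.0)
    return slope, intercept, r2, npts


def fit_linearity(matrix: pd.DataFrame, amounts: Sequence[float]) -> pd.DataFrame:
    """Per-protein OLS of log2 intensity on log2 amount; R² is the score.

    ``matrix`` is proteins x dilution points of log2 intensities (NaN =
    missing); ``amounts`` are the loaded amounts in ng, one per column.
    Proteins with fewer than 3 finite points are returned unscored
    (NaN slope/r2) so they can be reported separately.
    """
    amounts = np.asarray(list(amounts), dtype=float)
    if matrix.shape[1] != len(amounts):
        raise ValueError("one amount per matrix column required")
    x = np.log2(amounts)
    slope, intercept, r2, npts = _ols_rows(matrix.to_numpy(dtype=float), x)
    return pd.DataFrame(
        {
            "protein": matrix.index,
            "slope": slope,
            "intercept": intercept,
            "r2": r2,
            "n_points": npts,
        }
    ).set_index("protein")


def make_shuffle_decoys(matrix: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Column-wise cross-protein permutation of intensities.

    Each dilution column is permuted independently so every protein adopts
    another protein's intensity at that point; per-column multisets are
    preserved exactly. Permutations are re-drawn (up to 100 times) until
    no protein keeps its own position, then accepted as-is.
    """
    if len(matrix) < 2:
        raise ValueError("cannot shuffle a single-protein matrix")
    rng = np.random.default_rng(seed)
    n = len(matrix)
    out = matrix.to_numpy(dtype=float).copy()
    for j in range(out.shape[1]):
        perm = rng.permutation(n)
        for _ in range(100):
            if not np.any(perm == np.arange(n)):
                break
            perm = rng.permutation(n)
        out[:, j] = out[perm, j]
    decoy = pd.DataFrame(out, columns=matrix.columns,
                         index=[f"DECOY_{p}" for p in matrix.index])
    return decoy


# ---------------------------------------------------------------------------
# shared target-decoy machinery


def target_decoy_fdr(target_scores, decoy_scores, threshold: float = 0.05):
    """Classical target-decoy FDR with running-minimum q-values.

    FDR at cutoff s = #{decoy >= s} / max(1, #{target >= s}); the q-value
    of a target is the minimum FDR over all cutoffs at or below its score,
    making q monotone non-increasing in score. Returns ``(qvalues,
    accepted)`` aligned with ``target_scores``; accepted means q <=
    ``threshold`` (inclusive, the "FDR < 5%" working point).
    """
    t = np.asarray(target_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if len(t) == 0 or len(d) == 0:
        raise ValueError("both score lists must be non-empty")
    order = np.argsort(-t, kind="stable")
    ts = t[order]
    d_sorted = np.sort(d)
    n_t = np.arange(1, len(ts) + 1, dtype=float)
    n_d = len(d) - np.searchsorted(d_sorted, ts, side="left")
    # ties in target scores: every equal score shares the largest counts
    _, inv, counts = np.unique(-ts, return_inverse=True, return_counts=True)
    last_of_group = np.cumsum(counts) - 1
    fdr = (n_d / np.maximum(n_t, 1.0))[last_of_group][inv]
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, q <= threshold


# ---------------------------------------------------------------------------
# empirical plasma branch


class ReferenceCDF(BaseEstimator, TransformerMixin):
    """Laplace-smoothed empirical CDF of plasma reference log2 intensities.

    ``transform`` maps a query log2 intensity to the plasma probability
    PDi = (#{reference <= query} + 1) / (n + 2), strictly inside (0, 1):
    a query below every reference value scores 1/(n+2), never 0, and a
    query at or above the maximum scores (n+1)/(n+2), never 1.
    """

    def __init__(self):
        pass

    def fit(self, reference: Union[ReferenceIntensities, Sequence[float]], y=None):
        if isinstance(reference, ReferenceIntensities):
            values = reference.log2_intensities
            self.accessions_ = reference.accessions
        else:
            values = np.asarray(list(reference), dtype=float)
            self.accessions_ = frozenset()
        if len(values) == 0:
            raise ValueError("empty reference")
        self.reference_ = np.sort(values)
        return self

    def transform(self, query_log2):
        scalar = np.isscalar(query_log2)
        q = np.atleast_1d(np.asarray(query_log2, dtype=float))
        n = len(self.reference_)
        k = np.searchsorted(self.reference_, q, side="right")
        pdi = (k + 1.0) / (n + 2.0)
        return float(pdi[0]) if scalar else pdi

    __call__ = transform


def plasma_probability(query_log2, ref) -> Union[float, np.ndarray]:
    """PDi of a query log2 intensity under a plasma reference CDF."""
    if not isinstance(ref, ReferenceCDF):
        ref = ReferenceCDF().fit(ref)
    return ref.transform(query_log2)


def empirical_score(rank1, n_total, pdi, rank_weight: float = 0.5):
    """Transfer credibility score from Rank1, N and PDi.

    ``rank1`` is the ascending-intensity rank of the protein's MS1
    intensity Ii within its run (1..N). With the default equal weights the
    score is (Rank1/N + PDi) / 2, in (0, 1], monotone in intensity (via
    the rank) and in plasma probability.
    """
    rank1 = np.asarray(rank1, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if np.any(n_total <= 0):
        raise ValueError("N must be positive")
    if np.any((rank1 < 1) | (rank1 > n_total)):
        raise ValueError("Rank1 must lie in [1, N]")
    pdi = np.asarray(pdi, dtype=float)
    if np.any((pdi <= 0) | (pdi >= 1)):
        raise ValueError("PDi must lie strictly in (0, 1)")
    return rank_weight * (rank1 / n_total) + (1.0 - rank_weight) * pdi


def make_simulated_decoys(target_log2_intensities, n_decoys: Optional[int] = None,
                          seed: int = 0) -> np.ndarray:
    """Decoy log2 intensities from a Gaussian fitted to the targets.

    The decoy population mimics the distribution of the transferred
    proteins' MS1 intensities; decoy accessions are by construction absent
    from the plasma reference set. Defaults to as many decoys as targets.
    """
    t = np.asarray(target_log2_intensities, dtype=float)
    if len(t) < 10:
        raise ValueError("need >= 10 target records to fit the decoy distribution")
    sd = t.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate target intensity distribution (SD = 0)")
    if n_decoys is None:
        n_decoys = len(t)
    rng = np.random.default_rng(seed)
    return rng.normal(t.mean(), sd, size=int(n_decoys))


# ---------------------------------------------------------------------------
# estimators


class LinearityFDR(BaseEstimator):
    """Dilution-linearity target-decoy FDR (R² score, shuffled decoys).

    Parameters
    ----------
    amounts : loaded amounts in ng, one per matrix column.
    fdr_threshold : acceptance threshold on the q-value (default 0.05).
    seed : seed of the decoy shuffle.

    After ``fit(X)`` on a proteins x dilutions log2 matrix:

    results_ : per-protein slope/intercept/r2/qvalue/accepted (+is_decoy=False)
    decoy_results_ : the same for the shuffled decoy matrix
    unscored_ : index of proteins with < 3 finite points
    """

    def __init__(self, amounts=(1000.0, 500.0, 200.0, 100.0, 40.0, 20.0, 10.0),
                 fdr_threshold: float = 0.05, seed: int = 0):
        self.amounts = amounts
        self.fdr_threshold = fdr_threshold
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        target = fit_linearity(X, self.amounts)
        decoy = fit_linearity(make_shuffle_decoys(X, seed=self.seed), self.amounts)
        scored = target["r2"].notna()
        d_scored = decoy["r2"].notna()
        q, acc = target_decoy_fdr(
            target.loc[scored, "r2"], decoy.loc[d_scored, "r2"], self.fdr_threshold
        )
        target["is_decoy"] = False
        decoy["is_decoy"] = True
        target["qvalue"] = np.nan
        target.loc[scored, "qvalue"] = q
        target["accepted"] = False
        target.loc[scored, "accepted"] = acc
        self.results_ = target
        self.decoy_results_ = decoy
        self.unscored_ = target.index[~scored]
        return self


class EmpiricalTransferFDR(BaseEstimator):
    """Empirical-score target-decoy FDR for plasma transfers.

    ``fit(intensities, reference)`` takes linear-scale MS1 intensities of
    candidate transfers (one run/sample) and a plasma reference
    (:class:`ReferenceCDF`, :class:`~wimt.io.ReferenceIntensities` or raw
    log2 values). Decoy intensities are Gaussian draws matched to the
    target log2 distribution, ranked against the target run, and scored
    through the same path.

    results_ : DataFrame with Ii, rank1, pdi, score, qvalue, accepted.
    """

    def __init__(self, fdr_threshold: float = 0.05, rank_weight: float = 0.5,
                 n_decoys: Optional[int] = None, seed: int = 0):
        self.fdr_threshold = fdr_threshold
        self.rank_weight = rank_weight
        self.n_decoys = n_decoys
        self.seed = seed

    def fit(self, intensities, reference, y=None):
        ii = np.asarray(intensities, dtype=float)
        if np.any(ii <= 0):
            raise ValueError("intensities must be positive")
        n = len(ii)
        ref = reference if isinstance(reference, ReferenceCDF) else ReferenceCDF().fit(reference)
        log2_ii = np.log2(ii)
        # ascending-intensity rank, ties stable by input order
        rank1 = np.empty(n, dtype=int)
        rank1[np.argsort(log2_ii, kind="stable")] = np.arange(1, n + 1)
        pdi = ref.transform(log2_ii)
        scores = empirical_score(rank1, n, pdi, self.rank_weight)

        decoy_log2 = make_simulated_decoys(log2_ii, self.n_decoys, self.seed)
        sorted_t = np.sort(log2_ii)
        d_rank = np.clip(np.searchsorted(sorted_t, decoy_log2, side="right"), 1, n)
        d_pdi = ref.transform(decoy_log2)
        decoy_scores = empirical_score(d_rank, n, d_pdi, self.rank_weight)

        q, acc = target_decoy_fdr(scores, decoy_scores, self.fdr_threshold)
        self.results_ = pd.DataFrame(
            {
                "Ii": ii,
                "rank1": rank1,
                "pdi": pdi,
                "score": scores,
                "qvalue": q,
                "accepted": acc,
            }
        )
        self.decoy_scores_ = decoy_scores
        self.reference_ = ref
        return self
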