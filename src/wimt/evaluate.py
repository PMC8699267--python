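"""Desk-scale end-to-end evaluations of the transfer method on synthetic data.

Each function runs one replicate of a validation experiment from scratch --
generate data with known ground truth, run the method, measure the outcome:

* :func:`dilution_linearity_R` -- the 7-point dilution series through the
  full align/link/transfer/rollup pipeline; returns the Pearson R of
  per-dilution medians of log2 protein intensity against log2 amount.
* :func:`linearity_fdp` -- realized false-discovery proportion of the
  dilution-linearity target-decoy procedure at q <= 0.05 on a matrix of
  truly linear plus profile-shuffled (non-linear) proteins.
* :func:`empirical_fdp` -- realized FDP of the empirical plasma-score
  target-decoy procedure on a cohort with spiked absent-protein false
  transfers.
"""

from __future__ import annotations

import numpy as np

from .fdr import EmpiricalTransferFDR, LinearityFDR, ReferenceCDF
from .io import TransferConfig
from .qc import dilution_median_linearity
from .simulate import (
    SimParams,
    simulate_dilution_series,
    simulate_plasma_cohort,
    true_protein_matrix,
)
from .workflow import per_dilution_log2, transfer_quantify

__all__ = ["dilution_linearity_R", "linearity_fdp", "empirical_fdp"]


def _run_amounts(columns):
    return {r: float(r.split("_")[0][3:]) for r in columns}


def dilution_linearity_R(seed: int, n_proteins: int = 500,
                         noise_sigma_ln: float = 0.08) -> float:
    """Median-regression linearity after full MS1 transfer (one seed)."""
    params = SimParams(n_proteins=n_proteins, noise_sigma_ln=noise_sigma_ln,
                       frac_nonlinear=0.0, seed=seed)
    sim = simulate_dilution_series(params)
    matrix, _, _ = transfer_quantify(sim.features, sim.ids, sim.run_levels,
                                     TransferConfig(seed=seed))
    run_amounts = _run_amounts(matrix.columns)
    per_dil = per_dilution_log2(matrix, run_amounts)
    amounts = sorted(set(run_amounts.values()), reverse=True)
    r, _, _ = dilution_median_linearity(per_dil, amounts)
    return float(r)


def linearity_fdp(seed: int, n_proteins: int = 1250,
                  frac_nonlinear: float = 0.2, threshold: float = 0.05) -> float:
    """Realized FDP of the R2 target-decoy procedure (one seed)."""
    params = SimParams(n_proteins=n_proteins, frac_nonlinear=frac_nonlinear, seed=seed)
    sim = simulate_dilution_series(params)
    matrix = true_protein_matrix(sim)
    per_dil = per_dilution_log2(2.0 ** matrix, _run_amounts(matrix.columns))
    est = LinearityFDR(amounts=per_dil.columns.to_list(),
                       fdr_threshold=threshold, seed=seed).fit(per_dil)
    res = est.results_.join(sim.truth.set_index("protein")["is_linear"])
    accepted = res[res["accepted"]]
    if len(accepted) == 0:
        return 0.0
    return float((~accepted["is_linear"].astype(bool)).mean())


def empirical_fdp(seed: int, n_proteins: int = 300, n_samples: int = 10,
                  frac_absent: float = 0.15, threshold: float = 0.05):
    """Realized FDP of the empirical-score procedure (one seed).

    Returns ``(fdp, n_accepted)``; the reference CDF is built from the
    ground-truth abundances of the proteins genuinely present in plasma.
    """
    params = SimParams(n_proteins=n_proteins, frac_absent=frac_absent, seed=seed)
    sim = simulate_plasma_cohort(params, n_samples=n_samples)
    truth = sim.truth.set_index("protein")
    present = truth["true_transfer"].astype(bool)
    ref = ReferenceCDF().fit(truth.loc[present, "true_log2_abundance"].to_numpy())
    n_accepted, n_false = 0, 0
    for s, grp in sim.candidates.groupby("sample"):
        est = EmpiricalTransferFDR(fdr_threshold=threshold,
                                   seed=seed * 131 + int(s)).fit(
            grp["intensity"].to_numpy(), ref
        )
        acc = est.results_["accepted"].to_numpy()
        n_accepted += int(acc.sum())
        n_false += int((acc & ~grp["true_transfer"].to_numpy()).sum())
    fdp = n_false / n_accepted if n_accepted else 0.0
    return float(fdp), n_accepted
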