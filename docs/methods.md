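# Methods

This note documents the models, numerical choices and known limitations of
`wimt`: what the algorithms assume, what the synthetic data does and does
not emulate, and where the design was genuinely open and a choice had to
be made. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The transfer model

MS1 identification transfer assumes that the same peptide precursor,
measured in two LC-MS runs on the same chromatographic setup, appears at
(i) the same m/z up to instrument mass error of a few ppm and (ii) the
same retention time up to a smooth, slowly varying drift of at most a few
minutes. Under these assumptions an MS2 identification made in one run
(here: an immunodepleted plasma run, where low-abundance precursors are
intense enough to be fragmented) can be assigned to the matching MS1
feature of another run (undepleted plasma) without new fragmentation
evidence.

### Retention-time alignment (`RTAligner`)

* **Anchors** are mutually-nearest feature pairs within `align_ppm`
  (default 10 ppm) in m/z and `max_rt_shift` (default 3 min) in RT, with
  S/N ≥ `min_snr` (default 5) on both sides. Mutual nearestness
  (lexicographic: ppm first, RT second) suppresses spurious pairs without
  needing identities.
* **Warp** = LOWESS smooth of anchor RT offsets. The span is adaptive,
  ~20 anchors per window (clipped to [0.03, 0.67] of the data), which
  tracks smooth drift with low bias while two robustness iterations
  down-weight stray mismatched anchors. The smoothed offset curve is
  evaluated on a 512-point grid, clipped to ±`max_rt_shift`, made strictly
  monotone (cumulative maximum plus an infinitesimal ramp), and tapers
  linearly to the identity over a 2·`max_rt_shift` margin outside the
  anchor range — far from any anchor the warp is the identity, as nothing
  supports a correction there.
* Fewer than 5 anchors is an error (`insufficient anchors`), not a silent
  identity warp.

### Feature linking (`FeatureLinker`)

Consensus features are seeded by the reference run's features (S/N ≥ 5;
low-S/N features may join but never seed). Per non-reference run, all
(feature, seed) pairs within tolerance are accepted greedily in ascending
(ppm distance, warped-RT distance) lexicographic order; each feature joins
at most one consensus, each consensus holds at most one member per run.
On well-separated maps this greedy scheme coincides with minimum-total-
distance assignment (asserted against an exhaustive oracle on ≤5×5
instances); its behaviour under heavy ambiguity is a declared stand-in
for the closed-source feature mapper it reimplements, whose exact linking
rule is not published.

**"Auto" tolerances.** The published workflow sets linking tolerances to
"0 = default", i.e. delegates them to an opaque vendor default. Here
`auto` resolves to the 95th percentile of post-alignment anchor residuals,
floored at 5 ppm and 0.2 min. The floors matter: with a well-calibrated
instrument the residual quantiles are *smaller* than the floors, so the
effective windows sit at several sigma of the cross-run error and linking
recall is limited by the mass dimension (~2.4 sigma at 1.5 ppm error →
~98% recall), not by a quantile that would structurally cap recall at 95%.

### Identity transfer and rollup

A consensus carrying two distinct peptide identities raises an error
listing both; conflicts are never resolved by vote, preserving
auditability. Transfers inherit `source_level` = the least-depleted level
among the identified members. Protein intensity is the sum of member
peptide intensities on the linear scale (total intensity is conserved
exactly); shared (razor) peptides go wholly to the protein with the larger
total unique-peptide intensity, ties broken by accession order.

## 2. The two target–decoy FDR procedures

Both branches use the classical estimator FDR(s) = #{decoy ≥ s} /
#{target ≥ s} (no +1 in the numerator), q-values as the running minimum of
FDR over decreasing score cutoffs, and inclusive acceptance q ≤ 0.05
(the published description mixes "FDR < 0.05" and "threshold of 5%";
inclusive q ≤ 0.05 is used consistently).

### Linearity branch

Per-protein OLS of log2 intensity on log2 loaded amount; R² is the score;
proteins with < 3 finite dilution points are unscored and reported
separately. A zero-variance response is scored R² = 0 (no linear signal).
Decoys permute intensities across proteins *within each dilution column
independently* — this destroys every protein's dilution profile while
preserving per-column intensity multisets exactly, which is the property
a linearity decoy must have. Permutations are re-drawn (≤ 100 times)
until no protein keeps its own row, then accepted. Note the decoys retain
the *common* dilution trend (each column is still scaled by its amount),
which makes them harder than independently-drawn profiles and the FDR
estimate correspondingly conservative.

### Empirical plasma branch

Score = `w·Rank1/N + (1−w)·PDi` with `w = 0.5`. `Rank1` is the ascending
intensity rank in the run, `PDi = (#{ref ≤ x}+1)/(n+2)` the
Laplace-smoothed empirical CDF of reference plasma log2 intensities
(never exactly 0 or 1). The published score combines exactly these three
ingredients (intensity, rank, plasma probability) but its literal
functional form is in an appendix that the available text does not
reproduce; the implemented equal-weight average is a **declared
surrogate**: it uses exactly the named ingredients, is monotone in each,
and the weight is configurable (`rank_weight`).

Decoys draw log2 intensities from a Gaussian fitted to the target log2
intensities (a lognormal on the linear scale, matching the lognormal
error premise of the quantification), are ranked against the target run
and scored through the same path.

**Conservatism.** Because the decoy population is distribution-matched to
the targets and the score is a monotone function of intensity alone, the
estimated FDR approaches 1 wherever the target intensity distribution is
no heavier-tailed than its Gaussian fit. On the synthetic plasma cohort
(log-uniform abundances) the procedure therefore accepts essentially
nothing, and its realized false-discovery proportion is trivially ≈ 0 —
well under the nominal 5%, but with essentially zero power. This is an
honest property of the published decoy construction as described, not of
this implementation; detecting it requires exactly the ground-truth
simulation built here. Real-data acceptance presumably relied on the
appendix's (unavailable) score form giving plasma-reference members an
advantage decoy accessions cannot attain.

## 3. The synthetic data: what it emulates, what it does not

All generators are deterministic under a fixed seed; every feature is
traceable to its generating protein/peptide (`feature_truth`), which is
the ground truth real data lacks.

Shared measurement model: peptide intensity = expected · exp(N(0, σ_ln));
m/z = true · (1 + N(0, ppm_σ)·1e−6); RT = base RT + smooth per-run drift
(monotone PCHIP through 4 jittered knots, shrunk until the warp is
monotone). There is **no per-feature RT jitter**: the stated world has
RT error only through drift, so post-alignment RT residuals reflect warp
estimation error alone. `rt_drift_max` bounds the *relative* drift
between any two runs (each run draws within ±half), since it is the
relative shift that alignment must recover within the 3-min window.

Defaults, chosen a priori and then frozen:

| parameter | default | why |
|---|---|---|
| `noise_sigma_ln` | 0.08 | median lognormal CV ≈ 8%, inside the reported <10% band for technical replicates |
| `ppm_sigma` | 1.5 ppm | well-calibrated Orbitrap; cross-run mass error SD ≈ 2.1 ppm, ~2.4σ inside the 5 ppm tolerance floor |
| `rt_drift_max` | 2 min | "a few minutes" of drift, inside the 3-min anchor window |
| `amounts` | 1000…10 ng | the published dilution ladder |
| `depletion_removals` | 7, 14, 60 | top-7 / top-14 / SuperMix-scale removal counts |
| peptides/protein | uniform 1–10, Dirichlet intensity split | keeps protein rollup testable |
| `frac_absent` | 0.15 | spiked false-transfer fraction in the plasma design |

**Dilution design.** Linear proteins scale proportionally with amount
(3 orders of base abundance spread); "non-linear" proteins draw each
dilution level independently of amount (log-uniform over 2 orders). MS2
identities attach only to the reference run (largest amount, first
replicate), optionally top-N censored.

**Depletion design.** Plasma's composition is top-heavy, and this matters
mechanistically: a log-uniform proteome with pure rank-based top-N MS2
censoring makes the identified-protein count *level-invariant* (each
removed abundant protein frees about as many MS2 slots as the newly
entering marginal proteins consume), which contradicts the observed
growth of identifications with depletion depth. The generator therefore
(i) places an abundant tier of `max(removals)` species on a steep,
jittered log-spacing over 1e8–1e11 (the albumin/IgG analogue) above a
log-uniform 1e3–1e7 bulk (~8 orders in total), and (ii) grants MS2
identity only to features that are both within the top-N rank *and* above
an absolute intensity floor (the undepleted run's 0.7 intensity quantile)
— the detection limit that constant-total rescaling after depletion
progressively relieves. With these two ingredients the identified count
rises monotonically with depth (mean +12/+23/+91% over the three depleted
levels at n = 300, versus the reported +18/+40/+98%).

**Plasma cohort design.** Samples share one abundance vector (log-uniform
over ~6 orders) with per-sample lognormal perturbation (σ = 0.25);
technical duplicates differ only by measurement noise. A 15% "absent"
subset has **zero features** in every undepleted run — the cleanest
ground truth for false transfers. Since geometric linking essentially
never produces a spurious match at desk scale (the probability that an
unrelated feature falls inside a 5 ppm × 0.2 min window is ~1e−5), false
*candidate* transfers are spiked explicitly: each run also carries
low-intensity background noise features (log2 ~ N(12, 1.5)), and the
candidate table assigns every absent protein the intensity of a randomly
chosen background feature — emulating what match-between-runs would
erroneously integrate at the expected coordinates.

Not emulated: MS2 spectra, chromatographic peak shapes, isotope
envelopes, charge-state splitting, missing-value mechanisms beyond
censoring, biological (disease) effects. A green test on this generator
establishes correctness of the pipeline's statistics under the stated
error model, not robustness to pathologies the generator lacks.

## 4. Numerical choices and degenerate inputs

* Readers validate whole files and report every bad row by number; rows
  are never silently dropped. Floats are written at `%.10g`, so TSV
  round-trips are lossless well beyond 6 significant digits.
* OLS is computed from centered closed-form sums; R² is clipped to [0, 1].
* q-value ties share the most permissive count of their score group.
* `abundance_groups` sorts descending with accession tie-break and splits
  with larger groups first ([3,3,3,3,3,2,2,2,2,2] for 25 proteins in 10
  groups); fewer proteins than groups reduces the group count with a
  warning rather than creating empty groups.
* The lognormal CV uses the natural-log SD with n−1 denominator; log2
  inputs must be converted (s_ln = s_log2 · ln 2) before applying it.
* Replicate correlation is complete-case on proteins present in both
  replicates.
* Degenerate FDR inputs error loudly: empty score lists, single-protein
  shuffle, zero-variance decoy fit.

## 5. Open design points resolved here

* "Group" for the ≥1-valid-value normalization filter = depletion level.
* Protein identity is the accession string; isoform/sequence-level
  grouping (the "proteins" vs "protein sequences" distinction) is out of
  scope.
* The reference run defaults to the run with the most features; pipelines
  that know the identified run pass it explicitly.
* The per-level ANOVA with Tukey pairwise comparisons is a reporting
  convenience, not part of the transfer method.
* CV is computed across technical replicates within each condition and
  reported per condition (not across dilution points).
* Decoy count defaults to the target count in the empirical branch.

## 6. Known limitations

* The linking rule is near-optimal greedy, not globally optimal matching;
  under extreme feature density both it and the published workflow are
  unvalidated.
* The empirical-branch score is a surrogate (see §2); absolute acceptance
  counts from it should not be compared against the published cohort
  counts, which additionally depend on raw-data scale (~1300-protein
  database, thousands of features per run) not reproduced at desk scale.
* FDR control is demonstrated under the generator's error model;
  correlated noise across dilutions (e.g. shared LC batches) would erode
  the linearity branch's decoy validity.
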