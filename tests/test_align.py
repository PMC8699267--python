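"""RT alignment, feature linking, identity transfer and protein rollup."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wimt import (
    ConflictingIdentityError,
    DepletionLevel,
    InsufficientAnchorsError,
    SimParams,
    TransferConfig,
    estimate_rt_warp,
    link_features,
    rollup_protein_intensity,
    simulate_dilution_series,
    transfer_identifications,
    transfer_ratio,
)
from wimt.align import FeatureLinker, IdentityWarp
from wimt.workflow import align_and_link, split_runs

from conftest import make_feature_frame


def _grid_run(run_id, n=60, shift=0.0, drift=None, seed=0):
    rng = np.random.default_rng(seed)
    mz = np.sort(rng.uniform(400.0, 1400.0, n))
    rt = np.linspace(5.0, 90.0, n)
    if drift is not None:
        rt = rt + drift(rt)
    rt = rt + shift
    return make_feature_frame(
        [(run_id, f"f{i}", mz[i], rt[i], 2, 1e6, 50.0) for i in range(n)]
    )


class TestRTAligner:
    def test_identity_on_same_table(self):
        run = _grid_run("a")
        warp = estimate_rt_warp(run, run)
        t = np.linspace(5.0, 90.0, 200)
        assert np.max(np.abs(warp.transform(t) - t)) < 1e-6

    def test_constant_shift_recovery_within_0p05(self):
        ref = _grid_run("ref")
        tgt = _grid_run("tgt", shift=1.5)
        warp = estimate_rt_warp(tgt, ref)
        t = np.linspace(tgt.rt_min.min(), tgt.rt_min.max(), 300)
        assert np.max(np.abs(warp.transform(t) - (t - 1.5))) < 0.05

    def test_smooth_drift_recovery_within_0p05(self):
        ref = _grid_run("ref", n=300)
        drift = lambda t: 1.0 * np.sin(t / 20.0)
        tgt = _grid_run("tgt", n=300, drift=drift)
        warp = estimate_rt_warp(tgt, ref)
        # check at anchor RTs (the criterion's "anchor range")
        rt_t = warp.anchor_pairs_[:, 0]
        rt_r = warp.anchor_pairs_[:, 1]
        assert np.percentile(np.abs(warp.transform(rt_t) - rt_r), 100) < 0.05

    def test_pair_beyond_max_rt_shift_is_not_an_anchor(self):
        # the 3 min limit: a 3.2 min offset pair must never anchor
        ref = _grid_run("ref")
        tgt = _grid_run("tgt")
        outlier_ref = make_feature_frame([("ref", "x", 700.0005, 50.0, 2, 1e6, 50.0)])
        outlier_tgt = make_feature_frame([("tgt", "x", 700.0005, 53.2, 2, 1e6, 50.0)])
        warp = estimate_rt_warp(
            pd.concat([tgt, outlier_tgt], ignore_index=True),
            pd.concat([ref, outlier_ref], ignore_index=True),
        )
        d_rt = np.abs(warp.anchor_pairs_[:, 1] - warp.anchor_pairs_[:, 0])
        assert np.all(d_rt <= 3.0)

    def test_insufficient_anchors_error_carries_count(self):
        ref = make_feature_frame([("r", "f0", 500.0, 10.0, 2, 1e6, 50.0)])
        tgt = make_feature_frame([("t", "f0", 900.0, 10.0, 2, 1e6, 50.0)])
        with pytest.raises(InsufficientAnchorsError, match="insufficient anchors"):
            estimate_rt_warp(tgt, ref)

    def test_warp_monotone_and_bounded(self, small_dilution):
        runs = split_runs(small_dilution.features)
        cfg = TransferConfig()
        ref = runs["dil1000_r1"]
        for rid in ("dil10_r1", "dil40_r2", "dil500_r3"):
            warp = estimate_rt_warp(runs[rid], ref, cfg)
            t = np.linspace(0.0, 100.0, 2000)
            w = warp.transform(t)
            assert np.all(np.diff(w) > 0)
            assert np.max(np.abs(w - t)) <= cfg.max_rt_shift + 1e-9


class TestFeatureLinker:
    def _link(self, runs, ppm=10.0, rt_tol=0.2):
        ref = sorted(runs)[0]
        warps = {r: IdentityWarp() for r in runs if r != ref}
        return FeatureLinker(ppm=ppm, rt_tol=rt_tol).fit(runs, ref, warps).result_

    def test_identical_single_features_link(self):
        runs = {
            "a": make_feature_frame([("a", "f0", 500.0, 10.0, 2, 1e6, 50.0)]),
            "b": make_feature_frame([("b", "f0", 500.0, 10.0, 2, 2e6, 50.0)]),
        }
        link = self._link(runs)
        assert len(link.consensus) == 1
        assert link.consensus["n_members"].iloc[0] == 2
        np.testing.assert_allclose(link.consensus["mz_consensus"], 500.0)

    def test_16ppm_apart_not_linked_at_10ppm(self):
        runs = {
            "a": make_feature_frame([("a", "f0", 500.0000, 10.0, 2, 1e6, 50.0)]),
            "b": make_feature_frame([("b", "f0", 500.0080, 10.0, 2, 1e6, 50.0)]),
        }
        link = self._link(runs, ppm=10.0)
        assert (link.consensus["n_members"] == 1).all()

    def test_low_snr_cannot_seed(self):
        runs = {
            "a": make_feature_frame([("a", "f0", 500.0, 10.0, 2, 1e6, 2.0)]),
            "b": make_feature_frame([("b", "f0", 500.0, 10.0, 2, 1e6, 50.0)]),
        }
        link = self._link(runs)
        assert len(link.consensus) == 0

    def test_matches_exhaustive_min_distance_on_small_grids(self):
        # 30 random <=5x5 instances: separation >> jitter keeps the optimum
        # unique, where greedy lexicographic linking must equal brute force
        rng = np.random.default_rng(99)
        for trial in range(30):
            n = int(rng.integers(2, 6))
            base_mz = 500.0 * (1 + 8e-6 * np.arange(n))  # 8 ppm spacing
            base_rt = 10.0 + 2.0 * np.arange(n)
            jit = lambda: rng.normal(0.0, 1e-6, n)  # ~1 ppm mass jitter
            a = make_feature_frame(
                [("a", f"a{i}", base_mz[i] * (1 + jit()[i]), base_rt[i], 2, 1e6, 50.0)
                 for i in range(n)]
            )
            b = make_feature_frame(
                [("b", f"b{i}", base_mz[i] * (1 + jit()[i]), base_rt[i] + rng.normal(0, 0.02),
                  2, 1e6, 50.0) for i in range(n)]
            )
            link = self._link({"a": a, "b": b}, ppm=10.0, rt_tol=0.5)
            got = {
                tuple(sorted(zip(g["run_id"], g["feature_id"])))
                for _, g in link.members.groupby("consensus_id") if len(g) == 2
            }
            # brute force: min total ppm distance over complete matchings
            best, best_cost = None, np.inf
            for perm in itertools.permutations(range(n)):
                cost, feasible = 0.0, True
                for i, j in enumerate(perm):
                    dppm = abs(a.mz[i] - b.mz[j]) / a.mz[i] * 1e6
                    if dppm > 10.0 or abs(a.rt_min[i] - b.rt_min[j]) > 0.5:
                        feasible = False
                        break
                    cost += dppm
                if feasible and cost < best_cost:
                    best, best_cost = perm, cost
            expect = {
                tuple(sorted([("a", f"a{i}"), ("b", f"b{j}")]))
                for i, j in enumerate(best)
            }
            assert got == expect, f"trial {trial}"

    def test_no_feature_in_two_consensus(self, small_dilution):
        link = align_and_link(split_runs(small_dilution.features), TransferConfig(),
                              reference="dil1000_r1")
        assert not link.members.duplicated(["run_id", "feature_id"]).any()
        assert (link.members.groupby(["consensus_id", "run_id"]).size() == 1).all()

    def test_linking_recall_and_precision(self, small_dilution):
        sim = small_dilution
        runs = split_runs(sim.features)
        ref = "dil1000_r1"
        link = align_and_link(runs, TransferConfig(), reference=ref)
        m = link.members.merge(sim.feature_truth, on=["run_id", "feature_id"])
        ref_pep = m[m.run_id == ref].set_index("consensus_id")["peptide"]
        m["true_pep"] = m["consensus_id"].map(ref_pep)
        nonref = m[m.run_id != ref]
        correct = (nonref["peptide"] == nonref["true_pep"]).sum()
        precision = correct / len(nonref)
        seeded = set(
            sim.feature_truth[sim.feature_truth.run_id == ref]
            .merge(runs[ref][runs[ref].snr >= 5], on=["run_id", "feature_id"])["peptide"]
        )
        linkable = sim.feature_truth[
            (sim.feature_truth.run_id != ref) & sim.feature_truth.peptide.isin(seeded)
        ]
        recall = correct / len(linkable)
        assert precision >= 0.95
        assert recall >= 0.95

    def test_missing_warp_raises(self):
        runs = {
            "a": make_feature_frame([("a", "f0", 500.0, 10.0, 2, 1e6, 50.0)]),
            "b": make_feature_frame([("b", "f0", 500.0, 10.0, 2, 1e6, 50.0)]),
        }
        with pytest.raises(ValueError, match="missing RT warp"):
            FeatureLinker(ppm=10, rt_tol=0.2).fit(runs, "a", {})


def _id_row(run_id, psm, pep, mz, rt, protein):
    return (run_id, psm, pep, 2, mz, rt, (protein,), 0.001)


def _ids_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["run_id", "psm_id", "peptide", "charge", "mz", "rt_min", "proteins", "qvalue"],
    )


class TestTransfer:
    def _two_run_setup(self, n_transfer=20, n_native=5):
        n = n_transfer + n_native
        mz = 500.0 + 10.0 * np.arange(n)
        rt = 5.0 + 3.0 * np.arange(n)
        dep = make_feature_frame(
            [("dep", f"f{i}", mz[i], rt[i], 2, 1e6, 50.0) for i in range(n)]
        )
        und = make_feature_frame(
            [("und", f"f{i}", mz[i], rt[i], 2, 5e5, 50.0) for i in range(n)]
        )
        ids = [_id_row("dep", f"p{i}", f"PEP{i}K", mz[i], rt[i], f"P{i:03d}") for i in range(n)]
        ids += [
            _id_row("und", f"q{i}", f"PEP{i}K", mz[i], rt[i], f"P{i:03d}")
            for i in range(n_native)
        ]
        runs = {"dep": dep, "und": und}
        levels = {"dep": DepletionLevel.DEEP_DEP, "und": DepletionLevel.UNDEPLETED}
        link = FeatureLinker(ppm=10, rt_tol=0.2).fit(runs, "dep", {"und": IdentityWarp()}).result_
        return runs, levels, link, _ids_frame(ids)

    def test_counts_transfers_vs_natives(self):
        runs, levels, link, ids = self._two_run_setup()
        rec = transfer_identifications(link, ids, levels, runs)
        und = rec[rec.run_id == "und"]
        assert int((~und.native).sum()) == 20
        assert int(und.native.sum()) == 5
        transfers = und[~und.native]
        assert (transfers.source_level == int(DepletionLevel.DEEP_DEP)).all()

    def test_native_only_yields_no_transfers(self):
        runs, levels, link, ids = self._two_run_setup(n_transfer=0, n_native=5)
        rec = transfer_identifications(link, ids, levels, runs)
        assert (~rec.native).sum() == 0

    def test_conflicting_identities_raise(self):
        runs, levels, link, ids = self._two_run_setup(n_transfer=2, n_native=0)
        bad = _ids_frame(
            [_id_row("und", "qx", "OTHERK", ids.mz.iloc[0], ids.rt_min.iloc[0], "PX")]
        )
        with pytest.raises(ConflictingIdentityError, match="conflicting"):
            transfer_identifications(link, pd.concat([ids, bad], ignore_index=True),
                                     levels, runs)


class TestRollup:
    def test_single_and_pair_sums(self):
        df = pd.DataFrame(
            {
                "run_id": ["r"] * 3,
                "peptide": ["A", "B", "C"],
                "protein": ["P1", "P2", "P2"],
                "intensity": [1000.0, 100.0, 200.0],
            }
        )
        out = rollup_protein_intensity(df)
        assert out.loc["P1", "r"] == 1000.0
        assert out.loc["P2", "r"] == 300.0

    def test_razor_peptide_assignment(self):
        df = pd.DataFrame(
            {
                "run_id": ["r"] * 4,
                "peptide": ["u1", "u2", "shared", "u3"],
                "proteins": [("P1",), ("P2",), ("P1", "P2"), ("P2",)],
                "intensity": [100.0, 400.0, 50.0, 200.0],
            }
        )
        out = rollup_protein_intensity(df)
        # P2 unique total 600 > P1's 100, so the shared peptide goes to P2
        assert out.loc["P1", "r"] == 100.0
        assert out.loc["P2", "r"] == 650.0

    def test_conservation_on_fixture(self, rng):
        n = 300
        df = pd.DataFrame(
            {
                "run_id": rng.choice(["r1", "r2"], n),
                "peptide": [f"pep{i}" for i in range(n)],
                "protein": rng.choice([f"P{j}" for j in range(50)], n),
                "intensity": rng.uniform(1.0, 1e6, n),
            }
        )
        out = rollup_protein_intensity(df)
        np.testing.assert_allclose(out.sum().sum(), df.intensity.sum(), rtol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            rollup_protein_intensity(pd.DataFrame(columns=["run_id", "peptide", "intensity"]))


class TestTransferRatio:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["protein", "run_id", "native", "accepted"]
        )

    def test_fractions_and_missing_level(self):
        db = {
            DepletionLevel.LOW_DEP: {f"P{i}" for i in range(10)},
            DepletionLevel.MID_DEP: {"P0", "P1"},
            DepletionLevel.DEEP_DEP: set(),
        }
        rec = self._records(
            [(f"P{i}", "und", False, True) for i in range(8)]
            + [("P0", "und", True, False)]
        )
        levels = {"und": DepletionLevel.UNDEPLETED}
        out = transfer_ratio(db, rec, levels)
        assert out[DepletionLevel.LOW_DEP] == pytest.approx(0.8)
        assert out[DepletionLevel.MID_DEP] == pytest.approx(1.0)
        assert np.isnan(out[DepletionLevel.DEEP_DEP])

    def test_all_transferred(self):
        db = {DepletionLevel.LOW_DEP: {"A", "B"}}
        rec = self._records([("A", "und", False, True), ("B", "und", True, False)])
        out = transfer_ratio(db, rec, {"und": DepletionLevel.UNDEPLETED})
        assert out[DepletionLevel.LOW_DEP] == 1.0

    def test_unaccepted_transfers_do_not_count(self):
        db = {DepletionLevel.LOW_DEP: {"A"}}
        rec = self._records([("A", "und", False, False)])
        out = transfer_ratio(db, rec, {"und": DepletionLevel.UNDEPLETED})
        assert out[DepletionLevel.LOW_DEP] == 0.0
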