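import numpy as np
import pandas as pd
import pytest
from scipy import stats

import roicrosstalk as rc
from roicrosstalk import core_model as cm
from roicrosstalk import crosstalk

from conftest import make_annotation


def log2_expr(arr, genes=None, rois=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    rois = rois or [f"r{j}" for j in range(arr.shape[1])]
    return cm.ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=rois), "log2")


def prior_from(rows):
    return cm.LigandTargetPrior(pd.DataFrame(rows, columns=["ligand", "target", "weight"]))


class TestBuildPairs:
    def test_three_single_roi_cores(self, rng):
        annot = make_annotation(
            [(f"t{i}", f"c{i}", "tumour") for i in range(3)]
            + [(f"s{i}", f"c{i}", "stroma") for i in range(3)]
        )
        arr = rng.normal(5, 1, size=(8, 6))
        expr = log2_expr(arr, rois=["t0", "t1", "t2", "s0", "s1", "s2"])
        pairs = crosstalk.build_pairs(annot, expr, "stroma", "tumour")
        assert pairs.n_pairs == 3
        np.testing.assert_allclose(pairs.sender["c1"], arr[:, 4])
        np.testing.assert_allclose(pairs.receiver["c1"], arr[:, 1])

    def test_multi_roi_core_mean(self):
        annot = make_annotation(
            [("t0", "c0", "tumour"), ("s0a", "c0", "stroma"), ("s0b", "c0", "stroma")]
            + [(f"t{i}", f"c{i}", "tumour") for i in (1, 2)]
            + [(f"s{i}", f"c{i}", "stroma") for i in (1, 2)]
        )
        arr = np.ones((1, 7)) * 5.0
        rois = ["t0", "s0a", "s0b", "t1", "t2", "s1", "s2"]
        arr[0, 1] = 2.0  # s0a
        arr[0, 2] = 4.0  # s0b
        expr = log2_expr(arr, genes=["g"], rois=rois)
        pairs = crosstalk.build_pairs(annot, expr, "stroma", "tumour")
        assert pairs.sender.loc["g", "c0"] == pytest.approx(3.0)

    def test_core_missing_compartment_skipped(self, rng):
        rows = []
        for i in range(5):
            rows.append((f"t{i}", f"c{i}", "tumour"))
            if i != 3:  # c3 lacks stroma
                rows.append((f"s{i}", f"c{i}", "stroma"))
        annot = make_annotation(rows)
        expr = log2_expr(rng.normal(size=(4, 9)), rois=[r[0] for r in rows])
        pairs = crosstalk.build_pairs(annot, expr, "stroma", "tumour")
        assert pairs.n_pairs == 4
        assert pairs.skipped_cores == ["c3"]

    def test_sender_equals_receiver_identical_profiles(self, rng):
        annot = make_annotation([(f"s{i}", f"c{i}", "stroma") for i in range(4)])
        expr = log2_expr(rng.normal(size=(5, 4)), rois=[f"s{i}" for i in range(4)])
        pairs = crosstalk.build_pairs(annot, expr, "stroma", "stroma")
        pd.testing.assert_frame_equal(pairs.sender, pairs.receiver)

    def test_too_few_pairs_raises(self, rng):
        annot = make_annotation(
            [("t0", "c0", "tumour"), ("s0", "c0", "stroma"), ("t1", "c1", "tumour")]
        )
        expr = log2_expr(rng.normal(size=(3, 3)), rois=["t0", "s0", "t1"])
        with pytest.raises(cm.ValidationError, match="at least 3"):
            crosstalk.build_pairs(annot, expr, "stroma", "tumour")

    def test_bad_compartment_rejected(self, rng):
        annot = make_annotation([("t0", "c0", "tumour")])
        expr = log2_expr(rng.normal(size=(2, 1)), rois=["t0"])
        with pytest.raises(cm.ValidationError, match="closed set"):
            crosstalk.build_pairs(annot, expr, "epithelium", "tumour")


class TestRestrictPrior:
    def test_missing_target_dropped(self):
        prior = prior_from(
            [("L", "A", 0.5), ("L", "B", 0.4), ("L", "C", 0.3)]
        )
        cfg = crosstalk.CrosstalkConfig(min_targets_present=2)
        out = crosstalk.restrict_prior(prior, {"L", "A", "B"}, cfg)
        assert sorted(out.data["target"]) == ["A", "B"]

    def test_ligand_below_min_targets_dropped(self):
        rows = [("L1", f"T{i}", 0.5) for i in range(4)] + [
            ("L2", f"T{i}", 0.5) for i in range(6)
        ]
        prior = prior_from(rows)
        genes = {"L1", "L2"} | {f"T{i}" for i in range(6)}
        out = crosstalk.restrict_prior(prior, genes, crosstalk.CrosstalkConfig(min_targets_present=5))
        assert set(out.data["ligand"]) == {"L2"}

    def test_top_k_by_weight_with_sort_oracle(self, rng):
        weights = rng.uniform(size=300)
        rows = [("L", f"T{i:03d}", w) for i, w in enumerate(weights)]
        prior = prior_from(rows)
        genes = {"L"} | {f"T{i:03d}" for i in range(300)}
        cfg = crosstalk.CrosstalkConfig(top_k_targets_per_ligand=200)
        out = crosstalk.restrict_prior(prior, genes, cfg)
        assert len(out.data) == 200
        # independent sort oracle (ties broken by target symbol)
        order = sorted(rows, key=lambda r: (-r[2], r[1]))[:200]
        assert sorted(out.data["target"]) == sorted(t for _, t, _ in order)

    def test_empty_result_rejected(self):
        prior = prior_from([("L", "T", 0.5)])
        with pytest.raises(cm.ValidationError, match="no ligand"):
            crosstalk.restrict_prior(prior, {"X"}, crosstalk.CrosstalkConfig())


def build_test_pairs(sender_arr, receiver_arr, genes):
    n = sender_arr.shape[1]
    cores = [f"c{i}" for i in range(n)]
    return crosstalk.RoiPairing(
        sender_compartment="stroma",
        receiver_compartment="tumour",
        core_ids=cores,
        sender=pd.DataFrame(sender_arr, index=genes, columns=cores),
        receiver=pd.DataFrame(receiver_arr, index=genes, columns=cores),
    )


class TestLigandActivity:
    def test_perfect_coupling_activity_one(self):
        genes = ["L", "T1", "T2"]
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sender = np.vstack([x, np.zeros(5), np.zeros(5)])
        receiver = np.vstack([np.zeros(5), x, 2 * x + 1])
        pairs = build_test_pairs(sender, receiver, genes)
        prior = prior_from([("L", "T1", 1.0), ("L", "T2", 1.0)])
        cfg = crosstalk.CrosstalkConfig(min_targets_present=2)
        (res,) = crosstalk.ligand_activity(pairs, prior, cfg)
        assert res.activity == pytest.approx(1.0)
        assert res.active

    def test_constant_ligand_not_evaluable(self, rng):
        genes = ["L", "T1", "T2"]
        sender = np.vstack([np.full(5, 3.0), rng.normal(size=(2, 5))])
        receiver = rng.normal(size=(3, 5))
        pairs = build_test_pairs(sender, receiver, genes)
        prior = prior_from([("L", "T1", 1.0), ("L", "T2", 1.0)])
        cfg = crosstalk.CrosstalkConfig(min_targets_present=2)
        (res,) = crosstalk.ligand_activity(pairs, prior, cfg)
        assert not res.evaluable
        assert res.activity is None
        assert not res.active

    def test_five_pair_hand_matrix_oracle(self):
        # brute-force oracle: scipy.stats.pearsonr per target, arithmetic mean
        genes = ["L", "T1", "T2", "T3"]
        sender = np.array(
            [
                [2.0, 4.0, 3.0, 7.0, 5.0],
                [0, 0, 0, 0, 0],
                [0, 0, 0, 0, 0],
                [0, 0, 0, 0, 0],
            ]
        )
        receiver = np.array(
            [
                [0, 0, 0, 0, 0],
                [1.0, 3.0, 2.0, 6.0, 4.5],
                [5.0, 1.0, 4.0, 2.0, 3.0],
                [2.2, 2.9, 2.4, 3.3, 3.0],
            ]
        )
        pairs = build_test_pairs(sender, receiver, genes)
        prior = prior_from([("L", "T1", 1.0), ("L", "T2", 0.8), ("L", "T3", 0.5)])
        cfg = crosstalk.CrosstalkConfig(min_targets_present=2)
        (res,) = crosstalk.ligand_activity(pairs, prior, cfg)
        expected = np.mean(
            [stats.pearsonr(sender[0], receiver[i]).statistic for i in (1, 2, 3)]
        )
        assert res.activity == pytest.approx(expected, abs=1e-12)
        assert res.target_r["T2"] == pytest.approx(
            stats.pearsonr(sender[0], receiver[2]).statistic, abs=1e-12
        )

    def test_zero_variance_target_skipped_and_counted(self, rng):
        genes = ["L", "T1", "T2"]
        sender = rng.normal(size=(3, 6))
        receiver = rng.normal(size=(3, 6))
        receiver[2] = 4.0  # constant target
        pairs = build_test_pairs(sender, receiver, genes)
        prior = prior_from([("L", "T1", 1.0), ("L", "T2", 1.0)])
        cfg = crosstalk.CrosstalkConfig(min_targets_present=2)
        (res,) = crosstalk.ligand_activity(pairs, prior, cfg)
        assert res.n_targets_used == 1
        assert res.n_targets_skipped == 1

    def test_affine_invariance(self, rng):
        genes = [f"g{i}" for i in range(6)]
        sender = rng.normal(size=(6, 8))
        receiver = rng.normal(size=(6, 8))
        prior = prior_from([("g0", f"g{i}", 1.0) for i in range(1, 6)])
        cfg = crosstalk.CrosstalkConfig(min_targets_present=2)
        (base,) = crosstalk.ligand_activity(build_test_pairs(sender, receiver, genes), prior, cfg)
        (scaled,) = crosstalk.ligand_activity(
            build_test_pairs(2.5 * sender + 1.0, 0.3 * receiver - 4.0, genes), prior, cfg
        )
        assert scaled.activity == pytest.approx(base.activity, abs=1e-12)

    def test_pair_permutation_invariance(self, rng):
        genes = [f"g{i}" for i in range(5)]
        sender = rng.normal(size=(5, 10))
        receiver = rng.normal(size=(5, 10))
        prior = prior_from([("g0", f"g{i}", 1.0) for i in range(1, 5)])
        cfg = crosstalk.CrosstalkConfig(min_targets_present=2)
        (base,) = crosstalk.ligand_activity(build_test_pairs(sender, receiver, genes), prior, cfg)
        perm = rng.permutation(10)
        (shuf,) = crosstalk.ligand_activity(
            build_test_pairs(sender[:, perm], receiver[:, perm], genes), prior, cfg
        )
        assert shuf.activity == pytest.approx(base.activity, abs=1e-12)

    def test_planted_recovery_and_ranking(self):
        # 10 coupled ligands vs 40 nulls over 30 pairs through the full
        # generator + pipeline; every planted ligand >= 0.2 and in the top 15
        from roicrosstalk.synthdata import PlantedLigand, SimConfig, generate_dataset

        lig = [
            PlantedLigand(sender="stroma", receiver="tumour", coupling=0.5, n_targets=6)
            for _ in range(10)
        ]
        cfg = SimConfig(
            seed=7,
            n_cores=30,
            compartment_presence={"tumour": 1.0, "stroma": 1.0, "immune": 0.0},
            n_genes=600,
            active_ligands=lig,
            n_null_ligands=40,
            n_de_genes=0,
            n_signature_genes=0,
            n_subtypes=2,
        )
        counts, annot, _, prior, _, _, truth = generate_dataset(cfg)
        kept, _ = rc.filter_rois(counts, annot)
        kept, _ = rc.filter_genes(kept)
        lg = rc.log2_transform(rc.q3_normalize(kept))
        pairs = crosstalk.build_pairs(annot.subset(kept.roi_ids), lg, "stroma", "tumour")
        ccfg = crosstalk.CrosstalkConfig(min_targets_present=2)
        res = crosstalk.ligand_activity(pairs, crosstalk.restrict_prior(prior, set(lg.gene_ids), ccfg), ccfg)
        planted = {p.ligand for p in truth.active_ligands}
        acts = {r.ligand: r.activity for r in res if r.activity is not None}
        assert all(acts[l] >= 0.2 for l in planted)
        ranked = sorted(acts, key=acts.get, reverse=True)
        assert planted <= set(ranked[:15])

    def test_oracle_equivalence_random(self, rng):
        genes = [f"g{i}" for i in range(12)]
        sender = rng.normal(size=(12, 9))
        receiver = rng.normal(size=(12, 9))
        rows = [("g0", f"g{i}", rng.uniform()) for i in range(1, 7)] + [
            ("g7", f"g{i}", rng.uniform()) for i in range(8, 12)
        ]
        prior = prior_from(rows)
        cfg = crosstalk.CrosstalkConfig(min_targets_present=2)
        results = crosstalk.ligand_activity(build_test_pairs(sender, receiver, genes), prior, cfg)
        gi = {g: i for i, g in enumerate(genes)}
        for r in results:
            targets = prior.targets_of(r.ligand)["target"]
            ref = np.mean(
                [stats.pearsonr(sender[gi[r.ligand]], receiver[gi[t]]).statistic for t in targets]
            )
            assert r.activity == pytest.approx(ref, abs=1e-12)


class TestPermutationNull:
    def test_null_calibration(self, rng):
        # 40 null ligands, 30 pairs, 200 shuffles: <= 10% of evaluable
        # ligands called active at the 0.2 threshold
        genes = [f"g{i}" for i in range(120)]
        sender = rng.normal(size=(120, 30))
        receiver = rng.normal(size=(120, 30))
        rows = []
        for k in range(40):
            lig = genes[k]
            for t in range(6):
                rows.append((lig, genes[40 + ((6 * k + t) % 80)], 1.0))
        prior = prior_from(rows)
        pairs = build_test_pairs(sender, receiver, genes)
        cfg = crosstalk.CrosstalkConfig(min_targets_present=2)
        fractions = crosstalk.permutation_null(pairs, prior, cfg, n_reps=200, seed=11)
        assert fractions.mean() <= 0.10


class TestCorrelateLigandsWithCells:
    def make_props(self, arr, rois):
        import roicrosstalk.deconv as dc

        cts = [f"ct{j}" for j in range(arr.shape[1])]
        return dc.CellProportions(
            data=pd.DataFrame(arr, index=rois, columns=cts),
            residuals=pd.Series(np.zeros(len(rois)), index=rois),
        )

    def test_identical_vector_edge(self):
        rois = [f"r{i}" for i in range(5)]
        v = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        props = self.make_props(np.column_stack([v, 1 - v]), rois)
        expr = log2_expr(v[None, :], genes=["LIG"], rois=rois)
        edges = crosstalk.correlate_ligands_with_cells(expr, props, ["LIG"])
        edge = edges[edges["cell_type"] == "ct0"]
        assert len(edge) == 1 and edge["r"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_no_edge(self):
        rois = [f"r{i}" for i in range(5)]
        v = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        props = self.make_props(np.column_stack([v, 1 - v]), rois)
        expr = log2_expr(-v[None, :] + 1.0, genes=["LIG"], rois=rois)
        edges = crosstalk.correlate_ligands_with_cells(expr, props, ["LIG"])
        assert (edges["cell_type"] != "ct0").all()

    def test_matches_full_matrix_oracle(self, rng):
        rois = [f"r{i}" for i in range(20)]
        props_arr = rng.dirichlet(np.ones(4), size=20)
        props = self.make_props(props_arr, rois)
        ligands = [f"L{i}" for i in range(6)]
        arr = rng.normal(size=(6, 20))
        expr = log2_expr(arr, genes=ligands, rois=rois)
        edges = crosstalk.correlate_ligands_with_cells(expr, props, ligands, r_threshold=0.2)
        expected = set()
        for i, lig in enumerate(ligands):
            for j in range(4):
                r = stats.pearsonr(arr[i], props_arr[:, j]).statistic
                if r > 0.2:
                    expected.add((f"ct{j}", lig))
        assert set(zip(edges["cell_type"], edges["ligand"])) == expected

    def test_too_few_shared_rois(self, rng):
        rois = ["r0", "r1"]
        props = self.make_props(rng.dirichlet(np.ones(2), size=2), rois)
        expr = log2_expr(rng.normal(size=(1, 2)), genes=["L"], rois=rois)
        with pytest.raises(cm.ValidationError, match="at least 3"):
            crosstalk.correlate_ligands_with_cells(expr, props, ["L"])
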