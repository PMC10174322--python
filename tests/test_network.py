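"""ceRNA network: correlation screens, MuTaME scoring, assembly, export."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cernet.network import (
    NEGATIVE,
    POSITIVE,
    ScreenThresholds,
    add_hyper_p,
    assemble_network,
    export_network,
    mutame_score,
    pearson_edges,
    run_network,
    shared_mirna_test,
    top_axes,
)


def frame(rows, samples=None):
    return pd.DataFrame(rows).T if samples is None else pd.DataFrame(rows, columns=samples)


class TestPearsonEdges:
    def test_perfect_anticorrelation_is_kept(self):
        x = np.arange(8, dtype=float)
        X = pd.DataFrame([x], index=["mi"])
        Y = pd.DataFrame([-x], index=["lnc"])
        edges = pearson_edges(X, Y, NEGATIVE)
        assert len(edges) == 1
        assert edges.loc[0, "r"] == pytest.approx(-1.0)
        assert edges.loc[0, "p"] == 0.0
        assert pearson_edges(X, Y, POSITIVE).empty

    def test_hand_worked_r(self):
        X = pd.DataFrame([[1.0, 2, 3, 4]], index=["a"])
        Y = pd.DataFrame([[2.0, 4, 6, 9]], index=["b"])
        edges = pearson_edges(X, Y, POSITIVE, ScreenThresholds(r_min=0.5, p_max=0.5))
        # cov = 11.5, sd_x^2 = 5, sd_y^2 = 26.75 -> r = 11.5/sqrt(133.75)
        assert edges.loc[0, "r"] == pytest.approx(11.5 / math.sqrt(5 * 26.75))
        assert edges.loc[0, "r"] == pytest.approx(0.9944, abs=5e-5)

    def test_null_retention_rate(self):
        """Independent pairs at n=8: P(pass at r_min=0.7, p<=0.05) ~ 0.05."""
        rng = np.random.default_rng(77)
        X = pd.DataFrame(rng.normal(size=(2000, 8)))
        Y = pd.DataFrame(rng.normal(size=(2000, 8)))
        # pairwise (diagonal) retention: screen each row pair separately
        kept = 0
        th = ScreenThresholds()
        for i in range(2000):
            e = pearson_edges(X.iloc[[i]], Y.iloc[[i]], NEGATIVE, th)
            e2 = pearson_edges(X.iloc[[i]], Y.iloc[[i]], POSITIVE, th)
            kept += len(e) + len(e2)
        assert 0.03 <= kept / 2000 <= 0.07

    def test_mismatched_samples_error(self):
        X = pd.DataFrame(np.ones((2, 4)), columns=list("abcd"))
        Y = pd.DataFrame(np.ones((2, 4)), columns=list("abce"))
        with pytest.raises(ValueError):
            pearson_edges(X, Y, NEGATIVE)

    def test_zero_variance_rows_are_skipped(self, rng):
        X = pd.DataFrame(np.vstack([np.ones(6), rng.normal(size=6)]))
        Y = pd.DataFrame(rng.normal(size=(3, 6)))
        edges = pearson_edges(X, Y, POSITIVE, ScreenThresholds(r_min=0.7, p_max=0.99))
        assert 0 not in set(edges["id_a"])


class TestMutame:
    def hits_frame(self, entries):
        return pd.DataFrame(
            [{"mirna": m, "transcript": t, "start": s, "end": s + 8, "score": 150.0,
              "seed_class": "8mer"} for m, t, s in entries]
        )

    def test_toy_pair_hand_worked(self):
        hits = self.hits_frame(
            [("k", "A", 10), ("k", "A", 50),
             ("k", "B", 20), ("k", "B", 90), ("k", "B", 160)]
        )
        out = mutame_score([("A", "B")], hits, {"k"}, {"A": 100, "B": 200})
        row = out.iloc[0]
        assert row.s1 == pytest.approx(1.0)
        # d_A = 2/(40+7), d_B = 3/(140+7)
        assert row.s2 == pytest.approx((2 / 47 + 3 / 147) / 2, rel=1e-9)
        assert row.s3 == pytest.approx(1.0)   # single gap / equal gaps
        assert row.s4 == pytest.approx(1.0)
        assert row.raw == pytest.approx(math.log((2 / 47 + 3 / 147) / 2), rel=1e-9)
        assert row.raw == pytest.approx(-3.4584, abs=5e-5)
        assert row.score == 100.0             # single evaluated pair

    def test_all_hits_shared_gives_unit_s1_s4(self):
        hits = self.hits_frame(
            [("k1", "A", 10), ("k1", "B", 30), ("k2", "A", 80), ("k2", "B", 120)]
        )
        out = mutame_score([("A", "B")], hits, {"k1", "k2"}, {"A": 300, "B": 300})
        assert out.iloc[0].s1 == 1.0
        assert out.iloc[0].s4 == 1.0

    def test_min_max_normalization_endpoints(self):
        hits = self.hits_frame(
            [("k", "A", 10), ("k", "B", 30),
             ("k", "A2", 10), ("k", "A2", 25), ("k", "B2", 30), ("k", "B2", 45)]
        )
        out = mutame_score([("A", "B"), ("A2", "B2")], hits, {"k"},
                           {"A": 500, "B": 500, "A2": 500, "B2": 500})
        scores = sorted(out["score"])
        assert scores == [0.0, 100.0]
        raws = out.sort_values("score")["raw"].to_numpy()
        assert raws[0] < raws[1]

    def test_pair_without_shared_mirna_is_excluded(self):
        hits = self.hits_frame([("k1", "A", 10), ("k2", "B", 30)])
        out = mutame_score([("A", "B")], hits, {"k1", "k2"}, {"A": 100, "B": 100})
        assert out.empty

    def test_components_bounded(self, small_nb_dataset):
        from cernet.targets import hits_to_frame, predict_targets

        ds = small_nb_dataset
        hits = hits_to_frame(predict_targets(ds.mirnas, ds.transcripts))
        tx_len = {t: len(s) for t, s in ds.transcripts.items()}
        lncs = [t for t in ds.transcripts if t.startswith("LNC")]
        mrnas = [t for t in ds.transcripts if t.startswith("MRNA")]
        pairs = list(itertools.product(lncs, mrnas))
        out = mutame_score(pairs, hits, set(ds.mirnas), tx_len)
        assert len(out) > 0
        for col in ("s1", "s3", "s4"):
            assert ((out[col] > 0) & (out[col] <= 1)).all()
        assert ((out["score"] >= 0) & (out["score"] <= 100)).all()

    def test_normalization_invariant_under_affine_shift(self):
        # scores depend only on the spread of raw values, so rescaling all
        # component inputs identically (which shifts raw by a constant)
        # leaves scores unchanged
        hits = self.hits_frame(
            [("k", "A", 10), ("k", "B", 30),
             ("k", "A2", 10), ("k", "A2", 25), ("k", "B2", 30), ("k", "B2", 45)]
        )
        lens1 = {"A": 500, "B": 500, "A2": 500, "B2": 500}
        lens2 = {k: v * 2 for k, v in lens1.items()}   # halves every 1/len density
        out1 = mutame_score([("A", "B"), ("A2", "B2")], hits, {"k"}, lens1)
        out2 = mutame_score([("A", "B"), ("A2", "B2")], hits, {"k"}, lens2)
        assert np.allclose(out1["score"], out2["score"])


class TestSharedMirnaTest:
    def test_full_overlap_closed_form(self):
        # P(overlap >= 5) with |A|=|B|=5 in universe 10 = 1/C(10,5)
        assert shared_mirna_test(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_zero_overlap_is_one(self):
        assert shared_mirna_test(0, 4, 4, 10) == 1.0

    def test_matches_enumeration_for_small_universes(self):
        for N in range(1, 13):
            for KA in range(N + 1):
                for KB in range(N + 1):
                    for m in range(0, min(KA, KB) + 1):
                        if m == 0:
                            continue
                        expect = sum(
                            math.comb(KA, i) * math.comb(N - KA, KB - i)
                            for i in range(m, min(KA, KB) + 1)
                        ) / math.comb(N, KB)
                        got = shared_mirna_test(m, KA, KB, N)
                        assert got == pytest.approx(expect, abs=1e-12)

    def test_inconsistent_sizes_error(self):
        with pytest.raises(ValueError):
            shared_mirna_test(3, 2, 5, 10)


def toy_inputs():
    edges_mi_lnc = pd.DataFrame(
        [{"id_a": "k", "id_b": "L", "r": -0.9, "p": 0.001, "n": 10}])
    edges_mi_mrna = pd.DataFrame(
        [{"id_a": "k", "id_b": "G", "r": -0.8, "p": 0.002, "n": 10}])
    edges_lnc_mrna = pd.DataFrame(
        [{"id_a": "L", "id_b": "G", "r": 0.85, "p": 0.001, "n": 10}])
    scored = pd.DataFrame([{
        "lnc_id": "L", "mrna_id": "G", "shared_mirnas": "k",
        "n_shared": 1, "n_mi_lnc": 1, "n_mi_mrna": 1,
        "s1": 1.0, "s2": 0.05, "s3": 1.0, "s4": 1.0, "raw": -3.0, "score": 100.0,
    }])
    return edges_mi_lnc, edges_mi_mrna, edges_lnc_mrna, scored


class TestAssembly:
    def test_valid_triplet_is_emitted(self):
        triplets, net = assemble_network(*toy_inputs())
        assert len(triplets) == 1
        assert net.number_of_nodes() == 3 and net.number_of_edges() == 3

    def test_missing_positive_edge_blocks_triplet(self):
        e1, e2, e3, scored = toy_inputs()
        triplets, net = assemble_network(e1, e2, e3.iloc[0:0], scored)
        assert triplets.empty and net.number_of_edges() == 0

    def test_low_score_blocks_triplet(self):
        e1, e2, e3, scored = toy_inputs()
        scored = scored.assign(score=10.0)
        triplets, _ = assemble_network(e1, e2, e3, scored)
        assert triplets.empty

    def test_hyper_filter(self):
        e1, e2, e3, scored = toy_inputs()
        scored = scored.assign(hyper_p=0.5)
        th = ScreenThresholds(require_hyper=True)
        triplets, _ = assemble_network(e1, e2, e3, scored, th)
        assert triplets.empty

    def test_empty_pair_list_gives_empty_network(self):
        e1, e2, e3, scored = toy_inputs()
        triplets, net = assemble_network(e1, e2, e3, scored.iloc[0:0])
        assert triplets.empty and net.number_of_nodes() == 0


class TestTopAxes:
    def make_triplets(self):
        return pd.DataFrame([
            {"lnc_id": "L1", "mirna_id": "k1", "mrna_id": "G1",
             "r_mi_lnc": -0.9, "r_mi_mrna": -0.9, "r_lnc_mrna": 0.8, "score": 90.0},
            {"lnc_id": "L2", "mirna_id": "k2", "mrna_id": "G2",
             "r_mi_lnc": -0.9, "r_mi_mrna": -0.9, "r_lnc_mrna": 0.95, "score": 70.0},
            {"lnc_id": "L0", "mirna_id": "k0", "mrna_id": "G0",
             "r_mi_lnc": -0.9, "r_mi_mrna": -0.9, "r_lnc_mrna": 0.95, "score": 70.0},
        ])

    def test_sort_keys_and_tie_break(self):
        out = top_axes(self.make_triplets(), 3)
        assert list(out["lnc_id"]) == ["L1", "L0", "L2"]

    def test_n_larger_than_input_returns_all(self):
        assert len(top_axes(self.make_triplets(), 100)) == 3

    def test_permutation_invariance(self, rng):
        t = self.make_triplets()
        perm = t.sample(frac=1, random_state=5).reset_index(drop=True)
        assert top_axes(t, 2).equals(top_axes(perm, 2))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_axes(self.make_triplets(), 0)


class TestExport:
    def test_single_triplet_files(self, tmp_path):
        _, net = assemble_network(*toy_inputs())
        paths = export_network(net, tmp_path)
        sif = open(paths["sif"]).read().splitlines()
        assert len(sif) == 3
        assert {line.split("\t")[1] for line in sif} == {"mi_lnc", "mi_mrna", "lnc_mrna"}
        nodes = pd.read_csv(paths["nodes"], sep="\t")
        assert len(nodes) == 3
        assert set(nodes["type"]) == {"lnc", "mirna", "mrna"}

    def test_reexport_is_byte_identical(self, tmp_path):
        _, net = assemble_network(*toy_inputs())
        p1 = export_network(net, tmp_path / "x")
        p2 = export_network(net, tmp_path / "y")
        for k in p1:
            assert open(p1[k], "rb").read() == open(p2[k], "rb").read()

    def test_shared_edges_deduplicated(self, tmp_path):
        """Two triplets sharing the miRNA-lncRNA edge: 5 SIF lines, not 6."""
        e1 = pd.DataFrame([{"id_a": "k", "id_b": "L", "r": -0.9, "p": 0.001, "n": 10}])
        e2 = pd.DataFrame([
            {"id_a": "k", "id_b": "G1", "r": -0.8, "p": 0.002, "n": 10},
            {"id_a": "k", "id_b": "G2", "r": -0.7, "p": 0.01, "n": 10},
        ])
        e3 = pd.DataFrame([
            {"id_a": "L", "id_b": "G1", "r": 0.85, "p": 0.001, "n": 10},
            {"id_a": "L", "id_b": "G2", "r": 0.75, "p": 0.01, "n": 10},
        ])
        scored = pd.DataFrame([
            {"lnc_id": "L", "mrna_id": g, "shared_mirnas": "k", "n_shared": 1,
             "n_mi_lnc": 1, "n_mi_mrna": 1, "s1": 1.0, "s2": 0.05, "s3": 1.0,
             "s4": 1.0, "raw": -3.0, "score": 100.0}
            for g in ("G1", "G2")
        ])
        triplets, net = assemble_network(e1, e2, e3, scored)
        assert len(triplets) == 2
        paths = export_network(net, tmp_path)
        assert len(open(paths["sif"]).read().splitlines()) == 5


class TestEndToEnd:
    def test_monotone_thresholds_give_nested_networks(self, small_nb_dataset):
        from cernet.targets import hits_to_frame, predict_targets

        ds = small_nb_dataset
        hits = hits_to_frame(predict_targets(ds.mirnas, ds.transcripts))
        tx_len = {t: len(s) for t, s in ds.transcripts.items()}
        loose, _, _ = run_network(ds.counts, hits,
                                  ScreenThresholds(r_min=0.6, score_min=20.0),
                                  tx_len=tx_len)
        tight, _, _ = run_network(ds.counts, hits,
                                  ScreenThresholds(r_min=0.8, score_min=60.0),
                                  tx_len=tx_len)
        key = ["lnc_id", "mirna_id", "mrna_id"]
        assert set(map(tuple, tight[key].to_numpy())) <= set(
            map(tuple, loose[key].to_numpy()))

    def test_emitted_triplets_satisfy_sign_pattern(self, small_nb_dataset):
        from cernet.targets import hits_to_frame, predict_targets

        ds = small_nb_dataset
        hits = hits_to_frame(predict_targets(ds.mirnas, ds.transcripts))
        tx_len = {t: len(s) for t, s in ds.transcripts.items()}
        triplets, _, scored = run_network(ds.counts, hits, tx_len=tx_len)
        assert len(triplets) > 0
        assert (triplets["r_mi_lnc"] < 0).all()
        assert (triplets["r_mi_mrna"] < 0).all()
        assert (triplets["r_lnc_mrna"] > 0).all()
        for t in triplets.itertuples(index=False):
            row = scored[(scored.lnc_id == t.lnc_id) & (scored.mrna_id == t.mrna_id)]
            assert t.mirna_id in row.iloc[0].shared_mirnas.split(",")


def test_add_hyper_p_matches_direct_call():
    scored = pd.DataFrame([{
        "lnc_id": "L", "mrna_id": "G", "shared_mirnas": "k", "n_shared": 2,
        "n_mi_lnc": 3, "n_mi_mrna": 4, "s1": 1.0, "s2": 0.1, "s3": 1.0,
        "s4": 1.0, "raw": -2.3, "score": 100.0,
    }])
    out = add_hyper_p(scored, 10)
    assert out["hyper_p"].iloc[0] == pytest.approx(shared_mirna_test(2, 3, 4, 10))
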