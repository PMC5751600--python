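import math

import numpy as np
import pandas as pd
import pytest

from modrepo import disease, drugs
from modrepo.io import (
    DiseaseModuleNetwork,
    DrugScoreTable,
    DrugTargetEvidence,
    EnrichmentResult,
    PPINetwork,
    ValidationError,
)


def make_modnet(module="turquoise", edges=None, direction=None, priority=None):
    edges = edges or [("p", "a", 0.9), ("p", "b", 0.8), ("a", "b", 0.7)]
    net = PPINetwork(edges)
    genes = net.nodes
    direction = direction or {g: 1 for g in genes}
    priority = priority or {g: 1.0 for g in genes}
    rp = {g: disease.node_rp_score(net, g) for g in genes}
    return DiseaseModuleNetwork(
        module, net, direction, {g: 0.1 for g in genes}, priority, rp
    )


class TestConf:
    def test_single_evidence(self):
        assert drugs.conf_dp(DrugTargetEvidence("d", "d", "g", [(1.0, 1)])) == 1.0

    def test_mixed_evidence(self):
        rec = DrugTargetEvidence("d", "d", "g", [(0.8, 1), (0.5, -1)])
        assert drugs.conf_dp(rec) == pytest.approx(0.3)

    def test_empty_evidence_zero(self):
        assert drugs.conf_dp(DrugTargetEvidence("d", "d", "g", [])) == 0.0

    def test_random_sum_oracle(self, rng):
        items = [(float(rng.random()), int(rng.choice([-1, 1]))) for _ in range(10)]
        rec = DrugTargetEvidence("d", "d", "g", items)
        assert drugs.conf_dp(rec) == pytest.approx(
            sum(p * s for p, s in items), rel=1e-12
        )


class TestWeight:
    def test_two_edge_example(self):
        net = PPINetwork([("p", "a", 0.9), ("p", "b", 0.8)])
        assert drugs.weight_p(net, "p", 2.0) == pytest.approx(
            2 * math.log(1.7) - math.log(2), rel=1e-12
        )

    def test_single_full_confidence_edge_is_zero(self):
        net = PPINetwork([("p", "a", 1.0)])
        assert drugs.weight_p(net, "p") == pytest.approx(0.0, abs=1e-15)

    def test_doubling_confs_adds_k_ln2(self, rng):
        confs = rng.uniform(0.1, 0.5, size=5)
        net1 = PPINetwork([("p", f"n{i}", c) for i, c in enumerate(confs)])
        net2 = PPINetwork([("p", f"n{i}", 2 * c) for i, c in enumerate(confs)])
        k = 2.0
        assert drugs.weight_p(net2, "p", k) - drugs.weight_p(net1, "p", k) == (
            pytest.approx(k * math.log(2), rel=1e-12)
        )

    def test_degree_zero_errors(self):
        net = PPINetwork([("a", "b", 0.5)])
        with pytest.raises(ValidationError, match="no PPI edges"):
            drugs.weight_p(net, "zzz")


class TestPScore:
    def test_zero_conf(self):
        assert drugs.p_score(0.0, 1.3) == 0.0

    def test_unit_conf_identity(self):
        assert drugs.p_score(1.0, 0.77) == 0.77

    def test_product_oracle(self, rng):
        for _ in range(20):
            c, w = rng.normal(), rng.normal()
            assert drugs.p_score(c, w) == c * w


class TestRPScore:
    def test_closed_form_equivalence(self):
        modnet = make_modnet(edges=[("p", "a", 0.9), ("p", "b", 0.8), ("a", "b", 0.5)])
        assert drugs.rp_score(modnet, "p", 2.0) == pytest.approx(
            1.7 ** 2 / 2, rel=1e-12
        )

    def test_single_unit_edge(self):
        modnet = make_modnet(edges=[("p", "a", 1.0)])
        assert drugs.rp_score(modnet, "p") == pytest.approx(1.0)

    def test_exp_weight_consistency(self, default_bundle):
        # rp_score == exp(weight computed on the module network), every protein
        modnet = make_modnet()
        for gene in modnet.genes:
            w = drugs.weight_p(modnet.network, gene, 2.0)
            assert drugs.rp_score(modnet, gene, 2.0) == pytest.approx(
                math.exp(w), rel=1e-12
            )

    def test_absent_protein_errors(self):
        with pytest.raises(ValidationError):
            drugs.rp_score(make_modnet(), "nope")


class TestDES:
    def _modnet_for_hand_example(self, direction=1):
        # single target gene "g" with RP-score forced to 8
        net = PPINetwork([("g", "x", 1.0)])
        return DiseaseModuleNetwork(
            "m", net, {"g": direction, "x": 0}, {"g": 0.1, "x": 0.0},
            {"g": 1.0, "x": 0.25}, {"g": 8.0, "x": 1.0},
        )

    def test_no_targets_in_module_is_zero(self):
        modnet = make_modnet()
        assert drugs.des({"elsewhere": 0.9}, modnet, {"elsewhere": 4.0}) == 0.0

    def test_single_term_hand_example(self):
        # up-regulated gene, inhibiting drug: +1 * log2(4) * log2(8) * 1 = 6
        modnet = self._modnet_for_hand_example(direction=+1)
        assert drugs.des({"g": -0.9}, modnet, {"g": -4.0}) == pytest.approx(6.0)

    def test_activating_drug_flips_sign(self):
        modnet = self._modnet_for_hand_example(direction=+1)
        assert drugs.des({"g": +0.9}, modnet, {"g": 4.0}) == pytest.approx(-6.0)

    def test_zero_direction_contributes_nothing(self):
        modnet = self._modnet_for_hand_example(direction=0)
        assert drugs.des({"g": -0.9}, modnet, {"g": -4.0}) == 0.0

    def test_log2_floor_zeroes_subunit_magnitudes(self):
        modnet = self._modnet_for_hand_example(direction=+1)
        # |P-score| = 0.5 < 1 -> log2 floored at 0 -> term vanishes
        assert drugs.des({"g": -0.9}, modnet, {"g": -0.5}) == 0.0


class TestDESS:
    def _enr(self, module, f):
        return EnrichmentResult(module, 100, 10, 20, 5, f)

    def test_no_selected_modules(self):
        assert drugs.dess({"m1": 3.0}, [self._enr("m1", -0.5)]) == 0.0

    def test_single_module_is_product(self):
        assert drugs.dess({"m1": 3.0}, [self._enr("m1", 0.9)]) == pytest.approx(2.7)

    def test_two_module_sum_oracle(self, rng):
        des_by = {"m1": float(rng.normal()), "m2": float(rng.normal())}
        enrs = [self._enr("m1", 0.9), self._enr("m2", 0.4)]
        assert drugs.dess(des_by, enrs) == pytest.approx(
            des_by["m1"] * 0.9 + des_by["m2"] * 0.4, rel=1e-12
        )

    def test_additivity_over_modules(self, rng):
        des_by = {"m1": 2.0, "m2": -1.5, "m3": 0.7}
        enrs = [self._enr("m1", 0.9), self._enr("m2", 0.4), self._enr("m3", 1.2)]
        total = drugs.dess(des_by, enrs)
        parts = sum(drugs.dess(des_by, [e]) for e in enrs)
        assert total == pytest.approx(parts, abs=1e-12)


class TestRankAndSelect:
    def _table(self, dess_values):
        df = pd.DataFrame(
            {"drug_name": "x", "dess": dess_values},
            index=pd.Index([f"D{i:05d}" for i in range(len(dess_values))],
                           name="drug_id"),
        )
        return DrugScoreTable(df)

    def test_1246_drugs_top_percent_is_12(self, rng):
        scores = self._table(list(rng.normal(size=1246)))
        ranked = drugs.rank_and_select(scores, 0.01)
        assert int(ranked.table["top"].sum()) == 12

    def test_single_drug_floor_guard(self):
        ranked = drugs.rank_and_select(self._table([1.0]), 0.01)
        assert int(ranked.table["top"].sum()) == 1

    def test_permutation_invariance(self, rng):
        values = list(rng.normal(size=50))
        scores = self._table(values)
        shuffled = DrugScoreTable(scores.table.sample(frac=1, random_state=1))
        r1 = drugs.rank_and_select(scores, 0.1)
        r2 = drugs.rank_and_select(shuffled, 0.1)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_descending_order_with_id_tiebreak(self):
        scores = self._table([1.0, 2.0, 2.0, 0.5])
        ranked = drugs.rank_and_select(scores, 0.5)
        assert list(ranked.table.index[:2]) == ["D00001", "D00002"]
        assert list(ranked.table["rank"]) == [1, 2, 3, 4]


class TestMonotonicity:
    def test_raising_aligned_conf_never_decreases_dess(self):
        modnet = make_modnet(direction={"p": 1, "a": 1, "b": -1})
        ppi = PPINetwork(
            [("p", "a", 0.9), ("p", "b", 0.8), ("a", "b", 0.7), ("p", "q", 0.9),
             ("a", "q", 0.9), ("b", "q", 0.8)]
        )
        enr = [EnrichmentResult("turquoise", 100, 10, 20, 8, 1.1)]
        last = -np.inf
        for conf in np.linspace(0.1, 2.0, 15):
            # inhibitor of the up-regulated gene p: reversal-aligned
            record = DrugTargetEvidence("D1", "d", "p", [(min(conf, 1.0), -1)])
            conf_map = {"p": -conf}
            w = drugs.weight_p(ppi, "p")
            value = drugs.dess(
                {"turquoise": drugs.des(conf_map, modnet, {"p": drugs.p_score(-conf, w)})},
                enr,
            )
            assert value >= last - 1e-12
            last = value


class TestExtendedNetwork:
    def _scores(self, top_ids):
        df = pd.DataFrame(
            {"drug_name": "x", "dess": 1.0, "rank": 1, "top": True},
            index=pd.Index(top_ids, name="drug_id"),
        )
        return DrugScoreTable(df)

    def test_minimal_network(self):
        modnet = make_modnet()
        ev = [DrugTargetEvidence("D1", "d", "p", [(0.9, 1)])]
        ppi = modnet.network
        nodes, edges = drugs.build_extended_drug_network(
            self._scores(["D1"]), [modnet], ev, PPINetwork([]), 0.75
        )
        drug_edges = edges[edges["action"] != "ppi"]
        assert len(drug_edges) == 1
        assert set(nodes["node"]) >= {"D1", "p"}

    def test_edge_sign_matches_conf(self):
        modnet = make_modnet()
        ev = [
            DrugTargetEvidence("D1", "d", "p", [(0.9, 1)]),
            DrugTargetEvidence("D1", "d", "a", [(0.9, -1)]),
        ]
        _, edges = drugs.build_extended_drug_network(
            self._scores(["D1"]), [modnet], ev, PPINetwork([]), 0.75
        )
        actions = dict(zip(edges["target"], edges["action"]))
        assert actions["p"] == "stimulation"
        assert actions["a"] == "inhibition"

    def test_ppi_edges_respect_threshold(self, default_bundle):
        modnet = make_modnet()
        ev = [DrugTargetEvidence("D1", "d", "p", [(0.9, 1)])]
        _, edges = drugs.build_extended_drug_network(
            self._scores(["D1"]), [modnet], ev, default_bundle.ppi, 0.75
        )
        ppi_edges = edges[edges["action"] == "ppi"]
        assert (ppi_edges["conf"] >= 0.75).all()
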