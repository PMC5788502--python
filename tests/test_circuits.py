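"""Gates, annihilation, network dynamics and application scenarios."""

import numpy as np
import pytest

from riboconnect.circuits import (
    EXPECTED_TRUTH,
    DeviceInstance,
    GateError,
    NetworkEdge,
    NetworkError,
    NetworkModel,
    Perturbation,
    SpeciesDef,
    and_classifier,
    annihilate,
    build_gate,
    digitize,
    opn_vegf_loop,
    redirect_scenario,
    rewire_scenario,
    simulate_gate,
    simulate_network,
)
from riboconnect.demo import (
    demo_classifier_device,
    demo_gate_pool,
    demo_redirect_devices,
    demo_rewire_connector,
)
from riboconnect.regulation import RegulationParams


class TestAnnihilation:
    def test_perfect_reverse_complement_annihilates(self, gate_pool):
        devs = {d.design.id: d.design for d in gate_pool["devices"]}
        assert annihilate(devs["R_theo_strong"], devs["R_tet_comp"]) == 0.0

    def test_unrelated_antisense_no_interaction(self, gate_pool):
        devs = {d.design.id: d.design for d in gate_pool["devices"]}
        assert annihilate(devs["R_theo_strong"], devs["R_tet_strong"]) == 1.0

    def test_threshold_boundary_16_of_20(self, gate_pool):
        """Exactly 16 complementary positions still annihilates."""
        from dataclasses import replace

        devs = {d.design.id: d.design for d in gate_pool["devices"]}
        d1 = devs["R_theo_strong"]  # antisense GGGG...G
        # complement of d1.antisense with 4 positions broken
        anti = "AAAA" + "C" * 16
        d2 = replace(devs["R_tet_comp"], antisense=anti)
        assert annihilate(d1, d2) == 0.0
        d3 = replace(devs["R_tet_comp"], antisense="AAAAA" + "C" * 15)
        assert annihilate(d1, d3) == 1.0


class TestDigitize:
    def test_levels_and_midpoint_tie(self):
        assert digitize(10.0, 10.0, 1.0) == 1
        assert digitize(1.0, 10.0, 1.0) == 0
        assert digitize(5.5, 10.0, 1.0) == 1  # tie resolves ON

    def test_inverted_levels_rejected(self):
        with pytest.raises(GateError):
            digitize(1.0, 1.0, 2.0)


class TestGates:
    @pytest.mark.parametrize("gate", list(EXPECTED_TRUTH))
    def test_truth_tables_match_expectations(self, gate_pool, gate):
        spec = build_gate(gate, gate_pool["devices"])
        assert simulate_gate(spec).digital() == EXPECTED_TRUTH[gate]

    def test_second_not_gate_other_ligand(self, gate_pool):
        spec = build_gate("not", gate_pool["devices"], ligand="tetracycline")
        assert spec.input_ligands == ("tetracycline",)
        assert simulate_gate(spec).digital() == EXPECTED_TRUTH["not"]

    def test_and_rejects_strong_activators(self, gate_pool):
        strong_only = [
            d for d in gate_pool["devices"]
            if d.mode == "activate" and "weak" not in d.design.id
        ]
        with pytest.raises(GateError, match="weak|non-complementary"):
            build_gate("and", strong_only)

    def test_xor_requires_complementary_pair(self, gate_pool):
        non_comp = [
            d for d in gate_pool["devices"]
            if d.design.id in ("A_theo_strong", "A_tet_strong")
        ]
        with pytest.raises(GateError, match="complementary"):
            build_gate("xor", non_comp)

    def test_gate_reporter_mode_enforced(self, gate_pool):
        with pytest.raises(GateError, match="capped"):
            build_gate("not", gate_pool["devices"], reporter_mode="uncapped")

    def test_unknown_gate_rejected(self, gate_pool):
        with pytest.raises(GateError, match="unknown"):
            build_gate("nope", gate_pool["devices"])

    def test_symmetric_devices_give_symmetric_outputs(self, gate_pool):
        """With identical device parameters the table is input-swap
        invariant."""
        spec = build_gate("nor", gate_pool["devices"])
        d0 = spec.devices[0]
        twin = DeviceInstance(
            spec.devices[1].design, d0.params, efficacy_override=d0.efficacy
        )
        from dataclasses import replace

        sym = replace(
            spec,
            devices=(d0, twin),
            inputs={lig: 1000.0 for lig in spec.input_ligands},
        )
        table = simulate_gate(sym)
        for (a, b), (analog, _) in table.rows.items():
            assert analog == pytest.approx(table.rows[(b, a)][0], rel=1e-12)


class TestNetwork:
    def simple_model(self, edges=()):
        return NetworkModel(
            species={
                "X": SpeciesDef(production=1.0, decay=0.1, init=0.0),
                "Y": SpeciesDef(production=0.5, decay=0.25, init=0.0),
            },
            edges=tuple(edges),
        )

    def test_no_edges_relaxes_to_production_over_decay(self):
        traj = simulate_network(self.simple_model(), t_end=120, dt=0.01)
        assert traj["X"][-1] == pytest.approx(10.0, rel=1e-4)
        assert traj["Y"][-1] == pytest.approx(2.0, rel=1e-4)

    def test_undeclared_edge_species_rejected(self):
        with pytest.raises(NetworkError, match="undeclared"):
            NetworkModel(
                species={"X": SpeciesDef(1.0, 0.1)},
                edges=(NetworkEdge("Z", "X", "repress", RegulationParams()),),
            )

    def test_rk4_halving_dt_agrees(self):
        model = opn_vegf_loop("negative")
        a = simulate_network(model, t_end=50, dt=0.02)
        b = simulate_network(model, t_end=50, dt=0.01)
        assert abs(a["OPN"][-1] - b["OPN"][-1]) < 1e-6
        assert abs(a["VEGF"][-1] - b["VEGF"][-1]) < 1e-6

    def test_negative_loop_directionality_and_return(self):
        model = opn_vegf_loop("negative")
        base = simulate_network(model, t_end=120, dt=0.01)
        ss_opn, ss_vegf = base["OPN"][-1], base["VEGF"][-1]
        # VEGF step up -> OPN falls; VEGF knockdown -> OPN rises again
        pert = simulate_network(
            model, t_end=300, dt=0.01,
            perturbations=[
                Perturbation(120, "VEGF", "set", 3 * ss_vegf),
                Perturbation(200, "VEGF", "production_scale", 0.05),
            ],
        )
        t = pert["t"]
        opn_mid = pert["OPN"][np.searchsorted(t, 150.0)]
        assert opn_mid < ss_opn
        assert pert["OPN"][-1] > ss_opn
        # transient perturbation: returns within 1% of steady state
        trans = simulate_network(
            model, t_end=300, dt=0.01,
            perturbations=[Perturbation(120, "VEGF", "set", 3 * ss_vegf)],
        )
        assert abs(trans["OPN"][-1] - ss_opn) / ss_opn < 0.01

    def test_positive_loop_amplifies(self):
        model = opn_vegf_loop("positive")
        base = simulate_network(model, t_end=200, dt=0.01)
        # settles far above the no-edge baseline production/decay = 10
        assert base["VEGF"][-1] > 10.0
        over = simulate_network(
            model, t_end=400, dt=0.01,
            perturbations=[Perturbation(200, "OPN", "production_scale", 3.0)],
        )
        assert over["VEGF"][-1] > base["VEGF"][-1] * 1.001

    def test_event_on_unknown_species_rejected(self):
        with pytest.raises(NetworkError, match="undeclared"):
            simulate_network(
                self.simple_model(), t_end=1, dt=0.1,
                perturbations=[Perturbation(0.5, "Q", "set", 1.0)],
            )


class TestScenarios:
    def test_rewire_mrna_up_protein_down(self):
        dev = demo_rewire_connector(0)
        m0, p0 = rewire_scenario(0.0, dev)
        m1, p1 = rewire_scenario(5.0, dev)
        assert m0 == p0 == 1.0
        assert m1 > m0 and p1 < p0

    def test_rewire_null_connector_tracks_mrna(self):
        dev = demo_rewire_connector(0)
        null = DeviceInstance(dev.design, dev.params, efficacy_override=0.0)
        m, p = rewire_scenario(5.0, null)
        assert p == pytest.approx(m, rel=1e-12)

    def test_classifier_fires_only_on_both_inputs(self):
        dev = demo_classifier_device(0)
        table = {
            (pa, lg): and_classifier(pa, lg, dev)
            for pa in (False, True)
            for lg in (False, True)
        }
        assert table[(True, True)] > 0.3
        assert table[(False, False)] == table[(False, True)] == 0.0
        assert table[(True, False)] == 0.0

    def test_classifier_requires_ribozyme_flag(self):
        dev = demo_rewire_connector(0)  # not ribozyme-flanked
        with pytest.raises(Exception, match="ribozyme"):
            and_classifier(True, True, dev)

    def test_redirect_simultaneous_on_off(self):
        activators, repressors = demo_redirect_devices(0)
        base = redirect_scenario(0.0, activators, repressors)
        assert all(v == pytest.approx(1.0) for v in base.values())
        high = redirect_scenario(10.0, activators, repressors)
        for a in activators:
            assert high[a.design.target_id] > 1.5
        for r in repressors:
            assert high[r.design.target_id] < 0.5

    def test_redirect_null_activators_decouple(self):
        activators, repressors = demo_redirect_devices(0)
        nulls = [
            DeviceInstance(a.design, a.params, efficacy_override=0.0)
            for a in activators
        ]
        out = redirect_scenario(10.0, nulls, repressors)
        for a in activators:
            assert out[a.design.target_id] == pytest.approx(1.0)
        for r in repressors:
            assert out[r.design.target_id] < 0.5
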