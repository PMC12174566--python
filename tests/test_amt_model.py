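"""Stage equations, the healthy fixed point, and CPN/direct equivalence."""

import numpy as np
import pytest

from amtsim import organ_registry as reg
from amtsim.amt_model import (
    ModelParams,
    ProtocolError,
    Trajectory,
    apply_stimulation,
    build_net,
    first_cycle_in_range,
    initial_states,
    simulate,
    step_bowels_to_viscera,
    step_viscera,
    step_viscera_to_bowels,
    stimulation_terms,
    stimulus_gated,
    stimulus_linear,
    substance_absorption,
    substance_generation,
    substance_transport,
    validate_protocol,
)
from amtsim.cpn_core import Marking, run as run_net
from amtsim.tgtc import augment, verify_order


class TestFiveElementsStage:
    def test_balanced_state_is_invariant(self, params):
        states = initial_states()
        assert step_viscera(states, params) == states

    def test_generation_raises_heart_from_strong_liver(self, params):
        states = initial_states(liver=5.0)
        out = step_viscera(states, params)
        assert out["heart"] == pytest.approx(0.15 * 5 - 0.05 * 3 + 0.9 * 3)  # 3.30

    def test_restriction_lowers_heart_from_strong_kidney(self, params):
        states = initial_states(kidney=5.0)
        out = step_viscera(states, params)
        assert out["heart"] == pytest.approx(2.90)

    def test_update_is_synchronous(self, params):
        """Every viscus must read the previous cycle's values, not the
        freshly updated ones."""
        states = initial_states(liver=5.0)
        out = step_viscera(states, params)
        # spleen = g*heart - r*liver + s*spleen with heart still at its OLD
        # value 3.0 (the heart moves to 3.30 this stage; an asynchronous
        # sweep would give 2.945 instead)
        assert out["spleen"] == pytest.approx(0.15 * 3 - 0.05 * 5 + 0.9 * 3)

    def test_bowels_and_pericardium_unchanged(self, params):
        states = initial_states(liver=5.0, gallbladder=2.0, pericardium=2.5)
        out = step_viscera(states, params)
        assert out["gallbladder"] == 2.0 and out["pericardium"] == 2.5


class TestPairStages:
    def test_pair_fixed_point(self, params):
        states = initial_states()
        assert step_viscera_to_bowels(states, states, params) == states
        assert step_bowels_to_viscera(states, params) == states

    @pytest.mark.parametrize("heart,si_prev,expected", [
        (3.3, 3.0, 3.03),
        (3.0, 1.0, 1.2),
    ])
    def test_viscus_drives_bowel(self, params, heart, si_prev, expected):
        cur = initial_states(heart=heart)
        prev = initial_states(small_intestine=si_prev)
        out = step_viscera_to_bowels(cur, prev, params)
        assert out["small_intestine"] == pytest.approx(expected)

    @pytest.mark.parametrize("si,heart,expected", [
        (3.03, 3.3, 3.273),
        (1.2, 3.0, 2.82),
    ])
    def test_bowel_feeds_back_to_viscus(self, params, si, heart, expected):
        cur = initial_states(small_intestine=si, heart=heart)
        out = step_bowels_to_viscera(cur, params)
        assert out["heart"] == pytest.approx(expected)

    def test_all_six_pairs_updated(self, params):
        cur = {o: 4.0 for o in reg.ALL_ORGANS}
        prev = initial_states()
        out = step_viscera_to_bowels(cur, prev, params)
        for bowel in reg.BOWELS:
            assert out[bowel] == pytest.approx(0.1 * 4.0 + 0.9 * 3.0)


class TestStimulus:
    def test_linear_kernel_printed_values(self, params):
        assert stimulus_linear(0, params) == 0.0
        assert stimulus_linear(3, params) == pytest.approx(0.6)
        assert stimulus_linear(-3, params) == pytest.approx(-0.6)

    def test_gated_kernel_vanishes_at_target_and_saturates(self, params):
        assert stimulus_gated(3, 3.0, params) == 0.0
        # far from target the gate saturates at the full gain e*v
        assert stimulus_gated(3, 1.0, params) == pytest.approx(3 * 0.25 * 10)
        assert stimulus_gated(-3, 1.0, params) == pytest.approx(-7.5)
        # halfway: |3 - 2.375| / 1.25 = 0.5
        assert stimulus_gated(2, 2.375, params) == pytest.approx(2 * 2.5 * 0.5)

    def test_empty_protocol_changes_nothing(self, params):
        states = initial_states(liver=4.0)
        assert apply_stimulation(states, {}, params) == states

    def test_single_point_linear_reconstruction(self):
        params = ModelParams(stimulus="linear")
        states = initial_states()
        out = apply_stimulation(states, {"KI3": 3}, params)
        assert out["kidney"] == pytest.approx(3.0 + 0.01 * 0.6)  # 3.006

    def test_same_meridian_contributions_sum(self, params):
        states = initial_states(gallbladder=2.0)
        both = apply_stimulation(states, {"GB20": -3, "GB39": 3}, params)
        assert both["gallbladder"] == pytest.approx(2.0)  # equal and opposite
        single = apply_stimulation(states, {"GB39": 3}, params)
        assert single["gallbladder"] > 2.0

    def test_vessel_points_route_to_viscera(self, params):
        terms = stimulation_terms({"GV20": 3}, params)
        assert set(terms) == set(reg.ELEMENT_VISCERA)
        assert all(t == [(3, 0.2)] for t in terms.values())
        none_params = ModelParams(vessel_routing="none")
        assert stimulation_terms({"GV20": 3}, none_params) == {}

    def test_stimulation_monotone_in_level(self, params):
        """On a deficient organ the post-stimulation state strictly
        increases with the stimulation level."""
        prev = [apply_stimulation(initial_states(kidney=1.0), {"KI3": mu}, params)["kidney"]
                for mu in range(-5, 6)]
        assert all(a < b for a, b in zip(prev, prev[1:]))

    @pytest.mark.parametrize("bad", [{"GB99": 3}, {"GB20": 9}, {"nope": 1}])
    def test_invalid_protocols_rejected(self, bad):
        with pytest.raises((ProtocolError, reg.AcupointError)):
            validate_protocol(bad)


class TestSubstances:
    def test_healthy_equilibrium_generation(self, params):
        fi = substance_generation(initial_states(), params)
        assert fi == {"qi": 3.0, "blood": 3.0, "fluid": 3.0}

    def test_generator_imbalance_cuts_production(self, params):
        states = initial_states(spleen=5.0)   # spleen generates all three pools
        fi = substance_generation(states, params)
        expected = 3.0 * (34 / 36) * (1 / 3)
        for sub in fi:
            assert fi[sub] == pytest.approx(expected)  # ~0.9444

    def test_total_collapse_gives_zero(self, params):
        # whole-body sum deviates by n*h: first factor is floored at zero
        states = {o: 0.5 for o in reg.ALL_ORGANS}
        states["spleen"] = 3.0
        lopsided = dict(states)
        total = sum(lopsided.values())
        # push the sum to exactly 2*n*h via the liver (within bounds not needed here)
        lopsided["liver"] = 2 * 36 - (total - lopsided["liver"])
        assert substance_generation(lopsided, params)["qi"] == 0.0

    def test_healthy_transport_delivers_tenth(self, params):
        fi = {"qi": 3.0, "blood": 3.0, "fluid": 3.0}
        deliveries = substance_transport(fi, initial_states(), params)
        assert deliveries == {"qi": 0.3, "blood": 0.3, "fluid": 0.3}

    def test_transporter_imbalance_scales_delivery(self, params):
        states = initial_states(lung=5.0)     # lung transports qi
        deliveries = substance_transport({"qi": 3.0, "blood": 3.0, "fluid": 3.0},
                                         states, params)
        body = (36 - abs(sum(states.values()) - 36)) / 36
        assert deliveries["qi"] == pytest.approx(3.0 / 10 * body * (1 / 3))
        assert deliveries["blood"] == pytest.approx(3.0 / 10 * body * 1.0)

    def test_zero_pool_zero_delivery(self, params):
        zero = {"qi": 0.0, "blood": 0.0, "fluid": 0.0}
        assert substance_transport(zero, initial_states(), params) == zero

    def test_absorption_reconstitutes_healthy_state_exactly(self, params):
        states = initial_states()
        deliveries = {"qi": 0.3, "blood": 0.3, "fluid": 0.3}
        out = substance_absorption(states, deliveries, params)
        assert out["liver"] == pytest.approx(3.0, abs=1e-15)

    def test_zero_delivery_is_pure_decay(self, params):
        out = substance_absorption(initial_states(), {s: 0.0 for s in ("qi", "blood", "fluid")}, params)
        assert out["liver"] == pytest.approx(3.0 * 0.999)

    def test_clamping_to_bounds(self, params):
        states = {o: 5.5 for o in reg.ALL_ORGANS}
        big = {"qi": 100.0, "blood": 100.0, "fluid": 100.0}
        out = substance_absorption(states, big, params)
        assert all(v == 5.5 for v in out.values())


class TestSimulate:
    def test_healthy_fixed_point_trajectory(self, params):
        traj = simulate(initial_states(), {}, 20, params)
        assert np.allclose(traj.organs().to_numpy(), 3.0, atol=1e-12)

    def test_trajectory_shape_and_initial_row(self, meniere_initial, params):
        traj = simulate(meniere_initial, {}, 10, params)
        assert len(traj.df) == 11
        assert traj.states_at(0) == meniere_initial

    def test_zero_steps(self, meniere_initial, params):
        traj = simulate(meniere_initial, {}, 0, params)
        assert len(traj.df) == 1

    def test_negative_steps_rejected(self, params):
        with pytest.raises(Exception):
            simulate(initial_states(), {}, -1, params)

    def test_states_bounded_under_extreme_protocols(self, params):
        protocol = {"KI3": 5, "KI7": 5, "LR3": -5, "LR8": -5, "SP6": 5, "GB20": -5}
        traj = simulate(initial_states(liver=5.5, kidney=0.5), protocol, 60, params)
        organs = traj.organs().to_numpy()
        assert organs.min() >= 0.5 and organs.max() <= 5.5

    def test_reference_case_recovers_and_stabilizes(self, meniere_initial,
                                                    reference_protocol, params):
        traj = simulate(meniere_initial, reference_protocol, 50, params)
        first = first_cycle_in_range(traj, ["liver", "spleen", "kidney"])
        assert first is not None and first <= 8
        final = traj.states_at(50)
        for organ in ("liver", "spleen", "kidney"):
            assert abs(final[organ] - 3.0) < 0.5

    def test_stage_order_matters_on_deficiency_start(self, params):
        """Swapping the two exterior-interior stages changes the cycle
        output, guarding the pipeline ordering."""
        prev = initial_states(spleen=1.0)
        tau_p = step_viscera(prev, params)
        canonical = step_bowels_to_viscera(
            step_viscera_to_bowels(tau_p, prev, params), params)
        swapped = step_viscera_to_bowels(
            step_bowels_to_viscera(tau_p, params), prev, params)
        assert canonical != swapped

    def test_record_stages(self, meniere_initial, params):
        traj = simulate(meniere_initial, {}, 3, params, record_stages=True)
        assert traj.stages is not None
        assert set(traj.stages.index.get_level_values("stage")) == \
               {"tau_prime", "tau_second", "tau_hat"}


class TestCpnMode:
    def test_reference_net_has_one_place_per_treated_acupoint(self, reference_protocol):
        net, schedule, marking = build_net(reference_protocol)
        ap_places = [p for p in net.places if p.id.startswith("ap_")]
        assert len(ap_places) == 6
        assert all(marking.count(p.id) == 1 for p in ap_places)

    def test_empty_protocol_net_has_no_acupoint_places(self):
        net, _, marking = build_net({})
        assert not [p for p in net.places if p.id.startswith("ap_")]
        assert marking.places() == []

    def test_cpn_cycle_respects_schedule(self, meniere_initial, reference_protocol):
        net, schedule, proto_marking = build_net(reference_protocol)
        aug_net, aug = augment(net, schedule, "t_start")
        tokens = {f"p_{o}": [meniere_initial[o]] for o in reg.ALL_ORGANS}
        m0 = Marking(tokens)
        for pid in proto_marking.places():
            m0 = m0.updated(add={pid: proto_marking.tokens(pid)})
        for seed in (0, 5):
            trace = run_net(aug_net, aug.seed(m0), max_steps=60, seed=seed)
            assert verify_order(trace, schedule)

    def test_direct_and_cpn_agree_on_reference(self, meniere_initial,
                                               reference_protocol, params):
        direct = simulate(meniere_initial, reference_protocol, 12, params, mode="direct")
        cpn = simulate(meniere_initial, reference_protocol, 12, params, mode="cpn", seed=11)
        assert np.abs(direct.df.to_numpy() - cpn.df.to_numpy()).max() < 1e-9

    def test_modes_agree_with_linear_kernel(self, meniere_initial, reference_protocol):
        params = ModelParams(stimulus="linear")
        direct = simulate(meniere_initial, reference_protocol, 5, params, mode="direct")
        cpn = simulate(meniere_initial, reference_protocol, 5, params, mode="cpn")
        assert np.abs(direct.df.to_numpy() - cpn.df.to_numpy()).max() < 1e-9


class TestTrajectoryIO:
    def test_csv_round_trip(self, meniere_initial, reference_protocol, params, tmp_path):
        traj = simulate(meniere_initial, reference_protocol, 5, params)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert list(back.df.columns) == list(traj.df.columns)
        assert np.allclose(back.df.to_numpy(), traj.df.to_numpy(), atol=1e-5)
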