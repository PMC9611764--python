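import math
from dataclasses import replace

import numpy as np
import pytest

from ffr0d.network_solver import (
    CalibrationError,
    CircuitModel,
    SolverSettings,
    calibrate_distal_resistance,
    solve_circuit_closed_form,
    solve_tree,
    total_parallel_Rt,
)
from ffr0d.stenosis_model import StenosisModel
from ffr0d.vessel_model import (
    LumenProfile,
    OutletSpec,
    SideBranchSpec,
    VesselTree,
    mmhg_to_pa,
)

V90 = mmhg_to_pa(90.0)


class TestParallelRt:
    def test_equal_and_dominated(self):
        assert total_parallel_Rt(4.0, 4.0) == pytest.approx(2.0, rel=1e-15)
        assert total_parallel_Rt(1e10, 1e20) == pytest.approx(1e10, rel=1e-9)

    def test_murray_one_third_branch(self):
        # branch at one third the main diameter: R2 = 27 R1
        assert total_parallel_Rt(1e10, 2.7e11) == pytest.approx(9.643e9, rel=1e-3)


class TestClosedFormCircuit:
    def test_equal_divider_gives_half(self):
        m = CircuitModel(
            inlet_pressure=V90, stenosis=StenosisModel(1e10, 0.0), R1=1e10
        )
        assert solve_circuit_closed_form(m).ffr == pytest.approx(0.5, rel=1e-12)

    def test_no_branch_fixture_against_independent_quadratic(self):
        """Oracle: the stenosis-flow quadratic solved with numpy.roots."""
        c1, c2, r1 = 1e9, 1e12, 1e10
        m = CircuitModel(inlet_pressure=V90, stenosis=StenosisModel(c1, c2), R1=r1)
        sol = solve_circuit_closed_form(m)
        roots = np.roots([c2, c1 + r1, -V90])
        q_oracle = float(roots[roots > 0][0])
        assert sol.stenosis_flow == pytest.approx(q_oracle, rel=1e-10)
        assert sol.stenosis_flow == pytest.approx(1.0909e-6, rel=1e-3)
        assert sol.ffr == pytest.approx(r1 * q_oracle / V90, rel=1e-10)
        assert sol.ffr == pytest.approx(0.909, rel=1e-3)

    def test_upstream_branch_leaves_ffr_bitwise_unchanged(self):
        sten = StenosisModel(1e9, 1e12)
        none = solve_circuit_closed_form(
            CircuitModel(inlet_pressure=V90, stenosis=sten, R1=1e10)
        )
        up = solve_circuit_closed_form(
            CircuitModel(
                inlet_pressure=V90, stenosis=sten, R1=1e10, R2=2e10,
                branch_location="upstream",
            )
        )
        assert up.ffr == none.ffr
        assert up.main_outlet_flow == none.main_outlet_flow
        # the branch draws V/R2 straight from the inlet
        assert up.branch_flow == pytest.approx(V90 / 2e10, rel=1e-14)
        assert up.inlet_flow == pytest.approx(none.inlet_flow + V90 / 2e10, rel=1e-14)

    def test_downstream_branch_lowers_ffr(self):
        sten = StenosisModel(1e9, 1e12)
        none = solve_circuit_closed_form(
            CircuitModel(inlet_pressure=V90, stenosis=sten, R1=1e10)
        )
        down = solve_circuit_closed_form(
            CircuitModel(
                inlet_pressure=V90, stenosis=sten, R1=1e10, R2=2e10,
                branch_location="downstream",
            )
        )
        assert down.ffr < none.ffr
        assert down.stenosis_flow > none.stenosis_flow

    def test_downstream_reduces_to_no_branch_as_R2_grows(self):
        sten = StenosisModel(1e9, 1e12)
        none = solve_circuit_closed_form(
            CircuitModel(inlet_pressure=V90, stenosis=sten, R1=1e10)
        )
        down = solve_circuit_closed_form(
            CircuitModel(
                inlet_pressure=V90, stenosis=sten, R1=1e10, R2=1e20,
                branch_location="downstream",
            )
        )
        assert down.ffr == pytest.approx(none.ffr, rel=1e-9)

    def test_downstream_monotone_in_branch_size(self):
        """Smaller R2 (bigger branch): lower FFR, higher stenosis flow."""
        sten = StenosisModel(1e9, 1e12)
        ffrs, flows = [], []
        for r2 in (1e11, 3e10, 1e10, 3e9):
            sol = solve_circuit_closed_form(
                CircuitModel(
                    inlet_pressure=V90, stenosis=sten, R1=1e10, R2=r2,
                    branch_location="downstream",
                )
            )
            ffrs.append(sol.ffr)
            flows.append(sol.stenosis_flow)
        assert all(a > b for a, b in zip(ffrs, ffrs[1:]))
        assert all(a < b for a, b in zip(flows, flows[1:]))

    def test_upstream_branch_size_changes_inlet_flow_only(self):
        sten = StenosisModel(1e9, 1e12)
        sols = [
            solve_circuit_closed_form(
                CircuitModel(
                    inlet_pressure=V90, stenosis=sten, R1=1e10, R2=r2,
                    branch_location="upstream",
                )
            )
            for r2 in (1e11, 1e10, 3e9)
        ]
        assert len({s.ffr for s in sols}) == 1
        inflows = [s.inlet_flow for s in sols]
        assert all(a < b for a, b in zip(inflows, inflows[1:]))


def _two_point_tree(r_out: float, d: float = 3e-3, length: float = 0.05) -> VesselTree:
    s = np.linspace(0.0, length, 11)
    return VesselTree(
        main_vessel=LumenProfile(s, np.full(s.size, d)),
        stenoses=[],
        side_branches=[],
        inlet_pressure_P_in=V90,
        main_outlet=OutletSpec(r_out),
    )


class TestSolveTree:
    def test_single_segment_ohms_law(self):
        from ffr0d.vessel_model import poiseuille_resistance

        r_out = 1e10
        tree = _two_point_tree(r_out)
        sol = solve_tree(tree, SolverSettings())
        r_seg = poiseuille_resistance(0.05, 3e-3, 0.0035)
        assert sol.inlet_flow == pytest.approx(V90 / (r_out + r_seg), rel=1e-9)
        sol_neglect = solve_tree(tree, SolverSettings(neglect_healthy_resistance=True))
        assert sol_neglect.inlet_flow == pytest.approx(V90 / r_out, rel=1e-9)

    def test_matches_closed_form_on_all_three_fixtures(
        self, model1, model2, model3, neglect_settings
    ):
        from ffr0d.network_solver import compile_network

        for tree, loc in ((model1, "none"), (model2, "upstream"), (model3, "downstream")):
            net = compile_network(tree, neglect_settings)
            sten = next(m for e in net.main_edges for m in e.stenoses)
            r2 = tree.side_branches[0].outlet.resistance_R_out if tree.side_branches else None
            circuit = CircuitModel(
                inlet_pressure=tree.inlet_pressure_P_in,
                stenosis=sten,
                R1=tree.main_outlet.resistance_R_out,
                R2=r2,
                branch_location=loc,
            )
            oracle = solve_circuit_closed_form(circuit)
            sol = solve_tree(tree, neglect_settings)
            assert sol.distal_ffr == pytest.approx(oracle.ffr, rel=1e-8)
            assert sol.inlet_flow == pytest.approx(oracle.inlet_flow, rel=1e-8)
            assert sol.main_section_flows[-1] == pytest.approx(
                oracle.main_outlet_flow, rel=1e-8
            )

    def test_upstream_branch_preserves_outlet_flow(self, model1, model2, neglect_settings):
        q1 = solve_tree(model1, neglect_settings).main_section_flows[-1]
        q2 = solve_tree(model2, neglect_settings).main_section_flows[-1]
        assert abs(q1 - q2) / q1 < 1e-10

    def test_flow_conservation_at_every_junction(self, model3, neglect_settings):
        sol = solve_tree(model3, neglect_settings)
        assert sol.converged
        assert sol.residual < 1e-10
        assert sol.inlet_flow == pytest.approx(
            sol.main_section_flows[-1] + sol.branch_flows.sum(), rel=1e-12
        )

    def test_adding_a_branch_lowers_total_resistance(self, model1, model3, neglect_settings):
        r_no = V90 / solve_tree(model1, neglect_settings).inlet_flow
        r_with = V90 / solve_tree(model3, neglect_settings).inlet_flow
        assert r_with < r_no

    def test_ffr_in_unit_interval_and_nonincreasing(self, model3):
        sol = solve_tree(model3, SolverSettings())
        names = ["inlet", "junction_1", "main_outlet"]
        ffrs = [sol.ffr_at(n) for n in names]
        assert all(0.0 < f <= 1.0 for f in ffrs)
        assert all(a >= b for a, b in zip(ffrs, ffrs[1:]))


class TestCalibration:
    def test_round_trip_recovers_resistance(self, model3, neglect_settings):
        target = solve_tree(model3, neglect_settings).distal_ffr
        r1 = calibrate_distal_resistance(model3, target, neglect_settings)
        truth = model3.main_outlet.resistance_R_out
        assert abs(r1 - truth) / truth < 1e-3

    def test_equal_divider_closed_form(self, straight_profile, reference_stenosis):
        """With C2 = 0, FFR = 0.5 forces R1 = C1 exactly."""
        from ffr0d.network_solver import compile_network

        tree = VesselTree(
            main_vessel=straight_profile,
            stenoses=[reference_stenosis],
            side_branches=[],
            inlet_pressure_P_in=V90,
            main_outlet=OutletSpec(1e10),
        )
        settings = SolverSettings(neglect_healthy_resistance=True, rho=1050.0, Kt=0.0)
        net = compile_network(tree, settings)
        c1 = net.main_edges[0].stenoses[0].C1
        r1 = calibrate_distal_resistance(tree, 0.5, settings)
        assert r1 == pytest.approx(c1, rel=1e-6)

    def test_unreachable_target_raises(self, neglect_settings):
        # no stenosis: FFR is 1 for every distal resistance
        tree = _two_point_tree(1e10)
        with pytest.raises(CalibrationError):
            calibrate_distal_resistance(tree, 0.8, neglect_settings)

    def test_invalid_target_rejected(self, model1, neglect_settings):
        with pytest.raises(ValueError):
            calibrate_distal_resistance(model1, 1.5, neglect_settings)
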