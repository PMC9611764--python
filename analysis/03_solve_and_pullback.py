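#!/usr/bin/env python
"""Solve the three idealized vessel trees and trace virtual FFR pullbacks.

Runs the network solver on each model (healthy-wall resistance neglected,
matching the circuit idealization), verifies the solutions against the
closed-form circuits, and writes a pullback curve per model.
"""

import csv
from pathlib import Path

from ffr0d import (
    CircuitModel,
    IdealizedFixtureSpec,
    SolverSettings,
    make_idealized,
    solve_circuit_closed_form,
    solve_tree,
    virtual_pullback,
)
from ffr0d.network_solver import compile_network
from ffr0d.synthetic_data import VARIANTS
from ffr0d.vessel_model import m3s_to_ml_min, pa_to_mmhg

OUT = Path(__file__).resolve().parent.parent / "results"
LOC = {"model1_no_branch": "none", "model2_upstream": "upstream", "model3_downstream": "downstream"}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    settings = SolverSettings(neglect_healthy_resistance=True)
    for variant in VARIANTS:
        tree = make_idealized(IdealizedFixtureSpec(variant=variant))
        sol = solve_tree(tree, settings)
        net = compile_network(tree, settings)
        sten = next(m for e in net.main_edges for m in e.stenoses)
        oracle = solve_circuit_closed_form(
            CircuitModel(
                inlet_pressure=tree.inlet_pressure_P_in,
                stenosis=sten,
                R1=tree.main_outlet.resistance_R_out,
                R2=tree.side_branches[0].outlet.resistance_R_out
                if tree.side_branches
                else None,
                branch_location=LOC[variant],
            )
        )
        rel = abs(sol.distal_ffr - oracle.ffr) / oracle.ffr
        print(
            f"{variant}: FFR={sol.distal_ffr:.4f} "
            f"inlet={m3s_to_ml_min(sol.inlet_flow):.1f} mL/min "
            f"outlet={m3s_to_ml_min(sol.main_section_flows[-1]):.1f} mL/min "
            f"(closed-form agreement {rel:.1e})"
        )
        curve = virtual_pullback(tree, sol, settings=settings)
        path = OUT / f"pullback_{variant}.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["s_mm", "FFR", "pressure_mmHg"])
            for s, f, p in zip(curve.arc_length, curve.ffr, curve.pressure):
                w.writerow([round(s * 1e3, 4), f, pa_to_mmhg(p)])
        print(f"  wrote {path}")


if __name__ == "__main__":
    main()
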