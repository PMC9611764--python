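"""Headline analyses: virtual FFR pullbacks, with/without-branch
comparisons, and Murray's-law flow-distribution checks.

A virtual pullback traces FFR(s) = P(s)/P_in along the main vessel of a
solved tree, mimicking the translation of a pressure-wire sensor.  The
with/without comparison quantifies the error committed by reconstructing
a vessel without its side branches while keeping the same distal
resistance.  Murray's law (flow proportional to diameter cubed at each
junction) provides an imaging-only estimate of the flow profile to
compare against the solved one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ffr0d.network_solver import (
    NetworkSolution,
    SolverSettings,
    compile_network,
    solve_tree,
)
from ffr0d.stenosis_model import pressure_drop
from ffr0d.vessel_model import VesselTree, _cumulative_resistance

__all__ = [
    "BranchComparison",
    "MurrayProfile",
    "PullbackCurve",
    "compare_with_without",
    "flow_profile_discrepancy",
    "murray_flow_profile",
    "virtual_pullback",
]


@dataclass
class PullbackCurve:
    """FFR, pressure and flow versus arc length along the main vessel."""

    arc_length: np.ndarray
    ffr: np.ndarray
    pressure: np.ndarray
    flow_values: np.ndarray  # per inter-junction section
    section_bounds: np.ndarray  # node positions delimiting the sections


@dataclass
class BranchComparison:
    """Paired solutions of a tree with and without its side branches.

    ``delta_ffr = ffr_without - ffr_with`` is positive when ignoring the
    branches overestimates FFR (the typical downstream-branch case).
    """

    ffr_with: float
    ffr_without: float
    delta_ffr: float
    inlet_flow_with: float
    inlet_flow_without: float
    section_flows_with: np.ndarray
    section_flows_without: np.ndarray
    solution_with: NetworkSolution
    solution_without: NetworkSolution


@dataclass
class MurrayProfile:
    """Flow profile predicted by Murray's law from diameters alone."""

    section_flows: np.ndarray
    branch_flows: np.ndarray


def virtual_pullback(
    tree: VesselTree,
    solution: NetworkSolution,
    step: float = 0.2e-3,
    settings: SolverSettings = SolverSettings(),
) -> PullbackCurve:
    """Sample FFR(s) along the main vessel of a solved tree.

    Within each inter-junction section the pressure falls by the local
    viscous gradient (zero when healthy resistance is neglected) and, across
    each stenosis, by the lumped drop ``C1 q + C2 q^2`` distributed along
    the lesion in proportion to the local ``d(s)^-4`` weight, so the drop
    concentrates at the throat.  FFR starts at exactly 1 at the inlet and
    is monotone non-increasing.
    """
    if not solution.converged:
        raise RuntimeError("virtual_pullback requires a converged solution")
    if step <= 0.0:
        raise ValueError("pullback step must be positive")
    net = compile_network(tree, settings)
    narrowed = net.stenosed_profile
    s0, s_end = tree.main_vessel.start, tree.main_vessel.end

    grids = [np.arange(s0, s_end, step), np.asarray([s_end]), net.node_positions]
    for edge in net.main_edges:
        for a, b in edge.stenosis_bounds:
            grids.append(np.asarray([a, b]))
    grid = np.unique(np.concatenate(grids))

    def cum(x: float) -> float:
        return _cumulative_resistance(narrowed, x, settings.mu, settings.quad_step)

    pressures = np.empty_like(grid)
    p_node = solution.inlet_pressure
    for i, edge in enumerate(net.main_edges):
        q = float(solution.main_section_flows[i])
        sel = (grid >= edge.start) & (grid <= edge.end)
        s_loc = grid[sel]
        cums = np.array([cum(x) for x in s_loc])
        # viscous d^-4 integral from the edge start; the stenotic spans are
        # removed from it and re-applied as fractions of the lumped drops
        visc = cums - cum(edge.start)
        drop = np.zeros_like(s_loc)
        for model, (a, b) in zip(edge.stenoses, edge.stenosis_bounds):
            f_a, f_b = cum(a), cum(b)
            overlap = np.clip(
                np.array([cum(min(x, b)) for x in s_loc]) - f_a, 0.0, f_b - f_a
            )
            visc -= overlap
            drop += (overlap / (f_b - f_a)) * pressure_drop(model, q)
        if settings.neglect_healthy_resistance:
            visc = np.zeros_like(s_loc)
        pressures[sel] = p_node - visc * q - drop
        p_node = pressures[sel][-1]

    pressures[0] = solution.inlet_pressure
    ffr = pressures / solution.inlet_pressure
    ffr[0] = 1.0
    return PullbackCurve(
        arc_length=grid,
        ffr=ffr,
        pressure=pressures,
        flow_values=solution.main_section_flows.copy(),
        section_bounds=net.node_positions.copy(),
    )


def compare_with_without(
    tree: VesselTree, settings: SolverSettings = SolverSettings()
) -> BranchComparison:
    """Solve a tree with its side branches and a pruned copy without them.

    The pruned copy keeps the identical distal main-vessel resistance —
    the same convention used when a calibrated resistance is re-imposed on
    a branchless reconstruction — so the difference isolates the effect of
    side-branch flow.
    """
    if not tree.side_branches:
        raise ValueError("tree has no side branches to compare against")
    sol_with = solve_tree(tree, settings)
    pruned = replace(tree, side_branches=[])
    sol_without = solve_tree(pruned, settings)
    return BranchComparison(
        ffr_with=sol_with.distal_ffr,
        ffr_without=sol_without.distal_ffr,
        delta_ffr=sol_without.distal_ffr - sol_with.distal_ffr,
        inlet_flow_with=sol_with.inlet_flow,
        inlet_flow_without=sol_without.inlet_flow,
        section_flows_with=sol_with.main_section_flows.copy(),
        section_flows_without=sol_without.main_section_flows.copy(),
        solution_with=sol_with,
        solution_without=sol_without,
    )


def murray_flow_profile(tree: VesselTree, inlet_flow: float) -> MurrayProfile:
    """Flow profile implied by Murray's law (Q proportional to d^3).

    Walking the junctions proximal to distal, the incoming flow is split
    between the side branch (its ostium diameter cubed) and the main-vessel
    continuation (the healthy main diameter immediately distal to the
    junction, cubed).  Requires no pressures or resistances — diameters
    only — which is what makes it usable directly from imaging.
    """
    if inlet_flow <= 0.0:
        raise ValueError("inlet flow must be positive")
    q = inlet_flow
    section_flows = [q]
    branch_flows = []
    for br in tree.side_branches:
        d_main = float(tree.main_vessel.diameter_at(br.attach_position))
        if d_main <= 0.0 or br.diameter <= 0.0:
            raise ValueError("zero diameter at a junction")
        w_branch = br.diameter**3
        w_main = d_main**3
        q_branch = q * w_branch / (w_branch + w_main)
        q = q - q_branch
        branch_flows.append(q_branch)
        section_flows.append(q)
    return MurrayProfile(
        section_flows=np.asarray(section_flows),
        branch_flows=np.asarray(branch_flows),
    )


def flow_profile_discrepancy(solver_flows, murray_flows) -> float:
    """Mean relative difference (murray - solver) / murray over sections."""
    solver_flows = np.asarray(solver_flows, dtype=float)
    murray_flows = np.asarray(murray_flows, dtype=float)
    if solver_flows.shape != murray_flows.shape:
        raise ValueError(
            f"profile shapes differ: {solver_flows.shape} vs {murray_flows.shape}"
        )
    return float(np.mean((murray_flows - solver_flows) / murray_flows))
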