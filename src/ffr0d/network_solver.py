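"""Steady 0D network solutions for vessel trees and idealized circuits.

Pressure plays the role of voltage and volumetric flow the role of
current.  Two solution paths are provided:

* :func:`solve_circuit_closed_form` — the three-element idealized circuit
  (inlet pressure source, stenosis resistor ``R(q) = C1 + C2 q``, distal
  resistances ``R1`` and optionally ``R2``) solved analytically via the
  positive root of ``C2 q^2 + (C1 + R) q - V = 0``.
* :func:`solve_tree` — an arbitrary single-main-vessel tree solved by
  damped fixed-point iteration: stenosis resistances are frozen at the
  current flows, the resulting linear resistive tree is reduced exactly by
  series/parallel elimination, flows are updated, and the loop repeats
  until the flow field is stationary.

Both report distal FFR as the ratio of main-outlet pressure to inlet
pressure, the clinical definition under hyperemia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from ffr0d.stenosis_model import (
    StenosisModel,
    default_coefficients,
    flow_resistance,
    pressure_drop,
)
from ffr0d.structured_tree import parallel
from ffr0d.vessel_model import (
    DEFAULT_QUAD_STEP,
    LumenProfile,
    VesselTree,
    segment_viscous_resistance,
)

__all__ = [
    "CircuitModel",
    "CircuitSolution",
    "ConvergenceError",
    "CalibrationError",
    "NetworkSolution",
    "SolverSettings",
    "calibrate_distal_resistance",
    "solve_circuit_closed_form",
    "solve_tree",
    "total_parallel_Rt",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


class CalibrationError(RuntimeError):
    """Distal-resistance calibration could not reach the target FFR."""


@dataclass(frozen=True)
class SolverSettings:
    """Physical constants and numerical tolerances for the tree solver.

    ``mu`` is the effective blood viscosity used for vessel-wall friction
    (default the Carreau infinite-shear plateau, 0.0035 Pa s), ``rho`` the
    blood density and ``Kt`` the stenosis expansion coefficient.  With
    ``neglect_healthy_resistance`` the non-stenotic main vessel is treated
    as lossless, reproducing the idealized circuit analysis exactly.
    """

    mu: float = 0.0035
    rho: float = 1050.0
    Kt: float = 1.52
    neglect_healthy_resistance: bool = False
    tol: float = 1e-10
    max_iter: int = 200
    damping: float = 0.5
    quad_step: float = DEFAULT_QUAD_STEP

    def __post_init__(self) -> None:
        if self.mu <= 0.0 or self.rho <= 0.0 or self.Kt < 0.0:
            raise ValueError("mu and rho must be positive, Kt non-negative")
        if self.tol <= 0.0 or self.max_iter < 1:
            raise ValueError("invalid solver tolerances")
        if not (0.0 < self.damping <= 1.0):
            raise ValueError("damping must lie in (0, 1]")


def total_parallel_Rt(R1: float, R2: float) -> float:
    """Total distal resistance ``R1 R2 / (R1 + R2)`` of main vessel and a
    downstream side branch in parallel."""
    return parallel(R1, R2)


# ---------------------------------------------------------------------------
# Idealized circuits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircuitModel:
    """The idealized stenosed-artery circuit.

    ``branch_location`` selects the topology: ``none`` (stenosis in series
    with distal resistance ``R1``), ``upstream`` (side-branch resistance
    ``R2`` taps the inlet node before the stenosis) or ``downstream``
    (``R2`` parallels ``R1`` behind the stenosis).
    """

    inlet_pressure: float
    stenosis: StenosisModel
    R1: float
    R2: float | None = None
    branch_location: Literal["none", "upstream", "downstream"] = "none"

    def __post_init__(self) -> None:
        if self.inlet_pressure <= 0.0:
            raise ValueError("inlet pressure must be positive")
        if self.R1 <= 0.0:
            raise ValueError("R1 must be positive")
        if self.branch_location not in ("none", "upstream", "downstream"):
            raise ValueError(f"unknown branch_location {self.branch_location!r}")
        if self.branch_location == "none":
            if self.R2 is not None:
                raise ValueError("R2 must be absent when there is no branch")
        elif self.R2 is None or self.R2 <= 0.0:
            raise ValueError("R2 must be positive when a branch is present")


@dataclass(frozen=True)
class CircuitSolution:
    """Closed-form solution of an idealized circuit."""

    ffr: float
    stenosis_flow: float
    inlet_flow: float
    main_outlet_flow: float
    branch_flow: float
    distal_pressure: float


def _positive_quadratic_root(c2: float, b: float, v: float) -> float:
    """Positive root of ``c2 q^2 + b q - v = 0`` with ``b, v > 0``.

    Uses the cancellation-free form ``q = 2 v / (b + sqrt(b^2 + 4 c2 v))``.
    """
    disc = b * b + 4.0 * c2 * v
    if disc < 0.0:  # impossible for positive parameters
        raise ArithmeticError("stenosis flow equation has no positive root")
    return 2.0 * v / (b + math.sqrt(disc))


def solve_circuit_closed_form(model: CircuitModel) -> CircuitSolution:
    """Analytic pressures, flows and FFR of the idealized circuit.

    For no branch or an upstream branch, the stenosis is in series with
    ``R1`` only, so the stenosis flow solves
    ``C2 q^2 + (C1 + R1) q = V`` and ``FFR = R1 q / V``; an upstream branch
    draws ``V / R2`` directly from the inlet and leaves FFR untouched.
    For a downstream branch, ``R1`` is replaced by
    ``Rt = R1 R2 / (R1 + R2)``, which both raises trans-stenotic flow
    (hence ``R(q)``) and shrinks the pressure-divider ratio — the two
    mechanisms by which a downstream branch depresses FFR.
    """
    v = model.inlet_pressure
    c1, c2 = model.stenosis.C1, model.stenosis.C2
    loc = model.branch_location

    r_distal = model.R1 if loc in ("none", "upstream") else total_parallel_Rt(
        model.R1, model.R2
    )
    q = _positive_quadratic_root(c2, c1 + r_distal, v)
    distal_pressure = r_distal * q
    ffr = distal_pressure / v

    if loc == "none":
        branch_flow = 0.0
        inlet_flow = q
        main_outlet_flow = q
    elif loc == "upstream":
        branch_flow = v / model.R2
        inlet_flow = q + branch_flow
        main_outlet_flow = q
    else:  # downstream
        branch_flow = distal_pressure / model.R2
        inlet_flow = q
        main_outlet_flow = distal_pressure / model.R1

    return CircuitSolution(
        ffr=ffr,
        stenosis_flow=q,
        inlet_flow=inlet_flow,
        main_outlet_flow=main_outlet_flow,
        branch_flow=branch_flow,
        distal_pressure=distal_pressure,
    )


# ---------------------------------------------------------------------------
# General vessel trees
# ---------------------------------------------------------------------------


@dataclass
class _MainEdge:
    """One inter-junction span of the main vessel."""

    start: float
    end: float
    R0: float  # linear (healthy-wall) resistance
    stenoses: list[StenosisModel]
    stenosis_bounds: list[tuple[float, float]]

    def resistance_at(self, q: float) -> float:
        return self.R0 + sum(flow_resistance(m, q) for m in self.stenoses)

    def pressure_drop_at(self, q: float) -> float:
        return self.R0 * q + sum(pressure_drop(m, q) for m in self.stenoses)


@dataclass
class CompiledNetwork:
    """Solver-ready circuit extracted from a :class:`VesselTree`."""

    node_positions: np.ndarray  # inlet, junctions..., main outlet
    main_edges: list[_MainEdge]
    branch_resistances: list[float]  # one per junction
    branch_labels: list[str]
    main_outlet_resistance: float
    inlet_pressure: float
    stenosed_profile: LumenProfile


def compile_network(tree: VesselTree, settings: SolverSettings) -> CompiledNetwork:
    """Reduce a vessel tree to node positions, edge resistances and
    stenosis models.  A stenotic interval must not straddle a junction."""
    positions = (
        [tree.main_vessel.start]
        + [b.attach_position for b in tree.side_branches]
        + [tree.main_vessel.end]
    )
    narrowed = tree.stenosed_profile(settings.quad_step)
    sten_models = {
        id(s): default_coefficients(
            tree.main_vessel,
            s,
            mu=settings.mu,
            rho=settings.rho,
            Kt=settings.Kt,
            step=settings.quad_step,
        )
        for s in tree.stenoses
    }
    edges: list[_MainEdge] = []
    for a, b in zip(positions, positions[1:]):
        inside = [s for s in tree.stenoses if s.start >= a and s.end <= b]
        for s in tree.stenoses:
            if s not in inside and (a < s.start < b or a < s.end < b):
                raise ValueError(
                    "a stenotic interval straddles a junction; refine the tree"
                )
        if settings.neglect_healthy_resistance:
            r0 = 0.0
        else:
            r0 = 0.0
            cursor = a
            for s in sorted(inside, key=lambda s: s.start):
                if s.start > cursor:
                    r0 += segment_viscous_resistance(
                        narrowed, settings.mu, cursor, s.start, step=settings.quad_step
                    )
                cursor = s.end
            if b > cursor:
                r0 += segment_viscous_resistance(
                    narrowed, settings.mu, cursor, b, step=settings.quad_step
                )
        edges.append(
            _MainEdge(
                start=a,
                end=b,
                R0=r0,
                stenoses=[sten_models[id(s)] for s in inside],
                stenosis_bounds=[(s.start, s.end) for s in inside],
            )
        )
    return CompiledNetwork(
        node_positions=np.asarray(positions),
        main_edges=edges,
        branch_resistances=[b.outlet.resistance_R_out for b in tree.side_branches],
        branch_labels=[b.outlet.label for b in tree.side_branches],
        main_outlet_resistance=tree.main_outlet.resistance_R_out,
        inlet_pressure=tree.inlet_pressure_P_in,
        stenosed_profile=narrowed,
    )


@dataclass
class NetworkSolution:
    """Converged pressures and flows of a solved vessel tree.

    ``main_section_flows[i]`` is the flow in the i-th inter-junction span
    of the main vessel (section 0 carries the inlet flow);
    ``branch_flows[j]`` the flow into the j-th side branch.  Node keys are
    ``inlet``, ``junction_1`` ... and ``main_outlet``.
    """

    node_pressures: dict[str, float]
    node_positions: dict[str, float]
    segment_flows: dict[str, float]
    main_section_flows: np.ndarray
    branch_flows: np.ndarray
    inlet_flow: float
    inlet_pressure: float
    converged: bool
    iterations: int
    residual: float

    @property
    def distal_ffr(self) -> float:
        return self.node_pressures["main_outlet"] / self.inlet_pressure

    def ffr_at(self, node: str) -> float:
        return self.node_pressures[node] / self.inlet_pressure


def _linear_solve(
    net: CompiledNetwork, q_frozen: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the tree exactly with stenosis resistances frozen at
    ``q_frozen``; returns (main flows, branch flows, node pressures)."""
    n_j = len(net.branch_resistances)
    r_edge = np.array(
        [e.resistance_at(q_frozen[i]) for i, e in enumerate(net.main_edges)]
    )
    # downstream equivalent resistance seen from each node
    d_eq = np.empty(n_j + 2)
    d_eq[n_j + 1] = net.main_outlet_resistance
    for j in range(n_j, 0, -1):
        series = r_edge[j] + d_eq[j + 1]
        d_eq[j] = parallel(net.branch_resistances[j - 1], series)
    d_eq[0] = r_edge[0] + d_eq[1]

    pressures = np.empty(n_j + 2)
    pressures[0] = net.inlet_pressure
    q_main = np.empty(n_j + 1)
    q_branch = np.empty(n_j)
    q_main[0] = net.inlet_pressure / d_eq[0]
    for j in range(1, n_j + 1):
        pressures[j] = pressures[j - 1] - r_edge[j - 1] * q_main[j - 1]
        q_branch[j - 1] = pressures[j] / net.branch_resistances[j - 1]
        q_main[j] = pressures[j] / (r_edge[j] + d_eq[j + 1])
    pressures[n_j + 1] = pressures[n_j] - r_edge[n_j] * q_main[n_j]
    return q_main, q_branch, pressures


def solve_tree(tree: VesselTree, settings: SolverSettings = SolverSettings()) -> NetworkSolution:
    """Solve steady flow in a vessel tree by damped fixed-point iteration.

    Each iteration freezes every stenosis at its current flow, reduces the
    resulting linear resistive tree exactly, and relaxes the main-vessel
    flows toward the new solution with the configured damping factor.
    Convergence is declared when the largest relative flow change drops
    below ``settings.tol``; a final undamped solve then produces an
    exactly flow-conserving state.
    """
    net = compile_network(tree, settings)
    n_edges = len(net.main_edges)
    q = np.zeros(n_edges)
    history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, settings.max_iter + 1):
        q_new, _, _ = _linear_solve(net, q)
        q_next = q + settings.damping * (q_new - q)
        change = float(np.max(np.abs(q_next - q) / np.maximum(np.abs(q_new), 1e-300)))
        history.append(change)
        q = q_next
        if change < settings.tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"tree solve did not converge in {settings.max_iter} iterations "
            f"(last relative change {history[-1]:.3e})",
            history,
        )
    # consistent (exactly conserving) final state at the converged flows
    q_main, q_branch, pressures = _linear_solve(net, q)
    # nonlinear pressure reconstruction at the final flows
    p = np.empty_like(pressures)
    p[0] = net.inlet_pressure
    for i, edge in enumerate(net.main_edges):
        p[i + 1] = p[i] - edge.pressure_drop_at(q_main[i])

    n_j = len(net.branch_resistances)
    node_names = ["inlet"] + [f"junction_{j}" for j in range(1, n_j + 1)] + ["main_outlet"]
    node_pressures = dict(zip(node_names, map(float, p)))
    node_positions = dict(zip(node_names, map(float, net.node_positions)))
    segment_flows: dict[str, float] = {
        f"main_{i}": float(q_main[i]) for i in range(n_j + 1)
    }
    for j in range(n_j):
        segment_flows[f"branch_{j + 1}"] = float(q_branch[j])

    # relative flow-conservation residual at each junction
    residual = 0.0
    for j in range(n_j):
        imbalance = q_main[j] - q_branch[j] - q_main[j + 1]
        residual = max(residual, abs(imbalance) / q_main[j])

    return NetworkSolution(
        node_pressures=node_pressures,
        node_positions=node_positions,
        segment_flows=segment_flows,
        main_section_flows=q_main,
        branch_flows=q_branch,
        inlet_flow=float(q_main[0]),
        inlet_pressure=net.inlet_pressure,
        converged=converged,
        iterations=iterations,
        residual=float(residual),
    )


def calibrate_distal_resistance(
    tree: VesselTree,
    measured_FFR: float,
    settings: SolverSettings = SolverSettings(),
    bracket: tuple[float, float] = (1e6, 1e16),
    ffr_tol: float = 1e-6,
) -> float:
    """Find the main-outlet resistance that reproduces a measured FFR.

    Distal FFR increases monotonically with the distal resistance (a
    larger R1 shrinks flow, hence the trans-stenotic drop), so a root
    bracketed on ``log10 R1`` is found with Brent's method.  Side-branch
    resistances are held fixed, mirroring the clinical workflow where the
    pressure-wire measurement constrains only the main-vessel bed.
    """
    if not (0.0 < measured_FFR < 1.0):
        raise ValueError("measured FFR must lie strictly between 0 and 1")

    def ffr_for(r1: float) -> float:
        trial = replace(tree, main_outlet=replace(tree.main_outlet, resistance_R_out=r1))
        return solve_tree(trial, settings).distal_ffr

    lo, hi = math.log10(bracket[0]), math.log10(bracket[1])
    f_lo = ffr_for(10.0**lo) - measured_FFR
    f_hi = ffr_for(10.0**hi) - measured_FFR
    if f_lo * f_hi > 0.0:
        raise CalibrationError(
            f"target FFR {measured_FFR} not bracketed in R1 range {bracket} "
            f"(FFR at ends: {f_lo + measured_FFR:.6f}, {f_hi + measured_FFR:.6f})"
        )
    log_r = brentq(lambda x: ffr_for(10.0**x) - measured_FFR, lo, hi, xtol=1e-12)
    r1 = 10.0**log_r
    if abs(ffr_for(r1) - measured_FFR) > ffr_tol:
        raise CalibrationError("root-find did not reach the target FFR tolerance")
    return r1
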