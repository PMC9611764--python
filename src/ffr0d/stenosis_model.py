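"""Nonlinear stenosis resistor.

A stenosis is modelled as the quadratic pressure-drop law
``dP = C1 q + C2 q^2``: the linear term is the viscous loss through the
narrowed lumen and the quadratic term the irreversible expansion
(Borda-Carnot) loss where the jet re-expands distal to the throat.  The
flow-dependent resistance is therefore ``R(q) = C1 + C2 q`` — the higher
the flow, the stiffer the stenosis, which is why a downstream side branch
(which raises trans-stenotic flow) lowers FFR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ffr0d.vessel_model import (
    DEFAULT_QUAD_STEP,
    LumenProfile,
    StenosisSpec,
    apply_stenoses,
    segment_viscous_resistance,
)

__all__ = [
    "StenosisModel",
    "calibrate_coefficients",
    "default_coefficients",
    "flow_resistance",
    "pressure_drop",
]


@dataclass(frozen=True)
class StenosisModel:
    """Coefficients of the quadratic stenosis pressure-drop law.

    ``C1`` (Pa s m^-3) multiplies flow; ``C2`` (Pa s^2 m^-6) multiplies
    flow squared.  Both depend only on lesion geometry and blood
    properties.
    """

    C1: float
    C2: float

    def __post_init__(self) -> None:
        if self.C1 < 0.0 or self.C2 < 0.0:
            raise ValueError("stenosis coefficients must be non-negative")
        if self.C1 == 0.0 and self.C2 == 0.0:
            raise ValueError("C1 and C2 cannot both be zero")


def pressure_drop(model: StenosisModel, q: float) -> float:
    """Pressure drop ``C1 q + C2 q^2`` across the stenosis at flow ``q``."""
    if q < 0.0:
        raise ValueError("reverse flow through a stenosis is out of model scope")
    return model.C1 * q + model.C2 * q * q


def flow_resistance(model: StenosisModel, q: float) -> float:
    """Flow-dependent resistance ``R(q) = C1 + C2 q`` of the stenosis."""
    if q < 0.0:
        raise ValueError("reverse flow through a stenosis is out of model scope")
    return model.C1 + model.C2 * q


def default_coefficients(
    profile: LumenProfile,
    sten: StenosisSpec,
    mu: float,
    rho: float = 1050.0,
    Kt: float = 1.52,
    step: float = DEFAULT_QUAD_STEP,
) -> StenosisModel:
    """Geometric default coefficients for a stenosis on a healthy profile.

    ``C1`` is the Poiseuille resistance of the tapered lumen integrated
    over the stenotic interval (quadrature at ``step``), i.e. the viscous
    loss.  ``C2`` follows the classical sudden-expansion decomposition

        C2 = Kt rho / 2 * (1/A_s - 1/A_0)^2

    with ``A_0`` the healthy lumen area at the lesion centre, ``A_s`` the
    minimum lumen area, and ``Kt`` an empirical expansion coefficient
    (default 1.52).
    """
    if sten.start < profile.start or sten.end > profile.end:
        raise ValueError("stenosis lies outside the lumen profile")
    a0 = float(profile.area_at(sten.center_position))
    a_s = sten.area_ratio * a0
    narrowed = apply_stenoses(profile, [sten], resample_step=step)
    c1 = segment_viscous_resistance(narrowed, mu, sten.start, sten.end, step=step)
    c2 = 0.5 * Kt * rho * (1.0 / a_s - 1.0 / a0) ** 2
    return StenosisModel(C1=c1, C2=c2)


def calibrate_coefficients(
    observations: list[tuple[float, float]],
) -> StenosisModel:
    """Fit (C1, C2) to two measured (flow, pressure-drop) pairs.

    Solves the 2x2 linear system ``dP_i = C1 q_i + C2 q_i^2`` exactly.
    Lets a user match an external CFD or pressure-wire characterisation of
    a lesion instead of the geometric defaults.
    """
    if len(observations) != 2:
        raise ValueError("exactly two (q, dP) observations are required")
    (q1, dp1), (q2, dp2) = observations
    if q1 <= 0.0 or q2 <= 0.0:
        raise ValueError("observation flows must be positive")
    if q1 == q2:
        raise ValueError("observation flows must be distinct")
    a = np.array([[q1, q1 * q1], [q2, q2 * q2]])
    c1, c2 = np.linalg.solve(a, np.array([dp1, dp2]))
    if c1 < 0.0 or c2 < 0.0:
        raise ValueError(
            f"calibration produced a non-physical coefficient (C1={c1:g}, C2={c2:g})"
        )
    return StenosisModel(C1=float(c1), C2=float(c2))
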