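"""Domain types for vessel trees and primitive hydraulic quantities.

All quantities inside the package are strictly SI: metres, pascals,
m^3 s^-1 and Pa s m^-3.  Clinical units (mm, mmHg, mL/min) appear only at
I/O boundaries through the conversion helpers defined here.

The hydraulic primitives are the Carreau shear-thinning viscosity law,
the Hagen-Poiseuille resistance of a straight segment, and the viscous
resistance of a segment with an arbitrary lumen-diameter profile obtained
by quadrature of ``128 mu / (pi d(s)^4)`` along the centerline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMHG_TO_PA",
    "ML_MIN_TO_M3_S",
    "CarreauParams",
    "LumenProfile",
    "OutletSpec",
    "SideBranchSpec",
    "StenosisSpec",
    "VesselTree",
    "apply_stenoses",
    "carreau_viscosity",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "m3s_to_ml_min",
    "ml_min_to_m3s",
    "poiseuille_resistance",
    "segment_viscous_resistance",
]

#: Conversion factor between millimetres of mercury and pascals.
MMHG_TO_PA = 133.322

#: Conversion factor between mL/min and m^3/s.
ML_MIN_TO_M3_S = 1e-6 / 60.0

#: Default quadrature step for centerline integrals (m); 0.05 mm resolves
#: a 10 mm stenosis with 200 panels.
DEFAULT_QUAD_STEP = 0.05e-3


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert pressure from mmHg to Pa."""
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    """Convert pressure from Pa to mmHg."""
    return p_pa / MMHG_TO_PA


def ml_min_to_m3s(q: float) -> float:
    """Convert volumetric flow from mL/min to m^3/s."""
    return q * ML_MIN_TO_M3_S


def m3s_to_ml_min(q: float) -> float:
    """Convert volumetric flow from m^3/s to mL/min."""
    return q / ML_MIN_TO_M3_S


# ---------------------------------------------------------------------------
# Blood rheology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CarreauParams:
    """Carreau shear-thinning viscosity parameters for whole blood.

    Parameters
    ----------
    mu_inf
        Infinite-shear viscosity (Pa s).  Default 0.0035.
    mu_0
        Zero-shear viscosity (Pa s).  Default 0.25.
    lambda_time
        Relaxation time constant (s).  Default 25.
    n_index
        Power-law index (dimensionless, < 1 for shear thinning).
        Default 0.25.
    """

    mu_inf: float = 0.0035
    mu_0: float = 0.25
    lambda_time: float = 25.0
    n_index: float = 0.25

    def __post_init__(self) -> None:
        if not (self.mu_0 > self.mu_inf > 0.0):
            raise ValueError("require mu_0 > mu_inf > 0")
        if self.lambda_time <= 0.0:
            raise ValueError("lambda_time must be positive")
        if not (0.0 < self.n_index < 1.0):
            raise ValueError("n_index must be in (0, 1) for shear thinning")


def carreau_viscosity(shear_rate, params: CarreauParams = CarreauParams()):
    """Effective viscosity of blood at a given shear rate.

    Implements ``mu = mu_inf + (mu_0 - mu_inf) [1 + (lambda S)^2]^((n-1)/2)``.
    Accepts scalars or numpy arrays; the result lies in ``[mu_inf, mu_0]``
    and decreases monotonically with shear rate.
    """
    s = np.asarray(shear_rate, dtype=float)
    if np.any(s < 0.0):
        raise ValueError("shear_rate must be non-negative")
    mu = params.mu_inf + (params.mu_0 - params.mu_inf) * (
        1.0 + (params.lambda_time * s) ** 2
    ) ** ((params.n_index - 1.0) / 2.0)
    return float(mu) if np.isscalar(shear_rate) else mu


# ---------------------------------------------------------------------------
# Geometry types
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class LumenProfile:
    """Sampled lumen geometry along a vessel centerline.

    Attributes
    ----------
    arc_length_samples
        Strictly increasing positions along the centerline (m).
    diameter_samples
        Positive lumen diameter at each position (m).  Between samples the
        diameter is interpolated linearly.
    """

    arc_length_samples: np.ndarray
    diameter_samples: np.ndarray

    def __post_init__(self) -> None:
        self.arc_length_samples = np.asarray(self.arc_length_samples, dtype=float)
        self.diameter_samples = np.asarray(self.diameter_samples, dtype=float)
        if self.arc_length_samples.ndim != 1 or self.diameter_samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.arc_length_samples.size < 2:
            raise ValueError("a lumen profile needs at least two samples")
        if self.arc_length_samples.size != self.diameter_samples.size:
            raise ValueError("arc_length and diameter sample counts differ")
        if np.any(np.diff(self.arc_length_samples) <= 0.0):
            raise ValueError("arc_length_samples must be strictly increasing")
        if np.any(self.diameter_samples <= 0.0):
            raise ValueError("diameters must be positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LumenProfile):
            return NotImplemented
        return np.array_equal(
            self.arc_length_samples, other.arc_length_samples
        ) and np.array_equal(self.diameter_samples, other.diameter_samples)

    @property
    def start(self) -> float:
        return float(self.arc_length_samples[0])

    @property
    def end(self) -> float:
        return float(self.arc_length_samples[-1])

    @property
    def length(self) -> float:
        return self.end - self.start

    def diameter_at(self, s) -> np.ndarray | float:
        """Linearly interpolated lumen diameter at arc length ``s`` (m)."""
        d = np.interp(s, self.arc_length_samples, self.diameter_samples)
        return float(d) if np.isscalar(s) else d

    def area_at(self, s) -> np.ndarray | float:
        """Lumen cross-sectional area ``pi d^2 / 4`` at arc length ``s``."""
        d = self.diameter_at(s)
        return math.pi * d**2 / 4.0 if np.isscalar(s) else np.pi * d**2 / 4.0


@dataclass(frozen=True)
class StenosisSpec:
    """A focal narrowing on the parent vessel.

    ``area_ratio`` is the minimum lumen area divided by the healthy lumen
    area at the same location, so 0.2 means an 80 % area reduction.  The
    narrowing extends over ``length_L`` centred on ``center_position``.
    """

    center_position: float
    length_L: float
    area_ratio: float

    def __post_init__(self) -> None:
        if self.length_L <= 0.0:
            raise ValueError("stenosis length must be positive")
        if not (0.0 < self.area_ratio < 1.0):
            raise ValueError("area_ratio must lie strictly between 0 and 1")

    @property
    def start(self) -> float:
        return self.center_position - self.length_L / 2.0

    @property
    def end(self) -> float:
        return self.center_position + self.length_L / 2.0


@dataclass(frozen=True)
class OutletSpec:
    """A lumped distal (microvascular) resistance attached at an outlet."""

    resistance_R_out: float
    label: str = "outlet"

    def __post_init__(self) -> None:
        if self.resistance_R_out <= 0.0:
            raise ValueError("outlet resistance must be positive")


@dataclass(frozen=True)
class SideBranchSpec:
    """A side branch leaving the main vessel.

    The branching angle is anatomical metadata only: a 0D network carries
    no momentum, so the angle never enters the hydraulics.
    """

    attach_position: float
    diameter: float
    outlet: OutletSpec
    angle: float = 90.0

    def __post_init__(self) -> None:
        if self.diameter <= 0.0:
            raise ValueError("branch diameter must be positive")


@dataclass
class VesselTree:
    """A main epicardial vessel with stenoses, side branches and outlets.

    The tree is the hydraulic domain solved by
    :func:`ffr0d.network_solver.solve_tree`: one inlet held at
    ``inlet_pressure_P_in``, one main distal outlet, and zero or more side
    branches each terminated by its own outlet resistance.  Stenoses and
    branch attachments are sorted by position on construction; stenotic
    intervals must lie inside the vessel, must not overlap each other, and
    no branch may attach inside a stenotic interval.
    """

    main_vessel: LumenProfile
    stenoses: list[StenosisSpec]
    side_branches: list[SideBranchSpec]
    inlet_pressure_P_in: float
    main_outlet: OutletSpec

    def __post_init__(self) -> None:
        if self.inlet_pressure_P_in <= 0.0:
            raise ValueError("inlet pressure must be positive")
        self.stenoses = sorted(self.stenoses, key=lambda s: s.center_position)
        self.side_branches = sorted(self.side_branches, key=lambda b: b.attach_position)
        lo, hi = self.main_vessel.start, self.main_vessel.end
        for sten in self.stenoses:
            if sten.start < lo or sten.end > hi:
                raise ValueError(
                    f"stenosis [{sten.start}, {sten.end}] outside vessel [{lo}, {hi}]"
                )
        for a, b in zip(self.stenoses, self.stenoses[1:]):
            if b.start < a.end:
                raise ValueError("stenotic intervals overlap")
        seen: set[float] = set()
        for br in self.side_branches:
            s = br.attach_position
            if not (lo < s < hi):
                raise ValueError("branch must attach strictly inside the vessel")
            if s in seen:
                raise ValueError("two branches attach at the same position")
            seen.add(s)
            for sten in self.stenoses:
                if sten.start < s < sten.end:
                    raise ValueError(
                        "a branch may not attach inside a stenotic interval"
                    )

    def stenosed_profile(self, resample_step: float = DEFAULT_QUAD_STEP) -> LumenProfile:
        """Lumen profile with all stenosis tapers applied."""
        return apply_stenoses(self.main_vessel, self.stenoses, resample_step)


def apply_stenoses(
    profile: LumenProfile,
    stenoses: list[StenosisSpec],
    resample_step: float = DEFAULT_QUAD_STEP,
) -> LumenProfile:
    """Impose cosine-tapered area narrowings on a healthy lumen profile.

    Within each stenotic interval the lumen area is scaled by
    ``1 - (1 - r) cos^2(pi (s - c) / L)`` where ``r`` is the minimum/healthy
    area ratio: the factor reaches ``r`` at the centre and 1 at the ends, so
    the profile joins the healthy lumen smoothly.  The returned profile is
    resampled densely (``resample_step``) inside the stenotic intervals so
    downstream quadrature resolves the taper.
    """
    if not stenoses:
        return profile
    grids = [profile.arc_length_samples]
    for sten in stenoses:
        n = max(2, int(math.ceil(sten.length_L / resample_step)) + 1)
        grids.append(np.linspace(sten.start, sten.end, n))
        grids.append(np.array([sten.center_position]))
    s = np.unique(np.concatenate(grids))
    s = s[(s >= profile.start) & (s <= profile.end)]
    d = profile.diameter_at(s)
    factor = np.ones_like(s)
    for sten in stenoses:
        inside = (s >= sten.start) & (s <= sten.end)
        w = np.cos(np.pi * (s[inside] - sten.center_position) / sten.length_L) ** 2
        factor[inside] *= np.sqrt(1.0 - (1.0 - sten.area_ratio) * w)
    return LumenProfile(s, d * factor)


# ---------------------------------------------------------------------------
# Hydraulic primitives
# ---------------------------------------------------------------------------


def poiseuille_resistance(length: float, diameter: float, mu: float) -> float:
    """Hagen-Poiseuille resistance ``128 mu L / (pi d^4)`` of a straight tube."""
    if length <= 0.0 or diameter <= 0.0 or mu <= 0.0:
        raise ValueError("length, diameter and viscosity must all be positive")
    return 128.0 * mu * length / (math.pi * diameter**4)


def _poiseuille_integrand(profile: LumenProfile, s, mu: float):
    d = np.interp(s, profile.arc_length_samples, profile.diameter_samples)
    return 128.0 * mu / (np.pi * d**4)


def _cumulative_resistance(
    profile: LumenProfile, x: float, mu: float, step: float
) -> float:
    """Trapezoid integral of the Poiseuille integrand from the profile start
    to ``x`` on a grid anchored at the profile start.

    Anchoring the grid makes interval resistances exactly additive:
    R(a, c) = F(c) - F(a) = [F(c) - F(b)] + [F(b) - F(a)].
    """
    s0 = profile.start
    if x <= s0:
        return 0.0
    n_full = int(math.floor((x - s0) / step))
    nodes = s0 + step * np.arange(n_full + 1)
    g = _poiseuille_integrand(profile, nodes, mu)
    total = float(np.trapezoid(g, dx=step)) if n_full > 0 else 0.0
    last = float(nodes[-1])
    if x > last:
        g_x = float(_poiseuille_integrand(profile, x, mu))
        total += 0.5 * (float(g[-1]) + g_x) * (x - last)
    return total


def segment_viscous_resistance(
    profile: LumenProfile,
    mu: float,
    from_s: float,
    to_s: float,
    step: float = DEFAULT_QUAD_STEP,
) -> float:
    """Viscous resistance of the profile between two arc lengths.

    Composite-trapezoid quadrature of ``128 mu / (pi d(s)^4)`` over
    ``[from_s, to_s]`` at the given step.  Reduces to
    :func:`poiseuille_resistance` for a constant diameter and is exactly
    additive over contiguous sub-intervals.
    """
    if mu <= 0.0:
        raise ValueError("viscosity must be positive")
    if step <= 0.0:
        raise ValueError("quadrature step must be positive")
    if not (from_s < to_s):
        raise ValueError("require from_s < to_s")
    if from_s < profile.start - 1e-12 or to_s > profile.end + 1e-12:
        raise ValueError("integration interval lies outside the lumen profile")
    return _cumulative_resistance(profile, to_s, mu, step) - _cumulative_resistance(
        profile, from_s, mu, step
    )
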