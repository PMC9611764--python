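"""Generators for test geometries and vessel-tree JSON I/O.

Two families of inputs are produced entirely in code:

* the three idealized stenosed-artery fixtures (straight 3 mm vessel,
  75 mm long, one 10 mm stenosis narrowing the lumen area to 20 %, and a
  2.5 mm side branch placed 25 mm up- or downstream of the stenosis
  centre, inlet held at 90 mmHg);
* randomized patient-like trees that emulate an intravascular-OCT
  pullback: lumen area sampled every 0.2 mm (36 mm/s pullback at 180
  frames/s) with multiplicative segmentation noise, a tapered main
  vessel, and preset branch/stenosis layouts.

Trees are serialized to a versioned JSON schema.  Geometry is stored in
millimetres using an exact decimal-shift of each float's shortest
representation, so ``read_tree(write_tree(tree)) == tree`` bit-for-bit;
pressures and resistances are stored in SI units.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

import numpy as np

from ffr0d.structured_tree import StructuredTreeParams, tree_resistance
from ffr0d.vessel_model import (
    LumenProfile,
    OutletSpec,
    SideBranchSpec,
    StenosisSpec,
    VesselTree,
    mmhg_to_pa,
)

__all__ = [
    "IdealizedFixtureSpec",
    "LayoutError",
    "SchemaError",
    "SyntheticTreeConfig",
    "make_idealized",
    "make_patient_like",
    "read_tree",
    "write_tree",
]

SCHEMA_VERSION = "vessel-tree/1"

VARIANTS = ("model1_no_branch", "model2_upstream", "model3_downstream")
PRESETS = ("patient1_like", "patient2_like")


class SchemaError(ValueError):
    """A vessel-tree JSON document violates the schema."""


class LayoutError(RuntimeError):
    """A feasible branch/stenosis layout could not be drawn."""


# ---------------------------------------------------------------------------
# Idealized fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IdealizedFixtureSpec:
    """Dimensions of the idealized stenosed-artery benchmark.

    Defaults (metres, Pa) encode the reference geometry: a 75 mm straight
    main vessel of 3 mm diameter, a 10 mm stenosis at mid-vessel reducing
    lumen area to 20 % of healthy, a 2.5 mm side branch 25 mm from the
    stenosis centre at 75 degrees, and a 90 mmHg inlet.
    """

    variant: str = "model1_no_branch"
    main_length: float = 75e-3
    main_diameter: float = 3e-3
    stenosis_center: float = 37.5e-3
    stenosis_length: float = 10e-3
    area_ratio: float = 0.2
    branch_diameter: float = 2.5e-3
    branch_offset: float = 25e-3
    branch_angle: float = 75.0
    inlet_pressure: float = mmhg_to_pa(90.0)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )


def make_idealized(
    spec: IdealizedFixtureSpec = IdealizedFixtureSpec(),
    outlet_policy: str = "structured_tree",
    tree_params: StructuredTreeParams = StructuredTreeParams(),
    main_resistance: float | None = None,
    branch_resistance: float | None = None,
    sample_step: float = 0.5e-3,
) -> VesselTree:
    """Build one of the three idealized fixtures as a :class:`VesselTree`.

    ``outlet_policy`` selects how outlet resistances are assigned:

    * ``"structured_tree"`` — hyperemic structured-tree resistance of the
      local outlet diameter (main 3 mm, branch 2.5 mm);
    * ``"explicit"`` — use ``main_resistance`` / ``branch_resistance``
      verbatim.

    ``model2_upstream`` and ``model3_downstream`` differ only in the
    branch attachment position (25 mm before vs after the stenosis
    centre).
    """
    n = int(round(spec.main_length / sample_step)) + 1
    s_mm = np.linspace(0.0, spec.main_length * 1e3, n)
    profile = LumenProfile(s_mm * 1e-3, np.full(n, spec.main_diameter))
    # pin the exact endpoint so fixture dimensions are bit-exact
    profile.arc_length_samples[-1] = spec.main_length

    stenosis = StenosisSpec(
        center_position=spec.stenosis_center,
        length_L=spec.stenosis_length,
        area_ratio=spec.area_ratio,
    )

    if outlet_policy == "structured_tree":
        r_main = tree_resistance(spec.main_diameter, tree_params, apply_hyperemia=True)
        r_branch = tree_resistance(
            spec.branch_diameter, tree_params, apply_hyperemia=True
        )
    elif outlet_policy == "explicit":
        if main_resistance is None:
            raise ValueError("explicit outlet policy requires main_resistance")
        r_main, r_branch = main_resistance, branch_resistance
    else:
        raise ValueError(f"unknown outlet policy {outlet_policy!r}")

    branches: list[SideBranchSpec] = []
    if spec.variant != "model1_no_branch":
        if r_branch is None:
            raise ValueError("explicit outlet policy requires branch_resistance")
        offset = -spec.branch_offset if spec.variant == "model2_upstream" else spec.branch_offset
        branches.append(
            SideBranchSpec(
                attach_position=spec.stenosis_center + offset,
                diameter=spec.branch_diameter,
                angle=spec.branch_angle,
                outlet=OutletSpec(resistance_R_out=r_branch, label="side_branch"),
            )
        )

    return VesselTree(
        main_vessel=profile,
        stenoses=[stenosis],
        side_branches=branches,
        inlet_pressure_P_in=spec.inlet_pressure,
        main_outlet=OutletSpec(resistance_R_out=r_main, label="main_distal"),
    )


# ---------------------------------------------------------------------------
# Patient-like randomized trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticTreeConfig:
    """Configuration for randomized OCT-pullback-like vessel trees.

    ``frame_spacing`` defaults to 0.2 mm (a 36 mm/s pullback imaged at
    180 frames/s); ``area_noise_sd`` is the relative SD of multiplicative
    Gaussian noise on lumen area (default 2 %, truncated at +/- 3 SD),
    emulating frame-to-frame segmentation jitter.  ``layout`` picks the
    branch/stenosis topology: ``patient1_like`` places the stenosis distal
    to most branches (plus one small distal branch), ``patient2_like``
    places a focal proximal stenosis before all branches.  Branches below
    0.5 mm diameter are never generated.
    """

    seed: int
    layout: str = "patient1_like"
    n_branches: int = 4
    branch_diameter_range: tuple[float, float] = (1.0e-3, 2.2e-3)
    small_branch_diameter: float = 0.9e-3
    stenosis_count: int = 1
    severity_range: tuple[float, float] = (0.25, 0.45)
    stenosis_length_range: tuple[float, float] = (8e-3, 14e-3)
    main_length: float = 75e-3
    main_diameter_proximal: float = 3.4e-3
    main_diameter_distal: float = 2.6e-3
    frame_spacing: float = 0.2e-3
    area_noise_sd: float = 0.02
    inlet_pressure: float = mmhg_to_pa(90.0)
    max_layout_tries: int = 100

    def __post_init__(self) -> None:
        if self.layout not in PRESETS:
            raise ValueError(f"unknown layout {self.layout!r}; expected {PRESETS}")
        for lo, hi in (
            self.branch_diameter_range,
            self.severity_range,
            self.stenosis_length_range,
        ):
            if not (0.0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")
        if self.branch_diameter_range[0] < 0.5e-3:
            raise ValueError("branches smaller than 0.5 mm are not generated")
        if self.n_branches < 1 or self.stenosis_count < 1:
            raise ValueError("need at least one branch and one stenosis")
        if not (0.0 < self.severity_range[1] < 1.0):
            raise ValueError("severity (area ratio) must lie in (0, 1)")
        if self.area_noise_sd < 0.0:
            raise ValueError("noise SD must be non-negative")


def _draw_positions(
    rng: np.random.Generator,
    n: int,
    window: tuple[float, float],
    forbidden: list[tuple[float, float]],
    min_gap: float,
    tries: int,
) -> list[float]:
    for _ in range(tries):
        pos = np.sort(rng.uniform(window[0], window[1], n))
        if n > 1 and np.min(np.diff(pos)) < min_gap:
            continue
        if any(a < p < b for p in pos for a, b in forbidden):
            continue
        return [float(p) for p in pos]
    raise LayoutError("could not place branches outside the stenotic intervals")


def make_patient_like(config: SyntheticTreeConfig) -> VesselTree:
    """Generate a reproducible patient-like vessel tree.

    All randomness flows from a single :class:`numpy.random.Generator`
    seeded with ``config.seed``, so the same configuration always yields a
    byte-identical serialized tree.
    """
    rng = np.random.default_rng(config.seed)
    L = config.main_length
    spacing_mm = config.frame_spacing * 1e3
    n_frames = int(math.floor(L * 1e3 / spacing_mm + 1e-9)) + 1
    s = (np.arange(n_frames) * spacing_mm) * 1e-3
    d_base = np.linspace(
        config.main_diameter_proximal, config.main_diameter_distal, n_frames
    )
    if config.area_noise_sd > 0.0:
        eps = rng.normal(0.0, config.area_noise_sd, n_frames)
        eps = np.clip(eps, -3.0 * config.area_noise_sd, 3.0 * config.area_noise_sd)
        area = (np.pi * d_base**2 / 4.0) * (1.0 + eps)
        d = np.sqrt(4.0 * area / np.pi)
    else:
        d = d_base
    profile = LumenProfile(s, d)

    # stenoses, then branches around them
    margin = 1e-3
    stenoses: list[StenosisSpec] = []
    if config.layout == "patient1_like":
        sten_window = (0.58 * L, 0.75 * L)
        branch_window = (0.08 * L, 0.45 * L)
    else:  # patient2_like
        sten_window = (0.18 * L, 0.32 * L)
        branch_window = (0.45 * L, 0.92 * L)
    for k in range(config.stenosis_count):
        length = float(rng.uniform(*config.stenosis_length_range))
        for _ in range(config.max_layout_tries):
            center = float(rng.uniform(*sten_window))
            cand = StenosisSpec(center, length, float(rng.uniform(*config.severity_range)))
            if cand.start < margin or cand.end > L - margin:
                continue
            if all(cand.end < s2.start - margin or cand.start > s2.end + margin for s2 in stenoses):
                stenoses.append(cand)
                break
        else:
            raise LayoutError("could not place a stenosis inside the vessel")

    forbidden = [(st.start - margin, st.end + margin) for st in stenoses]
    n_regular = config.n_branches - (1 if config.layout == "patient1_like" else 0)
    positions = _draw_positions(
        rng, n_regular, branch_window, forbidden, 2e-3, config.max_layout_tries
    )
    diameters = [float(rng.uniform(*config.branch_diameter_range)) for _ in positions]
    if config.layout == "patient1_like":
        # one small branch distal to the stenosed region
        distal_window = (max(st.end for st in stenoses) + margin, 0.97 * L)
        positions += _draw_positions(
            rng, 1, distal_window, forbidden, 2e-3, config.max_layout_tries
        )
        diameters.append(config.small_branch_diameter)

    params = StructuredTreeParams()
    branches = [
        SideBranchSpec(
            attach_position=pos,
            diameter=dia,
            angle=float(rng.uniform(45.0, 90.0)),
            outlet=OutletSpec(
                resistance_R_out=tree_resistance(dia, params, apply_hyperemia=True),
                label=f"branch_{i + 1}",
            ),
        )
        for i, (pos, dia) in enumerate(zip(positions, diameters))
    ]
    r_main = tree_resistance(
        config.main_diameter_distal, params, apply_hyperemia=True
    )
    return VesselTree(
        main_vessel=profile,
        stenoses=stenoses,
        side_branches=branches,
        inlet_pressure_P_in=config.inlet_pressure,
        main_outlet=OutletSpec(resistance_R_out=r_main, label="main_distal"),
    )


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


class _MM:
    """Marker for a metre value to be emitted as an exact mm decimal."""

    def __init__(self, literal: str):
        self.literal = literal


def _to_mm_literal(x: float) -> _MM:
    # shift the shortest decimal representation by 10^3: exact, and the
    # reverse shift recovers the identical float
    return _MM(str(Decimal(repr(float(x))).scaleb(3)))


def _from_mm(dec: Decimal) -> float:
    return float(dec.scaleb(-3))


_TOKEN = re.compile(r'"<<mm:([^"]*)>>"')


def _dump_json(obj) -> str:
    def encode(o):
        if isinstance(o, _MM):
            return f"<<mm:{o.literal}>>"
        raise TypeError(o)

    text = json.dumps(obj, indent=2, sort_keys=True, default=encode)
    return _TOKEN.sub(lambda m: m.group(1), text) + "\n"


def tree_to_json(tree: VesselTree) -> str:
    """Serialize a vessel tree to canonical schema-v1 JSON text."""
    doc = {
        "schema": SCHEMA_VERSION,
        "main_vessel": {
            "s_mm": [_to_mm_literal(x) for x in tree.main_vessel.arc_length_samples],
            "d_mm": [_to_mm_literal(x) for x in tree.main_vessel.diameter_samples],
        },
        "inlet_pressure_Pa": float(tree.inlet_pressure_P_in),
        "stenoses": [
            {
                "center_mm": _to_mm_literal(s.center_position),
                "length_mm": _to_mm_literal(s.length_L),
                "area_ratio": float(s.area_ratio),
            }
            for s in tree.stenoses
        ],
        "side_branches": [
            {
                "s_mm": _to_mm_literal(b.attach_position),
                "d_mm": _to_mm_literal(b.diameter),
                "angle_deg": float(b.angle),
                "outlet": {
                    "R": float(b.outlet.resistance_R_out),
                    "units": "Pa.s/m3",
                    "label": b.outlet.label,
                },
            }
            for b in tree.side_branches
        ],
        "main_outlet": {
            "R": float(tree.main_outlet.resistance_R_out),
            "units": "Pa.s/m3",
            "label": tree.main_outlet.label,
        },
    }
    return _dump_json(doc)


def write_tree(tree: VesselTree, path: str | Path) -> None:
    """Write a vessel tree to a schema-v1 JSON file."""
    Path(path).write_text(tree_to_json(tree))


def _require(doc: dict, key: str, pointer: str):
    if key not in doc:
        raise SchemaError(f"missing required member at {pointer}/{key}")
    return doc[key]


def tree_from_json(text: str) -> VesselTree:
    """Parse schema-v1 JSON text into a :class:`VesselTree`."""
    try:
        doc = json.loads(text, parse_float=Decimal)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("document root must be an object")
    version = _require(doc, "schema", "")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {version!r}; this reader supports "
            f"{SCHEMA_VERSION!r}"
        )
    mv = _require(doc, "main_vessel", "")
    s = [_from_mm(Decimal(x)) for x in _require(mv, "s_mm", "/main_vessel")]
    d = [_from_mm(Decimal(x)) for x in _require(mv, "d_mm", "/main_vessel")]
    mo = _require(doc, "main_outlet", "")
    try:
        stenoses = [
            StenosisSpec(
                center_position=_from_mm(Decimal(_require(st, "center_mm", f"/stenoses/{i}"))),
                length_L=_from_mm(Decimal(_require(st, "length_mm", f"/stenoses/{i}"))),
                area_ratio=float(_require(st, "area_ratio", f"/stenoses/{i}")),
            )
            for i, st in enumerate(_require(doc, "stenoses", ""))
        ]
        branches = []
        for i, br in enumerate(_require(doc, "side_branches", "")):
            outlet = _require(br, "outlet", f"/side_branches/{i}")
            branches.append(
                SideBranchSpec(
                    attach_position=_from_mm(Decimal(_require(br, "s_mm", f"/side_branches/{i}"))),
                    diameter=_from_mm(Decimal(_require(br, "d_mm", f"/side_branches/{i}"))),
                    angle=float(_require(br, "angle_deg", f"/side_branches/{i}")),
                    outlet=OutletSpec(
                        resistance_R_out=float(_require(outlet, "R", f"/side_branches/{i}/outlet")),
                        label=str(outlet.get("label", "outlet")),
                    ),
                )
            )
        return VesselTree(
            main_vessel=LumenProfile(np.asarray(s), np.asarray(d)),
            stenoses=stenoses,
            side_branches=branches,
            inlet_pressure_P_in=float(_require(doc, "inlet_pressure_Pa", "")),
            main_outlet=OutletSpec(
                resistance_R_out=float(_require(mo, "R", "/main_outlet")),
                label=str(mo.get("label", "outlet")),
            ),
        )
    except ValueError as exc:
        raise SchemaError(f"invalid vessel tree: {exc}") from exc


def read_tree(path: str | Path) -> VesselTree:
    """Read a vessel tree from a schema-v1 JSON file."""
    return tree_from_json(Path(path).read_text())
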