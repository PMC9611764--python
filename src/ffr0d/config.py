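"""Run configuration: physiology, structured-tree and solver settings.

A :class:`RunConfig` gathers every tunable constant behind one YAML file
so that command-line runs are reproducible.  Keys mirror the module
structure::

    physiology:
      rho_kg_m3: 1050.0
      carreau: {mu_inf: 0.0035, mu_0: 0.25, lambda_time: 25.0, n_index: 0.25}
    structured_tree:
      {alpha: 0.9, beta: 0.5, gamma: 25, d_min_um: 50,
       mu_Pa_s: 0.0035, hyperemia_factor: 0.24}
    stenosis:
      {Kt: 1.52, rho_kg_m3: 1050, neglect_healthy_resistance: false}
    solver:
      {tol: 1e-10, max_iter: 200, damping: 0.5, quad_step_mm: 0.05}
    seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ffr0d.network_solver import SolverSettings
from ffr0d.structured_tree import StructuredTreeParams
from ffr0d.vessel_model import CarreauParams

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Aggregated configuration for a pipeline run."""

    carreau: CarreauParams = CarreauParams()
    structured_tree: StructuredTreeParams = StructuredTreeParams()
    solver: SolverSettings = SolverSettings()
    seed: int = 0


def _build_solver(sten: dict, solv: dict, phys: dict) -> SolverSettings:
    quad_step_mm = solv.get("quad_step_mm")
    kwargs = dict(
        mu=phys.get("mu_Pa_s", SolverSettings.mu),
        rho=sten.get("rho_kg_m3", SolverSettings.rho),
        Kt=sten.get("Kt", SolverSettings.Kt),
        neglect_healthy_resistance=sten.get(
            "neglect_healthy_resistance", SolverSettings.neglect_healthy_resistance
        ),
        tol=float(solv.get("tol", SolverSettings.tol)),
        max_iter=int(solv.get("max_iter", SolverSettings.max_iter)),
        damping=float(solv.get("damping", SolverSettings.damping)),
    )
    if quad_step_mm is not None:
        kwargs["quad_step"] = float(quad_step_mm) * 1e-3
    return SolverSettings(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; missing keys keep defaults."""
    if path is None:
        return RunConfig()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    phys = doc.get("physiology", {})
    car = phys.get("carreau", {})
    st = doc.get("structured_tree", {})
    sten = doc.get("stenosis", {})
    solv = doc.get("solver", {})
    carreau = CarreauParams(
        mu_inf=car.get("mu_inf", CarreauParams.mu_inf),
        mu_0=car.get("mu_0", CarreauParams.mu_0),
        lambda_time=car.get("lambda_time", CarreauParams.lambda_time),
        n_index=car.get("n_index", CarreauParams.n_index),
    )
    tree_params = StructuredTreeParams(
        alpha=st.get("alpha", StructuredTreeParams.alpha),
        beta=st.get("beta", StructuredTreeParams.beta),
        gamma=st.get("gamma", StructuredTreeParams.gamma),
        d_min=st.get("d_min_um", StructuredTreeParams.d_min * 1e6) * 1e-6,
        mu=st.get("mu_Pa_s", StructuredTreeParams.mu),
        hyperemia_factor=st.get(
            "hyperemia_factor", StructuredTreeParams.hyperemia_factor
        ),
    )
    return RunConfig(
        carreau=carreau,
        structured_tree=tree_params,
        solver=_build_solver(sten, solv, phys),
        seed=int(doc.get("seed", 0)),
    )
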