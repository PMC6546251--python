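"""Configuration files, serialisation and run manifests.

Formats are deliberately diff-able and language-neutral: YAML for run
configuration and steady-state specifications, JSON for parameter sets
and fitted surfaces, CSV for trajectories.  Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import SchemaError
from .mt_population import MTParams, MTPopulationState
from .simulate import SystemState
from .solver import (
    FluxDecomposition,
    FreeChoices,
    ParameterSet,
    SteadyStateSpec,
)
from .surfaces import ResponseSurfaces
from .transport import TransportParams, VesicleSystemState


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit."""

    velocity: float
    t_end: float = 5000.0
    record_every: float = 500.0
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int = 1
    output_dir: str = "runs"
    log_level: str = "INFO"
    spec_overrides: dict = field(default_factory=dict)
    free_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.record_every <= 0:
            raise SchemaError("t_end and record_every must be > 0")
        n = self.t_end / self.record_every
        if abs(n - round(n)) > 1e-9:
            raise SchemaError("record_every must divide t_end")


def _known_fields(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    unknown = set(raw) - _known_fields(RunConfig)
    if unknown:
        raise SchemaError(f"{path}: unknown keys {sorted(unknown)}")
    if "velocity" not in raw:
        raise SchemaError(f"{path}: 'velocity' is required")
    try:
        return RunConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def spec_from_config(cfg: RunConfig) -> SteadyStateSpec:
    unknown = set(cfg.spec_overrides) - (
        _known_fields(SteadyStateSpec) - {"free", "velocity"}
    )
    if unknown:
        raise SchemaError(f"unknown spec overrides: {sorted(unknown)}")
    unknown = set(cfg.free_overrides) - _known_fields(FreeChoices)
    if unknown:
        raise SchemaError(f"unknown free-choice overrides: {sorted(unknown)}")
    free = FreeChoices(**cfg.free_overrides)
    try:
        return SteadyStateSpec(velocity=cfg.velocity, free=free, **cfg.spec_overrides)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


# ---------------------------------------------------------------------------
# ParameterSet <-> plain dicts (JSON round trip)
# ---------------------------------------------------------------------------


def _surfaces_to_dict(s: ResponseSurfaces) -> dict:
    return {
        "tu_domain": list(s.tu_domain),
        "h_domain": list(s.h_domain),
        "coef_mean": s.coef_mean.tolist(),
        "coef_deg": s.coef_deg.tolist(),
        "mean_length_space": s.mean_length_space,
        "fit_residuals": s.fit_residuals.to_dict(orient="list"),
    }


def _surfaces_from_dict(d: dict) -> ResponseSurfaces:
    import pandas as pd

    return ResponseSurfaces(
        coef_mean=np.asarray(d["coef_mean"], dtype=float),
        coef_deg=np.asarray(d["coef_deg"], dtype=float),
        tu_domain=tuple(d["tu_domain"]),
        h_domain=tuple(d["h_domain"]),
        fit_residuals=pd.DataFrame(d["fit_residuals"]),
        mean_length_space=d.get("mean_length_space", "log"),
    )


def parameter_set_to_dict(pset: ParameterSet) -> dict:
    tp = dataclasses.asdict(pset.transport)
    tp["production_rates"] = pset.transport.production_rates.tolist()
    tp["kd"] = pset.transport.kd.tolist()
    tp["f_kin"] = list(pset.transport.f_kin)
    tp["f_dyn"] = list(pset.transport.f_dyn)
    mt = {
        "nucleation_rate": pset.mt.nucleation_rate,
        "stabilization_rate": pset.mt.stabilization_rate,
        "tubulin_conc": pset.mt.tubulin_conc,
        "hydrolysis_rate": pset.mt.hydrolysis_rate,
        "n_cross": pset.mt.n_cross,
        "surfaces": _surfaces_to_dict(pset.mt.surfaces),
    }
    ves = pset.state0.vesicles
    state = {
        "area_tgn": ves.area_tgn,
        "area_gc_pm": ves.area_gc_pm,
        "area_shaft": ves.area_shaft,
        "counts": ves.counts.tolist(),
        "protein_ves": ves.protein_ves.tolist(),
        "protein_org": ves.protein_org.tolist(),
        "n_dyn": pset.state0.mt.n_dyn,
        "l_dyn_total": pset.state0.mt.L_dyn_total,
        "l_stable_total": pset.state0.mt.L_stable_total,
    }
    fluxes = {
        "phi_i": pset.fluxes.phi_i,
        "phi_ii": pset.fluxes.phi_ii,
        "phi_iii": pset.fluxes.phi_iii,
        "phi_iv": pset.fluxes.phi_iv,
        "a_v": pset.fluxes.a_v,
    }
    return {
        "transport": tp,
        "mt": mt,
        "state0": state,
        "fluxes": fluxes,
        "report": _jsonable(pset.report),
        "provenance": _jsonable(pset.provenance),
    }


def parameter_set_from_dict(d: dict) -> ParameterSet:
    tp = dict(d["transport"])
    tp["production_rates"] = np.asarray(tp["production_rates"], dtype=float)
    tp["kd"] = np.asarray(tp["kd"], dtype=float)
    tp["f_kin"] = tuple(tp["f_kin"])
    tp["f_dyn"] = tuple(tp["f_dyn"])
    transport = TransportParams(**tp)
    mtd = dict(d["mt"])
    surfaces = _surfaces_from_dict(mtd.pop("surfaces"))
    mt = MTParams(surfaces=surfaces, **mtd)
    st = d["state0"]
    state0 = SystemState(
        vesicles=VesicleSystemState(
            area_tgn=st["area_tgn"],
            area_gc_pm=st["area_gc_pm"],
            area_shaft=st["area_shaft"],
            counts=np.asarray(st["counts"], dtype=float),
            protein_ves=np.asarray(st["protein_ves"], dtype=float),
            protein_org=np.asarray(st["protein_org"], dtype=float),
        ),
        mt=MTPopulationState(
            n_dyn=st["n_dyn"],
            L_dyn_total=st["l_dyn_total"],
            L_stable_total=st["l_stable_total"],
        ),
    )
    fluxes = FluxDecomposition(**d["fluxes"])
    return ParameterSet(
        transport=transport,
        mt=mt,
        state0=state0,
        fluxes=fluxes,
        report=d.get("report", {}),
        provenance=d.get("provenance", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_manifest(path, config: dict, seed: int | None = None) -> dict:
    """Write a JSON run manifest: config hash, seed, library versions."""
    import pandas
    import scipy

    payload = _jsonable(config)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": payload,
        "config_sha256": digest,
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
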