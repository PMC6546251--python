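"""In-silico knockdown experiments: uncompensated perturbations and
coordinated compensation.

Two kinds of experiment are supported:

* **Knockdown panels** scale one parameter (and its linked quantities,
  e.g. a v-SNARE's count *and* production rate together) to a fraction of
  its predicted value without touching anything else, then simulate the
  imbalance.  Reduced exocytosis (v-SNARE V knockdown) overloads the
  growth-cone cytoplasm with anterograde vesicles — the model's proxy for
  a dystrophic bulb — without slowing outgrowth; reduced microtubule
  stabilization shortens the microtubule bundle and stalls outgrowth.
* **Compensation** re-runs the analytical solver with one parameter
  pinned below its preferred value (e.g. less Recruitment Factor 1 with
  the budding rate held), finding the reduced velocity and adapted
  production/receptor/SNARE amounts that restore every postulate at the
  unchanged cycling rate.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, InfeasibleSpecError
from .postulates import PostulateSet, check_constraints
from .simulate import TrajectoryRecord, integrate
from .solver import (
    FreeChoices,
    ParameterSet,
    SteadyStateSpec,
    decompose_fluxes,
    predict_parameter_set,
)
from .surfaces import ResponseSurfaces
from .transport import IDX_KR, IDX_U, IDX_V

#: perturbable parameters and what they touch
PERTURBATION_TARGETS = (
    "vsnare_v",
    "vsnare_u",
    "kinesin_receptor",
    "stabilization_rate",
    "nucleation_rate",
    "recruitment_factor_1",
    "tethering_rate",
)


def scale_parameter(pset: ParameterSet, target: str, factor: float) -> ParameterSet:
    """Return a copy of ``pset`` with ``target`` scaled by ``factor``.

    Linked quantities move together: a SNARE or receptor knockdown scales
    both the standing amounts (everywhere in the initial state) and the
    production rate, mimicking reduced expression.
    """
    if factor <= 0:
        raise DomainError("factor must be > 0")
    if target not in PERTURBATION_TARGETS:
        raise DomainError(
            f"unknown perturbation target {target!r}; valid: {PERTURBATION_TARGETS}"
        )
    out = copy.deepcopy(pset)
    if target in ("vsnare_v", "vsnare_u", "kinesin_receptor"):
        idx = {"vsnare_v": IDX_V, "vsnare_u": IDX_U, "kinesin_receptor": IDX_KR}[target]
        out.state0.vesicles.protein_ves[idx] *= factor
        out.state0.vesicles.protein_org[idx] *= factor
        prod = out.transport.production_rates.copy()
        prod[idx] *= factor
        out.transport = replace(out.transport, production_rates=prod)
    elif target == "stabilization_rate":
        out.mt = replace(out.mt, stabilization_rate=factor * out.mt.stabilization_rate)
    elif target == "nucleation_rate":
        out.mt = replace(out.mt, nucleation_rate=factor * out.mt.nucleation_rate)
    elif target == "recruitment_factor_1":
        out.transport = replace(out.transport, rf1_amount=factor * out.transport.rf1_amount)
    elif target == "tethering_rate":
        out.transport = replace(out.transport, tether_rate_gc=factor * out.transport.tether_rate_gc)
    out.report = dict(out.report, perturbation={"target": target, "factor": factor})
    return out


@dataclass(frozen=True)
class PerturbationSpec:
    base: ParameterSet
    target: str
    scale_factors: tuple = (0.25, 0.5, 0.75)
    horizon: float = 5000.0
    record_every: float = 500.0

    def __post_init__(self) -> None:
        if not all(0 < f <= 1 for f in self.scale_factors):
            raise DomainError("scale_factors must lie in (0, 1]")
        if self.target not in PERTURBATION_TARGETS:
            raise DomainError(
                f"unknown perturbation target {self.target!r}; "
                f"valid: {PERTURBATION_TARGETS}"
            )


@dataclass
class PerturbationResult:
    target: str
    baseline: dict
    per_factor: dict  # factor -> metrics dict
    trajectories: dict = field(default_factory=dict)  # factor -> TrajectoryRecord

    def summary_frame(self) -> pd.DataFrame:
        rows = [dict(factor=1.0, **self.baseline)]
        rows += [dict(factor=f, **m) for f, m in sorted(self.per_factor.items())]
        return pd.DataFrame(rows)


def _metrics(traj: TrajectoryRecord) -> dict:
    frame = traj.frame
    t = frame["time_min"].to_numpy()
    shaft = frame["shaft_length_um"].to_numpy()
    slope = np.polyfit(t, shaft, 1)[0] * 60.0
    # steady-state velocity: trailing-half slope, past the pool-adjustment
    # transient a perturbation induces
    tail = t >= t[-1] / 2.0
    steady = np.polyfit(t[tail], shaft[tail], 1)[0] * 60.0
    return {
        "final_shaft_length_um": float(shaft[-1]),
        "mean_velocity_um_per_h": float(slope),
        "steady_velocity_um_per_h": float(steady),
        "final_gcc_antero_count": float(frame["gcc_antero_count"].iloc[-1]),
        "final_mtb_length_um": float(frame["mtb_length_um"].iloc[-1]),
    }


def run_knockdown_panel(
    spec: PerturbationSpec,
    postulates: PostulateSet | None = None,
    validate_baseline: bool = True,
) -> PerturbationResult:
    """Simulate the knockdown panel; the unperturbed baseline must validate."""
    base_traj = integrate(
        spec.base.state0,
        spec.base.transport,
        spec.base.mt,
        t_end=spec.horizon,
        record_every=spec.record_every,
    )
    if validate_baseline:
        postulates = postulates or PostulateSet()
        target_v = spec.base.report.get("velocity_um_per_h", 0.0)
        report = check_constraints(base_traj, postulates, target_v)
        if not report.overall_pass:
            raise InfeasibleSpecError(
                "baseline parameter set fails validation; perturbation results "
                f"would be meaningless:\n{report.failed()}"
            )
    result = PerturbationResult(
        target=spec.target,
        baseline=_metrics(base_traj),
        per_factor={},
        trajectories={1.0: base_traj},
    )
    for factor in spec.scale_factors:
        perturbed = scale_parameter(spec.base, spec.target, factor)
        traj = integrate(
            perturbed.state0,
            perturbed.transport,
            perturbed.mt,
            t_end=spec.horizon,
            record_every=spec.record_every,
        )
        result.per_factor[factor] = _metrics(traj)
        result.trajectories[factor] = traj
    return result


def recompute_compensation(
    base_spec: SteadyStateSpec,
    surfaces: ResponseSurfaces,
    fixed_overrides: dict | None = None,
    hold_budding_rate: bool = True,
) -> ParameterSet:
    """Re-solve the parameter set with some free choices pinned.

    With ``rf1_amount`` pinned below its baseline (and the per-molecule
    budding rate held), the achievable budding flux drops; since the
    cycling rate is a postulate and stays fixed, the solver finds the
    reduced velocity whose total budding demand matches the pinned flux,
    then recomputes every dependent quantity (production rates, SNARE
    amounts, receptor counts) at that velocity.  Raises
    :class:`InfeasibleSpecError` naming the constraint when no velocity in
    [0, base] is feasible.
    """
    if not fixed_overrides:
        return predict_parameter_set(base_spec, surfaces)
    unknown = set(fixed_overrides) - set(FreeChoices.__dataclass_fields__)
    if unknown:
        raise DomainError(f"unknown free-choice overrides: {sorted(unknown)}")

    pinned_free = replace(base_spec.free, **fixed_overrides)
    spec = replace(base_spec, free=pinned_free)

    if "rf1_amount" in fixed_overrides and hold_budding_rate:
        base_fluxes = decompose_fluxes(base_spec)
        budding_rate = base_fluxes.budding_area / base_spec.a_v / base_spec.free.rf1_amount
        target_flux = budding_rate * pinned_free.rf1_amount  # vesicles/min available

        def gap(v):
            fl = decompose_fluxes(replace(spec, velocity=v))
            return fl.budding_area / spec.a_v - target_flux

        if gap(0.0) > 0:
            raise InfeasibleSpecError(
                "pinned recruitment_factor_1 cannot even sustain the cycling "
                f"flux: available budding {target_flux:.3f} vesicles/min < "
                f"required at v=0 ({gap(0.0) + target_flux:.3f})"
            )
        if gap(base_spec.velocity) <= 0:
            v_new = base_spec.velocity  # pin does not bind
        else:
            v_new = brentq(gap, 0.0, base_spec.velocity, xtol=1e-10)
        spec = replace(spec, velocity=v_new)

    pset = predict_parameter_set(spec, surfaces)
    pset.report = dict(
        pset.report,
        compensation={
            "overrides": {k: float(v) for k, v in fixed_overrides.items()},
            "adapted_velocity_um_per_h": spec.velocity,
            "base_velocity_um_per_h": base_spec.velocity,
        },
    )
    return pset
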