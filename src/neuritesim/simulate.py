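"""Coupled integration of the vesicle-transport and microtubule models.

The full system state stacks the vesicle state (membrane areas, vesicle
pools, protein loads) with the microtubule population state; both evolve
on the minutes-to-days scale and are integrated together with a
stiff-capable implicit method.  Trajectories are recorded at regular
checkpoints (default every 500 min over 5,000 min) as a tidy DataFrame
including derived fluxes and the moving fractions the constraint harness
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DomainError, IntegrationError
from .mt_population import MTParams, MTPopulationState, mt_population_rhs, mtb_length
from .transport import (
    ANTERO_CLASSES,
    IDX_GCC,
    IDX_KR,
    IDX_NSC,
    RETRO_CLASSES,
    TransportParams,
    VesicleClass,
    VesicleSystemState,
    motor_bound_probability,
    overflow_to_shaft,
    vesicle_fluxes,
    vesicle_rhs,
)


@dataclass
class SystemState:
    vesicles: VesicleSystemState
    mt: MTPopulationState

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.vesicles.to_vector(), self.mt.as_array()])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "SystemState":
        nv = VesicleSystemState.SIZE
        mt = MTPopulationState(
            n_dyn=max(y[nv], 0.0),
            L_dyn_total=max(y[nv + 1], 0.0),
            L_stable_total=max(y[nv + 2], 0.0),
        )
        return cls(vesicles=VesicleSystemState.from_vector(y[:nv]), mt=mt)


@dataclass
class TrajectoryRecord:
    """Checkpointed trajectory with derived diagnostics.

    ``frame`` holds one row per checkpoint; ``schema_version`` guards the
    column contract used by the constraint harness.
    """

    frame: pd.DataFrame
    transport: TransportParams
    mt_params: MTParams
    schema_version: str = "1"

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _checkpoint_row(
    t: float, state: SystemState, tp: TransportParams, mp: MTParams
) -> dict:
    ves = overflow_to_shaft(state.vesicles, tp.gc_pm_cap)
    fl = vesicle_fluxes(ves, tp)
    loads = fl["loads"]
    counts = ves.counts

    nsc_antero = float(sum(counts[vc, IDX_NSC] for vc in ANTERO_CLASSES))
    nsc_retro = float(sum(counts[vc, IDX_NSC] for vc in RETRO_CLASSES))
    gcc_antero = float(sum(counts[vc, IDX_GCC] for vc in ANTERO_CLASSES))

    # moving fractions via the motor-binding law on pool-average loads
    def _frac(classes, idx_motor, f_motor):
        tot = sum(counts[vc, IDX_NSC] for vc in classes)
        if tot <= 0:
            return 0.0
        mov = sum(
            counts[vc, IDX_NSC]
            * motor_bound_probability(loads[idx_motor, vc, IDX_NSC], f_motor)
            for vc in classes
        )
        return float(mov / tot)

    antero_mov_main = float(
        motor_bound_probability(
            loads[IDX_KR, VesicleClass.B_G, IDX_NSC], tp.f_kin[IDX_NSC]
        )
    )
    antero_mov_all = _frac(ANTERO_CLASSES, IDX_KR, tp.f_kin[IDX_NSC])
    retro_mov_main = float(
        motor_bound_probability(loads[3, VesicleClass.A_PM, IDX_NSC], tp.f_dyn[IDX_NSC])
    )

    gcc_fusing_frac = (
        float(fl["fuse_gc"].sum()) / gcc_antero if gcc_antero > 0 else 0.0
    )

    row = {
        "time_min": t,
        "area_tgn": ves.area_tgn,
        "area_gc_pm": ves.area_gc_pm,
        "area_shaft": ves.area_shaft,
        "shaft_length_um": ves.neurite_length(tp.diameter),
        "nsc_antero_count": nsc_antero,
        "nsc_retro_count": nsc_retro,
        "nsc_vesicle_count": nsc_antero + nsc_retro,
        "gcc_antero_count": gcc_antero,
        "antero_moving_frac_nsc": antero_mov_main,
        "antero_moving_frac_nsc_all": antero_mov_all,
        "retro_moving_frac_nsc": retro_mov_main,
        "gcc_fusing_frac": gcc_fusing_frac,
        "fusion_area_gc": fl["fusion_area_gc"],
        "retro_fusion_area_tgn": fl["retro_fusion_area_tgn"],
        "endocytosis_area": fl["endocytosis_area"],
        "overflow_area": fl["overflow_area"],
        "n_dyn": state.mt.n_dyn,
        "l_dyn_total": state.mt.L_dyn_total,
        "l_stable_total": state.mt.L_stable_total,
        "dynamic_span_um": state.mt.L_dyn_total / mp.n_cross,
        "mtb_length_um": mtb_length(state.mt, mp.n_cross),
        "total_membrane_area": ves.total_membrane_area(tp.a_v),
    }
    for vc in VesicleClass:
        for ci, comp in enumerate(("CBC", "NSC", "GCC")):
            row[f"n_{vc.name}_{comp}"] = counts[vc, ci]
    for si, sp in enumerate(("vSNARE_U", "vSNARE_V", "kinesin_receptor", "dynein_receptor")):
        row[f"total_{sp}"] = float(ves.total_protein()[si])
    row["kr_per_nsc_antero"] = (
        float(
            sum(ves.protein_ves[IDX_KR, vc, IDX_NSC] for vc in ANTERO_CLASSES)
        )
        / nsc_antero
        if nsc_antero > 0
        else 0.0
    )
    return row


def integrate(
    state0: SystemState,
    transport: TransportParams,
    mt_params: MTParams,
    t_end: float = 5000.0,
    record_every: float = 500.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> TrajectoryRecord:
    """Integrate the coupled system and record checkpoints.

    ``record_every`` must divide ``t_end``; checkpoints include t=0.
    """
    if t_end <= 0:
        raise DomainError("t_end must be > 0")
    n_rec = t_end / record_every
    if abs(n_rec - round(n_rec)) > 1e-9:
        raise DomainError("record_every must divide t_end")

    nv = VesicleSystemState.SIZE

    def rhs(t, y):
        state = SystemState.from_vector(y)
        dv = vesicle_rhs(state.vesicles, transport)
        dm = mt_population_rhs(state.mt, mt_params)
        return np.concatenate([dv, dm])

    t_eval = np.arange(0.0, t_end + 0.5 * record_every, record_every)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        state0.to_vector(),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        y_last = sol.y[:, -1] if sol.y.size else state0.to_vector()
        bad = int(np.argmin(y_last))
        raise IntegrationError(
            f"integrator failed: {sol.message}; most negative/smallest "
            f"component index {bad} = {y_last[bad]:.3e}"
        )
    rows = [
        _checkpoint_row(t, SystemState.from_vector(sol.y[:, k]), transport, mt_params)
        for k, t in enumerate(sol.t)
    ]
    return TrajectoryRecord(frame=pd.DataFrame(rows), transport=transport, mt_params=mt_params)
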