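"""Analytical steady-state parameter prediction for a target outgrowth velocity.

Given a desired neurite-outgrowth velocity and the postulated constraints
on subcellular-process dynamics (moving fractions, cycling-membrane rate,
growth-cone area, dynamic-microtubule span), this module constructs a
complete kinetic parameter set — synthesis, budding, SNARE amounts,
production rates, motor-receptor counts, microtubule nucleation and
stabilization rates — such that the coupled simulation started from the
matching initial condition holds all constraints at steady state.

The construction classifies membrane by destination into four types:

* type I   — buds from the TGN and accumulates in the growing
  neurite-shaft reservoir,
* type II  — reaches the growth-cone plasma membrane and is added to the
  neurite shaft (sets the outgrowth velocity),
* type III — reaches the GC-PM, is endocytosed and accumulates in the
  shaft as retrograde vesicles,
* type IV  — cycles TGN -> GC-PM -> TGN (the cycling membrane).

Budding, fusion and endocytosis rates are sums of the types passing each
step; the reservoir types I and III follow from the moving-fraction
closure (stationary density = through-flux / (p * motor speed + dL/dt)),
which couples back into the totals and is solved by a short fixed-point
iteration.  SNARE amounts follow by inverting the bilinear fusion law,
organelle surface concentrations by inverting the competitive coat
partition, and production rates from the reservoir accumulation of each
species.  Microtubule rates come from the response surfaces:
L̄ = mean_length(Tu, h), n_dyn = span * n_cross / L̄,
k_stab = (v/60) * n_cross / (n_dyn * L̄), k_deg = degradation_rate(Tu, h),
k_nuc = (k_deg + k_stab) * n_dyn.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .errors import DomainError, InfeasibleSpecError
from .mt_population import MTParams, MTPopulationState
from .simulate import SystemState
from .surfaces import ResponseSurfaces
from .transport import (
    COAT_A,
    COAT_B,
    IDX_DR,
    IDX_KR,
    IDX_U,
    IDX_V,
    SPECIES,
    TransportParams,
    VesicleSystemState,
    coat_partition,
    motor_bound_probability,
)

#: default dissociation constants (rows: U, V, kinesin-R, dynein-R;
#: columns: coat A, coat B).  The cycling v-SNAREs bind both coats equally
#: (each must travel in both vesicle streams); motor receptors prefer the
#: coat of their own direction (kinesin-R -> coat B, dynein-R -> coat A).
DEFAULT_KD = np.array(
    [
        [0.5, 0.5],  # vSNARE_U
        [0.5, 0.5],  # vSNARE_V
        [0.25, 0.05],  # kinesin_receptor
        [0.05, 0.25],  # dynein_receptor
    ]
)


@dataclass(frozen=True)
class FreeChoices:
    """Independent amounts and rates fixed before solving.

    These are the quantities the analytical solution does *not* determine:
    any combination yields a valid steady state, with the dependent
    parameters adapting (the source of the level-3 complementarity scans).
    """

    tether_rate_gc: float = 5e-4  # um^2/(molecule.min) at the GC-PM
    tether_rate_tgn: float = 4.5e-3  # um^2/(molecule.min) at the TGN
    tsnare_x_amount: float = 1000.0
    tsnare_y_amount: float = 1000.0
    rf1_amount: float = 1000.0
    rf2_amount: float = 1000.0
    f_kin_cbc: float = 0.9
    f_kin_nsc: float = 0.05
    n_dynein_receptors: int = 3
    kinesin_receptor_count: int | None = None  # solved from the postulate if None
    tgn_fusion_rate: float = 0.9  # per retro vesicle per min at the TGN
    transport_speed: float = 66.0  # um/min (~1.1 um/s fast axonal transport)
    coat_leak: float = 0.02
    n_slots: int = 100
    area_tgn0: float = 50.0
    initial_length: float = 50.0  # um of pre-existing neurite
    kd: np.ndarray = field(default_factory=lambda: DEFAULT_KD.copy())


@dataclass(frozen=True)
class SteadyStateSpec:
    """Top-down constraint bundle from which parameters are solved."""

    velocity: float  # um/h
    cycling_rate: float = 0.5  # um^2/min GC -> TGN back transport
    moving_fraction_antero_nsc: float = 0.10
    moving_fraction_antero_gcc: float = 0.10  # fraction of GCC pool fusing per min
    moving_fraction_retro: float = 0.90
    gc_pm_area: float = 50.0
    dynamic_span: float = 20.0  # um of the scaffold filled by dynamic MTs
    diameter: float = 1.0
    tubulin_conc: float = 9.0
    hydrolysis_rate: float = 0.72
    n_cross: int = 10
    a_v: float = 0.05
    free: FreeChoices = field(default_factory=FreeChoices)

    def __post_init__(self) -> None:
        if self.velocity < 0:
            raise DomainError("velocity must be >= 0")
        if self.cycling_rate <= 0:
            raise DomainError("cycling_rate must be > 0")
        for name in (
            "moving_fraction_antero_nsc",
            "moving_fraction_antero_gcc",
            "moving_fraction_retro",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise DomainError(f"{name} must lie in (0, 1]")
        if self.dynamic_span <= 0:
            raise DomainError("dynamic_span must be > 0")
        if self.diameter <= 0 or self.gc_pm_area <= 0:
            raise DomainError("geometry must be positive")


@dataclass
class FluxDecomposition:
    """Membrane fluxes by destination type, um^2/min."""

    phi_i: float  # into the NSC anterograde reservoir
    phi_ii: float  # added to the neurite shaft
    phi_iii: float  # endocytosed, accumulating as NSC retrograde vesicles
    phi_iv: float  # cycling membrane
    a_v: float = 0.05
    detail: dict | None = None  # converged class-resolved solution

    @property
    def budding_area(self) -> float:
        return self.phi_i + self.phi_ii + self.phi_iii + self.phi_iv

    @property
    def gc_fusion_area(self) -> float:
        return self.phi_ii + self.phi_iii + self.phi_iv

    @property
    def endocytosis_area(self) -> float:
        return self.phi_iii + self.phi_iv

    @property
    def tgn_retro_fusion_area(self) -> float:
        return self.phi_iv

    @property
    def nsc_accumulation_vesicles_per_min(self) -> float:
        return (self.phi_i + self.phi_iii) / self.a_v


def solve_kinesin_receptors(p_target: float, f_kin: float) -> int:
    """Integer kinesin-receptor count whose binding probability is closest
    to the target NSC moving fraction (receptors are whole molecules)."""
    if not (0 < f_kin < 1):
        raise InfeasibleSpecError(
            "f_kin must lie in (0,1) to solve the moving-fraction postulate"
        )
    exact = math.log(1.0 - p_target) / math.log(1.0 - f_kin)
    return max(1, round(exact))


def solve_dynein_fraction(p_target: float, n_receptors: int) -> float:
    """MT-bound dynein fraction giving the retrograde moving fraction."""
    return 1.0 - (1.0 - p_target) ** (1.0 / n_receptors)


def snare_surface_concentrations(
    required_loads: np.ndarray, kd_col: np.ndarray, n_slots: int
) -> np.ndarray:
    """Invert the competitive coat partition for surface concentrations.

    Solves ``n_slots * w_i / (1 + sum w)`` = required load for the
    concentrations ``c_i = kd_i * w_i``; round-trips through
    :func:`coat_partition` to 1e-8.
    """
    shares = np.asarray(required_loads, dtype=float) / n_slots
    total = shares.sum()
    if total >= 1.0:
        raise InfeasibleSpecError(
            f"required per-vesicle loads ({total * n_slots:.1f} molecules) "
            f"exceed the vesicle slot capacity ({n_slots})"
        )
    w = shares / (1.0 - total)
    return np.asarray(kd_col, dtype=float) * w


def _loads_and_concentrations(spec: SteadyStateSpec, f_fuse, f_endo):
    """Per-vesicle loads for all four classes plus organelle concentrations.

    ``f_fuse``/``f_endo`` are the total GC-PM fusion and endocytosis fluxes
    in vesicles/min; the cargo (return-leg) loads follow from species
    balance at the two organelles.
    """
    fc = spec.free
    if fc.tether_rate_gc <= 0 or fc.tsnare_y_amount <= 0:
        raise InfeasibleSpecError("GC tethering rate and t-SNARE Y must be > 0")
    v_v = spec.moving_fraction_antero_gcc / (
        fc.tether_rate_gc * fc.tsnare_y_amount / spec.gc_pm_area
    )
    u_u = fc.tgn_fusion_rate / (
        fc.tether_rate_tgn * fc.tsnare_x_amount / fc.area_tgn0
    )
    ratio = f_endo / f_fuse if f_fuse > 0 else 1.0
    u_ant = u_u * ratio
    v_ret = v_v / ratio
    n_kr = (
        fc.kinesin_receptor_count
        if fc.kinesin_receptor_count is not None
        else solve_kinesin_receptors(spec.moving_fraction_antero_nsc, fc.f_kin_nsc)
    )
    n_dr = fc.n_dynein_receptors
    kr_ret = n_kr / ratio
    dr_ant = n_dr * ratio

    load_bg = np.array([u_ant, v_v, n_kr, dr_ant])  # coat-B anterograde
    load_apm = np.array([u_u, v_ret, kr_ret, n_dr])  # coat-A retrograde
    conc_tgn = snare_surface_concentrations(load_bg, fc.kd[:, COAT_B], fc.n_slots)
    conc_gc = snare_surface_concentrations(load_apm, fc.kd[:, COAT_A], fc.n_slots)
    load_ag = fc.n_slots * coat_partition(conc_tgn, fc.kd, COAT_A)
    load_bpm = fc.n_slots * coat_partition(conc_gc, fc.kd, COAT_B)
    return {
        "load": {"A_G": load_ag, "B_G": load_bg, "A_PM": load_apm, "B_PM": load_bpm},
        "conc_tgn": conc_tgn,
        "conc_gc": conc_gc,
        "n_kr": n_kr,
        "n_dr": n_dr,
        "f_dyn": solve_dynein_fraction(spec.moving_fraction_retro, n_dr),
        "v_v": v_v,
        "u_u": u_u,
    }


def decompose_fluxes(spec: SteadyStateSpec) -> FluxDecomposition:
    """Solve the four membrane-type fluxes for a steady-state specification.

    phi_II follows from velocity and geometry, phi_IV is the cycling rate,
    and the reservoir types phi_I / phi_III follow from the moving-fraction
    closure, iterated to a fixed point together with the class-resolved
    vesicle loads they depend on.
    """
    v60 = spec.velocity / 60.0  # um/min
    phi_ii = math.pi * spec.diameter * v60
    phi_iv = spec.cycling_rate
    s = spec.free.transport_speed
    if s <= 0:
        raise InfeasibleSpecError("transport_speed must be > 0 for any outgrowth")
    eps = spec.free.coat_leak

    phi_i, phi_iii = 0.0, 0.0
    sol = None
    for _ in range(200):
        f_bud = (phi_i + phi_ii + phi_iii + phi_iv) / spec.a_v
        f_fuse = (phi_ii + phi_iii + phi_iv) / spec.a_v
        f_endo = (phi_iii + phi_iv) / spec.a_v
        sol = _loads_and_concentrations(spec, f_fuse, f_endo)
        # class-resolved NSC densities (vesicles per um of shaft)
        dens = {}
        for name, frac in (("A_G", eps), ("B_G", 1.0 - eps)):
            p_mov = motor_bound_probability(
                sol["load"][name][IDX_KR], spec.free.f_kin_nsc
            )
            if p_mov <= 0 and spec.velocity > 0:
                raise InfeasibleSpecError(
                    f"zero NSC moving fraction for class {name} with v > 0"
                )
            dens[name] = frac * f_bud / (p_mov * s + v60)
        for name, frac in (("A_PM", 1.0 - eps), ("B_PM", eps)):
            p_mov = motor_bound_probability(sol["load"][name][IDX_DR], sol["f_dyn"])
            dens[name] = frac * f_endo / (p_mov * s + v60)
        dens_a = dens["A_G"] + dens["B_G"]
        dens_r = dens["A_PM"] + dens["B_PM"]
        new_i = spec.a_v * v60 * dens_a
        new_iii = spec.a_v * v60 * dens_r
        if abs(new_i - phi_i) < 1e-14 and abs(new_iii - phi_iii) < 1e-14:
            phi_i, phi_iii = new_i, new_iii
            break
        phi_i, phi_iii = new_i, new_iii
    sol["dens_antero_per_um"] = dens_a
    sol["dens_retro_per_um"] = dens_r
    sol["dens_per_um"] = dens
    return FluxDecomposition(
        phi_i=phi_i,
        phi_ii=phi_ii,
        phi_iii=phi_iii,
        phi_iv=phi_iv,
        a_v=spec.a_v,
        detail=sol,
    )


def required_snare_V(
    spec: SteadyStateSpec, fluxes: FluxDecomposition, tethering_rate: float
) -> tuple[float, float, dict]:
    """Total v-SNARE V count, per-vesicle concentration and forward fluxes.

    Inverts the bilinear fusion law so that the GC-PM fusion flux carries
    the type II+III+IV membrane: per-vesicle fusion rate fixed by the GCC
    fusing fraction, so V per vesicle = rate / (tether * Y density).
    """
    if tethering_rate <= 0:
        raise InfeasibleSpecError("tethering_rate must be > 0")
    fc = spec.free
    v_v = spec.moving_fraction_antero_gcc / (
        tethering_rate * fc.tsnare_y_amount / spec.gc_pm_area
    )
    if v_v > fc.n_slots:
        raise InfeasibleSpecError(
            f"required v-SNARE V per vesicle ({v_v:.1f}) exceeds slot capacity"
        )
    f_fuse = fluxes.gc_fusion_area / spec.a_v
    v_flux = {
        "budding": fluxes.budding_area / spec.a_v * v_v,
        "gc_fusion": f_fuse * v_v,
    }
    pools = _steady_state_pools(spec, fluxes)
    vv_total = float(
        sum(
            pools["counts"][name][comp] * pools["load"][name][IDX_V]
            for name in pools["counts"]
            for comp in range(3)
        )
        + fluxes.detail["conc_tgn"][IDX_V] * fc.area_tgn0
        + fluxes.detail["conc_gc"][IDX_V] * spec.gc_pm_area
    )
    return vv_total, v_v, v_flux


def required_snare_U(
    spec: SteadyStateSpec, fluxes: FluxDecomposition, tgn_tethering_rate: float
) -> tuple[float, float, dict]:
    """Symmetric to :func:`required_snare_V` for fusion at the TGN."""
    if tgn_tethering_rate <= 0:
        raise InfeasibleSpecError("tgn_tethering_rate must be > 0")
    fc = spec.free
    u_u = fc.tgn_fusion_rate / (
        tgn_tethering_rate * fc.tsnare_x_amount / fc.area_tgn0
    )
    u_flux = {
        "endocytosis": fluxes.endocytosis_area / spec.a_v * u_u,
        "tgn_fusion": fluxes.tgn_retro_fusion_area / spec.a_v * u_u,
    }
    pools = _steady_state_pools(spec, fluxes)
    uu_total = float(
        sum(
            pools["counts"][name][comp] * pools["load"][name][IDX_U]
            for name in pools["counts"]
            for comp in range(3)
        )
        + fluxes.detail["conc_tgn"][IDX_U] * fc.area_tgn0
        + fluxes.detail["conc_gc"][IDX_U] * spec.gc_pm_area
    )
    if fluxes.phi_iv == 0:
        uu_total = 0.0
    return uu_total, u_u, u_flux


def production_rates(fluxes: FluxDecomposition, spec: SteadyStateSpec) -> np.ndarray:
    """Synthesis rate per cycling species, molecules/min into the TGN.

    At steady state the only net consumer of membrane proteins is the
    growing NSC reservoir (everything else cycles), so production equals
    the reservoir accumulation rate of each species: the sum over vesicle
    classes of stationary density x elongation rate x per-vesicle load.
    Zero at zero velocity.
    """
    det = fluxes.detail
    v60 = spec.velocity / 60.0
    prod = np.zeros(len(SPECIES))
    for name, dens in det["dens_per_um"].items():
        prod += dens * v60 * det["load"][name]
    return prod


def mt_steady_state(
    spec: SteadyStateSpec, surfaces: ResponseSurfaces
) -> tuple[float, float, float, float]:
    """(k_nuc, k_stab, n_dyn, k_deg) sustaining MTB growth at the velocity.

    n_dyn = span * n_cross / L̄ keeps dynamic filaments filling the distal
    span; the stable pool then must gain (v/60)*n_cross um/min, fixing the
    stabilization rate, and nucleation balances degradation + conversion.
    """
    lbar = float(surfaces.mean_length(spec.tubulin_conc, spec.hydrolysis_rate))
    if lbar <= 0:
        raise DomainError(
            f"fitted mean length is non-positive ({lbar:.3g}) at "
            f"(Tu={spec.tubulin_conc}, h={spec.hydrolysis_rate})"
        )
    k_deg = float(surfaces.degradation_rate(spec.tubulin_conc, spec.hydrolysis_rate))
    n_dyn = spec.dynamic_span * spec.n_cross / lbar
    k_stab = (spec.velocity / 60.0) * spec.n_cross / (n_dyn * lbar)
    k_nuc = (k_deg + k_stab) * n_dyn
    return k_nuc, k_stab, n_dyn, k_deg


def _steady_state_pools(spec: SteadyStateSpec, fluxes: FluxDecomposition) -> dict:
    """Analytical steady-state vesicle counts per class and compartment."""
    det = fluxes.detail
    fc = spec.free
    eps = fc.coat_leak
    s = fc.transport_speed
    v60 = spec.velocity / 60.0
    L0 = fc.initial_length
    f_bud = fluxes.budding_area / spec.a_v
    f_endo = fluxes.endocytosis_area / spec.a_v
    y_conc = fc.tsnare_y_amount / spec.gc_pm_area
    x_conc = fc.tsnare_x_amount / fc.area_tgn0

    counts = {}
    for name, frac in (("A_G", eps), ("B_G", 1.0 - eps)):
        load = det["load"][name]
        f_c = frac * f_bud
        p_cbc = motor_bound_probability(load[IDX_KR], fc.f_kin_cbc)
        p_nsc = motor_bound_probability(load[IDX_KR], fc.f_kin_nsc)
        n_cbc = f_c / max(p_cbc * s / 20.0, 1e-12)
        dens = f_c / (p_nsc * s + v60)
        f_into_gcc = f_c - dens * v60
        fuse_rate = fc.tether_rate_gc * load[IDX_V] * y_conc
        n_gcc = f_into_gcc / max(fuse_rate, 1e-12)
        counts[name] = np.array([n_cbc, dens * L0, n_gcc])
    for name, frac in (("A_PM", 1.0 - eps), ("B_PM", eps)):
        load = det["load"][name]
        f_c = frac * f_endo
        p_mov = motor_bound_probability(load[IDX_DR], det["f_dyn"])
        n_gcc = f_c / max(p_mov * s / 5.0, 1e-12)
        dens = f_c / (p_mov * s + v60)
        f_into_cbc = f_c - dens * v60
        fuse_rate = fc.tether_rate_tgn * load[IDX_U] * x_conc
        n_cbc = f_into_cbc / max(fuse_rate, 1e-12)
        counts[name] = np.array([n_cbc, dens * L0, n_gcc])
    return {"counts": counts, "load": det["load"]}


@dataclass
class ParameterSet:
    """A complete, self-consistent parameterisation plus initial state."""

    transport: TransportParams
    mt: MTParams
    state0: SystemState
    fluxes: FluxDecomposition
    report: dict
    provenance: dict

    def to_json(self, path) -> None:
        from .config import parameter_set_to_dict

        with open(path, "w") as fh:
            json.dump(parameter_set_to_dict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        from .config import parameter_set_from_dict

        with open(path) as fh:
            return parameter_set_from_dict(json.load(fh))


def predict_parameter_set(
    spec: SteadyStateSpec, surfaces: ResponseSurfaces
) -> ParameterSet:
    """Chain the analytical solution into a simulation-ready parameter set."""
    fluxes = decompose_fluxes(spec)
    det = fluxes.detail
    fc = spec.free

    vv_total, v_v, v_flux = required_snare_V(spec, fluxes, fc.tether_rate_gc)
    uu_total, u_u, u_flux = required_snare_U(spec, fluxes, fc.tether_rate_tgn)
    prod = production_rates(fluxes, spec)
    k_nuc, k_stab, n_dyn, k_deg = mt_steady_state(spec, surfaces)

    f_bud = fluxes.budding_area / spec.a_v
    transport = TransportParams(
        synthesis_area_rate=fluxes.phi_i + fluxes.phi_ii + fluxes.phi_iii,
        production_rates=prod,
        budding_rate_tgn=f_bud / fc.rf1_amount,
        rf1_amount=fc.rf1_amount,
        rf2_amount=fc.rf2_amount,
        endocytosis_rate=fluxes.endocytosis_area,
        tether_rate_gc=fc.tether_rate_gc,
        tether_rate_tgn=fc.tether_rate_tgn,
        tsnare_x_amount=fc.tsnare_x_amount,
        tsnare_y_amount=fc.tsnare_y_amount,
        kd=fc.kd,
        f_kin=(fc.f_kin_cbc, fc.f_kin_nsc, 0.0),
        f_dyn=(det["f_dyn"], det["f_dyn"], det["f_dyn"]),
        transport_speed=fc.transport_speed,
        coat_leak=fc.coat_leak,
        n_slots=fc.n_slots,
        a_v=spec.a_v,
        gc_pm_cap=spec.gc_pm_area,
        diameter=spec.diameter,
    )
    mt_params = MTParams(
        nucleation_rate=k_nuc,
        stabilization_rate=k_stab,
        tubulin_conc=spec.tubulin_conc,
        hydrolysis_rate=spec.hydrolysis_rate,
        n_cross=spec.n_cross,
        surfaces=surfaces,
    )

    pools = _steady_state_pools(spec, fluxes)
    class_order = ("A_G", "B_G", "A_PM", "B_PM")
    counts = np.array([pools["counts"][n] for n in class_order])
    pves = np.zeros((len(SPECIES), 4, 3))
    for ci, name in enumerate(class_order):
        for comp in range(3):
            pves[:, ci, comp] = counts[ci, comp] * det["load"][name]
    porg = np.column_stack(
        [det["conc_tgn"] * fc.area_tgn0, det["conc_gc"] * spec.gc_pm_area]
    )
    lbar = mt_params.mean_length
    l_stable0 = (fc.initial_length - 0.0) * spec.n_cross - spec.dynamic_span * spec.n_cross
    if l_stable0 < 0:
        raise InfeasibleSpecError(
            f"initial_length ({fc.initial_length} um) must be at least the "
            f"dynamic span ({spec.dynamic_span} um)"
        )
    state0 = SystemState(
        vesicles=VesicleSystemState(
            area_tgn=fc.area_tgn0,
            area_gc_pm=spec.gc_pm_area,
            area_shaft=math.pi * spec.diameter * fc.initial_length,
            counts=counts,
            protein_ves=pves,
            protein_org=porg,
        ),
        mt=MTPopulationState(
            n_dyn=n_dyn,
            L_dyn_total=n_dyn * lbar,
            L_stable_total=l_stable0,
        ),
    )
    report = {
        "velocity_um_per_h": spec.velocity,
        "phi_i": fluxes.phi_i,
        "phi_ii": fluxes.phi_ii,
        "phi_iii": fluxes.phi_iii,
        "phi_iv": fluxes.phi_iv,
        "budding_area": fluxes.budding_area,
        "gc_fusion_area": fluxes.gc_fusion_area,
        "endocytosis_area": fluxes.endocytosis_area,
        "nsc_accumulation_vesicles_per_min": fluxes.nsc_accumulation_vesicles_per_min,
        "vsnare_v_total": vv_total,
        "vsnare_v_per_vesicle": v_v,
        "vsnare_u_total": uu_total,
        "vsnare_u_per_vesicle": u_u,
        "kinesin_receptors_per_vesicle": det["n_kr"],
        "dynein_receptors_per_vesicle": det["n_dr"],
        "f_dyn": det["f_dyn"],
        "production_rates": dict(zip(SPECIES, prod.tolist())),
        "k_nuc": k_nuc,
        "k_stab": k_stab,
        "k_deg": k_deg,
        "n_dyn": n_dyn,
        "mean_mt_length_um": lbar,
    }
    return ParameterSet(
        transport=transport,
        mt=mt_params,
        state0=state0,
        fluxes=fluxes,
        report=report,
        provenance={"spec": _spec_to_dict(spec)},
    )


def _spec_to_dict(spec: SteadyStateSpec) -> dict:
    d = asdict(spec)
    d["free"]["kd"] = np.asarray(d["free"]["kd"]).tolist()
    return d


def spec_from_dict(d: dict) -> SteadyStateSpec:
    d = dict(d)
    free = dict(d.pop("free", {}))
    if "kd" in free:
        free["kd"] = np.asarray(free["kd"], dtype=float)
    return SteadyStateSpec(**d, free=FreeChoices(**free))


def with_velocity(spec: SteadyStateSpec, velocity: float) -> SteadyStateSpec:
    return replace(spec, velocity=velocity)
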