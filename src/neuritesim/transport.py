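"""Compartmental ODE model of vesicle transport and exocytosis.

Membrane is synthesised at the trans-Golgi network (TGN), leaves it in
coated vesicles, transits the cell-body (CBC), neurite-shaft (NSC) and
growth-cone (GCC) cytoplasm on microtubules, and fuses with the growth
cone plasma membrane (GC-PM).  Endocytosis at the GC-PM generates a
retrograde vesicle stream back to the TGN.  Four vesicle classes are
tracked — coat identity (A/B) crossed with origin organelle (TGN / GC-PM)
— each as a continuous pool per cytoplasmic compartment, together with
the per-pool load of four cycling membrane proteins (v-SNAREs U and V,
kinesin and dynein receptors).  Stationary species (t-SNAREs X and Y, the
recruitment factors) never enter vesicles and are plain parameters.

Key mechanisms
--------------
* **Budding** (TGN and GC-PM): vesicle flux proportional to the local
  recruitment-factor amount times a budding rate; membrane proteins are
  recruited into the bud by competitive binding to the coat
  (:func:`coat_partition`).
* **Motor-dependent transit**: the probability that a vesicle is bound to
  a microtubule follows the complement rule
  :func:`motor_bound_probability`; bound vesicles advance at the motor
  speed across the compartment, so the per-vesicle hop rate is
  ``p * speed / compartment_length``.  Because the NSC spans the growing
  shaft, its pool grows with the neurite — the stationary majority is the
  membrane reservoir, and the growing NSC is a sink for vesicles and
  their membrane proteins.
* **Fusion**: bilinear SNARE law — per-vesicle rate =
  tethering_rate x (v-SNARE per vesicle) x (t-SNARE surface density);
  V pairs with Y at the GC-PM, U with X at the TGN.
* **Overflow**: the GC-PM is capped at 50 um^2; membrane above the cap is
  added to the neurite shaft (proteins stay at the GC-PM).

Units: minutes, um, um^2, molecule counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, IntegrationError


class CompartmentId(enum.Enum):
    TGN = "TGN"
    CBC = "CBC"
    NSC = "NSC"
    GCC = "GCC"
    GC_PM = "GC_PM"
    SHAFT = "SHAFT"


class VesicleClass(enum.IntEnum):
    A_G = 0  # buds from TGN with coat A (missorted anterograde minority)
    B_G = 1  # buds from TGN with coat B (main anterograde carrier)
    A_PM = 2  # buds from GC-PM with coat A (main retrograde carrier)
    B_PM = 3  # buds from GC-PM with coat B (missorted retrograde minority)


ANTERO_CLASSES = (VesicleClass.A_G, VesicleClass.B_G)
RETRO_CLASSES = (VesicleClass.A_PM, VesicleClass.B_PM)


class ProteinSpecies(enum.Enum):
    """All membrane-associated species of the model.

    The cycling species (both v-SNAREs and both motor receptors) are
    dynamic state variables; coat proteins are budding machinery, and the
    t-SNAREs and recruitment factors are stationary at their home
    organelle (their dissociation constants for vesicle incorporation are
    effectively infinite), so they appear as parameters only.
    """

    coat_A = "coat_A"
    coat_B = "coat_B"
    recruitment_factor_1 = "recruitment_factor_1"
    recruitment_factor_2 = "recruitment_factor_2"
    vSNARE_U = "vSNARE_U"
    vSNARE_V = "vSNARE_V"
    tSNARE_X = "tSNARE_X"
    tSNARE_Y = "tSNARE_Y"
    kinesin_receptor = "kinesin_receptor"
    dynein_receptor = "dynein_receptor"

#: cycling membrane-protein species tracked in the state, in array order
SPECIES = ("vSNARE_U", "vSNARE_V", "kinesin_receptor", "dynein_receptor")
IDX_U, IDX_V, IDX_KR, IDX_DR = range(4)

#: transit compartments in array order
COMPS = ("CBC", "NSC", "GCC")
IDX_CBC, IDX_NSC, IDX_GCC = range(3)

COAT_A, COAT_B = 0, 1


def coat_partition(surface_conc: np.ndarray, kd: np.ndarray, coat: int) -> np.ndarray:
    """Fraction of a budding vesicle's protein slots taken by each species.

    Species compete for the coat: with surface concentrations ``c`` (per
    um^2) and dissociation constants ``kd[:, coat]``, the binding weight of
    species *i* is ``c_i / kd_i`` and its slot share is
    ``w_i / (1 + sum_j w_j)`` — single-species saturation, equal shares for
    equal ``c/kd``, and shares that always sum below 1.
    """
    c = np.asarray(surface_conc, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(c < 0):
        raise DomainError("surface concentrations must be >= 0")
    col = kd[:, coat] if kd.ndim == 2 else kd
    if np.any(col <= 0):
        raise DomainError("dissociation constants must be > 0")
    w = c / col
    return w / (1.0 + w.sum())


def motor_bound_probability(n_receptors: float, f_motor: float) -> float:
    """Probability that a vesicle is engaged with the microtubule.

    Each of ``n_receptors`` motor receptors independently holds a motor
    that is MT-bound with probability ``f_motor`` (motors saturating), so
    ``p = 1 - (1 - f_motor) ** n_receptors``.  ``n_receptors`` may be a
    pool-average (non-integer) count.
    """
    n = np.asarray(n_receptors, dtype=float)
    if np.any(n < 0):
        raise DomainError("n_receptors must be >= 0")
    if np.any((np.asarray(f_motor) < 0) | (np.asarray(f_motor) > 1)):
        raise DomainError("f_motor must lie in [0, 1]")
    return 1.0 - (1.0 - f_motor) ** n


def shaft_length(shaft_area: float, diameter: float) -> float:
    """Neurite shaft length from its lateral membrane area: L = A / (pi d)."""
    if diameter <= 0:
        raise DomainError("diameter must be > 0")
    return shaft_area / (np.pi * diameter)


@dataclass(frozen=True)
class TransportParams:
    """Complete kinetic parameterisation of the vesicle system."""

    synthesis_area_rate: float  # um^2/min of new membrane into the TGN
    production_rates: np.ndarray  # molecules/min per SPECIES, into the TGN
    budding_rate_tgn: float  # vesicles/min per recruitment-factor-1 molecule
    rf1_amount: float  # recruitment factor 1 at the TGN
    rf2_amount: float  # recruitment factor 2 at the GC-PM
    endocytosis_rate: float  # um^2/min internalised at the GC-PM
    tether_rate_gc: float  # um^2/(molecule.min), GC-PM tethering machinery
    tether_rate_tgn: float  # um^2/(molecule.min), TGN tethering machinery
    tsnare_x_amount: float  # t-SNARE X at the TGN (stationary)
    tsnare_y_amount: float  # t-SNARE Y at the GC-PM (stationary)
    kd: np.ndarray  # (4 species, 2 coats) dissociation constants
    f_kin: tuple  # MT-bound kinesin fraction per (CBC, NSC, GCC)
    f_dyn: tuple  # MT-bound dynein fraction per (CBC, NSC, GCC)
    transport_speed: float = 66.0  # um/min along the microtubule
    cbc_length: float = 20.0  # um traversed across the cell body
    gcc_length: float = 5.0  # um traversed across the growth cone
    coat_leak: float = 0.02  # minority-coat share of budding at each organelle
    n_slots: int = 100  # membrane-protein slots per vesicle
    a_v: float = 0.05  # um^2 membrane per vesicle
    gc_pm_cap: float = 50.0  # um^2, growth-cone P-domain area
    diameter: float = 1.0  # um, neurite diameter
    overflow_width: float = 0.02  # um^2, smoothness of the cap switch

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "production_rates", np.asarray(self.production_rates, dtype=float)
        )
        object.__setattr__(self, "kd", np.asarray(self.kd, dtype=float))
        scalars = (
            self.synthesis_area_rate,
            self.budding_rate_tgn,
            self.rf1_amount,
            self.rf2_amount,
            self.endocytosis_rate,
            self.tether_rate_gc,
            self.tether_rate_tgn,
            self.tsnare_x_amount,
            self.tsnare_y_amount,
            self.transport_speed,
        )
        if min(scalars) < 0 or np.any(self.production_rates < 0):
            raise DomainError("transport rates and amounts must be >= 0")
        if not (0 <= self.coat_leak <= 0.5):
            raise DomainError("coat_leak must lie in [0, 0.5]")
        for f in (*self.f_kin, *self.f_dyn):
            if not (0 <= f <= 1):
                raise DomainError("motor-bound fractions must lie in [0, 1]")
        if self.kd.shape != (len(SPECIES), 2) or np.any(self.kd <= 0):
            raise DomainError("kd must be a positive (n_species, 2) matrix")


@dataclass
class VesicleSystemState:
    """Membrane areas, vesicle pools and membrane-protein loads.

    ``counts`` has shape (4 classes, 3 compartments); ``protein_ves`` has
    shape (4 species, 4 classes, 3 compartments) holding total molecule
    counts per pool; ``protein_org`` has shape (4 species, 2) for the TGN
    and GC-PM surfaces.
    """

    area_tgn: float
    area_gc_pm: float
    area_shaft: float
    counts: np.ndarray
    protein_ves: np.ndarray
    protein_org: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.protein_ves = np.asarray(self.protein_ves, dtype=float)
        self.protein_org = np.asarray(self.protein_org, dtype=float)

    SIZE = 3 + 12 + 48 + 8

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                [self.area_tgn, self.area_gc_pm, self.area_shaft],
                self.counts.ravel(),
                self.protein_ves.ravel(),
                self.protein_org.ravel(),
            ]
        )

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "VesicleSystemState":
        y = np.asarray(y, dtype=float)
        return cls(
            area_tgn=y[0],
            area_gc_pm=y[1],
            area_shaft=y[2],
            counts=y[3:15].reshape(4, 3),
            protein_ves=y[15:63].reshape(4, 4, 3),
            protein_org=y[63:71].reshape(4, 2),
        )

    def neurite_length(self, diameter: float = 1.0) -> float:
        return shaft_length(self.area_shaft, diameter)

    def total_membrane_area(self, a_v: float = 0.05) -> float:
        return (
            self.area_tgn
            + self.area_gc_pm
            + self.area_shaft
            + a_v * float(self.counts.sum())
        )

    def total_protein(self) -> np.ndarray:
        """Total molecules per species across vesicles and organelles."""
        return self.protein_ves.sum(axis=(1, 2)) + self.protein_org.sum(axis=1)

    def copy(self) -> "VesicleSystemState":
        return VesicleSystemState(
            self.area_tgn,
            self.area_gc_pm,
            self.area_shaft,
            self.counts.copy(),
            self.protein_ves.copy(),
            self.protein_org.copy(),
        )


def overflow_to_shaft(state: VesicleSystemState, cap: float = 50.0) -> VesicleSystemState:
    """Clamp the GC-PM at its cap, moving excess membrane to the shaft.

    Protein content is untouched: membrane proteins stay at the GC-PM.
    """
    out = state.copy()
    if out.area_gc_pm > cap:
        out.area_shaft += out.area_gc_pm - cap
        out.area_gc_pm = cap
    return out


_TINY = 1e-12


def _per_vesicle_loads(state: VesicleSystemState) -> np.ndarray:
    """(species, class, comp) average loads; zero where the pool is empty."""
    n = np.maximum(state.counts, _TINY)
    loads = state.protein_ves / n[None, :, :]
    loads[:, state.counts <= _TINY] = 0.0
    return loads


def vesicle_fluxes(state: VesicleSystemState, params: TransportParams) -> dict:
    """Evaluate every membrane/vesicle/protein flux at a state.

    Returns a dictionary of named fluxes used both by :func:`vesicle_rhs`
    and by trajectory diagnostics; all vesicle fluxes are per minute, area
    fluxes in um^2/min.
    """
    p = params
    if state.area_tgn <= 0:
        raise IntegrationError("TGN membrane area is non-positive")
    L = max(shaft_length(state.area_shaft, p.diameter), 1e-6)
    loads = _per_vesicle_loads(state)

    # --- budding at the TGN --------------------------------------------
    f_bud = p.budding_rate_tgn * p.rf1_amount  # vesicles/min
    conc_tgn = np.maximum(state.protein_org[:, 0], 0.0) / state.area_tgn
    share_tgn = {
        COAT_A: coat_partition(conc_tgn, p.kd, COAT_A),
        COAT_B: coat_partition(conc_tgn, p.kd, COAT_B),
    }
    bud_flux = {
        VesicleClass.A_G: p.coat_leak * f_bud,
        VesicleClass.B_G: (1.0 - p.coat_leak) * f_bud,
    }

    # --- endocytosis at the GC-PM --------------------------------------
    f_endo = p.endocytosis_rate / p.a_v  # vesicles/min
    area_gc = max(state.area_gc_pm, 1e-6)
    conc_gc = np.maximum(state.protein_org[:, 1], 0.0) / area_gc
    share_gc = {
        COAT_A: coat_partition(conc_gc, p.kd, COAT_A),
        COAT_B: coat_partition(conc_gc, p.kd, COAT_B),
    }
    endo_flux = {
        VesicleClass.A_PM: (1.0 - p.coat_leak) * f_endo,
        VesicleClass.B_PM: p.coat_leak * f_endo,
    }

    # --- motor-dependent transit ---------------------------------------
    hop = np.zeros((4, 3))  # per-vesicle exit-toward-target rate, 1/min
    comp_len = {IDX_CBC: p.cbc_length, IDX_NSC: L, IDX_GCC: p.gcc_length}
    for vc in ANTERO_CLASSES:
        for comp in (IDX_CBC, IDX_NSC):  # GCC exit is fusion, not transit
            pb = motor_bound_probability(loads[IDX_KR, vc, comp], p.f_kin[comp])
            hop[vc, comp] = pb * p.transport_speed / comp_len[comp]
    for vc in RETRO_CLASSES:
        for comp in (IDX_GCC, IDX_NSC):  # CBC exit is fusion with the TGN
            pb = motor_bound_probability(loads[IDX_DR, vc, comp], p.f_dyn[comp])
            hop[vc, comp] = pb * p.transport_speed / comp_len[comp]

    # --- SNARE fusion ----------------------------------------------------
    y_conc = p.tsnare_y_amount / area_gc
    x_conc = p.tsnare_x_amount / state.area_tgn
    fuse_gc = np.zeros(4)  # vesicles/min fusing with GC-PM, per class
    fuse_tgn = np.zeros(4)  # vesicles/min fusing with TGN, per class
    for vc in ANTERO_CLASSES:
        fuse_gc[vc] = p.tether_rate_gc * state.protein_ves[IDX_V, vc, IDX_GCC] * y_conc
    for vc in RETRO_CLASSES:
        fuse_tgn[vc] = p.tether_rate_tgn * state.protein_ves[IDX_U, vc, IDX_CBC] * x_conc

    fusion_area_gc = p.a_v * float(fuse_gc.sum())
    net_gc = fusion_area_gc - p.endocytosis_rate
    switch = 0.5 * (1.0 + np.tanh((state.area_gc_pm - p.gc_pm_cap) / p.overflow_width))
    overflow = switch * max(net_gc, 0.0)

    return {
        "bud_flux": bud_flux,
        "endo_flux": endo_flux,
        "share_tgn": share_tgn,
        "share_gc": share_gc,
        "hop": hop,
        "fuse_gc": fuse_gc,
        "fuse_tgn": fuse_tgn,
        "fusion_area_gc": fusion_area_gc,
        "retro_fusion_area_tgn": p.a_v * float(fuse_tgn.sum()),
        "endocytosis_area": p.endocytosis_rate,
        "overflow_area": overflow,
        "loads": loads,
        "neurite_length": L,
    }


def vesicle_rhs(state: VesicleSystemState, params: TransportParams) -> np.ndarray:
    """Time derivative of the packed vesicle state vector (per minute)."""
    y = state.to_vector()
    if np.min(y) < -1e-5 * (1.0 + np.max(np.abs(y))):
        bad = int(np.argmin(y))
        raise IntegrationError(
            f"negative state component at index {bad}: {y[bad]:.3e}; state={y}"
        )
    p = params
    fl = vesicle_fluxes(state, params)
    loads = fl["loads"]

    d_counts = np.zeros((4, 3))
    d_pves = np.zeros((4, 4, 3))
    d_porg = np.zeros((4, 2))

    # synthesis (membrane and protein production at the TGN)
    d_area_tgn = p.synthesis_area_rate
    d_porg[:, 0] += p.production_rates

    # budding TGN -> CBC
    for vc, coat in ((VesicleClass.A_G, COAT_A), (VesicleClass.B_G, COAT_B)):
        f = fl["bud_flux"][vc]
        load = p.n_slots * fl["share_tgn"][coat]
        d_area_tgn -= f * p.a_v
        d_counts[vc, IDX_CBC] += f
        d_pves[:, vc, IDX_CBC] += f * load
        d_porg[:, 0] -= f * load

    # endocytosis GC-PM -> GCC
    d_area_gc = -p.endocytosis_rate
    for vc, coat in ((VesicleClass.A_PM, COAT_A), (VesicleClass.B_PM, COAT_B)):
        f = fl["endo_flux"][vc]
        load = p.n_slots * fl["share_gc"][coat]
        d_counts[vc, IDX_GCC] += f
        d_pves[:, vc, IDX_GCC] += f * load
        d_porg[:, 1] -= f * load

    # transit along the chain
    for vc in ANTERO_CLASSES:
        for comp, nxt in ((IDX_CBC, IDX_NSC), (IDX_NSC, IDX_GCC)):
            j = fl["hop"][vc, comp] * state.counts[vc, comp]
            d_counts[vc, comp] -= j
            d_counts[vc, nxt] += j
            jp = fl["hop"][vc, comp] * state.protein_ves[:, vc, comp]
            d_pves[:, vc, comp] -= jp
            d_pves[:, vc, nxt] += jp
    for vc in RETRO_CLASSES:
        for comp, nxt in ((IDX_GCC, IDX_NSC), (IDX_NSC, IDX_CBC)):
            j = fl["hop"][vc, comp] * state.counts[vc, comp]
            d_counts[vc, comp] -= j
            d_counts[vc, nxt] += j
            jp = fl["hop"][vc, comp] * state.protein_ves[:, vc, comp]
            d_pves[:, vc, comp] -= jp
            d_pves[:, vc, nxt] += jp

    # fusion with the GC-PM (anterograde, from GCC)
    for vc in ANTERO_CLASSES:
        j = fl["fuse_gc"][vc]
        if state.counts[vc, IDX_GCC] > _TINY:
            rate = j / state.counts[vc, IDX_GCC]
        else:
            rate = 0.0
            j = 0.0
        d_counts[vc, IDX_GCC] -= j
        d_area_gc += j * p.a_v
        jp = rate * state.protein_ves[:, vc, IDX_GCC]
        d_pves[:, vc, IDX_GCC] -= jp
        d_porg[:, 1] += jp

    # fusion with the TGN (retrograde, from CBC)
    for vc in RETRO_CLASSES:
        j = fl["fuse_tgn"][vc]
        if state.counts[vc, IDX_CBC] > _TINY:
            rate = j / state.counts[vc, IDX_CBC]
        else:
            rate = 0.0
            j = 0.0
        d_counts[vc, IDX_CBC] -= j
        d_area_tgn += j * p.a_v
        jp = rate * state.protein_ves[:, vc, IDX_CBC]
        d_pves[:, vc, IDX_CBC] -= jp
        d_porg[:, 0] += jp

    # GC-PM cap: membrane above 50 um^2 is routed to the neurite shaft
    d_area_gc -= fl["overflow_area"]
    d_area_shaft = fl["overflow_area"]

    return np.concatenate(
        [
            [d_area_tgn, d_area_gc, d_area_shaft],
            d_counts.ravel(),
            d_pves.ravel(),
            d_porg.ravel(),
        ]
    )
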