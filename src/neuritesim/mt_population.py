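"""Deterministic population model of dynamic and stable microtubules.

Single dynamic microtubules turn over in seconds to minutes, while neurite
outgrowth is simulated over days, so individual filaments are not tracked.
The dynamic pool is treated as instantaneously equilibrated at the mean
length L̄(Tu, h) from the fitted response surfaces: the only slow dynamic
variable is the filament count ``n_dyn``.  Dynamic filaments nucleate at a
constant rate, disappear by complete catastrophic breakdown at
k_deg(Tu, h), and convert to stable filaments at the stabilization rate;
stable filaments never shrink and form the growing neurite scaffold.  The
microtubule-bundle (MTB) length is the summed length of both pools divided
by the number of filaments per neurite cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .surfaces import ResponseSurfaces


@dataclass(frozen=True)
class MTParams:
    """Rates of the population model (per minute)."""

    nucleation_rate: float  # new dynamic MTs per min
    stabilization_rate: float  # dynamic -> stable conversion, 1/min
    tubulin_conc: float  # uM
    hydrolysis_rate: float  # 1/s
    n_cross: int  # MTs per neurite cross-section
    surfaces: ResponseSurfaces

    def __post_init__(self) -> None:
        if self.nucleation_rate < 0 or self.stabilization_rate < 0:
            raise DomainError("rates must be >= 0")
        if self.n_cross < 1:
            raise DomainError("n_cross must be >= 1")
        # raises DomainError when outside the fitted rectangle
        self.surfaces._check_domain(self.tubulin_conc, self.hydrolysis_rate)

    @property
    def mean_length(self) -> float:
        return float(self.surfaces.mean_length(self.tubulin_conc, self.hydrolysis_rate))

    @property
    def degradation_rate(self) -> float:
        return float(
            self.surfaces.degradation_rate(self.tubulin_conc, self.hydrolysis_rate)
        )


@dataclass
class MTPopulationState:
    n_dyn: float  # count of dynamic MTs
    L_dyn_total: float  # summed dynamic length, um (== n_dyn * Lbar)
    L_stable_total: float  # summed stable length, um

    def __post_init__(self) -> None:
        if min(self.n_dyn, self.L_dyn_total, self.L_stable_total) < 0:
            raise DomainError("population state components must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.n_dyn, self.L_dyn_total, self.L_stable_total])


def mt_population_rhs(state: MTPopulationState, params: MTParams) -> np.ndarray:
    """Time derivatives (per minute) of (n_dyn, L_dyn_total, L_stable_total).

    dn/dt = k_nuc - (k_deg + k_stab) n.  The dynamic pool is closed at
    L_dyn_total = n_dyn * L̄, so its derivative is slaved to dn/dt; the
    stable pool gains converted filaments at their average length and never
    shrinks.
    """
    k_deg = params.degradation_rate
    k_stab = params.stabilization_rate
    lbar = params.mean_length
    dn = params.nucleation_rate - (k_deg + k_stab) * state.n_dyn
    dl_dyn = lbar * dn
    dl_stable = k_stab * state.n_dyn * lbar
    return np.array([dn, dl_dyn, dl_stable])


def mtb_length(state: MTPopulationState, n_cross: int) -> float:
    """Microtubule-bundle length: total MT length per cross-section, um."""
    if n_cross < 1:
        raise DomainError("n_cross must be >= 1")
    return (state.L_dyn_total + state.L_stable_total) / n_cross


def n_dyn_closed_form(
    t: np.ndarray, n0: float, params: MTParams
) -> np.ndarray:
    """Closed-form n_dyn(t) for constant parameters (linear-ODE oracle)."""
    k = params.degradation_rate + params.stabilization_rate
    if k == 0:
        return n0 + params.nucleation_rate * np.asarray(t, dtype=float)
    n_inf = params.nucleation_rate / k
    return n_inf + (n0 - n_inf) * np.exp(-k * np.asarray(t, dtype=float))


def integrate_population(
    state0: MTPopulationState,
    params: MTParams,
    t_end: float,
    record_every: float = 500.0,
):
    """Integrate the population ODE and record checkpoints.

    Returns ``(times_min, states)`` where ``states`` has one row per
    checkpoint, columns (n_dyn, L_dyn_total, L_stable_total).  The system
    is linear with constant coefficients, so the closed form is used.
    """
    if t_end <= 0:
        raise DomainError("t_end must be > 0")
    times = np.arange(0.0, t_end + 0.5 * record_every, record_every)
    n = n_dyn_closed_form(times, state0.n_dyn, params)
    lbar = params.mean_length
    k_stab = params.stabilization_rate
    k = params.degradation_rate + k_stab
    # integral of n(t) dt in closed form feeds the stable pool
    if k == 0:
        integral = state0.n_dyn * times + 0.5 * params.nucleation_rate * times**2
    else:
        n_inf = params.nucleation_rate / k
        integral = n_inf * times + (state0.n_dyn - n_inf) * (1 - np.exp(-k * times)) / k
    l_stable = state0.L_stable_total + k_stab * lbar * integral
    l_dyn = n * lbar
    return times, np.column_stack([n, l_dyn, l_stable])
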