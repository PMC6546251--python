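"""Analytical steady-state solver: flux algebra, inversions, monotonicity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import neuritesim as ns
from neuritesim.solver import (
    FreeChoices,
    solve_dynein_fraction,
    solve_kinesin_receptors,
)
from neuritesim.transport import COAT_B, IDX_V


class TestFluxDecomposition:
    def test_shaft_flux_from_velocity_and_geometry(self):
        """10 um/h through a 1 um diameter tube needs 0.5236 um^2/min."""
        fl = ns.decompose_fluxes(ns.SteadyStateSpec(velocity=10.0))
        assert fl.phi_ii == pytest.approx(0.5236, rel=1e-3)
        assert fl.phi_iv == 0.5

    def test_zero_velocity_is_pure_cycling(self):
        fl = ns.decompose_fluxes(ns.SteadyStateSpec(velocity=0.0))
        assert fl.phi_i == 0.0 and fl.phi_ii == 0.0 and fl.phi_iii == 0.0
        c = fl.phi_iv
        assert fl.budding_area == pytest.approx(c)
        assert fl.gc_fusion_area == pytest.approx(c)
        assert fl.endocytosis_area == pytest.approx(c)

    def test_baseline_reservoir_accumulation(self):
        """The closure puts the 10 um/h NSC accumulation near 0.57
        vesicles/min."""
        fl = ns.decompose_fluxes(ns.SteadyStateSpec(velocity=10.0))
        assert fl.nsc_accumulation_vesicles_per_min == pytest.approx(0.57, rel=0.10)

    @given(v=st.floats(0.0, 20.0), c=st.floats(0.05, 1.0))
    def test_flux_invariants(self, v, c):
        """Either a valid decomposition (with the geometric identities) or
        an explicit infeasibility: a small cycling rate with fast growth
        makes the return-leg cargo exceed vesicle capacity."""
        try:
            fl = ns.decompose_fluxes(ns.SteadyStateSpec(velocity=v, cycling_rate=c))
        except ns.InfeasibleSpecError:
            return
        assert fl.phi_iv == c
        assert fl.phi_ii == pytest.approx(math.pi * v / 60.0)
        assert min(fl.phi_i, fl.phi_ii, fl.phi_iii, fl.phi_iv) >= 0


class TestSnareInversion:
    def test_doubling_tethering_halves_required_V(self):
        spec = ns.SteadyStateSpec(velocity=10.0)
        fl = ns.decompose_fluxes(spec)
        _, v1, _ = ns.required_snare_V(spec, fl, 5e-4)
        _, v2, _ = ns.required_snare_V(spec, fl, 1e-3)
        assert v1 == pytest.approx(2 * v2)

    def test_fusion_flux_identical_across_pairs(self):
        """Different (v-SNARE V, tethering) pairs solved for the same
        velocity produce the same fusion flux."""
        fluxes = []
        for tf in (0.5, 0.75, 1.0, 1.5, 2.0):
            spec = ns.SteadyStateSpec(
                velocity=15.0, free=FreeChoices(tether_rate_gc=5e-4 * tf)
            )
            fluxes.append(ns.decompose_fluxes(spec).gc_fusion_area)
        assert np.allclose(fluxes, fluxes[0], rtol=1e-9)

    def test_vesicle_borne_vv_vanishes_with_fusion_flux(self):
        """As the fusion flux goes to zero, the vesicle-borne v-SNARE V
        vanishes with it; only the standing organelle surface pool (needed
        to load any future vesicle at the postulated rate) remains."""
        spec = ns.SteadyStateSpec(velocity=0.0, cycling_rate=1e-9)
        fl = ns.decompose_fluxes(spec)
        vv_small, _, _ = ns.required_snare_V(spec, fl, 5e-4)
        base = ns.SteadyStateSpec(velocity=10.0)
        vv_base, _, _ = ns.required_snare_V(base, ns.decompose_fluxes(base), 5e-4)
        organelle_standing = (
            fl.detail["conc_tgn"][IDX_V] * spec.free.area_tgn0
            + fl.detail["conc_gc"][IDX_V] * spec.gc_pm_area
        )
        assert vv_small == pytest.approx(organelle_standing, rel=1e-3)
        assert vv_small < 0.01 * vv_base

    def test_halving_tgn_tethering_doubles_U(self):
        spec = ns.SteadyStateSpec(velocity=10.0)
        fl = ns.decompose_fluxes(spec)
        _, u1, _ = ns.required_snare_U(spec, fl, 4.5e-3)
        _, u2, _ = ns.required_snare_U(spec, fl, 2.25e-3)
        assert u2 == pytest.approx(2 * u1)

    def test_u_independent_of_velocity_at_fixed_cycling(self):
        us = []
        for v in (5.0, 10.0, 20.0):
            spec = ns.SteadyStateSpec(velocity=v)
            us.append(ns.required_snare_U(spec, ns.decompose_fluxes(spec), 4.5e-3)[1])
        assert np.allclose(us, us[0])

    def test_concentration_round_trip(self):
        """Solved surface concentrations reproduce the required loads
        through the coat partition to 1e-8."""
        loads = np.array([4.89, 10.0, 2.0, 1.47])
        kd = np.full(4, 0.5)
        conc = ns.snare_surface_concentrations(loads, kd, 100)
        back = 100 * ns.coat_partition(conc, np.column_stack([kd, kd]), COAT_B)
        assert np.allclose(back, loads, atol=1e-8)

    def test_symmetric_loads_give_symmetric_concentrations(self):
        conc = ns.snare_surface_concentrations(
            np.array([5.0, 5.0, 0.0, 0.0]), np.full(4, 0.5), 100
        )
        assert conc[0] == pytest.approx(conc[1])

    def test_capacity_exceeded_is_infeasible(self):
        with pytest.raises(ns.InfeasibleSpecError):
            ns.snare_surface_concentrations(np.array([60.0, 50.0, 0, 0]), np.full(4, 0.5), 100)


class TestProductionRates:
    def test_zero_velocity_zero_production(self):
        spec = ns.SteadyStateSpec(velocity=0.0)
        prod = ns.production_rates(ns.decompose_fluxes(spec), spec)
        assert np.allclose(prod, 0.0)

    def test_production_equals_reservoir_accumulation(self):
        """Production = NSC accumulation x per-vesicle load, per species."""
        spec = ns.SteadyStateSpec(velocity=10.0)
        fl = ns.decompose_fluxes(spec)
        prod = ns.production_rates(fl, spec)
        det = fl.detail
        v60 = 10.0 / 60.0
        expected = sum(
            det["dens_per_um"][name] * v60 * det["load"][name]
            for name in ("A_G", "B_G", "A_PM", "B_PM")
        )
        assert np.allclose(prod, expected)
        assert np.all(prod >= 0)


class TestMtSteadyState:
    def _const_surface(self, lbar, kdeg):
        import itertools

        import pandas as pd

        rows = [
            dict(
                tubulin_conc=tu,
                hydrolysis_rate=h,
                mean_length_um=lbar,
                degradation_rate_per_min=kdeg,
            )
            for tu, h in itertools.product((8, 8.7, 9.3, 10), (0.65, 0.68, 0.72, 0.75))
        ]
        return ns.fit_surfaces(pd.DataFrame(rows))

    def test_count_from_span(self):
        surf = self._const_surface(2.0, 0.01)
        spec = ns.SteadyStateSpec(velocity=10.0, dynamic_span=20.0, n_cross=10)
        k_nuc, k_stab, n_dyn, k_deg = ns.mt_steady_state(spec, surf)
        assert n_dyn == pytest.approx(100.0, rel=1e-6)
        # stable growth balance: k_stab n L = (v/60) n_cross
        assert k_stab == pytest.approx((10 / 60 * 10) / (100 * 2.0), rel=1e-6)
        assert k_nuc == pytest.approx((k_deg + k_stab) * 100.0, rel=1e-6)

    def test_nucleation_balance_example(self):
        surf = self._const_surface(2.0, 0.01)
        spec = ns.SteadyStateSpec(velocity=10.0)
        k_nuc, k_stab, n_dyn, k_deg = ns.mt_steady_state(spec, surf)
        assert k_nuc == pytest.approx((k_deg + k_stab) * n_dyn)


class TestComplementarity:
    def test_kinesin_requirement_decreases_with_bound_fraction(self):
        """More MT-bound kinesin means fewer receptors are needed to meet
        the moving-fraction postulate (strict, on the exact requirement)."""
        exact = [
            math.log(0.9) / math.log(1 - f) for f in np.arange(0.1, 1.0, 0.1)
        ]
        assert np.all(np.diff(exact) < 0)
        assert solve_kinesin_receptors(0.10, 0.1) == 1

    def test_vv_requirement_decreases_with_tethering(self, surfaces):
        vvs = []
        for tf in (0.5, 1.0, 1.5, 2.0):
            spec = ns.SteadyStateSpec(
                velocity=15.0, free=FreeChoices(tether_rate_gc=5e-4 * tf)
            )
            pset = ns.predict_parameter_set(spec, surfaces)
            vvs.append(pset.report["vsnare_v_total"])
        assert np.all(np.diff(vvs) < 0)

    def test_rf1_budding_rate_inverse(self):
        spec = ns.SteadyStateSpec(velocity=10.0)
        flux = ns.decompose_fluxes(spec).budding_area / spec.a_v
        rates = [flux / rf1 for rf1 in (250, 500, 1000, 2000)]
        assert np.all(np.diff(rates) < 0)
        assert np.allclose([r * rf for r, rf in zip(rates, (250, 500, 1000, 2000))], flux)

    def test_velocity_monotonicity(self, surfaces):
        """Budding flux, total v-SNARE V and nucleation rate all grow
        with the target velocity at fixed free choices."""
        buds, vvs, nucs = [], [], []
        for v in (0.0, 5.0, 10.0, 20.0):
            pset = ns.predict_parameter_set(ns.SteadyStateSpec(velocity=v), surfaces)
            buds.append(pset.report["budding_area"])
            vvs.append(pset.report["vsnare_v_total"])
            nucs.append(pset.report["k_nuc"])
        assert np.all(np.diff(buds) > 0)
        assert np.all(np.diff(vvs) > 0)
        assert np.all(np.diff(nucs) >= 0)


class TestParameterSet:
    def test_json_round_trip(self, tmp_path, baseline_pset):
        path = tmp_path / "pset.json"
        baseline_pset.to_json(path)
        back = ns.ParameterSet.from_json(path)
        assert back.transport.synthesis_area_rate == baseline_pset.transport.synthesis_area_rate
        assert np.allclose(back.transport.production_rates, baseline_pset.transport.production_rates)
        assert np.allclose(
            back.state0.vesicles.protein_ves, baseline_pset.state0.vesicles.protein_ves
        )
        assert back.mt.nucleation_rate == baseline_pset.mt.nucleation_rate
        assert back.mt.mean_length == pytest.approx(baseline_pset.mt.mean_length)
        assert back.report["velocity_um_per_h"] == 10.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ns.DomainError):
            ns.SteadyStateSpec(velocity=-1.0)
        with pytest.raises(ns.DomainError):
            ns.SteadyStateSpec(velocity=10.0, cycling_rate=-0.5)

    def test_dynein_fraction_solves_postulate(self):
        f = solve_dynein_fraction(0.9, 3)
        assert ns.motor_bound_probability(3, f) == pytest.approx(0.9)
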