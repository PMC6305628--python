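"""Heating rate, Pennes solver, CEM43 dose and lesion metrics against
closed-form and heat-kernel oracles."""

import numpy as np
import pytest

import hifupwm as hp
from hifupwm.bioheat import (CEM43_THRESHOLD_MIN, TemperatureHistory,
                             cell_volumes, max_stable_dt)
from _oracles import heat_kernel_gaussian


def _grid(n=65, spacing=0.2e-3):
    return hp.Grid(np.arange(n) * spacing, np.arange(n) * spacing)


def _props(**kw):
    defaults = dict(density=1060.0, sound_speed=1547.0, specific_heat=3421.0,
                    conductivity=0.49, perfusion_rate=0.0)
    defaults.update(kw)
    return hp.ThermalProperties(**defaults)


class TestHeatingRate:
    def _fmap(self, p_pa, grid):
        return hp.FieldMap(grid=grid,
                           pressures={1: np.full(grid.shape, p_pa)},
                           fundamental_frequency=1.1e6)

    def test_direct_substitution(self):
        """alpha p^2 / (rho c): 5 Np/m x (1 MPa)^2 / 1.5e6 ~ 3.33e6 W/m^3."""
        grid = _grid(5)
        props = hp.ThermalProperties(density=1000.0, sound_speed=1500.0,
                                     absorption_per_harmonic=(5.0,))
        Q = hp.heating_rate(self._fmap(1e6, grid), props)
        assert np.allclose(Q, 5.0 * 1e12 / 1.5e6)

    def test_additive_over_harmonics(self):
        grid = _grid(5)
        p = np.full(grid.shape, 1e6)
        fmap6 = hp.FieldMap(grid=grid, pressures={h: p for h in range(1, 7)},
                            fundamental_frequency=1.1e6)
        props = hp.ThermalProperties(density=1000.0, sound_speed=1500.0,
                                     absorption_per_harmonic=(5.0,) * 6)
        Q6 = hp.heating_rate(fmap6, props)
        Q1 = hp.heating_rate(self._fmap(1e6, grid),
                             hp.ThermalProperties(density=1000.0,
                                                  sound_speed=1500.0,
                                                  absorption_per_harmonic=(5.0,)))
        assert np.allclose(Q6, 6 * Q1)

    def test_quadratic_in_pressure(self):
        grid = _grid(5)
        props = hp.ThermalProperties(density=1000.0, sound_speed=1500.0,
                                     absorption_per_harmonic=(5.0,))
        Q1 = hp.heating_rate(self._fmap(1e6, grid), props)
        Q2 = hp.heating_rate(self._fmap(2e6, grid), props)
        assert np.allclose(Q2, 4 * Q1)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            hp.FieldMap(grid=_grid(5), pressures={1: np.zeros((3, 3))},
                        fundamental_frequency=1.1e6)
        with pytest.raises(ValueError, match="absorption"):
            hp.heating_rate(self._fmap(1e6, _grid(5)),
                            hp.ThermalProperties(absorption_per_harmonic=()))


class TestPennes:
    def test_zero_source_equilibrium(self):
        grid = _grid(17)
        hist = hp.pennes_solve(np.zeros(grid.shape), _props(), grid,
                               t_on=1.0, t_cool=0.5)
        assert np.all(hist.frames == 37.0)

    def test_conduction_free_linear_ramp(self):
        """k_t = 0, w_b = 0, uniform Q: exact ramp then flat."""
        grid = _grid(9)
        props = _props(conductivity=0.0)
        Q = np.full(grid.shape, 1e6)
        hist = hp.pennes_solve(Q, props, grid, t_on=2.0, t_cool=1.0, dt=0.01)
        rho_cp = props.density * props.specific_heat
        expect_end = 37.0 + 1e6 * 2.0 / rho_cp
        i_on = int(round(2.0 / hist.dt))
        assert np.allclose(hist.frames[i_on], expect_end, rtol=1e-12)
        assert np.allclose(hist.frames[-1], expect_end, rtol=1e-12)
        # mid-ramp exactness
        assert np.allclose(hist.frames[i_on // 2],
                           37.0 + 1e6 * (i_on // 2) * hist.dt / rho_cp,
                           rtol=1e-12)

    def test_gaussian_pulse_spread_matches_heat_kernel(self):
        """A conduction-only Gaussian pulse follows the analytic kernel:
        sigma^2 grows by 2 kappa t per axis, amplitude by (s0/s)^3."""
        grid = _grid(65, 0.2e-3)
        props = _props()
        sigma0, amp0, zc = 0.6e-3, 10.0, 6.4e-3
        T0 = 37.0
        T_init = T0 + heat_kernel_gaussian(grid.r, grid.z, zc, amp0, sigma0,
                                           props.diffusivity, 0.0)
        t_end = 1.0
        hist = hp.pennes_solve(np.zeros(grid.shape), props, grid,
                               t_on=0.0, t_cool=t_end, dt=0.02,
                               T_init=T_init)
        expect = T0 + heat_kernel_gaussian(grid.r, grid.z, zc, amp0, sigma0,
                                           props.diffusivity, t_end)
        err = np.abs(hist.frames[-1] - expect).max()
        assert err <= 0.02 * amp0

    def test_energy_conservation_insulated(self):
        """With w_b = 0 total enthalpy rise equals the injected energy to
        numerical roundoff (the radial scheme is flux-conservative)."""
        grid = _grid(33, 0.4e-3)
        props = _props()
        Q = np.zeros(grid.shape)
        Q[3:8, 10:20] = 5e7
        t_on = 1.0
        hist = hp.pennes_solve(Q, props, grid, t_on=t_on, t_cool=0.5, dt=0.05)
        vol = cell_volumes(grid)
        rho_cp = props.density * props.specific_heat
        enthalpy = (rho_cp * (hist.frames[-1] - 37.0) * vol).sum()
        injected = (Q * vol).sum() * t_on
        assert enthalpy == pytest.approx(injected, rel=1e-9)

    def test_perfusion_sink_closed_form(self):
        """Conduction-free uniform heating with perfusion approaches the
        exponential-relaxation closed form."""
        grid = _grid(9)
        props = _props(conductivity=0.0, perfusion_rate=0.01)
        Q = np.full(grid.shape, 1e6)
        dt = 1e-3
        hist = hp.pennes_solve(Q, props, grid, t_on=5.0, t_cool=0.0, dt=dt)
        rho_cp = props.density * props.specific_heat
        w = props.perfusion_rate * props.blood_density * \
            props.blood_specific_heat / rho_cp
        expect = 37.0 + 1e6 / (rho_cp * w) * (1 - np.exp(-w * 5.0))
        assert hist.frames[-1][0, 0] == pytest.approx(expect, rel=1e-3)

    def test_unstable_dt_rejected_with_suggestion(self):
        grid = _grid(17)
        props = _props()
        bound = max_stable_dt(props, grid)
        with pytest.raises(ValueError, match="maximum stable"):
            hp.pennes_solve(np.zeros(grid.shape), props, grid, dt=2 * bound)


class TestCem43:
    def _const_history(self, temp, minutes, grid=None, n=121):
        grid = grid or _grid(3)
        dt = minutes * 60.0 / (n - 1)
        frames = np.full((n,) + grid.shape, float(temp))
        return TemperatureHistory(times=np.arange(n) * dt, frames=frames,
                                  grid=grid)

    def test_reference_temperature_identity(self):
        dose = hp.cem43(self._const_history(43.0, 240.0))
        assert np.allclose(dose.cem43_min, 240.0)

    def test_47c_shortcut(self):
        """Each degree above 43 C doubles the rate: 15 min at 47 C = 240."""
        dose = hp.cem43(self._const_history(47.0, 15.0))
        assert np.allclose(dose.cem43_min, 240.0)

    def test_body_temperature_negligible(self):
        dose = hp.cem43(self._const_history(37.0, 0.5))
        assert np.all(dose.cem43_min < 1e-3)

    def test_monotone_in_exposure_time(self):
        d1 = hp.cem43(self._const_history(45.0, 5.0))
        d2 = hp.cem43(self._const_history(45.0, 10.0))
        assert np.all(d2.cem43_min >= d1.cem43_min)


class TestLesionMetrics:
    def test_empty_lesion(self):
        grid = _grid(11)
        dose = hp.ThermalDoseMap(grid, np.zeros(grid.shape))
        m = hp.lesion_metrics(dose)
        assert m.area_mm2 == 0.0 and m.n_cells == 0

    def test_half_ellipse_area(self):
        """A half-ellipse lesion of semi-axes 5 mm (axial) x 1.5 mm
        (radial) has a mirrored cross-section close to pi a b."""
        spacing = 0.2e-3
        grid = hp.Grid(np.arange(0, 3e-3, spacing),
                       np.arange(0, 14e-3, spacing))
        a, b, zc = 5e-3, 1.5e-3, 7e-3
        RR, ZZ = np.meshgrid(grid.r, grid.z, indexing="ij")
        inside = (RR / b) ** 2 + ((ZZ - zc) / a) ** 2 <= 1.0
        dose = hp.ThermalDoseMap(grid, np.where(inside, 1e4, 0.0))
        m = hp.lesion_metrics(dose)
        expect = np.pi * a * b * 1e6  # mm^2
        # within one cell-ring of the analytic ellipse area
        perimeter_cells = np.pi * (a + b) * 1e3 / (spacing * 1e3)
        tol = perimeter_cells * (spacing * 1e3) ** 2 * 2
        assert abs(m.area_mm2 - expect) <= tol
        assert m.axial_extent_mm == pytest.approx(10.0, abs=0.5)
        assert m.radial_extent_mm == pytest.approx(3.0, abs=0.5)

    def test_identical_run_zero_change(self):
        grid = _grid(11)
        cem = np.zeros(grid.shape)
        cem[:3, :3] = 1e3
        dose = hp.ThermalDoseMap(grid, cem)
        m = hp.lesion_metrics(dose, reference=dose)
        assert m.pct_change == 0.0

    def test_empty_reference_rejected(self):
        grid = _grid(11)
        dose = hp.ThermalDoseMap(grid, np.full(grid.shape, 1e3))
        empty = hp.ThermalDoseMap(grid, np.zeros(grid.shape))
        with pytest.raises(ValueError, match="reference"):
            hp.lesion_metrics(dose, reference=empty)

    def test_threshold_default(self):
        assert CEM43_THRESHOLD_MIN == 240.0
        grid = _grid(5)
        dose = hp.ThermalDoseMap(grid, np.full(grid.shape, 239.9))
        assert hp.lesion_metrics(dose).n_cells == 0
        dose2 = hp.ThermalDoseMap(grid, np.full(grid.shape, 240.0))
        assert hp.lesion_metrics(dose2).n_cells == grid.shape[0] * grid.shape[1]
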