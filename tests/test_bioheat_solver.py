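"""Discrete operator assembly, boundary handling and stepping."""

import numpy as np
import pytest

from cordcool.analytic_oracles import uniform_grid
from cordcool.bioheat_solver import (BoundarySpec, PennesOperator,
                                     SingularSystemError, SkinModel,
                                     TransientStepper,
                                     harmonic_mean_conductivity,
                                     perfusion_source, skin_heat_transfer,
                                     energy_balance)
from cordcool.geometry import LABEL_CODES, LabelGrid
from cordcool.tissue_db import BloodModel

MM = 1e-3
ADIABATIC_SKIN = SkinModel(kind="constant", coefficient=0.0)


def no_flux_bc():
    return BoundarySpec(phase="stoppage", catheter_mode="adiabatic",
                        skin=ADIABATIC_SKIN)


class TestPerfusionSource:
    def test_vanishes_at_arterial_temperature(self):
        assert perfusion_source(3.01, 3617.0, 37.0, 37.0) == 0.0

    def test_one_degree_deficit_cord(self):
        # w_b c_b * 1 K = 3.01 * 3617 = 10887.17 W/m^3
        assert perfusion_source(3.01, 3617.0, 37.0, 36.0) == pytest.approx(
            10887.17)

    def test_unperfused_tissue_is_inert(self):
        assert perfusion_source(0.0, 3617.0, 37.0, 20.0) == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            perfusion_source(-1.0, 3617.0, 37.0, 36.0)


class TestSkinHeatTransfer:
    def test_no_flux_without_temperature_difference(self):
        assert skin_heat_transfer(30.0, 30.0, SkinModel()) == 0.0

    def test_power_law_flux(self):
        # h = 2 * 5^0.25 = 2.9907 W/(m^2 K); q = h * 5 = 14.953 W/m^2
        q = skin_heat_transfer(35.0, 30.0, SkinModel())
        assert q == pytest.approx(2.0 * 5.0 ** 1.25, rel=1e-12)

    def test_constant_film_coefficient(self):
        q = skin_heat_transfer(34.0, 30.0,
                               SkinModel(kind="constant", coefficient=3.0))
        assert q == pytest.approx(12.0)


class TestAssembly:
    def test_uniform_five_point_stencil(self, blood):
        # single material, no sources: interior row must be k*(4, -1 x4)
        g = uniform_grid("catheter", 3, 3, 1.0 * MM)
        op = PennesOperator(
            g, _registry(), blood,
            no_flux_bc(),
            edge_bc={s: ("dirichlet", 30.0) for s in
                     ("left", "right", "top", "bottom")})
        A, b = op.system()
        k = _registry()["catheter"].thermal_conductivity
        center = 4  # middle of the 3x3 grid
        row = A.toarray()[center]
        assert row[center] == pytest.approx(4 * k)
        off = np.delete(row, center)
        assert sorted(off[off != 0]) == pytest.approx([-k] * 4)

    def test_interface_flux_uses_harmonic_mean(self, blood):
        k1, k2 = 0.51, 0.57093
        assert harmonic_mean_conductivity(k1, k2) == pytest.approx(
            2 * k1 * k2 / (k1 + k2))
        g = LabelGrid.empty(2, 1, 1.0 * MM)
        g.labels[0, 0] = LABEL_CODES["spinal_cord"]
        g.labels[0, 1] = LABEL_CODES["cerebrospinal_fluid"]
        op = PennesOperator(g, _registry(), blood, no_flux_bc())
        A, _ = op.system()
        assert -A.toarray()[0, 1] == pytest.approx(
            harmonic_mean_conductivity(k1, k2))

    def test_cooling_mode_pins_lumen_rows(self, registry, blood):
        g = uniform_grid("catheter", 5, 5, 0.5 * MM)
        g.lumen_mask[2, 2] = True
        op = PennesOperator(g, registry, blood, BoundarySpec.cooling(8.0))
        A, b = op.system()
        i = op.index[2, 2]
        row = A.toarray()[i]
        assert row[i] == 1.0 and np.count_nonzero(row) == 1
        assert b[i] == 8.0

    def test_unregistered_label_raises(self, blood):
        g = uniform_grid("spinal_cord", 3, 3, 1.0 * MM)
        with pytest.raises(KeyError):
            PennesOperator(g, {"muscle": _registry()["muscle"]}, blood,
                           no_flux_bc())

    def test_fully_adiabatic_unperfused_system_rejected(self, blood):
        g = uniform_grid("catheter", 4, 4, 1.0 * MM)
        with pytest.raises(SingularSystemError):
            PennesOperator(g, _registry(), blood, no_flux_bc())


class TestStationary:
    def test_uniform_dirichlet_no_sources_gives_uniform_field(self, blood):
        g = uniform_grid("catheter", 6, 6, 1.0 * MM)
        op = PennesOperator(
            g, _registry(), blood, no_flux_bc(),
            edge_bc={s: ("dirichlet", 30.0) for s in
                     ("left", "right", "top", "bottom")})
        f = op.solve_stationary()
        assert np.allclose(op.to_vector(f), 30.0, atol=1e-9)

    def test_insulated_perfused_tissue_reaches_pennes_fixed_point(self,
                                                                  registry):
        # T = Ta + q_m/(w_b c_b) = 37 + 2666/10887.17 = 37.2449 degC
        blood37 = BloodModel(arterial_temperature=37.0)
        g = uniform_grid("spinal_cord", 4, 4, 1.0 * MM)
        op = PennesOperator(g, registry, blood37, no_flux_bc())
        f = op.solve_stationary()
        assert np.allclose(op.to_vector(f), 37.2449, atol=1e-4)

    def test_energy_balance_closes_on_small_anatomy(self, small_grid,
                                                    registry, blood):
        op = PennesOperator(small_grid, registry, blood,
                            BoundarySpec.stoppage())
        f = op.solve_stationary()
        bal = energy_balance(op, f)
        assert bal["imbalance"] < 1e-3
        assert bal["skin_loss_W"] > 0


class TestTransient:
    def test_stationary_field_is_a_fixed_point(self, registry, blood):
        g = uniform_grid("spinal_cord", 4, 4, 1.0 * MM)
        op = PennesOperator(g, registry, blood, no_flux_bc())
        f = op.solve_stationary()
        T0 = op.to_vector(f)
        stepper = TransientStepper(op, dt=1.0)
        T1 = stepper.step(T0, 1.0)
        assert np.allclose(T1, T0, atol=1e-10)

    def test_single_cell_backward_euler_relaxation(self, registry, blood):
        # dT/dt = (Ta - T)/tau with tau = rho c/(w_b c_b) = 358.43 s for
        # cord tissue; one backward-Euler step of dt = tau halves the
        # deviation from Ta.
        cord = registry["spinal_cord"]
        tau = cord.volumetric_heat_capacity / blood.perfusion_coefficient(cord)
        assert tau == pytest.approx(1075 * 3630 / (3.01 * 3617.0), rel=1e-12)
        g = uniform_grid("spinal_cord", 1, 1, 1.0 * MM)
        op = PennesOperator(g, registry, blood, no_flux_bc())
        # the isolated cell relaxes to T_inf = Ta + q_m/(w_b c_b)
        T_inf = (blood.arterial_temperature
                 + cord.metabolic_heat / blood.perfusion_coefficient(cord))
        T1 = TransientStepper(op, dt=tau).step(np.array([T_inf - 2.0]), tau)
        assert T1[0] == pytest.approx(T_inf - 1.0, rel=1e-12)

    def test_discrete_maximum_principle_without_sources(self, blood):
        rng = np.random.default_rng(7)
        g = uniform_grid("catheter", 8, 8, 1.0 * MM)   # inert material
        op = PennesOperator(
            g, _registry(), blood, no_flux_bc(),
            edge_bc={"left": ("dirichlet", 28.0),
                     "right": ("dirichlet", 34.0)})
        T = rng.uniform(25.0, 35.0, size=op.n)
        lo, hi = min(T.min(), 28.0), max(T.max(), 34.0)
        stepper = TransientStepper(op, dt=5.0)
        for i in range(20):
            T = stepper.step(T, 5.0 * (i + 1))
            assert T.min() >= lo - 1e-9 and T.max() <= hi + 1e-9

    def test_non_finite_state_rejected(self, registry, blood):
        g = uniform_grid("spinal_cord", 2, 2, 1.0 * MM)
        op = PennesOperator(g, registry, blood, no_flux_bc())
        stepper = TransientStepper(op, dt=1.0)
        bad = np.array([36.0, np.nan, 36.0, 36.0])
        with pytest.raises(FloatingPointError):
            stepper.step(bad, 1.0)


class TestGridRefinement:
    def test_steady_cooled_cord_temperature_under_refinement(self, registry,
                                                             blood):
        # Steady cooled state (the transient plateau's limit): halving the
        # spacing from 1.0 to 0.5 mm moves the cord-center value by about
        # 0.2 degC — the residual comes from the catheter being only
        # 1.5 cells in radius on the desk grid.  This bounds the
        # desk-resolution discretization uncertainty.
        from cordcool.geometry import build_anatomy
        values = {}
        for spacing in (1.0e-3, 0.5e-3):
            g = build_anatomy(spacing=spacing)
            op = PennesOperator(g, registry, blood, BoundarySpec.cooling(20.0))
            f = op.solve_stationary(fill_lumen=False)
            values[spacing] = f.at(g.cord_center())
        assert abs(values[1.0e-3] - values[0.5e-3]) < 0.3


def _registry():
    from cordcool.tissue_db import default_registry
    return default_registry()
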