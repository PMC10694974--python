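"""EN-norm calculator tests: frozen hand-computed oracles, scaling-law
property tests, unit discipline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycomat.core import ConfigError, InsufficientRangeError, NoSteadyStateError, UnitError
from mycomat.properties import (
    BendingRecord,
    BoardGeometry,
    ConductivityRecord,
    DensityRecord,
    FlammabilityObservation,
    SoakRecord,
    StressStrainCurve,
    TensileRecord,
    VapourSeries,
    board_geometry,
    classify_flammability,
    compute_compression,
    flexural_strength,
    modulus_of_elasticity,
    raw_density,
    soak_metrics,
    thermal_conductivity,
    transverse_tensile_strength,
    vapour_coefficients,
)
from mycomat.synthetic import synth_bending_record, synth_vapour_series

positive = st.floats(min_value=0.1, max_value=1e3)


def linear_curve(k=20.0, A0=10_000.0, d0=100.0, x_max=15.0, n=301):
    x = np.linspace(0.0, x_max, n)
    return StressStrainCurve(
        displacement_mm=x, force_N=k * x, A0_mm2=A0, d0_mm=d0
    )


class TestCompression:
    def test_linear_curve_sigma10(self):
        # F = 20 X, A0 = 10,000 mm^2, d0 = 100 mm: F(10 mm) = 200 N -> 20 kPa
        res = compute_compression(linear_curve())
        assert res.sigma10_kPa == pytest.approx(20.0, rel=1e-12)

    def test_zero_force(self):
        x = np.linspace(0, 15, 50)
        curve = StressStrainCurve(x, np.zeros_like(x), 10_000.0, 100.0)
        assert compute_compression(curve).sigma10_kPa == 0.0

    def test_insufficient_range(self):
        with pytest.raises(InsufficientRangeError):
            compute_compression(linear_curve(x_max=5.0))

    def test_grid_refinement_stability(self):
        """Refining the sample grid of a smooth curve moves sigma10 < 0.1%."""
        from mycomat.synthetic import FoamModel, synth_compression_curve

        model = FoamModel()
        coarse = compute_compression(
            synth_compression_curve(80.0, model, 0, n_samples=41)
        ).sigma10_kPa
        fine = compute_compression(
            synth_compression_curve(80.0, model, 0, n_samples=2001)
        ).sigma10_kPa
        assert abs(coarse / fine - 1.0) < 1e-3

    def test_preload_zeroing_shifts_origin(self):
        x = np.linspace(0.0, 15.0, 301)
        curve = StressStrainCurve(x, 20.0 * x, 10_000.0, 100.0,
                                  preload_applied=False)
        res = compute_compression(curve, zero_at_preload=True)
        # preload 20 N crossed at X = 1 mm; 10% strain now at X = 11 mm
        assert res.sigma10_kPa == pytest.approx(22.0, rel=1e-9)


class TestBoardGeometry:
    def test_tn5(self):
        geo = board_geometry(5.0)
        assert geo.a_mm == 150.0  # B150 x 50 specimen

    def test_tn10(self):
        geo = board_geometry(10.0)
        assert geo.a_mm == 250.0
        assert geo.l1_mm == 200.0

    def test_tn0_intercept(self):
        assert board_geometry(0.0).a_mm == 50.0

    def test_negative_rejected(self):
        with pytest.raises(ConfigError):
            board_geometry(-1.0)


class TestBending:
    def _geo(self, t=10.0, b=50.0, l1=200.0):
        return BoardGeometry(t_N_mm=10.0, a_mm=250.0, b_mm=b, t_mm=t,
                             l1_mm=l1, l2_mm=250.0)

    def test_hand_example(self):
        rec = BendingRecord(np.array([0.0, 5.0]), np.array([0.0, 100.0]), self._geo())
        assert flexural_strength(rec) == pytest.approx(6.0, rel=1e-12)

    def test_zero_force(self):
        rec = BendingRecord(np.array([0.0, 5.0]), np.array([0.0, 0.0]), self._geo())
        assert flexural_strength(rec) == 0.0

    def test_thickness_scaling(self):
        rec1 = BendingRecord(np.array([0.0, 5.0]), np.array([0.0, 100.0]), self._geo(t=10.0))
        rec2 = BendingRecord(np.array([0.0, 5.0]), np.array([0.0, 100.0]), self._geo(t=20.0))
        assert flexural_strength(rec2) == pytest.approx(flexural_strength(rec1) / 4.0)

    def test_modulus_hand_example(self):
        # linear ramp, stiffness 30 N/mm: E_M = k l1^3 / (4 b t^3) = 1200
        geo = board_geometry(10.0, t_mm=10.0)
        rec = synth_bending_record(6.0, geo, stiffness_N_per_mm=30.0)
        assert modulus_of_elasticity(rec) == pytest.approx(1200.0, rel=1e-9)

    def test_modulus_of_linear_ramp_closed_form(self):
        geo = board_geometry(10.0, t_mm=10.0)
        k = 47.3
        rec = synth_bending_record(4.2, geo, stiffness_N_per_mm=k)
        expected = k * geo.l1_mm**3 / (4 * geo.b_mm * geo.t_mm**3)
        assert modulus_of_elasticity(rec) == pytest.approx(expected, rel=1e-6)

    def test_zero_force_increase(self):
        rec = BendingRecord(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.0, 0.0]),
                            self._geo())
        assert modulus_of_elasticity(rec) == 0.0

    @given(
        f=st.floats(min_value=1.0, max_value=1e4),
        l1=positive, b=positive, t=positive, scale=st.floats(min_value=1.5, max_value=4.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scaling_laws(self, f, l1, b, t, scale):
        def fm(F, L, B, T):
            geo = BoardGeometry(t_N_mm=1.0, a_mm=100.0, b_mm=B, t_mm=T,
                                l1_mm=L, l2_mm=100.0)
            return flexural_strength(
                BendingRecord(np.array([0.0, 1.0]), np.array([0.0, F]), geo)
            )

        base = fm(f, l1, b, t)
        assert fm(scale * f, l1, b, t) == pytest.approx(scale * base, rel=1e-9)
        assert fm(f, scale * l1, b, t) == pytest.approx(scale * base, rel=1e-9)
        assert fm(f, l1, b, scale * t) == pytest.approx(base / scale**2, rel=1e-9)

    @given(k=st.floats(min_value=1.0, max_value=1e3), scale=st.floats(min_value=1.5, max_value=3.0))
    @settings(max_examples=30, deadline=None)
    def test_modulus_l1_cubed(self, k, scale):
        def em(L):
            geo = BoardGeometry(t_N_mm=10.0, a_mm=250.0, b_mm=50.0, t_mm=10.0,
                                l1_mm=L, l2_mm=250.0)
            return modulus_of_elasticity(synth_bending_record(5.0, geo, k))

        assert em(200.0 * scale) == pytest.approx(em(200.0) * scale**3, rel=1e-6)


class TestTensileDensitySoak:
    def test_tensile_hand_example(self):
        assert transverse_tensile_strength(
            TensileRecord(250.0, 50.0, 50.0)
        ) == pytest.approx(0.1, rel=1e-12)

    def test_tensile_zero(self):
        assert transverse_tensile_strength(TensileRecord(0.0, 50.0, 50.0)) == 0.0

    def test_tensile_p1_threshold(self):
        assert transverse_tensile_strength(
            TensileRecord(775.0, 50.0, 50.0)
        ) == pytest.approx(0.31, rel=1e-12)

    def test_density_hand_example(self):
        assert raw_density(DensityRecord(30.0, 50.0, 50.0, 10.0)) == pytest.approx(
            1200.0, rel=1e-12
        )

    def test_density_zero_mass(self):
        assert raw_density(DensityRecord(0.0, 50.0, 50.0, 10.0)) == 0.0

    def test_density_666(self):
        assert raw_density(DensityRecord(16.65, 50.0, 50.0, 10.0)) == pytest.approx(
            666.0, rel=1e-12
        )

    def test_soak_hand_examples(self):
        g_t, _ = soak_metrics(SoakRecord(10.0, 15.0, 5.0, 6.0))
        assert g_t == pytest.approx(50.0, rel=1e-12)
        _, w_t = soak_metrics(SoakRecord(10.0, 10.0, 8.0, 8.0))
        assert w_t == 0.0
        _, w_t = soak_metrics(SoakRecord(10.0, 12.0, 10.0, 60.0))
        assert w_t == pytest.approx(500.0, rel=1e-12)

    def test_soak_zero_initials_rejected(self):
        with pytest.raises(ConfigError):
            soak_metrics(SoakRecord(0.0, 1.0, 1.0, 2.0))


class TestVapour:
    def test_worked_example_chain(self):
        series = synth_vapour_series(8.22, 0.0177, 2390.0, 0.05, 20, 0.0, 0,
                                     condition="B")
        c = vapour_coefficients(series)
        assert c.g_g_per_m2_h == pytest.approx(19.6458, rel=1e-9)
        assert c.W_mg_per_m2_h_Pa == pytest.approx(8.22, rel=1e-9)
        assert c.delta_mg_per_m_h_Pa == pytest.approx(0.411, rel=1e-9)
        assert c.mu == pytest.approx(0.72 / 0.411, rel=1e-9)

    def test_alternative_delta_air_mu(self):
        series = synth_vapour_series(8.22, 0.0177, 2390.0, 0.05, 20, 0.0, 0)
        c = vapour_coefficients(series, delta_air_mg_per_m_h_Pa=0.707)
        assert c.mu == pytest.approx(1.72, rel=0.01)

    @given(W=st.floats(min_value=0.5, max_value=50.0),
           dp=st.sampled_from([1400.0, 2390.0, 1210.0]),
           d=st.floats(min_value=0.01, max_value=0.2))
    @settings(max_examples=30, deadline=None)
    def test_algebraic_identities(self, W, dp, d):
        series = synth_vapour_series(W, 0.02, dp, d, 10, 0.0, 0)
        c = vapour_coefficients(series)
        # g = W * dp (unit factor mg -> g) and delta = W * d, identically
        assert c.g_g_per_m2_h == pytest.approx(
            c.W_mg_per_m2_h_Pa * dp * 1e-3, rel=1e-12
        )
        assert c.delta_mg_per_m_h_Pa == pytest.approx(
            c.W_mg_per_m2_h_Pa * d, rel=1e-12
        )

    def test_no_steady_state_raises(self):
        series = VapourSeries(
            time_h=np.arange(6.0) + 1.0,
            mass_g=np.array([5.0, 1.0, 9.0, 2.0, 8.0, 1.5]),
            area_m2=0.02, delta_p_Pa=2390.0, thickness_m=0.05,
        )
        with pytest.raises(NoSteadyStateError):
            vapour_coefficients(series)

    def test_condition_pressure_enforced(self):
        with pytest.raises(UnitError):
            VapourSeries(
                time_h=np.arange(3.0), mass_g=np.arange(3.0),
                area_m2=0.02, delta_p_Pa=999.0, thickness_m=0.05, condition="B",
            )

    def test_unit_tag_enforced(self):
        with pytest.raises(UnitError):
            VapourSeries(
                time_h=np.arange(3.0), mass_g=np.arange(3.0),
                area_m2=0.02, delta_p_Pa=2390.0, thickness_m=0.05,
                units=("s", "kg"),
            )


class TestThermal:
    def test_hand_example(self):
        rec = ConductivityRecord(phi_W=9.0, d_m=0.05, A_m2=0.25, T1_K=298.0, T2_K=288.0)
        assert thermal_conductivity(rec) == pytest.approx(0.18, rel=1e-12)

    def test_zero_flux(self):
        rec = ConductivityRecord(0.0, 0.05, 0.25, 298.0, 288.0)
        assert thermal_conductivity(rec) == 0.0

    @given(d=st.floats(min_value=0.01, max_value=0.2))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_thickness(self, d):
        lam1 = thermal_conductivity(ConductivityRecord(9.0, d, 0.25, 298.0, 288.0))
        lam2 = thermal_conductivity(ConductivityRecord(9.0, 2 * d, 0.25, 298.0, 288.0))
        assert lam2 == pytest.approx(2 * lam1, rel=1e-12)

    def test_zero_gradient_raises(self):
        with pytest.raises(ConfigError):
            thermal_conductivity(ConductivityRecord(9.0, 0.05, 0.25, 298.0, 298.0))


class TestFlammability:
    def _obs(self, **kw):
        base = dict(
            flame_spread_mm_at_60s=120.0,
            horizontal_spread=False,
            burning_droplets=False,
            smoke_class="s2",
            flaming_time_s=30.0,
        )
        base.update(kw)
        return FlammabilityObservation(**base)

    def test_reference_classification(self):
        assert classify_flammability(self._obs()).label == "B1-s2-d0"

    def test_excess_spread_not_b1(self):
        res = classify_flammability(self._obs(flame_spread_mm_at_60s=200.0))
        assert res.label == "unclassified"
        assert any("150 mm" in r for r in res.reasons)

    def test_horizontal_spread_is_E(self):
        assert classify_flammability(self._obs(horizontal_spread=True)).label == "E"

    def test_droplets_block_b1(self):
        res = classify_flammability(self._obs(burning_droplets=True))
        assert res.label == "unclassified"

    def test_smoke_class_validated(self):
        with pytest.raises(ConfigError):
            self._obs(smoke_class="s9")
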