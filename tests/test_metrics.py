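"""Stress-strain arithmetic, fracture/modulus/toughness extraction, anisotropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tensiledic import SpecimenGeometry, metrics
from tensiledic import synthetic as syn
from tensiledic.errors import InvalidArgumentError, NoFractureError

GEOM = SpecimenGeometry(gauge_length_mm=8.5, gap_width_mm=20.0, width0_mm=10.0, thickness0_mm=4.0)


def curve(strain, stress, **kw):
    kw.setdefault("area_model", "constant_volume")
    kw.setdefault("length_source", "machine")
    return metrics.StressStrainCurve(strain=strain, stress_pa=stress, **kw)


class TestAreas:
    def test_constant_volume_identity_and_halving(self):
        assert metrics.area_constant_volume(8.5, 8.5, 40.0) == pytest.approx(40.0)
        assert metrics.area_constant_volume(8.5, 17.0, 40.0) == pytest.approx(20.0)

    @given(st.floats(min_value=1.0, max_value=3.0))
    @settings(max_examples=50, deadline=None)
    def test_volume_conserved(self, factor):
        h_t = 8.5 * factor
        a_t = metrics.area_constant_volume(8.5, h_t, 40.0)
        assert a_t * h_t == pytest.approx(40.0 * 8.5, rel=1e-12)

    def test_dynamic_poisson_closed_forms(self):
        w0, t0 = 10.0, 4.0
        assert metrics.area_dynamic_poisson(w0, w0, t0) == pytest.approx(w0 * t0)
        assert metrics.area_dynamic_poisson(0.9 * w0, w0, t0) == pytest.approx(0.81 * w0 * t0)
        assert metrics.area_dynamic_poisson(0.5 * w0, w0, t0) == pytest.approx(0.25 * w0 * t0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            metrics.area_constant_volume(8.5, -1.0, 40.0)
        with pytest.raises(InvalidArgumentError):
            metrics.area_dynamic_poisson(-1.0, 10.0, 4.0)

    def test_incompressible_width_makes_models_agree(self):
        # w(t) = w0 (h0/h)^0.5 is the nu = 0.5 contraction: both area models
        # must coincide to within 1e-10 relative error
        h0, w0, t0 = 8.5, 10.0, 4.0
        h = np.linspace(h0, 2.5 * h0, 200)
        w = w0 * np.sqrt(h0 / h)
        a_cv = metrics.area_constant_volume(h0, h, w0 * t0)
        a_dp = metrics.area_dynamic_poisson(w, w0, t0)
        assert np.max(np.abs(a_dp / a_cv - 1.0)) < 1e-10

    @pytest.mark.parametrize("nu", [0.0, 0.2, 0.4])
    def test_subincompressible_poisson_lowers_stress(self, nu):
        # nu < 0.5 means less lateral contraction, larger true area, lower stress
        h0, w0, t0 = 8.5, 10.0, 4.0
        eps = np.linspace(0.0, 0.3, 100)
        h = h0 * np.exp(eps)
        w = w0 * np.exp(-nu * eps)
        force = np.full_like(eps, 5.0)
        s_cv = metrics.true_stress(force, metrics.area_constant_volume(h0, h, w0 * t0) * 1e-6)
        s_dp = metrics.true_stress(force, metrics.area_dynamic_poisson(w, w0, t0) * 1e-6)
        assert np.all(s_dp <= s_cv + 1e-12)


class TestStressStrain:
    def test_stress_arithmetic(self):
        out = metrics.true_stress(np.array([10.0, 0.0]), np.array([1e-5, 1e-5]))
        assert out[0] == pytest.approx(1e6)
        assert out[1] == 0.0

    def test_constant_force_shrinking_area_monotone(self):
        area = np.linspace(1e-5, 0.5e-5, 50)
        s = metrics.true_stress(np.full(50, 3.0), area)
        assert np.all(np.diff(s) > 0)

    def test_true_strain_closed_forms(self):
        h0 = 8.5
        assert metrics.true_strain(h0, h0) == pytest.approx(0.0)
        assert metrics.true_strain(h0, np.e * h0) == pytest.approx(1.0)
        assert metrics.true_strain(h0, 2 * h0) == pytest.approx(np.log(2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            metrics.true_stress(np.zeros(3), np.ones(4))


class TestDetectFracture:
    def test_monotone_curve_has_no_fracture(self):
        eps = np.linspace(0, 0.3, 200)
        with pytest.raises(NoFractureError):
            metrics.detect_fracture(curve(eps, 1e6 * eps))

    def test_clean_peak_found(self):
        eps = np.linspace(0, 0.3, 200)
        s = np.where(eps < 0.2, eps, 0.01)
        idx = metrics.detect_fracture(curve(eps, s * 1e6))
        assert idx == np.argmax(s)

    def test_three_stage_curve_fractures_at_first_major_drop(self):
        sched = syn.DeformationSchedule.ramp(8.0, 0.25, rate_mode="stretch")
        arch = syn.MaterialArchetype(label="anisotropic", peak_force_n=10.0, descending_stages=3)
        trace = syn.gen_force_trace(arch, GEOM, sched)
        h = GEOM.gauge_length_mm + trace.distance_mm
        c = curve(
            metrics.true_strain(GEOM.gauge_length_mm, h),
            metrics.true_stress(
                trace.force_n,
                metrics.area_constant_volume(GEOM.gauge_length_mm, h, GEOM.area0_mm2) * 1e-6,
            ),
        )
        assert metrics.detect_fracture(c) == trace.meta["fracture_index"]


class TestYoungsModulus:
    def test_exact_linear_curve(self):
        eps = np.linspace(0, 0.1, 200)
        e_mod, win, r2, below = metrics.youngs_modulus(curve(eps, 1e5 * eps))
        assert e_mod == pytest.approx(1e5, rel=1e-12)
        assert not below
        assert r2 == pytest.approx(1.0)

    def test_bilinear_curve_picks_first_segment(self):
        eps = np.linspace(0, 0.1, 400)
        s = np.where(eps < 0.05, 2e5 * eps, 2e5 * 0.05 + 5e4 * (eps - 0.05))
        e_mod, win, _, _ = metrics.youngs_modulus(curve(eps, s))
        assert e_mod == pytest.approx(2e5, rel=1e-9)
        assert win[0] == pytest.approx(0.0)

    def test_pure_noise_below_floor_flag(self):
        rng = np.random.default_rng(0)
        eps = np.linspace(0, 0.1, 300)
        s = rng.normal(0, 1e4, 300)
        _, _, _, below = metrics.youngs_modulus(curve(eps, s))
        assert below


class TestToughness:
    def test_triangle_closed_form(self):
        eps = np.linspace(0, 0.1, 101)
        s = 1e7 * eps  # peaks at 1e6 Pa
        assert metrics.toughness(curve(eps, s), fracture_index=100) == pytest.approx(5e4, rel=1e-4)

    def test_zero_stress_zero_toughness(self):
        eps = np.linspace(0, 0.1, 50)
        assert metrics.toughness(curve(eps, np.zeros(50))) == 0.0

    @given(st.integers(min_value=0, max_value=99))
    @settings(max_examples=30, deadline=None)
    def test_full_curve_at_least_to_fracture(self, idx):
        rng = np.random.default_rng(idx)
        eps = np.linspace(0, 0.2, 100)
        s = np.abs(rng.normal(1e5, 5e4, 100))
        c = curve(eps, s)
        assert metrics.toughness(c, include_descending=True) >= metrics.toughness(
            c, fracture_index=idx
        ) - 1e-9


class TestAnisotropy:
    @pytest.mark.parametrize(
        "par,perp,expect", [(5.0, 5.0, 1.0), (10.0, 5.0, 2.0), (0.5, 1.0, 0.5)]
    )
    def test_ratio(self, par, perp, expect):
        assert metrics.anisotropy_index(par, perp) == expect

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidArgumentError):
            metrics.anisotropy_index(1.0, 0.0)


class TestDeformationRate:
    def test_reference_mould_round_trips(self):
        assert metrics.deformation_rate_for_gap(26.0) == pytest.approx(60.0)

    def test_gap_proportionality(self):
        assert round(metrics.deformation_rate_for_gap(30.5), 1) == 70.4
        assert round(metrics.deformation_rate_for_gap(23.3), 1) == 53.8


class TestParameterRecovery:
    @pytest.mark.parametrize("label,stages", [("isotropic", 1), ("anisotropic", 3)])
    def test_noiseless_trace_recovery(self, label, stages):
        sched = syn.DeformationSchedule.ramp(8.0, 0.25, rate_mode="stretch")
        arch = syn.MaterialArchetype(
            label=label, peak_force_n=12.0, descending_stages=stages,
            youngs_modulus_pa=2.5e6,
        )
        trace = syn.gen_force_trace(arch, GEOM, sched)
        h = GEOM.gauge_length_mm + trace.distance_mm
        c = curve(
            metrics.true_strain(GEOM.gauge_length_mm, h),
            metrics.true_stress(
                trace.force_n,
                metrics.area_constant_volume(GEOM.gauge_length_mm, h, GEOM.area0_mm2) * 1e-6,
            ),
        )
        p = metrics.extract_parameters(c)
        assert abs(p.fracture_index - trace.meta["fracture_index"]) <= 1
        assert p.fracture_stress_pa == pytest.approx(trace.meta["sigma_peak_pa"], rel=0.01)
        assert p.youngs_modulus_pa == pytest.approx(2.5e6, rel=0.02)

    def test_unit_sanity(self):
        # doubling A0 halves stress; toughness scales with the stress scale
        sched = syn.DeformationSchedule.ramp(8.0, 0.25, rate_mode="stretch")
        arch = syn.MaterialArchetype(label="isotropic", peak_force_n=12.0)
        trace = syn.gen_force_trace(arch, GEOM, sched)
        h = GEOM.gauge_length_mm + trace.distance_mm
        eps = metrics.true_strain(GEOM.gauge_length_mm, h)
        for scale in (1.0, 2.0):
            a = metrics.area_constant_volume(GEOM.gauge_length_mm, h, scale * GEOM.area0_mm2)
            s = metrics.true_stress(trace.force_n, a * 1e-6)
            if scale == 1.0:
                base_stress, base_tough = s, metrics.toughness(curve(eps, s), include_descending=True)
        a2 = metrics.area_constant_volume(GEOM.gauge_length_mm, h, 2 * GEOM.area0_mm2)
        s2 = metrics.true_stress(trace.force_n, a2 * 1e-6)
        assert np.allclose(s2, base_stress / 2)
        tough2 = metrics.toughness(curve(eps, s2), include_descending=True)
        assert tough2 == pytest.approx(base_tough / 2, rel=1e-12)
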