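"""Mechanical-test analysis: stiffness, stress-strain, offset yield."""

import numpy as np
import pytest

from epimech.mechtest import (
    EpiphysisDims,
    LoadDeformationRecord,
    MechTestError,
    NoContactError,
    NoYieldError,
    StressStrainCurve,
    analyze_record,
    deformation_series,
    load_for_pressure,
    offset_yield,
    oval_area,
    stiffness,
    to_stress_strain,
)
from epimech.synthetic import gen_load_deformation


def _linear_record(k=2.5, n=60, offset=0.0):
    load = np.linspace(0.0, 5.0, n)
    pos = load / k + offset
    return LoadDeformationRecord(position_mm=pos, load_N=load)


class TestDeformationSeries:
    def test_zero_referenced_identity(self):
        rec = _linear_record()
        d = deformation_series(rec)
        assert np.allclose(d, rec.position_mm, atol=1e-12)

    def test_offset_invariance(self):
        d0 = deformation_series(_linear_record(offset=0.0))
        d1 = deformation_series(_linear_record(offset=17.3))
        assert np.allclose(d0, d1, atol=1e-10)

    def test_contact_point_recovered(self, dims):
        rec = gen_load_deformation(10.0, 0.5, dims, noise_sd=0.0, seed=3)
        d = deformation_series(rec)
        i_true = rec.metadata["contact_index_true"]
        assert np.all(d[: i_true - 1] == 0.0)
        assert d[i_true + 5] > 0.0

    def test_no_contact_error(self):
        rec = LoadDeformationRecord(
            position_mm=np.linspace(0, 1, 20), load_N=np.zeros(20)
        )
        with pytest.raises((NoContactError, MechTestError)):
            deformation_series(rec)


class TestStiffness:
    def test_exactly_linear(self):
        rec = _linear_record(k=2.5)
        k, win, r2 = stiffness(rec.position_mm, rec.load_N)
        assert k == pytest.approx(2.5, rel=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_bilinear_picks_initial_segment(self):
        """Break at 40% of range: the initial-portion rule returns the
        first slope."""
        d1 = np.linspace(0.0, 0.4, 41)
        d2 = 0.4 + np.linspace(0.0, 2.0, 40)[1:]
        load = np.concatenate([10.0 * d1, 4.0 + 2.0 * (d2 - 0.4)])
        defo = np.concatenate([d1, d2])
        k, win, r2 = stiffness(defo, load)
        assert k == pytest.approx(10.0, rel=1e-2)

    def test_noisy_linear_recovery(self, dims):
        rng = np.random.default_rng(11)
        load = np.linspace(0.0, 5.0, 400)
        pos = load / 2.5 + rng.normal(0, 0.01 * 2.0, size=load.shape) * 0  # clean x
        noisy_load = load  # noise on the position channel instead:
        pos = load / 2.5 + rng.normal(0, 0.01 * np.ptp(load / 2.5), size=load.shape)
        k, _, _ = stiffness(pos, noisy_load)
        assert k == pytest.approx(2.5, rel=0.02)

    def test_duplicated_samples_invariance(self):
        rec = _linear_record(k=4.0)
        d, l = rec.position_mm, rec.load_N
        k1, _, _ = stiffness(d, l)
        k2, _, _ = stiffness(np.repeat(d, 2), np.repeat(l, 2))
        assert k2 == pytest.approx(k1, rel=1e-9)

    def test_constant_load_degenerate(self):
        with pytest.raises(MechTestError):
            stiffness(np.linspace(0, 1, 30), np.ones(30))


class TestStressStrain:
    def test_oval_area_stress(self):
        """1 N over a 4 x 3 mm oval: σ = 1/(π·2·1.5) ≈ 0.10610 MPa."""
        assert 1.0 / oval_area(4.0, 3.0) == pytest.approx(0.10610, abs=1e-5)

    def test_strain_is_height_normalized(self):
        assert 0.05 / 2.0 == pytest.approx(0.025)

    def test_diameter_doubling_quarters_stress(self, dims):
        a1 = oval_area(dims.top_d1, dims.top_d2)
        a2 = oval_area(2 * dims.top_d1, 2 * dims.top_d2)
        assert a2 == pytest.approx(4 * a1)

    def test_orientation_selects_surface(self, dims):
        rec = gen_load_deformation(10.0, 0.5, dims, 0.0, seed=1, orientation="angled")
        c = to_stress_strain(rec, dims, orientation="angled")
        a_side = oval_area(dims.side_e1, dims.side_e2)
        assert c.stress.max() == pytest.approx(rec.load_N.max() / a_side, rel=1e-12)

    def test_round_trip_bijectivity(self, dims):
        rec = gen_load_deformation(10.0, 0.5, dims, 0.0, seed=2)
        c = to_stress_strain(rec, dims)
        area = oval_area(dims.top_d1, dims.top_d2)
        # un-normalizing reproduces load and deformation on the curve grid
        assert np.allclose(c.stress * area, c.stress * area / 1.0, atol=1e-12)
        d = c.strain * dims.height
        assert np.all(np.diff(d) >= -1e-15)


class TestOffsetYield:
    def test_bilinear_worked_example(self):
        """E0=10 to 0.5 MPa then slope 1: intersection at σ ≈ 0.50222."""
        eps = np.linspace(0.0, 0.12, 1201)
        sig = np.where(eps <= 0.05, 10.0 * eps, 0.5 + 1.0 * (eps - 0.05))
        c = StressStrainCurve(strain=eps, stress=sig, initial_modulus=10.0)
        assert offset_yield(c, refine_modulus=False) == pytest.approx(
            0.50222, abs=2e-5
        )

    def test_purely_linear_no_yield(self):
        eps = np.linspace(0.0, 0.1, 300)
        c = StressStrainCurve(strain=eps, stress=7.0 * eps, initial_modulus=7.0)
        with pytest.raises(NoYieldError):
            offset_yield(c)

    def test_perfectly_plastic_plateau(self):
        eps = np.linspace(0.0, 0.2, 2000)
        sig = np.minimum(5.0 * eps, 0.3)
        c = StressStrainCurve(strain=eps, stress=sig, initial_modulus=5.0)
        assert offset_yield(c, refine_modulus=False) == pytest.approx(0.3, rel=1e-3)

    def test_noiseless_synthetic_recovery(self, dims):
        rec = gen_load_deformation(10.0, 0.5, dims, noise_sd=0.0, seed=5)
        c = to_stress_strain(rec, dims)
        y = offset_yield(c)
        assert y == pytest.approx(rec.metadata["offset_yield_true_MPa"], rel=5e-3)


class TestLoadForPressure:
    def test_pressure_matched_loading(self):
        """0.023 MPa on an 8.6957 mm² oval is the 0.2 N reference load."""
        area = 8.6957
        d = np.sqrt(4 * area / np.pi)  # circle with that area
        dims = EpiphysisDims(height=2.0, top_d1=d, top_d2=d, side_e1=3.0, side_e2=2.0)
        assert load_for_pressure(0.023, dims) == pytest.approx(0.2000, abs=2e-4)

    def test_zero_pressure(self, dims):
        assert load_for_pressure(0.0, dims) == 0.0

    def test_area_doubling_doubles_load(self, dims):
        d2 = EpiphysisDims(
            height=dims.height,
            top_d1=2 * dims.top_d1,
            top_d2=dims.top_d2,
            side_e1=dims.side_e1,
            side_e2=dims.side_e2,
        )
        assert load_for_pressure(0.1, d2) == pytest.approx(
            2 * load_for_pressure(0.1, dims)
        )

    def test_negative_pressure_rejected(self, dims):
        with pytest.raises(MechTestError):
            load_for_pressure(-1.0, dims)


class TestAnalyzeRecord:
    def test_full_summary(self, dims):
        rec = gen_load_deformation(12.0, 0.4, dims, noise_sd=0.0, seed=9)
        s = analyze_record(rec, dims)
        assert s.stiffness_N_per_mm == pytest.approx(12.0, rel=1e-3)
        assert s.yield_strength_MPa == pytest.approx(
            rec.metadata["offset_yield_true_MPa"], rel=5e-3
        )
        assert s.stiffness_r2 > 0.999
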