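import math
import warnings

import numpy as np
import pytest

from whitefront import (
    SpecimenGeometry,
    build_rcurve,
    correct_modulus,
    fit_linear_slope,
    flexural_modulus,
    j_point,
    k_eff,
    plastic_area,
    seb_geometry_factor,
    stress_intensity,
)
from whitefront.fracture import MPA_SQRT_M_PER_N_MM15
from whitefront.notch_fe import NotchCorrectionModel

GEO = SpecimenGeometry(B=0.9, W=0.9, a0=0.3, S=6.15, nu=0.33)


def seb_factor_oracle(x):
    """Independent transcription of the SE(B) geometry polynomial.

    Written in expanded Horner form, term by term, deliberately different
    arithmetic from the implementation.
    """
    poly = 2.15 + x * (-3.93 + x * 2.7)
    bracket = 1.99 - (x - x * x) * poly
    return (3.0 * math.sqrt(x) * bracket) / (2.0 * (1.0 + 2.0 * x) * (1.0 - x) ** 1.5)


def shoelace_area(vertices):
    """Polygon area oracle for piecewise-linear F(d_pl) records."""
    s = 0.0
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


class TestLinearFit:
    def test_exact_line(self):
        d = np.linspace(0, 0.1, 50)
        fit = fit_linear_slope(100 * d, d)
        assert fit.m == pytest.approx(100.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_noisy_line_within_two_percent(self):
        rng = np.random.default_rng(11)
        d = np.linspace(0, 1.0, 50)
        f = 100 * d + rng.normal(0, 0.1, 50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_linear_slope(f, d)
        assert fit.m == pytest.approx(100.0, rel=0.02)

    def test_zero_force_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_slope(np.zeros(20), np.linspace(0, 1, 20))

    def test_window_restricted_to_rising_branch(self):
        d = np.linspace(0, 1.0, 100)
        f = np.concatenate([np.linspace(0, 10, 50), np.linspace(10, 0, 50)])
        fit = fit_linear_slope(f, d)
        assert fit.m > 0


class TestFlexuralModulus:
    def test_unnotched_standard_relation(self):
        g = GEO.with_notch(0.0)
        m = 4 * 12000.0 * g.B * g.W**3 / g.S**3
        assert flexural_modulus(m, g) == pytest.approx(12000.0, rel=1e-12)

    def test_printed_example_value(self):
        # S=6.15, B=W=0.9, a0=0, m=135.4 N/mm -> about 12 GPa
        assert flexural_modulus(135.4, GEO.with_notch(0.0)) == pytest.approx(
            12000.0, rel=1e-3
        )

    def test_linear_in_slope(self):
        assert flexural_modulus(270.8, GEO) == pytest.approx(
            2 * flexural_modulus(135.4, GEO), rel=1e-12
        )

    def test_notched_width_cubed(self):
        m = 50.0
        expect = GEO.S**3 * m / (4 * GEO.B * (GEO.W - GEO.a0) ** 3)
        assert flexural_modulus(m, GEO) == pytest.approx(expect, rel=1e-12)


class TestCorrectModulus:
    def test_identity_without_model_warns(self):
        with pytest.warns(UserWarning, match="no notch-correction model"):
            assert correct_modulus(15000.0, 0.3) == 15000.0

    def test_extrapolation_warns(self):
        model = NotchCorrectionModel(coeffs=(1.0, -1.0, 0.5), a0_range=(0.0, 0.3), r2=1.0)
        with pytest.warns(UserWarning, match="extrapolating"):
            model.correct(15000.0, 0.4)

    def test_identity_at_zero_notch(self):
        model = NotchCorrectionModel(coeffs=(1.0, -1.0, 0.5), a0_range=(0.0, 0.3), r2=1.0)
        assert model.correct(15000.0, 0.0) == pytest.approx(15000.0)


class TestStressIntensity:
    def test_zero_force_gives_zero(self):
        assert stress_intensity(0.0, GEO, 0.45) == 0.0

    def test_linear_in_force(self):
        k1 = stress_intensity(1.0, GEO, 0.45)
        k5 = stress_intensity(5.0, GEO, 0.45)
        assert k5 == pytest.approx(5 * k1, rel=1e-12)

    def test_geometry_polynomial_matches_independent_transcription(self):
        for x in np.linspace(0.1, 0.9, 33):
            assert seb_geometry_factor(float(x)) == pytest.approx(
                seb_factor_oracle(float(x)), rel=1e-10
            )

    def test_out_of_range_crack_rejected(self):
        with pytest.raises(ValueError):
            stress_intensity(1.0, GEO, 0.9)
        with pytest.raises(ValueError):
            stress_intensity(1.0, GEO, 0.0)

    def test_unit_conversion_roundtrip(self):
        k_nmm = stress_intensity(2.0, GEO, 0.45, si_units=False)
        k_si = stress_intensity(2.0, GEO, 0.45, si_units=True)
        assert k_si == pytest.approx(k_nmm * math.sqrt(1e-3), rel=1e-12)
        assert MPA_SQRT_M_PER_N_MM15 == pytest.approx(0.0316227766, rel=1e-8)


class TestPlasticArea:
    def test_purely_linear_record_zero_everywhere(self):
        d = np.linspace(0, 0.2, 40)
        f = 50.0 * d
        for i in range(1, 40):
            # zero up to float round-off of the work integral (~1 N*mm scale)
            assert plastic_area(f, d, 50.0, i) == pytest.approx(0.0, abs=1e-14)

    def test_ramp_then_plateau_matches_polygon_oracle(self):
        m = 100.0
        d = np.array([0.0, 0.1, 0.2, 0.3])
        f = np.array([0.0, 10.0, 10.0, 10.0])  # elastic ramp then plateau
        d_pl = d - f / m
        verts = list(zip(d_pl, f)) + [(d_pl[-1], 0.0), (d_pl[0], 0.0)]
        assert plastic_area(f, d, m) == pytest.approx(shoelace_area(verts), abs=1e-14)

    def test_non_decreasing_in_sample_index(self):
        # ramp then plateau: plastic displacement increases monotonically
        d = np.linspace(0, 0.5, 60)
        f = np.minimum(80 * d, 5.0)
        areas = [plastic_area(f, d, 200.0, i) for i in range(60)]
        assert np.all(np.diff(areas) >= -1e-12)


class TestJAndKeff:
    def test_elastic_only_identity(self):
        d = np.linspace(0, 0.01, 20)
        m = 40.0
        f = m * d
        E = 12000.0
        a = 0.45
        jp = j_point(f, d, 19, m, GEO, a, E)
        k = stress_intensity(f[19], GEO, a, si_units=False)
        assert jp.J_pl == 0.0
        assert jp.J == pytest.approx(k**2 * (1 - GEO.nu**2) / E, rel=1e-9)
        # K_eff round-trips to K exactly
        assert k_eff(jp.J, E, GEO.nu) == pytest.approx(
            stress_intensity(f[19], GEO, a), rel=1e-12
        )

    def test_plane_strain_factor(self):
        assert (1 - 0.33**2) == pytest.approx(0.8911)

    def test_doubling_plastic_area_doubles_jpl(self):
        m = 1e9  # negligible elastic displacement: d_pl ~ d, A_pl ~ plateau area
        f = np.array([0.0, 10.0, 10.0])
        d1 = np.array([0.0, 1e-9, 0.1])
        d2 = np.array([0.0, 1e-9, 0.2])  # plateau area exactly doubled
        j1 = j_point(f, d1, 2, m, GEO, 0.45, 12000.0).J_pl
        j2 = j_point(f, d2, 2, m, GEO, 0.45, 12000.0).J_pl
        assert j2 == pytest.approx(2 * j1, rel=1e-6)
        # and J_pl equals eta * A_pl / (B * b0) by construction
        a1 = plastic_area(f, d1, m)
        assert j1 == pytest.approx(1.9 * a1 / (GEO.B * GEO.b0), rel=1e-12)

    def test_keff_closed_form(self):
        # J = 1 kJ/m^2, E = 12 GPa, nu = 0.33
        assert k_eff(1.0, 12000.0, 0.33) == pytest.approx(
            math.sqrt(1.0e-3 * 12000.0 / 0.8911), rel=1e-4
        )

    def test_zero_j_gives_zero_keff(self):
        assert k_eff(0.0, 12000.0, 0.33) == 0.0

    def test_degenerate_ligament_rejected(self):
        g = SpecimenGeometry(B=0.9, W=0.9, a0=0.899999, S=6.15)
        d = np.linspace(0, 0.01, 6)
        with pytest.raises(ValueError):
            j_point(40 * d, d, 5, 40.0, g.with_notch(0.8999999999), 0.9, 12000.0)


class TestBuildRCurve:
    def test_decomposition_conserved(self, recovered_rcurve):
        pipeline, _ = recovered_rcurve
        for pt in pipeline.points:
            assert pt.J == pytest.approx(pt.J_el + pt.J_pl, rel=1e-14)
            assert pt.J_el >= 0 and pt.J_pl >= 0

    def test_no_point_beyond_specimen_width(self, recovered_rcurve):
        pipeline, _ = recovered_rcurve
        for pt in pipeline.points:
            assert pt.a_mm < pipeline.geometry.W

    def test_extension_non_decreasing(self, recovered_rcurve):
        pipeline, _ = recovered_rcurve
        da = [pt.da_mm for pt in pipeline.points]
        assert np.all(np.diff(da) >= 0.0)

    def test_empty_trajectory_gives_empty_curve(self):
        from whitefront.tracking import FrontTrajectory

        traj = FrontTrajectory(
            front_px=np.zeros((0, 2)),
            da_raw_mm=np.zeros(0),
            da_mono_mm=np.zeros(0),
            synced=[],
            shifts=[],
            calibration=None,
            notch_tip_px=(0, 0),
        )
        curve = build_rcurve(traj, GEO, 12000.0)
        assert len(curve) == 0
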