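"""PMF well integration, K_d conversion, Van't Hoff fitting, decompositions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from acidassoc import assoc_thermo as at
from acidassoc import evaluate_pmf, make_default_pmf, make_water_pmf
from acidassoc.synthetic_umbrella import GaussianWell, ModelPMF
from acidassoc.units import kT, reference_volume_molar
from acidassoc.wham import PMFProfile


def rasterize(model, lo, hi, step, temperature, zero_region):
    r = np.arange(lo, hi + step / 2, step)
    return PMFProfile(bin_centers=r, W=evaluate_pmf(model, r),
                      temperature=temperature, zero_region=zero_region)


@pytest.fixture(scope="module")
def acid_profile():
    return rasterize(make_default_pmf(), 3.2, 12.0, 0.01, 300.0, (10.0, 12.0))


@pytest.fixture(scope="module")
def coh_profile():
    return rasterize(make_water_pmf("COH"), 2.0, 9.0, 0.005, 345.0, (6.0, 9.0))


class TestFindMinima:
    def test_default_model_minima_positions(self, acid_profile):
        mins = at.find_minima(acid_profile)
        assert len(mins) == 2
        assert mins[0][0] == pytest.approx(3.8, abs=0.05)
        assert mins[1][0] == pytest.approx(4.6, abs=0.05)
        assert mins[0][1] < mins[1][1]

    def test_monotone_profile_has_no_minima(self):
        r = np.linspace(3.0, 10.0, 100)
        prof = PMFProfile(bin_centers=r, W=r * 2.0, temperature=300.0,
                          zero_region=(9.0, 10.0))
        with pytest.raises(ValueError, match="no minima"):
            at.find_minima(prof)

    def test_parabola_vertex_refinement(self):
        r = np.linspace(3.0, 7.0, 81)  # bin width 0.05
        r_star = 5.013  # off-grid vertex
        prof = PMFProfile(bin_centers=r, W=4.0 * (r - r_star) ** 2 - 3.0,
                          temperature=300.0, zero_region=(6.5, 7.0))
        mins = at.find_minima(prof)
        assert len(mins) == 1
        assert mins[0][0] == pytest.approx(r_star, abs=0.05)


class TestWellIntegration:
    def test_flat_well_analytic_volume(self):
        r = np.arange(3.0, 12.001, 0.05)
        prof = PMFProfile(bin_centers=r, W=np.zeros_like(r), temperature=300.0,
                          zero_region=(10.0, 12.0))
        q = at.well_integral(prof, 3.9, 5.3, 300.0)
        exact = 4.0 * np.pi / 3.0 * (5.3**3 - 3.9**3)
        assert q == pytest.approx(exact, rel=1e-4)

    def test_constant_offset_shifts_dG_exactly(self):
        r = np.arange(3.0, 12.001, 0.05)
        eps = 7.3
        base = PMFProfile(bin_centers=r, W=np.zeros_like(r), temperature=300.0,
                          zero_region=(10.0, 12.0))
        shifted = PMFProfile(bin_centers=r, W=np.full_like(r, -eps), temperature=300.0,
                             zero_region=(10.0, 12.0))
        dg0 = at.integrate_association(base).dG_dissociation
        dg1 = at.integrate_association(shifted).dG_dissociation
        assert dg1 - dg0 == pytest.approx(eps, abs=1e-9)

    def test_matches_adaptive_quadrature_oracle(self, acid_profile):
        res = at.integrate_association(acid_profile)
        model = make_default_pmf()
        integrand = lambda x: 4 * np.pi * x * x * np.exp(-evaluate_pmf(model, x) / kT(300.0))
        q, _ = quad(integrand, 3.9, 5.3, limit=200)
        dg_oracle = kT(300.0) * math.log(q / reference_volume_molar())
        assert abs(res.dG_dissociation - dg_oracle) < 1e-3

    def test_standard_state_conventions(self, acid_profile):
        v_s = at.solvent_molar_volume(814.0, 84.16)
        res_m = at.integrate_association(acid_profile)
        res_x = at.integrate_association(acid_profile, standard_state="solvent_mole_fraction",
                                         v_s=v_s)
        # smaller reference volume -> harder to dissociate on that scale:
        # conventions differ by exactly kT ln(V_1M / v_s)
        expected = kT(300.0) * math.log(reference_volume_molar() / v_s)
        assert res_x.dG_dissociation - res_m.dG_dissociation == pytest.approx(expected, abs=1e-9)
        with pytest.raises(ValueError):
            at.integrate_association(acid_profile, standard_state="solvent_mole_fraction")
        with pytest.raises(ValueError):
            at.integrate_association(acid_profile, standard_state="bogus")

    def test_temperature_mismatch_rejected(self, acid_profile):
        with pytest.raises(ValueError, match="temperature"):
            at.integrate_association(acid_profile, temperature=345.0)

    def test_unsampled_bins_in_window_rejected(self):
        r = np.arange(3.0, 12.001, 0.05)
        w = np.zeros_like(r)
        w[(r > 4.4) & (r < 4.6)] = np.inf
        prof = PMFProfile(bin_centers=r, W=w, temperature=300.0, zero_region=(10.0, 12.0))
        with pytest.raises(ValueError, match="unsampled"):
            at.well_integral(prof, 3.9, 5.3, 300.0)

    def test_quadrature_refinement_stability(self):
        model = make_default_pmf()
        dgs = [
            at.integrate_association(
                rasterize(model, 3.2, 12.0, step, 300.0, (10.0, 12.0))
            ).dG_dissociation
            for step in (0.05, 0.025)
        ]
        assert abs(dgs[0] - dgs[1]) < 0.05


class TestKdConversion:
    @pytest.mark.parametrize(
        "dg, T, kd_expected",
        [(20.71, 300.0, 0.249), (18.23, 345.0, 1.741)],
    )
    def test_printed_pairs(self, dg, T, kd_expected):
        assert at.kd_from_dG(dg, T) == pytest.approx(kd_expected, rel=0.01)

    def test_zero_free_energy_gives_standard_concentration(self):
        assert at.kd_from_dG(0.0, 298.0) == pytest.approx(1000.0)

    @given(st.floats(-30.0, 30.0), st.floats(250.0, 400.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, dg, T):
        assert at.dG_from_kd(at.kd_from_dG(dg, T), T) == pytest.approx(dg, abs=1e-10)


class TestVantHoff:
    def test_noiseless_recovery_is_exact(self):
        K0, dH, T0 = 1.0, 50.0, 298.0
        temps = [290.0, 310.0, 330.0]
        pts = [(T, K0 * math.exp(-(dH * 1000 / 8.314) * (1 / T - 1 / T0))) for T in temps]
        fit = at.vant_hoff_fit(pts, T0=T0)
        assert fit.dH == pytest.approx(dH, rel=1e-12)
        assert fit.K_d0 == pytest.approx(K0, rel=1e-10)
        assert np.abs(fit.residuals).max() < 1e-12

    def test_predict_at_T0_returns_K_d0(self):
        fit = at.vant_hoff_fit([(300.0, 0.249), (323.0, 0.705), (345.0, 1.741)])
        assert fit.predict(fit.T0) == pytest.approx(fit.K_d0, rel=1e-12)

    def test_kd_increases_with_T_for_positive_dH(self):
        fit = at.vant_hoff_fit([(300.0, 0.249), (323.0, 0.705), (345.0, 1.741)])
        T = np.linspace(280.0, 360.0, 50)
        assert (np.diff(fit.predict(T)) > 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="duplicate"):
            at.vant_hoff_fit([(300.0, 1.0), (300.0, 2.0)])
        with pytest.raises(ValueError):
            at.vant_hoff_fit([(300.0, -1.0), (320.0, 2.0)])
        with pytest.raises(ValueError):
            at.vant_hoff_fit([(300.0, 1.0)])


class TestDecompositions:
    def test_open_closed_fractions_sum_and_oracle(self):
        # fine raster so trapezoid vs adaptive quadrature agree to < 1e-4
        prof = rasterize(make_default_pmf(), 3.2, 12.0, 0.0025, 300.0, (10.0, 12.0))
        fo, fc = at.open_closed_decomposition(prof, 4.2)
        assert fo + fc == pytest.approx(1.0, abs=1e-12)
        # independent adaptive quadrature on the same interpolated profile
        f = lambda x: 4 * np.pi * x * x * np.exp(-prof.interp_W(x) / kT(300.0))
        q_open, _ = quad(f, 4.2, 5.3, limit=200)
        q_closed, _ = quad(f, 3.9, 4.2, limit=200)
        assert fo == pytest.approx(q_open / (q_open + q_closed), abs=1e-4)

    def test_boundary_at_edges(self, acid_profile):
        fo_hi, _ = at.open_closed_decomposition(acid_profile, 5.3 - 1e-6)
        assert fo_hi < 1e-4
        with pytest.raises(ValueError):
            at.open_closed_decomposition(acid_profile, 5.3)
        with pytest.raises(ValueError):
            at.open_closed_decomposition(acid_profile, 3.9)

    def test_symmetric_double_well_near_half(self):
        m = ModelPMF(
            wells=(GaussianWell(4.0, 15.0, 0.2), GaussianWell(5.0, 15.0, 0.2)),
            wall_position=3.0,
        )
        prof = rasterize(m, 3.3, 12.0, 0.005, 300.0, (10.0, 12.0))
        fo, fc = at.open_closed_decomposition(prof, 4.5, r0=3.6, r1=5.4)
        # r^2 weight favors the outer well slightly
        f = lambda x: 4 * np.pi * x * x * np.exp(-prof.interp_W(x) / kT(300.0))
        q_open, _ = quad(f, 4.5, 5.4, limit=200)
        q_tot = q_open + quad(f, 3.6, 4.5, limit=200)[0]
        assert fo == pytest.approx(q_open / q_tot, abs=1e-4)
        assert fo > 0.5

    def test_secondary_minimum_within_paper_band(self, coh_profile):
        pct = at.secondary_minimum_contribution(coh_profile, (2.4, 3.6), (4.4, 5.6))
        assert 0.0 <= pct <= 8.0

    def test_secondary_contribution_zero_for_flat_tiny_range(self):
        r = np.arange(2.0, 9.001, 0.01)
        w = np.zeros_like(r)
        w[r < 3.0] = -20.0
        prof = PMFProfile(bin_centers=r, W=w, temperature=300.0, zero_region=(6.0, 9.0))
        pct = at.secondary_minimum_contribution(prof, (2.0, 3.0), (5.0, 5.02))
        assert pct == pytest.approx(0.0, abs=0.05)

    def test_secondary_contribution_monotone_in_depth(self):
        pcts = []
        for depth in (0.5, 1.0, 2.0, 4.0):
            m = ModelPMF(
                wells=(GaussianWell(2.7, 30.0, 0.2), GaussianWell(5.0, depth, 0.3)),
                wall_position=2.4, wall_steepness=25.0,
            )
            prof = rasterize(m, 2.1, 9.0, 0.005, 345.0, (6.0, 9.0))
            pcts.append(at.secondary_minimum_contribution(prof, (2.4, 3.6), (4.4, 5.6)))
        assert all(b > a for a, b in zip(pcts, pcts[1:]))

    def test_overlapping_ranges_rejected(self, coh_profile):
        with pytest.raises(ValueError, match="overlap"):
            at.secondary_minimum_contribution(coh_profile, (2.4, 4.6), (4.4, 5.6))


class TestSolventVolume:
    def test_cyclohexane_and_water(self):
        assert at.solvent_molar_volume(814.0, 84.16) == pytest.approx(171.7, rel=1e-3)
        assert at.solvent_molar_volume(1000.0, 18.015) == pytest.approx(29.9, rel=1e-2)

    def test_doubling_density_halves_volume(self):
        assert at.solvent_molar_volume(1628.0, 84.16) == pytest.approx(
            at.solvent_molar_volume(814.0, 84.16) / 2.0, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            at.solvent_molar_volume(-1.0, 84.16)
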