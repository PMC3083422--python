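"""Multi-event microdosimetry: geometry, Poisson statistics, spectra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutroskin import microdosim as md


class TestSiteGeometry:
    @pytest.mark.parametrize("diameter,expected", [(1.0, 2.0 / 3.0), (3.0, 2.0)])
    def test_mean_chord_is_cauchy_two_thirds_diameter(self, diameter, expected):
        site = md.SphericalSite(diameter=diameter)
        assert md.mean_chord_length(site) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("diameter,density", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_invalid_geometry_rejected(self, diameter, density):
        with pytest.raises(md.InvalidGeometryError):
            md.SphericalSite(diameter=diameter, density=density)


class TestSpecificEnergyConversion:
    def test_zbar_f_matches_first_principles(self):
        # independent oracle: energy per event / site mass, both from scratch
        y_f, d, rho = 10.0, 1.0, 1.0
        mass_kg = rho * 1e3 * math.pi / 6.0 * (d * 1e-6) ** 3
        energy_j = y_f * (2.0 * d / 3.0) * 1.602e-16
        expected = energy_j / mass_kg  # = 2.0397 Gy
        site = md.SphericalSite(diameter=d, density=rho)
        assert md.zbar_f_from_yf(y_f, site) == pytest.approx(expected, rel=1e-12)
        assert md.zbar_f_from_yf(y_f, site) == pytest.approx(2.040, rel=1e-3)

    def test_zero_lineal_energy_gives_zero(self):
        assert md.zbar_f_from_yf(0.0, md.SphericalSite(1.0)) == 0.0

    def test_inverse_square_diameter_scaling(self):
        z1 = md.zbar_f_from_yf(5.0, md.SphericalSite(1.0))
        z2 = md.zbar_f_from_yf(5.0, md.SphericalSite(2.0))
        assert z1 / z2 == pytest.approx(4.0, rel=1e-12)

    def test_negative_yf_rejected(self):
        with pytest.raises(md.InvalidParameterError):
            md.zbar_f_from_yf(-1.0, md.SphericalSite(1.0))


class TestMeanEventNumber:
    def test_examples(self):
        assert md.mean_event_number(0.0, 2.5) == 0.0
        assert md.mean_event_number(1.0, 2.5) == pytest.approx(0.4, rel=1e-12)

    def test_linear_in_dose(self):
        z = md.zbar_f_from_yf(10.0, md.SphericalSite(1.3))
        assert md.mean_event_number(1.0, z) / md.mean_event_number(0.2, z) == pytest.approx(5.0)

    def test_invalid_zbar_rejected(self):
        with pytest.raises(md.InvalidParameterError):
            md.mean_event_number(1.0, 0.0)


def poisson_tail_bruteforce(n: float, k: int) -> float:
    """Oracle: 1 - sum of Poisson pmf terms 0..k-1, computed from scratch."""
    return 1.0 - sum(math.exp(-n) * n**i / math.factorial(i) for i in range(k))


class TestPoissonTail:
    @pytest.mark.parametrize("n", [0.01, 0.1, 1.0, 10.0])
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_bruteforce_summation(self, n, k):
        assert abs(md.prob_at_least(n, k) - poisson_tail_bruteforce(n, k)) < 1e-12

    def test_zero_mean_gives_zero(self):
        for k in (1, 2, 5):
            assert md.prob_at_least(0.0, k) == 0.0

    def test_closed_form_f2_at_unit_mean(self):
        # 1 - 2 e^{-1} = 0.264241...
        assert md.prob_at_least(1.0, 2) == pytest.approx(0.264241, abs=5e-7)

    def test_f1_closed_form(self):
        n = 0.37
        assert md.prob_at_least(n, 1) == pytest.approx(1.0 - math.exp(-n), rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=15.0))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_monotone_in_n_and_k(self, n):
        assert md.prob_at_least(n + 0.5, 2) > md.prob_at_least(n, 2)
        assert md.prob_at_least(n, 3) < md.prob_at_least(n, 2)

    def test_invalid_k_rejected(self):
        with pytest.raises(md.InvalidParameterError):
            md.prob_at_least(1.0, 0)


class TestInvertProb:
    @given(st.floats(min_value=1e-4, max_value=20.0))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_round_trip_identity(self, n):
        f = md.prob_at_least(n, 2)
        assert md.invert_prob(f, 2) == pytest.approx(n, abs=1e-8, rel=1e-8)

    def test_frozen_examples(self):
        assert md.invert_prob(0.264241, 2) == pytest.approx(1.0, abs=2e-6)
        # the printed 0.3% multi-event probability at 0.2 Gy in a 1 µm site
        assert md.invert_prob(0.003, 2) == pytest.approx(0.0795, abs=5e-4)

    def test_small_target_small_n(self):
        assert md.invert_prob(1e-9, 2) < 1e-3

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_target_out_of_range_rejected(self, bad):
        with pytest.raises(md.InvalidParameterError):
            md.invert_prob(bad, 2)


class TestF2Scan:
    def test_requires_exactly_one_calibration(self):
        with pytest.raises(md.InvalidParameterError):
            md.f2_scan([1.0], [1.0])
        with pytest.raises(md.InvalidParameterError):
            md.f2_scan([1.0], [1.0], y_f=10.0, reference=(0.2, 1.0, 0.003))

    def test_monotone_in_dose_and_diameter(self):
        scan = md.f2_scan([0.1, 0.2, 0.5, 1.0], [0.5, 1.0, 2.0, 4.0],
                          reference=(0.2, 1.0, 0.003))
        by_diam = scan.sort_values("dose_gy").groupby("diameter_um")["F2"]
        assert all(g.is_monotonic_increasing for _, g in by_diam)
        by_dose = scan.sort_values("diameter_um").groupby("dose_gy")["F2"]
        assert all(g.is_monotonic_increasing for _, g in by_dose)

    def test_reference_point_reproduced(self):
        scan = md.f2_scan([0.2], [1.0], reference=(0.2, 1.0, 0.003))
        assert scan["F2"].iloc[0] == pytest.approx(0.003, rel=1e-9)

    def test_yf_and_reference_paths_agree(self):
        # calibrate the reference triple from the y_f path itself: paths must coincide
        y_f = 25.0
        site = md.SphericalSite(1.0)
        n_ref = md.mean_event_number(0.2, md.zbar_f_from_yf(y_f, site))
        f2_ref = md.prob_at_least(n_ref, 2)
        a = md.f2_scan([0.2, 1.0], [0.5, 1.0, 2.0], y_f=y_f)
        b = md.f2_scan([0.2, 1.0], [0.5, 1.0, 2.0], reference=(0.2, 1.0, f2_ref))
        np.testing.assert_allclose(a["F2"], b["F2"], rtol=1e-9)

    def test_submicron_sites_rarely_see_multiple_events(self):
        scan = md.f2_scan([0.2, 1.0], [0.25], reference=(0.2, 1.0, 0.003))
        assert (scan["F2"] < 0.001).all()


class TestSpectra:
    def test_tsv_round_trip(self, tmp_path, lineal_spectrum):
        path = tmp_path / "f1.tsv"
        md.write_spectrum_tsv(lineal_spectrum, path)
        back = md.read_spectrum_tsv(path)
        assert back.kind == "lineal"
        np.testing.assert_allclose(back.grid, lineal_spectrum.grid, rtol=1e-12)
        np.testing.assert_allclose(back.density, lineal_spectrum.density, rtol=1e-9)

    def test_unnormalized_density_rejected(self):
        with pytest.raises(md.InvalidSpectrumError):
            md.SingleEventSpectrum(np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0, 1.0]), "lineal")

    def test_conversion_preserves_mass_and_maps_mean(self, lineal_spectrum):
        site = md.SphericalSite(1.0)
        zspec = md.single_event_z_spectrum(lineal_spectrum, site)
        assert zspec.kind == "specific"
        assert np.trapezoid(zspec.density, zspec.grid) == pytest.approx(1.0, abs=1e-9)
        expected_mean = md.zbar_f_from_yf(lineal_spectrum.frequency_mean, site)
        assert zspec.frequency_mean == pytest.approx(expected_mean, rel=1e-9)

    def test_narrow_peak_maps_to_transformed_location(self):
        y = np.linspace(9.0, 11.0, 200)
        peak = md.SingleEventSpectrum.from_samples(y, np.exp(-((y - 10) ** 2) / 0.02), "lineal")
        site = md.SphericalSite(1.0)
        z = md.single_event_z_spectrum(peak, site)
        c = md.zbar_f_from_yf(1.0, site)
        assert z.grid[np.argmax(z.density)] == pytest.approx(10.0 * c, rel=1e-3)

    def test_wrong_kind_rejected(self, specific_spectrum):
        with pytest.raises(md.InvalidSpectrumError):
            md.single_event_z_spectrum(specific_spectrum, md.SphericalSite(1.0))


class TestMultiEventDistribution:
    def test_zero_mean_is_pure_point_mass(self, specific_spectrum):
        dist = md.multi_event_distribution(specific_spectrum, 0.0)
        assert dist.zero_mass == 1.0
        assert np.all(dist.density == 0.0)

    @pytest.mark.parametrize("n", [0.1, 1.0, 5.0])
    def test_mass_and_mean_identities(self, specific_spectrum, n):
        dist = md.multi_event_distribution(specific_spectrum, n)
        assert dist.total_mass == pytest.approx(1.0, abs=1e-6)
        assert dist.mean == pytest.approx(n * specific_spectrum.frequency_mean, rel=1e-3)

    def test_mean_equals_dose_when_n_from_dose(self, specific_spectrum):
        dose = 1.0
        n = md.mean_event_number(dose, specific_spectrum.frequency_mean)
        dist = md.multi_event_distribution(specific_spectrum, n)
        assert dist.mean == pytest.approx(dose, rel=1e-3)

    def test_requires_specific_kind(self, lineal_spectrum):
        with pytest.raises(md.InvalidSpectrumError):
            md.multi_event_distribution(lineal_spectrum, 1.0)


class TestMonteCarloSampler:
    def test_zero_mean_all_zero(self, specific_spectrum):
        assert np.all(md.sample_multi_event(specific_spectrum, 0.0, 100, seed=1) == 0.0)

    def test_seed_reproducibility(self, specific_spectrum):
        a = md.sample_multi_event(specific_spectrum, 1.5, 500, seed=42)
        b = md.sample_multi_event(specific_spectrum, 1.5, 500, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_sample_mean_clt(self, specific_spectrum):
        n, draws = 2.0, 20000
        z = md.sample_multi_event(specific_spectrum, n, draws, seed=7)
        m1 = specific_spectrum.frequency_mean
        m2 = specific_spectrum.second_moment
        se = math.sqrt(n * m2 / draws)
        assert abs(z.mean() - n * m1) < 3 * se
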