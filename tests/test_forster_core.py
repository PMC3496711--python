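import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fret_ensemble.forster_core import (
    DarkStateParams,
    ForsterSystem,
    Spectrum,
    blinking_mean_efficiency,
    efficiency_from_distance,
    efficiency_from_rate,
    forster_radius,
    kappa_squared,
    overlap_integral,
    r0_attenuation,
    transfer_rate,
)


class TestForsterSystem:
    def test_valid(self):
        s = ForsterSystem(tau0D=3.0, R0=5.4, QD=0.6, regime="static")
        assert s.tau0D == 3.0 and s.regime == "static"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(tau0D=0.0, R0=5.4),
            dict(tau0D=3.0, R0=-1.0),
            dict(tau0D=3.0, R0=5.4, QD=1.5),
            dict(tau0D=3.0, R0=5.4, refractive_index=0.9),
            dict(tau0D=3.0, R0=5.4, regime="wobbly"),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ForsterSystem(**kwargs)


class TestEfficiencyFromDistance:
    def test_half_at_r0(self, system):
        assert efficiency_from_distance(5.4, system) == pytest.approx(0.5, abs=1e-15)

    def test_at_twice_r0(self, system):
        # E(2 R0) = 1/65, below 1.6%
        e = efficiency_from_distance(10.8, system)
        assert e == pytest.approx(1 / 65, rel=1e-12)
        assert e < 0.016

    def test_at_half_r0(self, system):
        e = efficiency_from_distance(2.7, system)
        assert e == pytest.approx(64 / 65, rel=1e-12)
        assert e > 0.984

    def test_far_limit(self, system):
        assert efficiency_from_distance(540.0, system) == pytest.approx(0.0, abs=1e-10)

    def test_domain_errors(self, system):
        with pytest.raises(ValueError):
            efficiency_from_distance(0.0, system)
        with pytest.raises(ValueError):
            efficiency_from_distance(-1.0, system)

    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_in_unit_interval(self, r):
        s = ForsterSystem(tau0D=3.0, R0=5.4)
        assert 0.0 < efficiency_from_distance(r, s) < 1.0

    def test_strictly_decreasing(self, system, rng):
        r = np.sort(rng.uniform(0.5, 20.0, 200))
        e = efficiency_from_distance(r, system)
        assert np.all(np.diff(e) < 0)


class TestTransferRate:
    def test_at_r0_equals_inverse_lifetime(self, system):
        assert transfer_rate(5.4, system) == pytest.approx(1 / 3, rel=1e-12)

    def test_at_twice_r0(self, system):
        # (1/3) * (1/2)^6 = 1/192
        assert transfer_rate(10.8, system) == pytest.approx(1 / 192, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=50)
    def test_composition_identity(self, r):
        s = ForsterSystem(tau0D=3.0, R0=5.4)
        via_rate = efficiency_from_rate(transfer_rate(r, s), s.tau0D)
        assert via_rate == pytest.approx(efficiency_from_distance(r, s), abs=1e-12)


class TestEfficiencyFromRate:
    @pytest.mark.parametrize(
        "k, expected", [(0.0, 0.0), (1 / 3, 0.5), (4 / 3, 0.8)]
    )
    def test_examples(self, k, expected):
        assert efficiency_from_rate(k, 3.0) == pytest.approx(expected, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            efficiency_from_rate(-0.1, 3.0)


class TestForsterRadius:
    def test_zero_kappa2(self):
        assert forster_radius(0.6, 1e6, 1.33, 0.0) == 0.0

    def test_zero_overlap(self):
        assert forster_radius(0.6, 0.0, 1.33, 2 / 3) == 0.0

    def test_doubling_j_scales_by_sixth_root_of_two(self):
        r1 = forster_radius(0.6, 1e6, 1.33, 2 / 3)
        r2 = forster_radius(0.6, 2e6, 1.33, 2 / 3)
        assert r2 / r1 == pytest.approx(2 ** (1 / 6), rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=6.0))
    @settings(max_examples=30)
    def test_kappa2_sixth_root_scaling(self, c):
        base = forster_radius(0.6, 1e6, 1.33, 2 / 3)
        scaled = forster_radius(0.6, 1e6, 1.33, 2 / 3 * c)
        assert scaled / base == pytest.approx(c ** (1 / 6), rel=1e-10)

    def test_refractive_index_below_one_rejected(self):
        with pytest.raises(ValueError):
            forster_radius(0.6, 1e6, 0.5, 2 / 3)


class TestOverlapIntegral:
    def test_disjoint_spectra(self):
        donor = Spectrum(np.array([450.0, 460.0]), np.array([1.0, 1.0]))
        acceptor = Spectrum(np.array([600.0, 610.0]), np.array([1.0, 1.0]))
        assert overlap_integral(donor, acceptor) == 0.0

    def test_constant_spectra_analytic(self):
        # J = (1/1nm) * integral of lambda^4 on [500, 501] = (501^5 - 500^5)/5
        wl = np.linspace(500.0, 501.0, 201)
        donor = Spectrum(wl, np.ones_like(wl))
        acceptor = Spectrum(wl, np.ones_like(wl))
        expected = (501.0**5 - 500.0**5) / 5.0
        assert overlap_integral(donor, acceptor) == pytest.approx(expected, rel=1e-6)
        assert overlap_integral(donor, acceptor) == pytest.approx(500.5**4, rel=1e-4)

    def test_donor_rescaling_invariance(self, rng):
        wl = np.linspace(450.0, 600.0, 100)
        fd = np.exp(-((wl - 490.0) ** 2) / 400.0)
        ea = np.exp(-((wl - 520.0) ** 2) / 600.0)
        donor, donor10 = Spectrum(wl, fd), Spectrum(wl, 10.0 * fd)
        acceptor = Spectrum(wl, ea)
        assert overlap_integral(donor, acceptor) == pytest.approx(
            overlap_integral(donor10, acceptor), rel=1e-12
        )

    def test_acceptor_homogeneity(self):
        wl = np.linspace(450.0, 600.0, 100)
        fd = np.exp(-((wl - 490.0) ** 2) / 400.0)
        ea = np.exp(-((wl - 520.0) ** 2) / 600.0)
        donor = Spectrum(wl, fd)
        j1 = overlap_integral(donor, Spectrum(wl, ea))
        j3 = overlap_integral(donor, Spectrum(wl, 3.0 * ea))
        assert j3 == pytest.approx(3.0 * j1, rel=1e-12)

    def test_different_grids_interpolated(self):
        donor = Spectrum(np.linspace(480.0, 560.0, 81), np.ones(81))
        acceptor = Spectrum(np.linspace(500.0, 600.0, 51), np.ones(51))
        # overlap [500, 560]; denominator over donor's full 80 nm support
        expected = ((560.0**5 - 500.0**5) / 5.0) / 80.0
        assert overlap_integral(donor, acceptor) == pytest.approx(expected, rel=1e-5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([500.0]), np.array([1.0]))


class TestKappaSquared:
    def test_perpendicular_field_gives_zero(self):
        for theta in (0.0, 0.7, np.pi / 2):
            assert kappa_squared(theta, np.pi / 2) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_maximum(self):
        assert kappa_squared(0.0, 0.0) == pytest.approx(4.0, abs=1e-12)

    def test_perpendicular_dipole(self):
        assert kappa_squared(np.pi / 2, 0.0) == pytest.approx(1.0, abs=1e-12)

    @given(
        st.floats(min_value=-10.0, max_value=10.0),
        st.floats(min_value=-10.0, max_value=10.0),
    )
    @settings(max_examples=200)
    def test_range_and_symmetry(self, theta, omega):
        k = kappa_squared(theta, omega)
        assert 0.0 <= k <= 4.0 + 1e-12
        assert k == pytest.approx(kappa_squared(np.pi - theta, omega), abs=1e-9)
        assert k == pytest.approx(kappa_squared(theta, np.pi - omega), abs=1e-9)


class TestDarkStates:
    @pytest.mark.parametrize(
        "e, f, expected", [(0.5, 0.0, 0.5), (0.5, 1.0, 0.0), (0.5, 0.5, 0.25)]
    )
    def test_blinking_mean(self, e, f, expected):
        assert blinking_mean_efficiency(e, f) == pytest.approx(expected, abs=1e-12)

    def test_blinking_out_of_range(self):
        with pytest.raises(ValueError):
            blinking_mean_efficiency(1.2, 0.5)
        with pytest.raises(ValueError):
            blinking_mean_efficiency(0.5, -0.1)

    @pytest.mark.parametrize(
        "fd, fa, expected",
        [(0.0, 0.0, 1.0), (1.0, 0.3, 0.0), (0.0, 0.5, 0.5 ** (1 / 6))],
    )
    def test_r0_attenuation_examples(self, fd, fa, expected):
        params = DarkStateParams(f_dark_donor=fd, f_dark_acceptor=fa)
        assert r0_attenuation(params) == pytest.approx(expected, abs=1e-12)

    def test_r0_attenuation_monotone(self):
        levels = np.linspace(0.0, 0.9, 10)
        vals = [r0_attenuation(DarkStateParams(f_dark_acceptor=f)) for f in levels]
        assert np.all(np.diff(vals) < 0)
        vals_d = [r0_attenuation(DarkStateParams(f_dark_donor=f)) for f in levels]
        assert np.all(np.diff(vals_d) < 0)

    def test_dark_params_validation(self):
        with pytest.raises(ValueError):
            DarkStateParams(f_dark_acceptor=1.5)


class TestSpectrumIO:
    def test_csv_round_trip(self, tmp_path):
        wl = np.linspace(450.0, 600.0, 50)
        s = Spectrum(wl, np.exp(-((wl - 500.0) ** 2) / 200.0))
        path = tmp_path / "spec.csv"
        s.to_csv(path)
        back = Spectrum.from_csv(path)
        np.testing.assert_allclose(back.wavelengths, s.wavelengths)
        np.testing.assert_allclose(back.values, s.values)

    def test_decreasing_wavelengths_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([500.0, 490.0]), np.array([1.0, 1.0]))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([500.0, 510.0]), np.array([1.0, -1.0]))
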