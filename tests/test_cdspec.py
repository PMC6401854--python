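"""CD normalization, differential series, peak finding and sigmoid fits."""

import numpy as np
import pytest

from paacs.cdspec import (
    CDSpectrum,
    SigmoidTransitionModel,
    differential_series,
    find_peaks,
    fit_sigmoid,
    repeat_unit_concentration,
    to_molar_ellipticity,
)
from paacs.exceptions import (
    AnalysisError,
    ConfigurationError,
    DomainError,
    FitError,
    InsufficientDataError,
)
from paacs.polymers import M_L_ALA, M_L_LEU, M_L_VAL


def _spectrum(lam, theta, ph, conc=1.83e-3, normalized=True):
    return CDSpectrum(
        wavelengths=lam, ellipticity=theta, ph=ph,
        repeat_unit_conc=conc, normalized=normalized,
    )


class TestRepeatUnitConcentration:
    @pytest.mark.parametrize(
        "mass, expected_mM",
        [(271.32, 1.843), (243.26, 2.056)],  # valine / alanine polymer
    )
    def test_atomic_mass_arithmetic(self, mass, expected_mM):
        assert repeat_unit_concentration(0.5, mass) * 1e3 == pytest.approx(
            expected_mM, abs=1e-3
        )

    def test_mean_over_three_polymers_matches_nominal_band(self):
        concs = [
            repeat_unit_concentration(0.5, p.repeat_unit_mass)
            for p in (M_L_ALA, M_L_VAL, M_L_LEU)
        ]
        assert 1.83e-3 - 0.17e-3 < np.mean(concs) < 1.83e-3 + 0.17e-3

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            repeat_unit_concentration(0.0, 243.0)
        with pytest.raises(DomainError):
            repeat_unit_concentration(0.5, -1.0)


class TestNormalization:
    def test_scalar_example(self):
        lam = np.array([228.0, 229.0])
        raw = CDSpectrum(lam, np.array([9.15, 9.15]), ph=7.0,
                         repeat_unit_conc=1.83e-3, path_length=1.0)
        norm = to_molar_ellipticity(raw)
        assert norm.ellipticity == pytest.approx([5000.0, 5000.0], rel=1e-6)
        assert norm.normalized and not raw.normalized

    def test_zero_preserved_and_linear_scaling(self, rng):
        lam = np.arange(200.0, 280.0)
        zero = to_molar_ellipticity(
            CDSpectrum(lam, np.zeros_like(lam), 5.0, repeat_unit_conc=2e-3)
        )
        assert np.all(zero.ellipticity == 0)
        raw = rng.normal(size=lam.size)
        a = to_molar_ellipticity(CDSpectrum(lam, raw, 5.0, repeat_unit_conc=1e-3))
        b = to_molar_ellipticity(CDSpectrum(lam, raw, 5.0, repeat_unit_conc=2e-3))
        assert np.allclose(a.ellipticity, 2.0 * b.ellipticity)

    def test_sum_of_signals_normalizes_to_sum(self, rng):
        lam = np.arange(200.0, 280.0)
        r1, r2 = rng.normal(size=lam.size), rng.normal(size=lam.size)
        n = lambda raw: to_molar_ellipticity(
            CDSpectrum(lam, raw, 5.0, repeat_unit_conc=1.83e-3)
        ).ellipticity
        assert np.allclose(n(r1 + r2), n(r1) + n(r2))

    def test_missing_concentration_is_configuration_error(self):
        lam = np.arange(200.0, 210.0)
        with pytest.raises(ConfigurationError):
            to_molar_ellipticity(CDSpectrum(lam, np.ones_like(lam), 5.0))


class TestDifferentialSeries:
    def test_reference_differences_to_zero_and_toy_arithmetic(self):
        lam = np.arange(200.0, 281.0)
        flat100 = _spectrum(lam, np.full(lam.size, 100.0), ph=3.0)
        flat600 = _spectrum(lam, np.full(lam.size, 600.0), ph=9.0)
        df = differential_series([flat100, flat600], wavelength=228.0)
        assert df.loc[df.ph == 3.0, "delta_theta"].item() == 0.0
        assert df.loc[df.ph == 9.0, "delta_theta"].item() == pytest.approx(500.0)

    def test_monotone_for_deprotonation_coupled_amplitude(self):
        lam = np.arange(200.0, 281.0)
        ph_values = np.arange(3.0, 11.1, 0.5)
        spectra = []
        for ph in ph_values:
            amp = 1000.0 * float(M_L_VAL.base_group.fraction_deprotonated(ph))
            band = amp * np.exp(-0.5 * ((lam - 234.0) / 8.0) ** 2)
            spectra.append(_spectrum(lam, band, ph))
        df = differential_series(spectra, wavelength=234.0)
        assert np.all(np.diff(df.delta_theta.to_numpy()) >= -1e-9)

    def test_missing_reference_raises(self):
        lam = np.arange(200.0, 281.0)
        spectra = [_spectrum(lam, np.ones(lam.size), ph) for ph in (5.0, 7.0)]
        with pytest.raises(AnalysisError, match="3"):
            differential_series(spectra, ref_ph=3.0)

    def test_unnormalized_input_rejected(self):
        lam = np.arange(200.0, 281.0)
        spectra = [
            _spectrum(lam, np.ones(lam.size), ph, normalized=False)
            for ph in (3.0, 7.0)
        ]
        with pytest.raises(ConfigurationError):
            differential_series(spectra)


class TestFindPeaks:
    def test_gaussian_band_located_to_grid_step(self):
        lam = np.arange(200.0, 280.5, 0.5)
        band = np.exp(-0.5 * ((lam - 231.0) / 7.0) ** 2)
        pk = find_peaks(_spectrum(lam, band, 9.0))
        assert abs(pk.lambda_max - 231.0) <= 0.5

    def test_low_ph_couplet_negative_band_below_positive(self):
        lam = np.arange(200.0, 280.5, 0.5)
        theta = 300.0 * np.exp(-0.5 * ((lam - 228.0) / 8.0) ** 2)
        theta -= 900.0 * np.exp(-0.5 * ((lam - 210.0) / 9.0) ** 2)
        pk = find_peaks(_spectrum(lam, theta, 3.0))
        assert pk.min_below_max and pk.lambda_min < pk.lambda_max

    def test_flat_spectrum_flagged_degenerate(self):
        lam = np.arange(200.0, 280.5, 0.5)
        pk = find_peaks(_spectrum(lam, np.zeros(lam.size), 5.0))
        assert pk.degenerate

    def test_agrees_with_exhaustive_argmax_argmin(self, rng):
        lam = np.arange(195.0, 300.5, 0.5)
        for _ in range(20):
            theta = rng.normal(size=lam.size)
            pk = find_peaks(_spectrum(lam, theta, 5.0), window=(200.0, 280.0))
            mask = (lam >= 200.0) & (lam <= 280.0)
            assert pk.theta_max == theta[mask].max()
            assert pk.theta_min == theta[mask].min()

    def test_window_outside_data_raises(self):
        lam = np.arange(210.0, 280.0)
        with pytest.raises(DomainError):
            find_peaks(_spectrum(lam, np.ones(lam.size), 5.0), window=(200.0, 280.0))


class TestSigmoidFit:
    def test_noise_free_logistic_recovered_exactly(self):
        ph = np.arange(3.0, 11.0 + 1e-9, 0.25)
        y = 0.0 + 1000.0 / (1.0 + 10.0 ** (1.0 * (6.8 - ph)))
        fit = fit_sigmoid(ph, y)
        assert fit.inflection_ph == pytest.approx(6.8, abs=1e-6)
        assert fit.lower_plateau == pytest.approx(0.0, abs=1e-6)
        assert fit.upper_plateau == pytest.approx(1000.0, abs=1e-5)
        assert fit.slope == pytest.approx(1.0, abs=1e-6)

    def test_constant_series_raises_fit_error(self):
        ph = np.arange(3.0, 11.0, 0.5)
        with pytest.raises(FitError, match="amplitude"):
            fit_sigmoid(ph, np.full(ph.size, 123.4))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            SigmoidTransitionModel(np.arange(5.0), np.arange(5.0))

    def test_noisy_inflection_mean_error_below_tolerance(self):
        ph = np.arange(3.0, 11.0 + 1e-9, 0.25)
        truth = 7.3
        amp = 1000.0
        y0 = amp / (1.0 + 10.0 ** (0.8 * (truth - ph)))
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fit = fit_sigmoid(ph, y0 + rng.normal(0, 0.02 * amp, ph.size))
            errors.append(abs(fit.inflection_ph - truth))
        assert np.mean(errors) < 0.05

    def test_plateaus_bracket_nearly_all_points_at_two_percent_noise(self):
        ph = np.arange(3.0, 11.0 + 1e-9, 0.2)
        amp = 1000.0
        rng = np.random.default_rng(7)
        y = amp / (1.0 + 10.0 ** (1.0 * (7.0 - ph)))
        y = y + rng.normal(0, 0.02 * amp, ph.size)
        fit = fit_sigmoid(ph, y)
        outside = np.sum(
            (fit.delta_theta < fit.lower_plateau - 0.05 * fit.amplitude)
            | (fit.delta_theta > fit.upper_plateau + 0.05 * fit.amplitude)
        )
        assert outside <= 0.05 * ph.size

    def test_decreasing_transition_reoriented_canonically(self):
        ph = np.arange(3.0, 11.0 + 1e-9, 0.25)
        y = 500.0 - 500.0 / (1.0 + 10.0 ** (1.2 * (6.0 - ph)))
        fit = fit_sigmoid(ph, y)
        assert fit.slope > 0
        assert fit.inflection_ph == pytest.approx(6.0, abs=1e-5)

    def test_summary_and_plateau_intervals_report(self):
        ph = np.arange(3.0, 11.0 + 1e-9, 0.25)
        y = 1000.0 / (1.0 + 10.0 ** (1.0 * (6.8 - ph)))
        fit = fit_sigmoid(ph, y)
        text = fit.summary()
        assert "inflection pH" in text
        lo, hi = fit.plateau_intervals()
        assert lo is not None and lo[0] == pytest.approx(3.0)
        assert hi is not None and hi[1] == pytest.approx(11.0)
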