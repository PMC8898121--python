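import numpy as np
import pytest

from ferrohem import (
    GridError,
    Spectrum,
    UndefinedValueError,
    ValidationError,
    derivative_fractions,
    fit_spectrum,
    hemolysis_level,
    model_spectrum,
)
from ferrohem.spectra import SpectralUnmixing, scatter_basis


class TestForwardModel:
    def test_zero_concentrations_give_zero_od(self, extinction):
        sp = model_spectrum(0, 0, 0, 0, 0, extinction)
        assert np.all(sp.optical_density == 0.0)

    def test_unit_concentration_identity(self, extinction):
        """1 mM MetHb at L = 1 cm reproduces the MetHb absorptivity curve."""
        sp = model_spectrum(0, 0, 1000.0, 0, 0, extinction, path_length_cm=1.0)
        assert np.allclose(sp.optical_density, extinction.eps_methb, rtol=1e-12)

    def test_scatter_basis_exponent(self, extinction):
        g = scatter_basis(np.array([550.0, 1100.0]), exponent=-4)
        assert g[0] == pytest.approx(1.0)
        assert g[1] == pytest.approx(1.0 / 16.0)
        with pytest.raises(ValidationError):
            scatter_basis(np.array([550.0]), exponent=2)

    def test_negative_concentration_rejected(self, extinction):
        with pytest.raises(ValidationError):
            model_spectrum(-1.0, 0, 0, 0, 0, extinction)


class TestUnmixing:
    def test_exact_round_trip_with_scatter(self, extinction):
        sp = model_spectrum(2.0, 0.5, 2.5, 0.01, 0.02, extinction)
        fit = fit_spectrum(sp, extinction)
        assert fit.c_hbo2 == pytest.approx(2.0, rel=1e-6)
        assert fit.c_hb == pytest.approx(0.5, rel=1e-6)
        assert fit.c_methb == pytest.approx(2.5, rel=1e-6)
        assert fit.k_scatter == pytest.approx(0.01, rel=1e-6)
        assert fit.s_scatter == pytest.approx(0.02, rel=1e-6)
        assert fit.r2_adjusted == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_over_random_parameter_draws(self, extinction):
        rng = np.random.default_rng(99)
        for _ in range(100):
            c = rng.uniform(0.1, 8.0, size=3)
            k, s = rng.uniform(0.0, 0.05, size=2)
            sp = model_spectrum(*c, k, s, extinction)
            fit = fit_spectrum(sp, extinction)
            got = np.array([fit.c_hbo2, fit.c_hb, fit.c_methb, fit.k_scatter, fit.s_scatter])
            assert np.allclose(got, [*c, k, s], rtol=1e-6, atol=1e-9)

    def test_pure_absorption_recovers_zero_scatter(self, extinction):
        """Lysate-like spectra: K and S come out as zero when fitted free."""
        sp = model_spectrum(3.0, 0.2, 1.5, 0.0, 0.0, extinction)
        fit = fit_spectrum(sp, extinction, allow_scatter=True)
        assert abs(fit.k_scatter) < 1e-6
        assert abs(fit.s_scatter) < 1e-6

    def test_all_zero_spectrum_fits_to_zero(self, extinction):
        sp = Spectrum(extinction.wavelengths, np.zeros(len(extinction)))
        fit = fit_spectrum(sp, extinction)
        assert fit.c_total == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_is_unbiased(self, extinction, rng):
        """With sigma = 0.002 absorbance the unmixed concentrations are
        unbiased within three standard errors over 200 replicates."""
        truth = np.array([3.0, 0.5, 1.5])
        clean = model_spectrum(*truth, 0.0, 0.0, extinction)
        n_rep = 200
        rec = np.empty((n_rep, 3))
        for i in range(n_rep):
            noisy = Spectrum(
                clean.wavelengths,
                clean.optical_density + rng.normal(0, 0.002, len(clean)),
            )
            fit = fit_spectrum(noisy, extinction, allow_scatter=False)
            rec[i] = [fit.c_hbo2, fit.c_hb, fit.c_methb]
        se = rec.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(rec.mean(axis=0) - truth) < 3 * se + 1e-12)

    def test_scatter_never_worsens_residual(self, extinction, rng):
        """The scatter-free model is nested in the full model."""
        sp = model_spectrum(2.0, 0.3, 1.0, 0.005, 0.01, extinction)
        noisy = Spectrum(sp.wavelengths, sp.optical_density + rng.normal(0, 0.002, len(sp)))
        full = fit_spectrum(noisy, extinction, allow_scatter=True)
        reduced = fit_spectrum(noisy, extinction, allow_scatter=False)
        assert full.residual_norm <= reduced.residual_norm + 1e-12

    def test_coarser_spectrum_grid_is_interpolated(self, extinction):
        wl = np.arange(510.0, 690.0, 2.0)
        sub = extinction.interp_to(wl)
        sp = model_spectrum(1.0, 0.5, 2.0, 0.0, 0.0, sub)
        fit = fit_spectrum(sp, extinction)  # full 0.5 nm table, coarse spectrum
        assert fit.c_methb == pytest.approx(2.0, rel=1e-6)

    def test_out_of_range_grid_rejected(self, extinction):
        sp = Spectrum(np.arange(400.0, 520.0, 1.0), np.zeros(120))
        with pytest.raises(GridError):
            fit_spectrum(sp, extinction)

    def test_too_few_points_rejected(self, extinction):
        wl = extinction.wavelengths[:8]
        with pytest.raises(ValidationError):
            SpectralUnmixing(Spectrum(wl, np.zeros(8)), extinction)


class TestFractions:
    @pytest.mark.parametrize(
        "c_methb,c_total,expected",
        [(4.10, 5.0, 82.0), (1.0, 5.0, 20.0), (0.0, 5.0, 0.0)],
    )
    def test_percent_examples(self, c_methb, c_total, expected):
        class F:
            pass

        f = F()
        f.c_methb = c_methb
        f.c_hbo2 = c_total - c_methb
        f.c_hb = 0.0
        fr = derivative_fractions(f)
        assert fr.methb_percent == pytest.approx(expected, abs=1e-9)

    def test_percentages_sum_to_100(self, rng):
        class F:
            pass

        for _ in range(50):
            f = F()
            f.c_hbo2, f.c_hb, f.c_methb = rng.uniform(0.01, 10, 3)
            fr = derivative_fractions(f)
            assert fr.methb_percent + fr.hbo2_percent + fr.hb_percent == pytest.approx(
                100.0, abs=1e-9
            )

    def test_zero_total_rejected(self):
        class F:
            c_hbo2 = 0.0
            c_hb = 0.0
            c_methb = 0.0

        with pytest.raises(UndefinedValueError):
            derivative_fractions(F())


class TestHemolysis:
    def test_identical_spectra_read_zero(self, extinction):
        sp = model_spectrum(3.0, 0.0, 2.0, 0.0, 0.0, extinction)
        assert hemolysis_level(sp, sp, extinction) == pytest.approx(0.0, abs=1e-9)

    def test_empty_spectrum_reads_full_hemolysis(self, extinction):
        sp0 = model_spectrum(5.0, 0.0, 0.0, 0.0, 0.0, extinction)
        spt = Spectrum(extinction.wavelengths, np.zeros(len(extinction)))
        assert hemolysis_level(spt, sp0, extinction) == pytest.approx(100.0, abs=1e-9)

    def test_recovers_generated_pigment_loss(self, extinction):
        """A 58 % reduction in total pigment reads as 58 % hemolysis."""
        sp0 = model_spectrum(4.0, 0.2, 0.8, 0.0, 0.0, extinction)
        spt = model_spectrum(4.0 * 0.42, 0.2 * 0.42, 0.8 * 0.42, 0.0, 0.0, extinction)
        assert hemolysis_level(spt, sp0, extinction) == pytest.approx(58.0, abs=1e-6)

    def test_zero_reference_rejected(self, extinction):
        zero = Spectrum(extinction.wavelengths, np.zeros(len(extinction)))
        with pytest.raises(UndefinedValueError):
            hemolysis_level(zero, zero, extinction)
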