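import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ferrohem import (
    FitError,
    ForceCurve,
    ModulusSample,
    NoStructureError,
    ProbeParams,
    ValidationError,
    fit_youngs_modulus,
    fraction_beyond_control,
    hertz_force,
    modulus_distribution,
    profile_features,
)
from ferrohem.mechanics import HertzContact

PROBE = ProbeParams(radius_nm=150.0, poisson_ratio=0.5)


def synth_curve(e_kpa, probe=PROBE, n=50, h_max=1000.0):
    h = np.linspace(0.0, h_max, n)
    return ForceCurve(h, np.asarray(hertz_force(e_kpa, probe, h)))


class TestHertzForce:
    def test_zero_indentation_zero_force(self):
        assert hertz_force(17.0, PROBE, 0.0) == 0.0

    def test_printed_modulus_at_micron_indentation(self):
        # E = 17 kPa, R = 150 nm, nu = 0.5, h = 1000 nm
        assert hertz_force(17.0, PROBE, 1000.0) == pytest.approx(11.705, rel=1e-3)

    def test_linear_in_modulus_and_three_halves_in_depth(self):
        f1 = hertz_force(10.0, PROBE, 400.0)
        assert hertz_force(20.0, PROBE, 400.0) == pytest.approx(2 * f1, rel=1e-12)
        assert hertz_force(10.0, PROBE, 1600.0) == pytest.approx(8 * f1, rel=1e-12)

    def test_negative_indentation_rejected(self):
        with pytest.raises(ValidationError):
            hertz_force(17.0, PROBE, -5.0)


class TestModulusFit:
    @pytest.mark.parametrize("e_true", [11.0, 17.0])
    def test_noiseless_round_trip_at_printed_group_means(self, e_true):
        assert fit_youngs_modulus(synth_curve(e_true)) == pytest.approx(e_true, rel=1e-6)

    @given(e=st.floats(1.0, 100.0))
    def test_round_trip_across_modulus_range(self, e):
        assert fit_youngs_modulus(synth_curve(e)) == pytest.approx(e, rel=1e-6)

    def test_noisy_mean_recovery_within_2_percent(self, rng):
        e_true = 17.0
        clean = synth_curve(e_true)
        estimates = []
        for _ in range(100):
            noisy = ForceCurve(
                clean.indentation_nm,
                clean.force_nN * (1 + rng.normal(0, 0.02, len(clean))),
            )
            estimates.append(fit_youngs_modulus(noisy))
        assert np.mean(estimates) == pytest.approx(e_true, rel=0.02)

    def test_results_object_reports_uncertainty(self):
        res = HertzContact(synth_curve(17.0), PROBE).fit()
        assert res.e_kpa == pytest.approx(17.0, rel=1e-6)
        assert res.stderr_kpa == pytest.approx(0.0, abs=1e-9)
        assert "Hertz" in res.summary()

    def test_negative_force_curve_fails(self):
        h = np.linspace(0, 1000, 50)
        with pytest.raises(FitError):
            HertzContact(ForceCurve(h, -np.asarray(hertz_force(5.0, PROBE, h))), PROBE).fit()

    def test_too_few_contact_points_rejected(self):
        h = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            HertzContact(ForceCurve(h, np.zeros(6)), PROBE)


class TestDistributions:
    def test_single_value_is_a_unit_step(self):
        dist = modulus_distribution(ModulusSample([12.0]), bins=4)
        assert dist.ecdf(11.99) == 0.0
        assert dist.ecdf(12.0) == 1.0

    def test_histogram_area_is_one(self, rng):
        for bins in (5, 10, 37):
            vals = rng.lognormal(2.5, 0.4, size=200)
            dist = modulus_distribution(ModulusSample(vals), bins=bins)
            area = np.sum(dist.density * np.diff(dist.bin_edges))
            assert area == pytest.approx(1.0, rel=1e-9)

    def test_ecdf_matches_sorted_rank_oracle(self, rng):
        vals = rng.normal(15, 5, size=100)
        vals = vals[vals > 0]
        dist = modulus_distribution(ModulusSample(vals), bins=10)
        xs = np.sort(vals)
        for i, x in enumerate(xs):
            # brute-force: fraction of sample <= x
            assert dist.ecdf(x) == pytest.approx(np.mean(vals <= x), abs=1e-12)
            assert dist.ecdf_y[i] == pytest.approx((i + 1) / xs.size)

    def test_ecdf_consistent_with_histogram_integral(self, rng):
        vals = rng.normal(20, 4, 500)
        dist = modulus_distribution(ModulusSample(vals[vals > 0]), bins=20)
        for edge_idx in (5, 10, 15):
            x = dist.bin_edges[edge_idx]
            integral = np.sum(
                dist.density[:edge_idx] * np.diff(dist.bin_edges)[:edge_idx]
            )
            assert integral == pytest.approx(dist.ecdf(x), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            modulus_distribution(ModulusSample([]), bins=5)


class TestExceedance:
    def test_self_comparison_gives_tail_mass(self, rng):
        vals = rng.normal(15, 5, size=5000)
        sample = ModulusSample(vals[vals > 0])
        frac = fraction_beyond_control(sample, sample, level=0.95)
        assert frac == pytest.approx(5.0, abs=0.5)

    def test_fully_shifted_treatment(self):
        control = ModulusSample(np.linspace(5, 15, 50))
        treatment = ModulusSample(np.linspace(100, 200, 50))
        assert fraction_beyond_control(treatment, control) == 100.0

    def test_matches_direct_counting_oracle(self, rng):
        """Seeded normals shaped after the printed 24-h group moments."""
        control = rng.normal(15, 5, 100)
        treatment = rng.normal(23, 8, 100)
        control = np.abs(control) + 0.1
        treatment = np.abs(treatment) + 0.1
        frac = fraction_beyond_control(
            ModulusSample(treatment), ModulusSample(control), level=0.95
        )
        threshold = np.quantile(control, 0.95)
        count = sum(1 for v in treatment if v > threshold)
        assert frac == pytest.approx(100.0 * count / treatment.size, abs=1e-12)
        assert 10.0 < frac < 70.0  # same order as the study's ~35-37 %

    def test_invariant_under_common_monotone_rescale(self, rng):
        control = ModulusSample(rng.uniform(5, 25, 80))
        treatment = ModulusSample(rng.uniform(10, 40, 80))
        base = fraction_beyond_control(treatment, control)
        rescaled = fraction_beyond_control(
            ModulusSample(treatment.values_kpa**1.7),
            ModulusSample(control.values_kpa**1.7),
        )
        assert rescaled == base

    def test_invalid_level_rejected(self):
        s = ModulusSample([1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            fraction_beyond_control(s, s, level=1.0)


class TestProfileFeatures:
    def test_pure_cosine(self):
        pos = np.linspace(0, 5000, 2001)
        period, amp = 1000.0, 120.0
        y = amp * np.cos(2 * np.pi * pos / period)
        feats = profile_features(y, pos)
        assert feats.period_nm == pytest.approx(period, rel=0.01)
        assert feats.height_nm == pytest.approx(2 * amp, rel=0.01)

    def test_flat_profile_rejected(self):
        pos = np.linspace(0, 100, 50)
        with pytest.raises(NoStructureError):
            profile_features(np.ones(50), pos)

    def test_monotone_profile_rejected(self):
        pos = np.linspace(0, 100, 50)
        with pytest.raises(NoStructureError):
            profile_features(pos * 2.0, pos)

    def test_two_harmonic_profile_matches_extrema_scan_oracle(self):
        pos = np.linspace(0, 6000, 3001)
        y = 100 * np.cos(2 * np.pi * pos / 1500) + 15 * np.sin(2 * np.pi * pos / 400)
        feats = profile_features(y, pos)
        # brute-force scan for strict local minima
        minima = [
            i
            for i in range(1, y.size - 1)
            if y[i] < y[i - 1] and y[i] < y[i + 1]
        ]
        expected_period = np.mean(np.diff(pos[minima]))
        assert feats.period_nm == pytest.approx(expected_period, rel=1e-9)


def test_probe_validation():
    with pytest.raises(ValidationError):
        ProbeParams(radius_nm=0.0)
    with pytest.raises(ValidationError):
        ProbeParams(poisson_ratio=0.7)
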