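"""Two-state exchange: analytic limits, ODE oracle, joint titration fitting."""

import numpy as np
import pytest
from scipy.optimize import brentq

from conftest import brute_force_bound_complex, ode_oracle_signal
from serobind import synthetic_data as sd
from serobind.exchange_lineshape import (
    AcquisitionParams,
    ExchangeModel,
    ResiduePrior,
    ResidueResonance,
    SamplePoint,
    bound_fraction,
    bootstrap_koff,
    fit_exchange,
    koff_confidence,
    simulate_spectrum,
)
from serobind.exchange_lineshape import _components, _time_signal


def ligand_for_pb(p_total, k_d, pb):
    return brentq(lambda l: bound_fraction(p_total, l, k_d) - pb, 0.0, 1.0)


class TestBoundFraction:
    def test_no_ligand_means_no_complex(self):
        assert bound_fraction(1.9e-4, 0.0, 3e-7) == 0.0

    def test_tight_binding_with_excess_ligand_saturates(self):
        assert bound_fraction(1e-4, 2e-4, 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_against_fixed_point_oracle(self):
        p, l, kd = 190e-6, 95e-6, 0.3e-6
        pb = bound_fraction(p, l, kd)
        assert pb == pytest.approx(0.498, abs=5e-3)
        oracle = brute_force_bound_complex(p, l, kd) / p
        assert pb == pytest.approx(oracle, rel=1e-9)

    def test_zero_protein_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction(0.0, 1e-4, 1e-7)


class TestSimulatorLimits:
    def test_apo_limit_single_peak_at_free_shift_with_expected_width(self, acq):
        res = ResidueResonance("x", 8.0, 115.0, 8.3, 117.5, 20, 20, 15, 15)
        model = ExchangeModel(50.0, 2e-7, (res,))
        spec = simulate_spectrum(model, SamplePoint(1.9e-4, 0.0), acq)
        i_n, i_h = np.unravel_index(np.argmax(spec.data), spec.data.shape)
        step_h = spec.ppm_h[1] - spec.ppm_h[0]
        assert abs(spec.ppm_h[i_h] - 8.0) <= step_h
        # FWHM of the direct-dimension slice: R2/pi + lb Hz
        row = spec.data[i_n]
        half = row.max() / 2.0
        above = np.flatnonzero(row > half)
        fwhm_hz = (above[-1] - above[0] + 1) * step_h * acq.h_freq_mhz
        expected = res.r2h_free / np.pi + acq.lb_h
        assert fwhm_hz == pytest.approx(expected, abs=2 * step_h * acq.h_freq_mhz)

    def test_fast_exchange_peak_at_population_weighted_shift(self, acq):
        res = ResidueResonance("x", 8.0, 115.0, 8.3, 117.5)
        model = ExchangeModel(1e5, 2e-7, (res,))
        lig = ligand_for_pb(1.9e-4, model.k_d, 0.5)
        spec = simulate_spectrum(model, SamplePoint(1.9e-4, lig), acq)
        i_n, i_h = np.unravel_index(np.argmax(spec.data), spec.data.shape)
        assert abs(spec.ppm_h[i_h] - 8.15) <= spec.ppm_h[1] - spec.ppm_h[0]
        assert abs(spec.ppm_n[i_n] - 116.25) <= spec.ppm_n[1] - spec.ppm_n[0]

    def test_slow_exchange_intensity_partition(self):
        # edge delays off: they imprint a per-state phase roll that turns the
        # far tails dispersive, which is irrelevant to the population physics
        acq = AcquisitionParams(t1_edge_delay=0.0)
        res = ResidueResonance("x", 7.8, 112.0, 8.6, 121.0)
        model = ExchangeModel(1.0, 2e-7, (res,))
        lig = ligand_for_pb(1.9e-4, model.k_d, 0.3)
        spec = simulate_spectrum(model, SamplePoint(1.9e-4, lig), acq)
        mid = np.searchsorted(spec.ppm_n, 116.5)
        free_int = spec.data[:mid].sum()
        bound_int = spec.data[mid:].sum()
        assert bound_int / (free_int + bound_int) == pytest.approx(0.30, abs=0.015)

    def test_total_intensity_independent_of_koff(self):
        # exchange conserves magnetization: at fixed populations, relaxation
        # and apodization the integrated spectrum must not depend on k_off
        acq = AcquisitionParams(t1_edge_delay=0.0)
        res = ResidueResonance("x", 8.0, 113.0, 8.4, 120.0)
        totals = []
        for koff in (2.0, 50.0, 1e3, 1e5):
            model = ExchangeModel(koff, 2e-7, (res,))
            lig = ligand_for_pb(1.9e-4, model.k_d, 0.4)
            spec = simulate_spectrum(model, SamplePoint(1.9e-4, lig), acq)
            totals.append(spec.data.sum())
        totals = np.array(totals)
        assert np.max(np.abs(totals - totals[0])) / abs(totals[0]) < 0.01

    def test_agrees_with_ode_integrator_on_random_instances(self, small_acq):
        rng = np.random.default_rng(7)
        for _ in range(3):
            res = ResidueResonance(
                "o",
                h_free=float(rng.uniform(7.5, 8.5)),
                n_free=float(rng.uniform(110, 122)),
                h_bound=float(rng.uniform(7.5, 8.5)),
                n_bound=float(rng.uniform(110, 122)),
                r2h_free=float(rng.uniform(10, 30)),
                r2h_bound=float(rng.uniform(10, 30)),
                r2n_free=float(rng.uniform(10, 30)),
                r2n_bound=float(rng.uniform(10, 30)),
                amplitude=float(rng.uniform(0.5, 2.0)),
            )
            model = ExchangeModel(float(rng.uniform(5, 500)), 10 ** rng.uniform(-7.5, -6), (res,))
            pt = SamplePoint(1.9e-4, float(rng.uniform(0.3, 1.5)) * 1.9e-4)
            lam_n, lam_h, coef = _components(model, [pt], small_acq)
            sig = _time_signal(lam_n[0], lam_h[0], coef[0], small_acq)
            oracle = ode_oracle_signal(model, pt, small_acq)
            assert np.max(np.abs(oracle - sig)) / np.max(np.abs(sig)) < 1e-6


@pytest.fixture(scope="module")
def truth_model(acq):
    return sd.example_exchange_model(k_off=50.0, k_d=2e-7, seed=0, acq=acq)


@pytest.fixture(scope="module")
def priors(truth_model):
    return [ResiduePrior(r.name, r.h_free, r.n_free) for r in truth_model.residues]


@pytest.fixture(scope="module")
def noiseless_fit(truth_model, priors, acq):
    points = sd.default_titration_points()
    spectra = sd.generate_titration_spectra(truth_model, points, acq, 0.0, 0)
    return fit_exchange(list(zip(points, spectra)), priors, acq, kd_box=(1e-8, 1e-5))


@pytest.fixture(scope="module")
def noisy_fit(truth_model, priors, acq):
    points = sd.default_titration_points()
    clean = sd.generate_titration_spectra(truth_model, points, acq, 0.0, 0)
    noise = sd.noise_sd_for_snr(clean, 50.0)
    spectra = sd.generate_titration_spectra(truth_model, points, acq, noise, 42)
    return fit_exchange(list(zip(points, spectra)), priors, acq, kd_box=(1e-8, 1e-5))


class TestFitExchange:
    def test_noiseless_recovery_within_one_percent(self, noiseless_fit):
        assert noiseless_fit.converged
        assert abs(noiseless_fit.k_off - 50.0) / 50.0 < 0.01

    def test_misstated_ligand_concentration_absorbed_by_lig_scale(
        self, truth_model, priors, acq
    ):
        nominal = sd.default_titration_points()
        actual = [SamplePoint(p.p_total, p.l_total * 1.1) for p in nominal]
        spectra = sd.generate_titration_spectra(truth_model, actual, acq, 0.0, 0)
        fit = fit_exchange(list(zip(nominal, spectra)), priors, acq, kd_box=(1e-8, 1e-5))
        assert fit.lig_scale == pytest.approx(1.1, abs=0.03)
        assert abs(fit.k_off - 50.0) / 50.0 < 0.02

    def test_halving_true_koff_halves_estimate(self, truth_model, priors, acq, noiseless_fit):
        from dataclasses import replace

        slow = replace(truth_model, k_off=25.0)
        points = sd.default_titration_points()
        spectra = sd.generate_titration_spectra(slow, points, acq, 0.0, 0)
        fit = fit_exchange(list(zip(points, spectra)), priors, acq, kd_box=(1e-8, 1e-5))
        assert fit.k_off / noiseless_fit.k_off == pytest.approx(0.5, abs=0.02)

    def test_single_point_rejected(self, truth_model, priors, acq):
        points = sd.default_titration_points()[:1]
        spectra = sd.generate_titration_spectra(truth_model, points, acq, 0.0, 0)
        with pytest.raises(ValueError, match="2 titration points"):
            fit_exchange(list(zip(points, spectra)), priors, acq)


class TestBootstrap:
    def test_seed_determinism_and_default_replicas(self, noisy_fit):
        import inspect

        assert inspect.signature(bootstrap_koff).parameters["n_replicas"].default == 100
        se_a = bootstrap_koff(noisy_fit, n_replicas=10, seed=1)
        se_b = bootstrap_koff(noisy_fit, n_replicas=10, seed=1)
        assert se_a == se_b
        assert se_a > 0

    def test_more_noise_increases_bootstrap_se(self, truth_model, priors, acq, noisy_fit):
        points = sd.default_titration_points()
        clean = sd.generate_titration_spectra(truth_model, points, acq, 0.0, 0)
        noise = sd.noise_sd_for_snr(clean, 50.0)
        spectra = sd.generate_titration_spectra(truth_model, points, acq, 3 * noise, 42)
        loud_fit = fit_exchange(list(zip(points, spectra)), priors, acq, kd_box=(1e-8, 1e-5))
        se_quiet = bootstrap_koff(noisy_fit, n_replicas=10, seed=3)
        se_loud = bootstrap_koff(loud_fit, n_replicas=10, seed=3)
        assert se_loud > se_quiet


class TestConfidenceGrid:
    def test_zero_noise_interval_collapses_onto_truth(self, noiseless_fit):
        ci = koff_confidence(noiseless_fit, grid=np.geomspace(40, 62.5, 9))
        step = np.log(ci.grid[1] / ci.grid[0])
        assert ci.low <= noiseless_fit.k_off <= ci.high
        assert np.log(ci.high / ci.low) <= 2 * step

    def test_interval_contains_estimate_and_brackets_required(self, noisy_fit):
        ci = koff_confidence(noisy_fit, grid=np.geomspace(noisy_fit.k_off / 1.5,
                                                          noisy_fit.k_off * 1.5, 7))
        assert ci.low <= noisy_fit.k_off <= ci.high
        assert ci.threshold > min(ci.ssr_profile.min(), noisy_fit.ssr)
        with pytest.raises(ValueError, match="bracket"):
            koff_confidence(noisy_fit, grid=np.array([1.0, 2.0]))
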