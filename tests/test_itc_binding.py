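"""One-set-of-sites ITC model: oracle agreement, recovery, decomposition."""

import numpy as np
import pytest

from conftest import brute_force_bound_complex
from serobind import synthetic_data as sd
from serobind.itc_binding import (
    R_GAS,
    BindingParameters,
    InjectionProtocol,
    Thermogram,
    fit_one_site,
    one_site_heat,
    thermo_decompose,
)
from serobind.itc_binding import _cell_concentrations


def oracle_heats(params: BindingParameters, protocol: InjectionProtocol) -> np.ndarray:
    """Per-injection heats from the brute-force mass-balance solver."""
    m, x = _cell_concentrations(protocol)
    v0 = protocol.cell_volume
    q = np.array(
        [
            brute_force_bound_complex(params.n * mi, xi, params.k_d) * params.dh * v0
            for mi, xi in zip(m, x)
        ]
    )
    q_prev = np.concatenate(([0.0], q[:-1]))
    dv = np.asarray(protocol.injection_volumes)
    return q - q_prev + (dv / v0) * (q + q_prev) / 2.0 + params.q_dil


class TestOneSiteHeat:
    def test_zero_enthalpy_gives_zero_heat(self, protocol):
        params = BindingParameters(n=1.0, k_d=1e-7, dh=0.0, q_dil=0.0)
        assert np.all(one_site_heat(params, protocol) == 0.0)

    def test_agrees_with_mass_balance_oracle_on_paper_protocol(self, protocol):
        params = BindingParameters(n=1.0, k_d=0.098e-6, dh=-8.0 * 4184.0)
        model = one_site_heat(params, protocol)
        oracle = oracle_heats(params, protocol)
        scale = np.max(np.abs(oracle))
        # first injection to 6 significant digits, all others equally tight
        assert abs(model[0] - oracle[0]) / abs(oracle[0]) < 1e-6
        assert np.max(np.abs(model - oracle)) / scale < 1e-6

    def test_agrees_with_oracle_on_random_draws(self, protocol):
        rng = np.random.default_rng(42)
        for _ in range(100):
            params = BindingParameters(
                n=float(rng.uniform(0.5, 2.0)),
                k_d=float(10 ** rng.uniform(-9, -5)),
                dh=float(rng.uniform(-60e3, 60e3)),
                q_dil=float(rng.uniform(-1e-6, 1e-6)),
            )
            model = one_site_heat(params, protocol)
            oracle = oracle_heats(params, protocol)
            scale = max(np.max(np.abs(oracle)), 1e-12)
            assert np.max(np.abs(model - oracle)) / scale < 1e-6

    def test_tight_binding_limit_binds_every_injection_until_saturation(self, protocol):
        # K_D -> 0: early injections each release dH per mole injected,
        # post-equivalence injections release essentially nothing
        params = BindingParameters(n=1.0, k_d=1e-13, dh=-8.0 * 4184.0)
        heats = one_site_heat(params, protocol)
        per_mole = params.dh * protocol.syringe_conc * protocol.injection_volumes[0]
        assert np.all(np.abs(heats[:10] - per_mole) / abs(per_mole) < 0.02)
        assert np.all(np.abs(heats[-5:]) < 0.01 * abs(heats[0]))

    def test_cumulative_conservation(self, protocol, wt_params):
        # without the displacement term, per-injection heats telescope to Q_final
        heats = one_site_heat(wt_params, protocol)
        m, x = _cell_concentrations(protocol)
        nm = wt_params.n * m
        r, k = x / nm, wt_params.k_d / nm
        b = 1 + r + k
        q = 0.5 * nm * wt_params.dh * protocol.cell_volume * (b - np.sqrt(b * b - 4 * r))
        q_prev = np.concatenate(([0.0], q[:-1]))
        dv = np.asarray(protocol.injection_volumes)
        plain = heats - (dv / protocol.cell_volume) * (q + q_prev) / 2.0
        assert abs(plain.sum() - q[-1]) / abs(q[-1]) < 1e-10

    def test_tighter_binding_steepens_isotherm(self, protocol):
        loose = one_site_heat(BindingParameters(1.0, 1e-6, 8e3), protocol)
        tight = one_site_heat(BindingParameters(1.0, 1e-8, 8e3), protocol)
        # pre-equivalence injections (equivalence falls near injection 13)
        assert np.all(tight[:10] >= loose[:10] - 1e-15)

    def test_rejects_bad_protocol_fields(self):
        with pytest.raises(ValueError, match="cell_conc"):
            InjectionProtocol(1.4e-3, -1e-6, 3e-4, (1e-5,))
        with pytest.raises(ValueError, match="injection_volumes"):
            InjectionProtocol(1.4e-3, 3e-5, 3e-4, (1e-5, 0.0))


class TestFitOneSite:
    def test_zero_noise_recovery_within_tenth_percent(self, protocol):
        truth = BindingParameters(n=1.05, k_d=0.26e-6, dh=-8.0 * 4184.0, q_dil=3e-7)
        thermo = sd.generate_itc_thermogram(truth, protocol, 0.0, seed=0)
        fit = fit_one_site(thermo)
        assert fit.converged
        assert abs(fit.estimates.n - truth.n) / truth.n < 1e-3
        assert abs(fit.estimates.k_d - truth.k_d) / truth.k_d < 1e-3
        assert abs(fit.estimates.dh - truth.dh) / abs(truth.dh) < 1e-3

    def test_heuristic_start_matches_informed_start(self, protocol, wt_params):
        thermo = sd.generate_itc_thermogram(wt_params, protocol, 0.0, seed=0)
        fit_default = fit_one_site(thermo)
        fit_informed = fit_one_site(thermo, init=wt_params)
        assert (
            abs(fit_default.estimates.k_d - fit_informed.estimates.k_d)
            / fit_informed.estimates.k_d
            < 1e-4
        )

    def test_monte_carlo_kd_recovery_under_realistic_noise(self, protocol, wt_params):
        errs = []
        for seed in range(100):
            thermo = sd.generate_itc_thermogram(
                wt_params, protocol, sd.REALISTIC_ITC_NOISE_J, seed=seed
            )
            fit = fit_one_site(thermo)
            errs.append(abs(fit.estimates.k_d - wt_params.k_d) / wt_params.k_d)
        assert np.median(errs) < 0.10

    def test_too_few_injections_rejected(self, wt_params):
        short = InjectionProtocol.default(n_injections=5)
        thermo = Thermogram(short, one_site_heat(wt_params, short))
        with pytest.raises(ValueError, match="6 injections"):
            fit_one_site(thermo)


class TestThermoDecompose:
    def test_molar_kd_gives_zero_free_energy(self):
        params = BindingParameters(n=1.0, k_d=1.0, dh=-5e3)
        dg, tds = thermo_decompose(params, 293.15)
        assert dg == pytest.approx(0.0)
        assert tds == pytest.approx(params.dh)

    def test_enthalpy_equal_to_free_energy_means_zero_entropy(self):
        k_d = 0.098e-6
        dg_expected = R_GAS * 293.15 * np.log(k_d)
        params = BindingParameters(n=1.0, k_d=k_d, dh=dg_expected)
        dg, tds = thermo_decompose(params, 293.15)
        assert tds == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_hand_value(self):
        # R * 293.15 * ln(9.8e-8) J/mol, evaluated independently
        dg, _ = thermo_decompose(BindingParameters(1.0, 0.098e-6, 0.0), 293.15)
        assert dg == pytest.approx(8.314462618 * 293.15 * np.log(9.8e-8), rel=1e-12)
        assert dg == pytest.approx(-39350.0, abs=50.0)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            thermo_decompose(BindingParameters(1.0, 1e-7, 0.0), 0.0)
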