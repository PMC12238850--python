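"""Self-contained validation studies on synthetic data.

Each study generates data with :mod:`serobind.synthetic_data`, runs the
matching fitter and reports recovery statistics.  They document what the
estimators can and cannot deliver under realistic noise and are reused by
the acceptance machinery.
"""

from __future__ import annotations

import numpy as np

from . import synthetic_data as sd
from .exchange_lineshape import (
    AcquisitionParams,
    ResiduePrior,
    fit_exchange,
    koff_confidence,
)
from .itc_binding import BindingParameters, InjectionProtocol, fit_one_site

__all__ = [
    "itc_zero_noise_recovery",
    "itc_noise_recovery",
    "lineshape_recovery_grid",
    "lineshape_ci_coverage",
]

_KD_BOX = (1e-8, 1e-5)  # generous 0.01-10 µM box for synthetic fits


def itc_zero_noise_recovery(
    truth: BindingParameters | None = None,
    protocol: InjectionProtocol | None = None,
) -> dict[str, float]:
    """Relative errors of (n, K_D, dH) recovered from a noiseless thermogram."""
    if truth is None:
        truth = BindingParameters(n=1.0, k_d=0.26e-6, dh=-8.0 * 4184.0)
    if protocol is None:
        protocol = InjectionProtocol.default()
    thermo = sd.generate_itc_thermogram(truth, protocol, 0.0, seed=0)
    fit = fit_one_site(thermo)
    est = fit.estimates
    return {
        "n": abs(est.n - truth.n) / truth.n,
        "k_d": abs(est.k_d - truth.k_d) / truth.k_d,
        "dh": abs(est.dh - truth.dh) / abs(truth.dh),
        "converged": float(fit.converged),
    }


def itc_noise_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    noise_sd: float = sd.REALISTIC_ITC_NOISE_J,
    truth: BindingParameters | None = None,
    protocol: InjectionProtocol | None = None,
) -> dict[str, float]:
    """Median relative K_D error across noisy thermogram replicates."""
    if truth is None:
        truth = BindingParameters(n=1.0, k_d=0.26e-6, dh=-8.0 * 4184.0)
    if protocol is None:
        protocol = InjectionProtocol.default()
    errs = []
    for i in range(n_replicates):
        thermo = sd.generate_itc_thermogram(truth, protocol, noise_sd, seed=seed + i)
        fit = fit_one_site(thermo)
        errs.append(abs(fit.estimates.k_d - truth.k_d) / truth.k_d)
    return {
        "median_kd_rel_err": float(np.median(errs)),
        "n_replicates": float(n_replicates),
    }


def _fit_synthetic_series(k_off, k_d, snr, model_seed, noise_seed, acq):
    model = sd.example_exchange_model(k_off=k_off, k_d=k_d, seed=model_seed, acq=acq)
    points = sd.default_titration_points()
    clean = sd.generate_titration_spectra(model, points, acq, 0.0, 0)
    noise = sd.noise_sd_for_snr(clean, snr) if snr else 0.0
    spectra = sd.generate_titration_spectra(model, points, acq, noise, noise_seed)
    priors = [ResiduePrior(r.name, r.h_free, r.n_free) for r in model.residues]
    return fit_exchange(list(zip(points, spectra)), priors, acq, kd_box=_KD_BOX)


def lineshape_recovery_grid(
    koffs: tuple[float, ...] = (20.0, 50.0, 200.0),
    kds: tuple[float, ...] = (0.1e-6, 0.3e-6, 2e-6),
    snr: float = 50.0,
    seed: int = 0,
    acq: AcquisitionParams | None = None,
) -> dict:
    """Relative k_off error of the joint line-shape fit across a (k_off, K_D)
    grid of 3-point titrations with 6 residues at the given spectral SNR."""
    if acq is None:
        acq = AcquisitionParams()
    cells = []
    for i, ko in enumerate(koffs):
        for j, kd in enumerate(kds):
            fit = _fit_synthetic_series(
                ko, kd, snr, model_seed=seed, noise_seed=seed + 17 * i + 31 * j + 1,
                acq=acq,
            )
            cells.append(
                {
                    "k_off_true": ko,
                    "k_d_true": kd,
                    "k_off_hat": fit.k_off,
                    "rel_err": abs(fit.k_off - ko) / ko,
                    "converged": fit.converged,
                }
            )
    return {
        "cells": cells,
        "median_rel_err": float(np.median([c["rel_err"] for c in cells])),
    }


def lineshape_ci_coverage(
    n_replicates: int = 20,
    k_off: float = 50.0,
    k_d: float = 0.3e-6,
    snr: float = 50.0,
    seed: int = 0,
    acq: AcquisitionParams | None = None,
) -> dict:
    """Fraction of replicates whose 95 % F-grid confidence interval covers
    the true k_off."""
    if acq is None:
        acq = AcquisitionParams()
    hits = 0
    intervals = []
    for i in range(n_replicates):
        fit = _fit_synthetic_series(
            k_off, k_d, snr, model_seed=seed, noise_seed=seed + 1000 + i, acq=acq
        )
        ci = koff_confidence(
            fit, grid=np.geomspace(fit.k_off / 1.6, fit.k_off * 1.6, 7)
        )
        hit = ci.low <= k_off <= ci.high
        hits += hit
        intervals.append({"k_off_hat": fit.k_off, "low": ci.low, "high": ci.high, "hit": bool(hit)})
    return {
        "coverage": hits / n_replicates,
        "n_replicates": n_replicates,
        "intervals": intervals,
    }
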