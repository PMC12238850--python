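import numpy as np
import pytest

from serobind.exchange_lineshape import AcquisitionParams
from serobind.itc_binding import BindingParameters, InjectionProtocol


@pytest.fixture(scope="session")
def protocol() -> InjectionProtocol:
    """29 x 10 µl of 300 µM peptide into 30 µM protein, 1.4 ml cell, 20 °C."""
    return InjectionProtocol.default()


@pytest.fixture(scope="session")
def wt_params() -> BindingParameters:
    """Wild-type-like one-site truth: K_D 0.26 µM, exothermic binding."""
    return BindingParameters(n=1.0, k_d=0.26e-6, dh=-8.0 * 4184.0, q_dil=0.0)


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionParams:
    """Tiny time grid for brute-force oracle comparisons."""
    return AcquisitionParams(npts_h=8, npts_n=8, zero_fill_factor=1)


def ode_oracle_signal(model, point, acq) -> np.ndarray:
    """Brute-force oracle for the two-state line-shape simulator: integrates
    the coupled free/bound magnetization ODEs numerically for every (t1, t2)
    grid point, including the zz-filter and t1 edge delays.  Independent of
    the eigendecomposition path used by the package."""
    from scipy.integrate import solve_ivp

    from serobind.exchange_lineshape import bound_fraction

    pb = bound_fraction(point.p_total, point.l_total * point.lig_scale, model.k_d)
    kfb = model.k_off * pb / (1.0 - pb)
    tn = np.arange(acq.npts_n) / acq.sw_n_hz
    th = np.arange(acq.npts_h) / acq.sw_h_hz
    total = np.zeros((len(tn), len(th)), complex)

    def omega(ppm, center, mhz):
        return 2.0 * np.pi * (ppm - center) * mhz

    def prop(mat, t, v):
        if t == 0:
            return v
        sol = solve_ivp(lambda _, y: mat @ y, (0.0, t), v, rtol=1e-12, atol=1e-14)
        return sol.y[:, -1]

    for res in model.residues:
        def gen(wf, wb, rf, rb):
            return np.array(
                [[1j * wf - rf - kfb, model.k_off], [kfb, 1j * wb - rb - model.k_off]]
            )

        ln = gen(
            omega(res.n_free, acq.center_n_ppm, acq.n_freq_mhz),
            omega(res.n_bound, acq.center_n_ppm, acq.n_freq_mhz),
            res.r2n_free, res.r2n_bound,
        )
        lh = gen(
            omega(res.h_free, acq.center_h_ppm, acq.h_freq_mhz),
            omega(res.h_bound, acq.center_h_ppm, acq.h_freq_mhz),
            res.r2h_free, res.r2h_bound,
        )
        kx = np.array([[-kfb, model.k_off], [kfb, -model.k_off]])
        m0 = res.amplitude * np.array([1.0 - pb, pb], complex)
        for i, t1 in enumerate(tn):
            v = prop(ln, t1 + 2 * acq.t1_edge_delay, m0)
            v = prop(kx, acq.zz_filter_delay, v)
            for j, t2 in enumerate(th):
                total[i, j] += prop(lh, t2, v).sum()
    return total


def brute_force_bound_complex(site_conc: float, lig_conc: float, k_d: float) -> float:
    """Bisection on the mass-balance equation for [PL]: independent oracle
    for the quadratic solutions used throughout the package."""
    if lig_conc == 0.0 or site_conc == 0.0:
        return 0.0

    def imbalance(pl: float) -> float:
        return (site_conc - pl) * (lig_conc - pl) - k_d * pl

    lo, hi = 0.0, min(site_conc, lig_conc)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if imbalance(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
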