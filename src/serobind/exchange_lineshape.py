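"""Two-state chemical-exchange 2D line-shape simulation and titration fitting.

A protein resonance exchanging between a free and a ligand-bound environment
(free <-> bound, populations p_f and p_b set by 1:1 binding mass balance)
evolves under the two-state Bloch-McConnell generator in each spectral
dimension d:

    L_d = i * Omega_d - R_d + K

where Omega_d holds the state angular frequencies, R_d the state transverse
relaxation rates, and K = [[-k_fb, k_off], [k_fb, -k_off]] with the
pseudo-first-order forward rate k_fb = k_off * p_b / p_f fixed by detailed
balance.  An HSQC-type experiment is modelled: exchange-only evolution
during the zz-filter delay, full indirect-dimension evolution during
t1 (plus short edge delays at both t1 edges), and direct-dimension
evolution during t2.  The detected signal

    s(t1, t2) = 1^T exp(L_H t2) D exp(L_N (t1 + 2 t_edge)) m0,   m0 ∝ (p_f, p_b)

is apodized with exponential line broadening, zero-filled and Fourier
transformed into a real 2D spectrum in ppm.

Because every propagator is a 2x2 complex matrix, the signal is a sum of
four complex exponentials per residue; both the full-grid simulator and the
fast region evaluator used by the fitter compute the same discrete Fourier
sums in closed form (finite geometric series), so fitting never pays for a
full-spectrum FFT.

The joint titration fit shares k_off, K_D, bound shifts and relaxation
rates across all spectra, with a per-spectrum amplitude and a single
ligand-concentration scale factor, and provides residual-resampling
bootstrap standard errors and F-statistic grid-search confidence limits
for k_off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

__all__ = [
    "GAMMA_N_OVER_H",
    "AcquisitionParams",
    "ResidueResonance",
    "ExchangeModel",
    "SamplePoint",
    "Spectrum2D",
    "ExchangeFit",
    "ConfidenceInterval",
    "ResiduePrior",
    "SpectralRegion",
    "bound_fraction",
    "simulate_spectrum",
    "fit_exchange",
    "bootstrap_koff",
    "koff_confidence",
]

GAMMA_N_OVER_H = 0.10136767  # |gamma(15N) / gamma(1H)|

_PB_CLIP = 1.0 - 1e-9


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


@dataclass(frozen=True)
class AcquisitionParams:
    """Spectral windows, sampling and processing of the simulated HSQC.

    Delays follow the modelled pulse sequence: ``zz_filter_delay`` (s) of
    exchange-only evolution and ``t1_edge_delay`` (s) of indirect-dimension
    evolution applied at both edges of t1.  ``lb_h``/``lb_n`` are the
    exponential line broadenings (Hz) applied before Fourier transform in
    the direct/indirect dimension; grids are zero-filled to the next power
    of two times ``zero_fill_factor``.
    """

    h_freq_mhz: float = 900.0
    center_h_ppm: float = 8.25
    sw_h_ppm: float = 3.0
    npts_h: int = 256
    center_n_ppm: float = 117.0
    sw_n_ppm: float = 26.0
    npts_n: int = 128
    zz_filter_delay: float = 1.2e-3
    t1_edge_delay: float = 0.6e-3
    lb_h: float = 10.0
    lb_n: float = 15.0
    zero_fill_factor: int = 2

    def __post_init__(self) -> None:
        if self.zz_filter_delay < 0 or self.t1_edge_delay < 0:
            raise ValueError("delays must be >= 0")
        if self.lb_h < 0 or self.lb_n < 0:
            raise ValueError("line broadening must be >= 0")
        if self.npts_h < 4 or self.npts_n < 4 or self.zero_fill_factor < 1:
            raise ValueError("grid sizes must be >= 4 points, zero_fill_factor >= 1")

    @property
    def n_freq_mhz(self) -> float:
        return self.h_freq_mhz * GAMMA_N_OVER_H

    @property
    def sw_h_hz(self) -> float:
        return self.sw_h_ppm * self.h_freq_mhz

    @property
    def sw_n_hz(self) -> float:
        return self.sw_n_ppm * self.n_freq_mhz

    @property
    def grid_h(self) -> int:
        return _next_pow2(self.npts_h) * self.zero_fill_factor

    @property
    def grid_n(self) -> int:
        return _next_pow2(self.npts_n) * self.zero_fill_factor

    def ppm_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """(direct 1H, indirect 15N) ppm grids, ascending."""
        fh = np.fft.fftshift(np.fft.fftfreq(self.grid_h, d=1.0 / self.sw_h_hz))
        fn = np.fft.fftshift(np.fft.fftfreq(self.grid_n, d=1.0 / self.sw_n_hz))
        return self.center_h_ppm + fh / self.h_freq_mhz, self.center_n_ppm + fn / self.n_freq_mhz


@dataclass(frozen=True)
class ResidueResonance:
    """Free/bound chemical shifts (ppm), per-state transverse relaxation
    rates (s^-1) per dimension and an arbitrary amplitude for one amide."""

    name: str
    h_free: float
    n_free: float
    h_bound: float
    n_bound: float
    r2h_free: float = 20.0
    r2h_bound: float = 20.0
    r2n_free: float = 15.0
    r2n_bound: float = 15.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        for nm in ("r2h_free", "r2h_bound", "r2n_free", "r2n_bound"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"ResidueResonance.{nm} must be > 0")


@dataclass(frozen=True)
class ExchangeModel:
    """Kinetic and spectral description of a set of exchanging resonances."""

    k_off: float
    k_d: float
    residues: tuple[ResidueResonance, ...]

    def __post_init__(self) -> None:
        if self.k_off <= 0:
            raise ValueError("ExchangeModel.k_off must be > 0")
        if self.k_d <= 0:
            raise ValueError("ExchangeModel.k_d must be > 0")
        object.__setattr__(self, "residues", tuple(self.residues))

    @property
    def k_on(self) -> float:
        """Association rate constant, M^-1 s^-1."""
        return self.k_off / self.k_d


@dataclass(frozen=True)
class SamplePoint:
    """Total concentrations (mol/L) of one titration sample; ``lig_scale``
    is a dimensionless correction for pipetting/concentration errors that
    multiplies the nominal ligand concentration."""

    p_total: float
    l_total: float
    lig_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.p_total < 0 or self.l_total < 0:
            raise ValueError("concentrations must be >= 0")
        if self.lig_scale <= 0:
            raise ValueError("lig_scale must be > 0")


@dataclass
class Spectrum2D:
    """Real 2D intensity map on strictly monotone ppm grids."""

    ppm_h: np.ndarray
    ppm_n: np.ndarray
    data: np.ndarray  # shape (len(ppm_n), len(ppm_h))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm_h = np.asarray(self.ppm_h, float)
        self.ppm_n = np.asarray(self.ppm_n, float)
        self.data = np.asarray(self.data, float)
        for ax in (self.ppm_h, self.ppm_n):
            d = np.diff(ax)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("ppm grids must be strictly monotone")
        if self.data.shape != (self.ppm_n.size, self.ppm_h.size):
            raise ValueError("data shape must be (len(ppm_n), len(ppm_h))")


def bound_fraction(p_total: float, l_total: float, k_d: float) -> float:
    """Bound fraction p_b = [PL]/P_total of the 1:1 equilibrium.

    [PL] is the smaller root of the binding quadratic; satisfies
    0 <= p_b <= min(1, L/P).
    """
    if k_d <= 0:
        raise ValueError("k_d must be > 0")
    if p_total <= 0:
        raise ValueError("p_total must be > 0")
    if l_total < 0:
        raise ValueError("l_total must be >= 0")
    b = p_total + l_total + k_d
    disc = b * b - 4.0 * p_total * l_total
    pl = 0.5 * (b - math.sqrt(max(disc, 0.0)))
    return min(max(pl / p_total, 0.0), 1.0)


# ---------------------------------------------------------------------------
# closed-form two-state propagator components


def _components(model: ExchangeModel, points: list[SamplePoint], acq: AcquisitionParams):
    """Eigenvalues and signal coefficients of every (spectrum, residue).

    Returns ``lam_n``, ``lam_h`` of shape (S, R, 2) (complex rad/s, no
    apodization) and coefficients ``coef`` of shape (S, R, 2, 2) such that
    the raw time-domain signal of residue r in spectrum s is

        s(t1, t2) = sum_{b,a} coef[s,r,b,a] exp(lam_n[s,r,a] t1) exp(lam_h[s,r,b] t2)
    """
    res = model.residues
    S, R = len(points), len(res)
    koff = model.k_off
    pb = np.array(
        [bound_fraction(pt.p_total, pt.l_total * pt.lig_scale, model.k_d) for pt in points]
    )
    pb = np.clip(pb, 0.0, _PB_CLIP)
    kfb = koff * pb / (1.0 - pb)  # (S,)

    def omega_h(ppm):
        return 2.0 * np.pi * (ppm - acq.center_h_ppm) * acq.h_freq_mhz

    def omega_n(ppm):
        return 2.0 * np.pi * (ppm - acq.center_n_ppm) * acq.n_freq_mhz

    hf = omega_h(np.array([r.h_free for r in res]))
    hb = omega_h(np.array([r.h_bound for r in res]))
    nf = omega_n(np.array([r.n_free for r in res]))
    nb = omega_n(np.array([r.n_bound for r in res]))
    r2hf = np.array([r.r2h_free for r in res])
    r2hb = np.array([r.r2h_bound for r in res])
    r2nf = np.array([r.r2n_free for r in res])
    r2nb = np.array([r.r2n_bound for r in res])
    amp = np.array([r.amplitude for r in res])

    def eig(a_free, a_bound):
        """Vectorized eigendecomposition of [[A, koff], [kfb, D]].

        a_free/a_bound: (R,) complex diagonal entries before the exchange
        contribution.  Returns lam (S,R,2), V (S,R,2,2), Vinv (S,R,2,2).
        """
        A = a_free[None, :] - kfb[:, None]
        Dd = a_bound[None, :] - koff
        tr = A + Dd
        disc = np.sqrt((A - Dd) ** 2 + 4.0 * koff * kfb[:, None].astype(complex))
        small = np.abs(disc) < 1e-12 * (np.abs(tr) + 1.0)
        disc = np.where(small, disc + 1e-9, disc)
        lam1 = 0.5 * (tr + disc)
        lam2 = 0.5 * (tr - disc)
        lam = np.stack([lam1, lam2], axis=-1)  # (S,R,2)
        # eigenvector for lam_i: (koff, lam_i - A)
        V = np.empty(lam.shape[:-1] + (2, 2), complex)
        V[..., 0, 0] = koff
        V[..., 0, 1] = koff
        V[..., 1, 0] = lam1 - A
        V[..., 1, 1] = lam2 - A
        det = koff * (lam2 - lam1)
        Vinv = np.empty_like(V)
        Vinv[..., 0, 0] = V[..., 1, 1] / det
        Vinv[..., 0, 1] = -V[..., 0, 1] / det
        Vinv[..., 1, 0] = -V[..., 1, 0] / det
        Vinv[..., 1, 1] = V[..., 0, 0] / det
        return lam, V, Vinv

    lam_n, Vn, Vn_inv = eig(1j * nf - r2nf, 1j * nb - r2nb)
    lam_h, Vh, Vh_inv = eig(1j * hf - r2hf, 1j * hb - r2hb)

    # initial magnetization prop. to populations
    m0 = np.empty((S, R, 2), complex)
    m0[..., 0] = (1.0 - pb)[:, None] * amp[None, :]
    m0[..., 1] = pb[:, None] * amp[None, :]

    # exchange-only propagator during the zz filter: exp(K t) closed form
    ktot = kfb + koff  # (S,)
    e = np.exp(-ktot * acq.zz_filter_delay)
    D = np.empty((S, 2, 2))
    D[:, 0, 0] = (koff + kfb * e) / ktot
    D[:, 0, 1] = koff * (1.0 - e) / ktot
    D[:, 1, 0] = kfb * (1.0 - e) / ktot
    D[:, 1, 1] = (kfb + koff * e) / ktot

    with np.errstate(under="ignore"):
        alpha = np.einsum("srab,srb->sra", Vn_inv, m0)
        alpha = alpha * np.exp(lam_n * (2.0 * acq.t1_edge_delay))
        # B = Vh_inv @ D @ Vn  -> (S,R,2,2)
        B = np.einsum("srab,sbc,srcd->srad", Vh_inv, D.astype(complex), Vn)
        g = Vh.sum(axis=-2)  # 1^T V_h  -> (S,R,2)
        coef = g[..., :, None] * B * alpha[..., None, :]
    return lam_n, lam_h, coef


def _time_signal(lam_n, lam_h, coef, acq: AcquisitionParams) -> np.ndarray:
    """Raw (unapodized) time-domain signal summed over residues for one
    spectrum: shape (npts_n, npts_h), complex."""
    tn = np.arange(acq.npts_n) / acq.sw_n_hz
    th = np.arange(acq.npts_h) / acq.sw_h_hz
    with np.errstate(under="ignore"):
        en = np.exp(lam_n[..., None] * tn)  # (R,2,npts_n)
        eh = np.exp(lam_h[..., None] * th)
        return np.einsum("rba,ran,rbh->nh", coef, en, eh)


def _window_check(model: ExchangeModel, acq: AcquisitionParams) -> None:
    ph, pn = acq.ppm_axes()
    lo_h, hi_h = ph.min(), ph.max()
    lo_n, hi_n = pn.min(), pn.max()
    for r in model.residues:
        for v, lo, hi, dim in (
            (r.h_free, lo_h, hi_h, "1H"), (r.h_bound, lo_h, hi_h, "1H"),
            (r.n_free, lo_n, hi_n, "15N"), (r.n_bound, lo_n, hi_n, "15N"),
        ):
            if not (lo < v < hi):
                raise ValueError(
                    f"resonance {r.name}: {dim} shift {v} ppm outside spectral window "
                    f"[{lo:.2f}, {hi:.2f}]"
                )


def simulate_spectrum(
    model: ExchangeModel, point: SamplePoint, acq: AcquisitionParams
) -> Spectrum2D:
    """Simulate one processed 2D spectrum at the given titration point.

    Processing mirrors standard practice: exponential apodization
    (``acq.lb_h``/``acq.lb_n``), halving of the first time-domain point in
    each dimension (flat-baseline convention), zero filling to a power of
    two and complex Fourier transform; the real part is returned.
    """
    _window_check(model, acq)
    lam_n, lam_h, coef = _components(model, [point], acq)
    sig = _time_signal(lam_n[0], lam_h[0], coef[0], acq)
    tn = np.arange(acq.npts_n) / acq.sw_n_hz
    th = np.arange(acq.npts_h) / acq.sw_h_hz
    win = np.outer(np.exp(-np.pi * acq.lb_n * tn), np.exp(-np.pi * acq.lb_h * th))
    sig = sig * win
    sig[0, :] *= 0.5
    sig[:, 0] *= 0.5
    padded = np.zeros((acq.grid_n, acq.grid_h), complex)
    padded[: acq.npts_n, : acq.npts_h] = sig
    spec = np.fft.fftshift(np.fft.fft2(padded))
    # first-order phase correction in F1 compensating the linear phase roll
    # accrued during the t1 edge delays, restoring absorptive peaks
    fn = np.fft.fftshift(np.fft.fftfreq(acq.grid_n, d=1.0 / acq.sw_n_hz))
    spec = spec * np.exp(-2j * np.pi * fn * 2.0 * acq.t1_edge_delay)[:, None]
    ppm_h, ppm_n = acq.ppm_axes()
    return Spectrum2D(
        ppm_h=ppm_h,
        ppm_n=ppm_n,
        data=spec.real,
        meta={
            "p_total": point.p_total,
            "l_total": point.l_total,
            "lig_scale": point.lig_scale,
            "k_off": model.k_off,
            "k_d": model.k_d,
        },
    )


def _geom_dft(lam, dt, n_acq, q, q_pow, lb):
    """Closed-form DFT of the apodized, first-point-halved, zero-filled
    one-sided exponential at precomputed output-bin phase factors.

    lam : (..., 2) complex rates; ``q`` holds exp(-2i pi k / M) at the
    fftshifted bins and ``q_pow`` its n_acq-th power (both with a leading
    broadcast axis for the component dimension).  Returns
    broadcast(lam[..., :, None], q).
    """
    z = np.exp((lam - np.pi * lb) * dt)  # (...,2)
    x = z[..., :, None] * q
    x_pow = (z ** n_acq)[..., :, None] * q_pow
    with np.errstate(invalid="ignore", under="ignore"):
        g = (1.0 - x_pow) / (1.0 - x) - 0.5
    bad = np.abs(1.0 - x) < 1e-12
    if np.any(bad):
        g = np.where(bad, n_acq - 0.5, g)
    return g


def _bin_phases(idx, m_grid, n_acq):
    """exp(-2i pi k / M) and its n_acq-th power at fftshifted bins ``idx``,
    shaped (R, 1, nbins) for broadcasting against (S, R, 2, nbins)."""
    k = idx - m_grid // 2
    q = np.exp(-2j * np.pi * k / m_grid)[:, None, :]
    q_pow = np.exp(-2j * np.pi * k * n_acq / m_grid)[:, None, :]
    return q, q_pow


def _region_model(lam_n, lam_h, coef, acq: AcquisitionParams, idx_n, idx_h, amp_spec,
                  cache=None):
    """Model spectrum values inside per-residue rectangular regions.

    idx_n : (R, nn) fftshifted indirect-dimension bin indices per residue
    idx_h : (R, nh) direct-dimension bin indices per residue
    amp_spec : (S,) per-spectrum amplitude factors
    Returns (S, R, nn, nh) real values.
    """
    dt_n, dt_h = 1.0 / acq.sw_n_hz, 1.0 / acq.sw_h_hz
    if cache is None:
        qn, qn_pow = _bin_phases(idx_n, acq.grid_n, acq.npts_n)
        qh, qh_pow = _bin_phases(idx_h, acq.grid_h, acq.npts_h)
        f1 = (idx_n - acq.grid_n // 2) * acq.sw_n_hz / acq.grid_n  # (R, nn)
        phase_n = np.exp(-2j * np.pi * f1 * 2.0 * acq.t1_edge_delay)[:, None, :]
    else:
        qn, qn_pow, qh, qh_pow, phase_n = cache
    gn = _geom_dft(lam_n, dt_n, acq.npts_n, qn, qn_pow, acq.lb_n)
    gn = gn * phase_n  # F1 phase correction for the t1 edge delays
    gh = _geom_dft(lam_h, dt_h, acq.npts_h, qh, qh_pow, acq.lb_h)
    # batched matmuls: sum over N components, then over H components
    cn = np.matmul(coef, gn)  # (S,R,2_h,nn)
    vals = np.matmul(cn.swapaxes(-2, -1), gh).real  # (S,R,nn,nh)
    return vals * amp_spec[:, None, None, None]


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class ResiduePrior:
    """Assignment-derived knowledge about one fitted resonance: the free
    (apo) peak position and an optional initial guess for the bound one."""

    name: str
    h_free: float
    n_free: float
    h_bound_guess: float | None = None
    n_bound_guess: float | None = None


@dataclass
class SpectralRegion:
    """Rectangular fit region (fftshifted bin windows) for one residue."""

    name: str
    idx_n: np.ndarray
    idx_h: np.ndarray

    def overlaps(self, other: "SpectralRegion") -> bool:
        return (
            self.idx_n.min() <= other.idx_n.max()
            and other.idx_n.min() <= self.idx_n.max()
            and self.idx_h.min() <= other.idx_h.max()
            and other.idx_h.min() <= self.idx_h.max()
        )


@dataclass
class ExchangeFit:
    """Joint titration fit result.

    ``estimates`` holds the fitted kinetics and per-residue spectral
    parameters as an :class:`ExchangeModel`; ``lig_scale`` and ``amp_spec``
    are the fitted concentration correction and per-spectrum amplitudes.
    ``bootstrap_se`` and ``ci95`` are filled by :func:`bootstrap_koff` and
    :func:`koff_confidence`.
    """

    estimates: ExchangeModel
    lig_scale: float
    amp_spec: np.ndarray
    ssr: float
    converged: bool
    n_obs: int
    n_params: int
    kd_at_bound: bool
    bootstrap_se: float | None = None
    ci95: "ConfidenceInterval | None" = None
    problem: "_FitProblem" = field(default=None, repr=False)

    @property
    def k_off(self) -> float:
        return self.estimates.k_off

    @property
    def k_d(self) -> float:
        return self.estimates.k_d

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_params


@dataclass
class ConfidenceInterval:
    low: float
    high: float
    open_low: bool
    open_high: bool
    grid: np.ndarray
    ssr_profile: np.ndarray
    threshold: float


def _parabolic_peak(ax: np.ndarray, vals: np.ndarray, i: int) -> float:
    """Sub-grid peak position by 3-point parabola around index i."""
    if i <= 0 or i >= len(vals) - 1:
        return float(ax[i])
    y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(ax[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(ax[i] + delta * (ax[1] - ax[0]))


def _peak_in_window(spec: Spectrum2D, h_ppm, n_ppm, h_half, n_half):
    """(h, n) position of the maximum inside a ppm window, sub-grid refined."""
    mh = (spec.ppm_h >= h_ppm - h_half) & (spec.ppm_h <= h_ppm + h_half)
    mn = (spec.ppm_n >= n_ppm - n_half) & (spec.ppm_n <= n_ppm + n_half)
    sub = spec.data[np.ix_(mn, mh)]
    i_n, i_h = np.unravel_index(np.argmax(sub), sub.shape)
    gi_n = np.flatnonzero(mn)[i_n]
    gi_h = np.flatnonzero(mh)[i_h]
    h = _parabolic_peak(spec.ppm_h, spec.data[gi_n, :], gi_h)
    n = _parabolic_peak(spec.ppm_n, spec.data[:, gi_h], gi_n)
    return h, n, float(sub[i_n, i_h])


class _FitProblem:
    """Packing/unpacking of the joint fit and cached data regions."""

    def __init__(self, series, priors, acq, kd_box, koff_bounds, lig_scale_bounds,
                 region_pad_linewidths, r2_init):
        self.points = [pt for pt, _ in series]
        self.spectra = [sp for _, sp in series]
        self.priors = list(priors)
        self.acq = acq
        self.kd_box = kd_box
        self.koff_bounds = koff_bounds
        self.lig_scale_bounds = lig_scale_bounds
        self.S = len(self.points)
        self.R = len(self.priors)
        if self.S < 2:
            raise ValueError("fit_exchange requires >= 2 titration points")

        # --- free/bound peak positions from the end-point spectra
        apo_idx = int(np.argmin([pt.l_total for pt in self.points]))
        sat_idx = int(np.argmax([pt.l_total for pt in self.points]))
        apo, sat = self.spectra[apo_idx], self.spectra[sat_idx]
        lw_h = (r2_init / np.pi + acq.lb_h)  # Hz
        lw_n = (r2_init / np.pi + acq.lb_n)
        search_h = 0.6  # ppm search half-window for the bound peak
        search_n = 4.0
        self.h_free = np.empty(self.R)
        self.n_free = np.empty(self.R)
        h_b0 = np.empty(self.R)
        n_b0 = np.empty(self.R)
        self.apo_height = np.empty(self.R)
        for i, pr in enumerate(self.priors):
            hw_h = 3 * lw_h / acq.h_freq_mhz
            hw_n = 3 * lw_n / acq.n_freq_mhz
            h, n, amp = _peak_in_window(apo, pr.h_free, pr.n_free, hw_h, hw_n)
            self.h_free[i], self.n_free[i], self.apo_height[i] = h, n, amp
            if pr.h_bound_guess is not None and pr.n_bound_guess is not None:
                h_b0[i], n_b0[i] = pr.h_bound_guess, pr.n_bound_guess
            else:
                h_b0[i], n_b0[i], _ = _peak_in_window(
                    sat, pr.h_free, pr.n_free, search_h, search_n
                )
        self.h_bound0, self.n_bound0 = h_b0, n_b0

        # --- regions: cover free and bound positions, padded
        ppm_h, ppm_n = acq.ppm_axes()
        pad_h = region_pad_linewidths * lw_h / acq.h_freq_mhz
        pad_n = region_pad_linewidths * lw_n / acq.n_freq_mhz
        nh = nn = 0
        bounds_list = []
        for i in range(self.R):
            lo_h = min(self.h_free[i], h_b0[i]) - pad_h
            hi_h = max(self.h_free[i], h_b0[i]) + pad_h
            lo_n = min(self.n_free[i], n_b0[i]) - pad_n
            hi_n = max(self.n_free[i], n_b0[i]) + pad_n
            ih = np.flatnonzero((ppm_h >= lo_h) & (ppm_h <= hi_h))
            inn = np.flatnonzero((ppm_n >= lo_n) & (ppm_n <= hi_n))
            bounds_list.append((ih, inn))
            nh = max(nh, ih.size)
            nn = max(nn, inn.size)
        # standardize region shapes (centered extension, clipped to grid)
        self.idx_h = np.empty((self.R, nh), int)
        self.idx_n = np.empty((self.R, nn), int)
        for i, (ih, inn) in enumerate(bounds_list):
            self.idx_h[i] = _expand_window(ih, nh, acq.grid_h)
            self.idx_n[i] = _expand_window(inn, nn, acq.grid_n)
        self.regions = [
            SpectralRegion(self.priors[i].name, self.idx_n[i], self.idx_h[i])
            for i in range(self.R)
        ]
        for i in range(self.R):
            for j in range(i + 1, self.R):
                if self.regions[i].overlaps(self.regions[j]):
                    raise ValueError(
                        f"fit regions of {self.regions[i].name} and "
                        f"{self.regions[j].name} overlap; space the resonances or "
                        "reduce region padding"
                    )
        self.data = np.stack(
            [sp.data[np.ix_(self.idx_n[i], self.idx_h[i])] for sp in self.spectra for i in range(self.R)]
        ).reshape(self.S, self.R, nn, nh)
        self.n_obs = self.data.size
        self.r2_init = r2_init
        qn, qn_pow = _bin_phases(self.idx_n, acq.grid_n, acq.npts_n)
        qh, qh_pow = _bin_phases(self.idx_h, acq.grid_h, acq.npts_h)
        f1 = (self.idx_n - acq.grid_n // 2) * acq.sw_n_hz / acq.grid_n
        phase_n = np.exp(-2j * np.pi * f1 * 2.0 * acq.t1_edge_delay)[:, None, :]
        self._phase_cache = (qn, qn_pow, qh, qh_pow, phase_n)

    # --- parameter vector: [log10 koff, log10 kd, lig_scale, amp_spec[1:],
    #                        (h_f, n_f, h_b, n_b, r2h_f, r2h_b, r2n_f, r2n_b, amp_r) * R]
    N_PER_RES = 9

    def pack(self, log_koff, log_kd, lig_scale, amp_spec, hf, nf, hb, nb,
             r2h_f, r2h_b, r2n_f, r2n_b, amp_r):
        per_res = np.stack([hf, nf, hb, nb, r2h_f, r2h_b, r2n_f, r2n_b, amp_r], axis=1).ravel()
        return np.concatenate([[log_koff, log_kd, lig_scale], amp_spec[1:], per_res])

    def unpack(self, x, fixed_log_koff=None):
        if fixed_log_koff is None:
            log_koff, log_kd, lig = x[0], x[1], x[2]
            rest = x[3:]
        else:
            log_koff = fixed_log_koff
            log_kd, lig = x[0], x[1]
            rest = x[2:]
        amp_spec = np.concatenate([[1.0], rest[: self.S - 1]])
        per = rest[self.S - 1:].reshape(self.R, self.N_PER_RES)
        return log_koff, log_kd, lig, amp_spec, per

    def model_values(self, x, fixed_log_koff=None):
        log_koff, log_kd, lig, amp_spec, per = self.unpack(x, fixed_log_koff)
        residues = tuple(
            ResidueResonance(
                name=self.priors[i].name,
                h_free=per[i, 0],
                n_free=per[i, 1],
                h_bound=per[i, 2],
                n_bound=per[i, 3],
                r2h_free=per[i, 4],
                r2h_bound=per[i, 5],
                r2n_free=per[i, 6],
                r2n_bound=per[i, 7],
                amplitude=per[i, 8],
            )
            for i in range(self.R)
        )
        model = ExchangeModel(k_off=10.0 ** log_koff, k_d=10.0 ** log_kd, residues=residues)
        points = [replace(pt, lig_scale=pt.lig_scale * lig) for pt in self.points]
        lam_n, lam_h, coef = _components(model, points, self.acq)
        vals = _region_model(lam_n, lam_h, coef, self.acq, self.idx_n, self.idx_h,
                             amp_spec, cache=self._phase_cache)
        return vals, model, lig, amp_spec

    def residuals(self, x, data=None, fixed_log_koff=None):
        vals = self.model_values(x, fixed_log_koff)[0]
        target = self.data if data is None else data
        return (vals - target).ravel()

    def bounds(self, fixed_koff=False):
        lb, ub = [], []
        if not fixed_koff:
            lb.append(np.log10(self.koff_bounds[0]))
            ub.append(np.log10(self.koff_bounds[1]))
        lb += [np.log10(self.kd_box[0]), self.lig_scale_bounds[0]]
        ub += [np.log10(self.kd_box[1]), self.lig_scale_bounds[1]]
        lb += [1e-3] * (self.S - 1)
        ub += [1e3] * (self.S - 1)
        ppm_h, ppm_n = self.acq.ppm_axes()
        for _ in range(self.R):
            lb += [ppm_h.min(), ppm_n.min()] * 2 + [1.0] * 4 + [0.0]
            ub += [ppm_h.max(), ppm_n.max()] * 2 + [300.0] * 4 + [np.inf]
        return np.array(lb), np.array(ub)


def _expand_window(idx: np.ndarray, size: int, grid: int) -> np.ndarray:
    """Extend a contiguous index window symmetrically to ``size`` bins,
    sliding it to stay inside [0, grid)."""
    lo, hi = int(idx.min()), int(idx.max())
    need = size - (hi - lo + 1)
    lo -= need // 2
    hi += need - need // 2
    if lo < 0:
        hi -= lo
        lo = 0
    if hi >= grid:
        lo -= hi - grid + 1
        hi = grid - 1
    return np.arange(lo, hi + 1)


def fit_exchange(
    series: list[tuple[SamplePoint, Spectrum2D]],
    priors: list[ResiduePrior],
    acq: AcquisitionParams,
    kd_box: tuple[float, float] = (1e-9, 1e-4),
    koff_bounds: tuple[float, float] = (1.0, 1e4),
    lig_scale_bounds: tuple[float, float] = (0.7, 1.3),
    region_pad_linewidths: float = 5.0,
    r2_init: float = 20.0,
    koff_scan: np.ndarray | None = None,
    max_nfev: int | None = None,
) -> ExchangeFit:
    """Joint least-squares line-shape fit over all residues and spectra.

    Shared parameters: k_off, K_D (within the ``kd_box`` restraint), bound
    shifts and one R2 per residue per dimension (applied to both exchange
    states); per-spectrum amplitude (first spectrum fixed at 1) and a
    global ligand-concentration scale.  Free-state shifts are fixed at the
    sub-grid-refined apo peak positions.  Initial k_off comes from a coarse
    1-D scan with amplitudes re-scaled analytically at each candidate.
    """
    prob = _FitProblem(series, priors, acq, kd_box, koff_bounds,
                       lig_scale_bounds, region_pad_linewidths, r2_init)
    S, R = prob.S, prob.R

    # --- initial values
    log_kd0 = 0.5 * (np.log10(kd_box[0]) + np.log10(kd_box[1]))
    hb0, nb0 = prob.h_bound0, prob.n_bound0
    r2_0 = np.full(R, r2_init)
    amp0 = np.ones(R)
    amp_spec0 = np.ones(S)
    if koff_scan is None:
        koff_scan = np.geomspace(max(koff_bounds[0], 2.0), min(koff_bounds[1], 3e3), 12)

    hf0, nf0 = prob.h_free, prob.n_free
    best = None
    for ko in koff_scan:
        x = prob.pack(np.log10(ko), log_kd0, 1.0, amp_spec0, hf0, nf0, hb0, nb0,
                      r2_0, r2_0, r2_0, r2_0, amp0)
        vals = prob.model_values(x)[0]
        denom = float(np.sum(vals * vals))
        scale = float(np.sum(vals * prob.data)) / denom if denom > 0 else 1.0
        scale = max(scale, 1e-12)
        ssr = float(np.sum((vals * scale - prob.data) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, ko, scale)
    _, ko0, scale0 = best

    x0 = prob.pack(np.log10(ko0), log_kd0, 1.0, amp_spec0, hf0, nf0, hb0, nb0,
                   r2_0, r2_0, r2_0, r2_0, amp0 * scale0)
    lb, ub = prob.bounds()
    x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)
    res = least_squares(
        prob.residuals, x0, bounds=(lb, ub), method="trf",
        x_scale="jac", max_nfev=max_nfev,
    )
    # polish: the F-grid confidence search compares SSRs at ~1e-5 relative
    # precision, so the reference optimum must be tightly converged
    res = least_squares(
        prob.residuals, np.clip(res.x, lb + 1e-12, ub - 1e-12),
        bounds=(lb, ub), method="trf", x_scale="jac",
        ftol=1e-14, xtol=1e-12, gtol=1e-14, max_nfev=200,
    )
    log_koff, log_kd, lig, amp_spec, per = prob.unpack(res.x)
    _, model, lig, amp_spec = prob.model_values(res.x)
    kd_at_bound = (
        min(abs(log_kd - np.log10(kd_box[0])), abs(np.log10(kd_box[1]) - log_kd)) < 1e-3
    )
    fit = ExchangeFit(
        estimates=model,
        lig_scale=float(lig),
        amp_spec=amp_spec,
        ssr=float(2.0 * res.cost),
        converged=bool(res.success),
        n_obs=prob.n_obs,
        n_params=res.x.size,
        kd_at_bound=bool(kd_at_bound),
        problem=prob,
    )
    prob.best_x = res.x
    return fit


def bootstrap_koff(
    fit: ExchangeFit,
    n_replicas: int = 100,
    seed: int = 0,
    max_nfev: int = 60,
) -> float:
    """Residual-resampling bootstrap standard error of k_off.

    Residuals of the converged fit, pooled over all fit regions, are
    resampled with replacement onto the fitted model values; each replica
    is refit warm-started from the point estimate.  The SE is the sample
    standard deviation of the replica estimates.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    prob = fit.problem
    x_hat = prob.best_x
    model_vals = prob.model_values(x_hat)[0]
    resid = prob.data - model_vals
    pool = resid.ravel()
    rng = np.random.default_rng(seed)
    lb, ub = prob.bounds()
    koffs = []
    failures = 0
    for _ in range(n_replicas):
        fake = model_vals + rng.choice(pool, size=model_vals.shape, replace=True)
        try:
            r = least_squares(
                prob.residuals, x_hat, bounds=(lb, ub), method="trf",
                x_scale="jac", max_nfev=max_nfev, kwargs={"data": fake},
            )
            if not np.all(np.isfinite(r.x)):
                raise RuntimeError
            koffs.append(10.0 ** r.x[0])
        except Exception:
            failures += 1
    if failures > 0.2 * n_replicas:
        raise RuntimeError(
            f"bootstrap failed: {failures}/{n_replicas} replicas did not converge"
        )
    se = float(np.std(koffs, ddof=1))
    fit.bootstrap_se = se
    return se


def koff_confidence(
    fit: ExchangeFit,
    alpha: float = 0.05,
    grid: np.ndarray | None = None,
    max_nfev: int = 200,
) -> ConfidenceInterval:
    """F-statistic grid-search confidence limits for k_off.

    For each grid value, k_off is fixed and every other parameter refit;
    the interval is { k_off : SSR(k_off) <= SSR_min (1 + F(1, N-p; 1-alpha)
    / (N-p)) }, with endpoints interpolated linearly in (log k_off, SSR)
    between grid points.  An interval still open at a grid edge is flagged.
    """
    prob = fit.problem
    x_hat = prob.best_x
    k_hat = fit.k_off
    if grid is None:
        grid = np.geomspace(k_hat / 2.5, k_hat * 2.5, 11)
    grid = np.sort(np.asarray(grid, float))
    if not (grid[0] <= k_hat <= grid[-1]):
        raise ValueError("confidence grid must bracket the k_off estimate")
    lb, ub = prob.bounds(fixed_koff=True)
    x_center = np.clip(x_hat[1:], lb + 1e-12, ub - 1e-12)
    ssr_prof = np.empty_like(grid)
    i_center = int(np.argmin(np.abs(np.log(grid) - np.log(k_hat))))
    # walk outward from the estimate, warm-starting from the neighbour
    for direction in (range(i_center, len(grid)), range(i_center - 1, -1, -1)):
        x_start = x_center
        for i in direction:
            r = least_squares(
                prob.residuals, x_start, bounds=(lb, ub), method="trf",
                x_scale="jac", ftol=1e-14, xtol=1e-12, gtol=1e-14,
                max_nfev=max_nfev,
                kwargs={"fixed_log_koff": np.log10(grid[i])},
            )
            ssr_prof[i] = 2.0 * r.cost
            x_start = np.clip(r.x, lb + 1e-12, ub - 1e-12)
    dof = fit.dof
    ssr_min = min(fit.ssr, float(ssr_prof.min()))
    fcrit = float(f_dist.ppf(1.0 - alpha, 1, dof))
    threshold = ssr_min * (1.0 + fcrit / dof)

    logg = np.log(grid)
    # interpolate in sqrt(SSR - SSR_min), which is ~linear in log k_off for a
    # locally quadratic profile, so coarse grids do not bias the endpoints
    root = np.sqrt(np.maximum(ssr_prof - ssr_min, 0.0))
    root_thr = np.sqrt(threshold - ssr_min)

    def cross(side: int) -> tuple[float, bool]:
        """Walk outward from the estimate; side=-1 lower, +1 upper."""
        order = np.argsort(logg) if side > 0 else np.argsort(-logg)
        idx = [i for i in order if (grid[i] >= k_hat if side > 0 else grid[i] <= k_hat)]
        prev_i = None
        for i in idx:
            if ssr_prof[i] > threshold:
                if prev_i is None:
                    return float(grid[i]), False
                f = (root_thr - root[prev_i]) / (root[i] - root[prev_i])
                return float(np.exp(logg[prev_i] + f * (logg[i] - logg[prev_i]))), False
            prev_i = i
        return float(grid[idx[-1]] if idx else k_hat), True

    low, open_low = cross(-1)
    high, open_high = cross(+1)
    low = min(low, k_hat)
    high = max(high, k_hat)
    ci = ConfidenceInterval(
        low=low, high=high, open_low=open_low, open_high=open_high,
        grid=grid, ssr_profile=ssr_prof, threshold=threshold,
    )
    fit.ci95 = ci
    return ci
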