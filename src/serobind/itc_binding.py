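"""One-set-of-sites isothermal titration calorimetry (ITC) analysis.

Implements the Wiseman isotherm for a single class of ``n`` identical,
independent 1:1 binding sites: the forward model predicting the heat
released per injection of ligand into a protein-filled cell, nonlinear
least-squares estimation of (n, K_D, ΔH) plus a constant dilution-heat
offset, and the thermodynamic decomposition ΔG = RT ln K_D,
TΔS = ΔH − ΔG.

Units are SI throughout (litres, mol/L, joules, kelvin); the I/O layer
in :mod:`serobind.workbench` converts from the µcal / µM conventions of
calorimeter software at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R_GAS",
    "CAL_TO_J",
    "InjectionProtocol",
    "BindingParameters",
    "Thermogram",
    "BindingFit",
    "one_site_heat",
    "fit_one_site",
    "thermo_decompose",
]

R_GAS = 8.314462618  # J mol^-1 K^-1
CAL_TO_J = 4.184


@dataclass(frozen=True)
class InjectionProtocol:
    """Geometry and concentrations of a titration.

    cell_volume : active cell volume V0 in litres
    cell_conc : protein concentration in the cell before any injection (mol/L)
    syringe_conc : ligand concentration in the syringe (mol/L)
    injection_volumes : per-injection volumes in litres
    temperature : kelvin
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple[float, ...]
    temperature: float = 293.15

    def __post_init__(self) -> None:
        for name in ("cell_volume", "cell_conc", "syringe_conc", "temperature"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"InjectionProtocol.{name} must be > 0")
        vols = tuple(float(v) for v in self.injection_volumes)
        if len(vols) == 0 or any(v <= 0 or not np.isfinite(v) for v in vols):
            raise ValueError("InjectionProtocol.injection_volumes must all be > 0")
        object.__setattr__(self, "injection_volumes", vols)

    @classmethod
    def default(
        cls,
        cell_conc: float = 30e-6,
        syringe_conc: float = 300e-6,
        n_injections: int = 29,
        injection_volume: float = 10e-6,
        cell_volume: float = 1.4e-3,
        temperature: float = 293.15,
    ) -> "InjectionProtocol":
        """Standard protocol: 29 x 10 µl of 300 µM ligand into 30 µM protein
        at 20 °C in a 1.4 ml cell."""
        return cls(
            cell_volume=cell_volume,
            cell_conc=cell_conc,
            syringe_conc=syringe_conc,
            injection_volumes=(injection_volume,) * n_injections,
            temperature=temperature,
        )


@dataclass(frozen=True)
class BindingParameters:
    """Thermodynamic description of one 1:1 binding site.

    n : stoichiometry (sites per protein), dimensionless
    k_d : dissociation constant, mol/L
    dh : binding enthalpy, J/mol of ligand bound
    q_dil : constant per-injection dilution heat baseline, J
    """

    n: float
    k_d: float
    dh: float
    q_dil: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k_d) and self.k_d > 0):
            raise ValueError("BindingParameters.k_d must be > 0")
        if not (np.isfinite(self.n) and self.n > 0):
            raise ValueError("BindingParameters.n must be > 0")


@dataclass(frozen=True)
class Thermogram:
    """Per-injection heats (J) together with the protocol that produced them."""

    protocol: InjectionProtocol
    heats: tuple[float, ...]

    def __post_init__(self) -> None:
        heats = tuple(float(h) for h in self.heats)
        if len(heats) != len(self.protocol.injection_volumes):
            raise ValueError(
                "Thermogram.heats length must match number of injections"
            )
        if not np.all(np.isfinite(heats)):
            raise ValueError("Thermogram.heats must be finite")
        object.__setattr__(self, "heats", heats)


@dataclass(frozen=True)
class BindingFit:
    """Result of a one-site fit: point estimates, standard errors from the
    local curvature of the objective, residual sum of squares and an honest
    convergence flag."""

    estimates: BindingParameters
    ses: dict[str, float]
    ssr: float
    converged: bool
    n_obs: int
    n_params: int

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_params


def _cell_concentrations(protocol: InjectionProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Dilution-corrected total protein (M) and ligand (X) concentrations in
    the cell after each injection, cumulative-displacement convention: each
    injection of dV scales existing cell contents by (1 - dV/V0) and adds
    ligand at syringe_conc * dV/V0."""
    v0 = protocol.cell_volume
    m = np.empty(len(protocol.injection_volumes))
    x = np.empty_like(m)
    m_cur = protocol.cell_conc
    x_cur = 0.0
    for i, dv in enumerate(protocol.injection_volumes):
        f = 1.0 - dv / v0
        m_cur *= f
        x_cur = x_cur * f + protocol.syringe_conc * dv / v0
        m[i] = m_cur
        x[i] = x_cur
    return m, x


def one_site_heat(params: BindingParameters, protocol: InjectionProtocol) -> np.ndarray:
    """Per-injection heats (J) under the one-set-of-sites isotherm.

    Cumulative heat after injection i with cell protein M_i, cell ligand X_i,
    r = X/(nM), k = K_D/(nM):

        Q_i = (n M_i dH V0 / 2) [1 + r + k - sqrt((1 + r + k)^2 - 4 r)]

    The per-injection heat corrects for the heat carried out of the active
    volume by the displaced liquid:

        dQ_i = Q_i - Q_{i-1} + (dV_i/V0)(Q_i + Q_{i-1})/2 + q_dil
    """
    v0 = protocol.cell_volume
    m, x = _cell_concentrations(protocol)
    nm = params.n * m
    r = x / nm
    k = params.k_d / nm
    b = 1.0 + r + k
    disc = b * b - 4.0 * r
    if np.any(disc < 0):  # impossible for k > 0; guard against rounding
        disc = np.maximum(disc, 0.0)
    q = 0.5 * nm * params.dh * v0 * (b - np.sqrt(disc))
    q_prev = np.concatenate(([0.0], q[:-1]))
    dv = np.asarray(protocol.injection_volumes)
    return q - q_prev + (dv / v0) * (q + q_prev) / 2.0 + params.q_dil


def _heuristic_init(thermogram: Thermogram) -> BindingParameters:
    """Starting values when the caller supplies none: n = 1, dH from the
    first-injection heat assuming complete binding, K_D a modest fraction of
    the cell concentration, q_dil from the saturated tail."""
    prot = thermogram.protocol
    heats = np.asarray(thermogram.heats)
    q0 = float(np.median(heats[-3:])) if len(heats) >= 6 else 0.0
    mol_inj = prot.syringe_conc * prot.injection_volumes[0]
    dh0 = (heats[0] - q0) / mol_inj
    if dh0 == 0.0:
        dh0 = 1.0
    return BindingParameters(n=1.0, k_d=prot.cell_conc / 20.0, dh=float(dh0), q_dil=q0)


def fit_one_site(
    thermogram: Thermogram,
    init: BindingParameters | None = None,
    fix_n: bool = False,
    skip_first: int = 0,
) -> BindingFit:
    """Nonlinear least-squares fit of the one-set-of-sites model.

    Parameters are (n, log10 K_D, dH, q_dil); ``fix_n`` pins the
    stoichiometry at its initial value (vendor software supports both modes
    and the choice used is recorded in the returned fit). ``skip_first``
    drops the first k injections from the objective, a common practice when
    the first injection is compromised by diffusion from the syringe tip.
    """
    if len(thermogram.heats) < 6:
        raise ValueError("fit_one_site requires at least 6 injections")
    if skip_first >= len(thermogram.heats) - 4:
        raise ValueError("skip_first leaves too few injections to fit")
    prot = thermogram.protocol
    heats = np.asarray(thermogram.heats)
    mask = np.arange(len(heats)) >= skip_first
    if init is None:
        init = _heuristic_init(thermogram)

    scale = max(abs(init.dh), 1e3)

    def unpack(x: np.ndarray) -> BindingParameters:
        if fix_n:
            logkd, dh, qdil = x
            n = init.n
        else:
            n, logkd, dh, qdil = x
        return BindingParameters(
            n=float(n), k_d=float(10.0 ** logkd),
            dh=float(dh * scale), q_dil=float(qdil * scale * 1e-9),
        )

    def resid(x: np.ndarray) -> np.ndarray:
        model = one_site_heat(unpack(x), prot)
        return model[mask] - heats[mask]

    x0 = [np.log10(init.k_d), init.dh / scale, init.q_dil / (scale * 1e-9)]
    lb = [-12.0, -1e4, -1e7]
    ub = [-2.0, 1e4, 1e7]
    if not fix_n:
        x0 = [init.n] + x0
        lb = [0.05] + lb
        ub = [20.0] + ub

    res = least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    est = unpack(res.x)
    ssr = float(2.0 * res.cost)
    n_obs = int(mask.sum())
    n_params = len(res.x)
    dof = max(n_obs - n_params, 1)

    # SEs from the Gauss-Newton curvature at the optimum.
    ses: dict[str, float] = {}
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.pinv(jtj) * (ssr / dof)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
        names = (["n"] if not fix_n else []) + ["log_kd", "dh", "q_dil"]
        raw = dict(zip(names, sd))
        ses = {
            "n": float(raw.get("n", 0.0)),
            "k_d": float(est.k_d * np.log(10.0) * raw["log_kd"]),
            "dh": float(raw["dh"] * scale),
            "q_dil": float(raw["q_dil"] * scale * 1e-9),
        }
    except np.linalg.LinAlgError:  # pragma: no cover
        ses = {k: np.nan for k in ("n", "k_d", "dh", "q_dil")}

    converged = bool(res.success and np.all(np.isfinite(res.x)))
    return BindingFit(
        estimates=est,
        ses=ses,
        ssr=ssr,
        converged=converged,
        n_obs=n_obs,
        n_params=n_params,
    )


def thermo_decompose(
    fit: BindingFit | BindingParameters, temperature: float
) -> tuple[float, float]:
    """Free energy and entropic term of the fitted equilibrium.

    Returns ``(dG, TdS)`` in J/mol, with dG = RT ln K_D (K_D in mol/L, so
    dG < 0 for sub-molar affinity) and TdS = dH - dG.
    """
    params = fit.estimates if isinstance(fit, BindingFit) else fit
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    dg = R_GAS * temperature * np.log(params.k_d)
    return float(dg), float(params.dh - dg)
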