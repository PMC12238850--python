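"""Synthetic data generators with the statistical structure of the real
experiments: ITC thermograms, two-state titration spectra, amide shift
tables and NOESY peak lists.

Every generator is a pure function of (truth, seed): the same inputs give
byte-identical output, and noiseless output composed with the matching
fitter recovers the truth.  Unless noted, noise is additive i.i.d.
Gaussian on the observable; NOESY intensities carry multiplicative
fractional noise instead, matching how cross-peak volumes scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .exchange_lineshape import (
    AcquisitionParams,
    ExchangeModel,
    ResidueResonance,
    SamplePoint,
    Spectrum2D,
    simulate_spectrum,
)
from .itc_binding import BindingParameters, InjectionProtocol, Thermogram, one_site_heat
from .noe_restraints import NoePeak

__all__ = [
    "SyntheticSpec",
    "generate",
    "generate_itc_thermogram",
    "generate_titration_spectra",
    "generate_shift_table",
    "generate_noesy_peaks",
    "default_titration_points",
    "example_exchange_model",
    "example_acquisition",
    "noise_sd_for_snr",
    "REALISTIC_ITC_NOISE_J",
]

# Baseline scatter of integrated per-injection heats for a sensitive
# titration calorimeter, ~0.2 µcal.
REALISTIC_ITC_NOISE_J = 8.4e-7


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of one synthetic data set.

    kind : one of 'itc', 'titration_spectra', 'shift_table', 'noesy'
    truth : keyword arguments for the matching generator
    noise_sd : additive Gaussian noise SD in the observable's units
    seed : RNG seed; fixed seed means byte-identical output
    """

    kind: str
    truth: dict[str, Any]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in {"itc", "titration_spectra", "shift_table", "noesy"}:
            raise ValueError(f"unknown synthetic kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate(spec: SyntheticSpec):
    """Dispatch a :class:`SyntheticSpec` to the matching generator."""
    if spec.kind == "itc":
        return generate_itc_thermogram(noise_sd=spec.noise_sd, seed=spec.seed, **spec.truth)
    if spec.kind == "titration_spectra":
        return generate_titration_spectra(noise_sd=spec.noise_sd, seed=spec.seed, **spec.truth)
    if spec.kind == "shift_table":
        return generate_shift_table(seed=spec.seed, **spec.truth)
    return generate_noesy_peaks(seed=spec.seed, **spec.truth)


def generate_itc_thermogram(
    params: BindingParameters,
    protocol: InjectionProtocol,
    noise_sd: float,
    seed: int,
) -> Thermogram:
    """Noiseless one-site heats plus i.i.d. Gaussian noise (J)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    heats = one_site_heat(params, protocol)
    rng = np.random.default_rng(seed)
    noisy = heats + rng.normal(0.0, noise_sd, size=heats.shape) if noise_sd > 0 else heats
    return Thermogram(protocol=protocol, heats=tuple(float(h) for h in noisy))


def default_titration_points(
    p_total: float = 1.9e-4, equivalents: tuple[float, ...] = (0.0, 0.5, 1.5)
) -> list[SamplePoint]:
    """The titration design used for off-rate fitting: labelled protein at
    0.19 mM observed with 0 %, 50 % and 150 % peptide."""
    return [SamplePoint(p_total=p_total, l_total=p_total * e) for e in equivalents]


def example_acquisition() -> AcquisitionParams:
    """Acquisition/processing defaults used throughout the examples."""
    return AcquisitionParams()


def example_exchange_model(
    k_off: float = 50.0,
    k_d: float = 2e-7,
    n_residues: int = 6,
    seed: int = 0,
    acq: AcquisitionParams | None = None,
) -> ExchangeModel:
    """A realistic set of exchanging amide resonances.

    Free shifts are laid out on a staggered grid inside the spectral
    window so per-residue fit regions never overlap; binding shifts each
    resonance by 0.15-0.28 ppm in 1H (alternating sign) and 1.5-2.5 ppm in
    15N (outward from the window centre), within the ranges seen for a
    reader-domain/peptide interface.  R2 rates are drawn uniformly from
    15-25 s^-1 per state and dimension.
    """
    if acq is None:
        acq = example_acquisition()
    rng = np.random.default_rng(seed)
    h_lo = acq.center_h_ppm - 0.36 * acq.sw_h_ppm
    h_hi = acq.center_h_ppm + 0.36 * acq.sw_h_ppm
    n_lo = acq.center_n_ppm - 0.36 * acq.sw_n_ppm
    n_hi = acq.center_n_ppm + 0.36 * acq.sw_n_ppm
    h_free = np.linspace(h_lo, h_hi, n_residues) + rng.uniform(-0.01, 0.01, n_residues)
    # stride the 15N positions so residues adjacent in 1H sit far apart in
    # 15N, and shift bound peaks outward from the 15N centre, so the
    # per-residue fit regions stay disjoint for every seed
    order = np.concatenate([np.arange(0, n_residues, 2), np.arange(1, n_residues, 2)])
    n_slots = np.linspace(n_lo, n_hi, n_residues)
    n_free = n_slots[order] + rng.uniform(-0.3, 0.3, n_residues)
    n_mid = 0.5 * (n_lo + n_hi)
    residues = []
    for i in range(n_residues):
        sign = 1.0 if i % 2 == 0 else -1.0
        dh = sign * rng.uniform(0.15, 0.28)
        dn = (1.0 if n_free[i] >= n_mid else -1.0) * rng.uniform(1.5, 2.5)
        residues.append(
            ResidueResonance(
                name=f"res{i + 1}",
                h_free=float(h_free[i]),
                n_free=float(n_free[i]),
                h_bound=float(h_free[i] + dh),
                n_bound=float(n_free[i] + dn),
                r2h_free=float(rng.uniform(15, 25)),
                r2h_bound=float(rng.uniform(15, 25)),
                r2n_free=float(rng.uniform(15, 25)),
                r2n_bound=float(rng.uniform(15, 25)),
                amplitude=1.0,
            )
        )
    return ExchangeModel(k_off=k_off, k_d=k_d, residues=tuple(residues))


def noise_sd_for_snr(spectra: list[Spectrum2D], snr: float) -> float:
    """Noise SD that puts the tallest peak of the series at the given
    signal-to-noise ratio."""
    peak = max(float(np.max(np.abs(s.data))) for s in spectra)
    return peak / snr


def generate_titration_spectra(
    model: ExchangeModel,
    points: list[SamplePoint],
    acq: AcquisitionParams,
    noise_sd: float,
    seed: int,
) -> list[Spectrum2D]:
    """One simulated 2D spectrum per titration point plus Gaussian noise on
    the intensity grid."""
    if not points:
        raise ValueError("points must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for pt in points:
        spec = simulate_spectrum(model, pt, acq)
        if noise_sd > 0:
            spec.data = spec.data + rng.normal(0.0, noise_sd, size=spec.data.shape)
        spec.meta["noise_sd"] = noise_sd
        out.append(spec)
    return out


def generate_shift_table(
    n_residues: int,
    background_scale: float,
    spiked: set | frozenset,
    spike_size: float,
    seed: int,
    n_weight: float = 6.5,
):
    """Reference and perturbed amide shift tables for CSP analysis.

    Unspiked residues receive a composite CSP of exactly
    ``background_scale`` in a random direction of the (δH, δN) plane;
    spiked residues receive a composite CSP of ``spike_size`` (also in a
    random direction), so the trimmed-null detector's behaviour on the
    output is deterministic.  Returns ``(reference, perturbed)`` pandas
    DataFrames with columns residue_id, h_ppm, n_ppm.
    """
    import pandas as pd

    if n_residues < 4:
        raise ValueError("n_residues must be >= 4 (threshold statistic undefined below)")
    if background_scale < 0 or spike_size < 0:
        raise ValueError("scales must be >= 0")
    spiked = set(spiked)
    ids = list(range(1, n_residues + 1))
    unknown = spiked - set(ids)
    if unknown:
        raise ValueError(f"spiked residues not in table: {sorted(unknown)}")
    if spiked and spike_size <= background_scale:
        raise ValueError("spike_size must exceed background_scale")
    rng = np.random.default_rng(seed)
    h = rng.uniform(6.5, 10.0, n_residues)
    n = rng.uniform(105.0, 130.0, n_residues)
    ref = pd.DataFrame({"residue_id": ids, "h_ppm": h, "n_ppm": n})
    theta = rng.uniform(0.0, 2.0 * np.pi, n_residues)
    mag = np.array([spike_size if i in spiked else background_scale for i in ids])
    dh = mag * np.cos(theta)
    dn = mag * n_weight * np.sin(theta)
    pert = pd.DataFrame({"residue_id": ids, "h_ppm": h + dh, "n_ppm": n + dn})
    return ref, pert


def generate_noesy_peaks(
    distances: list[tuple[tuple[str, str], float]],
    calib_const: float,
    noise_frac: float,
    reciprocal: bool,
    seed: int,
    noise_floor: float | None = None,
) -> list[NoePeak]:
    """NOESY peak list with I = C r^-6 (1 + eps), eps ~ N(0, noise_frac).

    With ``reciprocal`` each pair is emitted in both transfer directions
    with independent noise.  ``noise_floor`` sets the denominator of the
    reported s/n; the default places the weakest resolvable distance
    (7.1 Å) at s/n 10.
    """
    if noise_frac >= 1.0:
        raise ValueError("noise_frac must be < 1")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    if any(r <= 0 for _, r in distances):
        raise ValueError("all distances must be > 0")
    if calib_const <= 0:
        raise ValueError("calib_const must be > 0")
    if noise_floor is None:
        noise_floor = calib_const * 7.1 ** -6 / 10.0
    rng = np.random.default_rng(seed)
    peaks: list[NoePeak] = []
    for (a, b), r in distances:
        ideal = calib_const * r ** -6
        directions = [(a, b), (b, a)] if reciprocal else [(a, b)]
        for pa, pb in directions:
            eps = rng.normal(0.0, noise_frac) if noise_frac > 0 else 0.0
            inten = max(ideal * (1.0 + eps), 0.0)
            peaks.append(
                NoePeak(
                    proton_a=pa,
                    proton_b=pb,
                    intensity=float(inten),
                    snr=float(inten / noise_floor),
                    source_spectrum="synthetic",
                )
            )
    return peaks
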