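"""I/O, configuration and the end-to-end pipeline.

File formats are deliberately plain: two-column text for per-injection
ITC heats (µcal at the boundary, J internally), TSV for shift tables,
peak lists and ratio tables, YAML for run configuration, and an HDF5
container for gridded 2D spectra.  Every reader validates the loaded
object's invariants and reports malformed lines by number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import affinity_stats, csp_analysis, noe_restraints, synthetic_data
from .exchange_lineshape import Spectrum2D
from .itc_binding import (
    CAL_TO_J,
    BindingParameters,
    InjectionProtocol,
    Thermogram,
    fit_one_site,
    thermo_decompose,
)
from .noe_restraints import NoePeak

__all__ = [
    "load_protocol",
    "read_itc_table",
    "write_itc_table",
    "read_shift_table",
    "write_shift_table",
    "read_peak_list",
    "write_peak_list",
    "save_spectrum",
    "load_spectrum",
    "read_ratio_input",
    "RunConfig",
    "run_pipeline",
]

UCAL_TO_J = CAL_TO_J * 1e-6


def load_protocol(source) -> InjectionProtocol:
    """Injection protocol from a YAML file path or an already-parsed dict.

    Keys (µM / µl / ml / °C at the file boundary): cell_volume_ml,
    cell_conc_uM, syringe_conc_uM, n_injections, injection_volume_ul,
    temperature_C.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    try:
        vols = cfg.get("injection_volumes_ul")
        if vols is None:
            vols = [cfg["injection_volume_ul"]] * int(cfg["n_injections"])
        return InjectionProtocol(
            cell_volume=float(cfg.get("cell_volume_ml", 1.4)) * 1e-3,
            cell_conc=float(cfg["cell_conc_uM"]) * 1e-6,
            syringe_conc=float(cfg["syringe_conc_uM"]) * 1e-6,
            injection_volumes=tuple(float(v) * 1e-6 for v in vols),
            temperature=float(cfg.get("temperature_C", 20.0)) + 273.15,
        )
    except KeyError as exc:
        raise ValueError(f"protocol config missing key {exc.args[0]!r}") from None


def read_itc_table(path, protocol: InjectionProtocol) -> Thermogram:
    """Two-column text (injection index, heat in µcal); '#' comments."""
    heats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'index heat_ucal', got {line!r}")
            try:
                heats.append(float(parts[1]) * UCAL_TO_J)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric heat {parts[1]!r}") from None
    return Thermogram(protocol=protocol, heats=tuple(heats))


def write_itc_table(path, thermogram: Thermogram) -> None:
    with open(path, "w") as fh:
        fh.write("# injection  heat_ucal\n")
        for i, h in enumerate(thermogram.heats, 1):
            fh.write(f"{i}  {h / UCAL_TO_J:.6f}\n")


_SHIFT_COLUMNS = ["residue_id", "aa", "h_ppm", "n_ppm", "intensity", "overlap"]


def read_shift_table(path) -> pd.DataFrame:
    """Shift table TSV with columns residue_id, aa, h_ppm, n_ppm and
    optional intensity / overlap."""
    df = pd.read_csv(path, sep="\t")
    for col in ("residue_id", "h_ppm", "n_ppm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["residue_id"].duplicated().any():
        dupes = df.loc[df["residue_id"].duplicated(), "residue_id"].tolist()
        raise ValueError(f"{path}: duplicate residue ids {dupes}")
    if not np.all(np.isfinite(df[["h_ppm", "n_ppm"]].to_numpy(float))):
        raise ValueError(f"{path}: non-finite chemical shifts")
    if "overlap" in df.columns:
        df["overlap"] = df["overlap"].astype(bool)
    return df


def write_shift_table(path, table: pd.DataFrame) -> None:
    cols = [c for c in _SHIFT_COLUMNS if c in table.columns]
    table.to_csv(path, sep="\t", index=False, columns=cols)


def read_peak_list(path) -> list[NoePeak]:
    """NOESY peak list.

    Two dialects, auto-detected per line:
      * TSV with header: proton_a, proton_b, intensity, snr and optional
        source_spectrum, diastereotopic_partner;
      * assignment-style text: ``A901.HA-Q5.HSD1  intensity  snr``.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    peaks: list[NoePeak] = []
    if text and text[0].lower().startswith("proton_a"):
        header = text[0].rstrip("\n").split("\t")
        for lineno, line in enumerate(text[1:], 2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < len([h for h in header if h in ("proton_a", "proton_b", "intensity", "snr")]):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields")
            row = dict(zip(header, parts))
            try:
                peaks.append(
                    NoePeak(
                        proton_a=row["proton_a"],
                        proton_b=row["proton_b"],
                        intensity=float(row["intensity"]),
                        snr=float(row["snr"]),
                        source_spectrum=row.get("source_spectrum", ""),
                        diastereotopic_partner=row.get("diastereotopic_partner") or None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
        return peaks
    for lineno, line in enumerate(text, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: expected 'A-B intensity snr', got {line!r}"
            )
        assignment = parts[0]
        if "-" not in assignment:
            raise ValueError(f"{path}:{lineno}: malformed assignment {assignment!r}")
        a, b = assignment.split("-", 1)
        try:
            inten, snr = float(parts[1]), float(parts[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric intensity or s/n") from None
        peaks.append(NoePeak(proton_a=a, proton_b=b, intensity=inten, snr=snr))
    return peaks


def write_peak_list(path, peaks: list[NoePeak]) -> None:
    with open(path, "w") as fh:
        fh.write("proton_a\tproton_b\tintensity\tsnr\tsource_spectrum\tdiastereotopic_partner\n")
        for p in peaks:
            fh.write(
                f"{p.proton_a}\t{p.proton_b}\t{p.intensity:.6g}\t{p.snr:.6g}\t"
                f"{p.source_spectrum}\t{p.diastereotopic_partner or ''}\n"
            )


def save_spectrum(path, spectrum: Spectrum2D) -> None:
    """Gridded 2D spectrum to HDF5 (ppm axes + real intensity + metadata)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("ppm_h", data=spectrum.ppm_h)
        fh.create_dataset("ppm_n", data=spectrum.ppm_n)
        fh.create_dataset("data", data=spectrum.data)
        for k, v in spectrum.meta.items():
            fh.attrs[k] = v


def load_spectrum(path) -> Spectrum2D:
    with h5py.File(path, "r") as fh:
        return Spectrum2D(
            ppm_h=fh["ppm_h"][...],
            ppm_n=fh["ppm_n"][...],
            data=fh["data"][...],
            meta=dict(fh.attrs),
        )


def read_ratio_input(path) -> list[tuple[str, float, float, float, float]]:
    """TSV with columns label, kd_a, se_a, kd_b, se_b (µM)."""
    df = pd.read_csv(path, sep="\t")
    need = ["label", "kd_a", "se_a", "kd_b", "se_b"]
    for col in need:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [tuple(row) for row in df[need].itertuples(index=False)]


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Validated run configuration: stage selection plus per-stage blocks.

    Loaded from YAML; CLI flags may override individual values.  Stage
    blocks are passed to the corresponding stage runner unchanged.
    """

    stages: list[str]
    outdir: Path
    seed: int = 0
    itc: dict = field(default_factory=dict)
    ratios: dict = field(default_factory=dict)
    csp: dict = field(default_factory=dict)
    noe: dict = field(default_factory=dict)

    KNOWN = ("itc", "ratios", "csp", "noe")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        stages = cfg.get("stages", [])
        bad = [s for s in stages if s not in cls.KNOWN]
        if bad:
            raise ValueError(f"unknown stages {bad}; known: {list(cls.KNOWN)}")
        base = Path(path).parent
        rc = cls(
            stages=stages,
            outdir=Path(cfg.get("outdir", base / "serobind_out")),
            seed=int(cfg.get("seed", 0)),
        )
        for s in cls.KNOWN:
            setattr(rc, s, cfg.get(s, {}) or {})
        for s in stages:
            block = getattr(rc, s)
            for key in ("data", "table", "peaks"):
                if key in block and not Path(base / block[key]).exists():
                    raise ValueError(f"stage {s}: input path {block[key]!r} does not exist")
                if key in block:
                    block[key] = str(base / block[key])
        return rc


def _stage_itc(block: dict, seed: int) -> dict:
    if "data" in block:
        protocol = load_protocol(block.get("protocol", {}))
        thermo = read_itc_table(block["data"], protocol)
    else:
        sim = block.get("simulate", {})
        protocol = load_protocol(sim.get("protocol", {"cell_conc_uM": 30, "syringe_conc_uM": 300, "n_injections": 29, "injection_volume_ul": 10}))
        params = BindingParameters(
            n=float(sim.get("n", 1.0)),
            k_d=float(sim.get("kd_uM", 0.26)) * 1e-6,
            dh=float(sim.get("dh_kcal_mol", -8.0)) * 4184.0,
            q_dil=float(sim.get("q_dil_ucal", 0.0)) * UCAL_TO_J,
        )
        thermo = synthetic_data.generate_itc_thermogram(
            params, protocol, noise_sd=float(sim.get("noise_ucal", 0.2)) * UCAL_TO_J, seed=seed
        )
    fit = fit_one_site(thermo, skip_first=int(block.get("skip_first", 0)),
                       fix_n=bool(block.get("fix_n", False)))
    dg, tds = thermo_decompose(fit, protocol.temperature)
    return {
        "n": fit.estimates.n,
        "kd_uM": fit.estimates.k_d * 1e6,
        "dh_kcal_mol": fit.estimates.dh / 4184.0,
        "q_dil_ucal": fit.estimates.q_dil / UCAL_TO_J,
        "se_kd_uM": fit.ses["k_d"] * 1e6,
        "se_n": fit.ses["n"],
        "dG_kcal_mol": dg / 4184.0,
        "TdS_kcal_mol": tds / 4184.0,
        "ssr": fit.ssr,
        "converged": fit.converged,
    }


def _stage_ratios(block: dict, outdir: Path) -> dict:
    rows = read_ratio_input(block["table"])
    table = affinity_stats.build_affinity_table(rows)
    out = outdir / "ratio_table.tsv"
    table.to_csv(out, sep="\t", index=False)
    return {
        "rows": len(table),
        "significant": int(table["significant"].sum()),
        "output": str(out),
    }


def _stage_csp(block: dict, outdir: Path) -> dict:
    ref_tables = [read_shift_table(p) for p in block["reference_tables"]]
    mod_tables = [read_shift_table(p) for p in block["modified_tables"]]
    ref_avg = csp_analysis.state_average_shifts(ref_tables)
    mod_avg = csp_analysis.state_average_shifts(mod_tables)
    csp = csp_analysis.compute_csp(ref_avg, mod_avg)
    flagged = csp_analysis.detect_ser_specific(csp)
    out = outdir / "csp_flags.tsv"
    flagged.to_csv(out, sep="\t", index=False)
    return {
        "residues": len(flagged),
        "flagged": int(flagged["flagged"].sum()),
        "threshold_ppm": float(flagged["threshold_used"].iloc[0]),
        "output": str(out),
    }


def _stage_noe(block: dict, outdir: Path) -> dict:
    peaks = read_peak_list(block["peaks"])
    kept = noe_restraints.filter_peaks(peaks, snr_min=float(block.get("snr_min", 8.0)))
    merged = noe_restraints.merge_reciprocal(kept)
    restraints = noe_restraints.calibrate_distances(merged)
    out = outdir / "restraints.tbl"
    out.write_text(noe_restraints.write_restraints(restraints, dialect=block.get("dialect", "xplor")))
    counts = noe_restraints.restraint_counts(restraints)
    return {
        "peaks_in": len(peaks),
        "peaks_kept": len(kept),
        "restraints": counts["total"],
        "intermolecular": counts["intermolecular"],
        "ambiguous": counts["ambiguous"],
        "capped": sum(1 for r in restraints if r.capped),
        "output": str(out),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order; deterministic given the seed.

    Returns the run report (also written to ``report.json`` in the output
    directory): effective config, per-stage results and warnings.  A stage
    failure aborts with the stage name; outputs of completed stages stay
    on disk.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {
            "stages": config.stages,
            "seed": config.seed,
            "outdir": str(config.outdir),
        },
        "stages": {},
        "warnings": [],
    }
    runners = {
        "itc": lambda: _stage_itc(config.itc, config.seed),
        "ratios": lambda: _stage_ratios(config.ratios, config.outdir),
        "csp": lambda: _stage_csp(config.csp, config.outdir),
        "noe": lambda: _stage_noe(config.noe, config.outdir),
    }
    for stage in config.stages:
        try:
            report["stages"][stage] = runners[stage]()
        except Exception as exc:
            report["warnings"].append(f"stage {stage} failed: {exc}")
            (config.outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (config.outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
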