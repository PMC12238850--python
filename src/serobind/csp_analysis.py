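"""Chemical-shift-perturbation (CSP) statistics for amide resonances.

Shift tables are pandas DataFrames with columns ``residue_id`` (unique),
``h_ppm``, ``n_ppm`` and optionally ``intensity`` and ``overlap``.  The
composite CSP down-weights the 15N dimension by a factor of 6.5:

    CSP = sqrt(dH^2 + (dN / 6.5)^2)    [ppm, 1H-equivalent]

Modification-specific residues are detected against a trimmed null: the
threshold is mean + 1 SD of the 50 % smallest CSPs, so that residues whose
perturbation exceeds what the quiet half of the protein shows are flagged.
Peak intensities are made comparable across samples by anchoring a
reference residue (a flexible C-terminal one, unaffected by binding) to 1.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "N_WEIGHT",
    "weighted_csp",
    "compute_csp",
    "state_average_shifts",
    "detect_ser_specific",
    "normalize_intensities",
    "intensity_ratio",
]

N_WEIGHT = 6.5

_SHIFT_COLS = ("residue_id", "h_ppm", "n_ppm")


def _check_shift_table(table: pd.DataFrame, name: str = "table") -> pd.DataFrame:
    for col in _SHIFT_COLS:
        if col not in table.columns:
            raise ValueError(f"{name} lacks required column {col!r}")
    if table["residue_id"].duplicated().any():
        dupes = table.loc[table["residue_id"].duplicated(), "residue_id"].tolist()
        raise ValueError(f"{name} has duplicate residue ids: {dupes}")
    return table


def weighted_csp(dh, dn, n_weight: float = N_WEIGHT):
    """Composite 1H-equivalent CSP from 1H and 15N shift differences (ppm)."""
    dh = np.asarray(dh, float)
    dn = np.asarray(dn, float)
    out = np.sqrt(dh ** 2 + (dn / n_weight) ** 2)
    return float(out) if out.ndim == 0 else out


def compute_csp(
    reference: pd.DataFrame, perturbed: pd.DataFrame, n_weight: float = N_WEIGHT
) -> pd.DataFrame:
    """Per-residue shift differences and composite CSP between two states.

    Residues present in only one table are dropped.
    """
    _check_shift_table(reference, "reference")
    _check_shift_table(perturbed, "perturbed")
    merged = reference.merge(
        perturbed, on="residue_id", suffixes=("_ref", "_new")
    )
    dh = merged["h_ppm_new"] - merged["h_ppm_ref"]
    dn = merged["n_ppm_new"] - merged["n_ppm_ref"]
    return pd.DataFrame(
        {
            "residue_id": merged["residue_id"],
            "dh_ppm": dh,
            "dn_ppm": dn,
            "csp": weighted_csp(dh.to_numpy(), dn.to_numpy(), n_weight),
        }
    )


def state_average_shifts(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of 1H/15N shifts across states, per residue.

    Residues missing from some states are averaged over the states where
    they are present; the ``n_states`` column records the coverage.
    Residues absent everywhere do not appear.
    """
    if len(tables) == 0:
        raise ValueError("state_average_shifts requires at least one table")
    frames = []
    for i, t in enumerate(tables):
        _check_shift_table(t, f"tables[{i}]")
        frames.append(t[list(_SHIFT_COLS)])
    stacked = pd.concat(frames, ignore_index=True)
    grouped = stacked.groupby("residue_id", sort=True)
    out = grouped.agg(
        h_ppm=("h_ppm", "mean"), n_ppm=("n_ppm", "mean"), n_states=("h_ppm", "size")
    ).reset_index()
    return out


def detect_ser_specific(
    csps: pd.DataFrame,
    trim_frac: float = 0.5,
    n_sd: float = 1.0,
    sd_ddof: int = 1,
) -> pd.DataFrame:
    """Flag residues whose CSP exceeds the trimmed-null threshold.

    The CSPs are sorted ascending (ties broken by residue id, so the cut is
    deterministic) and the smallest ``floor(trim_frac * n)`` form the null
    sample; the threshold is its mean + ``n_sd`` sample standard deviations
    (``sd_ddof=1``).  Residues with CSP *strictly* above the threshold are
    flagged.  Residues with missing CSPs are excluded from thresholding but
    retained in the output with ``flagged = False``.
    """
    if "csp" not in csps.columns or "residue_id" not in csps.columns:
        raise ValueError("csps must have 'residue_id' and 'csp' columns")
    work = csps.copy()
    finite = work["csp"].notna() & np.isfinite(work["csp"])
    vals = work.loc[finite].sort_values(["csp", "residue_id"], kind="stable")
    n = len(vals)
    if n < 4:
        raise ValueError("detect_ser_specific requires >= 4 finite CSP values")
    k = max(int(math.floor(trim_frac * n)), 2)
    null = vals["csp"].to_numpy()[:k]
    threshold = float(null.mean() + n_sd * null.std(ddof=sd_ddof))
    work["threshold_used"] = threshold
    # strict inequality; the relative guard keeps values that equal the
    # threshold up to floating-point rounding from being flagged
    guard = 1e-9 * abs(threshold)
    work["flagged"] = finite & (work["csp"] > threshold + guard)
    return work


def normalize_intensities(table: pd.DataFrame, reference_residue) -> pd.DataFrame:
    """Divide every peak intensity by the reference residue's intensity.

    The reference maps to exactly 1; idempotent.
    """
    _check_shift_table(table)
    if "intensity" not in table.columns:
        raise ValueError("table lacks an 'intensity' column")
    ref_rows = table.loc[table["residue_id"] == reference_residue, "intensity"]
    if ref_rows.empty:
        raise ValueError(f"reference residue {reference_residue!r} not in table")
    ref = float(ref_rows.iloc[0])
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(
            f"reference residue {reference_residue!r} has non-positive intensity"
        )
    out = table.copy()
    out["intensity"] = out["intensity"] / ref
    return out


def intensity_ratio(
    ser_table: pd.DataFrame, nonser_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-residue ratio of normalized intensities, modified / unmodified.

    Residues flagged as overlapped in either table, missing from either
    table, or with a non-positive denominator are excluded; the second
    returned frame records each exclusion and its reason.
    """
    _check_shift_table(ser_table, "ser_table")
    _check_shift_table(nonser_table, "nonser_table")
    merged = ser_table.merge(
        nonser_table, on="residue_id", how="outer", suffixes=("_ser", "_ref"),
        indicator=True,
    )
    ratios = []
    excluded = []
    for _, row in merged.iterrows():
        rid = row["residue_id"]
        if row["_merge"] != "both":
            excluded.append({"residue_id": rid, "reason": "missing in one table"})
            continue
        if bool(row.get("overlap_ser", False)) or bool(row.get("overlap_ref", False)):
            excluded.append({"residue_id": rid, "reason": "overlapped"})
            continue
        denom = row["intensity_ref"]
        if not np.isfinite(denom) or denom <= 0:
            excluded.append({"residue_id": rid, "reason": "non-positive reference intensity"})
            continue
        ratios.append({"residue_id": rid, "ratio": row["intensity_ser"] / denom})
    ratio_df = pd.DataFrame(ratios, columns=["residue_id", "ratio"])
    excl_df = pd.DataFrame(excluded, columns=["residue_id", "reason"])
    return ratio_df, excl_df
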