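"""Affinity-ratio statistics for comparing binding between modification states.

Given two fitted dissociation constants with standard errors, computes the
ratio K_D(A)/K_D(B), its first-order (delta-method) propagated standard
error assuming uncorrelated errors, the Z-score against the null ratio = 1,
and a two-sided significance call at 99 % confidence (z_crit = 2.5758).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = ["Z_CRIT_99", "Verdict", "RatioResult", "kd_ratio", "build_affinity_table"]

Z_CRIT_99 = 2.5758  # two-sided 99 % critical value of the standard normal


class Verdict(str, Enum):
    INCREASED = "Increased"
    DECREASED = "Decreased"
    NO_CHANGE = "NoChange"


@dataclass(frozen=True)
class RatioResult:
    """K_D ratio with propagated SE, Z-score and 99 %-confidence call.

    ``degenerate`` flags the zero-SE corner cases where the Z-score is
    infinite (se = 0, ratio != 1) or undefined (se = 0, ratio = 1).
    """

    ratio: float
    se: float
    z: float
    significant: bool
    verdict: Verdict
    degenerate: bool = False


def kd_ratio(
    kd_a: float,
    se_a: float,
    kd_b: float,
    se_b: float,
    z_crit: float = Z_CRIT_99,
    log_scale: bool = False,
) -> RatioResult:
    """Ratio kd_a/kd_b with delta-method error propagation.

    se(ratio) = ratio * sqrt((se_a/kd_a)^2 + (se_b/kd_b)^2) and
    z = (ratio - 1)/se; significance requires |z| strictly greater than
    ``z_crit``.  With ``log_scale`` the test is run on ln(ratio) with
    se(ln ratio) = sqrt((se_a/kd_a)^2 + (se_b/kd_b)^2) instead; the
    reported ratio and se are unchanged.
    """
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be > 0")
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be >= 0")
    ratio = kd_a / kd_b
    rel = math.sqrt((se_a / kd_a) ** 2 + (se_b / kd_b) ** 2)
    se = ratio * rel
    degenerate = False
    if se == 0.0:
        if ratio == 1.0:
            z = float("nan")
            significant = False
        else:
            z = math.copysign(float("inf"), ratio - 1.0)
            significant = True
        degenerate = True
    elif log_scale:
        z = math.log(ratio) / rel
        significant = abs(z) > z_crit
    else:
        z = (ratio - 1.0) / se
        significant = abs(z) > z_crit
    if not significant:
        verdict = Verdict.NO_CHANGE
    else:
        verdict = Verdict.INCREASED if ratio > 1.0 else Verdict.DECREASED
    return RatioResult(
        ratio=ratio, se=se, z=z, significant=significant, verdict=verdict, degenerate=degenerate
    )


def build_affinity_table(
    rows: list[tuple[str, float, float, float, float]],
    z_crit: float = Z_CRIT_99,
    log_scale: bool = False,
) -> pd.DataFrame:
    """One :func:`kd_ratio` per (label, kd_a, se_a, kd_b, se_b) row.

    Returns a DataFrame with columns label, kd_a, se_a, kd_b, se_b, ratio,
    se, z, significant, verdict.  Labels must be unique.
    """
    labels = [r[0] for r in rows]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    records = []
    for label, kd_a, se_a, kd_b, se_b in rows:
        r = kd_ratio(kd_a, se_a, kd_b, se_b, z_crit=z_crit, log_scale=log_scale)
        records.append(
            {
                "label": label,
                "kd_a": kd_a,
                "se_a": se_a,
                "kd_b": kd_b,
                "se_b": se_b,
                "ratio": r.ratio,
                "se": r.se,
                "z": r.z,
                "significant": r.significant,
                "verdict": r.verdict.value,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "label", "kd_a", "se_a", "kd_b", "se_b",
            "ratio", "se", "z", "significant", "verdict",
        ],
    )
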