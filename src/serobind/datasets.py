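"""Published reference values used as inputs by examples and reproduction runs.

These are measured quantities for the Taf3-PHD chromatin reader binding
H3K4-methylated histone tail peptides with and without glutamine-5
serotonylation (H3Q5ser), as reported in the primary literature for this
system.  They are *inputs* to the statistics in
:mod:`serobind.affinity_stats` (the package recomputes ratios, propagated
errors and significance from the K_D ± SE pairs), not outputs of this
package.
"""

from __future__ import annotations

__all__ = ["AFFINITY_ROWS", "OFF_RATES"]

# ITC dissociation constants (µM) with standard errors from individual
# one-site curve fits.  Columns: label, K_D(me3), SE, K_D(me3 + Q5ser), SE.
# The first nine rows are Taf3-PHD point mutants; the last three are other
# PHD-finger readers assayed the same way.
AFFINITY_ROWS: list[tuple[str, float, float, float, float]] = [
    ("TAF3 WT", 0.260, 0.016, 0.098, 0.008),
    ("TAF3 A902L", 0.166, 0.017, 0.051, 0.003),
    ("TAF3 S880A", 0.207, 0.034, 0.065, 0.005),
    ("TAF3 P881E", 0.148, 0.004, 0.136, 0.004),
    ("TAF3 P881F", 0.130, 0.004, 0.124, 0.007),
    ("TAF3 W894F", 0.126, 0.012, 0.102, 0.001),
    ("TAF3 W894I", 0.279, 0.017, 0.106, 0.008),
    ("TAF3 W894L", 0.595, 0.035, 0.324, 0.018),
    ("TAF3 P881E W894F", 0.123, 0.010, 0.111, 0.014),
    ("BPTF", 1.297, 0.049, 1.236, 0.050),
    ("PHF2", 0.286, 0.023, 0.201, 0.022),
    ("PHF8", 0.418, 0.020, 0.275, 0.019),
]

# Binding off-rates (s^-1) from two-state line-shape fits of wild-type
# Taf3-PHD titrations: (label, k_off without Q5ser, k_off with Q5ser).
OFF_RATES: dict[str, tuple[float, float]] = {
    "H3K4me3": (48.8, 16.8),
    "H3K4me2": (207.0, 71.0),
}
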