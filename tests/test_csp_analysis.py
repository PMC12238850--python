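"""Weighted CSPs, state averaging, trimmed-null detection, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serobind import synthetic_data as sd
from serobind.csp_analysis import (
    compute_csp,
    detect_ser_specific,
    intensity_ratio,
    normalize_intensities,
    state_average_shifts,
    weighted_csp,
)


def shift_table(ids, h, n, intensity=None, overlap=None):
    data = {"residue_id": ids, "h_ppm": h, "n_ppm": n}
    if intensity is not None:
        data["intensity"] = intensity
    if overlap is not None:
        data["overlap"] = overlap
    return pd.DataFrame(data)


class TestWeightedCsp:
    @pytest.mark.parametrize(
        "dh, dn, expected",
        [
            (0.0, 0.0, 0.0),
            (0.10, 0.0, 0.10),
            (0.03, 0.65, np.sqrt(0.03 ** 2 + 0.10 ** 2)),  # 0.104403...
        ],
    )
    def test_hand_values(self, dh, dn, expected):
        assert weighted_csp(dh, dn) == pytest.approx(expected, rel=1e-9)

    @given(
        dh=st.floats(-1, 1), dn=st.floats(-5, 5), c=st.floats(0, 100)
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_homogeneity(self, dh, dn, c):
        assert weighted_csp(c * dh, c * dn) == pytest.approx(
            c * weighted_csp(dh, dn), rel=1e-9, abs=1e-12
        )


class TestStateAveraging:
    def test_single_table_unchanged(self):
        t = shift_table([1, 2], [8.0, 8.5], [110.0, 120.0])
        avg = state_average_shifts([t])
        assert np.allclose(avg["h_ppm"], t["h_ppm"])
        assert (avg["n_states"] == 1).all()

    def test_identical_tables_average_to_themselves(self):
        t = shift_table([1, 2, 3], [8.0, 8.5, 9.0], [110.0, 120.0, 125.0])
        avg = state_average_shifts([t, t.copy(), t.copy()])
        assert np.allclose(avg["h_ppm"], t["h_ppm"])
        assert (avg["n_states"] == 3).all()

    def test_partial_coverage_averages_available_states(self):
        t1 = shift_table([1, 2], [8.0, 8.4], [110.0, 120.0])
        t2 = shift_table([1, 2], [8.2, 8.6], [112.0, 121.0])
        t3 = shift_table([1], [8.4], [114.0])  # residue 2 unassigned here
        avg = state_average_shifts([t1, t2, t3]).set_index("residue_id")
        assert avg.loc[1, "h_ppm"] == pytest.approx((8.0 + 8.2 + 8.4) / 3)
        assert avg.loc[2, "h_ppm"] == pytest.approx((8.4 + 8.6) / 2)
        assert avg.loc[2, "n_states"] == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            state_average_shifts([])


class TestDetectSerSpecific:
    def test_worked_example(self):
        # smallest half {0.01..0.05}: mean 0.03, sample SD 0.0158 -> 0.0458
        vals = [0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.5, 0.6]
        df = pd.DataFrame({"residue_id": range(1, 11), "csp": vals})
        out = detect_ser_specific(df)
        assert out["threshold_used"].iloc[0] == pytest.approx(0.045811, abs=1e-5)
        assert out["flagged"].sum() == 6
        assert set(out.loc[out["flagged"], "csp"]) == {0.05, 0.06, 0.07, 0.08, 0.5, 0.6}

    def test_all_equal_none_flagged(self):
        df = pd.DataFrame({"residue_id": range(6), "csp": [0.1] * 6})
        out = detect_ser_specific(df)
        assert out["flagged"].sum() == 0

    def test_order_invariance_and_missing_values_ignored(self):
        vals = [0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.5, 0.6]
        df = pd.DataFrame({"residue_id": range(1, 11), "csp": vals})
        shuffled = df.sample(frac=1.0, random_state=1)
        with_nan = pd.concat(
            [shuffled, pd.DataFrame({"residue_id": [99], "csp": [np.nan]})]
        )
        out = detect_ser_specific(with_nan)
        assert out["threshold_used"].iloc[0] == pytest.approx(0.045811, abs=1e-5)
        assert out["flagged"].sum() == 6
        assert not out.loc[out["residue_id"] == 99, "flagged"].iloc[0]

    @pytest.mark.parametrize("spreads", [(0.0, 2.0), (2.0, 3.0), (0.0, 3.0)])
    def test_outlier_flags_non_increasing_with_wider_null(self, spreads):
        # same outliers on a null of growing spread: the threshold rises, so
        # the number of flagged outliers can only stay equal or drop
        upper = [0.05, 0.055, 0.5, 0.6, 0.7]
        counts = []
        for s in spreads:
            lower = (0.03 + s * 0.005 * np.array([-2, -1, 0, 1, 2])).tolist()
            df = pd.DataFrame({"residue_id": range(10), "csp": lower + upper})
            out = detect_ser_specific(df)
            counts.append(int(out.loc[out["residue_id"] >= 5, "flagged"].sum()))
        assert counts[1] <= counts[0]

    def test_too_few_values_rejected(self):
        df = pd.DataFrame({"residue_id": [1, 2, 3], "csp": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match=">= 4"):
            detect_ser_specific(df)

    def test_spiked_generator_round_trip(self):
        ref, pert = sd.generate_shift_table(
            n_residues=20, background_scale=0.02, spiked={5, 17},
            spike_size=0.2, seed=7,
        )
        csp = compute_csp(ref, pert)
        out = detect_ser_specific(csp)
        assert set(out.loc[out["flagged"], "residue_id"]) == {5, 17}


class TestIntensities:
    def test_reference_maps_to_one_and_idempotent(self):
        t = shift_table([1, 2, 3], [8, 8, 8], [110, 111, 112], [50.0, 100.0, 200.0])
        norm = normalize_intensities(t, 2)
        assert norm["intensity"].tolist() == [0.5, 1.0, 2.0]
        again = normalize_intensities(norm, 2)
        assert again["intensity"].tolist() == [0.5, 1.0, 2.0]

    def test_missing_or_nonpositive_reference_rejected(self):
        t = shift_table([1, 2], [8, 8], [110, 111], [50.0, 0.0])
        with pytest.raises(ValueError, match="not in table"):
            normalize_intensities(t, 99)
        with pytest.raises(ValueError, match="non-positive"):
            normalize_intensities(t, 2)

    def test_ratio_identical_tables_all_one(self):
        t = shift_table([1, 2], [8, 8], [110, 111], [1.0, 2.0])
        ratios, excl = intensity_ratio(t, t)
        assert np.allclose(ratios["ratio"], 1.0)
        assert excl.empty

    def test_halved_intensity_gives_half_ratio(self):
        ref = shift_table([1, 2], [8, 8], [110, 111], [1.0, 1.0])
        ser = shift_table([1, 2], [8, 8], [110, 111], [0.5, 1.0])
        ratios, _ = intensity_ratio(ser, ref)
        assert ratios.set_index("residue_id")["ratio"].tolist() == [0.5, 1.0]

    def test_overlapped_residue_excluded_with_reason(self):
        ref = shift_table([1, 2], [8, 8], [110, 111], [1.0, 1.0], [False, True])
        ser = shift_table([1, 2], [8, 8], [110, 111], [0.5, 1.0], [False, False])
        ratios, excl = intensity_ratio(ser, ref)
        assert ratios["residue_id"].tolist() == [1]
        assert excl["residue_id"].tolist() == [2]
        assert excl["reason"].iloc[0] == "overlapped"
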