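import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hemifit as hf
from hemifit.data import FitnessTable

HEADER = "line,sex,sex_ratio,day,vial,eggs,red,total\n"


def female_table(day_values: dict) -> FitnessTable:
    """Female-only table: day label -> list of (line, eggs)."""
    rows = "".join(
        f"{line},F,MB,{day},{i},{eggs},,\n"
        for day, recs in day_values.items()
        for i, (line, eggs) in enumerate(recs)
    )
    return hf.read_fitness_table(io.StringIO(HEADER + rows))


class TestArcsinSqrt:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, 0.0), (1.0, np.pi / 2), (0.25, np.pi / 6), (0.5, np.pi / 4)],
    )
    def test_known_values(self, p, expected):
        assert hf.arcsin_sqrt(p) == pytest.approx(expected, abs=1e-12)

    def test_clamps_float_slop_only(self):
        assert hf.arcsin_sqrt(1 + 1e-13) == pytest.approx(np.pi / 2)
        with pytest.raises(ValueError):
            hf.arcsin_sqrt(1.001)
        with pytest.raises(ValueError):
            hf.arcsin_sqrt(-0.01)

    @given(st.floats(0, 1))
    def test_monotone(self, p):
        assert hf.arcsin_sqrt(p) <= hf.arcsin_sqrt(min(p + 0.01, 1.0)) + 1e-15


class TestScaleCenter:
    def test_known_values(self):
        np.testing.assert_allclose(hf.scale_center([1, 2, 3]), [-1, 0, 1])
        np.testing.assert_allclose(
            hf.scale_center([10, 20]), [-0.7071067811865476, 0.7071067811865476]
        )

    def test_idempotent(self):
        x = hf.scale_center([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_allclose(hf.scale_center(x), x, atol=1e-12)

    def test_degenerate(self):
        with pytest.raises(ValueError, match="zero sample SD"):
            hf.scale_center([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="at least 2"):
            hf.scale_center([1.0])


class TestDayNormalize:
    def test_mean_divide_example(self):
        t = female_table({"d1": [("L1", 2), ("L2", 4)]})
        std = hf.day_normalize(t, "mean_divide")
        np.testing.assert_allclose(sorted(std.df["value"]), [2 / 3, 4 / 3])

    def test_equal_values_become_one(self):
        t = female_table({"d1": [("L1", 5), ("L2", 5), ("L3", 5)]})
        assert (hf.day_normalize(t, "mean_divide").df["value"] == 1).all()

    def test_scale_center_example(self):
        t = female_table({"d1": [("L1", 1), ("L2", 2), ("L3", 3)]})
        std = hf.day_normalize(t, "scale_center")
        np.testing.assert_allclose(sorted(std.df["value"]), [-1, 0, 1])

    def test_zero_mean_day_rejected(self):
        t = female_table({"d1": [("L1", 0), ("L2", 0)]})
        with pytest.raises(ValueError, match="zero mean"):
            hf.day_normalize(t, "mean_divide")

    def test_male_values_arcsin_transformed(self):
        t = hf.read_fitness_table(
            io.StringIO(HEADER + "L1,M,MB,d1,1,,25,100\nL2,M,MB,d1,2,,100,100\n")
        )
        std = hf.day_normalize(t, "mean_divide")
        expect = np.array([np.pi / 6, np.pi / 2])
        np.testing.assert_allclose(
            np.sort(std.df["value"]), np.sort(expect / expect.mean())
        )

    def test_per_day_invariants_on_panel(self, small_table):
        md = hf.day_normalize(small_table, "mean_divide")
        assert np.allclose(md.df.groupby("day")["value"].mean(), 1.0, atol=1e-10)
        sc = hf.standardize_for_lmm(small_table)
        assert np.allclose(sc.df.groupby("day")["value"].mean(), 0.0, atol=1e-10)
        assert np.allclose(sc.df.groupby("day")["value"].std(), 1.0, atol=1e-10)


class TestTwoStepLineMeans:
    def test_day_weighting(self):
        # day means 2 and 4 -> two-step mean 3, regardless of vial counts
        t = female_table({"d1": [("L1", 1), ("L1", 3)], "d2": [("L1", 4)]})
        std = hf.day_normalize(t, "mean_divide")
        lm = hf.two_step_line_means(std, standardize=False)
        d1m, d2m = 2 / 2, 4 / 4  # each day self-normalises here
        assert lm.matrix.loc["L1", "F_MB"] == pytest.approx((d1m + d2m) / 2)

    def test_two_step_vs_pooled_weighting(self):
        # raw two-step with unequal vials differs from the pooled mean by the
        # equal-day-weight formula; on a single-line/day-pair toy this is
        # (m1 + m2)/2 vs (n1 m1 + n2 m2)/(n1 + n2)
        df = pd.DataFrame({
            "line": "L1", "sex": "F", "sex_ratio": "MB",
            "day": ["d1", "d1", "d2"], "vial": ["1", "2", "1"],
            "value": [1.0, 3.0, 4.0],
        })
        from hemifit.transforms import StandardizedTable, two_step_line_means

        std = StandardizedTable(df, "mean_divide", ["L1"])
        lm = two_step_line_means(std, standardize=False)
        assert lm.matrix.loc["L1", "F_MB"] == pytest.approx(3.0)  # (2+4)/2
        assert lm.matrix.loc["L1", "F_MB"] != pytest.approx(8 / 3)  # pooled

    def test_single_day_line(self):
        t = female_table(
            {"d1": [("L1", 2), ("L2", 6)], "d2": [("L2", 4), ("L2", 8)]}
        )
        lm = hf.two_step_line_means(
            hf.day_normalize(t, "mean_divide"), standardize=False
        )
        # L1 observed on day 1 only: its value is that day's normalised mean
        assert lm.matrix.loc["L1", "F_MB"] == pytest.approx(2 / 4)

    def test_vial_and_day_label_invariance(self, small_table):
        std = hf.day_normalize(small_table, "mean_divide")
        lm1 = hf.two_step_line_means(std)
        df = small_table.df.sample(frac=1, random_state=0)
        relabel = {d: f"x{i}" for i, d in enumerate(pd.unique(df["day"]))}
        df = df.assign(day=df["day"].map(relabel))
        lm2 = hf.two_step_line_means(
            hf.day_normalize(hf.FitnessTable(df), "mean_divide")
        )
        pd.testing.assert_frame_equal(
            lm1.matrix, lm2.matrix.reindex(lm1.matrix.index), atol=1e-12
        )

    def test_standardized_columns(self, small_table):
        lm = hf.two_step_line_means(hf.day_normalize(small_table, "mean_divide"))
        m = lm.matrix.to_numpy()
        assert np.allclose(np.nanmean(m, axis=0), 0, atol=1e-10)
        assert np.allclose(np.nanstd(m, axis=0, ddof=1), 1, atol=1e-10)

    def test_chain_deterministic(self, small_table):
        a = hf.two_step_line_means(hf.day_normalize(small_table, "mean_divide"))
        b = hf.two_step_line_means(hf.day_normalize(small_table, "mean_divide"))
        assert a.matrix.equals(b.matrix)
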