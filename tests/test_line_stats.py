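import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hemifit as hf
from hemifit.line_stats import _PipelineEngine, _stat_fn
from hemifit.transforms import LineMeans, scale_center


def lm_from_columns(**cols) -> LineMeans:
    """LineMeans with explicit columns; unspecified cells stay missing."""
    n = len(next(iter(cols.values())))
    m = pd.DataFrame(
        np.nan, index=[f"L{i}" for i in range(n)], columns=list(hf.CELL_LABELS)
    )
    for k, v in cols.items():
        m[k] = np.asarray(v, float)
    return LineMeans(m, standardized=True)


def standardized_pair(r, n=39, seed=0):
    """Two exactly standardised vectors with exact sample correlation r."""
    rng = np.random.default_rng(seed)
    x = scale_center(rng.normal(size=n))
    z = rng.normal(size=n)
    z = z - x * (x @ z) / (x @ x)
    z = scale_center(z)
    return x, scale_center(r * x + np.sqrt(1 - r**2) * z)


class TestRotation:
    @pytest.mark.parametrize(
        "wf,wm,wc,wa",
        [
            (1.0, 1.0, np.sqrt(2), 0.0),
            (1.0, -1.0, 0.0, -np.sqrt(2)),
            (0.5, 0.3, 0.565685, -0.141421),
        ],
    )
    def test_known_points(self, wf, wm, wc, wa):
        lm = lm_from_columns(F_MB=[wf, 0, 0], M_MB=[wm, 0, 0])
        rot = hf.rotate_to_sa_axes(lm, "MB")
        assert rot.frame.loc["L0", "W_C"] == pytest.approx(wc, abs=1e-6)
        assert rot.frame.loc["L0", "W_A"] == pytest.approx(wa, abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_norm_and_variance_preserved(self, seed):
        rng = np.random.default_rng(seed)
        wf, wm = rng.normal(size=20), rng.normal(size=20)
        lm = lm_from_columns(F_EQ=wf, M_EQ=wm)
        rot = hf.rotate_to_sa_axes(lm, "EQ")
        wc, wa = rot.frame["W_C"], rot.frame["W_A"]
        np.testing.assert_allclose(wc**2 + wa**2, wf**2 + wm**2, atol=1e-12)
        assert np.var(wc, ddof=1) + np.var(wa, ddof=1) == pytest.approx(
            np.var(wf, ddof=1) + np.var(wm, ddof=1), abs=1e-10
        )


class TestCorrelations:
    def test_identical_columns_give_one(self):
        x = np.arange(5.0)
        lm = lm_from_columns(F_MB=x, M_MB=x, F_FB=x)
        assert hf.intersexual_correlation(lm, "MB").value == pytest.approx(1.0)
        assert hf.cross_ratio_correlation(lm, "F", ("MB", "FB")).value == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        lm = lm_from_columns(F_MB=[-1, 0, 1], M_MB=[1, 0, -1])
        assert hf.intersexual_correlation(lm, "MB").value == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        lm = lm_from_columns(F_MB=[1, 2, np.nan], M_MB=[1, np.nan, 2])
        with pytest.raises(ValueError, match="at least 3"):
            hf.intersexual_correlation(lm, "MB")

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        wf, wm = rng.normal(size=15), rng.normal(size=15)
        r0 = hf.intersexual_correlation(lm_from_columns(F_EQ=wf, M_EQ=wm), "EQ").value
        r1 = hf.intersexual_correlation(
            lm_from_columns(F_EQ=3.2 * wf + 7, M_EQ=0.1 * wm - 2), "EQ"
        ).value
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_pairwise_complete_n_reported(self):
        wf = np.r_[np.arange(10.0), np.nan]
        wm = np.r_[np.arange(10.0) * 2, 5.0]
        est = hf.intersexual_correlation(lm_from_columns(F_FB=wf, M_FB=wm), "FB")
        assert est.n_lines == 10


class TestSaProportion:
    @pytest.mark.parametrize("r,expected", [(1.0, 0.0), (-1.0, 1.0), (0.0, 0.5)])
    def test_limits(self, r, expected):
        x, y = standardized_pair(r, n=20, seed=2)
        lm = lm_from_columns(F_MB=x, M_MB=y)
        assert hf.sa_variance_proportion(lm, "MB").value == pytest.approx(
            expected, abs=1e-10
        )

    @given(st.floats(-0.99, 0.99))
    @settings(max_examples=30, deadline=None)
    def test_identity_one_minus_r_over_two(self, r):
        x, y = standardized_pair(r, n=25, seed=4)
        lm = lm_from_columns(F_EQ=x, M_EQ=y)
        sa = hf.sa_variance_proportion(lm, "EQ")
        assert sa.value == pytest.approx((1 - r) / 2, abs=1e-9)
        assert sa.value + sa.concordant == pytest.approx(1.0)


class TestBootstrap:
    def test_engine_matches_pandas_pathway(self, small_table):
        eng = _PipelineEngine(small_table)
        lm = hf.two_step_line_means(hf.day_normalize(small_table, "mean_divide"))
        np.testing.assert_allclose(
            eng.line_means(), lm.matrix.to_numpy(), atol=1e-12
        )
        for spec, direct in [
            ("rwmf:MB", hf.intersexual_correlation(lm, "MB").value),
            ("sa_prop:FB", hf.sa_variance_proportion(lm, "FB").value),
            ("cross_ratio:M:MB-EQ",
             hf.cross_ratio_correlation(lm, "M", ("MB", "EQ")).value),
        ]:
            assert _stat_fn(spec)(eng.line_means()) == pytest.approx(direct)

    def test_stratum_sizes_preserved(self, small_table):
        eng = _PipelineEngine(small_table)
        rng = np.random.default_rng(0)
        strata = eng.rec_start  # stratum id of each sorted record slot
        for _ in range(100):
            idx = eng.resample_indices(rng)
            assert np.array_equal(strata[idx], strata)

    def test_constant_strata_zero_width_ci(self):
        # vials identical within every stratum: resampling reproduces the
        # table, so the CI collapses onto the point estimate
        rng = np.random.default_rng(3)
        rows = []
        for k in range(8):
            for ratio in ("MB", "EQ", "FB"):
                for d in (1, 2):
                    fe = int(rng.integers(30, 90))
                    for v in range(3):
                        rows.append((f"L{k}", "F", ratio, f"F_{ratio}_d{d}", str(v), fe, None, None))
                    red = int(rng.integers(20, 80))
                    for v in range(3):
                        rows.append((f"L{k}", "M", ratio, f"M_{ratio}_d{d}", str(v), None, red, 100))
        df = pd.DataFrame(rows, columns=["line", "sex", "sex_ratio", "day", "vial", "eggs", "red", "total"])
        for c in ("eggs", "red", "total"):
            df[c] = pd.array(df[c], dtype="Int64")
        table = hf.FitnessTable(df)
        est = hf.stratified_bootstrap(table, "rwmf:EQ", n_boot=50, seed=1)
        assert est.ci_lower == pytest.approx(est.value, abs=1e-12)
        assert est.ci_upper == pytest.approx(est.value, abs=1e-12)

    def test_reproducible_from_seed(self, small_table):
        a = hf.stratified_bootstrap(small_table, "rwmf:MB", n_boot=40, seed=11)
        b = hf.stratified_bootstrap(small_table, "rwmf:MB", n_boot=40, seed=11)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)
        c = hf.stratified_bootstrap(small_table, "rwmf:MB", n_boot=40, seed=12)
        assert (a.ci_lower, a.ci_upper) != (c.ci_lower, c.ci_upper)

    def test_bca_runs_and_brackets_estimate(self, small_table):
        est = hf.stratified_bootstrap(
            small_table, "rwmf:MB", n_boot=200, seed=5, ci_method="bca"
        )
        assert est.ci_lower < est.ci_upper

    def test_difference_same_cell_is_zero(self, small_table):
        d = hf.bootstrap_difference(small_table, "rwmf", "MB", "MB", n_boot=30, seed=2)
        assert d.value == 0.0
        assert d.ci_lower == d.ci_upper == 0.0
        assert d.includes_zero

    def test_ci_width_shrinks_with_lines(self):
        widths = []
        for n in (40, 160):
            t = hf.simulate(hf.default_reference_params(n_lines=n, seed=77))
            est = hf.stratified_bootstrap(t, "rwmf:EQ", n_boot=150, seed=8)
            widths.append(est.ci_upper - est.ci_lower)
        assert widths[1] < widths[0]


class TestModelSurface:
    def test_fit_reports_all_statistics(self, small_table):
        res = hf.LineAverageModel(small_table).fit()
        assert len(res.estimates) == 12  # 3 rwmf + 3 sa + 6 cross-ratio
        assert res.estimates["estimate"].between(-1, 1).all()
        assert "r_wgmf[MB]" in res.summary()

    def test_fit_with_bootstrap_has_cis(self, small_table):
        res = hf.LineAverageModel(small_table).fit(n_boot=30, seed=3)
        assert res.estimates["lower"].notna().all()
        assert (res.estimates["lower"] <= res.estimates["upper"]).all()
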