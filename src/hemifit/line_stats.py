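"""Line-average statistics: genetic correlations, the sexually antagonistic
axis decomposition, and stratified-bootstrap confidence intervals.

All estimators operate on the standardised per-line cell means produced by
:func:`hemifit.transforms.two_step_line_means`. The antagonism decomposition
rotates each sex ratio's (female, male) line-mean plane by 45 degrees
anti-clockwise::

    W_C = ( W_F + W_M) / sqrt(2)      (sexually concordant axis)
    W_A = (-W_F + W_M) / sqrt(2)      (sexually antagonistic axis)

so for exactly standardised columns the proportion of line-mean variance
along the antagonistic axis equals (1 - r) / 2, with r the intersexual
correlation of that cell.

Uncertainty comes from a stratified bootstrap that resamples vial records
with replacement independently within every sex x line x day stratum
(preserving stratum sizes) and re-runs the entire transform + estimator
pipeline per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SEX_RATIOS, CELL_LABELS, FitnessTable
from .transforms import LineMeans, arcsin_sqrt, day_normalize, two_step_line_means

_SQRT2 = np.sqrt(2.0)
#: statistic spec strings accepted by the bootstrap:
#:   "rwmf:<ratio>", "sa_prop:<ratio>", "cross_ratio:<sex>:<ratio>-<ratio>"


@dataclass
class CorrelationEstimate:
    value: float
    n_lines: int
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_boot: int | None = None
    seed: int | None = None


@dataclass
class SaProportion:
    value: float
    n_lines: int
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_boot: int | None = None
    seed: int | None = None

    @property
    def concordant(self) -> float:
        return 1.0 - self.value


@dataclass
class DifferenceEstimate:
    value: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int

    @property
    def includes_zero(self) -> bool:
        return self.ci_lower <= 0.0 <= self.ci_upper


class RotatedLineMeans:
    """Concordant/antagonistic components per line for one sex ratio."""

    def __init__(self, frame: pd.DataFrame, ratio: str):
        self.frame = frame  # columns W_C, W_A indexed by line
        self.ratio = ratio


def _pairwise(x: np.ndarray, y: np.ndarray):
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    x, y = _pairwise(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 complete line pairs")
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm @ xm) * (ym @ ym))
    if denom == 0:
        raise ValueError("degenerate (zero-variance) column")
    return float(np.clip(xm @ ym / denom, -1.0, 1.0)), len(x)


def intersexual_correlation(lm: LineMeans, ratio: str) -> CorrelationEstimate:
    """Pearson correlation between female and male line means, r_w,g,mf."""
    r, n = _pearson(
        lm.column("F", ratio).to_numpy(), lm.column("M", ratio).to_numpy()
    )
    return CorrelationEstimate(value=r, n_lines=n)


def cross_ratio_correlation(lm: LineMeans, sex: str, pair) -> CorrelationEstimate:
    """Pearson correlation of one sex's line means between two sex ratios."""
    a, b = pair
    r, n = _pearson(lm.column(sex, a).to_numpy(), lm.column(sex, b).to_numpy())
    return CorrelationEstimate(value=r, n_lines=n)


def rotate_to_sa_axes(lm: LineMeans, ratio: str) -> RotatedLineMeans:
    """45-degree anti-clockwise rotation of the (female, male) plane."""
    wf = lm.column("F", ratio).to_numpy()
    wm = lm.column("M", ratio).to_numpy()
    frame = pd.DataFrame(
        {"W_C": (wf + wm) / _SQRT2, "W_A": (-wf + wm) / _SQRT2},
        index=lm.matrix.index,
    )
    return RotatedLineMeans(frame, ratio)


def sa_variance_proportion(lm: LineMeans, ratio: str) -> SaProportion:
    """Proportion of line-mean fitness variance on the antagonistic axis."""
    rot = rotate_to_sa_axes(lm, ratio)
    wc, wa = _pairwise(rot.frame["W_C"].to_numpy(), rot.frame["W_A"].to_numpy())
    if len(wc) < 3:
        raise ValueError("need at least 3 complete line pairs")
    va, vc = np.var(wa, ddof=1), np.var(wc, ddof=1)
    if va + vc == 0:
        raise ValueError("degenerate variance")
    return SaProportion(value=float(va / (va + vc)), n_lines=len(wc))


# ---------------------------------------------------------------------------
# Vectorised pipeline engine used by the bootstrap

class _PipelineEngine:
    """Array-based re-implementation of the full line-average pipeline.

    Records are sorted by (sex, line, day) stratum once; a bootstrap
    replicate is then a single vectorised gather of record indices followed
    by bincount group means, which keeps 10^4-replicate runs tractable.
    Produces bit-comparable results to the pandas pathway (tested).
    """

    def __init__(self, table: FitnessTable):
        df = table.df
        fem = (df["sex"] == "F").to_numpy()
        value = np.empty(len(df))
        value[fem] = df["eggs"].to_numpy(dtype=float, na_value=np.nan)[fem]
        prop = (
            df["red"].to_numpy(dtype=float, na_value=np.nan)
            / df["total"].to_numpy(dtype=float, na_value=np.nan)
        )[~fem]
        value[~fem] = arcsin_sqrt(prop)

        lines = table.lines
        line_code = pd.Categorical(df["line"], categories=lines).codes.astype(int)
        cell_lab = df["sex"].astype(str) + "_" + df["sex_ratio"].astype(str)
        cell_code = pd.Categorical(cell_lab, categories=list(CELL_LABELS)).codes.astype(int)
        day_code = pd.Categorical(df["day"]).codes.astype(int)

        # strata are sex x line x day; day labels are nested in a cell, so
        # (line, day) identifies the stratum
        strat_key = line_code * (day_code.max() + 1) + day_code
        order = np.argsort(strat_key, kind="stable")

        self.n_lines = len(lines)
        self.lines = lines
        self.value = value[order]
        self.day = day_code[order]
        self.n_days = self.day.max() + 1
        self.day_count = np.bincount(self.day, minlength=self.n_days).astype(float)
        if np.any(self.day_count == 0):
            raise ValueError("empty assay day")

        # line x day groups and their parent line x cell groups
        ld_key = line_code[order] * self.n_days + self.day
        ld_codes, self.ld = np.unique(ld_key, return_inverse=True)
        self.n_ld = len(ld_codes)
        self.ld_count = np.bincount(self.ld).astype(float)
        ld_line = ld_codes // self.n_days
        ld_day = ld_codes % self.n_days
        day_cell = np.full(self.n_days, -1, dtype=int)
        day_cell[self.day] = cell_code[order]
        self.lc_of_ld = ld_line * 6 + day_cell[ld_day]
        self.n_lc = self.n_lines * 6
        self.lc_count = np.bincount(self.lc_of_ld, minlength=self.n_lc).astype(float)

        # per-record stratum bounds for resampling
        sk = strat_key[order]
        starts = np.flatnonzero(np.r_[True, sk[1:] != sk[:-1]])
        sizes = np.diff(np.r_[starts, len(sk)])
        if np.any(sizes == 0):
            raise ValueError("empty sex x line x day stratum")
        self.rec_start = np.repeat(starts, sizes)
        self.rec_size = np.repeat(sizes, sizes).astype(float)

    def resample_indices(self, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(len(self.value))
        return self.rec_start + (u * self.rec_size).astype(int)

    def line_means(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Standardised lines x 6 cell-mean matrix (NaN for missing cells)."""
        v = self.value if indices is None else self.value[indices]
        day_mean = np.bincount(self.day, v, minlength=self.n_days) / self.day_count
        v = v / day_mean[self.day]
        ld_mean = np.bincount(self.ld, v, minlength=self.n_ld) / self.ld_count
        lc = np.full(self.n_lc, np.nan)
        sums = np.bincount(self.lc_of_ld, ld_mean, minlength=self.n_lc)
        present = self.lc_count > 0
        lc[present] = sums[present] / self.lc_count[present]
        m = lc.reshape(self.n_lines, 6)
        mean = np.nanmean(m, axis=0)
        sd = np.nanstd(m, axis=0, ddof=1)
        return (m - mean) / sd


def _stat_fn(statistic: str):
    """Compile a statistic spec string into a function of the standardised
    lines x 6 matrix."""
    parts = statistic.split(":")
    kind = parts[0]
    col = {lab: i for i, lab in enumerate(CELL_LABELS)}

    if kind == "rwmf":
        (ratio,) = parts[1:]
        i, j = col[f"F_{ratio}"], col[f"M_{ratio}"]
        return lambda m: _pearson(m[:, i], m[:, j])[0]
    if kind == "sa_prop":
        (ratio,) = parts[1:]
        i, j = col[f"F_{ratio}"], col[f"M_{ratio}"]

        def f(m):
            wf, wm = _pairwise(m[:, i], m[:, j])
            wc, wa = (wf + wm) / _SQRT2, (-wf + wm) / _SQRT2
            va, vc = np.var(wa, ddof=1), np.var(wc, ddof=1)
            return float(va / (va + vc))

        return f
    if kind == "cross_ratio":
        sex, pair = parts[1], parts[2]
        a, b = pair.split("-")
        i, j = col[f"{sex}_{a}"], col[f"{sex}_{b}"]
        return lambda m: _pearson(m[:, i], m[:, j])[0]
    raise ValueError(f"unknown statistic spec {statistic!r}")


def _percentile_ci(draws: np.ndarray, level: float = 0.95):
    lo, hi = np.quantile(draws, [(1 - level) / 2, (1 + level) / 2], method="linear")
    return float(lo), float(hi)


def _bca_ci(draws, theta_hat, jack, level=0.95):
    from scipy.stats import norm

    eps = 1e-12
    p0 = np.clip(np.mean(draws < theta_hat), eps, 1 - eps)
    z0 = norm.ppf(p0)
    d = jack.mean() - jack
    denom = (d @ d) ** 1.5
    a = (d**3).sum() / (6 * denom) if denom > 0 else 0.0
    alpha = np.array([(1 - level) / 2, (1 + level) / 2])
    z = norm.ppf(alpha)
    adj = norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(draws, adj, method="linear")
    return float(lo), float(hi)


def stratified_bootstrap(
    table: FitnessTable,
    statistic: str,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_method: str = "percentile",
):
    """Stratified bootstrap CI for a line-average statistic.

    Each of ``n_boot`` replicates resamples vial records with replacement
    independently within every sex x line x day stratum (stratum sizes
    preserved) and re-runs the full pipeline -- arcsin-sqrt, day-mean
    division, two-step line averaging, per-cell re-standardisation -- before
    recomputing the statistic. Returns a :class:`CorrelationEstimate` or
    :class:`SaProportion` carrying the 95% percentile CI (``ci_method="bca"``
    switches to bias-corrected accelerated intervals with a delete-one-line
    jackknife for the acceleration constant).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    engine = _PipelineEngine(table)
    fn = _stat_fn(statistic)
    m0 = engine.line_means()
    theta = fn(m0)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        draws[b] = fn(engine.line_means(engine.resample_indices(rng)))

    if ci_method == "percentile":
        lo, hi = _percentile_ci(draws)
    elif ci_method == "bca":
        jack = np.array(
            [fn(np.delete(m0, i, axis=0)) for i in range(engine.n_lines)]
        )
        lo, hi = _bca_ci(draws, theta, jack)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    cls = SaProportion if statistic.startswith("sa_prop") else CorrelationEstimate
    n = len(_pairwise(*_stat_cols(m0, statistic))[0])
    return cls(value=theta, n_lines=n, ci_lower=lo, ci_upper=hi, n_boot=n_boot, seed=seed)


def _stat_cols(m: np.ndarray, statistic: str):
    parts = statistic.split(":")
    col = {lab: i for i, lab in enumerate(CELL_LABELS)}
    if parts[0] in ("rwmf", "sa_prop"):
        return m[:, col[f"F_{parts[1]}"]], m[:, col[f"M_{parts[1]}"]]
    sex, (a, b) = parts[1], parts[2].split("-")
    return m[:, col[f"{sex}_{a}"]], m[:, col[f"{sex}_{b}"]]


def bootstrap_difference(
    table: FitnessTable,
    statistic: str,
    ratio_a: str,
    ratio_b: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> DifferenceEstimate:
    """Bootstrap CI for the difference of one statistic between two sex
    ratios (e.g. r_w,g,mf at MB minus FB), both recomputed per replicate on
    the same resampled table."""
    if statistic not in ("rwmf", "sa_prop"):
        raise ValueError("difference supported for 'rwmf' and 'sa_prop'")
    engine = _PipelineEngine(table)
    fa, fb = _stat_fn(f"{statistic}:{ratio_a}"), _stat_fn(f"{statistic}:{ratio_b}")
    theta = fa(engine.line_means()) - fb(engine.line_means())
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        m = engine.line_means(engine.resample_indices(rng))
        draws[b] = fa(m) - fb(m)
    lo, hi = _percentile_ci(draws)
    return DifferenceEstimate(theta, lo, hi, n_boot, seed)


# ---------------------------------------------------------------------------
# Model/Results surface

class LineAverageModel:
    """Line-average pathway over a vial-level fitness table.

    Computes the standardised per-line cell means and, on :meth:`fit`, the
    full set of line-average statistics -- intersexual genetic correlations,
    antagonistic variance proportions, and within-sex across-ratio genetic
    correlations -- with stratified-bootstrap CIs when ``n_boot > 0``.
    """

    def __init__(self, table: FitnessTable):
        self.table = table
        self.std = day_normalize(table, mode="mean_divide")
        self.line_means = two_step_line_means(self.std, standardize=True)

    def fit(self, n_boot: int = 0, seed: int = 0, ci_method: str = "percentile"):
        rows = []

        def add(statistic, label, est):
            rows.append({
                "statistic": label, "spec": statistic,
                "estimate": est.value,
                "lower": getattr(est, "ci_lower", None),
                "upper": getattr(est, "ci_upper", None),
                "n_lines": est.n_lines,
            })

        for ratio in SEX_RATIOS:
            spec = f"rwmf:{ratio}"
            est = (
                stratified_bootstrap(self.table, spec, n_boot, seed, ci_method)
                if n_boot
                else intersexual_correlation(self.line_means, ratio)
            )
            add(spec, f"r_wgmf[{ratio}]", est)
        for ratio in SEX_RATIOS:
            spec = f"sa_prop:{ratio}"
            est = (
                stratified_bootstrap(self.table, spec, n_boot, seed, ci_method)
                if n_boot
                else sa_variance_proportion(self.line_means, ratio)
            )
            add(spec, f"sa_prop[{ratio}]", est)
        for sex in ("F", "M"):
            for a, b in (("MB", "EQ"), ("MB", "FB"), ("EQ", "FB")):
                spec = f"cross_ratio:{sex}:{a}-{b}"
                est = (
                    stratified_bootstrap(self.table, spec, n_boot, seed, ci_method)
                    if n_boot
                    else cross_ratio_correlation(self.line_means, sex, (a, b))
                )
                add(spec, f"r_wg[{sex},{a}-{b}]", est)
        return LineAverageResults(self, pd.DataFrame(rows), n_boot=n_boot, seed=seed)


class LineAverageResults:
    def __init__(self, model: LineAverageModel, estimates: pd.DataFrame,
                 n_boot: int, seed: int):
        self.model = model
        self.estimates = estimates
        self.n_boot = n_boot
        self.seed = seed

    def difference(self, statistic: str, ratio_a: str, ratio_b: str,
                   n_boot: int | None = None, seed: int | None = None):
        return bootstrap_difference(
            self.model.table, statistic, ratio_a, ratio_b,
            n_boot=n_boot or self.n_boot or 1000,
            seed=self.seed if seed is None else seed,
        )

    def summary(self) -> str:
        with pd.option_context("display.float_format", "{:.4f}".format):
            body = self.estimates.drop(columns="spec").to_string(index=False)
        head = "Line-average statistics"
        if self.n_boot:
            head += f" (stratified bootstrap, n_boot={self.n_boot}, seed={self.seed})"
        return f"{head}\n{'=' * len(head)}\n{body}"
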