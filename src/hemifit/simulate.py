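"""Synthetic hemiclone-panel generator.

Emulates the study design the analysis assumes: a panel of hemigenome lines,
each expressed in both sexes under three operational sex ratios (male biased,
equal, female biased), with two replicate assay days per sex x sex-ratio cell,
seven female and five male adult-competition vials per line and day. Line
effects are drawn from a 6-dimensional genetic covariance matrix over the
sex x sex-ratio cells; assay-day and day x line effects and cell-specific
residual noise act on a latent scale that is mapped to realised vial data
through an exponential link for female egg counts (overdispersed counts) and
a logistic link for the male red-eyed-progeny proportion (binomial counts).

The links are a stand-in: the analysis operates on transformed/standardised
values, which leaves the raw-scale generative model open; exponential and
logistic links keep counts and proportions in valid ranges and make the
per-day mean division the natural correction for multiplicative day effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CELLS, CELL_LABELS, SEX_RATIOS, FitnessTable

_CELL_INDEX = {lab: i for i, lab in enumerate(CELL_LABELS)}

#: order of the across-sex, across-ratio correlation arguments
CROSS_SEX_CROSS_RATIO_PAIRS = (
    ("F_MB", "M_EQ"), ("F_MB", "M_FB"),
    ("F_EQ", "M_MB"), ("F_EQ", "M_FB"),
    ("F_FB", "M_MB"), ("F_FB", "M_EQ"),
)
#: order of within-sex across-ratio correlation arguments
RATIO_PAIRS = (("MB", "EQ"), ("MB", "FB"), ("EQ", "FB"))


@dataclass
class DesignSpec:
    """Assay design constants (reference defaults: 39-line panel)."""

    n_lines: int = 39
    days_per_cell: int = 2
    vials_per_line_day_female: int = 7
    vials_per_line_day_male: int = 5
    dams_per_male_vial: int = 7
    focal_females_per_vial: int = 2
    mean_progeny_per_dam: float = 30.0
    mean_eggs_per_vial: float = 60.0

    def __post_init__(self):
        for name in (
            "n_lines", "days_per_cell", "vials_per_line_day_female",
            "vials_per_line_day_male", "dams_per_male_vial",
            "focal_females_per_vial",
        ):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.mean_progeny_per_dam <= 0 or self.mean_eggs_per_vial <= 0:
            raise ValueError("mean counts must be positive")

    @property
    def n_female_vials(self) -> int:
        return (
            self.n_lines * len(SEX_RATIOS) * self.days_per_cell
            * self.vials_per_line_day_female
        )

    @property
    def n_male_vials(self) -> int:
        return (
            self.n_lines * len(SEX_RATIOS) * self.days_per_cell
            * self.vials_per_line_day_male
        )


@dataclass
class NoiseSpec:
    """Non-genetic variance sources on the latent scale.

    ``residual_sd`` maps cell label -> SD of the vial-level latent residual;
    ``female_dispersion`` is the negative-binomial size parameter k of the
    female egg counts (variance m + m^2/k); ``inf`` gives Poisson counts and
    ``0`` the degenerate no-count-noise limit (eggs = rounded latent mean).
    """

    day_effect_sd: float = 0.0
    day_line_sd: float = 0.0
    residual_sd: dict = field(default_factory=lambda: {c: 0.0 for c in CELL_LABELS})
    female_dispersion: float = np.inf

    def __post_init__(self):
        if self.day_effect_sd < 0 or self.day_line_sd < 0:
            raise ValueError("SDs must be >= 0")
        missing = set(CELL_LABELS) - set(self.residual_sd)
        if missing:
            raise ValueError(f"residual_sd missing cells: {sorted(missing)}")
        if any(v < 0 for v in self.residual_sd.values()):
            raise ValueError("residual SDs must be >= 0")
        if self.female_dispersion < 0:
            raise ValueError(
                "female_dispersion must be >= 0 (inf for Poisson, 0 for no count noise)"
            )


class GMatrix:
    """6x6 genetic covariance over the sex x sex-ratio cells.

    Rows/columns follow ``CELL_LABELS`` (F_MB, F_EQ, F_FB, M_MB, M_EQ, M_FB).
    Diagonals hold the cell-specific additive genetic variances, within-ratio
    cross-sex entries the intersexual genetic covariances, within-sex
    off-diagonals the across-ratio covariances.
    """

    PSD_TOL = 1e-10

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (6, 6):
            raise ValueError("GMatrix must be 6x6")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("GMatrix must be symmetric")
        w = np.linalg.eigvalsh(m)
        if w[0] < -self.PSD_TOL:
            raise ValueError(
                f"GMatrix is not positive semi-definite (smallest eigenvalue {w[0]:.6g})"
            )
        self.values = m

    def __getitem__(self, key):
        a, b = key
        return self.values[_CELL_INDEX[a], _CELL_INDEX[b]]

    def correlation(self, cell_a: str, cell_b: str) -> float:
        va, vb = self[cell_a, cell_a], self[cell_b, cell_b]
        if va <= 0 or vb <= 0:
            raise ValueError("correlation undefined for zero genetic variance")
        return self[cell_a, cell_b] / np.sqrt(va * vb)

    def intersexual_correlation(self, ratio: str) -> float:
        return self.correlation(f"F_{ratio}", f"M_{ratio}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=CELL_LABELS, columns=CELL_LABELS)


def make_g_matrix(
    genetic_variances,
    rwmf_per_ratio,
    cross_ratio_corr_female,
    cross_ratio_corr_male,
    cross_sex_cross_ratio_corr,
) -> GMatrix:
    """Assemble a :class:`GMatrix` from variances and named correlations.

    Parameters
    ----------
    genetic_variances : 6 values in ``CELL_LABELS`` order.
    rwmf_per_ratio : 3 intersexual correlations for (MB, EQ, FB).
    cross_ratio_corr_female, cross_ratio_corr_male : 3 values each in
        ``RATIO_PAIRS`` order (MB-EQ, MB-FB, EQ-FB).
    cross_sex_cross_ratio_corr : 6 values in ``CROSS_SEX_CROSS_RATIO_PAIRS``
        order.

    Raises
    ------
    ValueError
        if any correlation is outside [-1, 1], a variance is negative, or the
        assembled matrix is not positive semi-definite (the error reports the
        smallest eigenvalue).
    """
    v = np.asarray(genetic_variances, dtype=float)
    if v.shape != (6,) or np.any(v < 0):
        raise ValueError("need 6 non-negative genetic variances")
    corrs = (
        list(rwmf_per_ratio)
        + list(cross_ratio_corr_female)
        + list(cross_ratio_corr_male)
        + list(cross_sex_cross_ratio_corr)
    )
    if len(corrs) != 15 or any(abs(c) > 1 for c in corrs):
        raise ValueError("correlations must be 3+3+3+6 values in [-1, 1]")

    r = np.eye(6)

    def put(a, b, val):
        i, j = _CELL_INDEX[a], _CELL_INDEX[b]
        r[i, j] = r[j, i] = val

    for ratio, val in zip(SEX_RATIOS, rwmf_per_ratio):
        put(f"F_{ratio}", f"M_{ratio}", val)
    for (ra, rb), val in zip(RATIO_PAIRS, cross_ratio_corr_female):
        put(f"F_{ra}", f"F_{rb}", val)
    for (ra, rb), val in zip(RATIO_PAIRS, cross_ratio_corr_male):
        put(f"M_{ra}", f"M_{rb}", val)
    for (a, b), val in zip(CROSS_SEX_CROSS_RATIO_PAIRS, cross_sex_cross_ratio_corr):
        put(a, b, val)

    sd = np.sqrt(v)
    return GMatrix(r * np.outer(sd, sd))


@dataclass
class SimulationParams:
    design: DesignSpec
    g: GMatrix
    noise: NoiseSpec
    seed: int = 0

    def to_config(self) -> dict:
        """Flat, YAML-serialisable representation."""
        cfg = {f"design.{k}": v for k, v in asdict(self.design).items()}
        cfg["g.matrix"] = [[float(x) for x in row] for row in self.g.values]
        cfg["noise.day_effect_sd"] = self.noise.day_effect_sd
        cfg["noise.day_line_sd"] = self.noise.day_line_sd
        for cell in CELL_LABELS:
            cfg[f"noise.residual_sd.{cell}"] = float(self.noise.residual_sd[cell])
        disp = self.noise.female_dispersion
        cfg["noise.female_dispersion"] = "inf" if np.isinf(disp) else float(disp)
        cfg["seed"] = int(self.seed)
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "SimulationParams":
        design = DesignSpec(**{
            k.split(".", 1)[1]: v for k, v in cfg.items() if k.startswith("design.")
        })
        noise = NoiseSpec(
            day_effect_sd=cfg.get("noise.day_effect_sd", 0.0),
            day_line_sd=cfg.get("noise.day_line_sd", 0.0),
            residual_sd={
                c: float(cfg.get(f"noise.residual_sd.{c}", 0.0)) for c in CELL_LABELS
            },
            female_dispersion=float(cfg.get("noise.female_dispersion", np.inf)),
        )
        return cls(design, GMatrix(cfg["g.matrix"]), noise, int(cfg.get("seed", 0)))


def simulate(params: SimulationParams, seed: int | None = None) -> FitnessTable:
    """Draw one vial-level fitness table from the generative model.

    Per line a 6-vector of cell effects is drawn from MVN(0, G); per
    (cell, day) a day effect, per (cell, day, line) a day x line effect, and
    per vial a cell-specific residual, all Gaussian on the latent scale.
    Female vials realise eggs ~ NegBin(mean = mean_eggs_per_vial * exp(latent),
    size = female_dispersion); male vials realise total as the sum of
    per-dam Poisson(mean_progeny_per_dam) broods and
    red ~ Binomial(total, expit(latent)), so a latent score of 0 corresponds
    to an expected proportion of 0.5.

    RNG streams are split hierarchically (line effects / day effects /
    day x line effects / vial noise), so changing vial counts does not perturb
    the drawn line effects under the same seed. The realised line-effect
    matrix is attached to the returned table as ``table.line_effects``
    (lines x 6 DataFrame) for parameter-recovery studies.
    """
    if seed is None:
        seed = params.seed
    des, g, noise = params.design, params.g, params.noise
    ss = np.random.SeedSequence(int(seed))
    rng_lines, rng_days, rng_dayline, rng_vials = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    lines = [f"L{i + 1:03d}" for i in range(des.n_lines)]
    L = rng_lines.multivariate_normal(
        np.zeros(6), g.values, size=des.n_lines, method="svd"
    )

    day_eff = {
        (cell, d): rng_days.normal(0.0, noise.day_effect_sd)
        for cell in CELL_LABELS
        for d in range(des.days_per_cell)
    }
    dayline_eff = {
        (cell, d): rng_dayline.normal(0.0, noise.day_line_sd, size=des.n_lines)
        for cell in CELL_LABELS
        for d in range(des.days_per_cell)
    }

    rows: dict[str, list] = {k: [] for k in
                             ("line", "sex", "sex_ratio", "day", "vial", "eggs", "red", "total")}
    for ci, (sex, ratio) in enumerate(CELLS):
        cell = CELL_LABELS[ci]
        n_vials = (
            des.vials_per_line_day_female if sex == "F" else des.vials_per_line_day_male
        )
        for d in range(des.days_per_cell):
            day_label = f"{cell}_d{d + 1}"
            base = day_eff[(cell, d)]
            dl = dayline_eff[(cell, d)]
            for li, line in enumerate(lines):
                latent = (
                    L[li, ci] + base + dl[li]
                    + rng_vials.normal(0.0, noise.residual_sd[cell], size=n_vials)
                )
                for vi in range(n_vials):
                    rows["line"].append(line)
                    rows["sex"].append(sex)
                    rows["sex_ratio"].append(ratio)
                    rows["day"].append(day_label)
                    rows["vial"].append(str(vi + 1))
                    if sex == "F":
                        mean = des.mean_eggs_per_vial * np.exp(latent[vi])
                        if noise.female_dispersion == 0:
                            eggs = round(mean)
                        elif np.isinf(noise.female_dispersion):
                            eggs = rng_vials.poisson(mean)
                        else:
                            k = noise.female_dispersion
                            eggs = rng_vials.negative_binomial(k, k / (k + mean))
                        rows["eggs"].append(int(eggs))
                        rows["red"].append(None)
                        rows["total"].append(None)
                    else:
                        total = 0
                        while total == 0:  # zero-progeny vials are never stored
                            total = int(
                                rng_vials.poisson(
                                    des.mean_progeny_per_dam, size=des.dams_per_male_vial
                                ).sum()
                            )
                        red = int(rng_vials.binomial(total, expit(latent[vi])))
                        rows["eggs"].append(None)
                        rows["red"].append(red)
                        rows["total"].append(total)

    df = pd.DataFrame(rows)
    for col in ("eggs", "red", "total"):
        df[col] = pd.array(df[col], dtype="Int64")
    table = FitnessTable(df)
    table.line_effects = pd.DataFrame(L, index=lines, columns=CELL_LABELS)
    return table


# Reference scenario ---------------------------------------------------------

#: variance fractions of the standardised observed scale implied by the
#: reference heritabilities (h2/2 = sigma_g / (sigma_g + sigma_r)) with the
#: day x line fraction 0.0353 (sigma_g + sigma_r = 1 - 0.0353)
_REF_H2 = {"F_MB": 0.8702, "F_EQ": 0.9992, "F_FB": 0.7385,
           "M_MB": 0.4788, "M_EQ": 0.5762, "M_FB": 0.2229}
_REF_DAYLINE_FRAC = 0.0353
_REF_RWMF = (0.3805, 0.4027, 0.2515)            # MB, EQ, FB
_REF_CROSS_F = (0.7493, 0.7688, 0.8421)         # MB-EQ, MB-FB, EQ-FB
_REF_CROSS_M = (0.6995, 0.5567, 0.5415)

#: overall latent SD scale: per-day standardisation removes the absolute
#: latent scale from the analysis, so it is fixed once for realism -- a raw
#: female fecundity CV of roughly 0.5
_REF_LATENT_SCALE = 0.45


def default_reference_params(n_lines: int = 39, seed: int = 0) -> SimulationParams:
    """Reference scenario: genetic correlations and variance fractions that
    mirror the study's estimates, with the default 39-line assay design.

    Intersexual correlations are (0.3805, 0.4027, 0.2515) for (MB, EQ, FB);
    within-sex across-ratio correlations follow the line-average estimates;
    across-sex across-ratio correlations (not separately reported) are set to
    0.5 * (r_mf[a] * Rm[a, b] + r_mf[b] * Rf[a, b]), the intersexual
    correlation propagated through each sex's across-ratio structure and
    averaged, which yields a positive-definite matrix. Genetic and residual
    variance fractions are implied by the reference heritabilities via
    h2 = 2 sigma_g / (sigma_g + sigma_r); the day x line variance fraction is
    0.0353. All fractions are scaled by a single latent SD scale (0.45).
    """
    s2 = _REF_LATENT_SCALE ** 2
    tot = 1.0 - _REF_DAYLINE_FRAC
    g_frac = {c: _REF_H2[c] / 2.0 * tot for c in CELL_LABELS}
    r_frac = {c: tot - g_frac[c] for c in CELL_LABELS}

    rmf = dict(zip(SEX_RATIOS, _REF_RWMF))
    rf = dict(zip(RATIO_PAIRS, _REF_CROSS_F))
    rm = dict(zip(RATIO_PAIRS, _REF_CROSS_M))

    def within(sex, a, b):
        d = rf if sex == "F" else rm
        return d.get((a, b), d.get((b, a)))

    cross = []
    for fa, mb in CROSS_SEX_CROSS_RATIO_PAIRS:
        a, b = fa.split("_")[1], mb.split("_")[1]
        cross.append(0.5 * (rmf[a] * within("M", a, b) + rmf[b] * within("F", a, b)))

    g = make_g_matrix(
        [g_frac[c] * s2 for c in CELL_LABELS],
        _REF_RWMF, _REF_CROSS_F, _REF_CROSS_M, cross,
    )
    noise = NoiseSpec(
        day_effect_sd=0.15,
        day_line_sd=float(np.sqrt(_REF_DAYLINE_FRAC * s2)),
        residual_sd={c: float(np.sqrt(r_frac[c] * s2)) for c in CELL_LABELS},
        female_dispersion=50.0,
    )
    return SimulationParams(DesignSpec(n_lines=n_lines), g, noise, seed=seed)
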