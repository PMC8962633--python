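"""Deterministic transformation chain from raw vial records to line means.

Two standardisation pathways are used downstream:

* line-average pathway: male proportions are arcsin-square-root transformed,
  every value is divided by its assay-day mean, vials are averaged per line
  within each day and the two day averages are averaged again; the resulting
  per-line cell means are finally scaled and centred within each
  sex x sex-ratio cell;
* mixed-model pathway: male proportions are arcsin-square-root transformed
  and values are scaled and centred (mean 0, sample SD 1) within each day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CELL_LABELS, FitnessTable

_CLAMP_TOL = 1e-12


def arcsin_sqrt(p):
    """Angular transform asin(sqrt(p)) of a proportion, in radians.

    Values outside [0, 1] by no more than 1e-12 (floating-point slop) are
    clamped; larger excursions raise ``ValueError``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < -_CLAMP_TOL) or np.any(p > 1 + _CLAMP_TOL):
        raise ValueError("proportion outside [0, 1] beyond clamp tolerance 1e-12")
    out = np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0)))
    return out if out.ndim else float(out)


def scale_center(values) -> np.ndarray:
    """Scale and centre to mean 0 and sample SD 1 (n-1 denominator).

    NaNs are ignored in the mean/SD and propagated through the output.
    """
    x = np.asarray(values, dtype=float)
    n = np.sum(~np.isnan(x))
    if n < 2:
        raise ValueError("scale_center needs at least 2 non-missing values")
    sd = np.nanstd(x, ddof=1)
    if sd == 0:
        raise ValueError("scale_center: zero sample SD")
    return (x - np.nanmean(x)) / sd


def _vial_values(table: FitnessTable) -> pd.DataFrame:
    """Raw analysis values per vial: eggs for females, arcsin-sqrt proportion
    for males. Female counts enter untransformed."""
    df = table.df.copy()
    fem = df["sex"] == "F"
    value = np.empty(len(df), dtype=float)
    value[fem.to_numpy()] = df.loc[fem, "eggs"].astype(float).to_numpy()
    prop = (
        df.loc[~fem, "red"].astype(float) / df.loc[~fem, "total"].astype(float)
    ).to_numpy()
    value[(~fem).to_numpy()] = arcsin_sqrt(prop)
    df["value"] = value
    return df


class StandardizedTable:
    """Vial-level table with a standardised ``value`` column.

    ``mode`` is ``"mean_divide"`` (each day's values divided by the day mean;
    day means become 1) or ``"scale_center"`` (each day centred and scaled to
    sample SD 1).
    """

    def __init__(self, df: pd.DataFrame, mode: str, lines: list):
        self.df = df
        self.mode = mode
        self.lines = lines


def day_normalize(table: FitnessTable, mode: str = "mean_divide") -> StandardizedTable:
    """Normalise vial values within each assay day.

    Male proportions are arcsin-square-root transformed first; female egg
    counts enter untransformed. With ``mode="mean_divide"`` each day's values
    are divided by the day mean; with ``mode="scale_center"`` each day is
    centred and scaled to unit sample SD (the mixed-model pathway).
    """
    if mode not in ("mean_divide", "scale_center"):
        raise ValueError(f"unknown mode {mode!r}")
    df = _vial_values(table)
    if mode == "mean_divide":
        means = df.groupby("day")["value"].transform("mean")
        if (means == 0).any():
            bad = df.loc[means == 0, "day"].iloc[0]
            raise ValueError(f"day {bad!r} has zero mean fitness; cannot mean-divide")
        df["value"] = df["value"] / means
    else:
        sizes = df.groupby("day")["value"].transform("size")
        if (sizes < 2).any():
            bad = df.loc[sizes < 2, "day"].iloc[0]
            raise ValueError(f"day {bad!r} has fewer than 2 records; cannot scale_center")
        sds = df.groupby("day")["value"].transform("std")  # ddof=1
        if (sds == 0).any():
            bad = df.loc[sds == 0, "day"].iloc[0]
            raise ValueError(f"day {bad!r} has zero SD; cannot scale_center")
        df["value"] = (df["value"] - df.groupby("day")["value"].transform("mean")) / sds
    return StandardizedTable(df, mode, FitnessTable(table.df).lines)


class LineMeans:
    """Per-line mean standardised fitness, one column per sex x sex-ratio cell.

    ``matrix`` is a lines x 6 DataFrame with columns F_MB, F_EQ, F_FB, M_MB,
    M_EQ, M_FB (the W-bar_F and W-bar_M of the antagonism rotation). Missing
    line x cell combinations are NaN and handled pairwise-complete downstream.
    """

    def __init__(self, matrix: pd.DataFrame, standardized: bool):
        self.matrix = matrix
        self.standardized = standardized

    @property
    def lines(self) -> list:
        return list(self.matrix.index)

    def column(self, sex: str, ratio: str) -> pd.Series:
        return self.matrix[f"{sex}_{ratio}"]


def two_step_line_means(std: StandardizedTable, standardize: bool = True) -> LineMeans:
    """Average vials within each day, then average the day averages per line.

    The two replicate assay days of each cell get equal weight regardless of
    vial counts; a line observed on one day only contributes that day's mean.
    With ``standardize=True`` each cell column is then scaled and centred
    (sample SD, n-1) over its non-missing lines.
    """
    if std.mode != "mean_divide":
        raise ValueError("line-average pathway expects mean_divide standardisation")
    df = std.df
    day_means = (
        df.groupby(["line", "sex", "sex_ratio", "day"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    cell_means = (
        day_means.groupby(["line", "sex", "sex_ratio"], sort=False)["value"].mean()
    )
    wide = cell_means.unstack(["sex", "sex_ratio"])
    wide.columns = [f"{s}_{r}" for s, r in wide.columns]
    wide = wide.reindex(index=std.lines, columns=list(CELL_LABELS))
    if standardize:
        for col in wide.columns:
            if wide[col].notna().sum() >= 2:
                wide[col] = scale_center(wide[col].to_numpy())
    return LineMeans(wide, standardized=standardize)


def standardize_for_lmm(table: FitnessTable) -> StandardizedTable:
    """Mixed-model pathway: arcsin-sqrt male proportions, then per-day scale
    and centre. Shares the :func:`day_normalize` code path."""
    return day_normalize(table, mode="scale_center")
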