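"""Vial-level hemiclone fitness data: container, CSV I/O and validation.

The unit of observation is an adult-competition vial. Female fitness is the
number of eggs laid in 18 h by the two focal females of the vial; male fitness
is the count of red-eyed progeny among all progeny pooled over the vial's
seven test tubes, stored as (red, total) counts rather than a precomputed
proportion so the arcsin-square-root transform operates on exact integers.

Long-format CSV schema (header exactly)::

    line,sex,sex_ratio,day,vial,eggs,red,total

with ``sex`` in {F, M}, ``sex_ratio`` in {MB, EQ, FB}; ``eggs`` empty on male
rows and ``red``/``total`` empty on female rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("F", "M")
SEX_RATIOS = ("MB", "EQ", "FB")
#: canonical (sex, sex_ratio) cell order used by every downstream matrix
CELLS = tuple((s, r) for s in SEXES for r in SEX_RATIOS)
CELL_LABELS = tuple(f"{s}_{r}" for s, r in CELLS)

CSV_COLUMNS = ["line", "sex", "sex_ratio", "day", "vial", "eggs", "red", "total"]

_SEX_ALIASES = {"f": "F", "female": "F", "m": "M", "male": "M"}
_RATIO_ALIASES = {
    "mb": "MB", "male_biased": "MB",
    "eq": "EQ", "equal": "EQ",
    "fb": "FB", "female_biased": "FB",
}


class SchemaError(ValueError):
    """Raised when a CSV file does not match the long-format schema."""


class RecordError(ValueError):
    """Raised when individual records violate hard invariants at ingest."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: tallies plus a list of violations."""

    n_records: int
    n_lines: int
    cell_vial_counts: pd.DataFrame
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = f"{self.n_records} records, {self.n_lines} lines"
        if self.ok:
            return f"ValidationReport({head}, no violations)"
        body = "\n  ".join(self.violations)
        return f"ValidationReport({head}, {len(self.violations)} violations)\n  {body}"


class FitnessTable:
    """Vial-level fitness records for a hemiclone panel.

    Thin wrapper around a :class:`pandas.DataFrame` with the long-format
    columns; preserves an ordered set of line labels (row order of every
    downstream line-means matrix).
    """

    def __init__(self, df: pd.DataFrame, design=None):
        self.df = df.reset_index(drop=True)
        self.design = design

    @property
    def lines(self) -> list:
        seen: dict = {}
        for v in self.df["line"]:
            seen.setdefault(v, None)
        return list(seen)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FitnessTable):
            return NotImplemented
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        for col in CSV_COLUMNS:
            av, bv = a[col], b[col]
            if col in ("eggs", "red", "total"):
                if not ((av.isna() == bv.isna()).all() and (av.dropna() == bv.dropna()).all()):
                    return False
            elif not (av.astype(str) == bv.astype(str)).all():
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FitnessTable({self.n_records} records, {len(self.lines)} lines)"


def _canon(series: pd.Series, aliases: dict, allowed: tuple, what: str) -> pd.Series:
    out = series.astype(str).str.strip().map(lambda v: aliases.get(v.lower(), v.upper()))
    bad = sorted(set(out) - set(allowed))
    if bad:
        raise SchemaError(f"unrecognised {what} value(s): {bad}; allowed {list(allowed)}")
    return out


def read_fitness_table(path, drop_zero_total: bool = True) -> FitnessTable:
    """Read a long-format CSV into a :class:`FitnessTable`.

    Parameters
    ----------
    path : str or file-like
        CSV with the exact header ``line,sex,sex_ratio,day,vial,eggs,red,total``.
    drop_zero_total : bool
        Male vials whose seven test tubes yielded no progeny at all have an
        undefined fitness proportion; they are excluded with a logged warning.

    Raises
    ------
    SchemaError
        on a missing or unknown column.
    RecordError
        on a sex/measure mismatch or ``red > total``.
    """
    df = pd.read_csv(path, dtype={"line": str, "day": str, "vial": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s): {unknown}")
    df = df[CSV_COLUMNS].copy()
    df["sex"] = _canon(df["sex"], _SEX_ALIASES, SEXES, "sex")
    df["sex_ratio"] = _canon(df["sex_ratio"], _RATIO_ALIASES, SEX_RATIOS, "sex_ratio")
    for col in ("eggs", "red", "total"):
        df[col] = pd.array(pd.to_numeric(df[col], errors="raise"), dtype="Int64")

    fem = df["sex"] == "F"
    bad = fem & (df["eggs"].isna() | df["red"].notna() | df["total"].notna())
    if bad.any():
        raise RecordError(
            f"{int(bad.sum())} female row(s) without eggs or with red/total populated "
            f"(first at row {int(np.flatnonzero(bad)[0])})"
        )
    bad = ~fem & (df["eggs"].notna() | df["red"].isna() | df["total"].isna())
    if bad.any():
        raise RecordError(
            f"{int(bad.sum())} male row(s) without red/total or with eggs populated "
            f"(first at row {int(np.flatnonzero(bad)[0])})"
        )
    if (fem & (df["eggs"] < 0)).any():
        raise RecordError("negative egg count")
    if (~fem & ((df["red"] < 0) | (df["total"] < 0))).any():
        raise RecordError("negative progeny count")
    bad_zero = ~fem & (df["total"] == 0) & (df["red"] > 0)
    if bad_zero.any():
        raise RecordError(
            f"{int(bad_zero.sum())} male row(s) with red > 0 but total = 0 "
            "(zero-denominator proportion)"
        )
    over = ~fem & (df["red"] > df["total"])
    if over.any():
        raise RecordError(f"red > total in {int(over.sum())} male row(s)")

    zero = ~fem & (df["total"] == 0)
    if zero.any():
        if not drop_zero_total:
            raise RecordError(
                f"{int(zero.sum())} male row(s) with total = 0 (zero-denominator proportion)"
            )
        logger.warning(
            "dropping %d male vial(s) with zero scored progeny (undefined proportion)",
            int(zero.sum()),
        )
        df = df[~zero]
    return FitnessTable(df)


def write_fitness_table(table: FitnessTable, path) -> None:
    """Write the long-format CSV (round-trips exactly through read)."""
    table.df.to_csv(path, index=False, columns=CSV_COLUMNS)


def validate(table: FitnessTable) -> ValidationReport:
    """Check every table invariant; violations are data, not exceptions.

    Checks: key uniqueness of (line, sex, sex_ratio, day, vial); day labels
    nested within a single sex x sex-ratio cell; measure/sex consistency;
    red <= total.
    """
    df = table.df
    violations: list[str] = []

    key = ["line", "sex", "sex_ratio", "day", "vial"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        for _, grp in df[dup].groupby(key, sort=False):
            violations.append(
                "duplicate record key " + "/".join(str(v) for v in grp.iloc[0][key])
            )

    cells_per_day = df.groupby("day")[["sex", "sex_ratio"]].nunique()
    for day, row in cells_per_day.iterrows():
        if row["sex"] > 1 or row["sex_ratio"] > 1:
            violations.append(f"day {day!r} spans more than one sex x sex_ratio cell")

    fem = df["sex"] == "F"
    n_bad_f = int((fem & (df["eggs"].isna() | df["red"].notna() | df["total"].notna())).sum())
    if n_bad_f:
        violations.append(f"{n_bad_f} female record(s) with missing eggs or male counts set")
    n_bad_m = int((~fem & (df["eggs"].notna() | df["red"].isna() | df["total"].isna())).sum())
    if n_bad_m:
        violations.append(f"{n_bad_m} male record(s) with missing counts or eggs set")
    n_over = int((~fem & (df["red"] > df["total"])).sum())
    if n_over:
        violations.append(f"{n_over} male record(s) with red > total")
    n_zero = int((~fem & (df["total"] == 0)).sum())
    if n_zero:
        violations.append(f"{n_zero} male record(s) with total = 0")

    counts = (
        df.groupby(["line", "sex", "sex_ratio", "day"], sort=False)
        .size()
        .rename("n_vials")
        .reset_index()
    )
    return ValidationReport(
        n_records=len(df),
        n_lines=len(table.lines),
        cell_vial_counts=counts,
        violations=violations,
    )
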