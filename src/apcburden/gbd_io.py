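"""Read and write burden tables in the GBD-results comma-separated dialect.

The dialect is long format with columns
``measure, location, sex, age, cause, rei, metric, year, val, upper, lower``
(UTF-8, "." decimal separator).  ``metric="rate"`` values are per 100,000
person-years; ``metric="number"`` values are event counts.  Age-group labels
are closed integer ranges ``"X to Y"`` plus a terminal open group
``"Z plus"``.

Also provided: standard-population weight tables (with a builtin world
standard), population (person-years) grids, and conversion of a burden
table into a :class:`~apcburden.lexis.LexisGrid`.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .lexis import LexisGrid

__all__ = [
    "BurdenTable",
    "StandardPopulation",
    "PopulationGrid",
    "SchemaError",
    "ValidationError",
    "parse_age_group",
    "age_sort_key",
    "read_burden_table",
    "write_burden_table",
    "read_standard_population",
    "read_population_grid",
    "write_population_grid",
    "to_lexis_grid",
]

GBD_COLUMNS = [
    "measure",
    "location",
    "sex",
    "age",
    "cause",
    "rei",
    "metric",
    "year",
    "val",
    "upper",
    "lower",
]
KEY_COLUMNS = ["measure", "location", "sex", "age", "rei", "metric", "year"]
MEASURES = {"incidence", "deaths", "DALYs", "prevalence"}
METRICS = {"number", "rate"}
SEXES = {"male", "female", "both"}

_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A file does not carry the columns the dialect requires."""


class ValidationError(ValueError):
    """A record violates a table invariant."""


def parse_age_group(label: str) -> tuple[int, int | None]:
    """Parse ``"X to Y"`` into (X, Y) and ``"Z plus"`` into (Z, None)."""
    label = str(label).strip()
    m = re.fullmatch(r"(\d+)\s+to\s+(\d+)", label)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise ValidationError(f"age group {label!r} has upper bound below lower")
        return lo, hi
    m = re.fullmatch(r"(\d+)\s+plus", label)
    if m:
        return int(m.group(1)), None
    raise ValidationError(f"cannot parse age-group label {label!r} (expect 'X to Y' or 'Z plus')")


def age_sort_key(label: str) -> int:
    return parse_age_group(label)[0]


@dataclasses.dataclass
class BurdenTable:
    """Long-format burden records in the GBD-results dialect.

    Wraps a :class:`pandas.DataFrame` with the dialect columns; extra
    columns are preserved untouched.  Invariants (checked on construction):
    ``lower <= val <= upper`` per record, and the key
    (measure, location, sex, age, rei, metric, year) is unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in GBD_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["year"] = df["year"].astype(int)
        for c in ("val", "upper", "lower"):
            df[c] = df[c].astype(float)
        df["rei"] = df["rei"].fillna("")
        bad_measure = set(df["measure"]) - MEASURES
        if bad_measure:
            raise ValidationError(f"unknown measure value(s): {sorted(bad_measure)}")
        bad_metric = set(df["metric"]) - METRICS
        if bad_metric:
            raise ValidationError(f"unknown metric value(s): {sorted(bad_metric)}")
        bad_sex = set(df["sex"]) - SEXES
        if bad_sex:
            raise ValidationError(f"unknown sex value(s): {sorted(bad_sex)}")
        for label in df["age"].unique():
            parse_age_group(label)
        if np.any(df["val"] < 0):
            raise ValidationError("negative burden value(s)")
        bad = ~((df["lower"] <= df["val"]) & (df["val"] <= df["upper"]))
        if bad.any():
            key = df.loc[bad.idxmax(), KEY_COLUMNS].tolist()
            raise ValidationError(f"value outside [lower, upper] for record {key}")
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            key = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
            raise ValidationError(f"duplicate record key {key}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def select(self, **where: str | int) -> pd.DataFrame:
        """Records matching equality conditions on dialect columns."""
        df = self.data
        for col, value in where.items():
            df = df[df[col] == value]
        return df


@dataclasses.dataclass
class StandardPopulation:
    """Age-group weights of a standard population (arbitrary scale).

    Weights are kept unnormalized; normalization happens inside
    :func:`apcburden.metrics.compute_asr`, which is invariant to positive
    rescaling.
    """

    age_groups: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.age_groups) != self.weights.size:
            raise ValueError("age_groups and weights must have equal length")
        if np.any(self.weights < 0) or np.any(~np.isfinite(self.weights)):
            raise ValidationError("standard-population weights must be finite and nonnegative")
        if not np.any(self.weights > 0):
            raise ValidationError("standard population must have at least one positive weight")
        bounds = [parse_age_group(g) for g in self.age_groups]
        order = np.argsort([b[0] for b in bounds])
        bounds = [bounds[i] for i in order]
        for (lo1, hi1), (lo2, _) in zip(bounds[:-1], bounds[1:]):
            if hi1 is None:
                raise ValidationError("open age group must be terminal")
            if hi1 + 1 != lo2:
                raise ValidationError(
                    f"age groups not contiguous: gap/overlap between bound {hi1} and {lo2}"
                )

    def as_mapping(self) -> Mapping[str, float]:
        return dict(zip(self.age_groups, self.weights))

    def collapse_to(self, age_groups: Iterable[str]) -> "StandardPopulation":
        """Aggregate weights onto a coarser, contiguous set of age groups.

        Each target group receives the summed weight of the source groups
        whose bounds it contains (a terminal open target absorbs every
        source group from its lower bound up).
        """
        targets = list(age_groups)
        out = np.zeros(len(targets))
        src = [(parse_age_group(g), w) for g, w in zip(self.age_groups, self.weights)]
        assigned = np.zeros(len(src), dtype=bool)
        for j, tg in enumerate(targets):
            lo, hi = parse_age_group(tg)
            for i, ((slo, shi), w) in enumerate(src):
                if slo >= lo and (hi is None or (shi is not None and shi <= hi)):
                    out[j] += w
                    assigned[i] = True
        if not assigned.all():
            left = [self.age_groups[i] for i in np.where(~assigned)[0]]
            raise ValidationError(f"source age group(s) not covered by targets: {left}")
        return StandardPopulation(age_groups=targets, weights=out)


@dataclasses.dataclass
class PopulationGrid:
    """Person-years n[a, t] over A age groups x T calendar years."""

    person_years: np.ndarray
    age_groups: list[str]
    years: np.ndarray

    def __post_init__(self) -> None:
        self.person_years = np.asarray(self.person_years, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        A, T = self.person_years.shape
        if len(self.age_groups) != A or self.years.shape != (T,):
            raise ValueError("person_years shape must match age_groups x years")
        if np.any(self.person_years <= 0) or np.any(~np.isfinite(self.person_years)):
            raise ValidationError("person-years must be finite and strictly positive")


def read_burden_table(path: str | Path, dialect: str = "gbd") -> BurdenTable:
    """Read a comma-separated burden table; unknown columns are preserved."""
    if dialect != "gbd":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return BurdenTable(df)


def write_burden_table(table: BurdenTable, path: str | Path) -> None:
    """Write a burden table deterministically (sorted rows, %.10g floats)."""
    df = table.data.copy()
    df["_age_lo"] = df["age"].map(age_sort_key)
    df = df.sort_values(
        ["measure", "location", "sex", "rei", "metric", "year", "_age_lo"],
        kind="mergesort",
    ).drop(columns="_age_lo")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_standard_population(source: str | Path = "world_standard") -> StandardPopulation:
    """Load a standard population from a CSV path or a builtin name.

    The builtin ``"world_standard"`` is the WHO 2000-2025 world standard age
    distribution on 20 five-year groups (terminal ``95 plus``).
    """
    if isinstance(source, str) and source == "world_standard":
        ref = importlib.resources.files("apcburden.data") / "world_standard_population.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path)
        if df.empty:
            raise ValidationError(f"standard-population file {path} is empty")
    for col in ("age_group", "weight"):
        if col not in df.columns:
            raise SchemaError(f"missing required column(s): {col}")
    return StandardPopulation(
        age_groups=df["age_group"].astype(str).tolist(),
        weights=df["weight"].to_numpy(dtype=float),
    )


def read_population_grid(path: str | Path) -> PopulationGrid:
    """Read person-years from long CSV with columns age_group, year, person_years."""
    df = pd.read_csv(path)
    for col in ("age_group", "year", "person_years"):
        if col not in df.columns:
            raise SchemaError(f"missing required column(s): {col}")
    ages = sorted(df["age_group"].unique(), key=age_sort_key)
    years = np.sort(df["year"].unique())
    pivot = df.pivot(index="age_group", columns="year", values="person_years")
    pivot = pivot.loc[ages, years]
    if pivot.isna().any().any():
        raise ValidationError("population grid has missing (age_group, year) cells")
    return PopulationGrid(pivot.to_numpy(dtype=float), list(ages), years)


def write_population_grid(pop: PopulationGrid, path: str | Path) -> None:
    rows = []
    for i, g in enumerate(pop.age_groups):
        for j, yr in enumerate(pop.years):
            rows.append((g, int(yr), pop.person_years[i, j]))
    df = pd.DataFrame(rows, columns=["age_group", "year", "person_years"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def to_lexis_grid(
    table: BurdenTable,
    population: PopulationGrid,
    measure: str,
    location: str,
    sex: str,
    *,
    metric: str = "number",
    age_width: int = 5,
    allow_missing: bool = False,
) -> LexisGrid:
    """Align a burden table's counts with a population grid into a Lexis grid.

    With ``metric="number"`` the table values are used as counts directly;
    with ``metric="rate"`` counts are reconstructed as rate * n / 100000.
    Missing (age_group, year) cells raise an error naming them unless
    ``allow_missing`` is set, in which case they become NaN.
    """
    df = table.select(measure=measure, location=location, sex=sex, metric=metric, rei="")
    ages = population.age_groups
    years = population.years
    y = np.full((len(ages), len(years)), np.nan)
    sub = df.set_index(["age", "year"])["val"]
    missing: list[tuple[str, int]] = []
    for i, g in enumerate(ages):
        for j, yr in enumerate(years):
            try:
                y[i, j] = sub.loc[(g, int(yr))]
            except KeyError:
                missing.append((g, int(yr)))
    if missing and not allow_missing:
        shown = ", ".join(f"({g}, {yr})" for g, yr in missing[:10])
        more = "" if len(missing) <= 10 else f" and {len(missing) - 10} more"
        raise ValidationError(f"missing cell(s): {shown}{more}")
    if metric == "rate":
        y = y * population.person_years / 1e5
    if allow_missing:
        y = np.where(np.isnan(y), 0.0, y)
    return LexisGrid(
        counts=y,
        person_years=population.person_years,
        age_groups=list(ages),
        years=years,
        age_width=age_width,
    )
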