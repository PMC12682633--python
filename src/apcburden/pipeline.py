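"""End-to-end orchestration: descriptive analysis and projections.

``run_burden_analysis`` reads a GBD-dialect burden table and emits per-
stratum ASR series, EAPC estimates, attributable burden (when a PAF table
is configured) and SDI quintile assignments (when an SDI table is
configured).  ``run_projection`` converts counts to Lexis grids per
(measure, sex) stratum, fits the Bayesian APC model, projects the
configured horizon, and optionally back-tests at a split year.  Strata are
fit independently; the "both" sex stratum is the fit of pooled counts, not
an average of sex-specific forecasts.  Every run writes a manifest
recording inputs, seed and library versions; reruns of the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .forecast import forecast
from .gbd_io import (
    BurdenTable,
    PopulationGrid,
    StandardPopulation,
    age_sort_key,
    read_burden_table,
    read_population_grid,
    read_standard_population,
    to_lexis_grid,
)
from .lexis import LexisGrid
from .metrics import attributable_table, compute_asr, compute_eapc, stratify_by_sdi
from .model import APCModelSpec, Covariate, fit_apc
from .validation import backtest

__all__ = ["RunConfig", "run_burden_analysis", "run_projection"]

_FLOAT_FMT = "%.10g"
_QUANTITY = {"incidence": "asir", "deaths": "asmr", "DALYs": "asdr", "prevalence": "aspr"}


@dataclasses.dataclass
class RunConfig:
    """Configuration of a pipeline run (loadable from YAML)."""

    burden_path: str
    out_dir: str
    population_path: str | None = None
    paf_path: str | None = None
    sdi_path: str | None = None
    standard_population: str = "world_standard"
    measures: list[str] | None = None
    locations: list[str] | None = None
    sexes: list[str] | None = None
    pooled_sex: bool = True
    model: dict[str, Any] = dataclasses.field(default_factory=dict)
    split_year: int | None = None
    horizon: int = 30
    scenario: str = "hold"
    seed: int = 0
    age_width: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def model_spec(self) -> APCModelSpec:
        kwargs = dict(self.model)
        covs = kwargs.pop("covariates", [])
        built = []
        for c in covs:
            if isinstance(c, Covariate):
                built.append(c)
            else:
                df = pd.read_csv(c["path"])
                built.append(
                    Covariate.from_series(
                        c.get("name", Path(c["path"]).stem),
                        df["year"],
                        df["value"],
                        scenario=c.get("scenario", self.scenario),
                        coefficient=c.get("coefficient"),
                    )
                )
        kwargs.setdefault("seed", self.seed)
        return APCModelSpec(covariates=tuple(built), **kwargs)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _manifest(config: RunConfig, out_dir: Path, stage: str, extra: dict | None = None) -> None:
    payload = {
        "stage": stage,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "versions": {
            "apcburden": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    if extra:
        payload.update(extra)
    (out_dir / f"manifest_{stage}.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n"
    )


def _strata(table: BurdenTable, config: RunConfig):
    df = table.data
    measures = config.measures or sorted(df["measure"].unique())
    locations = config.locations or sorted(df["location"].unique())
    sexes = config.sexes or sorted(df["sex"].unique())
    for m in measures:
        for loc in locations:
            for s in sexes:
                yield m, loc, s


def _asr_table(table: BurdenTable, std: StandardPopulation, config: RunConfig) -> pd.DataFrame:
    """Per-stratum, per-year ASR from metric=rate records."""
    rows = []
    for measure, loc, sex in _strata(table, config):
        sub = table.select(measure=measure, location=loc, sex=sex, metric="rate", rei="")
        if sub.empty:
            continue
        ages = sorted(sub["age"].unique(), key=age_sort_key)
        w = std.collapse_to(ages) if std.age_groups != ages else std
        pivot = sub.pivot(index="age", columns="year", values="val").loc[ages]
        for year in pivot.columns:
            rates = pivot[year].to_numpy() / 1e5  # dialect rates are per 100,000
            rows.append((measure, loc, sex, int(year), "asr", compute_asr(rates, w)))
    return pd.DataFrame(
        rows, columns=["measure", "location", "sex", "year", "quantity", "value"]
    )


def run_burden_analysis(config: RunConfig) -> dict[str, Path]:
    """Descriptive layer: ASR series, EAPC, attribution, SDI quintiles."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = read_burden_table(config.burden_path)
    std = read_standard_population(config.standard_population)
    outputs: dict[str, Path] = {}

    asr = _asr_table(table, std, config)
    if asr.empty:
        raise ValueError("no metric=rate records matched the configured strata")
    path = out_dir / "asr_series.csv"
    _write_csv(asr, path)
    outputs["asr_series"] = path

    eapc_rows = []
    for (measure, loc, sex), g in asr.groupby(["measure", "location", "sex"], sort=True):
        if len(g) < 3 or (g["value"] <= 0).any():
            continue
        r = compute_eapc(g.rename(columns={"value": "asr"})[["year", "asr"]])
        eapc_rows.append((measure, loc, sex, r.eapc, r.ci_lower, r.ci_upper, r.slope, r.slope_se))
    eapc = pd.DataFrame(
        eapc_rows,
        columns=["measure", "location", "sex", "eapc", "ci_lower", "ci_upper", "slope", "slope_se"],
    )
    path = out_dir / "eapc.csv"
    _write_csv(eapc, path)
    outputs["eapc"] = path

    if config.paf_path:
        paf = pd.read_csv(config.paf_path)
        burden = table.data[table.data["rei"] == ""].rename(
            columns={"age": "age_group", "val": "value"}
        )
        att = attributable_table(burden, paf)
        att = att.sort_values(
            ["measure", "location", "sex", "risk", "metric", "year", "age_group"],
            kind="mergesort",
        )
        path = out_dir / "attributable.csv"
        _write_csv(att, path)
        outputs["attributable"] = path

    if config.sdi_path:
        sdi = pd.read_csv(config.sdi_path)
        quintiles = stratify_by_sdi(dict(zip(sdi["location"], sdi["sdi"])))
        qdf = pd.DataFrame(sorted(quintiles.items()), columns=["location", "sdi_quintile"])
        path = out_dir / "sdi_quintiles.csv"
        _write_csv(qdf, path)
        outputs["sdi_quintiles"] = path

    _manifest(config, out_dir, "analyze", {"records": len(table)})
    outputs["manifest"] = out_dir / "manifest_analyze.json"
    return outputs


def _pooled_grid(table, pop, measure, loc, age_width) -> LexisGrid:
    """Pool male+female counts when no 'both' records exist."""
    grids = [
        to_lexis_grid(table, pop, measure, loc, s, age_width=age_width)
        for s in ("male", "female")
    ]
    return LexisGrid(
        counts=grids[0].counts + grids[1].counts,
        person_years=grids[0].person_years + grids[1].person_years,
        age_groups=grids[0].age_groups,
        years=grids[0].years,
        age_width=age_width,
    )


def run_projection(config: RunConfig) -> dict[str, Path]:
    """Fit and project each (measure, location, sex) stratum; optional back-test."""
    if config.population_path is None:
        raise ValueError("projection needs a population_path (person-years grid)")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = read_burden_table(config.burden_path)
    pop = read_population_grid(config.population_path)
    std = read_standard_population(config.standard_population)
    spec = config.model_spec()
    rows = []
    bt_frames = []
    present_sexes = set(table.data["sex"].unique())
    for measure, loc, sex in _strata(table, config):
        if sex == "both" and "both" not in present_sexes and config.pooled_sex:
            grid = _pooled_grid(table, pop, measure, loc, config.age_width)
        else:
            sub = table.select(measure=measure, location=loc, sex=sex, metric="number")
            if sub.empty:
                continue
            grid = to_lexis_grid(table, pop, measure, loc, sex, age_width=config.age_width)
        fit = fit_apc(grid, spec)
        fc = forecast(fit, config.horizon, standard_population=std)
        quantity = _QUANTITY.get(measure, "asr")
        for _, r in fc.summary.iterrows():
            rows.append(
                (measure, loc, sex, quantity, int(r["year"]), r["asr"], r["lower"], r["upper"])
            )
        if config.split_year is not None:
            report = backtest(grid, spec, config.split_year, standard_population=std)
            bt_frames.append(report.to_frame(stratum=f"{measure}|{loc}|{sex}"))
    if not rows:
        raise ValueError("no strata matched the configured selection")
    fdf = pd.DataFrame(
        rows,
        columns=["measure", "location", "sex", "quantity", "year", "val", "lower", "upper"],
    ).sort_values(["measure", "location", "sex", "year"], kind="mergesort")
    outputs: dict[str, Path] = {}
    path = out_dir / "forecast.csv"
    _write_csv(fdf, path)
    outputs["forecast"] = path
    if bt_frames:
        bt = pd.concat(bt_frames, ignore_index=True)
        path = out_dir / "backtest.csv"
        _write_csv(bt, path)
        outputs["backtest"] = path
    _manifest(
        config,
        out_dir,
        "project",
        {"horizon": config.horizon, "split_year": config.split_year},
    )
    outputs["manifest"] = out_dir / "manifest_project.json"
    return outputs
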