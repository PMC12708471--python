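"""End-to-end orchestration of the four analytical steps.

1. Record observed and smoking-eliminated life-expectancy trends (with
   linear trend slopes) across the roster, per sex.
2. Lag tables for the final analysis year, including the pseudo-country
   MEAN built from the unweighted average of age-specific death rates
   across countries.
3. Lag-change table between the two analysis years.
4. Age-specific lag grids (observed and eliminated variants, both sexes)
   against the smoothed record-holder death-rate series.

All results are written as CSV plus a machine-readable JSON-lines run log;
reruns with the same config and seed are byte-identical.
"""
from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agegrid import CANONICAL
from .attribution import (eliminate_smoking, load_beta, load_never_smoker,
                          saf_surface)
from .io import SEXES, CauseSurface, MortalitySurface, read_tidy
from .lag import (RecordTrend, age_lag_grid, build_record_trend, lag_change,
                  lag_table, record_rate_series, trend_slope)
from .lifetable import e0_surface, lifetable_surface
from .smoothing import RateSurface, smooth_lung_rates
from .synth import SyntheticScenario, generate_surface

KEYS = ["country", "sex", "year", "age_start"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    scenario: str | None = None        # synthetic-scenario YAML path
    tidy_input: str | None = None      # canonical tidy CSV path
    outdir: str = "results"
    analysis_years: tuple = (2000, 2019)
    never_smoker_path: str | None = None
    beta_path: str | None = None
    k_age: int = 10
    k_year: int = 10
    no_smooth: bool = False            # raw-rate passthrough (testing)
    no_smoking: bool = False           # force SAF to 0 (ablation)
    mode: str = "expected"             # synthetic count mode
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "analysis_years" in doc:
            doc["analysis_years"] = tuple(doc["analysis_years"])
        return cls(**doc)


@dataclass
class PipelineResult:
    """In-memory bundle of every table the pipeline writes."""

    e0_observed: pd.DataFrame
    e0_eliminated: pd.DataFrame
    saf: pd.DataFrame
    record_trends: pd.DataFrame
    trend_slopes: pd.DataFrame
    lag_tables: dict            # year -> DataFrame (both sexes stacked)
    lag_changes: pd.DataFrame
    age_grids: dict             # (variant, sex) -> DataFrame
    rates: pd.DataFrame         # per-cell observed + eliminated rates
    outdir: Path | None = None


def _load_inputs(cfg: RunConfig):
    if cfg.scenario is not None:
        scenario = SyntheticScenario.from_yaml(cfg.scenario)
        scenario.seed = cfg.seed
        mortality, cause, _ = generate_surface(scenario, mode=cfg.mode)
        return mortality, cause
    if cfg.tidy_input is not None:
        mortality, cause = read_tidy(cfg.tidy_input)
        if cause is None:
            raise ValueError("tidy input lacks a lung_deaths column")
        return mortality, cause
    raise ValueError("config must set either 'scenario' or 'tidy_input'")


def _raw_lung_rates(cause: CauseSurface, mortality: MortalitySurface) -> RateSurface:
    """Raw-rate passthrough used by --no-smooth."""
    d = mortality.data.merge(cause.data, on=KEYS, how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where((d["exposures"] > 0) & d["lung_deaths"].notna(),
                        d["lung_deaths"].fillna(0.0) / d["exposures"], 0.0)
    out = d[KEYS].copy()
    out["rate"] = rate
    out["observed"] = d["lung_deaths"].notna()
    return RateSurface(out)


def _mean_pseudo_country(rates: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of age-specific rates across countries, labelled MEAN."""
    g = (rates.groupby(["sex", "year", "age_start"], as_index=False)
         [["rate", "rate_eliminated"]].mean())
    g.insert(0, "country", "MEAN")
    return g


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis described in the module docstring."""
    log_records = [{"stage": "start", "config": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in cfg.__dict__.items()},
        "versions": {"mortlag": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "python": platform.python_version()},
    }]

    mortality, cause = _load_inputs(cfg)
    cause.check_against(mortality)
    year_lo, year_hi = int(mortality.years.min()), int(mortality.years.max())
    for y in cfg.analysis_years:
        if not year_lo <= y <= year_hi:
            raise ValueError(f"analysis year {y} outside data span "
                             f"{year_lo}-{year_hi}")
    log_records.append({"stage": "inputs", "countries": mortality.countries,
                        "years": [year_lo, year_hi]})

    # --- smoking-eliminated rates -----------------------------------------
    if cfg.no_smooth:
        lung_rates = _raw_lung_rates(cause, mortality)
    else:
        lung_rates = smooth_lung_rates(cause, mortality, k_age=cfg.k_age,
                                       k_year=cfg.k_year)
    ns = load_never_smoker(cfg.never_smoker_path)
    bt = load_beta(cfg.beta_path)
    saf = saf_surface(mortality, lung_rates, never_smoker=ns, beta_table=bt)
    if cfg.no_smoking:
        saf.data[["A_lung", "A_other", "A_total"]] = 0.0
    rates = eliminate_smoking(mortality.rates(), saf)
    log_records.append({"stage": "attribution",
                        "mean_A_total": float(saf.data["A_total"].mean())})

    # --- life expectancy, records, lags -----------------------------------
    rates_all = pd.concat([rates[KEYS + ["rate", "rate_eliminated"]],
                           _mean_pseudo_country(rates)], ignore_index=True)
    e0_obs = e0_surface(rates_all, "rate")
    e0_eli = e0_surface(rates_all, "rate_eliminated")

    trends, slopes = [], []
    ref_by_sex: dict = {}
    for sex in SEXES:
        obs = e0_obs[(e0_obs["sex"] == sex) & (e0_obs["country"] != "MEAN")]
        eli = e0_eli[(e0_eli["sex"] == sex) & (e0_eli["country"] != "MEAN")]
        t_obs = build_record_trend(obs)
        t_eli = build_record_trend(eli)
        ref_by_sex[sex] = t_eli
        for variant, tr in (("observed", t_obs), ("eliminated", t_eli)):
            trends.append(pd.DataFrame({
                "sex": sex, "variant": variant, "year": tr.years,
                "value": tr.value, "holder": tr.holder,
                "monotone_value": tr.monotone}))
            s, r2 = trend_slope(tr.value, tr.years)
            slopes.append({"sex": sex, "variant": variant,
                           "slope_per_decade": s, "r_squared": r2})
    record_trends = pd.concat(trends, ignore_index=True)
    trend_slopes = pd.DataFrame(slopes)
    log_records.append({"stage": "record_trends",
                        "slopes": trend_slopes.to_dict("records")})

    lag_tables = {}
    for year in cfg.analysis_years:
        per_sex = []
        for sex in SEXES:
            tab = lag_table(e0_obs[e0_obs["sex"] == sex],
                            e0_eli[e0_eli["sex"] == sex], year, ref_by_sex[sex])
            tab.insert(1, "sex", sex)
            per_sex.append(tab)
        lag_tables[year] = pd.concat(per_sex, ignore_index=True)
    final_year = cfg.analysis_years[-1]
    changes = []
    for sex in SEXES:
        a = lag_tables[cfg.analysis_years[0]]
        b = lag_tables[final_year]
        ch = lag_change(a[a["sex"] == sex], b[b["sex"] == sex])
        ch.insert(1, "sex", sex)
        changes.append(ch)
    lag_changes = pd.concat(changes, ignore_index=True)

    # countries ordered by the lag in observed life expectancy, final year
    order = (lag_tables[final_year].groupby("country")["lag_observed"].mean()
             .sort_values().index.tolist())
    for year in lag_tables:
        lag_tables[year] = (lag_tables[year]
                            .assign(_o=lambda d: d["country"].map(order.index))
                            .sort_values(["sex", "_o"]).drop(columns="_o")
                            .reset_index(drop=True))
    lag_changes = (lag_changes.assign(_o=lambda d: d["country"].map(order.index))
                   .sort_values(["sex", "_o"]).drop(columns="_o")
                   .reset_index(drop=True))
    log_records.append({"stage": "lags", "country_order": order})

    # --- age-specific lag grids -------------------------------------------
    age_grids = {}
    final_rates = rates_all[rates_all["year"] == final_year]
    for sex in SEXES:
        elim_lt = rates_all[(rates_all["sex"] == sex)
                            & (rates_all["country"] != "MEAN")]
        elim_lt = elim_lt.rename(columns={"rate_eliminated": "m"})
        ref_series = record_rate_series(ref_by_sex[sex],
                                        elim_lt[["country", "year", "age_start", "m"]])
        sub = final_rates[(final_rates["sex"] == sex)
                          & (final_rates["country"] != "MEAN")]
        grid = age_lag_grid(
            sub[["country", "age_start", "rate"]],
            sub[["country", "age_start", "rate_eliminated"]]
            .rename(columns={"rate_eliminated": "rate"}),
            ref_series, final_year)
        grid = (grid.assign(_o=lambda d: d["country"].map(order.index))
                .sort_values(["variant", "_o", "age_start"]).drop(columns="_o")
                .reset_index(drop=True))
        for variant in ("observed", "eliminated"):
            age_grids[(variant, sex)] = grid[grid["variant"] == variant]
    log_records.append({"stage": "age_grids", "done": True})

    result = PipelineResult(
        e0_observed=e0_obs, e0_eliminated=e0_eli, saf=saf.data,
        record_trends=record_trends, trend_slopes=trend_slopes,
        lag_tables=lag_tables, lag_changes=lag_changes, age_grids=age_grids,
        rates=rates_all)

    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_outputs(result, outdir, cfg, log_records)
        result.outdir = outdir
    return result


def _round_lags(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for c in df.columns:
        if c.startswith(("lag", "delta", "smoking_contribution", "equivalent_year")):
            df[c] = df[c].round(1)
    return df


def _write_outputs(result: PipelineResult, outdir: Path, cfg: RunConfig,
                   log_records: list) -> None:
    result.e0_observed.to_csv(outdir / "e0_observed.csv", index=False)
    result.e0_eliminated.to_csv(outdir / "e0_eliminated.csv", index=False)
    result.saf.to_csv(outdir / "saf.csv", index=False)
    result.rates.to_csv(outdir / "rates.csv", index=False)
    result.record_trends.to_csv(outdir / "record_trends.csv", index=False)
    result.trend_slopes.to_csv(outdir / "trend_slopes.csv", index=False)
    for year, tab in result.lag_tables.items():
        _round_lags(tab).to_csv(outdir / f"lags_{year}.csv", index=False)
    _round_lags(result.lag_changes).to_csv(outdir / "lag_changes.csv", index=False)
    short = {"observed": "obs", "eliminated": "elim"}
    for (variant, sex), grid in result.age_grids.items():
        _round_lags(grid).to_csv(
            outdir / f"age_lag_grid_{short[variant]}_{sex}.csv", index=False)
    with open(outdir / "run_log.jsonl", "w") as fh:
        for rec in log_records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
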