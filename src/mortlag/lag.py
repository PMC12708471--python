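"""Record (benchmark) trends and time-lag estimation.

The time lag answers: "how many calendar years back along the reference
trend do we have to go to find a value equivalent to this country's current
value?" The reference is the record trend — the best value across the
country roster in each year (highest for life expectancy, lowest for death
rates). Before inversion the trend is replaced by its monotone envelope
(running best), which guarantees a unique equivalent year; plateaus invert
to their latest year, the most favorable (smallest-lag) choice.

Values at or beyond the envelope's current best are censored "at_or_better"
(lag ≤ 0); values worse than the envelope's earliest value are censored
"beyond_range" (lag at least the full span, rendered as e.g. "69≤" for a
1950–2019 reference).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoothing import smooth_reference_series

#: Decimal places used when rendering lags in output tables.
LAG_DECIMALS = 1


@dataclass
class RecordTrend:
    """Per-year benchmark value, record-holder label and monotone envelope."""

    years: np.ndarray
    value: np.ndarray
    holder: np.ndarray | None
    direction: str  # "increasing" (e0) or "decreasing" (death rates)

    def __post_init__(self):
        self.years = np.asarray(self.years)
        self.value = np.asarray(self.value, dtype=float)
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"direction must be increasing/decreasing, "
                             f"got {self.direction!r}")
        if len(self.years) != len(self.value):
            raise ValueError("years and values differ in length")
        if self.direction == "increasing":
            self.monotone = np.maximum.accumulate(self.value)
        else:
            self.monotone = np.minimum.accumulate(self.value)

    @property
    def span(self) -> int:
        return int(self.years[-1] - self.years[0])


@dataclass
class LagEstimate:
    """Lag in calendar years, the equivalent year, and a censoring flag."""

    lag: float
    equivalent_year: float
    censored: str  # "none", "at_or_better", "beyond_range"

    def label(self, span: int) -> str:
        if self.censored == "at_or_better":
            return "≤0"  # ≤0
        if self.censored == "beyond_range":
            return f"{span}≤"  # e.g. 69≤
        return f"{self.lag:.{LAG_DECIMALS}f}"


def build_record_trend(e0: pd.DataFrame, direction: str = "increasing",
                       value_col: str = "e0") -> RecordTrend:
    """Record trend of the best value per year across countries.

    ``e0`` carries columns country, year and ``value_col``. Ties are broken
    by the first country in alphabetical order. Every year must be present
    for every country.
    """
    wide = e0.pivot_table(index="year", columns="country", values=value_col)
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"missing country values in years {missing[:5]}")
    years = wide.index.to_numpy()
    gaps = sorted(set(range(int(years.min()), int(years.max()) + 1)) - set(years))
    if gaps:
        raise ValueError(f"missing years in e0 input: {gaps[:5]}")
    cols = sorted(wide.columns)  # alphabetical tie-break via stable argmax
    arr = wide[cols].to_numpy()
    idx = np.argmax(arr, axis=1) if direction == "increasing" else np.argmin(arr, axis=1)
    value = arr[np.arange(len(years)), idx]
    holder = np.array([cols[i] for i in idx])
    return RecordTrend(years=years, value=value, holder=holder, direction=direction)


def estimate_lag(ref: RecordTrend, value: float, query_year: float) -> LagEstimate:
    """Lag of ``value`` at ``query_year`` behind the reference trend.

    The equivalent year is found by linear inverse interpolation of the
    monotone envelope; censoring follows the open bins described in the
    module docstring.
    """
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    sign = 1.0 if ref.direction == "increasing" else -1.0
    R = sign * ref.monotone
    if np.any(np.diff(R) < 0):  # pragma: no cover - construction guarantees this
        raise ValueError("monotone envelope is not monotone (construction bug)")
    v = sign * value
    years = ref.years.astype(float)

    if v >= R[-1]:
        return LagEstimate(lag=float(query_year - years[-1]),
                           equivalent_year=float(years[-1]),
                           censored="at_or_better")
    if v < R[0]:
        return LagEstimate(lag=float(query_year - years[0]),
                           equivalent_year=float(years[0]),
                           censored="beyond_range")
    # last index with R[i] <= v; plateaus therefore invert to their latest year
    i = int(np.searchsorted(R, v, side="right")) - 1
    if R[i] == v:
        eq = years[i]
    else:
        eq = years[i] + (v - R[i]) / (R[i + 1] - R[i]) * (years[i + 1] - years[i])
    return LagEstimate(lag=float(query_year - eq), equivalent_year=float(eq),
                       censored="none")


def record_rate_series(trend: RecordTrend, lifetables: pd.DataFrame,
                       smooth: bool = True) -> pd.DataFrame:
    """Age-specific death-rate series of the annual record holders.

    For each canonical age group, takes the ``m`` column from each year's
    record-holder lifetable (``lifetables``: columns country, year,
    age_start, m, for one sex) and, by default, smooths each series over
    year. Returns a frame indexed by year with one column per age_start.
    """
    if trend.holder is None:
        raise ValueError("record trend carries no holder labels")
    key = lifetables.set_index(["country", "year", "age_start"])["m"]
    recs = {}
    for age in sorted(lifetables["age_start"].unique()):
        vals = []
        for year, holder in zip(trend.years, trend.holder):
            try:
                vals.append(key.loc[(holder, year, age)])
            except KeyError:
                raise ValueError(f"missing lifetable for record holder "
                                 f"{holder} in {year} (age {age})")
        series = pd.Series(vals, index=trend.years)
        recs[age] = smooth_reference_series(series) if smooth else series
    return pd.DataFrame(recs)


def lag_table(e0_obs: pd.DataFrame, e0_elim: pd.DataFrame, year: int,
              ref: RecordTrend) -> pd.DataFrame:
    """Per-country lags of observed and smoking-eliminated life expectancy.

    Both inputs carry country, year, e0. The smoking contribution is the
    lag reduction achieved by eliminating smoking,
    ``lag_observed − lag_eliminated``. Rows may include the pseudo-country
    MEAN if the caller added average-rate life expectancies upstream.
    """
    obs = e0_obs[e0_obs["year"] == year].set_index("country")["e0"]
    eli = e0_elim[e0_elim["year"] == year].set_index("country")["e0"]
    countries = sorted(obs.index)
    if sorted(eli.index) != countries:
        raise ValueError("observed and eliminated e0 cover different countries")
    rows = []
    for c in countries:
        lo = estimate_lag(ref, obs[c], year)
        le = estimate_lag(ref, eli[c], year)
        rows.append({
            "country": c, "year": year,
            "e0_observed": obs[c], "e0_eliminated": eli[c],
            "lag_observed": lo.lag, "lag_eliminated": le.lag,
            "equivalent_year_observed": lo.equivalent_year,
            "equivalent_year_eliminated": le.equivalent_year,
            "censored_observed": lo.censored, "censored_eliminated": le.censored,
            "smoking_contribution": lo.lag - le.lag,
        })
    return pd.DataFrame(rows)


def lag_change(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Change in lags between two analysis years (positive = falling behind)."""
    if sorted(table_a["country"]) != sorted(table_b["country"]):
        raise ValueError("lag tables cover different country rosters")
    a = table_a.set_index("country")
    b = table_b.set_index("country")
    out = pd.DataFrame({
        "country": a.index,
        "year_a": a["year"].to_numpy(), "year_b": b.loc[a.index, "year"].to_numpy(),
        "delta_observed": (b.loc[a.index, "lag_observed"] - a["lag_observed"]).to_numpy(),
        "delta_eliminated": (b.loc[a.index, "lag_eliminated"]
                             - a["lag_eliminated"]).to_numpy(),
    })
    return out.reset_index(drop=True)


def age_lag_grid(rates_obs: pd.DataFrame, rates_elim: pd.DataFrame,
                 ref_series: pd.DataFrame, year: int) -> pd.DataFrame:
    """Lag of each country's age-specific death rates behind the reference.

    ``rates_obs``/``rates_elim``: columns country, age_start, rate for the
    query year (one sex). ``ref_series``: year-indexed frame of reference
    death rates per age_start (record-holder series, smoothed). Death rates
    compare in the decreasing direction: lower is better. Returns a long
    frame with numeric lag, censoring flag and the rendered bin label.
    """
    span = int(ref_series.index[-1] - ref_series.index[0])
    rows = []
    for variant, rates in (("observed", rates_obs), ("eliminated", rates_elim)):
        for _, r in rates.iterrows():
            ref = RecordTrend(years=ref_series.index.to_numpy(),
                              value=ref_series[r["age_start"]].to_numpy(),
                              holder=None, direction="decreasing")
            est = estimate_lag(ref, r["rate"], year)
            rows.append({
                "country": r["country"], "age_start": r["age_start"],
                "variant": variant, "rate": r["rate"], "lag": est.lag,
                "equivalent_year": est.equivalent_year,
                "censored": est.censored, "label": est.label(span),
            })
    return pd.DataFrame(rows)


def trend_slope(values, years) -> tuple:
    """OLS slope of a yearly series, in years per decade, plus R².

    Used to summarize record trends; requires at least three points and
    non-degenerate year variance.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(years, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 points for a trend slope")
    if np.var(x) == 0:
        raise ValueError("degenerate year variance")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = np.sum((y - fitted) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope * 10.0), float(r2)
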