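"""Smoking-attributable fractions by the indirect (lung-cancer proxy) method.

The approach uses lung-cancer mortality as a proxy for the accumulated
damage of smoking. Two pieces are combined per (country, sex, age group,
year) cell:

* the attributable fraction of lung-cancer deaths,
  ``A_lung = max(0, (m_lung − λ*) / m_lung)``, where λ* is the lung-cancer
  death rate expected among never-smokers (a CPS-II-style schedule), and
* the attributable fraction of deaths from all other causes,
  ``A_other = 1 − exp(−β · max(0, m_lung − λ*))``, with regression
  coefficients β linking excess lung-cancer mortality to other-cause
  smoking mortality, varying by sex, age group and calendar-period band.

The total fraction averages the two with the observed lung / non-lung death
split, and is forced to zero for age groups entirely below 45, where the
method is not applied. Multiplying observed death rates by (1 − A_total)
yields the counterfactual smoking-eliminated schedule.

The packaged default λ* and β tables (``*_synthetic.csv``) are constructed,
plausible-magnitude illustrations, not transcriptions of any published
coefficient set; replace them with study-specific tables for substantive
use.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .agegrid import CANONICAL, TERMINAL_MIDPOINT_OFFSET
from .io import MortalitySurface
from .smoothing import RateSurface

#: Age (years) below which the smoking-attributable fraction is fixed at 0.
MIN_ATTRIBUTION_AGE = 45


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("mortlag.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_never_smoker(path=None) -> pd.DataFrame:
    """Never-smoker lung-cancer rate schedule (columns sex, age_start, rate)."""
    df = pd.read_csv(path) if path is not None else _packaged(
        "never_smoker_rates_synthetic.csv")
    if (df["rate"] < 0).any():
        raise ValueError("never-smoker rates must be non-negative")
    return df


def load_beta(path=None) -> pd.DataFrame:
    """Other-cause attribution coefficients (sex, age_start, period bands, beta)."""
    df = pd.read_csv(path) if path is not None else _packaged(
        "beta_coefficients_synthetic.csv")
    if not np.isfinite(df["beta"]).all():
        raise ValueError("beta coefficients must be finite")
    return df


def lung_saf(m_lung, lambda_ns):
    """Attributable fraction of lung-cancer deaths.

    Zero when observed lung mortality is at or below the never-smoker
    schedule (negative attributable deaths are not meaningful here), and
    zero when there is no lung mortality at all.
    """
    m = np.asarray(m_lung, dtype=float)
    lam = np.asarray(lambda_ns, dtype=float)
    if np.any(m < 0) or np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(m > 0, (m - lam) / np.where(m > 0, m, 1.0), 0.0)
    out = np.maximum(frac, 0.0)
    return out if out.ndim else float(out)


def other_saf(m_lung, lambda_ns, beta):
    """Attributable fraction of deaths from causes other than lung cancer."""
    m = np.asarray(m_lung, dtype=float)
    lam = np.asarray(lambda_ns, dtype=float)
    b = np.asarray(beta, dtype=float)
    if np.any(m < 0) or np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    if not np.all(np.isfinite(b)):
        raise ValueError("beta must be finite")
    out = -np.expm1(-b * np.maximum(m - lam, 0.0))
    return out if out.ndim else float(out)


def _midpoint(age_start: np.ndarray) -> np.ndarray:
    mids = dict(zip(CANONICAL.starts, CANONICAL.midpoints))
    return np.array([mids.get(a, a + TERMINAL_MIDPOINT_OFFSET) for a in age_start])


def extrapolate_beta(table: pd.DataFrame, target_ages) -> pd.DataFrame:
    """Extend β to further age groups by a linear fit in age-group midpoint.

    Within each (sex, period band) stratum, a least-squares line of β
    against age midpoint is fit on the source rows and evaluated at target
    ages missing from the table. Existing entries are unchanged.
    """
    target_ages = sorted(set(int(a) for a in target_ages))
    frames = [table]
    for (sex, p0, p1), sub in table.groupby(["sex", "period_start", "period_end"]):
        have = set(sub["age_start"])
        need = [a for a in target_ages if a not in have]
        if not need:
            continue
        if sub["age_start"].nunique() < 2:
            raise ValueError(
                f"cannot extrapolate beta for {sex}/{p0}-{p1}: fewer than two "
                "source age groups")
        x = _midpoint(sub["age_start"].to_numpy())
        slope, intercept = np.polyfit(x, sub["beta"].to_numpy(), 1)
        xt = _midpoint(np.array(need))
        frames.append(pd.DataFrame({
            "sex": sex, "age_start": need, "period_start": p0,
            "period_end": p1, "beta": slope * xt + intercept,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["sex", "period_start", "age_start"]).reset_index(drop=True)


def beta_for_year(table: pd.DataFrame, year) -> pd.DataFrame:
    """β rows (sex, age_start, beta) for the period band containing ``year``.

    Years after the last band reuse the last band; years before the first
    band use the first.
    """
    bands = table[["period_start", "period_end"]].drop_duplicates().sort_values(
        "period_start")
    sel = None
    for _, b in bands.iterrows():
        if b["period_start"] <= year <= b["period_end"]:
            sel = b
            break
    if sel is None:
        sel = bands.iloc[-1] if year > bands["period_end"].max() else bands.iloc[0]
    sub = table[(table["period_start"] == sel["period_start"])
                & (table["period_end"] == sel["period_end"])]
    return sub[["sex", "age_start", "beta"]]


def total_saf(all_deaths, lung_deaths, a_lung, a_other, age_start=None):
    """Total smoking-attributable fraction of deaths in a cell.

    Weighted combination ``(A_lung·D_lung + A_other·(D_all − D_lung)) /
    D_all``; 0 where there are no deaths, and forced to 0 for age groups
    entirely below 45 when ``age_start`` is given.
    """
    D = np.asarray(all_deaths, dtype=float)
    Dl = np.asarray(lung_deaths, dtype=float)
    if np.any(Dl > D + 1e-9):
        raise ValueError("lung deaths exceed all-cause deaths")
    al = np.asarray(a_lung, dtype=float)
    ao = np.asarray(a_other, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(D > 0, (al * Dl + ao * (D - Dl)) / np.where(D > 0, D, 1.0), 0.0)
    if age_start is not None:
        out = np.where(np.asarray(age_start) < MIN_ATTRIBUTION_AGE, 0.0, out)
    return out if out.ndim else float(out)


@dataclass
class SafSurface:
    """Smoking-attributable fractions per cell.

    ``data`` columns: country, sex, year, age_start, A_lung, A_other,
    A_total, all in [0, 1); zero for every age group below 45.
    """

    data: pd.DataFrame

    def __post_init__(self):
        d = self.data
        for c in ("A_lung", "A_other", "A_total"):
            if (d[c] < 0).any() or (d[c] >= 1).any() or not np.isfinite(d[c]).all():
                raise ValueError(f"{c} must lie in [0, 1)")
        below = d[d["age_start"] < MIN_ATTRIBUTION_AGE]
        if (below[["A_lung", "A_other", "A_total"]].to_numpy() != 0).any():
            raise ValueError("attributable fractions must be zero below age 45")


def saf_surface(mortality: MortalitySurface, lung_rates: RateSurface,
                never_smoker: pd.DataFrame | None = None,
                beta_table: pd.DataFrame | None = None) -> SafSurface:
    """Attributable fractions for every cell of a mortality surface.

    Smoothed lung-cancer rates enter both the SAF formulas and the
    lung/other death split (lung deaths taken as smoothed rate x exposure,
    capped at all-cause deaths). β coefficients are extrapolated to all
    attribution ages present in the grid before the period-band lookup.
    """
    ns = never_smoker if never_smoker is not None else load_never_smoker()
    bt = beta_table if beta_table is not None else load_beta()
    attr_ages = [a for a in CANONICAL.starts if a >= MIN_ATTRIBUTION_AGE]
    bt = extrapolate_beta(bt, attr_ages)

    d = mortality.data.merge(
        lung_rates.data[["country", "sex", "year", "age_start", "rate"]]
        .rename(columns={"rate": "m_lung"}),
        on=["country", "sex", "year", "age_start"], how="left", validate="1:1")
    if d["m_lung"].isna().any():
        raise ValueError("lung-rate surface does not cover the mortality grid")
    d = d.merge(ns.rename(columns={"rate": "lambda_ns"}),
                on=["sex", "age_start"], how="left")
    d["lambda_ns"] = d["lambda_ns"].fillna(0.0)

    betas = []
    for year, sub in d.groupby("year"):
        by = beta_for_year(bt, year).rename(columns={"beta": "beta_y"})
        merged = sub.merge(by, on=["sex", "age_start"], how="left")
        betas.append(merged)
    d = pd.concat(betas, ignore_index=True)
    d["beta_y"] = d["beta_y"].fillna(0.0)

    active = d["age_start"] >= MIN_ATTRIBUTION_AGE
    al = np.where(active, lung_saf(d["m_lung"], d["lambda_ns"]), 0.0)
    ao = np.where(active, other_saf(d["m_lung"], d["lambda_ns"], d["beta_y"]), 0.0)
    lung_deaths = np.minimum(d["m_lung"] * d["exposures"], d["deaths"])
    at = total_saf(d["deaths"], lung_deaths, al, ao, d["age_start"].to_numpy())
    at = np.clip(at, 0.0, np.nextafter(1.0, 0.0))

    out = d[["country", "sex", "year", "age_start"]].copy()
    out["A_lung"], out["A_other"], out["A_total"] = al, ao, at
    return SafSurface(out.sort_values(["country", "sex", "year", "age_start"])
                      .reset_index(drop=True))


def eliminate_smoking(rates: pd.DataFrame, saf: SafSurface,
                      rate_col: str = "rate") -> pd.DataFrame:
    """Smoking-eliminated rate surface: M*(x, t) = M(x, t) · (1 − A_total).

    ``rates`` must carry country, sex, year, age_start and the rate column
    on exactly the same grid as ``saf``; a grid mismatch is an error.
    The returned frame adds ``rate_eliminated``.
    """
    keys = ["country", "sex", "year", "age_start"]
    try:
        merged = rates.merge(saf.data[keys + ["A_total"]], on=keys,
                             how="left", validate="1:1")
    except pd.errors.MergeError as exc:
        raise ValueError(f"rate/SAF grid mismatch: {exc}") from exc
    if merged["A_total"].isna().any():
        missing = merged[merged["A_total"].isna()][keys].head()
        raise ValueError(f"SAF surface does not cover rate grid: {missing.to_dict('records')}")
    merged["rate_eliminated"] = merged[rate_col] * (1.0 - merged["A_total"])
    return merged
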