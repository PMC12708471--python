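"""Synthetic mortality surfaces with known smoking-attributable structure.

The generator emulates the statistical structure the analysis assumes:

* a smooth smoke-free hazard surface per country and sex,
  ``m0(x, t) = c + a·exp(b·x)·exp(−ρ·(t − 1950))`` (Makeham level ``c``,
  Gompertz slope ``b`` and level ``a``, annual improvement rate ρ);
* a smoking epidemic overlay on lung-cancer mortality: excess lung rate
  ``amplitude · profile(x) · wave(t − τ)`` with a Gaussian wave in period
  and an age profile that is zero below 45, ramps linearly over 45-60 and
  is flat above 60 (matching the method's zero-below-45 assumption);
* other-cause smoking mortality constructed through the same functional
  form the attribution step inverts, ``A_other = 1 − exp(−β·excess)`` with
  the packaged β table, so the true attributable fraction of every cell is
  known in closed form;
* death counts taken either as exact expectations ("expected" mode) or as
  Poisson draws with a seeded generator ("poisson" mode).

Female epidemics start ``sex_delay`` years after male ones and are scaled
by ``female_amplitude``; female baseline hazards carry a modest survival
advantage. The truth bundle returned alongside the surfaces carries the
planted attributable fractions, the smoke-free rates and the smoke-free
life expectancy, so every pipeline stage can be checked against its target.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .agegrid import CANONICAL
from .attribution import (MIN_ATTRIBUTION_AGE, beta_for_year, extrapolate_beta,
                          load_beta, load_never_smoker, other_saf, total_saf)
from .io import CauseSurface, MortalitySurface, SEXES
from .lifetable import e0_surface


@dataclass(frozen=True)
class CountryParams:
    """Hazard and epidemic parameters of one synthetic country."""

    makeham: float = 1.5e-4       # age-independent hazard level (1/yr)
    gompertz_a: float = 4.0e-5    # senescent hazard at age 0 (1/yr)
    gompertz_b: float = 0.095     # log-slope of senescent hazard (1/yr of age)
    rho: float = 0.012            # annual improvement rate of senescent hazard
    onset: float = 1980.0         # male epidemic peak year τ
    amplitude: float = 2.0e-3     # peak excess lung-cancer rate, flat ages (1/yr)
    width: float = 18.0           # Gaussian wave SD (years)
    sex_delay: float = 20.0       # female epidemic peak delay (years)
    female_amplitude: float = 0.6  # female amplitude as share of male
    female_factor: float = 0.82   # female senescent-hazard multiplier


@dataclass
class SyntheticScenario:
    """A roster of synthetic countries plus exposure schedule and seed."""

    countries: dict = field(default_factory=dict)
    exposure: float = 5.0e5       # person-years per (sex, age group, year)
    years: tuple = (1950, 2019)
    seed: int = 0

    def to_yaml(self, path) -> None:
        doc = {
            "exposure": float(self.exposure),
            "years": [int(y) for y in self.years],
            "seed": int(self.seed),
            "countries": {c: {k: float(v) for k, v in asdict(p).items()}
                          for c, p in self.countries.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            countries={c: CountryParams(**p) for c, p in doc["countries"].items()},
            exposure=doc.get("exposure", 5.0e5),
            years=tuple(doc.get("years", (1950, 2019))),
            seed=doc.get("seed", 0),
        )


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """Four-country study roster: leader, lagged leader, heavy smoker, middling.

    The laggard (LAG) is an exact 12-year shifted clone of the leader (LEA),
    so the planted life-expectancy lag is known by construction.
    """
    lea = CountryParams(onset=1975.0, amplitude=1.2e-3)
    scenario = SyntheticScenario(countries={
        "LEA": lea,
        "SMK": CountryParams(makeham=2.0e-4, gompertz_a=5.0e-5, rho=0.010,
                             onset=1985.0, amplitude=3.5e-3),
        "AVG": CountryParams(makeham=1.8e-4, gompertz_a=4.5e-5, rho=0.011,
                             onset=1982.0, amplitude=2.0e-3),
    }, seed=seed)
    return shifted_clone(scenario, "LEA", 12, "LAG")


def shifted_clone(scenario: SyntheticScenario, code: str, k: int,
                  new_code: str) -> SyntheticScenario:
    """Add a clone of country ``code`` whose rates at year t equal the
    donor's at year t − k.

    The shift is applied to the hazard parameters themselves (improvement
    rebased by exp(ρ·k), epidemic onset moved k years later), so pre-1950
    donor values are extended by the donor's own trend formula and the
    identity holds exactly at every cell.
    """
    if k < 0 or int(k) != k:
        raise ValueError("shift k must be a non-negative integer")
    p = scenario.countries[code]
    clone = replace(p, gompertz_a=p.gompertz_a * np.exp(p.rho * k),
                    onset=p.onset + k)
    countries = dict(scenario.countries)
    countries[new_code] = clone
    return replace_scenario(scenario, countries=countries)


def replace_scenario(scenario: SyntheticScenario, **kwargs) -> SyntheticScenario:
    d = {"countries": scenario.countries, "exposure": scenario.exposure,
         "years": scenario.years, "seed": scenario.seed}
    d.update(kwargs)
    return SyntheticScenario(**d)


@dataclass
class TruthBundle:
    """Planted quantities: per-cell SAF, smoke-free rates, smoke-free e0."""

    saf: pd.DataFrame           # country, sex, year, age_start, A_lung/other/total
    smoke_free_rates: pd.DataFrame  # ... rate (true m0 incl. never-smoker lung)
    observed_rates: pd.DataFrame    # ... rate, lung_rate (true observed hazards)
    smoke_free_e0: pd.DataFrame     # country, sex, year, e0


def _age_profile(mids: np.ndarray) -> np.ndarray:
    """Epidemic age profile: 0 below 45, linear ramp 45-60, flat 60+."""
    return np.clip((mids - 45.0) / 15.0, 0.0, 1.0)


def generate_surface(scenario: SyntheticScenario, mode: str = "expected",
                     never_smoker: pd.DataFrame | None = None,
                     beta_table: pd.DataFrame | None = None):
    """Generate a MortalitySurface, CauseSurface and truth bundle.

    ``mode`` is "expected" (deaths equal their expectations exactly) or
    "poisson" (seeded Poisson draws; lung and other-cause deaths drawn
    separately so lung deaths never exceed the all-cause total).
    """
    if mode not in ("expected", "poisson"):
        raise ValueError(f"unknown mode {mode!r}")
    ns = never_smoker if never_smoker is not None else load_never_smoker()
    bt = beta_table if beta_table is not None else load_beta()
    attr_ages = [a for a in CANONICAL.starts if a >= MIN_ATTRIBUTION_AGE]
    bt = extrapolate_beta(bt, attr_ages)

    years = np.arange(scenario.years[0], scenario.years[1] + 1)
    mids = CANONICAL.midpoints
    ages = np.array(CANONICAL.starts)
    profile = _age_profile(mids)
    rng = np.random.default_rng(scenario.seed)

    lam_by_sex = {}
    beta_by_sex = {}
    for sex in SEXES:
        lam = np.zeros(len(ages))
        sub = ns[ns["sex"] == sex].set_index("age_start")["rate"]
        for i, a in enumerate(ages):
            lam[i] = sub.get(a, 0.0)
        lam_by_sex[sex] = lam
        bmat = np.zeros((len(ages), len(years)))
        for j, year in enumerate(years):
            by = beta_for_year(bt, year)
            s = by[by["sex"] == sex].set_index("age_start")["beta"]
            for i, a in enumerate(ages):
                bmat[i, j] = s.get(a, 0.0)
        beta_by_sex[sex] = bmat

    mort_rows, cause_rows, truth_rows = [], [], []
    for country in sorted(scenario.countries):
        p = scenario.countries[country]
        for sex in SEXES:
            sex_f = p.female_factor if sex == "F" else 1.0
            onset = p.onset + (p.sex_delay if sex == "F" else 0.0)
            amp = p.amplitude * (p.female_amplitude if sex == "F" else 1.0)
            lam = lam_by_sex[sex][:, None]
            beta = beta_by_sex[sex]

            t = years[None, :].astype(float)
            x = mids[:, None]
            m0 = (p.makeham * sex_f
                  + p.gompertz_a * sex_f * np.exp(p.gompertz_b * x)
                  * np.exp(-p.rho * (t - 1950.0)))
            excess = amp * profile[:, None] * np.exp(-0.5 * ((t - onset) / p.width) ** 2)
            excess = np.where(ages[:, None] < MIN_ATTRIBUTION_AGE, 0.0, excess)

            lam_eff = np.minimum(np.broadcast_to(lam, m0.shape), 0.5 * m0)
            m_lung = lam_eff + excess
            a_other = -np.expm1(-beta * excess)
            m_other = (m0 - lam_eff) / (1.0 - a_other)
            m_all = m_lung + m_other
            if np.any(m_all >= 1.0):
                raise ValueError(
                    f"scenario yields hazards >= 1 for {country}/{sex}; "
                    "reduce amplitude or baseline parameters")

            E = float(scenario.exposure)
            exp_lung = m_lung * E
            exp_other = m_other * E
            if mode == "poisson":
                lung_deaths = rng.poisson(exp_lung).astype(float)
                other_deaths = rng.poisson(exp_other).astype(float)
            else:
                lung_deaths, other_deaths = exp_lung, exp_other
            all_deaths = lung_deaths + other_deaths

            a_lung = np.where(m_lung > 0, excess / np.where(m_lung > 0, m_lung, 1.0), 0.0)
            a_tot = np.where(m_all > 0,
                             (a_lung * m_lung + a_other * m_other) / m_all, 0.0)

            na, ny = len(ages), len(years)
            cell = {
                "country": country, "sex": sex,
                "year": np.tile(years, na),
                "age_start": np.repeat(ages, ny),
            }
            mort_rows.append(pd.DataFrame({**cell,
                                           "deaths": all_deaths.ravel(),
                                           "exposures": E}))
            cause_rows.append(pd.DataFrame({**cell,
                                            "lung_deaths": lung_deaths.ravel()}))
            truth_rows.append(pd.DataFrame({**cell,
                                            "A_lung": a_lung.ravel(),
                                            "A_other": a_other.ravel(),
                                            "A_total": a_tot.ravel(),
                                            "rate_smoke_free": m0.ravel(),
                                            "rate_observed": m_all.ravel(),
                                            "lung_rate": m_lung.ravel()}))

    mortality = MortalitySurface(pd.concat(mort_rows, ignore_index=True))
    cause = CauseSurface(pd.concat(cause_rows, ignore_index=True))
    truth = pd.concat(truth_rows, ignore_index=True)
    keys = ["country", "sex", "year", "age_start"]
    smoke_free = truth[keys + ["rate_smoke_free"]].rename(
        columns={"rate_smoke_free": "rate"})
    observed = truth[keys + ["rate_observed", "lung_rate"]].rename(
        columns={"rate_observed": "rate"})
    bundle = TruthBundle(
        saf=truth[keys + ["A_lung", "A_other", "A_total"]],
        smoke_free_rates=smoke_free,
        observed_rates=observed,
        smoke_free_e0=e0_surface(smoke_free),
    )
    return mortality, cause, bundle


def write_scenario_files(scenario: SyntheticScenario, outdir,
                         mode: str = "expected") -> dict:
    """Generate a scenario and write HMD-style and WHO-style input files.

    Returns a dict of written paths (per-country deaths/exposures tables,
    one WHO-style CSV, and the scenario YAML), exercising the same readers
    the pipeline uses for real extracts.
    """
    from pathlib import Path

    from .io import write_hmd_table, write_who_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mortality, cause, _ = generate_surface(scenario, mode=mode)
    paths = {"scenario": outdir / "scenario.yaml"}
    scenario.to_yaml(paths["scenario"])
    for country in sorted(scenario.countries):
        for what in ("deaths", "exposures"):
            path = outdir / f"{country}_{what}.txt"
            write_hmd_table(mortality, country, path, what)
            paths[f"{country}_{what}"] = path
    paths["who"] = outdir / "lung_cancer_who.csv"
    write_who_csv(cause, paths["who"])
    return paths
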