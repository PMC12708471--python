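import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mortlag as ml
from mortlag.attribution import (beta_for_year, eliminate_smoking,
                                 extrapolate_beta, load_beta,
                                 load_never_smoker, lung_saf, other_saf,
                                 saf_surface, total_saf)

KEYS = ["country", "sex", "year", "age_start"]


@pytest.mark.parametrize("m,lam,expected", [
    (2e-4, 2e-4, 0.0),          # observed equals never-smoker schedule
    (2e-3, 2e-4, 0.9),          # (0.002 - 0.0002) / 0.002
    (1e-4, 2e-4, 0.0),          # below schedule: clamped at zero
    (0.0, 2e-4, 0.0),           # no lung mortality at all
])
def test_lung_attributable_fraction(m, lam, expected):
    assert lung_saf(m, lam) == pytest.approx(expected)


@pytest.mark.parametrize("m,lam,beta,expected", [
    (5e-4, 1e-4, 0.0, 0.0),                      # beta = 0
    (2e-4, 2e-4, 50.0, 0.0),                     # zero excess
    (1.1e-3, 1e-4, 100.0, 1 - np.exp(-0.1)),     # 1 - e^-0.1 = 0.0951626
])
def test_other_cause_attributable_fraction(m, lam, beta, expected):
    assert other_saf(m, lam, beta) == pytest.approx(expected, abs=1e-7)


def test_negative_rates_rejected():
    with pytest.raises(ValueError):
        lung_saf(-1e-4, 1e-4)
    with pytest.raises(ValueError):
        other_saf(1e-4, -1e-4, 10.0)


@given(m1=st.floats(1e-6, 1e-2), m2=st.floats(1e-6, 1e-2))
@settings(max_examples=50, deadline=None)
def test_saf_monotone_in_lung_rate(m1, m2):
    """Higher lung mortality never decreases any attributable fraction."""
    lam, beta = 2e-4, 80.0
    lo, hi = min(m1, m2), max(m1, m2)
    assert lung_saf(hi, lam) >= lung_saf(lo, lam)
    assert other_saf(hi, lam, beta) >= other_saf(lo, lam, beta)
    a_lo = total_saf(100.0, 10.0, lung_saf(lo, lam), other_saf(lo, lam, beta))
    a_hi = total_saf(100.0, 10.0, lung_saf(hi, lam), other_saf(hi, lam, beta))
    assert a_hi >= a_lo


def _beta_table(rows):
    return pd.DataFrame(rows, columns=["sex", "age_start", "period_start",
                                       "period_end", "beta"])


def test_beta_linear_extrapolation_in_age_midpoint():
    tab = _beta_table([("M", 50, 1990, 2019, 0.10),
                       ("M", 60, 1990, 2019, 0.20),
                       ("M", 70, 1990, 2019, 0.30)])
    out = extrapolate_beta(tab, [80])
    got = out[out["age_start"] == 80]["beta"].iloc[0]
    assert got == pytest.approx(0.40)
    # existing entries unchanged
    assert out[out["age_start"] == 60]["beta"].iloc[0] == 0.20


def test_beta_extrapolation_identity_and_flat_cases():
    tab = _beta_table([("M", 50, 1990, 2019, 0.25),
                       ("M", 60, 1990, 2019, 0.25),
                       ("M", 70, 1990, 2019, 0.25)])
    out = extrapolate_beta(tab, [60, 85])
    assert out[out["age_start"] == 60]["beta"].iloc[0] == 0.25
    assert out[out["age_start"] == 85]["beta"].iloc[0] == pytest.approx(0.25)
    with pytest.raises(ValueError, match="fewer than two"):
        extrapolate_beta(_beta_table([("M", 50, 1990, 2019, 0.1)]), [80])


def test_beta_period_band_lookup_reuses_last_band():
    tab = _beta_table([("M", 50, 1950, 1969, 1.0),
                       ("M", 50, 1970, 1989, 2.0)])
    assert beta_for_year(tab, 1960)["beta"].iloc[0] == 1.0
    assert beta_for_year(tab, 1975)["beta"].iloc[0] == 2.0
    assert beta_for_year(tab, 2010)["beta"].iloc[0] == 2.0  # after last band
    assert beta_for_year(tab, 1940)["beta"].iloc[0] == 1.0  # before first


@pytest.mark.parametrize("all_d,lung_d,al,ao,expected", [
    (100.0, 30.0, 0.5, 0.5, 0.5),            # equal fractions: split-free
    (100.0, 10.0, 0.9, 0.1, 0.18),           # (9 + 9) / 100
    (0.0, 0.0, 0.9, 0.9, 0.0),               # no deaths
])
def test_total_saf_weighted_combination(all_d, lung_d, al, ao, expected):
    assert total_saf(all_d, lung_d, al, ao) == pytest.approx(expected)


def test_total_saf_forced_zero_below_45_and_split_validation():
    assert total_saf(100.0, 10.0, 0.9, 0.9, age_start=40) == 0.0
    assert total_saf(100.0, 10.0, 0.9, 0.9, age_start=45) == pytest.approx(0.9)
    with pytest.raises(ValueError, match="exceed"):
        total_saf(10.0, 11.0, 0.5, 0.5)


def test_eliminate_smoking_identity_and_scaling(expected_surfaces):
    _, mortality, _, _ = expected_surfaces
    rates = mortality.rates()
    zero = ml.SafSurface(rates[KEYS].assign(A_lung=0.0, A_other=0.0,
                                            A_total=0.0))
    out = eliminate_smoking(rates, zero)
    assert np.allclose(out["rate_eliminated"], out["rate"])
    quarter = ml.SafSurface(rates[KEYS].assign(
        A_lung=0.0, A_other=0.0,
        A_total=np.where(rates["age_start"] >= 45, 0.25, 0.0)))
    out = eliminate_smoking(rates, quarter)
    old = out[out["age_start"] >= 45]
    assert np.allclose(old["rate_eliminated"], 0.75 * old["rate"])
    with pytest.raises(ValueError, match="cover"):
        eliminate_smoking(rates, ml.SafSurface(
            zero.data[zero.data["year"] != 2000]))


def test_packaged_coefficient_tables_load_and_cover_attribution_ages():
    ns = load_never_smoker()
    bt = load_beta()
    assert set(ns["sex"]) == {"F", "M"}
    assert ns["age_start"].min() == 45
    assert (ns["rate"] > 0).all()
    # non-decreasing in age above 45 for each sex
    for _, sub in ns.groupby("sex"):
        assert (sub.sort_values("age_start")["rate"].diff().dropna() >= 0).all()
    assert bt["period_start"].min() == 1950


def test_saf_recovers_planted_fractions_on_smoothed_expected_counts(
        expected_surfaces):
    """Inverse consistency: the pipeline SAF matches the generator's SAF."""
    _, mortality, cause, truth = expected_surfaces
    lung = ml.smooth_lung_rates(cause, mortality)
    saf = saf_surface(mortality, lung)
    merged = saf.data.merge(truth.saf, on=KEYS, suffixes=("_est", "_true"))
    adult = merged[merged["age_start"] >= 45]
    for col in ("A_lung", "A_other", "A_total"):
        err = np.abs(adult[f"{col}_est"] - adult[f"{col}_true"])
        assert err.max() < 0.005, col
    young = merged[merged["age_start"] < 45]
    assert (young[["A_lung_est", "A_other_est", "A_total_est"]] == 0).all().all()
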