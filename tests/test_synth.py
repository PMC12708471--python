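import numpy as np
import pandas as pd
import pytest

import mortlag as ml
from mortlag.synth import (CountryParams, SyntheticScenario, default_scenario,
                           generate_surface, shifted_clone)

KEYS = ["country", "sex", "year", "age_start"]


def _one_country(**kwargs):
    return SyntheticScenario(countries={"SYN": CountryParams(**kwargs)}, seed=3)


def test_no_epidemic_means_zero_saf_and_identical_surfaces():
    mortality, cause, truth = generate_surface(_one_country(amplitude=0.0),
                                               mode="expected")
    assert (truth.saf[["A_lung", "A_other", "A_total"]] == 0).all().all()
    merged = truth.observed_rates.merge(truth.smoke_free_rates, on=KEYS,
                                        suffixes=("_obs", "_free"))
    assert np.allclose(merged["rate_obs"], merged["rate_free"])


def test_same_seed_reproduces_identical_poisson_counts():
    scen = default_scenario(seed=11)
    m1, c1, _ = generate_surface(scen, mode="poisson")
    m2, c2, _ = generate_surface(scen, mode="poisson")
    pd.testing.assert_frame_equal(m1.data, m2.data)
    pd.testing.assert_frame_equal(c1.data, c2.data)
    m3, _, _ = generate_surface(default_scenario(seed=12), mode="poisson")
    assert not m3.data["deaths"].equals(m1.data["deaths"])


def test_poisson_totals_within_three_sd_of_expectation():
    scen = default_scenario(seed=5)
    m_exp, _, _ = generate_surface(scen, mode="expected")
    m_poi, _, _ = generate_surface(scen, mode="poisson")
    for country, sub in m_exp.data.groupby("country"):
        mu = sub["deaths"].sum()
        got = m_poi.data[m_poi.data["country"] == country]["deaths"].sum()
        assert abs(got - mu) < 3 * np.sqrt(mu), country


def test_female_epidemic_peaks_sex_delay_years_later():
    mortality, cause, truth = generate_surface(_one_country(sex_delay=20.0),
                                               mode="expected")
    saf = truth.saf[truth.saf["age_start"] == 70]
    # A_lung is monotone in the epidemic excess, so it peaks at the wave peak
    peak = saf.groupby("sex").apply(
        lambda d: d.loc[d["A_lung"].idxmax(), "year"], include_groups=False)
    assert peak["F"] - peak["M"] == 20


def test_zero_below_45_everywhere():
    _, _, truth = generate_surface(_one_country(), mode="expected")
    young = truth.saf[truth.saf["age_start"] < 45]
    assert (young[["A_lung", "A_other", "A_total"]] == 0).all().all()


def test_unreasonable_hazards_rejected():
    with pytest.raises(ValueError, match="hazards"):
        generate_surface(_one_country(gompertz_a=5e-3), mode="expected")
    with pytest.raises(ValueError, match="mode"):
        generate_surface(_one_country(), mode="bootstrap")


def test_shifted_clone_zero_shift_is_identity():
    scen = shifted_clone(_one_country(), "SYN", 0, "CLN")
    _, _, truth = generate_surface(scen, mode="expected")
    wide = truth.observed_rates.pivot_table(
        index=["sex", "year", "age_start"], columns="country", values="rate")
    assert np.allclose(wide["SYN"], wide["CLN"])


def test_shifted_clone_rates_equal_donor_k_years_earlier():
    """Smoke-free and lung rates shift exactly; observed rates shift exactly
    wherever the other-cause coefficient period band is unchanged, and to
    within ~2% across band boundaries."""
    scen = shifted_clone(_one_country(), "SYN", 12, "CLN")
    _, _, truth = generate_surface(scen, mode="expected")
    free = truth.smoke_free_rates.set_index(KEYS)["rate"]
    lung = truth.observed_rates.set_index(KEYS)["lung_rate"]
    obs = truth.observed_rates.set_index(KEYS)["rate"]
    for year in (1970, 1990, 2019):
        for age in (0, 45, 65, 85):
            for sex in ("F", "M"):
                a = ("CLN", sex, year, age)
                b = ("SYN", sex, year - 12, age)
                assert free.loc[a] == pytest.approx(free.loc[b], rel=1e-12)
                assert lung.loc[a] == pytest.approx(lung.loc[b], rel=1e-12)
                assert obs.loc[a] == pytest.approx(obs.loc[b], rel=2e-2)


def test_shifted_clone_smoke_free_e0_shifts_exactly_in_expected_mode():
    scen = shifted_clone(_one_country(), "SYN", 12, "CLN")
    _, _, truth = generate_surface(scen, mode="expected")
    e0 = truth.smoke_free_e0.set_index(["country", "sex", "year"])["e0"]
    for year in (1975, 2000, 2019):
        assert e0.loc[("CLN", "M", year)] == pytest.approx(
            e0.loc[("SYN", "M", year - 12)], abs=1e-9)
    with pytest.raises(ValueError, match="non-negative"):
        shifted_clone(_one_country(), "SYN", -3, "CLN")


def test_scenario_yaml_round_trip(tmp_path):
    scen = default_scenario(seed=9)
    p = tmp_path / "scen.yaml"
    scen.to_yaml(p)
    back = SyntheticScenario.from_yaml(p)
    assert back.seed == 9
    assert set(back.countries) == set(scen.countries)
    for c in scen.countries:
        assert back.countries[c].onset == pytest.approx(scen.countries[c].onset)
        assert back.countries[c].gompertz_a == pytest.approx(
            scen.countries[c].gompertz_a)


def test_written_input_files_round_trip_through_readers(tmp_path):
    scen = _one_country()
    paths = ml.write_scenario_files(scen, tmp_path)
    mortality, cause, _ = generate_surface(scen, mode="expected")
    surf = ml.read_hmd_surface(paths["SYN_deaths"], paths["SYN_exposures"],
                               "SYN")
    orig = mortality.data.sort_values(KEYS).reset_index(drop=True)
    got = surf.data.sort_values(KEYS).reset_index(drop=True)
    assert np.allclose(got["deaths"], orig["deaths"], rtol=1e-4)
    assert np.allclose(got["exposures"], orig["exposures"], rtol=1e-4)
    who = ml.read_who_lung(paths["who"], roster=("SYN",))
    merged = who.data.merge(cause.data, on=KEYS, suffixes=("_rt", ""))
    assert np.allclose(merged["lung_deaths_rt"], merged["lung_deaths"],
                       rtol=1e-4, atol=1e-4)
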