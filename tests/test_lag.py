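import numpy as np
import pandas as pd
import pytest

from mortlag.lag import (RecordTrend, age_lag_grid, build_record_trend,
                         estimate_lag, lag_change, lag_table,
                         record_rate_series, trend_slope)

YEARS = np.arange(1950, 2020)


def _e0_frame(series_by_country):
    rows = []
    for c, vals in series_by_country.items():
        for y, v in zip(YEARS, vals):
            rows.append((c, y, v))
    return pd.DataFrame(rows, columns=["country", "year", "e0"])


def _linear_ref(slope=0.2, start=50.0):
    vals = start + slope * (YEARS - 1950)
    return RecordTrend(years=YEARS, value=vals, holder=None,
                       direction="increasing")


def test_single_country_trend_is_its_own_series():
    vals = 50 + 0.1 * (YEARS - 1950)
    tr = build_record_trend(_e0_frame({"AAA": vals}))
    assert np.allclose(tr.value, vals)
    assert (tr.holder == "AAA").all()


def test_dominant_country_holds_record_everywhere():
    lo = 50 + 0.1 * (YEARS - 1950)
    tr = build_record_trend(_e0_frame({"LOW": lo, "HIGH": lo + 2}))
    assert (tr.holder == "HIGH").all()
    assert np.allclose(tr.value, lo + 2)


def test_crossing_series_switch_holder_matches_bruteforce():
    a = 50 + 0.10 * (YEARS - 1950)
    b = 48 + 0.16 * (YEARS - 1950)  # crosses a in ~1983
    tr = build_record_trend(_e0_frame({"AAA": a, "BBB": b}))
    brute_val = np.maximum(a, b)
    brute_holder = np.where(a >= b, "AAA", "BBB")  # alphabetical tie-break
    assert np.allclose(tr.value, brute_val)
    assert (tr.holder == brute_holder).all()


def test_missing_year_is_an_error():
    df = _e0_frame({"AAA": 50 + 0.1 * (YEARS - 1950)})
    with pytest.raises(ValueError, match="missing"):
        build_record_trend(df[df["year"] != 1990])


def test_self_lag_is_zero_on_strictly_increasing_envelope():
    ref = _linear_ref()
    est = estimate_lag(ref, ref.value[30], int(YEARS[30]))
    assert est.lag == pytest.approx(0.0, abs=1e-9)
    assert est.censored == "none"


def test_linear_envelope_inverts_exactly():
    ref = _linear_ref(slope=0.2, start=50.0)
    value = 50.0 + 0.2 * (2004 - 1950)
    est = estimate_lag(ref, value, 2019)
    assert est.lag == pytest.approx(15.0, abs=1e-9)
    assert est.equivalent_year == pytest.approx(2004.0)


def test_value_below_range_censored_with_span_lag():
    ref = _linear_ref()
    est = estimate_lag(ref, 40.0, 2019)
    assert est.censored == "beyond_range"
    assert est.lag >= 69
    assert est.label(ref.span) == "69≤"


def test_value_at_or_above_best_censored_nonpositive_lag():
    ref = _linear_ref()
    est = estimate_lag(ref, ref.monotone[-1] + 1.0, 2019)
    assert est.censored == "at_or_better"
    assert est.lag <= 0
    assert est.label(ref.span) == "≤0"


def test_plateau_inverts_to_latest_year():
    vals = np.concatenate([np.full(30, 60.0), 60 + 0.2 * np.arange(40)])
    ref = RecordTrend(years=YEARS, value=vals, holder=None,
                      direction="increasing")
    est = estimate_lag(ref, 60.0, 2019)
    assert est.equivalent_year == pytest.approx(1980.0)  # end of plateau


def test_decreasing_direction_for_death_rates():
    vals = 0.05 * np.exp(-0.01 * (YEARS - 1950))
    ref = RecordTrend(years=YEARS, value=vals, holder=None,
                      direction="decreasing")
    est = estimate_lag(ref, vals[50], int(YEARS[60]))
    assert est.lag == pytest.approx(10.0, abs=1e-9)
    est = estimate_lag(ref, vals[-1] * 0.5, 2019)  # better than today's best
    assert est.censored == "at_or_better"


def _brute_force_equivalent_year(ref, value, step=0.01):
    grid = np.arange(ref.years[0], ref.years[-1] + step / 2, step)
    env = np.interp(grid, ref.years, ref.monotone)
    sign = 1 if ref.direction == "increasing" else -1
    ok = np.nonzero(sign * env <= sign * value)[0]
    return grid[ok[-1]] if len(ok) else None


def test_inverse_interpolation_matches_bruteforce_scan():
    rng = np.random.default_rng(7)
    vals = np.cumsum(np.abs(rng.normal(0.15, 0.1, len(YEARS)))) + 50
    ref = RecordTrend(years=YEARS, value=vals, holder=None,
                      direction="increasing")
    for q in np.linspace(0.02, 0.98, 25):
        v = np.quantile(vals, q)
        est = estimate_lag(ref, v, 2019)
        brute = _brute_force_equivalent_year(ref, v)
        assert abs(est.equivalent_year - brute) <= 0.02


def test_lag_antitone_in_value():
    rng = np.random.default_rng(3)
    vals = np.cumsum(np.abs(rng.normal(0.2, 0.15, len(YEARS)))) + 50
    ref = RecordTrend(years=YEARS, value=vals, holder=None,
                      direction="increasing")
    values = np.linspace(vals.min() - 1, vals.max() + 1, 60)
    lags = [estimate_lag(ref, v, 2019).lag for v in values]
    assert (np.diff(lags) <= 1e-9).all()


def test_lag_table_contribution_zero_without_smoking_effect():
    e0s = _e0_frame({"AAA": 50 + 0.2 * (YEARS - 1950),
                     "BBB": 48 + 0.2 * (YEARS - 1950)})
    ref = build_record_trend(e0s)
    tab = lag_table(e0s, e0s, 2019, ref)
    assert np.allclose(tab["smoking_contribution"], 0.0)
    bbb = tab.set_index("country").loc["BBB"]
    assert bbb["lag_observed"] == pytest.approx(10.0, abs=1e-6)


def test_lag_table_roster_mismatch_errors():
    e0s = _e0_frame({"AAA": 50 + 0.2 * (YEARS - 1950)})
    ref = build_record_trend(e0s)
    other = _e0_frame({"BBB": 50 + 0.2 * (YEARS - 1950)})
    with pytest.raises(ValueError, match="countries"):
        lag_table(e0s, other, 2019, ref)


def test_lag_change_identity_and_envelope_pace():
    e0s = _e0_frame({"AAA": 50 + 0.25 * (YEARS - 1950),
                     "BBB": 45 + 0.25 * (YEARS - 1950)})
    ref = build_record_trend(e0s)
    t1 = lag_table(e0s, e0s, 2000, ref)
    t2 = lag_table(e0s, e0s, 2019, ref)
    ch = lag_change(t1, t2)
    assert np.allclose(ch["delta_observed"], 0.0, atol=1e-6)  # parallel paths
    same = lag_change(t1, t1)
    assert np.allclose(same["delta_observed"], 0.0)


def test_lag_change_detects_stagnating_country():
    rising = 50 + 0.25 * (YEARS - 1950)
    flat = np.full(len(YEARS), 55.0)
    e0s = _e0_frame({"AAA": rising, "BBB": flat})
    ref = build_record_trend(e0s)
    ch = lag_change(lag_table(e0s, e0s, 2000, ref),
                    lag_table(e0s, e0s, 2019, ref))
    delta = ch.set_index("country").loc["BBB", "delta_observed"]
    assert delta == pytest.approx(19.0, abs=0.5)


def test_trend_slope_exact_line_and_degenerate_inputs():
    years = np.arange(1950, 2020)
    slope, r2 = trend_slope(60 + 0.22 * (years - 1950), years)
    assert slope == pytest.approx(2.2)
    assert r2 == pytest.approx(1.0)
    slope, r2 = trend_slope(np.full(70, 60.0), years)
    assert slope == pytest.approx(0.0)
    with pytest.raises(ValueError):
        trend_slope([1.0, 2.0], [1990, 1991])
    with pytest.raises(ValueError, match="degenerate"):
        trend_slope([1.0, 2.0, 3.0], [1990, 1990, 1990])


def test_trend_slope_invariant_to_symmetric_perturbation():
    years = np.arange(1950, 2020).astype(float)
    vals = 60 + 0.22 * (years - 1950)
    pert = vals.copy()
    pert[10] += 0.5
    pert[-11] += 0.5  # equal bumps symmetric about the mean year cancel in OLS
    s0, _ = trend_slope(vals, years)
    s1, _ = trend_slope(pert, years)
    assert s1 == pytest.approx(s0, abs=1e-9)


def _lifetable_store(series_by_country, age_starts=(0, 45, 85)):
    rows = []
    for c, vals in series_by_country.items():
        for y, v in zip(YEARS, vals):
            for a in age_starts:
                rows.append((c, y, a, v * (1 + a / 100)))
    return pd.DataFrame(rows, columns=["country", "year", "age_start", "m"])


def test_record_rate_series_selects_holder_rates():
    a = 0.05 * np.exp(-0.010 * (YEARS - 1950))
    b = 0.06 * np.exp(-0.012 * (YEARS - 1950))
    e0s = _e0_frame({"AAA": 70 + 0.1 * (YEARS - 1950),
                     "BBB": 69 + 0.1 * (YEARS - 1950)})
    trend = build_record_trend(e0s)  # AAA always holds the record
    store = _lifetable_store({"AAA": a, "BBB": b})
    raw = record_rate_series(trend, store, smooth=False)
    assert np.allclose(raw[45].to_numpy(), a * 1.45)
    # per-year argmin brute force on a switching trend
    e0s2 = _e0_frame({"AAA": 70 + 0.05 * (YEARS - 1950),
                      "BBB": 68 + 0.12 * (YEARS - 1950)})
    trend2 = build_record_trend(e0s2)
    raw2 = record_rate_series(trend2, store, smooth=False)
    expect = np.where(trend2.holder == "AAA", a, b)
    assert np.allclose(raw2[0].to_numpy(), expect)
    with pytest.raises(ValueError, match="missing lifetable"):
        record_rate_series(trend2, store[store["country"] == "AAA"])


def test_age_lag_grid_open_bins_and_monotone_variants():
    ref = pd.DataFrame(
        {a: 0.05 * (1 + a / 100) * np.exp(-0.01 * (YEARS - 1950))
         for a in (45, 85)}, index=YEARS)
    obs = pd.DataFrame({"country": ["XXX", "XXX"], "age_start": [45, 85],
                        "rate": [ref[45].iloc[-1], 0.2]})
    elim = obs.assign(rate=[ref[45].iloc[-1] * 0.8, 0.2])
    grid = age_lag_grid(obs, elim, ref, 2019)
    g = grid.set_index(["variant", "age_start"])
    assert g.loc[("observed", 45), "lag"] == pytest.approx(0.0, abs=1e-9)
    assert g.loc[("eliminated", 45), "censored"] == "at_or_better"
    assert g.loc[("eliminated", 45), "label"] == "≤0"
    assert g.loc[("observed", 85), "censored"] == "beyond_range"
    assert g.loc[("observed", 85), "label"] == "69≤"
    # eliminated lag never exceeds observed lag
    both = grid.pivot_table(index="age_start", columns="variant", values="lag")
    assert (both["eliminated"] <= both["observed"] + 1e-9).all()
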