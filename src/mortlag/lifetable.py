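"""Abridged period lifetables on the canonical age grid.

Columns follow standard demographic notation: for each age group of width n,
``m`` is the central death rate, ``a`` the average years lived in the
interval by those dying in it, ``q`` the probability of dying,
``l`` survivors at the group's start (radix 100 000), ``d`` lifetable
deaths, ``L`` person-years lived in the interval, ``T`` person-years lived
at and above the interval start, and ``e`` remaining life expectancy.

The conversion q = n·m / (1 + (n − a)·m) is used for closed intervals; the
open terminal interval is closed with L = l/m (exponential closure, so the
remaining expectancy at 85+ is 1/m). Separation factors: a0 = 0.07 + 1.7·m0
for the infant group, a = 1.5 for ages 1-4, and a = n/2 elsewhere.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .agegrid import CANONICAL

RADIX = 100_000.0


def _separation_factors(m: np.ndarray, widths: np.ndarray) -> np.ndarray:
    a = widths / 2.0
    a[0] = min(0.07 + 1.7 * m[0], widths[0])
    if len(a) > 1:
        a[1] = 1.5
    return a


def abridged_lifetable(m, sex: str | None = None, radix: float = RADIX) -> pd.DataFrame:
    """Build an abridged lifetable from canonical age-group death rates.

    Parameters
    ----------
    m : array-like
        Central death rates for the 19 canonical age groups, in order.
    sex : optional
        Carried through unused; kept for symmetric call sites.
    radix : float
        Initial cohort size l(0).

    Returns
    -------
    pandas.DataFrame with columns age_start, n, m, a, q, l, d, L, T, e.
    """
    m = np.asarray(m, dtype=float)
    if len(m) != len(CANONICAL):
        raise ValueError(f"expected {len(CANONICAL)} rates, got {len(m)}")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError("death rates must be finite and non-negative")
    if m[-1] <= 0:
        raise ValueError("terminal (85+) death rate must be positive: the open "
                         "interval cannot be closed with m = 0")
    widths = np.array([w if np.isfinite(w) else np.nan for w in CANONICAL.widths])
    n_closed = widths[:-1]
    a = _separation_factors(m, widths.copy())

    q = np.empty_like(m)
    q[:-1] = n_closed * m[:-1] / (1.0 + (n_closed - a[:-1]) * m[:-1])
    q[:-1] = np.clip(q[:-1], 0.0, 1.0)
    q[-1] = 1.0

    l = np.empty_like(m)
    l[0] = radix
    for i in range(1, len(m)):
        l[i] = l[i - 1] * (1.0 - q[i - 1])
    d = l * q

    L = np.empty_like(m)
    L[:-1] = n_closed * (l[:-1] - d[:-1]) + a[:-1] * d[:-1]
    L[-1] = l[-1] / m[-1] if l[-1] > 0 else 0.0
    a[-1] = L[-1] / d[-1] if d[-1] > 0 else np.nan

    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)

    return pd.DataFrame({
        "age_start": list(CANONICAL.starts), "n": widths, "m": m, "a": a,
        "q": q, "l": l, "d": d, "L": L, "T": T, "e": e,
    })


def e0(m, **kwargs) -> float:
    """Life expectancy at birth for a canonical rate schedule."""
    return float(abridged_lifetable(m, **kwargs)["e"].iloc[0])


def e0_surface(rates: pd.DataFrame, rate_col: str = "rate") -> pd.DataFrame:
    """Life expectancy at birth per (country, sex, year).

    ``rates`` is a tidy frame with columns country, sex, year, age_start and
    the rate column; each (country, sex, year) must hold a complete
    canonical schedule. Errors from individual lifetables are re-raised
    with the offending cell identity.
    """
    order = {s: i for i, s in enumerate(CANONICAL.starts)}
    recs = []
    for (country, sex, year), sub in rates.groupby(["country", "sex", "year"]):
        if len(sub) != len(CANONICAL):
            raise ValueError(
                f"incomplete age schedule for {country}/{sex}/{year}: "
                f"{len(sub)} of {len(CANONICAL)} groups")
        m = sub.sort_values("age_start", key=lambda s: s.map(order))[rate_col]
        try:
            recs.append((country, sex, year, e0(m.to_numpy())))
        except ValueError as exc:
            raise ValueError(f"lifetable failed for {country}/{sex}/{year}: {exc}")
    return pd.DataFrame(recs, columns=["country", "sex", "year", "e0"])


def lifetable_surface(rates: pd.DataFrame, rate_col: str = "rate") -> pd.DataFrame:
    """Full lifetable columns for every (country, sex, year) in ``rates``."""
    order = {s: i for i, s in enumerate(CANONICAL.starts)}
    frames = []
    for (country, sex, year), sub in rates.groupby(["country", "sex", "year"]):
        m = sub.sort_values("age_start", key=lambda s: s.map(order))[rate_col]
        lt = abridged_lifetable(m.to_numpy())
        lt.insert(0, "country", country)
        lt.insert(1, "sex", sex)
        lt.insert(2, "year", year)
        frames.append(lt)
    return pd.concat(frames, ignore_index=True)
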