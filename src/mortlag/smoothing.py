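"""Penalized-spline smoothing of death-rate surfaces and reference series.

Two smoothers are provided, both P-splines (B-spline bases with a
second-order difference penalty on the coefficients) fitted by penalized
IRLS, with the smoothing parameter chosen by a GCV-style criterion:

* :func:`smooth_lung_rates` — a two-dimensional tensor-product smooth over
  age x calendar year of lung-cancer death counts, Poisson family with log
  link and log-exposure offset, fit per country and sex. It fills calendar
  years with missing cause-of-death data and damps small-count noise.
* :func:`smooth_reference_series` — a one-dimensional quasi-binomial smooth
  over year, on the logit scale, for the age-specific death-rate series of
  the record-holding populations. Death rates are treated as proportions of
  a fixed ceiling of 1 (they are all far below it), so the link only
  enforces boundedness.

The second-difference penalty leaves constants and straight lines (on the
link scale) unpenalized, and because B-spline columns sum to one, the
penalized Poisson fit reproduces total observed deaths exactly at
convergence (mean matching).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .agegrid import CANONICAL
from .io import CauseSurface, MortalitySurface

#: Default basis dimensions for the 2-D age x year smooth; the difference
#: penalty, not the basis size, controls the effective smoothness.
K_AGE = 10
K_YEAR = 10

_LAMBDA_GRID = np.logspace(-4, 6, 11)


# ---------------------------------------------------------------------------
# B-spline basis and penalized IRLS machinery
# ---------------------------------------------------------------------------

def _bspline_knots(lo: float, hi: float, k: int, degree: int = 3) -> tuple:
    """Open knot vector giving exactly ``k`` cubic B-spline basis functions."""
    k = max(int(k), 1)
    if hi <= lo:
        hi = lo + 1.0
    degree = min(degree, k - 1)
    n_inner = k - degree - 1
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
    t = np.r_[[lo] * (degree + 1), inner, [hi] * (degree + 1)]
    return t, degree


def _design(x, knots, degree) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    # clamp to the knot span; evaluation outside it is not needed here
    x = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    if k <= order:
        return np.zeros((k, k))
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


class FitError(RuntimeError):
    """Penalized IRLS failed to converge."""


def _pirls(y, X, offset, penalty, family, max_iter=100, tol=1e-11):
    """Penalized IRLS for Poisson(log) or quasibinomial(logit) families.

    Returns dict with coefficients, fitted means, deviance and effective
    degrees of freedom (trace of the hat matrix).
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if family == "poisson":
        eta = np.log(y + np.mean(y) * 0.1 + 1e-10) - offset
    elif family == "quasibinomial":
        mu0 = np.clip(y, 1e-10, 1 - 1e-10)
        eta = np.log(mu0 / (1 - mu0))
    else:  # pragma: no cover
        raise ValueError(family)
    beta = None
    dev_old = np.inf
    ridge = 1e-9 * np.eye(p)
    for _ in range(max_iter):
        if family == "poisson":
            mu = np.exp(np.clip(eta + offset, -300, 40))
            w = mu
            z = eta + (y - mu) / np.maximum(mu, 1e-300)
            dev = 2.0 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
        else:
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -40, 40)))
            w = mu * (1 - mu)
            z = eta + (y - mu) / np.maximum(w, 1e-300)
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
                t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
            dev = 2.0 * np.sum(t1 + t2)
        XtW = X.T * w
        A = XtW @ X
        try:
            beta = np.linalg.solve(A + penalty + ridge, XtW @ z)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FitError(f"singular system in penalized IRLS: {exc}") from exc
        eta = X @ beta
        if np.isfinite(dev) and abs(dev - dev_old) < tol * (abs(dev) + 1e-3):
            dev_old = dev
            break
        dev_old = dev
    else:
        if not np.isfinite(dev_old):
            raise FitError("penalized IRLS did not converge")
    H = np.linalg.solve(A + penalty + ridge, A)
    edf = float(np.trace(H))
    if family == "poisson":
        mu = np.exp(np.clip(eta + offset, -300, 40))
    else:
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -40, 40)))
    return {"beta": beta, "mu": mu, "dev": dev_old, "edf": edf}


def _gcv_fit(y, X, offset, pen_base, family, lambdas=_LAMBDA_GRID):
    """Fit over a grid of smoothing parameters, keep the GCV minimizer."""
    n = len(y)
    best, best_gcv = None, np.inf
    for lam in lambdas:
        try:
            fit = _pirls(y, X, offset, lam * pen_base, family)
        except FitError:
            continue
        denom = max(n - fit["edf"], 1.0) ** 2
        gcv = n * max(fit["dev"], 0.0) / denom
        if gcv < best_gcv - 1e-12:
            best, best_gcv, = fit, gcv
            best["lambda"] = lam
    if best is None:
        raise FitError("no smoothing parameter produced a converged fit")
    return best


# ---------------------------------------------------------------------------
# 2-D lung-cancer rate smoothing
# ---------------------------------------------------------------------------

@dataclass
class RateSurface:
    """Smoothed death rates on a complete (country, sex, age, year) grid.

    ``data`` columns: ``country, sex, year, age_start, rate, observed``
    where ``observed`` flags calendar years with source data (False marks
    years filled in by the smooth).
    """

    data: pd.DataFrame

    def __post_init__(self):
        d = self.data
        if (d["rate"] < 0).any() or not np.isfinite(d["rate"]).all():
            raise ValueError("RateSurface rates must be finite and non-negative")


def smooth_lung_rates(cause: CauseSurface, mortality: MortalitySurface,
                      k_age: int = K_AGE, k_year: int = K_YEAR,
                      years: tuple | None = None) -> RateSurface:
    """Smooth lung-cancer death rates over age and year, per country and sex.

    Counts are modelled as Poisson with log link and offset log(exposure),
    with a tensor-product P-spline over (age midpoint, year). The smooth is
    evaluated on every year of the target span, including years absent from
    the cause data. Cells with zero exposure are excluded from the fit but
    still predicted. Age groups whose observed counts are zero in every year
    (structurally zero lung mortality, e.g. childhood) are returned as
    exact zeros rather than fitted on the log scale.
    """
    mort = mortality.data
    if years is None:
        years = (int(mort["year"].min()), int(mort["year"].max()))
    all_years = np.arange(years[0], years[1] + 1)
    mids = dict(zip(CANONICAL.starts, CANONICAL.midpoints))

    out_frames = []
    for (country, sex), sub in cause.data.groupby(["country", "sex"]):
        expo = mort[(mort["country"] == country) & (mort["sex"] == sex)]
        cells = sub.merge(expo[["year", "age_start", "exposures"]],
                          on=["year", "age_start"], how="inner")
        if (cells["exposures"] > 0).sum() < 10:
            raise ValueError(
                f"too few country-years with nonzero exposure for {country}/{sex}"
            )
        by_age = cells.groupby("age_start")["lung_deaths"].sum()
        fit_ages = sorted(by_age.index[by_age > 0])
        zero_ages = sorted(set(expo["age_start"].unique()) - set(fit_ages))

        grid = pd.MultiIndex.from_product(
            [sorted(expo["age_start"].unique()), all_years],
            names=["age_start", "year"]).to_frame(index=False)

        if not fit_ages:
            warnings.warn(f"all-zero lung counts for {country}/{sex}; "
                          "returning an all-zero rate surface")
            pred = grid.assign(rate=0.0)
        else:
            fit_cells = cells[(cells["age_start"].isin(fit_ages))
                              & (cells["exposures"] > 0)]
            x_age = np.array([mids[a] for a in fit_cells["age_start"]])
            x_year = fit_cells["year"].to_numpy(dtype=float)
            obs_years = np.sort(fit_cells["year"].unique()).astype(float)
            ta, da = _bspline_knots(min(mids[a] for a in fit_ages),
                                    max(mids[a] for a in fit_ages),
                                    min(k_age, len(fit_ages)))
            # knots span the observed years only; years outside that span are
            # filled by constant extension of the boundary fit
            ty, dy = _bspline_knots(obs_years[0], obs_years[-1],
                                    min(k_year, len(obs_years)))
            Ba = _design(x_age, ta, da)
            By = _design(x_year, ty, dy)
            # row-wise tensor product basis
            X = (Ba[:, :, None] * By[:, None, :]).reshape(len(fit_cells), -1)
            ka, ky = Ba.shape[1], By.shape[1]
            pen = (np.kron(_diff_penalty(ka), np.eye(ky))
                   + np.kron(np.eye(ka), _diff_penalty(ky)))
            try:
                fit = _gcv_fit(fit_cells["lung_deaths"].to_numpy(dtype=float), X,
                               np.log(fit_cells["exposures"].to_numpy(dtype=float)),
                               pen, "poisson")
            except FitError as exc:
                raise FitError(f"lung-rate smooth failed for {country}/{sex}: {exc}")
            B_age_pred = _design([mids[a] for a in fit_ages], ta, da)
            B_year_pred = _design(all_years.astype(float), ty, dy)
            log_rate = B_age_pred @ fit["beta"].reshape(ka, ky) @ B_year_pred.T
            pred_fit = pd.DataFrame({
                "age_start": np.repeat(fit_ages, len(all_years)),
                "year": np.tile(all_years, len(fit_ages)),
                "rate": np.exp(log_rate).ravel(),
            })
            pred = grid.merge(pred_fit, on=["age_start", "year"], how="left")
            pred["rate"] = pred["rate"].fillna(0.0)  # structural-zero ages

        pred["country"] = country
        pred["sex"] = sex
        pred["observed"] = pred["year"].isin(sub["year"].unique())
        out_frames.append(pred)

    out = pd.concat(out_frames, ignore_index=True)
    return RateSurface(out[["country", "sex", "year", "age_start", "rate", "observed"]])


# ---------------------------------------------------------------------------
# 1-D reference-series smoothing
# ---------------------------------------------------------------------------

def smooth_reference_series(series: pd.Series, ceiling: float = 1.0,
                            k: int = 10) -> pd.Series:
    """Smooth a yearly reference death-rate series on the logit scale.

    ``series`` is indexed by calendar year with values strictly inside
    (0, ceiling). The values are divided by the ceiling, fitted with a
    quasi-binomial P-spline over year, and evaluated on every year between
    the first and last index entries.
    """
    series = series.sort_index()
    years = series.index.to_numpy(dtype=float)
    vals = series.to_numpy(dtype=float)
    if len(vals) < 20:
        raise ValueError("reference series needs at least 20 yearly values")
    if np.any(vals <= 0) or np.any(vals >= ceiling):
        raise ValueError("reference series values must lie strictly in "
                         f"(0, {ceiling})")
    p = vals / ceiling
    t, deg = _bspline_knots(years[0], years[-1], min(k, len(vals)))
    X = _design(years, t, deg)
    pen = _diff_penalty(X.shape[1])
    fit = _gcv_fit(p, X, np.zeros_like(p), pen, "quasibinomial")
    all_years = np.arange(int(years[0]), int(years[-1]) + 1)
    eta = _design(all_years.astype(float), t, deg) @ fit["beta"]
    smoothed = ceiling / (1.0 + np.exp(-np.clip(eta, -40, 40)))
    return pd.Series(smoothed, index=all_years, name=series.name)
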