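"""Reading, validation and harmonization of HMD-style and WHO-style inputs.

Two source layouts are supported:

* HMD 5x1 text tables (columns ``Year  Age  Female  Male  Total``), one file
  per country and measure (deaths, exposures).
* A single documented flat-table dialect of WHO Mortality Database
  cause-of-death extracts, as CSV with columns ``country_iso3, year, sex,
  icd_revision, cause_code, age_group_start, age_group_width, deaths``.
  Other WHO dialects must be pre-converted to this schema.

Everything is harmonized onto the canonical abridged age grid
(:data:`mortlag.agegrid.CANONICAL`): HMD ages above 85 are aggregated into
the open 85+ group by summing deaths and exposures, and WHO age intervals
must each fall inside exactly one canonical group.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .agegrid import CANONICAL, CANONICAL_STARTS, TERMINAL_AGE

logger = logging.getLogger(__name__)

#: The 20-country analysis roster (ISO3 codes).
ROSTER = (
    "AUS", "AUT", "BEL", "CAN", "CHE", "DEU", "DNK", "ESP", "FIN", "FRA",
    "GBR", "IRL", "ITA", "JPN", "NLD", "NOR", "NZL", "PRT", "SWE", "USA",
)

_LUNG_CODES = {
    7: ["162", "163"],
    8: ["162"],
    9: ["162"],
    10: ["C33", "C34"],
}

SEXES = ("F", "M")

TIDY_COLUMNS = ["country", "sex", "year", "age_start", "deaths", "exposures"]


def map_lung_icd(icd_revision: int) -> list:
    """Lung-cancer cause codes for an ICD revision.

    Revision 7 uses "162, 163"; revisions 8 and 9 use "162"; revision 10
    uses "C33" and "C34" (trachea, bronchus and lung).
    """
    try:
        return list(_LUNG_CODES[int(icd_revision)])
    except (KeyError, ValueError, TypeError):
        raise ValueError(
            f"unsupported ICD revision {icd_revision!r}; expected one of 7, 8, 9, 10"
        ) from None


@dataclass
class MortalitySurface:
    """All-cause deaths and person-years of exposure on the canonical grid.

    ``data`` is a tidy frame with columns
    ``country, sex, year, age_start, deaths, exposures``, one row per cell.
    """

    data: pd.DataFrame

    def __post_init__(self):
        d = self.data
        missing = [c for c in TIDY_COLUMNS if c not in d.columns]
        if missing:
            raise ValueError(f"MortalitySurface missing columns {missing}")
        if len(d) == 0:
            raise ValueError("MortalitySurface is empty")
        bad = d[(d["deaths"] < 0) | ~np.isfinite(d["deaths"])]
        if len(bad):
            raise ValueError(f"negative or non-finite deaths in rows: {_preview(bad)}")
        bad = d[(d["exposures"] < 0) | ~np.isfinite(d["exposures"])]
        if len(bad):
            raise ValueError(f"negative or non-finite exposures in rows: {_preview(bad)}")
        if d.duplicated(["country", "sex", "year", "age_start"]).any():
            raise ValueError("duplicate (country, sex, year, age_start) cells")
        unknown = set(d["age_start"]) - set(CANONICAL_STARTS)
        if unknown:
            raise ValueError(f"age_start values not on canonical grid: {sorted(unknown)}")
        self.data = d.reset_index(drop=True)

    @property
    def countries(self) -> list:
        return sorted(self.data["country"].unique())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    def rates(self) -> pd.DataFrame:
        """Tidy frame with an all-cause death-rate column (0 where exposure 0)."""
        d = self.data.copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            d["rate"] = np.where(d["exposures"] > 0, d["deaths"] / d["exposures"], 0.0)
        return d


@dataclass
class CauseSurface:
    """Lung-cancer deaths on the canonical grid.

    ``data`` columns: ``country, sex, year, age_start, lung_deaths``.
    Calendar-year gaps are allowed; they are filled later by smoothing.
    """

    data: pd.DataFrame

    def __post_init__(self):
        d = self.data
        req = ["country", "sex", "year", "age_start", "lung_deaths"]
        missing = [c for c in req if c not in d.columns]
        if missing:
            raise ValueError(f"CauseSurface missing columns {missing}")
        bad = d[(d["lung_deaths"] < 0) | ~np.isfinite(d["lung_deaths"])]
        if len(bad):
            raise ValueError(f"negative or non-finite lung deaths: {_preview(bad)}")
        if len(d) and d.duplicated(["country", "sex", "year", "age_start"]).any():
            raise ValueError("duplicate (country, sex, year, age_start) cells")
        self.data = d.reset_index(drop=True)

    def check_against(self, mortality: MortalitySurface) -> None:
        """Hard error if lung deaths exceed all-cause deaths in any shared cell."""
        keys = ["country", "sex", "year", "age_start"]
        merged = self.data.merge(mortality.data, on=keys, how="inner")
        bad = merged[merged["lung_deaths"] > merged["deaths"] + 1e-9]
        if len(bad):
            raise ValueError(
                "lung-cancer deaths exceed all-cause deaths (data corruption) in "
                f"cells: {_preview(bad[keys + ['lung_deaths', 'deaths']])}"
            )


def _preview(df: pd.DataFrame, n: int = 5) -> str:
    head = df.head(n).to_dict("records")
    more = f" (+{len(df) - n} more)" if len(df) > n else ""
    return f"{head}{more}"


# ---------------------------------------------------------------------------
# HMD 5x1 text layout
# ---------------------------------------------------------------------------

def _parse_hmd_age(token: str) -> int:
    token = token.strip()
    if token.endswith("+"):
        return int(token[:-1])
    if "-" in token:
        return int(token.split("-")[0])
    return int(token)


def _read_hmd_table(source) -> pd.DataFrame:
    """Parse an HMD 5x1 text table into Year/Age/Female/Male/Total columns."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    start = None
    for i, ln in enumerate(lines):
        if ln.split() and ln.split()[0] == "Year":
            start = i + 1
            break
    if start is None:
        # headerless table: accept raw 5-column rows
        start = 0
    records, bad = [], []
    for ln in lines[start:]:
        parts = ln.split()
        if len(parts) != 5:
            bad.append(ln)
            continue
        try:
            year = int(parts[0])
            age = _parse_hmd_age(parts[1])
            vals = [np.nan if p == "." else float(p) for p in parts[2:]]
        except ValueError:
            bad.append(ln)
            continue
        records.append((year, age, *vals))
    if bad:
        raise ValueError(f"malformed HMD rows: {bad[:5]}")
    if not records:
        raise ValueError("empty HMD table: no data rows found")
    return pd.DataFrame(records, columns=["Year", "Age", "Female", "Male", "Total"])


def _harmonize_hmd(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Collapse HMD ages onto the canonical grid (85+ terminal aggregation)."""
    df = df.copy()
    bad = df[df[["Female", "Male"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing {what} values in rows: {_preview(bad)}")
    neg = df[(df["Female"] < 0) | (df["Male"] < 0)]
    if len(neg):
        raise ValueError(f"negative {what} in rows: {_preview(neg)}")
    df["age_start"] = [
        TERMINAL_AGE if a >= TERMINAL_AGE else CANONICAL.start_of(a) for a in df["Age"]
    ]
    out = df.groupby(["Year", "age_start"], as_index=False)[["Female", "Male"]].sum()
    years = np.sort(out["Year"].unique())
    gaps = sorted(set(range(years.min(), years.max() + 1)) - set(years))
    if gaps:
        raise ValueError(f"missing calendar years in {what} table: {gaps}")
    return out


def read_hmd_surface(deaths_source, exposures_source, country: str,
                     years: tuple | None = None) -> MortalitySurface:
    """Read one country's HMD 5x1 deaths and exposures tables.

    Ages above 85 are aggregated into the open 85+ group by summing both
    deaths and exposures. ``years`` optionally restricts the calendar span
    (inclusive); by default all years present are kept.
    """
    deaths = _harmonize_hmd(_read_hmd_table(deaths_source), "deaths")
    expos = _harmonize_hmd(_read_hmd_table(exposures_source), "exposures")
    merged = deaths.merge(expos, on=["Year", "age_start"], how="outer",
                          suffixes=("_d", "_e"), indicator=True)
    lonely = merged[merged["_merge"] != "both"]
    if len(lonely):
        raise ValueError(
            f"deaths/exposures tables do not align on cells: {_preview(lonely)}"
        )
    if years is not None:
        merged = merged[(merged["Year"] >= years[0]) & (merged["Year"] <= years[1])]
        got = set(merged["Year"].unique())
        want = set(range(years[0], years[1] + 1))
        if got != want:
            raise ValueError(f"years missing from HMD tables: {sorted(want - got)}")
    frames = []
    for sex, col in (("F", "Female"), ("M", "Male")):
        frames.append(pd.DataFrame({
            "country": country,
            "sex": sex,
            "year": merged["Year"].to_numpy(),
            "age_start": merged["age_start"].to_numpy(),
            "deaths": merged[f"{col}_d"].to_numpy(),
            "exposures": merged[f"{col}_e"].to_numpy(),
        }))
    return MortalitySurface(pd.concat(frames, ignore_index=True))


def write_hmd_table(surface: MortalitySurface, country: str, path, value: str) -> None:
    """Write one country's measure (``deaths`` or ``exposures``) in HMD 5x1 layout."""
    d = surface.data[surface.data["country"] == country]
    wide = d.pivot_table(index=["year", "age_start"], columns="sex",
                         values=value).reset_index()
    labels = dict(zip(CANONICAL.starts, CANONICAL.labels))
    with open(path, "w") as fh:
        fh.write(f"{country}, {value.capitalize()} (abridged)\n\n")
        fh.write(f"{'Year':>6} {'Age':>10} {'Female':>16} {'Male':>16} {'Total':>16}\n")
        for _, row in wide.sort_values(["year", "age_start"]).iterrows():
            f, m = row["F"], row["M"]
            fh.write(f"{int(row['year']):>6} {labels[row['age_start']]:>10} "
                     f"{f:>16.4f} {m:>16.4f} {f + m:>16.4f}\n")


# ---------------------------------------------------------------------------
# WHO-style cause-of-death CSV
# ---------------------------------------------------------------------------

WHO_COLUMNS = ["country_iso3", "year", "sex", "icd_revision", "cause_code",
               "age_group_start", "age_group_width", "deaths"]


def read_who_lung(source, roster=ROSTER) -> CauseSurface:
    """Read lung-cancer deaths from a WHO-style flat CSV.

    Rows whose cause code matches the lung-cancer code set for their ICD
    revision are kept and summed per (country, sex, year, canonical age
    group); other causes are dropped. Countries outside ``roster`` are
    silently dropped with a logged count. An age interval that does not fit
    inside a single canonical group is an error.
    """
    df = pd.read_csv(source, dtype={"cause_code": str})
    missing = [c for c in WHO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"WHO table missing columns {missing}")
    n0 = df["country_iso3"].nunique()
    df = df[df["country_iso3"].isin(roster)]
    dropped = n0 - df["country_iso3"].nunique()
    if dropped:
        logger.info("read_who_lung: dropped %d countries outside roster", dropped)

    keep = np.zeros(len(df), dtype=bool)
    for rev, sub in df.groupby("icd_revision"):
        codes = map_lung_icd(rev)
        keep[df.index.get_indexer(sub.index)] = sub["cause_code"].isin(codes).to_numpy()
    df = df[keep]

    age_start = []
    for _, row in df.iterrows():
        s, w = row["age_group_start"], row["age_group_width"]
        if s >= TERMINAL_AGE:
            age_start.append(TERMINAL_AGE)
            continue
        try:
            g = CANONICAL.index_of(s)
        except ValueError as exc:
            raise ValueError(f"unknown age format in WHO row {row.to_dict()}") from exc
        gs, gw = CANONICAL.starts[g], CANONICAL.widths[g]
        if not np.isinf(gw) and s + w > gs + gw:
            raise ValueError(
                f"WHO age interval [{s}, {s + w}) spans more than one canonical "
                f"group (row {row.to_dict()})"
            )
        age_start.append(gs)
    df = df.assign(age_start=age_start, sex=df["sex"].astype(str))
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex codes {sorted(bad_sex)}; expected F/M")
    out = (df.groupby(["country_iso3", "sex", "year", "age_start"], as_index=False)
             ["deaths"].sum()
             .rename(columns={"country_iso3": "country", "deaths": "lung_deaths"}))
    return CauseSurface(out)


def write_who_csv(cause: CauseSurface, path, icd_revision: int = 10) -> None:
    """Write a CauseSurface back out in the WHO-style flat dialect.

    Lung deaths in each cell are emitted under the first lung-cancer code of
    the given revision; widths follow the canonical grid (85+ written as a
    wide closed interval, which still collapses into 85+ on re-read).
    """
    code = map_lung_icd(icd_revision)[0]
    widths = {s: (999 if np.isinf(w) else int(w))
              for s, w in zip(CANONICAL.starts, CANONICAL.widths)}
    d = cause.data
    out = pd.DataFrame({
        "country_iso3": d["country"],
        "year": d["year"],
        "sex": d["sex"],
        "icd_revision": icd_revision,
        "cause_code": code,
        "age_group_start": d["age_start"],
        "age_group_width": [widths[s] for s in d["age_start"]],
        "deaths": d["lung_deaths"],
    })
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Canonical tidy exchange format
# ---------------------------------------------------------------------------

def write_tidy(path, mortality: MortalitySurface, cause: CauseSurface | None = None) -> None:
    """Write the canonical tidy CSV (optionally including lung deaths)."""
    d = mortality.data.copy()
    if cause is not None:
        d = d.merge(cause.data, on=["country", "sex", "year", "age_start"], how="left")
    d.sort_values(["country", "sex", "year", "age_start"]).to_csv(path, index=False)


def read_tidy(path) -> tuple:
    """Read the canonical tidy CSV; returns (MortalitySurface, CauseSurface | None)."""
    d = pd.read_csv(path)
    mort = MortalitySurface(d[TIDY_COLUMNS].copy())
    cause = None
    if "lung_deaths" in d.columns:
        c = d[["country", "sex", "year", "age_start", "lung_deaths"]].dropna(
            subset=["lung_deaths"])
        cause = CauseSurface(c.copy())
    return mort, cause
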