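"""Readers/writers for WHO-Mortality-Database-style flat files.

The death flat file has one row per country/year/ICD-list/cause/sex with 26
age-banded count columns ``Deaths1..Deaths26`` (band 1 = all ages, bands
2-25 = ascending age bands under the ``Frmat`` scheme, band 26 = age
unspecified).  Only the full-detail age format (``Frmat`` 0: single years
0-4, then 5-year bands up to 95+) is supported; other formats would need an
under-specified band-merging matrix and are rejected row-wise.

Loading normalises to a tidy table, one row per (country, year, cause),
sexes combined, with the five 65+ age groups used throughout the analysis
(85-89/90-94/95+ merged into 85+).  The stored all-ages total is never
trusted: it is recomputed from the retained bands and mismatches are
counted in ``df.attrs["diagnostics"]``.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .icd_taxonomy import InvalidCauseCode, _parse

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_GROUPS",
    "INCOME_GROUPS",
    "MdbFormatError",
    "MdbValidationError",
    "PopulationLookupError",
    "read_death_file",
    "write_death_file",
    "read_population_file",
    "write_population_file",
    "read_income_lookup",
    "get_population",
]

#: the five 65+ age groups used throughout the analysis
AGE_GROUPS = ("65-69", "70-74", "75-79", "80-84", "85+")

#: World Bank analytical classes: low / lower-middle / upper-middle / high income
INCOME_GROUPS = ("LICT", "LMICT", "UMICT", "HICT")

# Frmat 0 band ages: Deaths2..Deaths25 start at these ages (Deaths26 = unknown)
_BAND_START_AGE = [0, 1, 2, 3, 4] + list(range(5, 100, 5))  # bands 2..25
_SUPPORTED_FRMATS = (0,)

_DEATH_COLS = ["Country", "Year", "List", "Cause", "Sex", "Frmat"] + [
    f"Deaths{i}" for i in range(1, 27)
]


class MdbFormatError(ValueError):
    """Fatal structural problem with an input file (e.g. missing column)."""


class MdbValidationError(ValueError):
    """Fatal content problem (e.g. negative count) with row context."""


class PopulationLookupError(KeyError):
    """A (country, year) pair needed downstream has no population record."""


def _age_group_of_band(band: int) -> str | None:
    """Map band index 2..25 to a 65+ age group label, None below 65."""
    start = _BAND_START_AGE[band - 2]
    if start < 65:
        return None
    if start >= 85:
        return "85+"
    return f"{start}-{start + 4}"


def read_death_file(path, age_floor: int = 65) -> pd.DataFrame:
    """Read a WHO-MDB-style death flat file into the tidy internal table.

    Parameters
    ----------
    path
        CSV with header containing Country, Year, List, Cause, Sex, Frmat and
        Deaths1..Deaths26; extra columns (Admin1, SubDiv, IM_Frmat, ...) are
        ignored.
    age_floor
        0 or 65.  Age bands below the floor are zeroed out of the retained
        vector; the recomputed ``total`` column covers retained bands only.

    Returns
    -------
    DataFrame with columns ``country, year, list_id, cause`` followed by the
    five 65+ age groups, ``total`` and ``unknown_age``; one row per
    (country, year, cause), sexes summed.  Load diagnostics are attached as
    ``df.attrs["diagnostics"]``.
    """
    if age_floor not in (0, 65):
        raise ValueError(f"age_floor must be 0 or 65, got {age_floor}")
    raw = pd.read_csv(path, dtype={"Country": str, "Cause": str, "List": str})
    missing = [c for c in _DEATH_COLS if c not in raw.columns]
    if missing:
        raise MdbFormatError(f"death file missing mandatory column(s): {missing}")

    death_cols = [f"Deaths{i}" for i in range(1, 27)]
    counts = raw[death_cols].fillna(0)
    neg = (counts.to_numpy() < 0).any(axis=1)
    if neg.any():
        rownum = int(np.flatnonzero(neg)[0]) + 2  # 1-based incl. header
        raise MdbValidationError(f"negative death count at file row {rownum}")

    diagnostics = {
        "rows_read": int(len(raw)),
        "rows_rejected_frmat": 0,
        "rows_dropped_bad_cause": 0,
        "rows_total_mismatch": 0,
        "unknown_age_deaths": 0,
    }

    frmat_ok = raw["Frmat"].astype(int).isin(_SUPPORTED_FRMATS)
    if (~frmat_ok).any():
        for i in np.flatnonzero(~frmat_ok.to_numpy()):
            logger.warning(
                "row %d rejected: unsupported age format Frmat=%s",
                int(i) + 2,
                raw["Frmat"].iloc[int(i)],
            )
        diagnostics["rows_rejected_frmat"] = int((~frmat_ok).sum())
        raw = raw[frmat_ok]

    def _valid_cause(c) -> bool:
        try:
            _parse(c)
            return True
        except InvalidCauseCode:
            return False

    cause_ok = raw["Cause"].map(_valid_cause)
    if (~cause_ok).any():
        bad = raw.loc[~cause_ok, "Cause"].unique()
        logger.warning(
            "%d row(s) dropped: unparseable cause code(s) %s",
            int((~cause_ok).sum()),
            list(bad)[:10],
        )
        diagnostics["rows_dropped_bad_cause"] = int((~cause_ok).sum())
        raw = raw[cause_ok]

    raw = raw.copy()
    raw["Cause"] = raw["Cause"].str.strip().str.upper()

    band_cols = [f"Deaths{i}" for i in range(2, 26)]
    retained = raw[band_cols].fillna(0).astype(float).copy()
    if age_floor > 0:
        for band in range(2, 26):
            if _BAND_START_AGE[band - 2] < age_floor:
                retained[f"Deaths{band}"] = 0.0

    out = pd.DataFrame(
        {
            "country": raw["Country"].astype(str),
            "year": raw["Year"].astype(int),
            "list_id": raw["List"].astype(str),
            "cause": raw["Cause"],
        }
    )
    for g in AGE_GROUPS:
        cols = [
            f"Deaths{b}" for b in range(2, 26) if _age_group_of_band(b) == g
        ]
        out[g] = retained[cols].sum(axis=1)
    out["total"] = retained.sum(axis=1)
    out["unknown_age"] = raw["Deaths26"].fillna(0).astype(float)

    stored_total = raw["Deaths1"].fillna(0).astype(float)
    recomputed_all = raw[band_cols].fillna(0).astype(float).sum(axis=1)
    mismatch = ~np.isclose(stored_total, recomputed_all + out["unknown_age"])
    diagnostics["rows_total_mismatch"] = int(mismatch.sum())
    diagnostics["unknown_age_deaths"] = float(out["unknown_age"].sum())
    if mismatch.any():
        logger.info(
            "%d row(s) had a stored all-ages total differing from the band sum; "
            "totals recomputed from bands",
            int(mismatch.sum()),
        )

    grouped = (
        out.groupby(["country", "year", "cause"], as_index=False)
        .agg(
            {
                "list_id": "first",
                **{g: "sum" for g in AGE_GROUPS},
                "total": "sum",
                "unknown_age": "sum",
            }
        )
        .sort_values(["country", "year", "cause"])
        .reset_index(drop=True)
    )
    grouped.attrs["diagnostics"] = diagnostics
    grouped.attrs["age_floor"] = age_floor
    return grouped


def write_death_file(raw: pd.DataFrame, path) -> None:
    """Write a file-dialect death table (Country..Deaths26 columns) to CSV."""
    missing = [c for c in _DEATH_COLS if c not in raw.columns]
    if missing:
        raise MdbFormatError(f"death table missing column(s): {missing}")
    raw.to_csv(path, index=False)


_POP_LABEL_MERGE = {"85-89": "85+", "90-94": "85+", "95+": "85+", "95-99": "85+", "100+": "85+"}


def read_population_file(path, units: str = "persons") -> pd.DataFrame:
    """Read a UN-WPP-style population table.

    CSV with columns ``location, year, age_group, population`` at 5-year
    age resolution; groups 85-89/90-94/95+ (and 95-99/100+) are collapsed
    into 85+.  ``units="thousands"`` rescales counts to persons.
    """
    raw = pd.read_csv(path, dtype={"location": str, "age_group": str})
    for col in ("location", "year", "age_group", "population"):
        if col not in raw.columns:
            raise MdbFormatError(f"population file missing mandatory column: {col}")
    if (raw["population"] <= 0).any():
        bad = raw[raw["population"] <= 0].iloc[0]
        raise MdbValidationError(
            f"non-positive population for {bad['location']} {bad['year']} "
            f"{bad['age_group']}"
        )
    scale = {"persons": 1.0, "thousands": 1000.0}
    if units not in scale:
        raise ValueError(f"units must be one of {sorted(scale)}, got {units!r}")
    df = raw.copy()
    df["age_group"] = df["age_group"].str.strip().replace(_POP_LABEL_MERGE)
    df["population"] = df["population"].astype(float) * scale[units]
    df = (
        df.groupby(["location", "year", "age_group"], as_index=False)["population"]
        .sum()
        .rename(columns={"location": "country"})
    )
    df["year"] = df["year"].astype(int)
    return df


def write_population_file(pop: pd.DataFrame, path) -> None:
    """Write a tidy population table back in the file dialect."""
    out = pop.rename(columns={"country": "location"})
    out.to_csv(path, index=False)


def read_income_lookup(path) -> pd.Series:
    """Read the country → World Bank income-group lookup.

    Two-column CSV (country, income_group); groups must be one of
    LICT/LMICT/UMICT/HICT.  Conflicting duplicate countries are fatal.
    """
    raw = pd.read_csv(path, dtype=str)
    if raw.shape[1] < 2:
        raise MdbFormatError("income lookup needs two columns (country, income_group)")
    raw = raw.iloc[:, :2]
    raw.columns = ["country", "income_group"]
    raw["income_group"] = raw["income_group"].str.strip().str.upper()
    bad = ~raw["income_group"].isin(INCOME_GROUPS)
    if bad.any():
        raise MdbValidationError(
            f"unknown income group label(s): {sorted(raw.loc[bad, 'income_group'].unique())}"
        )
    dup = raw.groupby("country")["income_group"].nunique()
    conflicts = dup[dup > 1]
    if not conflicts.empty:
        raise MdbValidationError(
            f"conflicting income class for country/ies: {list(conflicts.index)}"
        )
    return raw.drop_duplicates("country").set_index("country")["income_group"]


def get_population(
    pop: pd.DataFrame, country: str, year: int
) -> "pd.Series":
    """Population by 65+ age group for one country-year.

    Raises :class:`PopulationLookupError` naming the pair when absent, and
    :class:`MdbValidationError` when an age stratum is missing.
    """
    sub = pop[(pop["country"] == country) & (pop["year"] == year)]
    if sub.empty:
        raise PopulationLookupError(f"no population record for ({country}, {year})")
    series = sub.set_index("age_group")["population"].reindex(AGE_GROUPS)
    if series.isna().any():
        missing = [g for g in AGE_GROUPS if pd.isna(series[g])]
        raise MdbValidationError(
            f"population for ({country}, {year}) missing age group(s) {missing}"
        )
    return series
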