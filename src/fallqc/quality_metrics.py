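"""Data availability and the five coding-quality proportions.

For each country-year the five indicators are ratios of problematic-code
deaths to their reference universes:

1. unspecified deaths (R96/R98/R99) / total deaths
2. undetermined-intent injury deaths (Y30/Y31/Y34/Y87.2/Y89.9) / injury deaths
3. unspecified unintentional injuries (X59) / unintentional injury deaths
4. falls with unspecified mechanism (W19) / fall deaths
5. falls with unknown occurrence place (4th digit 9) / fall deaths

Values are kept as fractions in [0, 1]; percent formatting is display-only.
A proportion whose denominator is zero is undefined (``None``/NaN), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .icd_taxonomy import (
    CauseCategory,
    PlaceOfOccurrence,
    classify,
    place_of_occurrence,
)
from .mdb_io import AGE_GROUPS

__all__ = [
    "CategoryCounts",
    "QualityProfile",
    "AVAILABILITY_BINS",
    "tally_categories",
    "quality_profile",
    "quality_table",
    "availability",
    "income_group_comparison",
    "icd_revision",
]

INDICATOR_NAMES = (
    "proportion_one",
    "proportion_two",
    "proportion_three",
    "proportion_four",
    "proportion_five",
)

AVAILABILITY_BINS = ("0", "1-5", "6-10", "11-15", "16-20", "21-25", "26-30")


@dataclass(frozen=True)
class CategoryCounts:
    """Per country-year death totals for the indicator universes."""

    country: str
    year: int
    n_total: float
    n_unspecified: float
    n_injury: float
    n_undetermined: float
    n_unintentional: float
    n_x59: float
    n_fall: float
    n_w19: float
    n_fall_place_unknown: float

    def __post_init__(self):
        chain = [
            ("n_unspecified", "n_total"),
            ("n_undetermined", "n_injury"),
            ("n_injury", "n_total"),
            ("n_x59", "n_unintentional"),
            ("n_unintentional", "n_injury"),
            ("n_w19", "n_fall"),
            ("n_fall", "n_unintentional"),
            ("n_fall_place_unknown", "n_fall"),
        ]
        for lo, hi in chain:
            if getattr(self, lo) > getattr(self, hi) + 1e-9:
                raise ValueError(f"count invariant violated: {lo} > {hi}")


@dataclass(frozen=True)
class QualityProfile:
    """The five indicator fractions for one country-year (None = undefined)."""

    country: str
    year: int
    proportion_one: float | None
    proportion_two: float | None
    proportion_three: float | None
    proportion_four: float | None
    proportion_five: float | None


def tally_categories(rows: pd.DataFrame, restrict_65plus: bool = True) -> CategoryCounts:
    """Tally the indicator universes for one country-year.

    ``rows`` is a slice of the normalised death table sharing a single
    (country, year).  Deaths of unknown age are excluded throughout.
    """
    if rows.empty:
        raise ValueError("empty row set: need a country-year slice")
    countries, years = rows["country"].unique(), rows["year"].unique()
    if len(countries) != 1 or len(years) != 1:
        raise ValueError(
            f"rows must share one (country, year); got {countries} x {years}"
        )
    col = list(AGE_GROUPS) if restrict_65plus else ["total"]
    deaths = rows[col].sum(axis=1).to_numpy()
    cats = rows["cause"].map(classify)
    place = rows["cause"].map(place_of_occurrence)

    def _sum(flag: CauseCategory) -> float:
        mask = np.array([bool(c & flag) for c in cats])
        return float(deaths[mask].sum())

    unknown_place = np.array(
        [
            bool(c & CauseCategory.FALL) and p is PlaceOfOccurrence.UNKNOWN
            for c, p in zip(cats, place)
        ]
    )
    return CategoryCounts(
        country=str(countries[0]),
        year=int(years[0]),
        n_total=float(deaths.sum()),
        n_unspecified=_sum(CauseCategory.UNSPECIFIED_DEATH),
        n_injury=_sum(CauseCategory.INJURY),
        n_undetermined=_sum(CauseCategory.UNDETERMINED_INTENT),
        n_unintentional=_sum(CauseCategory.UNINTENTIONAL_INJURY),
        n_x59=_sum(CauseCategory.UNSPECIFIED_UNINTENTIONAL),
        n_fall=_sum(CauseCategory.FALL),
        n_w19=_sum(CauseCategory.FALL_UNSPECIFIED_MECHANISM),
        n_fall_place_unknown=float(deaths[unknown_place].sum()),
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def quality_profile(counts: CategoryCounts) -> QualityProfile:
    """The five indicator fractions from a category tally."""
    return QualityProfile(
        country=counts.country,
        year=counts.year,
        proportion_one=_ratio(counts.n_unspecified, counts.n_total),
        proportion_two=_ratio(counts.n_undetermined, counts.n_injury),
        proportion_three=_ratio(counts.n_x59, counts.n_unintentional),
        proportion_four=_ratio(counts.n_w19, counts.n_fall),
        proportion_five=_ratio(counts.n_fall_place_unknown, counts.n_fall),
    )


def quality_table(deaths: pd.DataFrame, restrict_65plus: bool = True) -> pd.DataFrame:
    """Indicator fractions and denominators for every country-year present."""
    records = []
    for (_, _), rows in deaths.groupby(["country", "year"]):
        counts = tally_categories(rows, restrict_65plus=restrict_65plus)
        prof = quality_profile(counts)
        rec = {f.name: getattr(counts, f.name) for f in fields(counts)}
        rec.update({k: getattr(prof, k) for k in INDICATOR_NAMES})
        records.append(rec)
    return pd.DataFrame(records)


def icd_revision(list_id: str) -> str:
    """Infer the ICD revision from the MDB list tag prefix."""
    s = str(list_id).strip()
    for prefix, rev in (("10", "ICD-10"), ("09", "ICD-9"), ("9", "ICD-9"),
                        ("08", "ICD-8"), ("8", "ICD-8"), ("07", "ICD-7"),
                        ("7", "ICD-7")):
        if s.startswith(prefix):
            return rev
    return "other"


def availability(
    deaths: pd.DataFrame,
    member_states: list[str] | None = None,
    year_range: tuple[int, int] = (1990, 2019),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bin each state by its number of data years and tag ICD revisions.

    Returns ``(per_country, per_country_year)``: the first has columns
    ``country, n_years, bin``; the second ``country, year, revision``.
    States in ``member_states`` absent from the data are binned "0".
    """
    lo, hi = year_range
    in_range = deaths[(deaths["year"] >= lo) & (deaths["year"] <= hi)]
    rev = (
        in_range.groupby(["country", "year"])["list_id"]
        .first()
        .map(icd_revision)
        .rename("revision")
        .reset_index()
    )
    n_years = rev.groupby("country")["year"].nunique()
    countries = set(n_years.index) | set(member_states or [])
    rows = []
    for c in sorted(countries):
        n = int(n_years.get(c, 0))
        if n == 0:
            b = "0"
        else:
            edge = min((n - 1) // 5, 5)
            b = AVAILABILITY_BINS[edge + 1]
        rows.append({"country": c, "n_years": n, "bin": b})
    return pd.DataFrame(rows), rev


@dataclass(frozen=True)
class IncomeComparison:
    indicator: str
    h_statistic: float
    p_value: float
    group_summary: pd.DataFrame  # income_group, n, median, p25, p75


def income_group_comparison(
    profiles: pd.DataFrame, income: pd.Series, indicator: int
) -> IncomeComparison:
    """Kruskal-Wallis comparison of one indicator across income groups.

    Analysis units are country-years (each year contributes one point).
    ``indicator`` is 1..5.  Quartiles use linear interpolation.
    """
    if indicator not in range(1, 6):
        raise ValueError("indicator must be 1..5")
    name = INDICATOR_NAMES[indicator - 1]
    df = profiles[["country", "year", name]].dropna(subset=[name]).copy()
    df["income_group"] = df["country"].map(income)
    df = df.dropna(subset=["income_group"])
    groups = {g: sub[name].to_numpy() for g, sub in df.groupby("income_group")}
    groups = {g: v for g, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 non-empty income groups for comparison, got {len(groups)}"
        )
    values = list(groups.values())
    flat = np.concatenate(values)
    if np.all(flat == flat[0]):
        h, p = 0.0, 1.0  # no variation anywhere: nothing to test
    else:
        h, p = stats.kruskal(*values)
    summary = pd.DataFrame(
        [
            {
                "income_group": g,
                "n": len(v),
                "median": float(np.median(v)),
                "p25": float(np.percentile(v, 25)),
                "p75": float(np.percentile(v, 75)),
            }
            for g, v in sorted(groups.items())
        ]
    )
    return IncomeComparison(
        indicator=name, h_statistic=float(h), p_value=float(p), group_summary=summary
    )
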