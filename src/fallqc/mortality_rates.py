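"""Direct age standardisation and corrected/uncorrected impact tiers.

Age-adjusted rates use the direct method with the WHO World Standard
Population (Ahmad et al., 2001): rate = 100000 × Σ_a w_a d_a / p_a over
the five 65+ age groups {65-69, 70-74, 75-79, 80-84, 85+}, with the
standard's 85-89/90-94/95-99/100+ weights merged into 85+ and the five
weights renormalised to sum to 1.  The weight table ships as a package
data file (``data/who_standard_population.csv``) so alternative standards
can be substituted.

The impact of problematic codes on a country is summarised by the yearly
ratio r(y) = corrected / uncorrected rate and classified into six tiers by
the country's *unrounded* maximum ratio: highest [1.00, 1.10), higher
[1.10, 1.20), high [1.20, 1.30), low [1.30, 1.40), lower [1.40, 1.50),
lowest >= 1.50.  Display rounding to two decimals is separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .garbage_redistribution import CorrectionResult
from .mdb_io import AGE_GROUPS, get_population

__all__ = [
    "TIER_NAMES",
    "load_standard_population",
    "standard_weights_65plus",
    "age_adjusted_rate",
    "rate_series",
    "classify_tier",
    "impact_ratio",
    "ImpactClassification",
]

TIER_NAMES = ("highest", "higher", "high", "low", "lower", "lowest")
_TIER_EDGES = (1.10, 1.20, 1.30, 1.40, 1.50)


def load_standard_population() -> pd.DataFrame:
    """The full WHO World Standard age distribution (percent by age group)."""
    with resources.files("fallqc.data").joinpath(
        "who_standard_population.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def standard_weights_65plus(table: pd.DataFrame | None = None) -> pd.Series:
    """Standard weights over the five 65+ groups, renormalised to sum 1.

    Groups 85-89/90-94/95-99/100+ of the published standard are merged
    into 85+ to match the lowest common age resolution of the death and
    population inputs.
    """
    if table is None:
        table = load_standard_population()
    t = table.copy()
    t["age_group"] = t["age_group"].replace(
        {"85-89": "85+", "90-94": "85+", "95-99": "85+", "95+": "85+", "100+": "85+"}
    )
    w = t.groupby("age_group")["percent"].sum().reindex(AGE_GROUPS)
    if w.isna().any() or (w <= 0).any():
        raise ValueError("standard population must cover all five 65+ groups")
    return w / w.sum()


def age_adjusted_rate(
    deaths: pd.Series,
    population: pd.Series,
    standard: pd.Series | None = None,
) -> float:
    """Directly age-standardised rate per 100,000.

    ``deaths`` and ``population`` are indexed by the five 65+ age groups;
    ``standard`` defaults to the WHO World Standard weights.
    """
    if standard is None:
        standard = standard_weights_65plus()
    d = pd.Series(deaths).reindex(AGE_GROUPS)
    p = pd.Series(population).reindex(AGE_GROUPS)
    w = pd.Series(standard).reindex(AGE_GROUPS)
    if d.isna().any():
        raise ValueError("deaths vector missing an age group")
    if p.isna().any() or (p <= 0).any():
        raise ValueError("population must be positive for all five age groups")
    return float(1e5 * (w * d / p).sum())


def rate_series(
    corrections: list[CorrectionResult],
    population: pd.DataFrame,
    standard: pd.Series | None = None,
) -> pd.DataFrame:
    """Uncorrected/corrected age-adjusted rate per year for one country.

    Years without a population record are dropped with a flag column
    rather than failing the whole series.
    """
    if standard is None:
        standard = standard_weights_65plus()
    if len({c.country for c in corrections}) > 1:
        raise ValueError("rate_series expects corrections for a single country")
    rows = []
    for c in sorted(corrections, key=lambda r: r.year):
        try:
            pop = get_population(population, c.country, c.year)
        except KeyError:
            continue
        r = age_adjusted_rate(c.observed_falls, pop, standard)
        r_star = age_adjusted_rate(c.corrected_falls, pop, standard)
        rows.append(
            {
                "country": c.country,
                "year": c.year,
                "rate_uncorrected": r,
                "rate_corrected": r_star,
                "ratio": (r_star / r) if r > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=[
        "country", "year", "rate_uncorrected", "rate_corrected", "ratio"
    ])


def classify_tier(max_ratio: float) -> str:
    """Six-tier quality label from the unrounded maximum ratio."""
    if not np.isfinite(max_ratio):
        raise ValueError("max ratio must be finite")
    idx = int(np.searchsorted(_TIER_EDGES, max_ratio, side="right"))
    return TIER_NAMES[idx]


@dataclass(frozen=True)
class ImpactClassification:
    country: str
    n_years: int
    median_ratio: float
    min_ratio: float
    max_ratio: float
    tier: str
    excluded_years: tuple[int, ...] = ()


def impact_ratio(series: pd.DataFrame) -> ImpactClassification:
    """Summarise a country's corrected/uncorrected ratios into a tier.

    Years with a zero uncorrected rate (ratio undefined) are excluded and
    reported.  The tier comes from the unrounded maximum ratio.
    """
    if series.empty:
        raise ValueError("empty rate series")
    valid = series.dropna(subset=["ratio"])
    excluded = tuple(int(y) for y in series.loc[series["ratio"].isna(), "year"])
    if valid.empty:
        raise ValueError("no year with a defined corrected/uncorrected ratio")
    ratios = valid["ratio"].to_numpy()
    return ImpactClassification(
        country=str(series["country"].iloc[0]),
        n_years=int(len(valid)),
        median_ratio=float(np.median(ratios)),
        min_ratio=float(ratios.min()),
        max_ratio=float(ratios.max()),
        tier=classify_tier(float(ratios.max())),
        excluded_years=excluded,
    )
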