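"""Effect of garbage-code correction on temporal comparisons.

Two complementary views: the 2005-vs-2015 rate change (absolute and
relative, before/after correction, with sign-reversal detection), and a
per-country ordinary least squares regression of the age-adjusted rate on
calendar year.  Countries need at least five data years for the trend
fit.  Significance is two-sided at alpha = 0.05 with classical standard
errors, matching the b (S_b) reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ChangePair",
    "TrendFit",
    "change_2005_2015",
    "fit_trend",
    "compare_trends",
    "reversal_summary",
]

ALPHA = 0.05
MIN_TREND_YEARS = 5


@dataclass(frozen=True)
class ChangePair:
    """2005-vs-2015 rate change, uncorrected and corrected."""

    country: str
    year_from: int
    year_to: int
    delta_uncorrected: float  # absolute difference, per 100,000
    relative_uncorrected: float  # percent of the earlier year's rate
    delta_corrected: float
    relative_corrected: float
    reversal: bool


def change_2005_2015(
    series: pd.DataFrame, year_from: int = 2005, year_to: int = 2015
) -> ChangePair:
    """Absolute and relative rate change between two anchor years.

    Raises ``KeyError`` naming the missing year when either anchor year is
    absent from the series (the country is then excluded upstream).
    """
    by_year = series.set_index("year")
    for y in (year_from, year_to):
        if y not in by_year.index:
            raise KeyError(f"year {y} missing for {series['country'].iloc[0]}")
    out = {}
    for tag, col in (("uncorrected", "rate_uncorrected"), ("corrected", "rate_corrected")):
        r0, r1 = float(by_year.loc[year_from, col]), float(by_year.loc[year_to, col])
        delta = r1 - r0
        out[f"delta_{tag}"] = delta
        out[f"relative_{tag}"] = 100.0 * delta / r0 if r0 > 0 else np.nan
    reversal = out["delta_uncorrected"] * out["delta_corrected"] < 0
    return ChangePair(
        country=str(series["country"].iloc[0]),
        year_from=year_from, year_to=year_to,
        reversal=bool(reversal), **out,
    )


def _ols_slope(years: np.ndarray, rates: np.ndarray) -> tuple[float, float, float]:
    """(slope, SE, two-sided p) of rate on year via OLS with intercept.

    Degenerate cases are resolved exactly: a zero standard error means a
    perfect line, so p is 0 for a non-zero slope and 1 for a flat one.
    """
    x = sm.add_constant(years.astype(float))
    fit = sm.OLS(rates.astype(float), x).fit()
    b = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    scale = max(1.0, float(np.max(np.abs(rates))))
    if se <= 1e-12 * scale or not np.isfinite(p):
        p = 1.0 if abs(b) <= 1e-12 * scale else 0.0
    return b, se, p


@dataclass(frozen=True)
class TrendFit:
    """OLS year-trend before/after correction for one country."""

    country: str
    n_years: int
    b: float
    se_b: float
    p: float
    b_corrected: float
    se_b_corrected: float
    p_corrected: float

    @property
    def sign_reversal(self) -> bool:
        return self.b * self.b_corrected < 0

    @property
    def significant(self) -> bool:
        return self.p <= ALPHA

    @property
    def significant_corrected(self) -> bool:
        return self.p_corrected <= ALPHA

    @property
    def classification(self) -> str:
        parts = []
        if self.sign_reversal:
            parts.append("sign_reversal")
        if self.significant and not self.significant_corrected:
            parts.append("lost_significance")
        if not self.significant and self.significant_corrected:
            parts.append("gained_significance")
        return "+".join(parts) if parts else "unchanged"


def fit_trend(series: pd.DataFrame, min_years: int = MIN_TREND_YEARS) -> TrendFit:
    """OLS of the age-adjusted rate on calendar year, both series.

    ``series`` is one country's ``rate_series`` output.  Countries with
    fewer than ``min_years`` data years are excluded with a ``ValueError``;
    zero variance in year is a contract violation.
    """
    df = series.dropna(subset=["rate_uncorrected", "rate_corrected"])
    years = df["year"].to_numpy(dtype=float)
    if len(years) < min_years:
        raise ValueError(
            f"{series['country'].iloc[0] if len(series) else '?'}: "
            f"{len(years)} data years < required {min_years}"
        )
    if np.unique(years).size < 2:
        raise ValueError("year has zero variance; trend undefined")
    b, se, p = _ols_slope(years, df["rate_uncorrected"].to_numpy())
    bc, sec, pc = _ols_slope(years, df["rate_corrected"].to_numpy())
    return TrendFit(
        country=str(df["country"].iloc[0]), n_years=int(len(years)),
        b=b, se_b=se, p=p, b_corrected=bc, se_b_corrected=sec, p_corrected=pc,
    )


def compare_trends(
    series_by_country: dict[str, pd.DataFrame], min_years: int = MIN_TREND_YEARS
) -> tuple[list[TrendFit], dict[str, str]]:
    """Fit trends for all countries; returns (fits, exclusions with reason)."""
    fits, excluded = [], {}
    for country, series in series_by_country.items():
        try:
            fits.append(fit_trend(series, min_years=min_years))
        except ValueError as exc:
            excluded[country] = str(exc)
    return fits, excluded


def reversal_summary(fits: list[TrendFit]) -> dict[str, float]:
    """Counts of slope-sign reversals and significance flips.

    Split by the sign of the uncorrected slope; exactly-zero slopes count
    as no reversal.  ``pct_sign_reversal`` is over all fitted countries.
    """
    n = len(fits)
    rev = [f for f in fits if f.sign_reversal]
    return {
        "n_countries": n,
        "n_sign_reversal": len(rev),
        "n_sign_reversal_from_positive": sum(1 for f in rev if f.b > 0),
        "n_sign_reversal_from_negative": sum(1 for f in rev if f.b < 0),
        "n_lost_significance": sum(
            1 for f in fits if f.significant and not f.significant_corrected
        ),
        "n_gained_significance": sum(
            1 for f in fits if not f.significant and f.significant_corrected
        ),
        "pct_sign_reversal": 100.0 * len(rev) / n if n else 0.0,
    }
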