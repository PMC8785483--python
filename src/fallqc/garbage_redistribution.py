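"""Adaptive-window proportionate redistribution of problematic ICD-10 codes.

Three garbage-code families inflate or hide unintentional-fall deaths and
are redistributed sequentially onto specific causes:

* stage 1 — unspecified deaths (R96/R98/R99), spread over all other causes;
* stage 2 — undetermined intent (Y30/Y31/Y34/Y87.2/Y89.9), spread over the
  injury universe V01-Y89 minus those codes;
* stage 3 — unspecified unintentional injury (X59), spread over the
  unintentional universe V01-X58.

Each stage allocates its garbage mass proportionally to the observed
cause distribution, pooled over an adaptive window of calendar years
around the study year: the worse that stage's problematic proportion, the
wider the window (1 / 3 / 5 / 7 years at breakpoints 30 / 50 / 70 %), so
sparse specific-cause distributions borrow strength from neighbouring
years.  Stages run in order 1→2→3 on a running (partially corrected)
count table, so garbage codes of later stages receive their share of
earlier allocations before being redistributed themselves; with
single-year windows this composes to the closed form
``d_fall × Π_s (T_s + G_s) / T_s`` on each age stratum.

Redistribution is age-group specific within 65+ (corrected age-specific
counts feed direct standardisation), with a pooled-over-ages fallback
when an age stratum has an empty target denominator.  Corrected counts
are real-valued; rates, not counts, are the downstream quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .icd_taxonomy import CauseCategory, classify
from .mdb_io import AGE_GROUPS
from .quality_metrics import quality_profile, tally_categories

__all__ = [
    "WindowPolicy",
    "StageSpec",
    "STAGES",
    "StageAudit",
    "CorrectionResult",
    "window_length",
    "pooled_share",
    "correct_year",
    "correct_country",
    "correction_table",
]


@dataclass(frozen=True)
class WindowPolicy:
    """Breakpoints on the problematic proportion and the window lengths.

    Defaults: below 30% use the study year alone; 30-49% a 3-year window;
    50-69% a 5-year window; 70%+ a 7-year window (all centred).
    """

    thresholds: tuple[float, ...] = (0.30, 0.50, 0.70)
    window_lengths: tuple[int, ...] = (1, 3, 5, 7)

    def __post_init__(self):
        t = self.thresholds
        if not all(0 < a < 1 for a in t) or list(t) != sorted(set(t)):
            raise ValueError("thresholds must be strictly increasing in (0,1)")
        w = self.window_lengths
        if len(w) != len(t) + 1 or any(x % 2 == 0 for x in w) or list(w) != sorted(w):
            raise ValueError("window_lengths must be odd, increasing, len(thresholds)+1")


def window_length(p: float, policy: WindowPolicy = WindowPolicy()) -> int:
    """Window length (years) for a problematic proportion ``p`` in [0,1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must lie in [0,1], got {p}")
    idx = int(np.searchsorted(policy.thresholds, p, side="right"))
    return policy.window_lengths[idx]


@dataclass(frozen=True)
class StageSpec:
    """One redistribution stage: its garbage family and target universe."""

    stage: int
    name: str
    garbage: CauseCategory
    universe: CauseCategory | None  # None = all causes
    indicator: str  # QualityProfile field driving the window choice

    def is_garbage(self, flags: CauseCategory) -> bool:
        return bool(flags & self.garbage)

    def is_target(self, flags: CauseCategory) -> bool:
        if self.is_garbage(flags):
            return False
        return True if self.universe is None else bool(flags & self.universe)


STAGES: tuple[StageSpec, ...] = (
    StageSpec(1, "unspecified_deaths", CauseCategory.UNSPECIFIED_DEATH, None,
              "proportion_one"),
    StageSpec(2, "undetermined_intent", CauseCategory.UNDETERMINED_INTENT,
              CauseCategory.INJURY, "proportion_two"),
    StageSpec(3, "unspecified_unintentional", CauseCategory.UNSPECIFIED_UNINTENTIONAL,
              CauseCategory.UNINTENTIONAL_INJURY, "proportion_three"),
)


@dataclass
class StageAudit:
    """Per-stage record of what was redistributed where."""

    stage: int
    name: str
    driving_proportion: float
    window_length: int
    window_years: tuple[int, ...]
    truncated_window: bool
    garbage_observed: pd.Series  # study-year observed garbage, by age
    garbage_redistributed: pd.Series  # mass moved at this stage, by age
    allocated_total: pd.Series  # mass received by targets, by age
    fall_allocation: pd.Series  # mass received by fall codes, by age
    fallback_ages: tuple[str, ...] = ()
    unallocated: float = 0.0


@dataclass
class CorrectionResult:
    """Observed vs corrected age-banded fall deaths for one country-year."""

    country: str
    year: int
    observed_falls: pd.Series
    corrected_falls: pd.Series
    stages: list[StageAudit] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def observed_total(self) -> float:
        return float(self.observed_falls.sum())

    @property
    def corrected_total(self) -> float:
        return float(self.corrected_falls.sum())


def _cause_matrix(rows: pd.DataFrame) -> pd.DataFrame:
    """Cause × age-group count matrix for a set of normalised rows."""
    m = rows.groupby("cause")[list(AGE_GROUPS)].sum()
    return m.astype(float)


def _flags_for(causes: pd.Index) -> list[CauseCategory]:
    return [classify(c) for c in causes]


def _window_years(avail: set[int], year: int, length: int) -> tuple[int, ...]:
    half = (length - 1) // 2
    return tuple(y for y in range(year - half, year + half + 1) if y in avail)


def pooled_share(
    deaths: pd.DataFrame,
    country: str,
    year: int,
    window: int,
    stage: StageSpec,
    age_group: str,
) -> tuple[float, bool]:
    """Share of falls within a stage's target universe, pooled over a window.

    Pools observed (uncorrected) counts over the existing years of the
    centred window.  Returns ``(share, fellback)``: if the age-specific
    pooled denominator is zero the all-65+ pooled share is used and the
    fallback flag is set; if that is zero too, the share is 0.
    """
    sub = deaths[deaths["country"] == country]
    years = _window_years(set(sub["year"].unique()), year, window)
    if not years:
        raise ValueError(f"no data years for {country} around {year}")
    mat = _cause_matrix(sub[sub["year"].isin(years)])
    flags = _flags_for(mat.index)
    target = np.array([stage.is_target(f) for f in flags])
    fall = np.array([bool(f & CauseCategory.FALL) for f in flags]) & target
    denom = float(mat.loc[target, age_group].sum())
    if denom > 0:
        return float(mat.loc[fall, age_group].sum()) / denom, False
    denom_all = float(mat.loc[target].to_numpy().sum())
    if denom_all > 0:
        return float(mat.loc[fall].to_numpy().sum()) / denom_all, True
    return 0.0, True


def correct_year(
    deaths: pd.DataFrame,
    country: str,
    year: int,
    policy: WindowPolicy = WindowPolicy(),
) -> CorrectionResult:
    """Redistribute the three problematic-code families for one country-year.

    ``deaths`` is the normalised table (all available years of the country
    are consulted for window pooling).  Stages run 1→2→3 on a running count
    table; shares come from observed counts pooled over each stage's
    adaptive window.  Nothing is fatal: degenerate strata fall back to the
    pooled 65+ share and every irregularity is flagged in the result.
    """
    sub = deaths[deaths["country"] == country]
    avail = set(sub["year"].unique())
    if year not in avail:
        raise ValueError(f"no rows for ({country}, {year})")

    study_rows = sub[sub["year"] == year]
    counts = tally_categories(study_rows)
    profile = quality_profile(counts)

    # union of causes over the widest possible window, so allocations can
    # land on causes seen only in neighbour years
    max_half = (max(policy.window_lengths) - 1) // 2
    wide_years = [y for y in avail if abs(y - year) <= max_half]
    wide = sub[sub["year"].isin(wide_years)]
    year_mats = {y: _cause_matrix(wide[wide["year"] == y]) for y in wide_years}
    all_causes = pd.Index(sorted(set().union(*(m.index for m in year_mats.values()))))
    year_mats = {y: m.reindex(all_causes, fill_value=0.0) for y, m in year_mats.items()}

    flags_by_cause = _flags_for(all_causes)
    fall_mask = np.array([bool(f & CauseCategory.FALL) for f in flags_by_cause])

    cur = year_mats[year].copy()
    observed_falls = cur.loc[fall_mask].sum(axis=0)

    result = CorrectionResult(
        country=country, year=year,
        observed_falls=observed_falls,
        corrected_falls=observed_falls.copy(),
    )

    for spec in STAGES:
        p = getattr(profile, spec.indicator)
        if p is None:
            p = 0.0
            result.flags.append(f"stage{spec.stage}:undefined_proportion")
        length = window_length(p, policy)
        wyears = _window_years(avail, year, length)
        truncated = len(wyears) < length

        garbage = np.array([spec.is_garbage(f) for f in flags_by_cause])
        target = np.array([spec.is_target(f) for f in flags_by_cause])
        gamma = cur.loc[garbage].sum(axis=0)  # current mass, by age
        observed_gamma = year_mats[year].loc[garbage].sum(axis=0)

        pooled = sum(year_mats[y] for y in wyears)
        pooled_targets = pooled.loc[target]
        denom_by_age = pooled_targets.sum(axis=0)
        denom_all = float(pooled_targets.to_numpy().sum())
        agg_shares = (
            pooled_targets.sum(axis=1) / denom_all if denom_all > 0 else None
        )

        allocated = pd.Series(0.0, index=list(AGE_GROUPS))
        fall_alloc = pd.Series(0.0, index=list(AGE_GROUPS))
        fallback_ages: list[str] = []
        unallocated = 0.0

        for a in AGE_GROUPS:
            g = float(gamma[a])
            if g == 0.0:
                continue
            if denom_by_age[a] > 0:
                shares = pooled_targets[a] / denom_by_age[a]
            elif agg_shares is not None:
                shares = agg_shares
                fallback_ages.append(a)
            else:
                unallocated += g
                fallback_ages.append(a)
                continue
            add = g * shares
            cur.loc[target, a] += add.to_numpy()
            allocated[a] = float(add.sum())
            fall_alloc[a] = float(add[fall_mask[target]].sum())
        cur.loc[garbage] = 0.0

        result.stages.append(
            StageAudit(
                stage=spec.stage, name=spec.name,
                driving_proportion=float(p),
                window_length=length, window_years=wyears,
                truncated_window=truncated,
                garbage_observed=observed_gamma,
                garbage_redistributed=gamma,
                allocated_total=allocated,
                fall_allocation=fall_alloc,
                fallback_ages=tuple(fallback_ages),
                unallocated=unallocated,
            )
        )
        if truncated:
            result.flags.append(f"stage{spec.stage}:truncated_window")
        if unallocated > 0:
            result.flags.append(f"stage{spec.stage}:unallocated_garbage")

    result.corrected_falls = cur.loc[fall_mask].sum(axis=0)
    return result


def correct_country(
    deaths: pd.DataFrame, country: str, policy: WindowPolicy = WindowPolicy()
) -> list[CorrectionResult]:
    """Run :func:`correct_year` for every available year of one country."""
    years = sorted(deaths.loc[deaths["country"] == country, "year"].unique())
    return [correct_year(deaths, country, int(y), policy) for y in years]


def correction_table(results: list[CorrectionResult]) -> pd.DataFrame:
    """Tidy per country-year summary of a batch of corrections."""
    rows = []
    for r in results:
        rec = {
            "country": r.country,
            "year": r.year,
            "observed_falls": r.observed_total,
            "corrected_falls": r.corrected_total,
            "flags": ";".join(r.flags),
        }
        for s in r.stages:
            rec[f"stage{s.stage}_window"] = s.window_length
            rec[f"stage{s.stage}_allocated_to_falls"] = float(s.fall_allocation.sum())
        rows.append(rec)
    return pd.DataFrame(rows)
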