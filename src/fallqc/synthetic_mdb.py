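"""Synthetic WHO-MDB-style death and population files with known truth.

The generator emulates vital-registration cause-of-death tables for a 65+
population: per country-year-age fall deaths drawn binomially from
population x rate (with optional linear secular trends), a configurable
mix of non-fall causes spanning the non-injury, injury and unintentional
universes, and matched population denominators.

Problematic codes are injected by *relabelling* true deaths — each death
independently becomes R99 with probability q1, else (if an injury) Y34
with probability q2, else (if unintentional) X59 with probability q3 — so
total mortality is preserved and the proportionate-redistribution
assumption (garbage follows the specific-cause distribution) holds by
construction.  Parameter-recovery tests therefore probe the
implementation, not the assumption.  Surviving falls are coded W19 with
probability q4 (else a random mechanism W00-W18) and get place-of-
occurrence digit 9 with probability q5 (else a random digit 0-8).

Every draw flows from one ``numpy`` generator seeded per call: identical
config + seed gives byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .icd_taxonomy import CauseCategory, classify
from .mdb_io import AGE_GROUPS

__all__ = [
    "CountryScenario",
    "ScenarioConfig",
    "GroundTruth",
    "SyntheticDataset",
    "GenerationError",
    "generate",
    "scenario_library",
]

_FALL = "FALL"  # internal label for the true-fall stratum before coding
_AGE_TO_BAND = {"65-69": 19, "70-74": 20, "75-79": 21, "80-84": 22, "85+": 23}


class GenerationError(ValueError):
    """A config inconsistency surfaced during generation (names the year)."""


def _rate_at(base: float, trend: float, year: int, year0: int) -> float:
    return base + trend * (year - year0)


def _q_at(q, year: int, year0: int, year1: int) -> float:
    """Resolve a constant or (start, end) linearly interpolated rate."""
    if isinstance(q, (tuple, list)):
        lo, hi = q
        if year1 == year0:
            return float(lo)
        return float(lo + (hi - lo) * (year - year0) / (year1 - year0))
    return float(q)


@dataclass(frozen=True)
class CountryScenario:
    """One synthetic country: demography, true rates, and injection rates."""

    code: str
    income: str
    population: dict[str, int]  # per 65+ age group, constant over years
    fall_rate: dict[str, float]  # per-person annual rate in the first year
    fall_trend: dict[str, float] = field(default_factory=dict)  # additive / year
    other_causes: dict[str, float] = field(default_factory=dict)  # code -> rate
    q1: float | tuple[float, float] = 0.0  # -> R99
    q2: float | tuple[float, float] = 0.0  # injuries -> Y34
    q3: float | tuple[float, float] = 0.0  # unintentional -> X59
    q4: float = 0.0  # surviving falls coded W19
    q5: float = 0.0  # place digit 9


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    countries: tuple[CountryScenario, ...]
    years: tuple[int, int]  # inclusive span

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        countries = tuple(
            CountryScenario(
                **{
                    **c,
                    "q1": tuple(c["q1"]) if isinstance(c.get("q1"), list) else c.get("q1", 0.0),
                    "q2": tuple(c["q2"]) if isinstance(c.get("q2"), list) else c.get("q2", 0.0),
                    "q3": tuple(c["q3"]) if isinstance(c.get("q3"), list) else c.get("q3", 0.0),
                }
            )
            for c in d["countries"]
        )
        return cls(name=d["name"], countries=countries, years=tuple(d["years"]))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Realised pre-relabelling truth plus the configured expectations."""

    config: ScenarioConfig
    falls: pd.DataFrame  # country, year, age_group, true_falls
    accounting: pd.DataFrame  # per stratum x source cause: generated/kept/relabelled

    def true_falls_total(self, country: str, year: int) -> float:
        sub = self.falls[(self.falls["country"] == country) & (self.falls["year"] == year)]
        return float(sub["true_falls"].sum())

    def true_rate_series(self, country: str, weights: pd.Series) -> pd.DataFrame:
        """Realised age-standardised true fall rate per 100,000 by year."""
        spec = next(c for c in self.config.countries if c.code == country)
        sub = self.falls[self.falls["country"] == country]
        rows = []
        for year, g in sub.groupby("year"):
            d = g.set_index("age_group")["true_falls"].reindex(AGE_GROUPS)
            p = pd.Series(spec.population).reindex(AGE_GROUPS).astype(float)
            rows.append(
                {"country": country, "year": int(year),
                 "rate_true": float(1e5 * (weights * d / p).sum())}
            )
        return pd.DataFrame(rows)

    def expected_slope(self, country: str, weights: pd.Series) -> float:
        """Configured (noise-free) trend of the standardised true rate."""
        spec = next(c for c in self.config.countries if c.code == country)
        w = pd.Series(weights).reindex(AGE_GROUPS)
        tr = pd.Series({a: spec.fall_trend.get(a, 0.0) for a in AGE_GROUPS})
        return float(1e5 * (w * tr).sum())


@dataclass
class SyntheticDataset:
    config: ScenarioConfig
    seed: int
    deaths: pd.DataFrame  # WHO-MDB file dialect
    population: pd.DataFrame  # UN-WPP file dialect
    truth: GroundTruth

    def write(self, outdir) -> dict[str, Path]:
        """Write deaths/population/income/ground-truth CSVs; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "deaths": outdir / "deaths.csv",
            "population": outdir / "population.csv",
            "income": outdir / "income.csv",
            "truth": outdir / "ground_truth_falls.csv",
        }
        self.deaths.to_csv(paths["deaths"], index=False)
        self.population.to_csv(paths["population"], index=False)
        pd.DataFrame(
            [{"country": c.code, "income_group": c.income} for c in self.config.countries]
        ).to_csv(paths["income"], index=False)
        self.truth.falls.to_csv(paths["truth"], index=False)
        return paths


def _fall_code_probs(q4: float, q5: float) -> tuple[list[str], np.ndarray]:
    """Final fall codes (mechanism x place digit) and their probabilities."""
    codes, probs = [], []
    for mech in range(20):
        p_mech = q4 if mech == 19 else (1.0 - q4) / 19.0
        for digit in "0123456789":
            p_digit = q5 if digit == "9" else (1.0 - q5) / 9.0
            codes.append(f"W{mech:02d}{digit}")
            probs.append(p_mech * p_digit)
    return codes, np.asarray(probs)


def generate(config: ScenarioConfig, seed: int = 0) -> SyntheticDataset:
    """Draw one synthetic dataset from a scenario.

    Deaths are Binomial(population, rate) per stratum and cause; garbage
    injection is by relabelling (see module docstring).  Output tables are
    in the exact file dialects :mod:`fallqc.mdb_io` reads.
    """
    rng = np.random.default_rng(seed)
    y0, y1 = config.years
    if y1 < y0:
        raise GenerationError(f"year span {config.years} is inverted")

    # (country, year, cause, sex) -> 26-band count vector
    rows: dict[tuple[str, int, str, int], np.ndarray] = {}
    truth_rows, acct_rows, pop_rows = [], [], []

    def _emit(country: str, year: int, cause: str, age: str, n: int) -> None:
        if n == 0:
            return
        m = int(rng.binomial(n, 0.5))
        for sex, cnt in ((1, m), (2, n - m)):
            if cnt == 0:
                continue
            key = (country, year, cause, sex)
            vec = rows.setdefault(key, np.zeros(26, dtype=np.int64))
            vec[_AGE_TO_BAND[age] - 1] += cnt

    for cs in config.countries:
        cause_flags = {c: classify(c) for c in cs.other_causes}
        for year in range(y0, y1 + 1):
            q1 = _q_at(cs.q1, year, y0, y1)
            q2 = _q_at(cs.q2, year, y0, y1)
            q3 = _q_at(cs.q3, year, y0, y1)
            for a in AGE_GROUPS:
                pop = int(cs.population[a])
                pop_rows.append(
                    {"location": cs.code, "year": year, "age_group": a,
                     "population": pop}
                )
                # true cause counts for this stratum
                stratum: dict[str, int] = {}
                rate = _rate_at(cs.fall_rate[a], cs.fall_trend.get(a, 0.0), year, y0)
                if not 0.0 <= rate <= 1.0:
                    raise GenerationError(
                        f"fall rate {rate:.4g} outside [0,1] for "
                        f"{cs.code}/{year}/{a}"
                    )
                stratum[_FALL] = int(rng.binomial(pop, rate))
                for cause, r in cs.other_causes.items():
                    if not 0.0 <= r <= 1.0:
                        raise GenerationError(
                            f"rate {r:.4g} for {cause} outside [0,1] ({cs.code}/{year})"
                        )
                    stratum[cause] = int(rng.binomial(pop, r))
                truth_rows.append(
                    {"country": cs.code, "year": year, "age_group": a,
                     "true_falls": stratum[_FALL]}
                )

                for cause, n in stratum.items():
                    if cause == _FALL:
                        injury = unintentional = True
                    else:
                        f = cause_flags[cause]
                        injury = bool(f & CauseCategory.INJURY)
                        unintentional = bool(f & CauseCategory.UNINTENTIONAL_INJURY)
                    r1 = int(rng.binomial(n, q1))
                    rem = n - r1
                    r2 = int(rng.binomial(rem, q2)) if injury else 0
                    rem -= r2
                    r3 = int(rng.binomial(rem, q3)) if unintentional else 0
                    rem -= r3
                    acct_rows.append(
                        {"country": cs.code, "year": year, "age_group": a,
                         "cause": cause, "generated": n, "kept": rem,
                         "to_r99": r1, "to_y34": r2, "to_x59": r3}
                    )
                    _emit(cs.code, year, "R99", a, r1)
                    _emit(cs.code, year, "Y349", a, r2)
                    _emit(cs.code, year, "X599", a, r3)
                    if cause == _FALL:
                        codes, probs = _fall_code_probs(cs.q4, cs.q5)
                        counts = rng.multinomial(rem, probs)
                        for code, cnt in zip(codes, counts):
                            _emit(cs.code, year, code, a, int(cnt))
                    else:
                        _emit(cs.code, year, cause, a, rem)

    file_rows = []
    for (country, year, cause, sex) in sorted(rows):
        vec = rows[(country, year, cause, sex)]
        rec = {"Country": country, "Admin1": "", "SubDiv": "", "Year": year,
               "List": "104", "Cause": cause, "Sex": sex, "Frmat": 0,
               "IM_Frmat": 0, "Deaths1": int(vec[1:].sum())}
        rec.update({f"Deaths{i}": int(vec[i - 1]) for i in range(2, 27)})
        file_rows.append(rec)

    deaths = pd.DataFrame(file_rows)
    population = pd.DataFrame(pop_rows)
    truth = GroundTruth(
        config=config,
        falls=pd.DataFrame(truth_rows),
        accounting=pd.DataFrame(acct_rows),
    )
    return SyntheticDataset(
        config=config, seed=seed, deaths=deaths, population=population, truth=truth
    )


# canonical non-fall cause mix: a non-injury backbone plus injury causes in
# each redistribution universe (per-person annual rates, 65+)
_BASE_CAUSES = {
    "C509": 0.004,   # breast cancer — non-injury
    "I219": 0.008,   # acute MI — non-injury
    "J189": 0.003,   # pneumonia — non-injury
    "X700": 0.0006,  # intentional self-harm — injury, not unintentional
    "V892": 0.0008,  # transport accident — unintentional, non-fall
    "W659": 0.0004,  # drowning — unintentional, non-fall
}

_BASE_FALL_RATE = {"65-69": 0.0015, "70-74": 0.0025, "75-79": 0.004,
                   "80-84": 0.007, "85+": 0.012}
_POP_100K = {a: 100_000 for a in AGE_GROUPS}


def scenario_library() -> dict[str, ScenarioConfig]:
    """Named study scenarios covering the pipeline's regimes.

    * ``clean`` — no garbage at all: correction must be an identity.
    * ``tiered`` — four countries with unspecified-death injection at
      20/40/60/75%, one per income class, driving the four window regimes.
    * ``improving-coding`` — injection rates decline linearly over time
      while true rates are flat, inducing a spurious upward uncorrected
      trend that correction should remove.
    * ``sparse`` — tiny populations exercising zero-denominator fallbacks.
    """
    years = (2004, 2016)
    lib: dict[str, ScenarioConfig] = {}

    lib["clean"] = ScenarioConfig(
        name="clean",
        years=years,
        countries=(
            CountryScenario(
                code="CLN1", income="HICT", population=_POP_100K,
                fall_rate=_BASE_FALL_RATE, other_causes=_BASE_CAUSES,
                q4=0.5, q5=0.5,
            ),
            CountryScenario(
                code="CLN2", income="UMICT", population=_POP_100K,
                fall_rate=_BASE_FALL_RATE, other_causes=_BASE_CAUSES,
                fall_trend={a: 2e-5 for a in AGE_GROUPS},
                q4=0.2, q5=0.8,
            ),
        ),
    )

    tier_rates = {"TIER20": 0.20, "TIER40": 0.40, "TIER60": 0.60, "TIER75": 0.75}
    incomes = dict(zip(tier_rates, ("LICT", "LMICT", "UMICT", "HICT")))
    lib["tiered"] = ScenarioConfig(
        name="tiered",
        years=years,
        countries=tuple(
            CountryScenario(
                code=code, income=incomes[code], population=_POP_100K,
                fall_rate=_BASE_FALL_RATE, other_causes=_BASE_CAUSES,
                q1=q, q4=0.4, q5=0.6,
            )
            for code, q in tier_rates.items()
        ),
    )

    lib["improving-coding"] = ScenarioConfig(
        name="improving-coding",
        years=years,
        countries=(
            CountryScenario(
                code="IMPR", income="UMICT", population=_POP_100K,
                fall_rate=_BASE_FALL_RATE, other_causes=_BASE_CAUSES,
                q1=(0.50, 0.05), q2=(0.20, 0.02), q3=(0.20, 0.02),
                q4=0.4, q5=0.6,
            ),
        ),
    )

    lib["sparse"] = ScenarioConfig(
        name="sparse",
        years=years,
        countries=(
            CountryScenario(
                code="SPRS", income="LMICT",
                population={a: 600 for a in AGE_GROUPS},
                fall_rate=_BASE_FALL_RATE, other_causes=_BASE_CAUSES,
                q1=0.6, q2=0.1, q3=0.1, q4=0.5, q5=0.5,
            ),
        ),
    )
    return lib
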