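"""Category tallies, the five indicator proportions, availability bins,
and the income-group comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_norm
from fallqc.icd_taxonomy import CauseCategory, classify, place_of_occurrence, PlaceOfOccurrence
from fallqc.quality_metrics import (
    CategoryCounts,
    availability,
    icd_revision,
    income_group_comparison,
    quality_profile,
    quality_table,
    tally_categories,
)

HAND_ROWS = [("W19", 10), ("W009", 5), ("X59", 3), ("R99", 2), ("C50", 80)]


def test_hand_tally():
    """Hand-derived tally: W19 (no 4th digit) counts as unknown place."""
    counts = tally_categories(make_norm(HAND_ROWS))
    assert counts.n_total == 100
    assert counts.n_unspecified == 2
    assert counts.n_injury == 18
    assert counts.n_undetermined == 0
    assert counts.n_unintentional == 18
    assert counts.n_x59 == 3
    assert counts.n_fall == 15
    assert counts.n_w19 == 10
    assert counts.n_fall_place_unknown == 15


def test_tally_matches_bruteforce_recount(tiered_data):
    """quality_table proportions equal a raw per-row recount that never
    builds CategoryCounts."""
    deaths = tiered_data["deaths"]
    qt = quality_table(deaths)
    ages = ["65-69", "70-74", "75-79", "80-84", "85+"]
    for _, rec in qt.sample(6, random_state=0).iterrows():
        rows = deaths[(deaths["country"] == rec["country"]) & (deaths["year"] == rec["year"])]
        tot = unspec = fall = w19 = 0.0
        for _, r in rows.iterrows():
            n = sum(r[a] for a in ages)
            f = classify(r["cause"])
            tot += n
            unspec += n if f & CauseCategory.UNSPECIFIED_DEATH else 0
            fall += n if f & CauseCategory.FALL else 0
            w19 += n if f & CauseCategory.FALL_UNSPECIFIED_MECHANISM else 0
        assert rec["proportion_one"] == pytest.approx(unspec / tot)
        assert rec["proportion_four"] == pytest.approx(w19 / fall)


def test_tally_rejects_mixed_country_year():
    df = pd.concat([make_norm([("W00", 1)], year=2010),
                    make_norm([("W00", 1)], year=2011)])
    with pytest.raises(ValueError, match="share"):
        tally_categories(df)


def test_tally_only_unspecified():
    counts = tally_categories(make_norm([("R99", 7)]))
    assert counts.n_total == 7 and counts.n_unspecified == 7
    assert counts.n_injury == counts.n_fall == 0


def test_counts_invariant_chain_enforced():
    with pytest.raises(ValueError, match="n_w19"):
        CategoryCounts("A", 2010, n_total=10, n_unspecified=0, n_injury=5,
                       n_undetermined=0, n_unintentional=5, n_x59=0,
                       n_fall=2, n_w19=3, n_fall_place_unknown=0)


def test_quality_profile_ratios_and_undefined():
    counts = tally_categories(make_norm(HAND_ROWS))
    prof = quality_profile(counts)
    assert prof.proportion_one == pytest.approx(0.02)
    assert prof.proportion_four == pytest.approx(10 / 15)
    assert prof.proportion_five == pytest.approx(1.0)
    # zero denominators are undefined, never 0/0 -> 0
    prof2 = quality_profile(tally_categories(make_norm([("C50", 5)])))
    assert prof2.proportion_two is None
    assert prof2.proportion_four is None
    assert prof2.proportion_one == 0.0


@pytest.mark.parametrize(
    "n_years,expected",
    [(1, "1-5"), (3, "1-5"), (5, "1-5"), (6, "6-10"), (15, "11-15"),
     (27, "26-30"), (30, "26-30")],
)
def test_availability_bins(n_years, expected):
    df = pd.concat(
        [make_norm([("W00", 1)], country="AAA", year=1990 + i) for i in range(n_years)]
    )
    bins, _ = availability(df)
    assert bins.set_index("country").loc["AAA", "bin"] == expected


def test_availability_absent_state_binned_zero():
    df = make_norm([("W00", 1)], country="AAA", year=2000)
    bins, revs = availability(df, member_states=["AAA", "ZZZ"])
    b = bins.set_index("country")
    assert b.loc["ZZZ", "bin"] == "0" and b.loc["ZZZ", "n_years"] == 0
    assert revs.set_index(["country", "year"]).loc[("AAA", 2000), "revision"] == "ICD-10"


@pytest.mark.parametrize(
    "list_id,rev",
    [("104", "ICD-10"), ("10M", "ICD-10"), ("09B", "ICD-9"), ("08A", "ICD-8"),
     ("07A", "ICD-7"), ("UE1", "other")],
)
def test_icd_revision_from_list_tag(list_id, rev):
    assert icd_revision(list_id) == rev


def _profiles(values_by_country):
    rows = []
    for country, values in values_by_country.items():
        for i, v in enumerate(values):
            rows.append({"country": country, "year": 2000 + i, "proportion_one": v})
    return pd.DataFrame(rows)


def test_income_comparison_no_variation():
    profs = _profiles({"A": [0.2, 0.2], "B": [0.2], "C": [0.2], "D": [0.2]})
    income = pd.Series({"A": "LICT", "B": "LMICT", "C": "UMICT", "D": "HICT"})
    res = income_group_comparison(profs, income, 1)
    assert res.h_statistic == 0.0 and res.p_value == 1.0


def test_income_comparison_separated_groups():
    """Two fully separated groups of 3: H matches the rank-sum formula
    computed independently, and the asymptotic p is significant."""
    profs = _profiles({"A": [0.1, 0.2, 0.3], "B": [0.7, 0.8, 0.9]})
    income = pd.Series({"A": "LICT", "B": "HICT"})
    res = income_group_comparison(profs, income, 1)
    # brute-force H: ranks 1..6, group means 2 and 5
    h = 12 / (6 * 7) * (3 * (2 - 3.5) ** 2 + 3 * (5 - 3.5) ** 2)
    assert res.h_statistic == pytest.approx(h)
    assert res.p_value < 0.05


def test_income_comparison_group_summary_quartiles():
    rng = np.random.default_rng(0)
    sizes = {"A": 6, "B": 121, "C": 60, "D": 97}
    profs = _profiles({c: rng.uniform(0, 1, n).tolist() for c, n in sizes.items()})
    income = pd.Series({"A": "LICT", "B": "LMICT", "C": "UMICT", "D": "HICT"})
    res = income_group_comparison(profs, income, 1)
    assert len(res.group_summary) == 4
    # sort-based quartile oracle (linear interpolation convention)
    for _, row in res.group_summary.iterrows():
        grp = [c for c, g in income.items() if g == row["income_group"]][0]
        vals = np.sort(profs.loc[profs["country"] == grp, "proportion_one"].to_numpy())
        assert row["n"] == sizes[grp]
        assert row["median"] == pytest.approx(np.quantile(vals, 0.5))
        assert row["p25"] == pytest.approx(np.quantile(vals, 0.25))
        assert row["p75"] == pytest.approx(np.quantile(vals, 0.75))


def test_income_comparison_needs_two_groups():
    profs = _profiles({"A": [0.1, 0.2]})
    income = pd.Series({"A": "HICT"})
    with pytest.raises(ValueError, match="2"):
        income_group_comparison(profs, income, 1)
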