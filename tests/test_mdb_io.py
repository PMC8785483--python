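"""Flat-file loading: normalisation, validation, and round-trips."""

import logging

import numpy as np
import pandas as pd
import pytest

from conftest import make_raw_row, write_raw
from fallqc import mdb_io
from fallqc.mdb_io import (
    AGE_GROUPS,
    MdbFormatError,
    MdbValidationError,
    PopulationLookupError,
)


def test_single_row_65plus_passthrough(tmp_path):
    """Seven 65+ bands of one death each give a 65+ total of 7, with the
    three terminal bands merged into 85+."""
    path = write_raw(
        [make_raw_row(cause="W19", bands={i: 1 for i in range(19, 26)})],
        tmp_path / "d.csv",
    )
    df = mdb_io.read_death_file(path, age_floor=65)
    assert len(df) == 1
    row = df.iloc[0]
    assert row["total"] == 7
    assert row["65-69"] == row["70-74"] == row["75-79"] == row["80-84"] == 1
    assert row["85+"] == 3


def test_age_floor_zeroes_younger_bands(tmp_path):
    path = write_raw(
        [make_raw_row(cause="W00", bands={7: 10, 19: 2})], tmp_path / "d.csv"
    )
    df65 = mdb_io.read_death_file(path, age_floor=65)
    assert df65.iloc[0]["total"] == 2
    df0 = mdb_io.read_death_file(path, age_floor=0)
    assert df0.iloc[0]["total"] == 12
    assert df0.iloc[0]["65-69"] == 2


def test_unsupported_frmat_rejected_with_diagnostic(tmp_path, caplog):
    rows = [
        make_raw_row(cause="W00", bands={19: 1}),
        make_raw_row(cause="W01", bands={19: 1}, frmat=2),
    ]
    path = write_raw(rows, tmp_path / "d.csv")
    with caplog.at_level(logging.WARNING):
        df = mdb_io.read_death_file(path)
    assert df["cause"].tolist() == ["W00"]
    assert df.attrs["diagnostics"]["rows_rejected_frmat"] == 1
    assert any("Frmat" in r.message for r in caplog.records)


def test_sexes_combined_per_country_year_cause(tmp_path):
    rows = [
        make_raw_row(cause="W00", sex=1, bands={19: 3}),
        make_raw_row(cause="W00", sex=2, bands={19: 4}),
    ]
    df = mdb_io.read_death_file(write_raw(rows, tmp_path / "d.csv"))
    assert len(df) == 1
    assert df.iloc[0]["65-69"] == 7


def test_missing_column_is_fatal_and_named(tmp_path):
    path = tmp_path / "d.csv"
    pd.DataFrame({"Country": ["A"], "Year": [2000]}).to_csv(path, index=False)
    with pytest.raises(MdbFormatError, match="Cause"):
        mdb_io.read_death_file(path)


def test_negative_count_is_fatal_with_row_number(tmp_path):
    rows = [
        make_raw_row(cause="W00", bands={19: 1}),
        make_raw_row(cause="W01", bands={19: -2}, deaths1=-2),
    ]
    path = write_raw(rows, tmp_path / "d.csv")
    with pytest.raises(MdbValidationError, match="row 3"):
        mdb_io.read_death_file(path)


def test_unparseable_cause_dropped_and_counted(tmp_path, caplog):
    rows = [
        make_raw_row(cause="W00", bands={19: 1}),
        make_raw_row(cause="AAA", bands={19: 5}),
    ]
    path = write_raw(rows, tmp_path / "d.csv")
    with caplog.at_level(logging.WARNING):
        df = mdb_io.read_death_file(path)
    assert df["cause"].tolist() == ["W00"]
    assert df.attrs["diagnostics"]["rows_dropped_bad_cause"] == 1


def test_stored_total_mismatch_flagged_not_fatal(tmp_path):
    path = write_raw(
        [make_raw_row(cause="W00", bands={19: 5}, deaths1=99)], tmp_path / "d.csv"
    )
    df = mdb_io.read_death_file(path)
    assert df.iloc[0]["total"] == 5  # recomputed, stored total ignored
    assert df.attrs["diagnostics"]["rows_total_mismatch"] == 1


def test_unknown_age_excluded_from_totals_but_logged(tmp_path):
    path = write_raw(
        [make_raw_row(cause="W00", bands={19: 5}, unknown=3)], tmp_path / "d.csv"
    )
    df = mdb_io.read_death_file(path)
    assert df.iloc[0]["total"] == 5
    assert df.attrs["diagnostics"]["unknown_age_deaths"] == 3


def test_synthetic_round_trip_preserves_counts(sparse_data):
    """Write-then-read of a generated file reproduces every count."""
    ds, deaths = sparse_data["ds"], sparse_data["deaths"]
    raw = ds.deaths
    band_cols = [f"Deaths{i}" for i in range(2, 26)]
    want = (
        raw.assign(n=raw[band_cols].sum(axis=1))
        .groupby(["Country", "Year", "Cause"])["n"].sum()
    )
    got = deaths.set_index(["country", "year", "cause"])["total"]
    assert len(want) == len(got)
    for key, n in want.items():
        assert got[key] == n


def test_population_collapse_85plus(tmp_path):
    path = tmp_path / "p.csv"
    pd.DataFrame(
        {
            "location": ["AAA"] * 3,
            "year": [2010] * 3,
            "age_group": ["85-89", "90-94", "95+"],
            "population": [100, 50, 10],
        }
    ).to_csv(path, index=False)
    pop = mdb_io.read_population_file(path)
    assert len(pop) == 1
    assert pop.iloc[0]["age_group"] == "85+"
    assert pop.iloc[0]["population"] == 160


def test_population_thousands_scaling(tmp_path):
    path = tmp_path / "p.csv"
    pd.DataFrame(
        {"location": ["AAA"], "year": [2010], "age_group": ["65-69"],
         "population": [12.5]}
    ).to_csv(path, index=False)
    pop = mdb_io.read_population_file(path, units="thousands")
    assert pop.iloc[0]["population"] == 12500


def test_population_nonpositive_fatal(tmp_path):
    path = tmp_path / "p.csv"
    pd.DataFrame(
        {"location": ["AAA"], "year": [2010], "age_group": ["65-69"],
         "population": [0]}
    ).to_csv(path, index=False)
    with pytest.raises(MdbValidationError):
        mdb_io.read_population_file(path)


def test_population_round_trip(tmp_path, sparse_data):
    pop = sparse_data["pop"]
    out = tmp_path / "pop2.csv"
    mdb_io.write_population_file(pop, out)
    again = mdb_io.read_population_file(out)
    pd.testing.assert_frame_equal(
        pop.sort_values(["country", "year", "age_group"]).reset_index(drop=True),
        again.sort_values(["country", "year", "age_group"]).reset_index(drop=True),
    )


def test_income_lookup_reads_all_four_classes(tmp_path):
    path = tmp_path / "i.csv"
    pd.DataFrame(
        {"country": ["A", "B", "C", "D"],
         "income_group": ["LICT", "LMICT", "UMICT", "HICT"]}
    ).to_csv(path, index=False)
    lut = mdb_io.read_income_lookup(path)
    assert len(lut) == 4
    assert lut["D"] == "HICT"


def test_income_lookup_rejects_unknown_label(tmp_path):
    path = tmp_path / "i.csv"
    pd.DataFrame({"country": ["A"], "income_group": ["MIDDLE"]}).to_csv(
        path, index=False
    )
    with pytest.raises(MdbValidationError, match="MIDDLE"):
        mdb_io.read_income_lookup(path)


def test_income_lookup_conflicting_duplicate_fatal(tmp_path):
    path = tmp_path / "i.csv"
    pd.DataFrame(
        {"country": ["A", "A"], "income_group": ["HICT", "LICT"]}
    ).to_csv(path, index=False)
    with pytest.raises(MdbValidationError, match="A"):
        mdb_io.read_income_lookup(path)


def test_get_population_missing_pair_named(sparse_data):
    with pytest.raises(PopulationLookupError, match="XXX.*1901"):
        mdb_io.get_population(sparse_data["pop"], "XXX", 1901)
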