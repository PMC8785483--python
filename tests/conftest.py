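import numpy as np
import pandas as pd
import pytest

from fallqc import mdb_io, synthetic_mdb as sm
from fallqc.mdb_io import AGE_GROUPS

_DEATH_COLS = ["Country", "Admin1", "SubDiv", "Year", "List", "Cause", "Sex",
               "Frmat", "IM_Frmat"] + [f"Deaths{i}" for i in range(1, 27)]


def make_raw_row(country="AAA", year=2010, cause="W00", sex=1, frmat=0,
                 list_id="104", bands=None, deaths1=None, unknown=0):
    """One WHO-MDB-dialect file row; ``bands`` maps Deaths index -> count."""
    rec = dict.fromkeys(_DEATH_COLS, 0)
    rec.update(Country=country, Admin1="", SubDiv="", Year=year, List=list_id,
               Cause=cause, Sex=sex, Frmat=frmat, IM_Frmat=0)
    bands = bands or {}
    for idx, n in bands.items():
        rec[f"Deaths{idx}"] = n
    rec["Deaths26"] = unknown
    rec["Deaths1"] = deaths1 if deaths1 is not None else sum(bands.values()) + unknown
    return rec


def write_raw(rows, path):
    pd.DataFrame(rows, columns=_DEATH_COLS).to_csv(path, index=False)
    return path


def make_norm(records, country="AAA", year=2010):
    """Normalised death table from (cause, {age_group: n}) or (cause, n65) pairs.

    A bare integer count lands in the 65-69 group.
    """
    rows = []
    for cause, counts in records:
        if isinstance(counts, (int, float)):
            counts = {"65-69": counts}
        row = {"country": country, "year": year, "list_id": "104", "cause": cause}
        for a in AGE_GROUPS:
            row[a] = float(counts.get(a, 0))
        row["total"] = float(sum(counts.values()))
        row["unknown_age"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiered_data(tmp_path_factory):
    """Generated tiered scenario (seed 1) loaded through the file readers."""
    ds = sm.generate(sm.scenario_library()["tiered"], seed=1)
    d = tmp_path_factory.mktemp("tiered")
    paths = ds.write(d)
    deaths = mdb_io.read_death_file(paths["deaths"])
    pop = mdb_io.read_population_file(paths["population"])
    return {"ds": ds, "deaths": deaths, "pop": pop, "paths": paths}


@pytest.fixture(scope="session")
def sparse_data(tmp_path_factory):
    ds = sm.generate(sm.scenario_library()["sparse"], seed=5)
    d = tmp_path_factory.mktemp("sparse")
    paths = ds.write(d)
    deaths = mdb_io.read_death_file(paths["deaths"])
    pop = mdb_io.read_population_file(paths["population"])
    return {"ds": ds, "deaths": deaths, "pop": pop, "paths": paths}
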