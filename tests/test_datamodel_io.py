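"""Domain-type invariants, CSV round-trips, and fixture audits."""

import math

import pandas as pd
import pytest

from ecorisk import (
    DoseResponseDataset,
    QuantalCount,
    ToxicityRecord,
    Treatment,
    ValidationError,
    load_packaged_fixture,
    read_assay_dataset,
    read_toxicity_records,
    write_assay_dataset,
    write_toxicity_records,
)
from ecorisk.io import SchemaError, fixture_names, fixture_path


# --- domain type invariants -------------------------------------------------


def test_toxicity_record_invariants():
    with pytest.raises(ValidationError):
        ToxicityRecord("x", "algae", "EC50", "acute", 72, -1.0)
    with pytest.raises(ValidationError):
        ToxicityRecord("x", "algae", "EC50", "acute", 72, 5.0, ci_low=6.0, ci_high=7.0)
    with pytest.raises(ValidationError):
        ToxicityRecord("x", "plankton", "EC50", "acute", 72, 5.0)


def test_quantal_count_invariants():
    with pytest.raises(ValidationError):
        QuantalCount(20, 21)
    assert QuantalCount(20, 5).proportion == 0.25


def _treatments(concs, sc=True):
    ts = [Treatment(label="C", nominal_conc=0, is_control=True, rates=(1.0, 1.1, 0.9))]
    if sc:
        ts.append(Treatment(label="SC", nominal_conc=0, is_solvent_control=True,
                            rates=(1.0, 1.1, 0.9)))
    ts += [Treatment(label=str(c), nominal_conc=c, rates=(0.5, 0.6, 0.4)) for c in concs]
    return ts


def test_dataset_invariants():
    with pytest.raises(ValidationError):  # too few treatments
        DoseResponseDataset("algal_growth", "x", 72, _treatments([1, 2, 3]))
    with pytest.raises(ValidationError):  # not strictly increasing
        DoseResponseDataset("algal_growth", "x", 72, _treatments([1, 2, 2, 4]))
    ds = DoseResponseDataset("algal_growth", "x", 72, _treatments([1, 2, 4, 8]))
    assert len(ds.exposed_treatments()) == 4
    assert ds.reference_treatment().is_solvent_control


def test_reference_falls_back_to_plain_control():
    ds = DoseResponseDataset("algal_growth", "x", 72, _treatments([1, 2, 4, 8], sc=False))
    assert ds.reference_treatment().is_control


# --- toxicity CSV -----------------------------------------------------------


def test_read_acute_fixture_species_composition():
    records = load_packaged_fixture("table4_acute")
    assert len(records) == 9
    by_taxon = {t: sum(r.taxon_group == t for r in records)
                for t in ("algae", "crustacean", "fish")}
    assert by_taxon == {"algae": 3, "crustacean": 2, "fish": 4}


def test_read_empty_and_malformed(tmp_path):
    p = tmp_path / "t.csv"
    header = "species,taxon_group,endpoint,exposure_class,duration_hours,value_ugL,ci_low,ci_high\n"
    p.write_text(header)
    assert read_toxicity_records(p) == []
    p.write_text(header + "x,algae,EC50,acute,72,-1,,\n")
    with pytest.raises(ValidationError, match="row 1"):
        read_toxicity_records(p)
    p.write_text("species,value_ugL\nx,1\n")
    with pytest.raises(SchemaError, match="missing required columns"):
        read_toxicity_records(p)


def test_toxicity_roundtrip(tmp_path):
    records = load_packaged_fixture("table4_chronic")
    out = tmp_path / "o.csv"
    write_toxicity_records(records, out)
    assert read_toxicity_records(out) == records


# --- assay CSV --------------------------------------------------------------


def test_assay_roundtrip_continuous(tmp_path, skeletonema):
    out = tmp_path / "a.csv"
    write_assay_dataset(skeletonema, out)
    back = read_assay_dataset(out)
    assert back == skeletonema


def test_assay_roundtrip_quantal(tmp_path, tigriopus):
    out = tmp_path / "q.csv"
    write_assay_dataset(tigriopus, out)
    assert read_assay_dataset(out) == tigriopus


def test_mixed_units_rejected(tmp_path, skeletonema):
    out = tmp_path / "a.csv"
    write_assay_dataset(skeletonema, out)
    df = pd.read_csv(out)
    df.loc[3:, "unit"] = "mg/L"
    df.to_csv(out, index=False)
    with pytest.raises(SchemaError, match="mixed units"):
        read_assay_dataset(out)


def test_mg_per_l_scaled_on_read(tmp_path, skeletonema):
    out = tmp_path / "a.csv"
    write_assay_dataset(skeletonema, out)
    df = pd.read_csv(out)
    df["unit"] = "mg/L"
    df.to_csv(out, index=False)
    ds = read_assay_dataset(out)
    assert ds.unit == "mg/L"
    assert max(t.nominal_conc for t in ds.treatments) == pytest.approx(14_000.0)


def test_duplicate_solvent_control_rejected(tmp_path, skeletonema):
    out = tmp_path / "a.csv"
    write_assay_dataset(skeletonema, out)
    df = pd.read_csv(out)
    df.loc[df["label"] == "Control", "is_solvent_control"] = True
    df.to_csv(out, index=False)
    with pytest.raises(ValidationError):
        read_assay_dataset(out)


def test_bad_quantal_counts_rejected(tmp_path, tigriopus):
    out = tmp_path / "q.csv"
    write_assay_dataset(tigriopus, out)
    df = pd.read_csv(out)
    df.loc[df.index[-1], "n_immobile"] = 99
    df.to_csv(out, index=False)
    with pytest.raises(ValidationError):
        read_assay_dataset(out)


# --- packaged fixtures ------------------------------------------------------


def test_unknown_fixture_lists_available():
    with pytest.raises(LookupError, match="table4_acute"):
        load_packaged_fixture("nosuch")


def test_fixture_registry_complete():
    names = fixture_names()
    for expected in ("table1_skeletonema", "table2_tigriopus", "table3_dmdc",
                     "table4_acute", "table5_reference", "exposure_hiroshima"):
        assert expected in names


# hand-transcribed spot checks: (fixture, row label, column, value)
_CELL_CHECKS = [
    ("table1_skeletonema", "7", "measured_start_ugL", 1.77),
    ("table1_skeletonema", "7", "geomean_ugL", 0.65),
    ("table1_skeletonema", "7", "rate_mean", 1.06),
    ("table1_skeletonema", "14", "rate_mean", -0.68),
    ("table1_dunaliella", "10", "rate_mean", 0.76),
    ("table1_dunaliella", "2.5", "geomean_ugL", 0.13),
    ("table2_tigriopus", "2.5", "geomean_ugL", 0.9),
    ("table2_tigriopus", "2.5", "n_exposed", 18),
    ("table2_tigriopus", "2.5", "n_immobile", 4),
    ("table2_bluecrab", "40", "n_immobile", 12),
    ("table3_dmdc", "5", "rate_mean", 0.93),
    ("table3_ebdc", "20", "rate_mean", -0.33),
]


@pytest.mark.parametrize("fixture, label, column, value", _CELL_CHECKS)
def test_fixture_cells_match_transcription(fixture, label, column, value):
    df = pd.read_csv(fixture_path(fixture))
    row = df[df["label"] == label].iloc[0]
    assert row[column] == pytest.approx(value)


def test_quantal_dataset_shape(tigriopus):
    exposed = tigriopus.exposed_treatments()
    assert len(exposed) == 5
    assert all(18 <= t.quantal.n_exposed <= 21 for t in exposed)


def test_skeletonema_dataset_shape(skeletonema):
    assert len(skeletonema.exposed_treatments()) == 5
    assert skeletonema.solvent_control is not None
    assert skeletonema.control is not None


def test_fixture_loads_are_identical():
    a = load_packaged_fixture("table1_skeletonema")
    b = load_packaged_fixture("table1_skeletonema")
    assert a == b
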