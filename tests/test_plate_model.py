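"""Readers, layout invariants, cross-validation, and tidy round-trips."""

import numpy as np
import pandas as pd
import pytest

from biofilmassay import plate_model as pm

READINGS_CSV = """plate_id,well,channel,timepoint_h,stage,absorbance
P1,A1,OD570,24,growth_endpoint,0.21
P1,A2,OD570,24,growth_endpoint,0.35
P1,A3,OD570,24,growth_endpoint,-0.02
"""

LAYOUT_CSV = """plate_id,well,role,isolate_id,factor,level,bio_rep,tech_rep
P1,A1,sample,ISO.A,baseline,,1,1
P1,A2,sample,ISO.A,baseline,,1,2
P1,A3,sample,ISO.B,baseline,,1,1
P1,H12,sterility_control,,baseline,,1,1
"""


@pytest.fixture
def readings_file(tmp_path):
    p = tmp_path / "readings.csv"
    p.write_text(READINGS_CSV)
    return p


@pytest.fixture
def layout_file(tmp_path):
    p = tmp_path / "layout.csv"
    p.write_text(LAYOUT_CSV)
    return p


class TestReadPlateLong:
    def test_row_count_preserved(self, readings_file):
        df = pm.read_plate_long(readings_file)
        assert len(df) == 3
        assert list(df["well"]) == ["A1", "A2", "A3"]
        # blanked negative absorbances are kept as-is
        assert df["absorbance"].iloc[2] == -0.02

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("plate_id,well,channel,timepoint_h,stage,absorbance\n")
        df = pm.read_plate_long(p)
        assert df.empty and list(df.columns) == pm.READING_COLUMNS

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(READINGS_CSV + "P1,A1,OD570,24,growth_endpoint,0.50\n")
        with pytest.raises(ValueError, match="duplicate"):
            pm.read_plate_long(p)

    @pytest.mark.parametrize("row, match", [
        ("P1,Z9,OD570,24,growth_endpoint,0.1", "line 5"),
        ("P1,A4,OD999,24,growth_endpoint,0.1", "line 5"),
        ("P1,A4,OD570,24,growth_endpoint,notanumber", "line 5"),
        ("P1,A4,OD570,-1,growth_endpoint,0.1", "line 5"),
        ("P1,A4,OD570,24,bogus_stage,0.1", "line 5"),
    ])
    def test_malformed_row_names_line(self, tmp_path, row, match):
        p = tmp_path / "bad.csv"
        p.write_text(READINGS_CSV + row + "\n")
        with pytest.raises(ValueError, match=match):
            pm.read_plate_long(p)


class TestReadLayout:
    def test_valid_layout(self, layout_file):
        df = pm.read_layout(layout_file)
        assert len(df) == 4
        assert set(df["role"]) == {"sample", "sterility_control"}

    def test_sterility_control_required(self, tmp_path):
        p = tmp_path / "nosc.csv"
        p.write_text("plate_id,well,role,isolate_id,factor,level,bio_rep,tech_rep\n"
                     "P1,A1,sample,ISO.A,baseline,,1,1\n")
        with pytest.raises(ValueError, match="sterility control required"):
            pm.read_layout(p)

    def test_sample_without_isolate_rejected(self, tmp_path):
        p = tmp_path / "anon.csv"
        p.write_text("plate_id,well,role,isolate_id,factor,level,bio_rep,tech_rep\n"
                     "P1,A1,sample,,baseline,,1,1\n"
                     "P1,H12,sterility_control,,baseline,,1,1\n")
        with pytest.raises(ValueError, match="isolate_id"):
            pm.read_layout(p)

    def test_many_isolates_recovered(self, tmp_path):
        # 10 isolates x 9 wells + 3 controls over two plates
        rows = ["plate_id,well,role,isolate_id,factor,level,bio_rep,tech_rep"]
        for plate, block in (("P1", range(5)), ("P2", range(5, 10))):
            idx = 0
            for i in block:
                for bio in (1, 2, 3):
                    for tech in (1, 2, 3):
                        rows.append(f"{plate},{pm.well_name(idx)},sample,ISO.{i},baseline,,{bio},{tech}")
                        idx += 1
            for tech in (1, 2, 3):
                rows.append(f"{plate},{pm.well_name(idx)},sterility_control,,baseline,,1,{tech}")
                idx += 1
        p = tmp_path / "big.csv"
        p.write_text("\n".join(rows) + "\n")
        df = pm.read_layout(p)
        samples = df[df["role"] == "sample"]
        assert samples["isolate_id"].nunique() == 10
        assert len(samples) == 90


class TestValidate:
    def test_consistent_dataset_passes(self, small_dataset):
        readings, layout, _ = small_dataset
        report = pm.validate(readings, layout)
        assert report.ok

    def test_orphan_reading_reported(self, readings_file, layout_file):
        readings = pm.read_plate_long(readings_file)
        layout = pm.read_layout(layout_file)
        orphan = readings.iloc[[0]].assign(well="B7")
        report = pm.validate(pd.concat([readings, orphan]), layout)
        assert [i for i in report.errors() if "absent from the layout" in i.message]

    def test_missing_rz_baseline_warns(self, readings_file, layout_file):
        readings = pm.read_plate_long(readings_file)
        layout = pm.read_layout(layout_file)
        rz_final = readings.iloc[[0]].assign(stage="rz_final", channel="OD600")
        report = pm.validate(pd.concat([readings, rz_final]), layout)
        assert any("Ro not computable" in i.message for i in report.warnings())

    def test_validate_is_idempotent(self, readings_file, layout_file):
        readings = pm.read_plate_long(readings_file)
        layout = pm.read_layout(layout_file)
        r1 = pm.validate(readings, layout)
        r2 = pm.validate(readings, layout)
        assert r1.issues == r2.issues


class TestTidyRoundTrip:
    def test_round_trip_identity(self, tmp_path, small_dataset):
        readings, _, _ = small_dataset
        path = tmp_path / "readings.tsv"
        pm.write_tidy(readings, path)
        back = pm.read_tidy(path)
        pd.testing.assert_frame_equal(back, readings)

    def test_null_table_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            pm.write_tidy(None, tmp_path / "x.tsv")


def test_grid_to_long_conversion(tmp_path):
    grid = ",1,2,3\nA,0.1,0.2,\nB,0.4,,0.6\n"
    p = tmp_path / "grid.csv"
    p.write_text(grid)
    df = pm.read_plate_grid(p, "P1", "OD570", 24.0, "growth_endpoint")
    assert len(df) == 4  # empty cells skipped
    assert set(df["well"]) == {"A1", "A2", "B1", "B3"}
    assert df.loc[df["well"] == "B3", "absorbance"].item() == 0.6
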