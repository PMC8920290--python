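"""Cell-table reading, unit conversion, QC and phenotype selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_cell_table
from mifspat import (
    RowParseError,
    SchemaError,
    UnknownMarkerError,
    filter_compartment,
    parse_phenotype,
    phenotype_name,
    phenotype_positive_cells,
    read_cell_table,
    read_cell_tables,
    read_clinical_table,
    resolve_conflicting_phenotypes,
    write_cell_tables,
)


def _write(tmp_path, text, name="cells.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


BASIC = "sample_id,subject_id,x,y,CD3,compartment\nS1,P1,100,200,1,tumor\nS1,P1,10,20,0,stroma\n"


class TestReading:
    def test_pixel_coordinates_scaled_by_resolution(self, tmp_path):
        t = read_cell_table(_write(tmp_path, BASIC), coord_units="pixels", mpp=0.4977)
        assert t.cells.loc[0, "x"] == pytest.approx(49.77)
        assert t.cells.loc[0, "y"] == pytest.approx(99.54)

    def test_micron_coordinates_unchanged(self, tmp_path):
        t = read_cell_table(_write(tmp_path, BASIC), coord_units="microns")
        assert t.cells.loc[0, "x"] == 100.0

    def test_missing_required_column_names_it(self, tmp_path):
        bad = "sample_id,subject_id,x,CD3\nS1,P1,1,1\n"
        with pytest.raises(SchemaError, match="y"):
            read_cell_tables(_write(tmp_path, bad))

    def test_non_numeric_coordinate_reports_row(self, tmp_path):
        bad = "sample_id,subject_id,x,y,CD3\nS1,P1,1,2,1\nS1,P1,oops,2,0\n"
        with pytest.raises(RowParseError, match="row 1"):
            read_cell_tables(_write(tmp_path, bad))

    def test_non_binary_marker_rejected(self, tmp_path):
        bad = "sample_id,subject_id,x,y,CD3\nS1,P1,1,2,2\n"
        with pytest.raises(SchemaError, match="CD3"):
            read_cell_tables(_write(tmp_path, bad))

    def test_tab_delimited_and_multiple_samples(self, tmp_path):
        text = "sample_id\tsubject_id\tx\ty\tCD3\nA\tP1\t1\t2\t1\nB\tP2\t3\t4\t0\n"
        tables = read_cell_tables(_write(tmp_path, text, "cells.tsv"))
        assert [t.sample_id for t in tables] == ["A", "B"]
        assert tables[0].subject_id == "P1"

    def test_missing_compartment_defaults_to_unknown(self, tmp_path):
        text = "sample_id,subject_id,x,y,CD3\nS1,P1,1,2,1\n"
        t = read_cell_table(_write(tmp_path, text))
        assert (t.cells["compartment"] == "unknown").all()

    def test_round_trip_preserves_counts_flags_coordinates(self, tmp_path, rng):
        coords = rng.uniform(0, 500, size=(40, 2))
        table = make_cell_table(coords, {"CD3": rng.integers(0, 2, 40), "CD8": rng.integers(0, 2, 40)})
        out = tmp_path / "out.tsv"
        write_cell_tables([table], out)
        back = read_cell_table(out)
        assert back.n_cells == table.n_cells
        np.testing.assert_allclose(back.coords(), table.coords(), atol=1e-6)
        for m in ("CD3", "CD8"):
            np.testing.assert_array_equal(back.cells[m], table.cells[m])


class TestConflictQC:
    def test_double_positive_demoted_to_cd3_only(self, t_cell_table):
        cleaned, n = resolve_conflicting_phenotypes(t_cell_table)
        assert n == 3
        was_conflict = (t_cell_table.cells["CD8"] == 1) & (t_cell_table.cells["FOXP3"] == 1)
        sub = cleaned.cells[was_conflict]
        assert (sub["CD3"] == 1).all() and (sub["CD8"] == 0).all() and (sub["FOXP3"] == 0).all()
        # locations retained
        np.testing.assert_array_equal(cleaned.coords(), t_cell_table.coords())

    def test_no_conflict_passes_through(self):
        table = make_cell_table([[0, 0], [1, 1]], {"CD3": [1, 1], "CD8": [1, 0], "FOXP3": [0, 0]})
        cleaned, n = resolve_conflicting_phenotypes(table)
        assert n == 0
        pd.testing.assert_frame_equal(cleaned.cells, table.cells)

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=30))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent(self, flags):
        cd3, cd8, fox = (list(c) for c in zip(*flags))
        coords = [[float(i), float(i)] for i in range(len(flags))]
        table = make_cell_table(coords, {"CD3": cd3, "CD8": cd8, "FOXP3": fox})
        once, n1 = resolve_conflicting_phenotypes(table)
        twice, n2 = resolve_conflicting_phenotypes(once)
        assert n2 == 0
        pd.testing.assert_frame_equal(once.cells, twice.cells)

    def test_missing_marker_column_is_schema_error(self):
        table = make_cell_table([[0, 0]], {"CD3": [1]})
        with pytest.raises(SchemaError):
            resolve_conflicting_phenotypes(table)


class TestCompartmentFilter:
    def _mixed(self):
        table = make_cell_table(
            np.arange(12).reshape(6, 2), {"CD3": [1, 0, 1, 0, 1, 0]},
        )
        table.cells["compartment"] = ["tumor"] * 4 + ["stroma"] * 2
        return table

    def test_filter_counts(self):
        assert filter_compartment(self._mixed(), "tumor").n_cells == 4
        assert filter_compartment(self._mixed(), "stroma").n_cells == 2

    def test_all_is_identity(self):
        table = self._mixed()
        assert filter_compartment(table, "all") is table

    def test_empty_result_allowed(self):
        table = self._mixed()
        table.cells["compartment"] = "stroma"
        assert filter_compartment(table, "tumor").n_cells == 0

    def test_unknown_only_table_rejects_compartment_filter(self):
        table = make_cell_table([[0, 0]], {"CD3": [1]})
        with pytest.raises(ValueError, match="compartment"):
            filter_compartment(table, "tumor")


class TestPhenotypes:
    def test_single_marker_count(self):
        table = make_cell_table([[0, 0], [1, 1], [2, 2]], {"CD3": [1, 0, 1]})
        assert len(phenotype_positive_cells(table, {"CD3"})) == 2

    def test_conjunction_requires_all_markers(self, t_cell_table):
        cd3 = phenotype_positive_cells(t_cell_table, "CD3")
        cyto = phenotype_positive_cells(t_cell_table, "CD3+CD8+")
        assert len(cyto) <= len(cd3)
        mask = (t_cell_table.cells["CD3"] == 1) & (t_cell_table.cells["CD8"] == 1)
        assert len(cyto) == int(mask.sum())

    def test_cd8_without_cd3_not_a_t_cell_phenotype(self):
        table = make_cell_table([[0, 0], [1, 1]], {"CD3": [0, 1], "CD8": [1, 1]})
        assert len(phenotype_positive_cells(table, ("CD3", "CD8"))) == 1

    def test_empty_phenotype_is_an_error(self, t_cell_table):
        with pytest.raises(ValueError):
            phenotype_positive_cells(t_cell_table, ())

    def test_unknown_marker_is_an_error(self, t_cell_table):
        with pytest.raises(UnknownMarkerError):
            phenotype_positive_cells(t_cell_table, {"CD99"})

    def test_parse_and_name(self):
        assert parse_phenotype("CD3+CD8+") == ("CD3", "CD8")
        assert phenotype_name(("CD3", "FOXP3")) == "CD3+FOXP3+"

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_conjunction_never_larger_than_single_marker(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 40))
        table = make_cell_table(
            r.uniform(0, 10, (n, 2)), {"CD3": r.integers(0, 2, n), "CD8": r.integers(0, 2, n)}
        )
        assert len(phenotype_positive_cells(table, {"CD3", "CD8"})) <= len(
            phenotype_positive_cells(table, {"CD3"})
        )


class TestClinical:
    GOOD = "subject_id,time_months,event,age_dx,stage\nP1,12.5,1,61,III\nP2,40,0,55,2\n"

    def test_reads_and_normalises_stage(self, tmp_path):
        df = read_clinical_table(_write(tmp_path, self.GOOD, "clin.csv"))
        assert list(df["stage"]) == ["III", "II"]

    def test_duplicate_subject_rejected(self, tmp_path):
        bad = self.GOOD + "P1,3,1,70,IV\n"
        with pytest.raises(SchemaError, match="duplicate"):
            read_clinical_table(_write(tmp_path, bad, "clin.csv"))

    def test_nonpositive_time_rejected(self, tmp_path):
        bad = "subject_id,time_months,event,age_dx,stage\nP1,0,1,61,III\n"
        with pytest.raises(SchemaError, match="time"):
            read_clinical_table(_write(tmp_path, bad, "clin.csv"))

    def test_invalid_stage_rejected(self, tmp_path):
        bad = "subject_id,time_months,event,age_dx,stage\nP1,5,1,61,V\n"
        with pytest.raises(SchemaError, match="stage"):
            read_clinical_table(_write(tmp_path, bad, "clin.csv"))
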