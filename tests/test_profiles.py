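"""Profile IO round trips and the marker/abundance/kitome filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suitbiome import profiles as prof


def test_roundtrip_write_read(tmp_path, tiny_matrix):
    path = tmp_path / "p.tsv"
    prof.write_profiles(tiny_matrix, path)
    back = prof.read_profiles(path)
    # zero cells are not serialized; compare on the nonzero support
    orig = tiny_matrix.counts.loc[back.counts.index, back.counts.columns]
    pd.testing.assert_frame_equal(back.counts, orig, check_dtype=False)
    mk = tiny_matrix.markers.loc[back.counts.index, back.counts.columns]
    pd.testing.assert_frame_equal(back.markers, mk, check_dtype=False)


def test_roundtrip_random_matrix(tmp_path):
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(1, 100, (3, 4)),
                          index=list("XYZ"), columns=[f"T{i}" for i in range(4)])
    m = prof.ProfileMatrix(counts=counts, markers=counts * 10)
    prof.write_profiles(m, tmp_path / "p.tsv")
    back = prof.read_profiles(tmp_path / "p.tsv")
    pd.testing.assert_frame_equal(back.counts, m.counts, check_dtype=False)


def test_unknown_columns_survive_roundtrip(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text("sample_id\ttaxon_id\ttaxon_name\trank\treads\tunique_kmers\tnote\n"
                    "A\tT0\tx\tspecies\t5\t600\thello\n")
    m = prof.read_profiles(path)
    assert m.extras is not None
    out = tmp_path / "q.tsv"
    prof.write_profiles(m, out)
    assert "note" in pd.read_csv(out, sep="\t").columns


def test_header_only_file_gives_empty_matrix(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text("\t".join(prof.REQUIRED_COLUMNS) + "\n")
    m = prof.read_profiles(path)
    assert m.counts.shape[0] == 0


def test_missing_column_and_negative_count_errors(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text("sample_id\ttaxon_id\treads\n")
    with pytest.raises(prof.ProfileFormatError, match="taxon_name"):
        prof.read_profiles(path)
    path.write_text("\t".join(prof.REQUIRED_COLUMNS) + "\n"
                    "A\tT0\tx\tspecies\t-1\t600\n")
    with pytest.raises(prof.ProfileFormatError, match="row 2"):
        prof.read_profiles(path)


class TestMarkerFilter:
    def test_boundary_511_removed_512_retained(self):
        counts = pd.DataFrame([[10, 10]], index=["A"], columns=["lo", "hi"])
        markers = pd.DataFrame([[511, 512]], index=["A"], columns=["lo", "hi"])
        m = prof.filter_by_markers(prof.ProfileMatrix(counts=counts, markers=markers))
        assert list(m.counts.columns) == ["hi"]
        assert m.counts.loc["A", "hi"] == 10

    def test_per_cell_rule(self, tiny_matrix):
        # T1 has 900 markers in A, 512 in B, 5 in C: kept in A and B only
        m = prof.filter_by_markers(tiny_matrix)
        assert m.counts.loc["A", "T1"] == 90
        assert m.counts.loc["B", "T1"] == 50
        assert m.counts.loc["C", "T1"] == 0

    def test_requires_markers(self):
        m = prof.ProfileMatrix(counts=pd.DataFrame([[1]], index=["A"], columns=["T"]))
        with pytest.raises(ValueError, match="skip"):
            prof.filter_by_markers(m)

    def test_idempotent(self, tiny_matrix):
        once = prof.filter_by_markers(tiny_matrix)
        twice = prof.filter_by_markers(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_richness_never_increases(self, tiny_matrix):
        before = prof.richness(tiny_matrix)
        after = prof.richness(prof.filter_by_markers(tiny_matrix)).reindex(before.index, fill_value=0)
        assert (after <= before).all()


class TestAbundanceFilter:
    def _matrix(self, fracs, total=1_000_000):
        counts = pd.DataFrame([np.array(fracs) * total], index=["A"],
                              columns=[f"T{i}" for i in range(len(fracs))]).astype(int)
        return prof.ProfileMatrix(counts=counts)

    def test_boundary_exactly_at_floor_retained(self):
        m = self._matrix([1e-4, 1 - 1e-4])
        out = prof.filter_by_abundance(m, 1e-4)
        assert out.counts.loc["A"].tolist() == m.counts.loc["A"].tolist()

    def test_below_floor_zeroed(self):
        m = self._matrix([0.00009, 1 - 0.00009])
        out = prof.filter_by_abundance(m, 1e-4)
        assert "T0" not in out.counts.columns

    def test_uniform_sample_unchanged(self):
        m = self._matrix([0.01] * 100)
        out = prof.filter_by_abundance(m, 1e-4)
        pd.testing.assert_frame_equal(out.counts, m.counts)

    def test_idempotent_on_default_data(self, filtered_dataset):
        again = prof.filter_by_abundance(filtered_dataset, 1e-4)
        pd.testing.assert_frame_equal(again.counts, filtered_dataset.counts)


class TestRelativeAbundance:
    def test_ppm_arithmetic(self):
        counts = pd.DataFrame([[10, 90]], index=["A"], columns=["x", "y"])
        ppm = prof.relative_abundance(prof.ProfileMatrix(counts=counts), "ppm")
        assert ppm.loc["A"].tolist() == [100000.0, 900000.0]

    def test_fraction_cases(self):
        counts = pd.DataFrame([[1, 2, 3]], index=["A"], columns=list("xyz"))
        frac = prof.relative_abundance(prof.ProfileMatrix(counts=counts))
        np.testing.assert_allclose(frac.loc["A"], [1 / 6, 1 / 3, 1 / 2])
        single = pd.DataFrame([[7]], index=["A"], columns=["x"])
        assert prof.relative_abundance(prof.ProfileMatrix(counts=single)).loc["A", "x"] == 1.0

    def test_projection_property(self, tiny_matrix):
        once = prof.relative_abundance(tiny_matrix)
        twice = prof.relative_abundance(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_zero_sample_error(self):
        counts = pd.DataFrame([[0, 0]], index=["empty"], columns=["x", "y"])
        with pytest.raises(ValueError, match="empty"):
            prof.relative_abundance(prof.ProfileMatrix(counts=counts))


class TestKitome:
    def _with_controls(self):
        counts = pd.DataFrame(
            {"kit": [6000, 5000, 100], "suit_only": [0, 0, 500],
             "weak": [10, 0, 50]},
            index=["C1", "C2", "S1"])
        meta = pd.DataFrame({
            "sample_id": ["C1", "C2", "S1"],
            "component": ["CONTROL", "CONTROL", "WJ"],
            "set_id": ["SET-1", "SET-1", "SET-1"]}).set_index("sample_id")
        return prof.ProfileMatrix(counts=counts, metadata=meta), meta

    def test_strictly_greater_than_threshold(self):
        m, meta = self._with_controls()
        report, _ = prof.flag_kitome(m, meta, kitome_min_reads=11_000)
        assert list(report.flagged["taxon_id"]) == []  # 11000 total == threshold
        report, _ = prof.flag_kitome(m, meta, kitome_min_reads=10_999)
        assert list(report.flagged["taxon_id"]) == ["kit"]
        assert report.flagged.iloc[0]["n_controls_present"] == 2

    def test_presence_annotation(self):
        m, meta = self._with_controls()
        report, annotated = prof.flag_kitome(m, meta, 10_000)
        assert bool(report.present_in_controls["weak"]) is True
        assert bool(report.present_in_controls["suit_only"]) is False
        assert annotated.taxa.loc["suit_only", "present_in_controls"] == False  # noqa: E712
        pd.testing.assert_frame_equal(annotated.counts, m.counts)  # flag, not subtract

    def test_no_controls_error(self, tiny_matrix):
        meta = pd.DataFrame({"sample_id": list("ABC"), "component": ["WJ"] * 3}
                            ).set_index("sample_id")
        with pytest.raises(ValueError, match="CONTROL"):
            prof.flag_kitome(tiny_matrix, meta)

    def test_default_dataset_kitome_recovered(self, default_dataset):
        d = default_dataset
        m = prof.ProfileMatrix(counts=d.counts, metadata=d.metadata)
        report, _ = prof.flag_kitome(m, d.metadata, 10_000)
        assert set(report.flagged["taxon_id"]) == set(d.kitome_taxa)


def test_richness_basic_cases():
    counts = pd.DataFrame([[0, 0], [5, 0]], index=["z", "o"], columns=["a", "b"])
    r = prof.richness(prof.ProfileMatrix(counts=counts))
    assert r["z"] == 0 and r["o"] == 1


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_filters_commute_with_sample_subsetting(seed):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(rng.integers(0, 2000, (4, 6)),
                          index=list("ABCD"), columns=[f"T{i}" for i in range(6)])
    markers = pd.DataFrame(rng.integers(0, 1024, (4, 6)),
                           index=counts.index, columns=counts.columns)
    m = prof.ProfileMatrix(counts=counts, markers=markers)
    sub_then_filter = prof.filter_by_markers(m.subset_samples(["A", "C"]))
    filter_then_sub = prof.filter_by_markers(m).subset_samples(["A", "C"]).drop_empty_taxa()
    pd.testing.assert_frame_equal(
        sub_then_filter.counts.sort_index(axis=1),
        filter_then_sub.counts.sort_index(axis=1))
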