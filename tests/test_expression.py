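import numpy as np
import pytest

from coexnet.expression import (
    ExpressionFormatError,
    ExpressionParseError,
    SampleAnnotation,
    average_replicates,
    flag_outlier_samples,
    read_annotation_file,
    read_expression_file,
    split_row_identifier,
    write_annotation_file,
    write_expression_file,
)
from conftest import make_matrix


class TestRowIdentifier:
    @pytest.mark.parametrize(
        "row_id, probeset, symbol",
        [
            ("ACTB_200801_x_at", "200801_x_at", "ACTB"),
            ("GAPDH_212581_x_at", "212581_x_at", "GAPDH"),
            ("TP53_201746_at", "201746_at", "TP53"),
            ("200801_x_at", "200801_x_at", ""),
            ("NKX2-1_1552257_a_at", "1552257_a_at", "NKX2-1"),
            ("no-probeset-here", "no-probeset-here", ""),
        ],
    )
    def test_split(self, row_id, probeset, symbol):
        assert split_row_identifier(row_id) == (probeset, symbol)


class TestExpressionFileIO:
    def test_round_trip_identity(self, tmp_path):
        m = make_matrix(
            [[1.5, 2.25, 3.0], [40.0, 50.5, 60.0]],
            probeset_ids=["200801_x_at", "212581_x_at"],
            gene_symbols=["ACTB", "GAPDH"],
        )
        path = tmp_path / "m.expression"
        write_expression_file(m, path)
        m2 = read_expression_file(path)
        assert m2.probeset_ids == m.probeset_ids
        assert m2.gene_symbols == m.gene_symbols
        assert m2.sample_ids == m.sample_ids
        np.testing.assert_array_equal(m2.values, m.values)
        # byte stability at the written precision
        path2 = tmp_path / "m2.expression"
        write_expression_file(m2, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_hand_written_file_id_convention(self, tmp_path):
        path = tmp_path / "hand.expression"
        path.write_text(
            "ID\tS1\tS2\tS3\n"
            "ACTB_200801_x_at\t1\t2\t3\n"
            "GAPDH_212581_x_at\t4\t5\t6\n"
        )
        m = read_expression_file(path)
        assert m.probeset_ids == ["200801_x_at", "212581_x_at"]
        assert m.gene_symbols == ["ACTB", "GAPDH"]

    def test_annotation_columns_skipped(self, tmp_path):
        path = tmp_path / "ann.expression"
        path.write_text(
            "ID\tDescription\tS1\tS2\tS3\n"
            "ACTB_200801_x_at\tactin beta\t1\t2\t3\n"
            "GAPDH_212581_x_at\tdehydrogenase\t4\t5\t6\n"
        )
        m = read_expression_file(path, dialect="expression")
        assert m.sample_ids == ["S1", "S2", "S3"]
        np.testing.assert_array_equal(m.values, [[1, 2, 3], [4, 5, 6]])

    def test_negative_value_is_parse_error_naming_cell(self, tmp_path):
        path = tmp_path / "neg.expression"
        path.write_text("ID\tS1\tS2\nACTB_200801_x_at\t1\t-3\nX_201746_at\t2\t4\n")
        with pytest.raises(ExpressionParseError, match="200801_x_at.*S2"):
            read_expression_file(path, dialect="expression")

    def test_non_numeric_cell_names_coordinates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("ID\tS1\tS2\nr1\t1\toops\nr2\t2\t4\n")
        with pytest.raises(ExpressionParseError, match="oops.*r1.*S2"):
            read_expression_file(path, dialect="tsv")

    def test_duplicate_rows_and_empty_matrix_are_format_errors(self, tmp_path):
        dup = tmp_path / "dup.tsv"
        dup.write_text("ID\tS1\tS2\tS3\nr1\t1\t2\t3\nr1\t4\t5\t6\n")
        with pytest.raises(ExpressionFormatError):
            read_expression_file(dup, dialect="tsv")
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        with pytest.raises(ExpressionFormatError):
            read_expression_file(empty, dialect="tsv")

    def test_single_cell_matrix_writes_two_lines(self, tmp_path):
        m = make_matrix([[7.0]])
        path = tmp_path / "one.expression"
        write_expression_file(m, path)
        assert len(path.read_text().splitlines()) == 2

    def test_empty_symbols_write_plain_probeset_ids(self, tmp_path):
        m = make_matrix([[1.0, 2.0]], probeset_ids=["201746_at"])
        path = tmp_path / "plain.expression"
        write_expression_file(m, path)
        assert path.read_text().splitlines()[1].split("\t")[0] == "201746_at"

    def test_geo_series_matrix_dialect_with_antilog(self, tmp_path):
        path = tmp_path / "series.txt"
        path.write_text(
            "!Series_title\t\"demo\"\n"
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\n'
            '"200801_x_at"\t1.0\t2.0\n'
            '"201746_at"\t3.0\t4.0\n'
            "!series_matrix_table_end\n"
        )
        m = read_expression_file(path, dialect="geo_series_matrix", transform="antilog2")
        assert m.sample_ids == ["GSM1", "GSM2"]
        np.testing.assert_allclose(m.values, [[2.0, 4.0], [8.0, 16.0]])


def _annotate(matrix, groups):
    """groups: sample_id -> (series, cell_class, replicate)."""
    return [
        SampleAnnotation(sid, *groups[sid][:2], "chip", groups[sid][2])
        for sid in matrix.sample_ids
    ]


class TestAverageReplicates:
    def test_identical_replicates_collapse_to_one(self):
        m = make_matrix([[2.0, 2.0], [5.0, 5.0]], sample_ids=["a", "b"])
        ann = _annotate(m, {"a": ("G1", "mono", 1), "b": ("G1", "mono", 2)})
        out = average_replicates(m, ann)
        assert out.n_samples == 1
        np.testing.assert_array_equal(out.values[:, 0], [2.0, 5.0])

    def test_mean_of_two_and_four_is_three(self):
        m = make_matrix([[2.0, 4.0]], sample_ids=["a", "b"])
        ann = _annotate(m, {"a": ("G1", "mono", 1), "b": ("G1", "mono", 2)})
        assert average_replicates(m, ann).values[0, 0] == 3.0

    def test_singleton_groups_are_identity_up_to_naming(self):
        m = make_matrix([[1.0, 2.0, 3.0]], sample_ids=["a", "b", "c"])
        ann = _annotate(
            m, {"a": ("G1", "x", 1), "b": ("G2", "y", 1), "c": ("G3", "z", 1)}
        )
        out = average_replicates(m, ann)
        np.testing.assert_array_equal(out.values, m.values)

    def test_equal_group_sizes_preserve_global_mean(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(1, 10, size=(5, 6)))
        groups = {
            sid: (f"G{j // 2}", f"c{j // 2}", j % 2 + 1)
            for j, sid in enumerate(m.sample_ids)
        }
        out = average_replicates(m, _annotate(m, groups))
        assert out.values.mean() == pytest.approx(m.values.mean())

    def test_unannotated_sample_error_lists_ids(self):
        m = make_matrix([[1.0, 2.0]], sample_ids=["a", "b"])
        ann = [SampleAnnotation("a", "G1", "mono", "chip", 1)]
        with pytest.raises(ValueError, match="b"):
            average_replicates(m, ann)


class TestFlagOutlierSamples:
    def _replicate_matrix(self, n_reps=5, seed=0, outlier_col=None):
        rng = np.random.default_rng(seed)
        profile = rng.uniform(10, 1000, size=200)
        values = np.tile(profile[:, None], (1, n_reps))
        if outlier_col is not None:
            values[:, outlier_col] = rng.uniform(10, 1000, size=200)
        m = make_matrix(values)
        ann = _annotate(m, {s: ("G1", "mono", i + 1) for i, s in enumerate(m.sample_ids)})
        return m, ann

    def test_identical_replicates_flag_nothing(self):
        m, ann = self._replicate_matrix()
        assert flag_outlier_samples(m, ann, 0.9) == []

    def test_random_profile_among_replicates_is_flagged(self):
        m, ann = self._replicate_matrix(outlier_col=2)
        assert flag_outlier_samples(m, ann, 0.9) == [m.sample_ids[2]]

    def test_zero_threshold_is_vacuous(self):
        m, ann = self._replicate_matrix(outlier_col=2)
        assert flag_outlier_samples(m, ann, 0.0) == []

    def test_invariant_under_sample_permutation(self):
        m, ann = self._replicate_matrix(outlier_col=1)
        perm = [3, 1, 4, 0, 2]
        m2 = make_matrix(
            m.values[:, perm], sample_ids=[m.sample_ids[j] for j in perm]
        )
        ann2 = [a for j in perm for a in ann if a.sample_id == m.sample_ids[j]]
        assert set(flag_outlier_samples(m, ann, 0.9)) == set(
            flag_outlier_samples(m2, ann2, 0.9)
        )

    def test_singleton_class_skipped_with_warning(self, caplog):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 7.0]], sample_ids=["a", "b"])
        ann = _annotate(m, {"a": ("G1", "solo", 1), "b": ("G2", "other", 1)})
        import logging

        with caplog.at_level(logging.WARNING):
            assert flag_outlier_samples(m, ann, 0.9) == []
        assert "solo" in caplog.text


def test_annotation_file_round_trip(tmp_path):
    ann = [
        SampleAnnotation("s1", "GSE1", "monocyte", "U133", 1),
        SampleAnnotation("s2", "GSE1", "monocyte", "U133", 2),
    ]
    path = tmp_path / "ann.tsv"
    write_annotation_file(ann, path)
    assert read_annotation_file(path) == ann
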