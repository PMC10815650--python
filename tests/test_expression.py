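import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from drugnmf.expression import (
    ExpressionStudy,
    collapse_probes,
    make_nonnegative,
    read_expression,
    split_by_class,
    write_expression,
)
from drugnmf.synthetic import make_two_class_study


class TestContainer:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene id"):
            ExpressionStudy(np.ones((2, 1)), ["g", "g"], ["s"])
        with pytest.raises(ValueError, match="duplicate sample id"):
            ExpressionStudy(np.ones((1, 2)), ["g"], ["s", "s"])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionStudy(np.array([[np.nan]]), ["g"], ["s"])

    def test_tumor_without_drug_rejected(self):
        with pytest.raises(ValueError, match="no drug name"):
            ExpressionStudy(
                np.ones((1, 1)), ["g"], ["s"], sample_class=["tumor"], sample_drug=[None]
            )

    def test_normal_with_drug_rejected(self):
        with pytest.raises(ValueError, match="has a drug name"):
            ExpressionStudy(
                np.ones((1, 1)), ["g"], ["s"], sample_class=["normal"], sample_drug=["x"]
            )


class TestIO:
    def test_shape_and_ids(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene_id\ts1\ts2\nga\t1\t2\ngb\t3\t4\ngc\t5\t6\n")
        study = read_expression(str(p))
        assert study.values.shape == (3, 2)
        assert study.gene_ids == ["ga", "gb", "gc"]
        assert study.sample_ids == ["s1", "s2"]

    def test_duplicate_gene_id_named_in_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene_id\ts1\nga\t1\nga\t2\n")
        with pytest.raises(ValueError, match="ga"):
            read_expression(str(p))

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene_id\ts1\ts2\nga\t1\toops\n")
        with pytest.raises(ValueError, match=r"'ga'.*'s2'"):
            read_expression(str(p))

    def test_ragged_row_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene_id\ts1\ts2\nga\t1\n")
        with pytest.raises(ValueError, match="line 2"):
            read_expression(str(p))

    def test_round_trip_lossless(self, tmp_path, tiny_study):
        mpath, dpath = tmp_path / "m.tsv", tmp_path / "meta.tsv"
        write_expression(tiny_study, str(mpath), str(dpath))
        back = read_expression(str(mpath), str(dpath))
        assert np.array_equal(back.values, tiny_study.values)
        assert back.gene_ids == tiny_study.gene_ids
        assert back.sample_ids == tiny_study.sample_ids
        assert back.sample_class == tiny_study.sample_class
        assert back.sample_drug == tiny_study.sample_drug


class TestCollapseProbes:
    def test_max_mean_probe_wins(self):
        study = ExpressionStudy(
            np.array([[5.0, 5.0], [7.0, 7.0]]), ["p1", "p2"], ["s1", "s2"]
        )
        out = collapse_probes(study, {"p1": "SYM", "p2": "SYM"})
        assert out.gene_ids == ["SYM"]
        assert np.array_equal(out.values, [[7.0, 7.0]])

    def test_unmapped_probe_dropped(self):
        study = ExpressionStudy(np.ones((2, 1)), ["p1", "p2"], ["s"])
        out = collapse_probes(study, {"p1": "SYM", "p2": ""})
        assert out.gene_ids == ["SYM"]

    def test_all_unmapped_is_error(self):
        study = ExpressionStudy(np.ones((1, 1)), ["p1"], ["s"])
        with pytest.raises(ValueError, match="no probe mapped"):
            collapse_probes(study, {})

    def test_matches_brute_force_argmax_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(size=(10, 5))
        probes = [f"p{i}" for i in range(10)]
        symbols = ["A", "B", "C", "D"]
        pmap = {p: symbols[i % 4] for i, p in enumerate(probes)}
        study = ExpressionStudy(values, probes, [f"s{j}" for j in range(5)])
        out = collapse_probes(study, pmap)
        assert out.gene_ids == sorted(symbols)
        for sym in symbols:
            rows = [i for i, p in enumerate(probes) if pmap[p] == sym]
            best = max(rows, key=lambda i: values[i].mean())
            assert np.array_equal(out.values[out.gene_ids.index(sym)], values[best])

    def test_symbol_count_bounded_by_probe_count(self):
        study = ExpressionStudy(np.ones((3, 2)), ["p1", "p2", "p3"], ["s1", "s2"])
        out = collapse_probes(study, {"p1": "A", "p2": "B", "p3": "C"})
        assert out.n_genes == 3  # injective map: equality


class TestMakeNonnegative:
    def test_nonnegative_input_unchanged(self, tiny_study):
        assert make_nonnegative(tiny_study) is tiny_study

    def test_negative_min_shifted_to_zero(self):
        study = ExpressionStudy(np.array([[-2.0, 1.0]]), ["g"], ["s1", "s2"])
        out = make_nonnegative(study)
        assert out.values.min() == 0.0
        assert np.array_equal(out.values, [[0.0, 3.0]])
        assert out.provenance["nonnegative_shift"] == 2.0

    @settings(deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            (4, 3),
            elements=st.floats(min_value=-50, max_value=50, allow_nan=False),
        )
    )
    def test_within_column_differences_preserved(self, values):
        study = ExpressionStudy(values, list("abcd"), list("xyz"))
        out = make_nonnegative(study)
        assert np.allclose(np.diff(out.values, axis=0), np.diff(values, axis=0))


class TestSplitByClass:
    def test_default_synthetic_dimensions(self):
        synth = make_two_class_study(n_genes=50, seed=0)
        normal, tumor = split_by_class(synth.expression)
        assert normal.n_samples == 12
        assert tumor.n_samples == 44

    def test_partition_is_disjoint_and_complete(self, tiny_study):
        normal, tumor = split_by_class(tiny_study)
        assert set(normal.sample_ids) | set(tumor.sample_ids) == set(tiny_study.sample_ids)
        assert not set(normal.sample_ids) & set(tumor.sample_ids)
        assert normal.gene_ids == tumor.gene_ids == tiny_study.gene_ids

    def test_missing_class_is_error(self):
        study = ExpressionStudy(
            np.ones((1, 2)),
            ["g"],
            ["s1", "s2"],
            sample_class=["tumor", "tumor"],
            sample_drug=["a", "b"],
        )
        with pytest.raises(ValueError, match="both classes"):
            split_by_class(study)
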