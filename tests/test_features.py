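import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugnmf.expression import ExpressionStudy
from drugnmf.features import (
    FISHER_EPS,
    FSV,
    fisher_score,
    fisher_select,
    fsv_select,
    select_top_k,
    set_overlap,
)
from drugnmf.synthetic import make_two_class_study


def two_class(values_a: np.ndarray, values_b: np.ndarray) -> ExpressionStudy:
    na, nb = values_a.shape[1], values_b.shape[1]
    return ExpressionStudy(
        np.hstack([values_a, values_b]),
        [f"g{i:03d}" for i in range(values_a.shape[0])],
        [f"n{j}" for j in range(na)] + [f"t{j}" for j in range(nb)],
        ["normal"] * na + ["tumor"] * nb,
        [None] * na + [f"drug{j}" for j in range(nb)],
    )


class TestFisherScore:
    def test_direct_evaluation(self):
        study = two_class(np.array([[1.0, 2.0, 3.0]]), np.array([[4.0, 5.0, 6.0]]))
        # (2-5)^2 / (1+1) with (n-1) variances
        assert fisher_score(study)[0] == pytest.approx(4.5)

    def test_equal_means_score_zero(self):
        study = two_class(np.array([[1.0, 3.0]]), np.array([[2.0, 2.0]]))
        assert fisher_score(study)[0] == 0.0

    def test_constant_classes_use_eps_guard(self):
        study = two_class(np.array([[1.0, 1.0]]), np.array([[4.0, 4.0]]))
        score = fisher_score(study)[0]
        assert np.isfinite(score)
        assert score == pytest.approx(9.0 / FISHER_EPS)

    def test_small_class_rejected(self):
        study = two_class(np.array([[1.0]]), np.array([[2.0, 3.0]]))
        with pytest.raises(ValueError, match="at least 2"):
            fisher_score(study)

    @settings(deadline=None, derandomize=True)
    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_affine_invariance_per_gene(self, shift, scale):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(5, 6)), rng.normal(1, 1, size=(5, 8))
        base = fisher_score(two_class(a, b))
        moved = fisher_score(two_class(a * scale + shift, b * scale + shift))
        assert np.allclose(moved, base, rtol=1e-9)


class TestSelectTopK:
    def test_zero_k_empty(self):
        assert select_top_k(["a", "b"], np.array([1.0, 2.0]), 0) == []

    def test_tie_breaks_by_gene_id(self):
        assert select_top_k(["b", "a"], np.array([1.0, 1.0]), 2) == ["a", "b"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i:02d}" for i in range(40)]
        scores = rng.uniform(size=40)
        oracle = [g for g, _ in sorted(zip(genes, scores), key=lambda t: (-t[1], t[0]))]
        assert select_top_k(genes, scores, 10) == oracle[:10]


class TestSetOverlap:
    def test_identical_and_disjoint(self):
        assert set_overlap(["a", "b"], ["b", "a"]) == (["a", "b"], 1.0)
        assert set_overlap(["a"], ["b"]) == ([], 0.0)

    def test_empty_inputs(self):
        assert set_overlap([], []) == ([], 0.0)

    def test_duplicates_reduced_before_overlap(self):
        inter, jac = set_overlap(["a", "a", "b"], ["a", "c"])
        assert inter == ["a"]
        assert jac == pytest.approx(1 / 3)


class TestFSV:
    def test_planted_single_gene_selected_first(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(51, 20))
            X[0, 8:] += 3.0  # only gene g000 separates 8 vs 12
            study = two_class(X[:, :8], X[:, 8:])
            fs, _ = fsv_select(study, 5, seed=seed)
            wins += bool(fs.selected and fs.selected[0] == "g000")
        assert wins >= 9

    def test_sla_objective_non_increasing(self, planted_two_class_study):
        res = FSV(planted_two_class_study.expression).fit()
        trace = res.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_sparsity_monotone_in_lambda(self, planted_two_class_study):
        study = planted_two_class_study.expression
        lo = FSV(study, lam=0.1).fit()
        hi = FSV(study, lam=0.9).fit()
        assert hi.selectable().sum() <= lo.selectable().sum()

    def test_deterministic_given_input_and_seed(self, planted_two_class_study):
        a, _ = fsv_select(planted_two_class_study.expression, 10, seed=3)
        b, _ = fsv_select(planted_two_class_study.expression, 10, seed=3)
        assert a.selected == b.selected

    def test_selections_are_planted_genes(self, planted_two_class_study):
        # the concave selector returns a minimal separating subset; with
        # effect-3 planted genes every selected gene should be planted
        fs, _ = fsv_select(planted_two_class_study.expression, 30)
        assert fs.selected
        assert set(fs.selected) <= planted_two_class_study.true_de_genes

    def test_invalid_parameters_rejected(self, planted_two_class_study):
        with pytest.raises(ValueError, match="lam"):
            FSV(planted_two_class_study.expression, lam=1.5)
        with pytest.raises(ValueError, match="alpha"):
            FSV(planted_two_class_study.expression, alpha=0)
        with pytest.raises(ValueError, match="k must be"):
            fsv_select(planted_two_class_study.expression, 0)


class TestRecovery:
    def test_fisher_recovers_planted_genes(self):
        hits = 0
        for seed in range(10):
            synth = make_two_class_study(
                n_genes=1000, n_de=30, effect=3.0, n_norm=12, n_tumor=44, seed=seed
            )
            fs = fisher_select(synth.expression, 30)
            hits += len(set(fs.selected) & synth.true_de_genes) >= 28
        assert hits >= 9

    def test_fisher_chance_overlap_at_zero_effect(self):
        # with no effect, top-n_de overlap with the planted set is at chance:
        # hypergeometric expectation n_de^2 / n_genes
        n_genes, n_de = 200, 20
        overlaps = []
        for seed in range(100):
            synth = make_two_class_study(
                n_genes=n_genes, n_de=n_de, effect=0.0, n_norm=6, n_tumor=8, seed=seed
            )
            fs = fisher_select(synth.expression, n_de)
            overlaps.append(len(set(fs.selected) & synth.true_de_genes))
        expected = n_de**2 / n_genes  # = 2
        assert np.mean(overlaps) == pytest.approx(expected, abs=1.0)

    def test_recoverability_monotone_in_effect(self):
        # 3-point grid: planted-truth recovery never degrades as effect grows
        means = []
        for effect in (0.0, 1.5, 3.0):
            vals = []
            for seed in range(5):
                synth = make_two_class_study(
                    n_genes=300, n_de=20, effect=effect, n_norm=12, n_tumor=44, seed=seed
                )
                fs = fisher_select(synth.expression, 20)
                vals.append(len(set(fs.selected) & synth.true_de_genes))
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
        assert means[2] >= 19
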