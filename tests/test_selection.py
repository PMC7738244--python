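"""Tests for combo enumeration, scoring, selection, clustering and ARI."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ndrindex import (
    ComboScore,
    InvalidInputError,
    MethodRegistry,
    NdrScore,
    adjusted_rand_index,
    cluster_embedding,
    default_registry,
    enumerate_combos,
    evaluate_combos,
    ndrindex_score,
    preprocess_combo,
    reduce_pca,
    score_all,
    select_best,
)
from ndrindex.selection import combo_seed

from _oracles import ari_contingency


def fake_score(mean):
    return NdrScore(
        mean_index=mean, repeats=1, per_repeat=np.array([mean]), seed=0
    )


def small_registry():
    reg = MethodRegistry()
    reg.add_normalization("identity", lambda X: X)
    reg.add_normalization(
        "log", lambda X: X.with_counts(np.log1p(X.counts))
    )
    reg.add_reduction("pca", lambda X, seed: reduce_pca(X, d=2))
    return reg


class TestEnumerate:
    def test_lexicographic_product(self):
        reg = MethodRegistry()
        for n in ("b_norm", "a_norm", "c_norm"):
            reg.add_normalization(n, lambda X: X)
        for r in ("z_red", "a_red"):
            reg.add_reduction(r, lambda X, seed: None)
        combos = enumerate_combos(reg)
        assert combos == [
            ("a_norm", "a_red"),
            ("a_norm", "z_red"),
            ("b_norm", "a_red"),
            ("b_norm", "z_red"),
            ("c_norm", "a_red"),
            ("c_norm", "z_red"),
        ]

    def test_single_pair(self):
        reg = small_registry()
        reg.normalizations.pop("log")
        assert enumerate_combos(reg) == [("identity", "pca")]

    def test_empty_side_rejected(self):
        reg = MethodRegistry()
        reg.add_normalization("identity", lambda X: X)
        with pytest.raises(InvalidInputError):
            enumerate_combos(reg)


class TestSelectBest:
    def test_argmax(self):
        scores = [
            ComboScore("a", "x", fake_score(0.2)),
            ComboScore("b", "y", fake_score(0.9)),
            ComboScore("c", "z", fake_score(0.5)),
        ]
        assert select_best(scores).norm_name == "b"

    def test_tie_goes_to_lexicographically_first(self):
        scores = [
            ComboScore("b", "y", fake_score(0.7)),
            ComboScore("a", "z", fake_score(0.7)),
            ComboScore("a", "x", fake_score(0.7)),
        ]
        best = select_best(scores)
        assert (best.norm_name, best.reduction_name) == ("a", "x")

    def test_single_element(self):
        only = ComboScore("a", "x", fake_score(0.1))
        assert select_best([only]) is only

    def test_failed_only_rejected(self):
        with pytest.raises(InvalidInputError):
            select_best([ComboScore("a", "x", None, error="boom")])

    def test_inserting_strictly_larger_changes_selection(self):
        scores = [ComboScore("a", "x", fake_score(0.4))]
        assert select_best(scores).norm_name == "a"
        scores.append(ComboScore("z", "z", fake_score(0.41)))
        assert select_best(scores).norm_name == "z"


class TestClusterEmbedding:
    @pytest.mark.parametrize("method", ["kmeans", "hierarchical"])
    def test_separated_blobs_recovered(self, method, blob_embedding):
        emb, truth = blob_embedding
        labels = cluster_embedding(emb, k=2, method=method, seed=0)
        assert adjusted_rand_index(truth, labels) == pytest.approx(1.0)

    def test_k_equals_n_gives_singletons(self, blob_embedding):
        emb, _ = blob_embedding
        labels = cluster_embedding(emb, k=emb.n, method="hierarchical")
        assert len(set(labels)) == emb.n

    def test_seeded_determinism(self, blob_embedding):
        emb, _ = blob_embedding
        a = cluster_embedding(emb, k=2, method="kmeans", seed=11)
        b = cluster_embedding(emb, k=2, method="kmeans", seed=11)
        np.testing.assert_array_equal(a, b)

    def test_invalid_k(self, blob_embedding):
        emb, _ = blob_embedding
        with pytest.raises(InvalidInputError):
            cluster_embedding(emb, k=1)
        with pytest.raises(InvalidInputError):
            cluster_embedding(emb, k=emb.n + 1)


class TestAri:
    def test_identical_and_relabeled_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_hand_built_contingency(self):
        a = [1, 1, 1, 1]
        b = [1, 1, 2, 2]
        assert adjusted_rand_index(a, b) == pytest.approx(ari_contingency(a, b))

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            adjusted_rand_index([1, 2], [1, 2, 3])

    @given(
        labels=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4)), min_size=2, max_size=30
        )
    )
    def test_matches_contingency_formula_and_symmetry(self, labels):
        a = [x for x, _ in labels]
        b = [y for _, y in labels]
        ours = adjusted_rand_index(a, b)
        assert ours == pytest.approx(ari_contingency(a, b), abs=1e-12)
        assert ours == pytest.approx(adjusted_rand_index(b, a), abs=1e-12)

    @given(
        labels=st.lists(st.integers(0, 3), min_size=2, max_size=25),
        perm=st.permutations([0, 1, 2, 3]),
    )
    def test_relabeling_invariance(self, labels, perm):
        relabeled = [perm[x] for x in labels]
        assert adjusted_rand_index(labels, relabeled) == pytest.approx(1.0)


class TestScoreAll:
    def test_single_path_equals_direct_scoring(self, small_counts):
        X, _ = small_counts
        reg = small_registry()
        reg.normalizations.pop("log")
        scores = score_all(X, reg, repeats=10, seed=5)
        assert len(scores) == 1
        emb = reduce_pca(X.counts, d=2)
        direct = ndrindex_score(emb, repeats=10, seed=combo_seed(5, "identity", "pca"))
        assert scores[0].score.mean_index == direct.mean_index

    def test_deterministic(self, small_counts):
        X, _ = small_counts
        reg = small_registry()
        a = score_all(X, reg, repeats=10, seed=3)
        b = score_all(X, reg, repeats=10, seed=3)
        assert [s.score.mean_index for s in a] == [s.score.mean_index for s in b]

    def test_matches_compositional_loop(self, small_counts):
        """The sweep reproduces an independent loop over the public
        per-combo functions with the same seed derivation."""
        X, _ = small_counts
        reg = small_registry()
        scores = score_all(X, reg, repeats=10, seed=7)
        for s in scores:
            emb = preprocess_combo(X, reg, s.norm_name, s.reduction_name, 7)
            expected = ndrindex_score(
                emb, repeats=10, seed=combo_seed(7, s.norm_name, s.reduction_name)
            )
            assert s.score.mean_index == expected.mean_index

    def test_failing_path_recorded_not_dropped(self, small_counts):
        X, _ = small_counts
        reg = small_registry()

        def broken(Xm):
            raise RuntimeError("synthetic failure")

        reg.add_normalization("broken", broken)
        scores = score_all(X, reg, repeats=5, seed=1)
        failed = [s for s in scores if not s.ok]
        assert len(failed) == 1
        assert "synthetic failure" in failed[0].error

    def test_all_failing_raises(self, small_counts):
        X, _ = small_counts
        reg = MethodRegistry()
        reg.add_normalization("broken", lambda Xm: 1 / 0)
        reg.add_reduction("pca", lambda Xm, seed: reduce_pca(Xm, d=2))
        with pytest.raises(RuntimeError, match="every preprocessing path"):
            score_all(X, reg, repeats=5, seed=1)


class TestEvaluateCombos:
    def test_single_combo_single_clusterer(self, small_counts):
        X, truth = small_counts
        reg = small_registry()
        reg.normalizations.pop("identity")
        report = evaluate_combos(
            X, reg, truth, k=3, clusterers=("kmeans",), repeats=10, seed=2
        )
        assert len(report.table) == 1
        assert report.selected == ("log", "pca")
        assert report.table["selected"].all()
        assert np.isfinite(report.table["ari"].iloc[0])

    def test_report_is_deterministic(self, small_counts):
        X, truth = small_counts
        reg = small_registry()
        a = evaluate_combos(X, reg, truth, k=3, clusterers=("kmeans",), repeats=10, seed=4)
        b = evaluate_combos(X, reg, truth, k=3, clusterers=("kmeans",), repeats=10, seed=4)
        assert a.table.equals(b.table)
        assert a.summary == b.summary

    def test_perfect_combo_scores_ari_one(self, blob_embedding):
        # embed an already-clustered 2-D point set as the "expression
        # matrix": PCA at full dimension preserves it, so clustering
        # recovers the truth exactly and that cell's ARI is 1
        from ndrindex import ExpressionMatrix

        emb, truth = blob_embedding
        X = ExpressionMatrix(emb.points - emb.points.min() + 1.0)
        reg = small_registry()
        reg.normalizations.pop("log")
        report = evaluate_combos(
            X, reg, truth, k=2, clusterers=("kmeans",), repeats=10, seed=0
        )
        assert report.table["ari"].iloc[0] == pytest.approx(1.0)

    def test_truth_length_checked(self, small_counts):
        X, truth = small_counts
        with pytest.raises(InvalidInputError):
            evaluate_combos(X, small_registry(), truth[:-1], k=3, repeats=5, seed=0)
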