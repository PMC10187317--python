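"""Fold construction, OLS mapping, design invariances, shuffle accounting."""

import numpy as np
import pytest

from perturbenc.corpus import Sentence, StimulusSet
from perturbenc.embeddings import embed_condition
from perturbenc.encoding import (
    BrainData,
    Design,
    expected_unshuffled_fraction,
    fit_linear_map,
    make_folds,
    pearson_columns,
    run_design,
    select_layer,
    unshuffled_fraction,
)
from perturbenc.perturb import generate_condition
from perturbenc.synthetic import MockBackend, generate_brain_data


class TestMakeFolds:
    def test_five_folds_of_ten(self):
        folds = make_folds(10, "by_sentence", 5, np.random.default_rng(0))
        assert [len(t) for t in folds.test_sets] == [2] * 5
        assert sorted(np.concatenate(folds.test_sets)) == list(range(10))

    def test_fold_sizes_384(self):
        folds = make_folds(384, "by_sentence", 5, np.random.default_rng(0))
        assert [len(t) for t in folds.test_sets] == [77, 77, 77, 77, 76]

    def test_by_passage_keeps_passages_whole(self):
        labels = [f"p{i // 4}" for i in range(20)]  # 5 passages of 4
        folds = make_folds(20, "by_passage", 5, np.random.default_rng(0), labels)
        for t in folds.test_sets:
            assert len({labels[i] for i in t}) == 1

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(3, "by_sentence", 5, np.random.default_rng(0))


class TestLinearMap:
    def test_single_feature_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 1))
        y = 3.0 * x[:, 0] + rng.standard_normal(50) * 0.1
        model = fit_linear_map(x, y)
        slope = np.cov(x[:, 0], y)[0, 1] / np.var(x[:, 0], ddof=1)
        assert model.coef_[0] == pytest.approx(slope)

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 5))
        W = rng.standard_normal((5, 3))
        model = fit_linear_map(X[:40], X[:40] @ W)
        pred = model.predict(X[40:])
        r = pearson_columns(pred, X[40:] @ W)
        np.testing.assert_allclose(r, 1.0)

    def test_independent_response_near_zero(self):
        rng = np.random.default_rng(2)
        rs = []
        for _ in range(50):
            X = rng.standard_normal((60, 3))
            y = rng.standard_normal((60, 1))
            model = fit_linear_map(X[:40], y[:40])
            rs.append(pearson_columns(model.predict(X[40:]), y[40:])[0])
        assert abs(np.mean(rs)) < 0.1

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_map(np.array([[np.nan]]), np.array([1.0]))


class TestUnshuffledFraction:
    def test_all_singletons(self):
        test_sets = [np.array([0, 1]), np.array([2, 3])]
        labels = ["a", "b", "c", "d"]
        assert unshuffled_fraction(test_sets, labels) == 1.0

    def test_group_inside_one_fold(self):
        test_sets = [np.array([0, 1, 2, 3])]
        labels = ["g", "g", "g", "g"]
        assert unshuffled_fraction(test_sets, labels) == 0.0

    def test_matches_hypergeometric_expectation(self):
        # 100 sentences, groups of 4, fold size 20: simulate vs closed form
        rng = np.random.default_rng(0)
        labels = [i // 4 for i in range(100)]
        fracs = []
        for _ in range(300):
            folds = make_folds(100, "by_sentence", 5, rng)
            fracs.append(unshuffled_fraction(folds.test_sets, labels))
        expected = expected_unshuffled_fraction(4, 100, 20)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.01)


@pytest.fixture(scope="module")
def encoded_study(study):
    _, stim, classes, counts = study
    backend = MockBackend(num_layers=2, dim=48, order_sensitivity=0.0, seed=8)
    brain, _ = generate_brain_data(
        stim, classes, backend=backend, readout="content_bag",
        participants=2, voxels=8, noise_sigma=0.5, seed=8,
    )
    names = ("Original", "ReverseOrder", "RandSent")
    emb = {"ctx": {}, "noctx": {}}
    for name in names:
        cond = generate_condition(
            name, stim, classes_per_sentence=classes, counts=counts, seed=13
        )
        emb["ctx"][name] = embed_condition(backend, cond, stim, contextualized=True)
        emb["noctx"][name] = embed_condition(backend, cond, stim, contextualized=False)
    return stim, brain, emb


class TestRunDesign:
    def test_original_invariant_to_train_axis(self, encoded_study):
        stim, brain, emb = encoded_study
        for ctx_key, ctx in (("ctx", True), ("noctx", False)):
            a = run_design(Design(True, ctx), "Original", emb[ctx_key], brain, stim, seed=3)
            b = run_design(Design(False, ctx), "Original", emb[ctx_key], brain, stim, seed=3)
            assert np.array_equal(a.scores, b.scores)

    def test_scores_bounded(self, encoded_study):
        stim, brain, emb = encoded_study
        res = run_design(Design(True, False), "ReverseOrder", emb["noctx"], brain, stim, seed=3)
        assert np.all(res.scores >= -1) and np.all(res.scores <= 1)

    def test_rand_sent_shuffles_and_reports_fraction(self, encoded_study):
        stim, brain, emb = encoded_study
        res = run_design(Design(True, False), "RandSent", emb["noctx"], brain, stim, seed=3)
        # whole-experiment scope: nearly every test sentence can be deranged
        assert res.unshuffled_fraction == 0.0
        assert abs(np.median(res.scores)) < 0.1

    def test_train_perturbed_uses_condition_embeddings(self, encoded_study):
        stim, brain, emb = encoded_study
        res_tp = run_design(Design(False, False), "RandSent", emb["noctx"], brain, stim, seed=3)
        assert res_tp.unshuffled_fraction is None

    def test_contextualization_mismatch_rejected(self, encoded_study):
        stim, brain, emb = encoded_study
        with pytest.raises(ValueError, match="contextualized"):
            run_design(Design(True, True), "Original", emb["noctx"], brain, stim, seed=3)

    def test_deterministic_under_seed(self, encoded_study):
        stim, brain, emb = encoded_study
        a = run_design(Design(True, False), "RandSent", emb["noctx"], brain, stim, seed=9)
        b = run_design(Design(True, False), "RandSent", emb["noctx"], brain, stim, seed=9)
        assert np.array_equal(a.scores, b.scores)


class TestSelectLayer:
    def _result(self, scores):
        from perturbenc.encoding import PredictivityResult

        return PredictivityResult("d", "c", ["p1", "p2"], np.asarray(scores))

    def test_single_layer(self):
        res = self._result([[0.5, 0.4]])
        assert select_layer(res) == (0, pytest.approx(0.45))

    def test_informative_layer_selected(self):
        res = self._result([[0.1, 0.1], [0.6, 0.5], [0.2, 0.2]])
        layer, score = select_layer(res)
        assert layer == 1 and score == pytest.approx(0.55)

    def test_ties_break_low(self):
        res = self._result([[0.5, 0.5], [0.5, 0.5]])
        assert select_layer(res)[0] == 0

    def test_best_on_original_fixes_layer(self):
        orig = self._result([[0.9, 0.9], [0.1, 0.1]])
        cond = self._result([[0.0, 0.0], [0.8, 0.8]])
        layer, score = select_layer(cond, "best_on_original", reference=orig)
        assert layer == 0 and score == pytest.approx(0.0)


class TestBrainData:
    def test_mismatched_sentences_rejected(self):
        with pytest.raises(ValueError, match="sentence counts"):
            BrainData("e", {"p1": np.zeros((3, 2)), "p2": np.zeros((4, 2))})

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            BrainData("e", {"p1": np.full((3, 2), np.inf)})
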