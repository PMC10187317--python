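"""Similarity and surprisal analyses, paired tests, dispersion estimates."""

import numpy as np
import pytest

from perturbenc.embeddings import EmbeddingTensor
from perturbenc.stats import (
    centered_mad,
    design_comparison_tests,
    paired_tests,
    representational_similarity,
    similarity_vs_predictivity,
    surprisal_vs_predictivity,
)


def _tensor(arr, name="c"):
    return EmbeddingTensor(name, False, "last_token", np.asarray(arr, dtype=float))


def oracle_spearman(a, b):
    """Brute-force rank correlation: rank by sorting, then Pearson on ranks."""

    def ranks(x):
        order = np.argsort(x, kind="stable")
        r = np.empty(len(x))
        r[order] = np.arange(1, len(x) + 1)
        # average ties
        for v in set(x):
            mask = np.asarray(x) == v
            r[mask] = r[mask].mean()
        return r

    ra, rb = ranks(list(a)), ranks(list(b))
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


class TestRepresentationalSimilarity:
    def test_identical_tensors_give_one(self):
        arr = np.random.default_rng(0).standard_normal((2, 3, 5))
        res = representational_similarity(_tensor(arr), _tensor(arr))
        np.testing.assert_allclose(res.rho, 1.0)

    def test_rank_reversal_gives_minus_one(self):
        arr = np.random.default_rng(0).standard_normal((1, 2, 5))
        res = representational_similarity(_tensor(arr), _tensor(-arr))
        np.testing.assert_allclose(res.rho, -1.0)

    def test_matches_brute_force_oracle_on_5_unit_vectors(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((1, 4, 5))
        b = rng.standard_normal((1, 4, 5))
        res = representational_similarity(_tensor(a), _tensor(b))
        expected = np.mean(
            [oracle_spearman(a[0, i], b[0, i]) for i in range(4)]
        )
        assert res.rho[0] == pytest.approx(expected)

    def test_invariant_to_common_monotone_transform(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((1, 3, 6))
        b = rng.standard_normal((1, 3, 6))
        base = representational_similarity(_tensor(a), _tensor(b))
        warped = representational_similarity(
            _tensor(np.exp(a)), _tensor(np.exp(b))
        )
        np.testing.assert_allclose(base.rho, warped.rho)

    def test_constant_vectors_skipped_with_warning(self):
        a = np.ones((1, 2, 5))
        b = np.random.default_rng(0).standard_normal((1, 2, 5))
        with pytest.warns(UserWarning, match="skipped"):
            res = representational_similarity(_tensor(a), _tensor(b))
        assert res.n_skipped == 2


class TestSimilarityVsPredictivity:
    def test_affine_relation_gives_one(self):
        sims = {"a": np.array([0.1, 0.5, 0.9]), "b": np.array([0.2, 0.4, 0.6])}
        preds = {k: 2 * v + 0.1 for k, v in sims.items()}
        r, per_cond = similarity_vs_predictivity(sims, preds)
        assert r == pytest.approx(1.0)
        assert per_cond["a"] == pytest.approx(1.0)

    def test_independent_noise_small(self):
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(30):
            sims = {"a": rng.standard_normal(20)}
            preds = {"a": rng.standard_normal(20)}
            rs.append(similarity_vs_predictivity(sims, preds)[0])
        assert abs(np.mean(rs)) < 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            similarity_vs_predictivity({"a": np.array([1.0])}, {"a": np.array([1.0])})


class TestSurprisalVsPredictivity:
    def test_collinear_deltas(self):
        surps = {"Original": 3.0, "a": 4.0, "b": 5.0, "c": 6.0}
        # drops proportional to surprisal increases -> r = 1
        scores = {"Original": 0.5, "a": 0.4, "b": 0.3, "c": 0.2}
        r = surprisal_vs_predictivity(surps, scores, ["a", "b", "c"])
        assert r == pytest.approx(1.0)

    def test_zero_surprisal_deltas_rejected(self):
        surps = {"Original": 3.0, "a": 3.0, "b": 3.0, "c": 3.0}
        scores = {"Original": 0.5, "a": 0.4, "b": 0.3, "c": 0.2}
        with pytest.raises(ValueError, match="degenerate"):
            surprisal_vs_predictivity(surps, scores, ["a", "b", "c"])

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            surprisal_vs_predictivity(
                {"Original": 1.0, "a": 2.0}, {"Original": 0.3, "a": 0.2}, ["a"]
            )


class TestPairedTests:
    def test_identical_samples(self):
        scores = {"a": np.array([0.1, 0.2, 0.3]), "b": np.array([0.1, 0.2, 0.3])}
        table = paired_tests(scores, [("a", "b")])
        assert table.loc[0, "t"] == 0.0
        assert table.loc[0, "p"] == 1.0

    def test_textbook_formula_oracle(self):
        a = np.array([0.35, 0.30, 0.42, 0.28])
        b = np.array([0.30, 0.28, 0.35, 0.25])
        table = paired_tests({"a": a, "b": b}, [("a", "b")])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert table.loc[0, "t"] == pytest.approx(t_hand)
        from scipy import stats as sps

        p_hand = 2 * sps.t.sf(abs(t_hand), df=len(d) - 1)
        assert table.loc[0, "p"] == pytest.approx(p_hand)

    def test_bonferroni_family_of_seven(self):
        rng = np.random.default_rng(4)
        scores = {k: rng.standard_normal(6) for k in "abcdefgh"}
        comps = [("a", c) for c in "bcdefgh"]
        table = paired_tests(scores, comps)
        assert (table["family"] == 7).all()
        for _, row in table.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p"] * 7))
            assert row["p_bonferroni"] >= row["p"]

    def test_constant_nonzero_difference_reported_undefined(self):
        scores = {"a": np.array([0.2, 0.3, 0.4]), "b": np.array([0.1, 0.2, 0.3])}
        table = paired_tests(scores, [("a", "b")])
        assert np.isnan(table.loc[0, "t"])

    def test_design_comparison_concatenates(self):
        by_design = {
            "d1": {"c1": np.array([0.1, 0.2]), "c2": np.array([0.3, 0.4])},
            "d2": {"c1": np.array([0.0, 0.1]), "c2": np.array([0.2, 0.3])},
        }
        table = design_comparison_tests(by_design, [("d1", "d2")])
        d = np.array([0.1, 0.1, 0.1, 0.1])
        assert np.isnan(table.loc[0, "t"])  # constant difference is undefined


class TestCenteredMad:
    def test_identical_rows_give_zero(self):
        scores = np.tile([0.1, 0.2, 0.3], (4, 1))
        np.testing.assert_allclose(centered_mad(scores), 0.0)

    def test_hand_computed_value(self):
        # centered values per condition {-0.05, 0, +0.05} -> 0.05 / 0.6745
        scores = np.array([[-0.05, 0.05], [0.0, 0.0], [0.05, -0.05]]) + 0.5
        out = centered_mad(scores)
        assert out[0] == pytest.approx(0.05 / 0.6745, abs=1e-4)

    def test_invariant_to_per_participant_constant(self):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal((5, 4))
        shifted = scores + rng.standard_normal((5, 1))
        np.testing.assert_allclose(centered_mad(scores), centered_mad(shifted))

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            centered_mad(np.array([[0.1, 0.2]]))
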