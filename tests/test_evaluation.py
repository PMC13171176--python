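import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chromexpr.evaluation import (
    MetricReport,
    auroc,
    ensemble_predict,
    metrics,
    naive_eval,
    naive_predict,
    subset_eval,
    variant_effect,
    wilcoxon_one_sided,
)


def brute_force_metrics(y, p):
    """Independent from-scratch formulas."""
    y, p = np.asarray(y, float), np.asarray(p, float)
    n = len(y)
    mse = ((y - p) ** 2).sum() / n
    r2 = 1 - ((y - p) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    cov = ((y - y.mean()) * (p - p.mean())).sum()
    pearson = cov / np.sqrt(((y - y.mean()) ** 2).sum() * ((p - p.mean()) ** 2).sum())
    ry, rp = stats.rankdata(y), stats.rankdata(p)
    cov_r = ((ry - ry.mean()) * (rp - rp.mean())).sum()
    spearman = cov_r / np.sqrt(((ry - ry.mean()) ** 2).sum() * ((rp - rp.mean()) ** 2).sum())
    return dict(pearson=pearson, spearman=spearman, mse=mse, r2=r2)


class TestMetrics:
    def test_perfect_prediction(self):
        out = metrics([0.1, 0.4, 0.9], [0.1, 0.4, 0.9])
        assert out == {"mse": 0.0, "r2": 1.0, "pearson": 1.0, "spearman": 1.0}

    def test_spearman_rank_formula_example(self):
        out = metrics([1, 2, 3], [3, 1, 2])
        assert np.isclose(out["spearman"], -0.5)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([0.2, 0.4, 0.9])
        out = metrics(y, np.full(3, y.mean()))
        assert np.isclose(out["r2"], 0.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y, p = rng.random(20), rng.random(20)
            got = metrics(y, p)
            want = brute_force_metrics(y, p)
            for k in want:
                assert abs(got[k] - want[k]) < 1e-10, k

    def test_constant_vector_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = metrics([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        assert np.isnan(out["pearson"]) and np.isnan(out["spearman"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            metrics([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=20, unique=True),
           st.floats(0.1, 5), st.floats(-3, 3))
    def test_pearson_invariant_to_positive_affine(self, y, a, b):
        p = np.linspace(0, 1, len(y))
        r1 = metrics(np.array(y), p)["pearson"]
        r2 = metrics(np.array(y), a * p + b)["pearson"]
        assert np.isclose(r1, r2, atol=1e-8)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=20, unique=True))
    def test_spearman_invariant_to_monotone_transform(self, y):
        p = np.linspace(0.1, 1, len(y))
        r1 = metrics(np.array(y), p)["spearman"]
        r2 = metrics(np.array(y), np.exp(3 * p))["spearman"]
        assert np.isclose(r1, r2, atol=1e-8)


class TestEnsemble:
    class _Fake:
        def __init__(self, value):
            self.value = value

        def predict(self, x, **kw):
            return np.full(x.shape[0], self.value)

    def test_mean_of_two_seeds(self):
        x = np.zeros((3, 5, 4), dtype=np.float32)
        out = ensemble_predict([self._Fake(0.2), self._Fake(0.4)], x)
        assert np.allclose(out, 0.3)

    def test_single_model_identity_and_order_invariance(self):
        x = np.zeros((2, 5, 4), dtype=np.float32)
        models = [self._Fake(v) for v in (0.1, 0.5, 0.9)]
        assert np.allclose(ensemble_predict(models[:1], x), 0.1)
        assert np.allclose(ensemble_predict(models, x),
                           ensemble_predict(models[::-1], x))

    def test_gene_set_mismatch_raises(self):
        x = np.zeros((2, 5, 4), dtype=np.float32)
        with pytest.raises(ValueError, match="mismatched gene sets"):
            ensemble_predict([self._Fake(0.1)], x, gene_ids=["a", "b"],
                             model_gene_ids=[["b", "a"]])


class TestNaivePredictor:
    def test_prediction_is_auatac(self):
        au = pd.Series({"g1": 3.0, "g2": 1.0})
        assert naive_predict(au, ["g2", "g1"]).tolist() == [1.0, 3.0]

    def test_monotone_relation_gives_spearman_one(self):
        au = {f"g{i}": float(i) for i in range(6)}
        gex = {f"g{i}": i**2 / 25 for i in range(6)}
        assert np.isclose(naive_eval(au, gex, list(au)), 1.0)

    def test_permuted_relation_near_zero(self):
        rng = np.random.default_rng(0)
        n = 400
        au = pd.Series(rng.random(n), index=[f"g{i}" for i in range(n)])
        gex = pd.Series(rng.permutation(au.to_numpy()), index=au.index)
        assert abs(naive_eval(au, gex, list(au.index))) < 2 / np.sqrt(n)

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError, match="missing"):
            naive_predict(pd.Series({"g1": 1.0}), ["g1", "g2"])

    def test_constant_auatac_warns_nan(self):
        au = {f"g{i}": 1.0 for i in range(5)}
        gex = {f"g{i}": i / 5 for i in range(5)}
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(naive_eval(au, gex, list(au)))


class TestSubsetEval:
    def make_inputs(self):
        rng = np.random.default_rng(0)
        genes = {0: [f"a{i}" for i in range(6)], 1: [f"b{i}" for i in range(6)]}
        y = {f: rng.random(6) for f in genes}
        p = {f: rng.random(6) for f in genes}
        return genes, y, p

    def test_full_subset_matches_plain_metrics(self):
        genes, y, p = self.make_inputs()
        rep = subset_eval(y, p, genes, set(genes[0]) | set(genes[1]))
        for f in (0, 1):
            want = metrics(y[f], p[f])
            for k, v in want.items():
                assert np.isclose(rep.per_fold.loc[f, k], v)

    def test_hand_built_subset_matches_direct_recomputation(self):
        genes, y, p = self.make_inputs()
        sub = {"a1", "a3", "a4", "a5"}
        rep = subset_eval(y, p, genes, sub)
        idx = [1, 3, 4, 5]
        want = metrics(y[0][idx], p[0][idx])
        assert np.isclose(rep.per_fold.loc[0, "pearson"], want["pearson"])
        assert rep.per_fold.loc[0, "n_genes"] == 4

    def test_empty_and_singleton_intersections_warn(self):
        genes, y, p = self.make_inputs()
        with pytest.warns(UserWarning):
            rep = subset_eval(y, p, genes, {"a2"})
        assert np.isnan(rep.per_fold.loc[0, "pearson"])
        assert np.isnan(rep.per_fold.loc[1, "pearson"])


class TestVariantEffect:
    class _LinearModel:
        def predict(self, x, **kw):
            return x.reshape(x.shape[0], -1).sum(axis=1) / 100.0

    def test_identical_sequences_give_zero_delta(self):
        ref = np.random.default_rng(0).random((5, 8)).astype(np.float32)
        from chromexpr.genome_io import one_hot_decode

        seq = one_hot_decode(ref[:4] > 0.5)
        ref[:4] = 0
        assert variant_effect(self._LinearModel(), ref, ref[:4]) == 0.0

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        ref = np.zeros((5, 6), dtype=np.float32)
        ref[0, :] = 1
        ref[4] = rng.random(6)
        alt_dna = np.zeros((4, 6), dtype=np.float32)
        alt_dna[1, :] = 1
        m = self._LinearModel()
        d1 = variant_effect(m, ref, alt_dna)
        alt_sample = ref.copy()
        alt_sample[:4] = alt_dna
        d2 = variant_effect(m, alt_sample, ref[:4])
        assert np.isclose(d1, -d2)

    def test_atac_row_kept_from_reference(self, toy_trained_model):
        rng = np.random.default_rng(2)
        ref = np.zeros((5, 120), dtype=np.float32)
        ref[0] = 1
        ref[4] = rng.random(120)
        alt = np.zeros((4, 120), dtype=np.float32)
        alt[2] = 1
        delta = variant_effect(toy_trained_model, ref, alt)
        assert np.isfinite(delta)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            variant_effect(self._LinearModel(), np.zeros((5, 8)), np.zeros((4, 7)))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_pairwise_concordance_example(self):
        assert auroc([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single class"):
            auroc([0.1, 0.2], [1, 1])

    def test_equals_mann_whitney_normalization(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert np.isclose(auroc(scores, labels), u / (len(pos) * len(neg)))


def exact_wilcoxon_by_enumeration(x, y, alternative="greater"):
    """Oracle: full 2^n enumeration of sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if alternative == "greater":
            count += w >= w_obs - 1e-12
        else:
            count += w <= w_obs + 1e-12
    return count / 2**n


class TestWilcoxon:
    def test_all_positive_differences_n3(self):
        assert wilcoxon_one_sided([1, 2, 3], [0, 0, 0], "greater") == 0.125

    def test_identical_samples_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_one_sided([1, 2], [1, 2])

    def test_matches_full_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for n in (5, 8, 12):
            for _ in range(5):
                x, y = rng.random(n), rng.random(n)
                for alt in ("greater", "less"):
                    assert np.isclose(wilcoxon_one_sided(x, y, alt),
                                      exact_wilcoxon_by_enumeration(x, y, alt))

    def test_exact_handles_ties_in_absolute_differences(self):
        x = np.array([2.0, 3.0, 5.0, 1.0])
        y = np.array([1.0, 2.0, 3.0, 2.0])  # |d| = 1,1,2,1 -> tied ranks
        assert np.isclose(wilcoxon_one_sided(x, y, "greater"),
                          exact_wilcoxon_by_enumeration(x, y, "greater"))

    def test_normal_approximation_close_to_exact_at_n12(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(12), rng.random(12)
        exact = wilcoxon_one_sided(x, y, "greater")
        d = x - y
        ranks = stats.rankdata(np.abs(d))
        w = ranks[d > 0].sum()
        n = 12
        mean, var = n * (n + 1) / 4, n * (n + 1) * (2 * n + 1) / 24
        approx = stats.norm.sf((w - mean - 0.5) / np.sqrt(var))
        assert abs(exact - approx) < 0.02

    def test_agrees_with_scipy_when_tie_free(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(15), rng.random(15)
        ours = wilcoxon_one_sided(x, y, "greater")
        ref = stats.wilcoxon(x, y, alternative="greater", mode="exact").pvalue
        assert np.isclose(ours, ref)

    def test_two_sided_consistency_property(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(10), rng.random(10)
        assert (wilcoxon_one_sided(x, y, "greater")
                + wilcoxon_one_sided(y, x, "greater")) >= 1.0


def test_metric_report_mean_and_std():
    rep = MetricReport.from_folds({
        0: {"pearson": 0.5, "spearman": 0.6, "mse": 0.1, "r2": 0.2, "n_genes": 10},
        1: {"pearson": 0.7, "spearman": 0.8, "mse": 0.3, "r2": 0.4, "n_genes": 10},
    })
    assert np.isclose(rep.mean["pearson"], 0.6)
    assert np.isclose(rep.std["mse"], np.std([0.1, 0.3], ddof=1))
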