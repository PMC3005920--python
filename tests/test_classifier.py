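import numpy as np
import pytest

from epibayes.classifier import (MetricsReport, SVMConfig, evaluate,
                                 evaluate_pools, grid_search_cv, load_model,
                                 predict, save_model, train)
from epibayes.datasets_io import Peptide, PeptidePool
from epibayes.synthetic import EnrichmentSpec, generate_pools

from .conftest import pool


def separable_pools(n=20, L=8):
    pos = pool(*["A" * L] * n, label="positive")
    neg = pool(*["C" * L] * n, label="negative")
    return pos, neg


def scores_for_confusion(tp, fn, tn, fp):
    """Decision scores realizing an exact confusion matrix at threshold 0."""
    scores = np.concatenate([np.full(tp, 2.0), np.full(fn, -1.0),
                             np.full(tn, -2.0), np.full(fp, 1.0)])
    truth = np.concatenate([np.ones(tp + fn), np.zeros(tn + fp)])
    return scores, truth


class TestSVMConfig:
    @pytest.mark.parametrize("kwargs", [
        {"C": 0}, {"C": -1}, {"gamma": 0}, {"cv_folds": 1},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SVMConfig(**kwargs)


class TestGridSearch:
    def test_separable_data_reaches_perfect_cv_accuracy(self):
        pos, neg = separable_pools()
        config, results = grid_search_cv(pos, neg, "binary",
                                         C_grid=[1.0, 8.0],
                                         gamma_grid=[0.01, 0.1],
                                         folds=5, seed=0)
        assert results["cv_accuracy"].max() == 1.0
        assert config.C > 0 and config.gamma > 0

    def test_single_point_grid_returned(self):
        pos, neg = separable_pools()
        config, _ = grid_search_cv(pos, neg, "binary", C_grid=[4.0],
                                   gamma_grid=[0.25], folds=5, seed=0)
        assert (config.C, config.gamma) == (4.0, 0.25)

    def test_same_seed_same_selection(self):
        spec = EnrichmentSpec(enrichment={("W", "all"): 3.0})
        pos, neg = generate_pools(spec, 30, 30, seed=3)
        kw = dict(C_grid=[0.5, 2.0], gamma_grid=[0.1, 1.0], folds=5)
        c1, r1 = grid_search_cv(pos, neg, "bfe", seed=42, **kw)
        c2, r2 = grid_search_cv(pos, neg, "bfe", seed=42, **kw)
        assert (c1.C, c1.gamma) == (c2.C, c2.gamma)
        assert r1.equals(r2)

    def test_ties_broken_toward_smallest_c_then_gamma(self):
        pos, neg = separable_pools()  # every point scores 100%
        config, _ = grid_search_cv(pos, neg, "binary",
                                   C_grid=[8.0, 0.5], gamma_grid=[1.0, 0.01],
                                   folds=5, seed=0)
        assert (config.C, config.gamma) == (0.5, 0.01)

    def test_more_folds_than_examples_rejected(self):
        pos, neg = separable_pools(n=2)
        with pytest.raises(ValueError, match="folds"):
            grid_search_cv(pos, neg, "binary", C_grid=[1.0],
                           gamma_grid=[0.1], folds=10)


class TestTrainPredict:
    def test_separable_training_is_perfect(self):
        pos, neg = separable_pools()
        model = train(pos, neg, "binary", SVMConfig(C=1.0, gamma=0.1))
        scores, labels = predict(model, pos)
        assert (scores > 0).all() and (labels == "positive").all()
        scores, labels = predict(model, neg)
        assert (scores <= 0).all()

    def test_bfe_model_stores_profiles_from_training_only(self):
        pos, neg = separable_pools()
        model = train(pos, neg, "bfe", SVMConfig(C=1.0, gamma=0.5))
        assert model.profiles is not None
        assert model.profiles.positive.n_sequences == len(pos)

    def test_duplicate_peptides_get_identical_scores(self):
        pos, neg = separable_pools()
        model = train(pos, neg, "binary", SVMConfig(C=1.0, gamma=0.1))
        scores, _ = predict(model, pool("AAAAAAAA", "AAAAAAAA"))
        assert scores[0] == scores[1]

    def test_length_mismatch_rejected(self):
        pos, neg = separable_pools(L=8)
        model = train(pos, neg, "binary", SVMConfig(C=1.0, gamma=0.1))
        with pytest.raises(ValueError, match="length"):
            predict(model, pool("AAAA"))

    def test_retraining_is_deterministic(self):
        spec = EnrichmentSpec(enrichment={("W", "all"): 3.0})
        pos, neg = generate_pools(spec, 40, 40, seed=9)
        probe, _ = generate_pools(spec, 10, 10, seed=10)
        cfg = SVMConfig(C=2.0, gamma=0.5, seed=1)
        s1, _ = predict(train(pos, neg, "bfe", cfg), probe)
        s2, _ = predict(train(pos, neg, "bfe", cfg), probe)
        assert np.array_equal(s1, s2)

    def test_model_round_trip_persistence(self, tmp_path):
        pos, neg = separable_pools()
        model = train(pos, neg, "bfe", SVMConfig(C=1.0, gamma=0.5))
        save_model(model, tmp_path)
        back = load_model(tmp_path)
        s1, _ = predict(model, pos)
        s2, _ = predict(back, pos)
        assert np.allclose(s1, s2)
        assert back.scheme == "bfe" and back.peptide_length == 8


class TestEvaluate:
    def test_balanced_confusion_arithmetic(self):
        # 100 epitope / 100 non-epitope test split with 81 and 68 correct
        scores, truth = scores_for_confusion(tp=81, fn=19, tn=68, fp=32)
        rep = evaluate(scores, truth)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (81, 19, 68, 32)
        assert rep.sn == pytest.approx(81.00)
        assert rep.sp == pytest.approx(68.00)
        assert rep.acc == pytest.approx(74.50)

    def test_balanced_accuracy_identity(self):
        scores, truth = scores_for_confusion(tp=70, fn=30, tn=55, fp=45)
        rep = evaluate(scores, truth)
        assert rep.acc == pytest.approx((rep.sn + rep.sp) / 2)

    def test_perfect_separation_auroc_one(self):
        rep = evaluate(np.array([3.0, 2.0, -1.0, -2.0]),
                       np.array([1, 1, 0, 0]))
        assert rep.auroc == 1.0

    def test_all_tied_scores_auroc_half(self):
        rep = evaluate(np.zeros(10), np.array([1] * 5 + [0] * 5))
        assert rep.auroc == 0.5

    def test_zero_threshold_not_score_sign_symmetric(self):
        rep = evaluate(np.array([0.0]), np.array([0]))
        assert rep.tn == 1  # score exactly 0 is called negative

    def test_one_class_truth_has_missing_auroc(self):
        rep = evaluate(np.array([1.0, -1.0]), np.array([1, 1]))
        assert rep.auroc is None
        assert np.isnan(rep.to_frame()["auroc"].iloc[0])

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=60)
        truth = rng.integers(0, 2, size=60)
        a = evaluate(scores, truth).auroc
        b = evaluate(np.tanh(scores) * 7 + 3, truth).auroc
        assert a == pytest.approx(b)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.zeros(3), np.zeros(4))

    def test_evaluate_pools_matches_manual_concat(self):
        pos, neg = separable_pools()
        model = train(pos, neg, "binary", SVMConfig(C=1.0, gamma=0.1))
        rep = evaluate_pools(model, pos, neg)
        assert rep.acc == 100.0 and rep.auroc == 1.0
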