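import numpy as np
import pytest

from selindex import (ConfusionCounts, auroc, classify_prediction,
                      evaluate_trait, kendall_tau, make_folds, mcc, nmse,
                      pearson_r, spearman_rho)
from selindex.evaluate import confusion, metrics_for_kind
from oracles import (auroc_oracle, mcc_oracle, pearson_oracle,
                     spearman_oracle, tau_b_oracle)


# ---------------------------------------------------------------- folds
class TestFolds:
    def test_sizes_balanced_at_ten(self):
        plan = make_folds([f"i{k}" for k in range(10)], k=5, seed=0)
        sizes = sorted(len(plan.fold_ids(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 2]

    def test_sizes_at_colony_scale(self):
        plan = make_folds([f"i{k}" for k in range(844)], k=5, seed=1)
        sizes = sorted((len(plan.fold_ids(f)) for f in range(5)), reverse=True)
        assert sizes == [169, 169, 169, 169, 168]

    def test_partition_and_determinism(self):
        ids = [f"i{k}" for k in range(37)]
        p1 = make_folds(ids, k=5, seed=9)
        p2 = make_folds(ids, k=5, seed=9)
        assert p1.assignments == p2.assignments
        assert sorted(p1.assignments) == sorted(ids)
        assert set(p1.assignments.values()) == set(range(5))

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=3)


# ---------------------------------------------------------------- metrics
class TestMetrics:
    def test_mcc_examples(self):
        assert mcc(ConfusionCounts(5, 0, 5, 0)) == 1.0
        assert mcc(ConfusionCounts(0, 0, 7, 3)) == 0.0  # one-class prediction
        assert mcc(ConfusionCounts(3, 1, 4, 2)) == pytest.approx(0.408, abs=5e-4)

    def test_auroc_examples(self):
        assert auroc([1, 2, 3, 10], [0, 0, 1, 1]) == 1.0
        assert auroc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75
        assert np.isnan(auroc([1, 2], [1, 1]))

    def test_rank_correlation_examples(self):
        assert kendall_tau([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0
        assert kendall_tau([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.667, abs=5e-4)
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_pearson_nmse_examples(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert pearson_r(obs, obs) == pytest.approx(1.0)
        assert nmse(obs, obs) == 0.0
        assert nmse(np.full(3, obs.mean()), obs) == pytest.approx(1.0)
        assert nmse(np.array([1.0, 1.0, 3.0]), obs) == pytest.approx(0.5)
        assert np.isnan(nmse(obs, np.ones(3)))

    def test_classification_thresholds(self):
        assert classify_prediction(np.array([0.2, 0.49, 0.5, 0.9]), "binary").tolist() == [0, 0, 1, 1]
        assert classify_prediction(np.array([1.6, -0.3, 2.7]), "ordinal", 3).tolist() == [2, 0, 2]

    def test_random_cases_match_oracles(self):
        """All six metrics agree with brute-force oracles on short vectors."""
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            scores = np.round(rng.normal(size=n), 2)
            labels = rng.integers(0, 2, size=n)
            if 0 < labels.sum() < n:
                assert auroc(scores, labels) == pytest.approx(
                    auroc_oracle(scores, labels), abs=1e-12)
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            t_mine, t_oracle = kendall_tau(x, y), tau_b_oracle(x, y)
            if not (np.isnan(t_mine) or np.isnan(t_oracle)):
                assert t_mine == pytest.approx(t_oracle, abs=1e-10)
            s_mine, s_oracle = spearman_rho(x, y), spearman_oracle(x, y)
            if not (np.isnan(s_mine) or np.isnan(s_oracle)):
                assert s_mine == pytest.approx(s_oracle, abs=1e-10)
            pm, po = pearson_r(x, y), pearson_oracle(x, y)
            if not (np.isnan(pm) or np.isnan(po)):
                assert pm == pytest.approx(po, abs=1e-10)
            if np.ptp(y) > 0:
                assert nmse(scores, y) == pytest.approx(
                    np.mean((scores - y) ** 2) / np.mean((y - y.mean()) ** 2), abs=1e-12)
            c = confusion((scores >= 0).astype(int), labels)
            assert mcc(c) == pytest.approx(mcc_oracle(c.tp, c.fp, c.tn, c.fn), abs=1e-12)

    def test_cross_check_against_sklearn(self):
        """Independent library route agrees on AUROC and MCC."""
        from sklearn.metrics import matthews_corrcoef, roc_auc_score
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = 40
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if not 0 < labels.sum() < n:
                continue
            assert auroc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)
            pred = (scores >= 0).astype(int)
            assert mcc(confusion(pred, labels)) == pytest.approx(
                matthews_corrcoef(labels, pred), abs=1e-12)

    def test_sign_reversal_maps_metrics(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        assert auroc(-scores, labels) == pytest.approx(1.0 - auroc(scores, labels))
        y = rng.normal(size=30)
        assert kendall_tau(-scores, y) == pytest.approx(-kendall_tau(scores, y))
        assert spearman_rho(-scores, y) == pytest.approx(-spearman_rho(scores, y))
        assert pearson_r(-scores, y) == pytest.approx(-pearson_r(scores, y))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=25)
        labels = rng.integers(0, 2, size=25)
        y = rng.normal(size=25)
        warped = np.exp(scores) + 3
        assert auroc(warped, labels) == pytest.approx(auroc(scores, labels))
        assert kendall_tau(warped, y) == pytest.approx(kendall_tau(scores, y))
        assert spearman_rho(warped, y) == pytest.approx(spearman_rho(scores, y))


# ---------------------------------------------------------------- CV driver
class TestEvaluateTrait:
    def test_pooled_predictions_cover_everyone_once(self, small_pop, small_grm):
        rep = evaluate_trait("gait", small_pop.phenotypes, small_grm, "continuous",
                             fixed_effects=["birth_year"], k=5, seed=4)
        preds = rep.predictions
        assert preds["predicted"].notna().all()
        assert sorted(preds.index) == sorted(small_grm.ids)
        assert sorted(preds["fold"].unique()) == [0, 1, 2, 3, 4]

    def test_metric_cells_match_trait_kind(self, small_pop, small_grm):
        rep_bin = evaluate_trait("atopic_dermatitis", small_pop.phenotypes, small_grm,
                                 "binary", fixed_effects=[], k=5, seed=4)
        assert set(rep_bin.pooled) == {"mcc", "auroc"}
        rep_ord = evaluate_trait("trainability", small_pop.phenotypes, small_grm,
                                 "ordinal", fixed_effects=[], k=5, seed=4)
        assert set(rep_ord.pooled) == {"kendall_tau", "spearman_rho"}
        rep_cont = evaluate_trait("gait", small_pop.phenotypes, small_grm,
                                  "continuous", fixed_effects=[], k=5, seed=4)
        assert set(rep_cont.pooled) == {"pearson_r", "nmse"}

    def test_metrics_for_kind_rejects_unknown(self):
        with pytest.raises(ValueError):
            metrics_for_kind(np.zeros(3), np.zeros(3), "fuzzy")


class TestParentalScoreSubset:
    def test_parent_score_fixed_effect_restricts_to_trio_subset(self):
        """A parental-score fixed effect runs only on dogs with both parents
        scored; everyone else drops out of the CV."""
        from selindex import score_table
        from selindex.evaluate import evaluate_success_with_fixed_effect
        from selindex.pipeline import make_fixture
        from selindex import compute_grm

        pop = make_fixture("trio", seed=3)
        pheno = pop.phenotypes.copy()
        for t, v in {"neck": 1, "distraction": 0, "rating": 3, "soundness": 1,
                     "trainability": 2, "pull": 1}.items():
            if t not in pheno.columns:
                pheno[t] = v
        scored = score_table(pheno)
        grm = compute_grm(pop.genotypes)
        rep = evaluate_success_with_fixed_effect("parent_total_score", scored, grm,
                                                 fixed_effects=[], k=5, seed=0)
        n_trio = scored["parent_total_score"].notna().sum()
        assert len(rep.predictions) == n_trio == 10
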