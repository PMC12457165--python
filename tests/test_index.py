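import numpy as np
import pandas as pd
import pytest

from selindex import (IndexWeights, behavior_score, category_counts,
                      default_trait_specs, health_score, load_trait_config,
                      normalize_negative, normalize_neutral, normalize_positive,
                      score_table, standardize_trait, total_score)
from selindex.index import BEHAVIOR_TRAITS, UnknownLabelError
from selindex.pipeline import CONDENSED_SCORE_COUNTS, make_fixture


@pytest.fixture(scope="module")
def specs():
    return default_trait_specs()


class TestStandardization:
    @pytest.mark.parametrize("trait,label,score", [
        ("pace", "High average", 2),
        ("pace", "Less than average", 0),
        ("rating", "3+", 3),
        ("rating", "2+", 0),
        ("soundness", "Sound", 2),
        ("neck", "Easy", 0),
        ("pull", "Defined average", 1),
        ("distraction", "High", 1),
    ])
    def test_condensation_map(self, trait, label, score):
        assert standardize_trait(label, None, trait) == score

    def test_unknown_label_lists_valid(self):
        with pytest.raises(UnknownLabelError, match="Sound"):
            standardize_trait("Supreme", None, "soundness")

    def test_reference_colony_counts_reproduced(self):
        """Condensing the raw-label fixture reproduces the published
        score-level counts exactly, for every behavior trait."""
        raw = make_fixture("behavior-counts", seed=0)
        for trait, expected in CONDENSED_SCORE_COUNTS.items():
            scores = [standardize_trait(v, None, trait) for v in raw[trait]]
            observed = pd.Series(scores).value_counts().to_dict()
            assert observed == expected


class TestNormalizations:
    def test_negative_direction_extremes_and_midpoint(self):
        assert normalize_negative(7, 7) == 0.0
        assert normalize_negative(0, 7) == 1.0
        assert normalize_negative(3, 7) == pytest.approx(4 / 7)

    def test_positive_direction(self):
        assert normalize_positive(2, 2) == 1.0
        assert normalize_positive(0, 2) == 0.0
        assert normalize_positive(1, 2) == 0.5

    def test_neutral_optimum_and_symmetry(self):
        assert normalize_neutral(1) == 1.0
        assert normalize_neutral(0) == 0.0
        assert normalize_neutral(2) == 0.0
        assert normalize_neutral(1.5) == 0.5

    def test_zero_x_max_rejected(self):
        with pytest.raises(ValueError):
            normalize_negative(1, 0)

    def test_normalized_values_bounded(self, specs):
        rng = np.random.default_rng(0)
        from selindex.index import normalize_by_direction
        for t in BEHAVIOR_TRAITS:
            spec = specs[t]
            for _ in range(20):
                x = rng.integers(0, int(spec.x_max) + 1)
                assert 0.0 <= normalize_by_direction(x, spec) <= 1.0


def _best_behavior():
    return {"neck": 0, "distraction": 0, "rating": 0, "soundness": 2,
            "trainability": 4, "pace": 1, "pull": 1}


class TestBehaviorScore:
    def test_all_worst_is_zero(self, specs):
        worst = {"neck": 2, "distraction": 1, "rating": 7, "soundness": 0,
                 "trainability": 0, "pace": 0, "pull": 0}
        assert behavior_score(worst, specs) == pytest.approx(0.0)

    def test_all_best_is_sum_of_weights(self, specs):
        expected = sum(abs(specs[t].weight_r) for t in BEHAVIOR_TRAITS)
        assert behavior_score(_best_behavior(), specs) == pytest.approx(expected)

    def test_soundness_only_contribution(self, specs):
        """Half-normalized soundness alone contributes 0.127 x 0.5 = 0.0635."""
        d = {"neck": 2, "distraction": 1, "rating": 7, "soundness": 1,
             "trainability": 0, "pace": 0, "pull": 0}
        assert behavior_score(d, specs) == pytest.approx(0.0635)

    def test_missing_trait_rejected(self, specs):
        d = _best_behavior()
        del d["pull"]
        with pytest.raises(ValueError, match="pull"):
            behavior_score(d, specs)

    def test_monotone_in_each_direction(self, specs):
        base = {"neck": 1, "distraction": 0, "rating": 3, "soundness": 1,
                "trainability": 2, "pace": 1, "pull": 1}
        s0 = behavior_score(base, specs)
        for t, better, worse in [("soundness", 2, 0), ("trainability", 4, 0),
                                 ("neck", 0, 2), ("distraction", 0, 1), ("rating", 0, 7)]:
            up = dict(base, **{t: better})
            down = dict(base, **{t: worse})
            assert behavior_score(up, specs) >= s0 >= behavior_score(down, specs)
        for t in ("pace", "pull"):
            for off in (0, 2):
                assert behavior_score(dict(base, **{t: off}), specs) <= s0

    def test_raw_sign_weights_flag(self, specs):
        """The literal signed-weight reading penalizes normalized negative traits."""
        s_abs = behavior_score(_best_behavior(), specs)
        s_raw = behavior_score(_best_behavior(), specs, raw_sign_weights=True)
        assert s_raw < s_abs


class TestHealthScore:
    def test_no_diagnoses_zero(self, specs):
        assert health_score({}, specs) == 0.0

    def test_single_diagnosis_equals_correlation(self, specs):
        assert health_score({"atopic_dermatitis": 1}, specs) == pytest.approx(-0.1)

    def test_two_diagnoses_sum(self, specs):
        d = {"atopic_dermatitis": 1, "mandibular_distocclusion": 1}
        assert health_score(d, specs) == pytest.approx(-0.205)

    def test_nonincreasing_in_diagnoses(self, specs):
        names = [n for n, s in specs.items() if s.kind == "binary_health"]
        acc = {}
        prev = health_score(acc, specs)
        for n in names:
            acc[n] = 1
            cur = health_score(acc, specs)
            assert cur <= prev
            prev = cur


class TestTotalScore:
    def test_behavior_only(self):
        w = IndexWeights(w_health=0.0, w_behavior=1.0)
        assert total_score(-0.3, 0.7, w) == pytest.approx(0.7)

    def test_zero_scores(self):
        assert total_score(0.0, 0.0, IndexWeights()) == 0.0

    def test_default_weights_arithmetic(self):
        assert total_score(-0.1, 0.5, IndexWeights()) == pytest.approx(0.160)

    def test_both_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            IndexWeights(0.0, 0.0)


class TestCategoryCounts:
    def test_no_diagnoses(self):
        assert category_counts({}) == (0, 0, 0, 0)

    def test_dental_plus_ocular(self):
        d = {"supernumerary_teeth": 1, "distichiasis": 1}
        assert category_counts(d) == (1, 1, 0, 2)

    def test_congenital_counts_toward_health_only(self):
        assert category_counts({"umbilical_hernia": 1}) == (0, 0, 0, 1)

    def test_health_count_covers_all_groups(self, specs):
        names = [n for n, s in specs.items() if s.kind == "binary_health"]
        d, o, m, h = category_counts({n: 1 for n in names}, specs)
        assert h == len(names)
        assert h >= d + o + m


class TestScoreTable:
    def test_labels_standardized_and_scores_added(self):
        raw = make_fixture("behavior-counts", seed=1).head(30).copy()
        raw["trainability"] = 3
        raw["atopic_dermatitis"] = 0
        scored = score_table(raw)
        for col in ("behavior_score", "health_score", "total_score",
                    "dental_count", "ocular_count", "dermal_count", "health_count"):
            assert col in scored.columns
        assert scored["health_score"].le(0).all()

    def test_parent_scores_joined_for_trios(self):
        pop = make_fixture("trio", seed=2)
        pheno = pop.phenotypes.copy()
        scored = score_table(_complete_behavior(pheno))
        trio_rows = scored[scored["sire"].notna()]
        assert len(trio_rows) == 10
        assert trio_rows["parent_total_score"].notna().all()
        founder_rows = scored[scored["sire"].isna()]
        assert founder_rows["parent_total_score"].isna().all()

    def test_yaml_config_matches_builtin_defaults(self, specs):
        yspecs, smap, weights = load_trait_config()
        assert set(yspecs) == set(specs)
        for n in specs:
            assert yspecs[n].weight_r == specs[n].weight_r
            assert yspecs[n].x_max == specs[n].x_max
            assert yspecs[n].direction == specs[n].direction
        from selindex.index import STANDARDIZATION_MAP
        assert smap == STANDARDIZATION_MAP
        assert (weights.w_health, weights.w_behavior) == (0.02, 0.324)


def _complete_behavior(pheno):
    """Fill any behavior columns the fixture lacks with neutral scores."""
    out = pheno.copy()
    defaults = {"neck": 1, "distraction": 0, "rating": 3, "soundness": 1,
                "trainability": 2, "pace": 1, "pull": 1}
    for t, v in defaults.items():
        if t not in out.columns:
            out[t] = v
    return out
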