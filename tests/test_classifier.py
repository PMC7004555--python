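import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import suzukii_morphs as sm
from suzukii_morphs.classifier import (
    CANDIDATE_ORDER,
    NoSplitError,
    SplitResult,
    fit_threshold_rule,
    predictor_value,
)
from suzukii_morphs.data_model import (
    ConfigurationError,
    DegenerateDataError,
    ValidationError,
)
from conftest import toy_records

W, S = sm.Morph.WINTER, sm.Morph.SUMMER


def brute_force_split(values, labels):
    """Independent oracle: evaluate every midpoint cutoff explicitly."""
    values = np.asarray(values, dtype=float)
    is_w = np.array([m is W for m in labels])
    n = values.size
    parent = sm.gini_impurity(int(is_w.sum()), int(n - is_w.sum()))
    best = None
    for cut in sorted(set((a + b) / 2.0 for a, b in zip(sorted(values), sorted(values)[1:])
                          if a != b)):
        right = values >= cut
        lw, ls = int(is_w[~right].sum()), int((~is_w[~right]).sum())
        rw, rs = int(is_w[right].sum()), int((~is_w[right]).sum())
        child = (
            (lw + ls) * sm.gini_impurity(lw, ls) + (rw + rs) * sm.gini_impurity(rw, rs)
        ) / n
        dec = parent - child
        if best is None or dec > best[0]:
            best = (dec, cut)
    return best


class TestGini:
    def test_pure_node_is_zero(self):
        assert sm.gini_impurity(10, 0) == 0.0
        assert sm.gini_impurity(0, 7) == 0.0

    def test_balanced_node_is_half(self):
        assert sm.gini_impurity(5, 5) == 0.5

    def test_hand_computed_two_one(self):
        assert sm.gini_impurity(2, 1) == pytest.approx(4.0 / 9.0)

    def test_empty_node_rejected(self):
        with pytest.raises(ValidationError):
            sm.gini_impurity(0, 0)


class TestBestSplit:
    def test_separated_classes_split_at_gap_midpoint(self):
        res = sm.best_split([1.0, 2.0, 10.0, 11.0], [S, S, W, W])
        assert res.cutoff == 6.0
        assert res.gini_decrease == pytest.approx(0.5)  # parent impurity, children pure
        assert res.left_counts == (0, 2) and res.right_counts == (2, 0)

    def test_alternating_labels_match_brute_force(self):
        values = [1.0, 2.0, 3.0, 4.0]
        labels = [S, W, S, W]
        res = sm.best_split(values, labels)
        dec, cut = brute_force_split(values, labels)
        assert res.gini_decrease == pytest.approx(dec)
        assert res.cutoff == cut
        assert res.gini_decrease < 0.5

    def test_single_class_and_constant_values_rejected(self):
        with pytest.raises(NoSplitError):
            sm.best_split([1.0, 2.0], [W, W])
        with pytest.raises(NoSplitError):
            sm.best_split([2.0, 2.0], [W, S])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 12), st.booleans()), min_size=2, max_size=30
        )
    )
    def test_equals_brute_force_on_random_instances(self, data):
        values = [float(v) for v, _ in data]
        labels = [W if w else S for _, w in data]
        try:
            res = sm.best_split(values, labels)
        except NoSplitError:
            is_w = [m is W for m in labels]
            assert all(is_w) or not any(is_w) or len(set(values)) == 1
            return
        dec, cut = brute_force_split(values, labels)
        assert res.gini_decrease == pytest.approx(dec, abs=1e-12)
        assert res.cutoff == pytest.approx(cut, abs=1e-12)
        assert res.gini_decrease >= 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(0.1, 5.0), st.booleans()), min_size=2, max_size=25
        )
    )
    def test_label_swap_leaves_cutoff_unchanged(self, data):
        values = [v for v, _ in data]
        labels = [W if w else S for _, w in data]
        swapped = [S if m is W else W for m in labels]
        try:
            a = sm.best_split(values, labels)
        except NoSplitError:
            with pytest.raises(NoSplitError):
                sm.best_split(values, swapped)
            return
        b = sm.best_split(values, swapped)
        assert a.cutoff == b.cutoff
        assert a.gini_decrease == pytest.approx(b.gini_decrease)

    def test_matches_sklearn_depth_one_tree(self, lab):
        sklearn = pytest.importorskip("sklearn.tree")
        for sex in sm.Sex:
            sub = lab.filter(sex=sex, source="lab")
            x = sub.values("wing_length")
            y = np.array([r.morph is W for r in sub])
            res = sm.best_split(x, [r.morph for r in sub])
            tree = sklearn.DecisionTreeClassifier(
                max_depth=1, criterion="gini"
            ).fit(x.reshape(-1, 1), y)
            # sklearn stores features as float32; match at that precision
            assert res.cutoff == pytest.approx(tree.tree_.threshold[0], abs=1e-5)


class TestSelectPredictor:
    def test_wing_length_wins_on_default_cohorts(self, lab, fits):
        for sex in sm.Sex:
            pred, rule = sm.select_predictor(
                lab, sex, candidates=CANDIDATE_ORDER[:3], fits=fits
            )
            assert pred is sm.Predictor.WING_LENGTH
            assert rule.sex is sex and rule.predictor is pred

    def test_single_candidate_returned(self, lab, fits):
        pred, _ = sm.select_predictor(
            lab, sm.Sex.FEMALE, candidates=[sm.Predictor.HIND_TIBIA], fits=fits
        )
        assert pred is sm.Predictor.HIND_TIBIA

    def test_tied_candidates_break_by_fixed_order(self):
        # wing_width duplicated from wing_length: identical splits, first wins
        ds = sm.MorphometricDataset(
            [
                sm.FlyRecord(
                    id=str(i), sex="F", source="lab", morph=m,
                    wing_length=v, wing_width=v, hind_tibia=1.0,
                )
                for i, (v, m) in enumerate(
                    [(1.0, S), (2.0, S), (5.0, W), (6.0, W)]
                )
            ]
        )
        pred, _ = sm.select_predictor(
            ds, sm.Sex.FEMALE,
            candidates=[sm.Predictor.WING_WIDTH, sm.Predictor.WING_LENGTH],
        )
        assert pred is sm.Predictor.WING_LENGTH

    def test_inverted_direction_guard(self):
        # winter smaller than summer violates the fixed biology
        ds = toy_records([1.0, 1.2, 3.0, 3.3], [W, W, S, S])
        with pytest.raises(DegenerateDataError):
            fit_threshold_rule(ds, sm.Sex.FEMALE, sm.Predictor.WING_LENGTH)


class TestClassify:
    RULE = sm.ThresholdRule(sex=sm.Sex.FEMALE, predictor="wing_length", cutoff=2.69)

    def _fly(self, wing, sex="F"):
        return sm.FlyRecord(
            id="x", sex=sex, source="field", wing_length=wing, hind_tibia=0.75
        )

    def test_above_cutoff_is_winter(self):
        assert sm.classify(self._fly(2.70), self.RULE) is W

    def test_boundary_belongs_to_winter(self):
        assert sm.classify(self._fly(2.69), self.RULE) is W

    def test_below_cutoff_is_summer(self):
        assert sm.classify(self._fly(2.68), self.RULE) is S

    def test_ratio_rule_uses_published_male_threshold(self, fits):
        rule = sm.ThresholdRule(sex=sm.Sex.MALE, predictor="transformed_ratio", cutoff=2.31)
        fit = fits[sm.Sex.MALE].with_alpha(0.762)
        # ratio (wing - 0.762)/tibia = 2.30 < 2.31 -> summer
        fly = sm.FlyRecord(
            id="m", sex="M", source="field",
            wing_length=0.762 + 2.30 * 0.75, hind_tibia=0.75,
        )
        assert sm.classify(fly, rule, {sm.Sex.MALE: fit}) is S

    def test_sex_mismatch_is_usage_error(self):
        with pytest.raises(ConfigurationError):
            sm.classify(self._fly(2.7, sex="M"), self.RULE)

    def test_monotone_in_predictor_value(self):
        labels = [sm.classify(self._fly(w), self.RULE) for w in np.linspace(2.0, 3.2, 40)]
        flips = sum(a is not b for a, b in zip(labels, labels[1:]))
        assert flips == 1 and labels[0] is S and labels[-1] is W


class TestMisclassification:
    def test_own_split_on_separated_toy_data_is_zero(self):
        ds = toy_records([1.0, 2.0, 10.0, 11.0], [S, S, W, W])
        rule, _ = fit_threshold_rule(ds, sm.Sex.FEMALE, sm.Predictor.WING_LENGTH)
        assert sm.misclassification_rate(ds, rule) == 0.0

    def test_one_wrong_of_four_is_25_percent(self):
        ds = toy_records([1.0, 2.0, 10.0, 11.0], [S, W, W, W])
        rule = sm.ThresholdRule(sex=sm.Sex.FEMALE, predictor="wing_length", cutoff=5.0)
        assert sm.misclassification_rate(ds, rule) == 25.0

    def test_equals_direct_enumeration(self, lab, fits):
        rule = sm.ThresholdRule(sex=sm.Sex.MALE, predictor="wing_length", cutoff=2.42)
        males = lab.filter(sex=sm.Sex.MALE)
        expected = sum(
            (predictor_value(r, rule.predictor) >= 2.42) != (r.morph is W)
            for r in males
        )
        assert sm.misclassification_rate(lab, rule) == pytest.approx(
            100.0 * expected / len(males)
        )

    def test_unlabelled_record_rejected(self, field):
        rule = sm.ThresholdRule(sex=sm.Sex.FEMALE, predictor="wing_length", cutoff=2.69)
        with pytest.raises(ValidationError):
            sm.misclassification_rate(field.filter(sex=sm.Sex.FEMALE), rule)
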