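import dataclasses
import math

import numpy as np
import pytest

import suzukii_morphs as sm
from suzukii_morphs.data_model import DegenerateDataError, InsufficientDataError
from suzukii_morphs.resampling import _bootstrap_partition
from conftest import toy_records

W, S = sm.Morph.WINTER, sm.Morph.SUMMER


class TestPartition:
    def _ten(self):
        return toy_records(
            [1, 2, 3, 4, 5, 11, 12, 13, 14, 15.0], [S] * 5 + [W] * 5
        )

    def test_sizes_disjoint_and_exhaustive(self, rng):
        ds = self._ten()
        train, val = sm.partition(ds, 0.7, rng)
        assert len(train) == 7 and len(val) == 3
        ids = {r.id for r in train} | {r.id for r in val}
        assert ids == {r.id for r in ds}
        assert not ({r.id for r in train} & {r.id for r in val})

    def test_same_rng_state_reproduces_partition(self):
        ds = self._ten()
        a = sm.partition(ds, 0.7, np.random.default_rng(5))
        b = sm.partition(ds, 0.7, np.random.default_rng(5))
        assert [r.id for r in a[0]] == [r.id for r in b[0]]

    def test_membership_frequency_near_train_fraction(self):
        ds = self._ten()
        rng = np.random.default_rng(99)
        reps = 1000
        counts = {r.id: 0 for r in ds}
        for _ in range(reps):
            train, _ = sm.partition(ds, 0.7, rng)
            for r in train:
                counts[r.id] += 1
        se = math.sqrt(0.7 * 0.3 / reps)
        for c in counts.values():
            assert abs(c / reps - 0.7) < 3 * se + 0.05  # finite-population slack

    def test_training_set_always_contains_both_classes(self):
        # 1 winter in 10 records: naive splits often isolate it
        ds = toy_records([1, 2, 3, 4, 5, 6, 7, 8, 9, 20.0], [S] * 9 + [W])
        rng = np.random.default_rng(2)
        for _ in range(50):
            train, _ = sm.partition(ds, 0.7, rng)
            assert {r.morph for r in train} == {W, S}

    def test_stratified_mode_preserves_class_balance(self):
        ds = self._ten()
        rng = np.random.default_rng(3)
        for _ in range(20):
            train, _ = sm.partition(ds, 0.7, rng, stratified=True)
            morphs = [r.morph for r in train]
            assert morphs.count(W) >= 3 and morphs.count(S) >= 3


class TestRepeatedSplits:
    def test_perfectly_separated_classes_have_zero_error_everywhere(self):
        ds = toy_records(
            [1.0, 1.1, 1.2, 1.3, 1.4, 9.0, 9.1, 9.2, 9.3, 9.4],
            [S] * 5 + [W] * 5,
        )
        summary = sm.repeated_split_evaluation(
            ds, sm.Sex.FEMALE, sm.Predictor.WING_LENGTH, n_iterations=500, seed=1
        )
        assert summary.error_mean == summary.error_min == summary.error_max == 0.0

    def test_single_iteration_collapses_summary(self, lab):
        summary = sm.repeated_split_evaluation(
            lab, sm.Sex.MALE, sm.Predictor.WING_LENGTH, n_iterations=1, seed=4
        )
        assert summary.cutoff_mean == summary.cutoff_min == summary.cutoff_max
        assert summary.error_mean == summary.error_min == summary.error_max

    def test_summary_ordering_and_bounds(self, lab):
        summary = sm.repeated_split_evaluation(
            lab, sm.Sex.FEMALE, sm.Predictor.WING_LENGTH, n_iterations=100, seed=4
        )
        assert summary.cutoff_min <= summary.cutoff_mean <= summary.cutoff_max
        assert 0.0 <= summary.error_min <= summary.error_mean <= summary.error_max <= 100.0
        assert summary.final_rule.cutoff == summary.cutoff_mean

    def test_same_seed_bitwise_identical(self, lab):
        a = sm.repeated_split_evaluation(
            lab, sm.Sex.MALE, sm.Predictor.TRANSFORMED_RATIO, n_iterations=50, seed=11
        )
        b = sm.repeated_split_evaluation(
            lab, sm.Sex.MALE, sm.Predictor.TRANSFORMED_RATIO, n_iterations=50, seed=11
        )
        assert a.cutoffs == b.cutoffs and a.errors == b.errors

    def test_iteration_stream_stable_under_extension(self, lab):
        short = sm.repeated_split_evaluation(
            lab, sm.Sex.MALE, sm.Predictor.WING_LENGTH, n_iterations=20, seed=11
        )
        long = sm.repeated_split_evaluation(
            lab, sm.Sex.MALE, sm.Predictor.WING_LENGTH, n_iterations=40, seed=11
        )
        assert long.cutoffs[:20] == short.cutoffs

    def test_fast_path_equals_composed_operations(self, lab):
        """The array loop must be draw-for-draw identical to composing
        partition -> training-set allometry refit -> stump -> validation error."""
        sex = sm.Sex.FEMALE
        summary = sm.repeated_split_evaluation(
            lab, sex, sm.Predictor.TRANSFORMED_RATIO, n_iterations=5, seed=3
        )
        lab_f = lab.filter(sex=sex, source=sm.Source.LAB)
        children = np.random.SeedSequence(3).spawn(5)
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            train, val = sm.partition(lab_f, 0.7, rng)
            fits = {sex: sm.fit_summer_allometry(train, sex)}
            from suzukii_morphs.classifier import fit_threshold_rule

            rule, _ = fit_threshold_rule(train, sex, sm.Predictor.TRANSFORMED_RATIO, fits)
            assert summary.cutoffs[i] == pytest.approx(rule.cutoff, rel=1e-9)
            assert summary.errors[i] == pytest.approx(
                sm.misclassification_rate(val, rule, fits), abs=1e-9
            )

    def test_error_never_increases_with_class_separation(self, specs):
        errors = []
        for gap_scale in (0.5, 1.0, 2.0, 4.0):
            scaled = dict(specs)
            fw = specs[(sm.Sex.FEMALE, sm.Morph.WINTER)]
            base_gap = fw.wing_mean - specs[(sm.Sex.FEMALE, sm.Morph.SUMMER)].wing_mean
            shift = (gap_scale - 1.0) * base_gap
            scaled[(sm.Sex.FEMALE, sm.Morph.WINTER)] = dataclasses.replace(
                fw, wing_intercept=fw.wing_intercept + shift
            )
            lab = sm.generate_lab_dataset(scaled, 555)  # common seed across the ladder
            summary = sm.repeated_split_evaluation(
                lab, sm.Sex.FEMALE, sm.Predictor.WING_LENGTH, n_iterations=200, seed=556
            )
            errors.append(summary.error_mean)
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_bootstrap_mode_runs_and_summarizes(self, lab):
        summary = sm.repeated_split_evaluation(
            lab, sm.Sex.MALE, sm.Predictor.WING_LENGTH,
            n_iterations=20, seed=7, with_replacement=True,
        )
        assert summary.n_iterations == 20
        assert 0.0 <= summary.error_mean <= 100.0

    def test_bootstrap_partition_validation_is_out_of_bag(self, lab):
        lab_m = lab.filter(sex=sm.Sex.MALE, source=sm.Source.LAB)
        train, val = _bootstrap_partition(lab_m, 0.7, np.random.default_rng(1))
        base_ids = {r.id.split("#")[0] for r in train}
        assert all(r.id not in base_ids for r in val)

    def test_invalid_iteration_count_rejected(self, lab):
        with pytest.raises(sm.data_model.ValidationError):
            sm.repeated_split_evaluation(
                lab, sm.Sex.MALE, sm.Predictor.WING_LENGTH, n_iterations=0, seed=1
            )


class TestDensityOverlap:
    def test_identical_samples_overlap_fully(self, rng):
        x = rng.normal(0, 1, 300)
        pct, _, _ = sm.density_overlap(x, x.copy())
        assert pct == pytest.approx(100.0, abs=0.5)

    def test_distant_samples_overlap_vanishes(self, rng):
        a = rng.normal(0.0, 0.01, 200)
        b = rng.normal(100.0, 0.01, 200)
        pct, _, _ = sm.density_overlap(a, b)
        assert pct < 0.1

    def test_symmetry(self, rng):
        a = rng.normal(0, 1, 150)
        b = rng.normal(1, 1.5, 180)
        ab, _, _ = sm.density_overlap(a, b)
        ba, _, _ = sm.density_overlap(b, a)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert 0.0 <= ab <= 100.0

    def test_zero_variance_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            sm.density_overlap([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_tiny_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            sm.density_overlap([1.0], [1.0, 2.0])

    def test_morph_overlap_on_lab_data_is_small(self, lab, fits):
        # the two morphs are nearly separated on wing length
        res = sm.morph_density_overlap(lab, sm.Sex.FEMALE, sm.Predictor.WING_LENGTH)
        assert res.overlap_percent < 15.0
        assert res.bandwidth_winter > 0 and res.bandwidth_summer > 0
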