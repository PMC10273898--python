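"""Repeated holdout protocol: splits, model fitting and chance calibration."""

import numpy as np
import pytest

from gazediff.classify import (
    EvalProtocol,
    UnknownModelError,
    evaluate_holdout,
    fit_and_score,
    make_model,
    repeated_protocol,
    repetition_seed,
    split_participants,
)
from gazediff.features import FeatureTable
from gazediff.questionnaire import GroupAssignment
from gazediff.simulate import generate_null_cohort

from conftest import analyse_cohort, small_sim_config


def groups_of(n_low, n_high):
    labels = {f"P{i:03d}": ("low" if i < n_low else "high") for i in range(n_low + n_high)}
    return GroupAssignment(labels=labels, split_value=0.0)


def cloud_features(labels: GroupAssignment, rng, centres=((100, 100), (1000, 800)), sigma=10.0):
    pids = sorted(labels.labels)
    X = np.array([
        rng.normal(centres[0 if labels.labels[p] == "low" else 1], sigma) for p in pids
    ])
    return FeatureTable(pids, ["V1"], X)


class TestSplits:
    def test_ten_participants_80_20(self):
        g = groups_of(5, 5)
        train, test = split_participants(sorted(g.labels), g, EvalProtocol(seed=1), 0)
        assert len(train) == 8 and len(test) == 2
        assert {g.labels[p] for p in test} == {"low", "high"}

    def test_determinism(self):
        g = groups_of(5, 5)
        p = EvalProtocol(seed=7)
        assert split_participants(sorted(g.labels), g, p, 3) == \
               split_participants(sorted(g.labels), g, p, 3)
        a = split_participants(sorted(g.labels), g, p, 3)
        b = split_participants(sorted(g.labels), g, p, 4)
        assert a != b

    def test_study_sized_split(self):
        """98 participants (53/45) at 0.8 -> train 78, test 20, stratified."""
        g = groups_of(53, 45)
        train, test = split_participants(sorted(g.labels), g, EvalProtocol(seed=0), 0)
        assert len(train) == 78 and len(test) == 20
        assert sum(g.labels[p] == "low" for p in train) == 42
        assert sum(g.labels[p] == "high" for p in train) == 36
        assert set(train) | set(test) == set(g.labels)
        assert not set(train) & set(test)

    def test_repetition_seed_is_bounded_and_distinct(self):
        seeds = {repetition_seed(123, r) for r in range(50)}
        assert len(seeds) == 50
        assert all(0 <= s < 2**31 for s in seeds)


class TestFitAndScore:
    @pytest.mark.parametrize("model", ["logistic", "knn", "tree", "forest"])
    def test_separable_clouds(self, model, rng):
        g = groups_of(20, 20)
        feats = cloud_features(g, rng)
        cv, fitted = fit_and_score(feats, g, EvalProtocol(), model)
        assert cv >= 0.95
        assert evaluate_holdout(fitted, feats, g, feats.participants) == 1.0

    def test_unknown_model_rejected(self, rng):
        g = groups_of(5, 5)
        with pytest.raises(UnknownModelError):
            fit_and_score(cloud_features(g, rng), g, EvalProtocol(), "svm")
        with pytest.raises(UnknownModelError):
            make_model("perceptron")

    def test_duplicated_columns_leave_logistic_stable(self, rng):
        """Correlated predictors should not break the regularised logistic fit."""
        g = groups_of(20, 20)
        feats = cloud_features(g, rng, sigma=150.0)
        doubled = FeatureTable(
            feats.participants, ["V1", "V2"], np.hstack([feats.values, feats.values])
        )
        cv1, _ = fit_and_score(feats, g, EvalProtocol(), "logistic")
        cv2, _ = fit_and_score(doubled, g, EvalProtocol(), "logistic")
        assert abs(cv1 - cv2) < 0.15

    def test_empty_test_set_rejected(self, rng):
        g = groups_of(5, 5)
        feats = cloud_features(g, rng)
        _, fitted = fit_and_score(feats, g, EvalProtocol(), "logistic")
        with pytest.raises(ValueError):
            evaluate_holdout(fitted, feats, g, [])


class TestRepeatedProtocol:
    def test_single_repetition_report(self, small_signal_cohort):
        matrices, groups, _ = analyse_cohort(small_signal_cohort)
        protocol = EvalProtocol(n_repetitions=1, cv_folds=3, seed=5)
        report = repeated_protocol(matrices, groups, protocol=protocol)
        assert len(report.repetitions) == 1
        rec = report.repetitions[0]
        assert sorted(rec.train + rec.test) == sorted(groups.labels)
        assert len(rec.selected_videos) == 2
        for m in protocol.models:
            assert 0.0 <= rec.cv_accuracy[m] <= 1.0
            assert 0.0 <= rec.test_accuracy[m] <= 1.0

    def test_same_seed_reproduces_report_exactly(self, small_signal_cohort):
        matrices, groups, _ = analyse_cohort(small_signal_cohort)
        protocol = EvalProtocol(n_repetitions=2, cv_folds=3, seed=9, models=("logistic", "tree"))
        a = repeated_protocol(matrices, groups, protocol=protocol)
        b = repeated_protocol(matrices, groups, protocol=protocol)
        assert a.to_json() == b.to_json()

    def test_chance_calibration_on_null_cohorts(self):
        """Grand mean test accuracy over 10 null cohorts stays within 3 SE of 0.5."""
        cohort_means = []
        for seed in range(10):
            cohort = generate_null_cohort(small_sim_config(
                n_participants=40, group_sizes=(20, 20), duration_s=4.0, seed=200 + seed))
            matrices, groups, _ = analyse_cohort(cohort)
            protocol = EvalProtocol(
                n_repetitions=3, cv_folds=3, seed=seed, models=("logistic",))
            report = repeated_protocol(matrices, groups, protocol=protocol)
            cohort_means.append(report.test_accuracies("logistic").mean())
        grand = np.mean(cohort_means)
        se = np.std(cohort_means, ddof=1) / np.sqrt(len(cohort_means))
        assert abs(grand - 0.5) <= 3 * se

    def test_summary_table_shape(self, small_signal_cohort):
        matrices, groups, _ = analyse_cohort(small_signal_cohort)
        report = repeated_protocol(
            matrices, groups, protocol=EvalProtocol(n_repetitions=2, cv_folds=3, seed=1)
        )
        df = report.summary()
        assert list(df["model"]) == ["logistic", "knn", "tree", "forest"]
        assert set(df.columns) == {"model", "cv_mean", "cv_sd", "test_mean", "test_sd"}
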