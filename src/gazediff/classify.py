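"""Group-membership prediction under a repeated 80/20 holdout protocol.

For each repetition: participants are split (stratified by craving group)
into training and test sets; frame-wise statistics, video ranking and
selection, and imputation statistics are computed on the training set
only; four classifier families (logistic regression, k-nearest
neighbours, decision tree, random forest) are fitted with stratified
k-fold cross-validation on the training participants and then scored on
the untouched test participants.  Accuracies are averaged over
repetitions so the result does not hinge on one lucky split.

Hyperparameters are pinned explicitly in :data:`DEFAULT_HYPERPARAMS`
rather than relying on silent library defaults, for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .features import (
    FeatureTable,
    build_features,
    guard_training_provenance,
    rank_videos,
    select_top_k,
)
from .framewise import AnalysisConfig, framewise_arrays, summarise
from .io_gaze import FrameGazeMatrix
from .questionnaire import GroupAssignment

MODEL_NAMES = ("logistic", "knn", "tree", "forest")

#: Pinned hyperparameters; scale-sensitive models are wrapped in a
#: standardiser fitted inside each training fold.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "logistic": {"C": 1.0, "max_iter": 1000, "solver": "lbfgs"},
    "knn": {"n_neighbors": 5, "weights": "uniform"},
    "tree": {"max_depth": None, "min_samples_split": 2, "min_samples_leaf": 1},
    "forest": {"n_estimators": 200, "max_depth": None, "min_samples_leaf": 1},
}


class UnknownModelError(ValueError):
    pass


@dataclass(frozen=True)
class EvalProtocol:
    """Constants of the repeated holdout evaluation."""

    train_fraction: float = 0.8
    n_repetitions: int = 18
    cv_folds: int = 5
    models: tuple[str, ...] = MODEL_NAMES
    seed: int = 0
    stratified: bool = True
    top_k: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repetitions < 1 or self.cv_folds < 2:
            raise ValueError("need n_repetitions >= 1 and cv_folds >= 2")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise UnknownModelError(f"unknown models: {sorted(unknown)}")


@dataclass
class RepetitionRecord:
    repetition: int
    train: list[str]
    test: list[str]
    selected_videos: list[str]
    cv_accuracy: dict[str, float]
    test_accuracy: dict[str, float]


@dataclass
class EvaluationReport:
    """Per-model accuracy arrays across repetitions plus split manifests."""

    protocol: EvalProtocol
    repetitions: list[RepetitionRecord]

    def cv_accuracies(self, model: str) -> np.ndarray:
        return np.array([r.cv_accuracy[model] for r in self.repetitions])

    def test_accuracies(self, model: str) -> np.ndarray:
        return np.array([r.test_accuracy[model] for r in self.repetitions])

    def summary(self) -> pd.DataFrame:
        """Mean and SD of cv/test accuracy per model over repetitions."""
        rows = []
        for m in self.protocol.models:
            cv = self.cv_accuracies(m)
            te = self.test_accuracies(m)
            rows.append(
                {
                    "model": m,
                    "cv_mean": cv.mean(),
                    "cv_sd": cv.std(ddof=1) if len(cv) > 1 else 0.0,
                    "test_mean": te.mean(),
                    "test_sd": te.std(ddof=1) if len(te) > 1 else 0.0,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "protocol": {
                "train_fraction": self.protocol.train_fraction,
                "n_repetitions": self.protocol.n_repetitions,
                "cv_folds": self.protocol.cv_folds,
                "models": list(self.protocol.models),
                "seed": self.protocol.seed,
                "stratified": self.protocol.stratified,
                "top_k": self.protocol.top_k,
            },
            "repetitions": [
                {
                    "repetition": r.repetition,
                    "train": r.train,
                    "test": r.test,
                    "selected_videos": r.selected_videos,
                    "cv_accuracy": r.cv_accuracy,
                    "test_accuracy": r.test_accuracy,
                }
                for r in self.repetitions
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def repetition_seed(master_seed: int, repetition: int) -> int:
    """Derive an independent, reproducible sub-seed for one repetition."""
    return int(np.random.SeedSequence((master_seed, repetition)).generate_state(1)[0] % (2**31))


def make_model(name: str, random_state: int = 0):
    """Instantiate one classifier with the pinned hyperparameters."""
    params = DEFAULT_HYPERPARAMS.get(name)
    if params is None:
        raise UnknownModelError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if name == "logistic":
        clf = LogisticRegression(**params)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if name == "knn":
        return Pipeline([("scale", StandardScaler()), ("clf", KNeighborsClassifier(**params))])
    if name == "tree":
        return DecisionTreeClassifier(random_state=random_state, **params)
    return RandomForestClassifier(random_state=random_state, **params)


def split_participants(
    participants: Sequence[str],
    labels: GroupAssignment,
    protocol: EvalProtocol,
    repetition: int,
) -> tuple[list[str], list[str]]:
    """Stratified random train/test split, deterministic per (seed, repetition).

    Rounding: floor(train_fraction * n) per class, then top-up classes by
    largest fractional remainder until the overall training size reaches
    round(train_fraction * N).
    """
    rng = np.random.default_rng(repetition_seed(protocol.seed, repetition))
    participants = list(participants)
    y = [labels.labels[p] for p in participants]
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need both groups present to split")
    if not protocol.stratified:
        classes = [None]
    target_total = int(round(protocol.train_fraction * len(participants)))
    members = {
        c: [p for p, lab in zip(participants, y) if c is None or lab == c] for c in classes
    }
    quota = {c: protocol.train_fraction * len(members[c]) for c in classes}
    take = {c: int(np.floor(quota[c])) for c in classes}
    by_remainder = sorted(classes, key=lambda c: quota[c] - take[c], reverse=True)
    i = 0
    while sum(take.values()) < target_total and i < len(by_remainder):
        c = by_remainder[i]
        if take[c] < len(members[c]) - 1:
            take[c] += 1
        i += 1
    train: list[str] = []
    for c in classes:
        perm = rng.permutation(len(members[c]))
        train.extend(members[c][j] for j in perm[: take[c]])
        if take[c] == 0:
            raise ValueError(f"class {c} absent from training set")
    train_set = set(train)
    train = [p for p in participants if p in train_set]
    test = [p for p in participants if p not in train_set]
    if not test:
        raise ValueError("empty test set")
    return train, test


def _xy(features: FeatureTable, labels: GroupAssignment, participants: Sequence[str]):
    X = features.rows(participants)
    y = np.array([1 if labels.labels[p] == "high" else 0 for p in participants])
    return X, y


def fit_and_score(
    features: FeatureTable,
    labels: GroupAssignment,
    protocol: EvalProtocol,
    model: str,
    train_participants: Sequence[str] | None = None,
    random_state: int = 0,
):
    """Stratified k-fold CV accuracy on training participants; refit on all of them.

    Returns (cv_accuracy, fitted_model).
    """
    participants = list(train_participants) if train_participants is not None else features.participants
    X, y = _xy(features, labels, participants)
    clf = make_model(model, random_state=random_state)
    folds = StratifiedKFold(
        n_splits=protocol.cv_folds, shuffle=True, random_state=random_state
    )
    cv_acc = float(cross_val_score(clf, X, y, cv=folds, scoring="accuracy").mean())
    clf.fit(X, y)
    return cv_acc, clf


def evaluate_holdout(
    model,
    features: FeatureTable,
    labels: GroupAssignment,
    test_participants: Sequence[str],
) -> float:
    """Accuracy on held-out participants."""
    if not list(test_participants):
        raise ValueError("empty test set")
    X, y = _xy(features, labels, test_participants)
    return float((model.predict(X) == y).mean())


def repeated_protocol(
    matrices: Mapping[str, FrameGazeMatrix],
    groups: GroupAssignment,
    cfg: AnalysisConfig = AnalysisConfig(),
    protocol: EvalProtocol = EvalProtocol(),
) -> EvaluationReport:
    """Run the full repeated holdout evaluation.

    Each repetition recomputes frame-wise statistics, video ranking and
    feature imputation on the training participants only (enforced through
    the ranking's provenance token), then fits and scores every model.
    """
    participants = sorted(groups.labels)
    records: list[RepetitionRecord] = []
    for r in range(protocol.n_repetitions):
        train, test = split_participants(participants, groups, protocol, r)
        summaries = []
        for video in sorted(matrices):
            sub = matrices[video].subset(train)
            summaries.append(summarise(framewise_arrays(sub, groups, cfg)))
        ranking = rank_videos(summaries, provenance=f"train:rep{r}:seed{protocol.seed}")
        guard_training_provenance(ranking)
        selected = select_top_k(ranking, protocol.top_k)
        features = build_features(
            matrices, selected, participants=train + test, train_participants=train
        )
        rep_seed = repetition_seed(protocol.seed, r)
        cv_acc: dict[str, float] = {}
        test_acc: dict[str, float] = {}
        for m in protocol.models:
            acc, fitted = fit_and_score(
                features, groups, protocol, m, train_participants=train,
                random_state=rep_seed % (2**31),
            )
            cv_acc[m] = acc
            test_acc[m] = evaluate_holdout(fitted, features, groups, test)
        records.append(
            RepetitionRecord(
                repetition=r,
                train=train,
                test=test,
                selected_videos=selected,
                cv_accuracy=cv_acc,
                test_accuracy=test_acc,
            )
        )
    return EvaluationReport(protocol=protocol, repetitions=records)


# ---------------------------------------------------------------------------
# Leakage demonstration
# ---------------------------------------------------------------------------

def _divergence_scores(
    matrices: Mapping[str, FrameGazeMatrix],
    groups: GroupAssignment,
    selection_participants: Sequence[str],
    all_participants: Sequence[str],
    cfg: AnalysisConfig,
    top_k: int,
) -> tuple[np.ndarray, list[str]]:
    """Signed distance-divergence score per participant and selected video.

    For each selected video, frames significant on the *selection cohort*
    are kept; each participant's feature is the mean over those frames of
    s_f * (d_if - mean_f), where d_if is the participant's distance to the
    frame's selection-cohort centre and s_f the sign of the selection
    cohort's low-minus-high difference.  The feature needs no label at
    prediction time, but the frames and signs encode whatever group
    difference — real or chance — the selection cohort showed.
    """
    sel_summaries = []
    per_video = {}
    for video in sorted(matrices):
        sub = matrices[video].subset(selection_participants)
        res = framewise_arrays(sub, groups, cfg)
        sel_summaries.append(summarise(res))
        per_video[video] = res
    ranking = rank_videos(sel_summaries, provenance="demo")
    selected = [v for v, _ in ranking.entries[:top_k]]
    cols = []
    for video in selected:
        res = per_video[video]
        sig = res.significant & np.isfinite(res.t_stat)
        pos_all = matrices[video].subset(all_participants).positions
        # distance of every participant to the selection cohort's frame centre
        sel_pos = matrices[video].subset(selection_participants).positions
        present = ~np.isnan(sel_pos[:, :, 0])
        counts = present.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            centres = np.nansum(sel_pos, axis=1) / counts[:, None]
        diff = pos_all - centres[:, None, :]
        d = np.hypot(diff[:, :, 0], diff[:, :, 1])
        with np.errstate(invalid="ignore"):
            frame_mean = np.nanmean(d, axis=1)
        signs = np.sign(res.t_stat)
        if not sig.any():
            cols.append(np.zeros(len(all_participants)))
            continue
        contrib = signs[sig, None] * (d[sig] - frame_mean[sig, None])
        with np.errstate(invalid="ignore"):
            score = np.nanmean(contrib, axis=0)
        cols.append(np.nan_to_num(score))
    return np.column_stack(cols), selected


def leakage_demonstration(
    matrices: Mapping[str, FrameGazeMatrix],
    groups: GroupAssignment,
    cfg: AnalysisConfig = AnalysisConfig(),
    n_repetitions: int = 6,
    seed: int = 0,
    leaky: bool = False,
    top_k: int = 2,
) -> float:
    """Mean holdout accuracy of a frame-selection pipeline, leaky or proper.

    The pipeline selects significant frames and builds signed
    distance-divergence features from them; ``leaky=True`` performs that
    selection on the full cohort (test participants included), the proper
    variant on training participants only.  On null data the proper
    variant stays at chance while the leaky one is inflated — the reason
    the evaluation protocol forbids full-cohort selection.
    """
    protocol = EvalProtocol(n_repetitions=n_repetitions, seed=seed, top_k=top_k)
    participants = sorted(groups.labels)
    accs = []
    for r in range(n_repetitions):
        train, test = split_participants(participants, groups, protocol, r)
        ordered = train + test
        selection = ordered if leaky else train
        X, _ = _divergence_scores(matrices, groups, selection, ordered, cfg, top_k)
        y = np.array([1 if groups.labels[p] == "high" else 0 for p in ordered])
        n_train = len(train)
        clf = make_model("logistic", random_state=repetition_seed(seed, r) % (2**31))
        clf.fit(X[:n_train], y[:n_train])
        accs.append(float((clf.predict(X[n_train:]) == y[n_train:]).mean()))
    return float(np.mean(accs))
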