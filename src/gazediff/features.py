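"""Video ranking, top-k selection and classifier feature construction.

Videos are ranked by how many of their frames show a below-alpha group
difference in distance-to-centre — computed on *training participants
only* when used inside an evaluation, which the provenance token on the
ranking enforces.  Features for the classifiers are, per participant and
selected video, the mean (x, y) viewing position over the video's frames;
a fully missing (participant, video) cell is imputed with the training
column mean and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .framewise import VideoDifferenceSummary
from .io_gaze import FrameGazeMatrix

#: Provenance token marking a ranking computed on the full cohort.
FULL_COHORT = "full-cohort"
_TRAIN_PREFIX = "train"


class ProtocolViolation(RuntimeError):
    """Raised when test-participant data leaks into selection or fitting."""


@dataclass
class VideoRanking:
    """Videos in descending order of percent-significant frames.

    ``provenance`` names the participant subset the percentages were
    computed on (``"train:..."`` or :data:`FULL_COHORT`); the evaluation
    protocol refuses full-cohort rankings.
    """

    entries: list[tuple[str, float]]
    provenance: str

    def videos(self) -> list[str]:
        return [v for v, _ in self.entries]


@dataclass
class FeatureTable:
    """Participant x (2 per selected video) mean-position feature matrix."""

    participants: list[str]
    selected_videos: list[str]
    values: np.ndarray
    imputation_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.participants), 2 * len(self.selected_videos)):
            raise ValueError("feature matrix shape does not match participants/videos")

    @property
    def column_names(self) -> list[str]:
        return [f"{v}_{ax}" for v in self.selected_videos for ax in ("x", "y")]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "participant_id", self.participants)
        return df

    def rows(self, participants: Sequence[str]) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.participants)}
        return self.values[[index[p] for p in participants]]


def rank_videos(
    summaries: Sequence[VideoDifferenceSummary], provenance: str
) -> VideoRanking:
    """Sort videos by pct_significant descending, ties by video id."""
    if not summaries:
        raise ValueError("no summaries to rank")
    ordered = sorted(summaries, key=lambda s: (-s.pct_significant, s.video_id))
    return VideoRanking(
        entries=[(s.video_id, s.pct_significant) for s in ordered],
        provenance=provenance,
    )


def select_top_k(ranking: VideoRanking, k: int) -> list[str]:
    """First k videos of the ranking."""
    if not 1 <= k <= len(ranking.entries):
        raise ValueError(f"k={k} out of range 1..{len(ranking.entries)}")
    return ranking.videos()[:k]


def guard_training_provenance(ranking: VideoRanking) -> None:
    """Refuse rankings not derived from a training subset.

    Inside the repeated holdout protocol, video selection must never see
    test participants; a full-cohort ranking is the canonical leak.
    """
    if not ranking.provenance.startswith(_TRAIN_PREFIX):
        raise ProtocolViolation(
            f"video ranking provenance {ranking.provenance!r} is not a training "
            "subset; selection inside evaluation must use training participants only"
        )


def _mean_positions(matrix: FrameGazeMatrix, participants: Sequence[str]) -> np.ndarray:
    """(participants, 2) mean of non-missing positions over frames; NaN if none."""
    sub = matrix.subset(participants).positions
    present = ~np.isnan(sub[:, :, 0])
    counts = present.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.nansum(sub, axis=0) / counts[:, None]
    means[counts == 0] = np.nan
    return means


def build_features(
    matrices: Mapping[str, FrameGazeMatrix],
    selected: Sequence[str],
    participants: Sequence[str],
    train_participants: Sequence[str] | None = None,
) -> FeatureTable:
    """Mean viewing position per participant and selected video.

    Imputation statistics (column means for fully missing cells) are fit on
    ``train_participants`` (default: all ``participants``) and applied to
    everyone, so transforming held-out participants uses training-derived
    values only.
    """
    if train_participants is None:
        train_participants = participants
    cols: list[np.ndarray] = []
    log: list[tuple[str, str]] = []
    for video in selected:
        if video not in matrices:
            raise KeyError(f"no frame matrix for selected video {video}")
        means = _mean_positions(matrices[video], participants)
        train_means = _mean_positions(matrices[video], train_participants)
        if np.isnan(train_means).all(axis=0).any():
            raise ValueError(
                f"video {video}: a feature column is fully missing across training"
            )
        fill = np.nanmean(train_means, axis=0)
        missing = np.isnan(means[:, 0])
        for i in np.flatnonzero(missing):
            log.append((participants[i], video))
        means[missing] = fill
        cols.append(means)
    values = np.concatenate(cols, axis=1) if cols else np.empty((len(participants), 0))
    return FeatureTable(
        participants=list(participants),
        selected_videos=list(selected),
        values=values,
        imputation_log=log,
    )


def write_feature_tsv(table: FeatureTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_selection_manifest(ranking: VideoRanking, selected: Sequence[str], path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(
            {
                "provenance": ranking.provenance,
                "k": len(selected),
                "selected": list(selected),
                "ranking": [{"video_id": v, "pct_significant": p} for v, p in ranking.entries],
            },
            fh,
            indent=2,
        )
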