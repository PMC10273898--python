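"""Frame-wise group-difference statistics for gaze on dynamic stimuli.

The core statistic: for every video frame, compute each group's gaze
centre (mean position of the group's non-missing participants), each
participant's Euclidean distance in pixels to their OWN group's centre,
and a two-sample pooled-variance Student's t-test comparing the low- and
high-group distance samples.  Large distances mean large within-group
dispersion, so the test asks whether the two groups diverge differently
around their respective centres.  A video is summarised by the percentage
of evaluable frames whose uncorrected p falls below alpha; the test is a
screening device for ranking videos, not a confirmatory procedure, so no
multiple-testing correction is applied by design.

Distances to the *other* group's centre are computed and stored as well
(the alternative contrast) but are not tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_gaze import FrameGazeMatrix
from .questionnaire import GroupAssignment


class UndefinedCentreError(ValueError):
    """Raised when a group centre is requested for zero non-missing positions."""


class UndefinedStatisticError(ValueError):
    """Raised when a summary statistic is undefined (e.g. zero variance)."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tuning knobs of the frame-wise analysis.

    alpha: uncorrected per-frame significance level (default 0.05).
    min_per_group: minimum non-missing participants per group for a frame
        to be evaluable (default 3); frames below it are excluded from the
        percentage denominator rather than imputed.
    fps: video frame rate used for sample binning.
    leave_one_out: exclude the participant from their own group centre.
        Off by default: the group centre is the plain mean including the
        contributing participant.
    """

    alpha: float = 0.05
    min_per_group: int = 3
    fps: float = 30.0
    leave_one_out: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_per_group < 2:
            raise ValueError("min_per_group must be >= 2")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass(frozen=True)
class FrameTestResult:
    t_stat: float
    p_value: float
    significant: bool
    zero_variance: bool = False


@dataclass
class FrameStat:
    """Per-frame centres, distances and test outcome for one video."""

    video_id: str
    frame: int
    centre_low: np.ndarray
    centre_high: np.ndarray
    distances_low: np.ndarray
    distances_high: np.ndarray
    distances_low_to_high_centre: np.ndarray
    distances_high_to_low_centre: np.ndarray
    t_stat: float
    p_value: float
    significant: bool
    evaluable: bool


@dataclass
class VideoDifferenceSummary:
    """Percentage of evaluable frames with a below-alpha group difference."""

    video_id: str
    category: str
    n_evaluable_frames: int
    pct_significant: float
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.n_evaluable_frames == 0:
            warnings.warn(
                f"video {self.video_id}: no evaluable frames", stacklevel=2
            )


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    eta_squared: float


def group_centre(positions) -> np.ndarray:
    """Componentwise mean of the non-missing (x, y) positions."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    present = ~np.isnan(pos).any(axis=1)
    if not present.any():
        raise UndefinedCentreError("no non-missing positions; centre undefined")
    return pos[present].mean(axis=0)


def distances_to_centre(positions, centre) -> np.ndarray:
    """Euclidean pixel distances of non-missing positions to ``centre``.

    Order-preserving over the non-missing entries.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    centre = np.asarray(centre, dtype=float)
    present = ~np.isnan(pos).any(axis=1)
    diff = pos[present] - centre
    return np.hypot(diff[:, 0], diff[:, 1])


def frame_ttest(d_low, d_high, alpha: float = 0.05) -> FrameTestResult:
    """Two-sample pooled-variance Student's t-test on distance samples.

    Two-sided p from the t distribution with n1+n2-2 df; significant iff
    p < alpha.  Zero pooled variance with equal means gives t=0, p=1;
    with unequal means the frame is significant by convention and flagged.
    """
    a = np.asarray(d_low, dtype=float)
    b = np.asarray(d_high, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    m1, m2 = a.mean(), b.mean()
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        if m1 == m2:
            return FrameTestResult(0.0, 1.0, False, zero_variance=True)
        t = np.inf if m1 > m2 else -np.inf
        return FrameTestResult(float(t), 0.0, True, zero_variance=True)
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), n1 + n2 - 2)
    return FrameTestResult(float(t), float(p), bool(p < alpha))


def _group_arrays(matrix: FrameGazeMatrix, groups: GroupAssignment) -> tuple[np.ndarray, np.ndarray]:
    labels = []
    for p in matrix.participants:
        if p not in groups.labels:
            raise KeyError(f"participant {p} has no group label")
        labels.append(groups.labels[p])
    labels = np.array(labels)
    low = labels == "low"
    high = labels == "high"
    if not low.any() or not high.any():
        raise ValueError(f"video {matrix.video_id}: a group is absent entirely")
    return low, high


def _per_frame_distances(
    pos: np.ndarray, member: np.ndarray, centres: np.ndarray
) -> np.ndarray:
    """(frames, members) distances to per-frame centres; NaN where missing."""
    sub = pos[:, member, :]
    diff = sub - centres[:, None, :]
    return np.hypot(diff[:, :, 0], diff[:, :, 1])


def _nan_centres(pos: np.ndarray, member: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean position and count over a group's non-missing cells."""
    sub = pos[:, member, :]
    present = ~np.isnan(sub[:, :, 0])
    counts = present.sum(axis=1).astype(float)
    sums = np.nansum(sub, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        centres = sums / counts[:, None]
    return centres, counts


def _loo_distances(pos: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Distances to the group centre excluding each contributing member."""
    sub = pos[:, member, :]
    present = ~np.isnan(sub[:, :, 0])
    counts = present.sum(axis=1).astype(float)
    sums = np.nansum(sub, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (sums[:, None, :] - np.nan_to_num(sub)) / (counts[:, None, None] - 1)
    diff = sub - loo
    return np.hypot(diff[:, :, 0], diff[:, :, 1])


def _nan_mean_var(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise mean, unbiased variance and count ignoring NaN."""
    present = ~np.isnan(d)
    n = present.sum(axis=1).astype(float)
    s = np.nansum(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        ss = np.nansum(d * d, axis=1) - n * mean * mean
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
    return mean, np.maximum(var, 0.0), n


@dataclass
class FramewiseResult:
    """Vectorised per-frame results for one video (arrays over frames)."""

    video_id: str
    centres_low: np.ndarray
    centres_high: np.ndarray
    dist_low_own: np.ndarray
    dist_high_own: np.ndarray
    dist_low_other: np.ndarray
    dist_high_other: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    evaluable: np.ndarray
    n_low: np.ndarray
    n_high: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.t_stat)

    def frame_stats(self) -> list[FrameStat]:
        """Materialise per-frame :class:`FrameStat` records."""
        out = []
        for f in range(self.n_frames):
            dl = self.dist_low_own[f]
            dh = self.dist_high_own[f]
            out.append(
                FrameStat(
                    video_id=self.video_id,
                    frame=f,
                    centre_low=self.centres_low[f],
                    centre_high=self.centres_high[f],
                    distances_low=dl[~np.isnan(dl)],
                    distances_high=dh[~np.isnan(dh)],
                    distances_low_to_high_centre=self.dist_low_other[f][
                        ~np.isnan(self.dist_low_other[f])
                    ],
                    distances_high_to_low_centre=self.dist_high_other[f][
                        ~np.isnan(self.dist_high_other[f])
                    ],
                    t_stat=float(self.t_stat[f]),
                    p_value=float(self.p_value[f]),
                    significant=bool(self.significant[f]),
                    evaluable=bool(self.evaluable[f]),
                )
            )
        return out


def framewise_arrays(
    matrix: FrameGazeMatrix,
    groups: GroupAssignment,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> FramewiseResult:
    """Per-frame centres, distances and pooled t-tests for one video."""
    low, high = _group_arrays(matrix, groups)
    pos = matrix.positions
    centres_low, n_low = _nan_centres(pos, low)
    centres_high, n_high = _nan_centres(pos, high)
    if cfg.leave_one_out:
        d_low = _loo_distances(pos, low)
        d_high = _loo_distances(pos, high)
    else:
        d_low = _per_frame_distances(pos, low, centres_low)
        d_high = _per_frame_distances(pos, high, centres_high)
    d_low_other = _per_frame_distances(pos, low, centres_high)
    d_high_other = _per_frame_distances(pos, high, centres_low)

    m1, v1, n1 = _nan_mean_var(d_low)
    m2, v2, n2 = _nan_mean_var(d_high)
    evaluable = (n1 >= cfg.min_per_group) & (n2 >= cfg.min_per_group)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    zero_var = evaluable & (sp2 == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var, np.where(m1 == m2, 0.0, np.sign(m1 - m2) * np.inf), t)
        p = np.where(zero_var, np.where(m1 == m2, 1.0, 0.0), p)
    t = np.where(evaluable, t, np.nan)
    p = np.where(evaluable, p, np.nan)
    significant = evaluable & (p < cfg.alpha)
    return FramewiseResult(
        video_id=matrix.video_id,
        centres_low=centres_low,
        centres_high=centres_high,
        dist_low_own=d_low,
        dist_high_own=d_high,
        dist_low_other=d_low_other,
        dist_high_other=d_high_other,
        t_stat=t,
        p_value=p,
        significant=significant,
        evaluable=evaluable,
        n_low=n1.astype(int),
        n_high=n2.astype(int),
    )


def summarise(result: FramewiseResult, category: str = "") -> VideoDifferenceSummary:
    """Percentage of evaluable frames whose test falls below alpha."""
    n_eval = int(result.evaluable.sum())
    pct = 100.0 * result.significant.sum() / n_eval if n_eval else 0.0
    return VideoDifferenceSummary(
        video_id=result.video_id,
        category=category,
        n_evaluable_frames=n_eval,
        pct_significant=float(pct),
        n_frames=result.n_frames,
    )


def video_framewise(
    matrix: FrameGazeMatrix,
    groups: GroupAssignment,
    cfg: AnalysisConfig = AnalysisConfig(),
    category: str = "",
) -> tuple[list[FrameStat], VideoDifferenceSummary]:
    """Full per-frame statistics plus the video-level summary."""
    result = framewise_arrays(matrix, groups, cfg)
    return result.frame_stats(), summarise(result, category)


def category_summary(
    summaries: Sequence[VideoDifferenceSummary],
) -> dict[str, tuple[float, float]]:
    """Mean and SEM of pct_significant per category, videos as the unit.

    SEM = sd / sqrt(k) over the k videos of a category; NaN (flagged by a
    warning) for single-video categories.
    """
    by_cat: dict[str, list[float]] = {}
    for s in summaries:
        by_cat.setdefault(s.category, []).append(s.pct_significant)
    out = {}
    for cat in sorted(by_cat):
        vals = np.array(by_cat[cat])
        if len(vals) < 2:
            warnings.warn(f"category {cat}: single video, SEM undefined", stacklevel=2)
            out[cat] = (float(vals.mean()), float("nan"))
        else:
            out[cat] = (float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals))))
    return out


def category_anova(summaries: Sequence[VideoDifferenceSummary]) -> AnovaResult:
    """One-way ANOVA of video-level percentages across categories.

    eta_squared = SS_between / SS_total.  df are (groups-1, N-groups).
    """
    by_cat: dict[str, list[float]] = {}
    for s in summaries:
        by_cat.setdefault(s.category, []).append(s.pct_significant)
    if len(by_cat) < 2:
        raise UndefinedStatisticError("need at least 2 categories for an ANOVA")
    groups = [np.array(v, dtype=float) for v in by_cat.values()]
    all_vals = np.concatenate(groups)
    n, k = len(all_vals), len(groups)
    if n <= k or max(len(g) for g in groups) < 2:
        raise UndefinedStatisticError("need replication within some category")
    grand = all_vals.mean()
    ss_total = float(((all_vals - grand) ** 2).sum())
    if ss_total == 0:
        raise UndefinedStatisticError("zero total variance; F undefined")
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = ss_total - ss_between
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        f = np.inf
        p = 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_stat=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        eta_squared=ss_between / ss_total,
    )


def write_frame_stats_tsv(result: FramewiseResult, path) -> None:
    """TSV of per-frame test outcomes: video_id, frame, t, p, significant, evaluable."""
    import pandas as pd

    pd.DataFrame(
        {
            "video_id": result.video_id,
            "frame": np.arange(result.n_frames),
            "t": result.t_stat,
            "p": result.p_value,
            "significant": result.significant.astype(int),
            "evaluable": result.evaluable.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_summary_tsv(summaries: Sequence[VideoDifferenceSummary], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "video_id": s.video_id,
                "category": s.category,
                "n_frames": s.n_frames,
                "n_evaluable_frames": s.n_evaluable_frames,
                "pct_significant": s.pct_significant,
            }
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
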