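"""Synthetic gaze cohorts with a planted two-group structure.

Emulates the study conditions the analysis assumes: 98 adolescent
participants in two latent craving groups (53 low / 45 high), 16 adverts
of ~30 s in four categories, gaze sampled at 60 Hz on a 1280 x 900
display with blinks as missing samples, plus matching 9-item craving
questionnaires whose median split recovers the latent groups with high
probability.

Every participant's gaze follows a shared smooth target trajectory per
video (the moving content of a dynamic advert) plus isotropic Gaussian
noise.  On *signal videos*, within a contiguous block of signal frames,
the high-craving group's noise SD is multiplied by ``dispersion_ratio``
(a divergence difference — what the frame-wise t-test detects) and its
mean is shifted by ``offset_px`` along a per-video direction (a location
difference — what mean-position classifiers detect).  The emitted truth
object records everything needed to score recovery exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .questionnaire import GacsResponse

CATEGORIES = ("FUN", "SPORT", "PRODUCT", "CONTROL")

#: Per-item response distributions over scores 1..7 for the two groups.
#: Low-craving adolescents cluster near the scale floor; the high group is
#: shifted upward enough that the total-score distributions barely overlap.
DEFAULT_GACS_PARAMS: dict[str, tuple[float, ...]] = {
    "low": (0.55, 0.30, 0.10, 0.05, 0.0, 0.0, 0.0),
    "high": (0.10, 0.25, 0.30, 0.20, 0.10, 0.04, 0.01),
}


class SimConfigError(ValueError):
    pass


def _default_videos() -> dict[str, str]:
    return {f"{cat}_{i}": cat for cat in CATEGORIES for i in range(1, 5)}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generation parameters; defaults are the study conditions."""

    n_participants: int = 98
    group_sizes: tuple[int, int] = (53, 45)  # (low, high)
    categories: Mapping[str, str] = field(default_factory=_default_videos)
    duration_s: float = 30.0
    fps: float = 30.0
    sampling_rate_hz: float = 60.0
    screen: tuple[float, float] = (1280.0, 900.0)
    sigma_base_px: float = 60.0
    dispersion_ratio: float = 1.5
    offset_px: float = 0.0
    signal_videos: tuple[str, ...] = ("FUN_1", "FUN_3")
    signal_frame_fraction: float = 0.5
    blink_rate: float = 0.05
    walk_step_px: float = 8.0
    gacs_params: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GACS_PARAMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_participants:
            raise SimConfigError("group sizes must sum to n_participants")
        if any(v not in self.categories for v in self.signal_videos):
            raise SimConfigError("signal_videos must be a subset of the videos")
        if not 0 <= self.signal_frame_fraction <= 1:
            raise SimConfigError("signal_frame_fraction must be in [0, 1]")
        if not 0 <= self.blink_rate < 1:
            raise SimConfigError("blink_rate must be in [0, 1)")
        if self.dispersion_ratio <= 0 or self.sigma_base_px <= 0:
            raise SimConfigError("dispersion and noise scales must be positive")
        for g, probs in self.gacs_params.items():
            if len(probs) != 7 or abs(sum(probs) - 1.0) > 1e-9:
                raise SimConfigError(f"gacs_params[{g!r}] must be 7 probabilities summing to 1")

    @property
    def videos(self) -> list[str]:
        return sorted(self.categories)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, sufficient to score recovery."""

    group_of: dict[str, str]
    signal_videos: list[str]
    signal_frames: dict[str, tuple[int, int]]  # video -> [start, stop)
    offset_direction: dict[str, tuple[float, float]]
    dispersion_ratio: float
    offset_px: float
    seed: int

    def to_json(self, path=None) -> str:
        payload = {
            "group_of": self.group_of,
            "signal_videos": self.signal_videos,
            "signal_frames": {v: list(se) for v, se in self.signal_frames.items()},
            "offset_direction": {v: list(d) for v, d in self.offset_direction.items()},
            "dispersion_ratio": self.dispersion_ratio,
            "offset_px": self.offset_px,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class Cohort:
    """Generated tables in the external CSV dialects, plus the truth."""

    gaze: pd.DataFrame
    questionnaire: pd.DataFrame
    manifest: pd.DataFrame
    truth: CohortTruth
    config: SimConfig

    def responses(self) -> list[GacsResponse]:
        return [
            GacsResponse(row.participant_id, tuple(int(getattr(row, f"item{i}")) for i in range(1, 10)))
            for row in self.questionnaire.itertuples(index=False)
        ]


def generate_target_trajectory(
    n_frames: int,
    screen: tuple[float, float] = (1280.0, 900.0),
    seed: int | np.random.Generator = 0,
    step_px: float = 8.0,
) -> np.ndarray:
    """Smooth bounded random walk over the screen; (n_frames, 2) positions.

    Gaussian steps of SD ``step_px`` per axis, reflected at the screen
    edges so the target never leaves the display.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width, height = screen
    steps = rng.normal(0.0, step_px, size=(n_frames, 2))
    steps[0] = 0.0
    raw = np.array([width / 2.0, height / 2.0]) + np.cumsum(steps, axis=0)
    out = np.empty_like(raw)
    for axis, bound in enumerate((width, height)):
        folded = np.mod(raw[:, axis], 2.0 * bound)
        out[:, axis] = np.where(folded > bound, 2.0 * bound - folded, folded)
    return out


def _signal_block(n_frames: int, fraction: float) -> tuple[int, int]:
    """Contiguous signal-frame block, centred at 25-75% of the video."""
    length = int(round(fraction * n_frames))
    start = (n_frames - length) // 2
    return start, start + length


def generate_cohort(cfg: SimConfig = SimConfig()) -> Cohort:
    """Generate gaze, questionnaire and manifest tables plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    width, height = cfg.screen
    pids = [f"P{i + 1:03d}" for i in range(cfg.n_participants)]
    n_low, n_high = cfg.group_sizes
    order = rng.permutation(cfg.n_participants)
    group_of = {
        pids[j]: ("low" if rank < n_low else "high") for rank, j in enumerate(order)
    }
    is_high = np.array([group_of[p] == "high" for p in pids])

    n_samples = int(round(cfg.duration_s * cfg.sampling_rate_hz))
    t_ms = np.arange(n_samples) * (1000.0 / cfg.sampling_rate_hz)
    frame_of_sample = np.floor(t_ms * cfg.fps / 1000.0).astype(np.intp)
    n_frames = cfg.n_frames

    signal_frames: dict[str, tuple[int, int]] = {}
    offset_direction: dict[str, tuple[float, float]] = {}
    gaze_parts = []
    for video in cfg.videos:
        traj = generate_target_trajectory(
            n_frames, cfg.screen, seed=rng, step_px=cfg.walk_step_px
        )
        target = traj[np.minimum(frame_of_sample, n_frames - 1)]  # (n_samples, 2)
        sigma = np.full((cfg.n_participants, n_samples), cfg.sigma_base_px)
        offset = np.zeros((cfg.n_participants, n_samples, 2))
        if video in cfg.signal_videos:
            lo, hi = _signal_block(n_frames, cfg.signal_frame_fraction)
            signal_frames[video] = (lo, hi)
            in_block = (frame_of_sample >= lo) & (frame_of_sample < hi)
            sigma[np.ix_(is_high, in_block)] *= cfg.dispersion_ratio
            theta = rng.uniform(0.0, 2.0 * np.pi)
            direction = (float(np.cos(theta)), float(np.sin(theta)))
            offset_direction[video] = direction
            offset[np.ix_(is_high, in_block)] = cfg.offset_px * np.array(direction)
        noise = rng.normal(size=(cfg.n_participants, n_samples, 2)) * sigma[:, :, None]
        pos = target[None, :, :] + offset + noise
        pos[:, :, 0] = np.clip(pos[:, :, 0], 0.0, width)
        pos[:, :, 1] = np.clip(pos[:, :, 1], 0.0, height)
        blink = rng.random((cfg.n_participants, n_samples)) < cfg.blink_rate
        pos[blink] = np.nan
        gaze_parts.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pids, n_samples),
                    "video_id": video,
                    "t_ms": np.tile(t_ms, cfg.n_participants),
                    "x_px": pos[:, :, 0].ravel(),
                    "y_px": pos[:, :, 1].ravel(),
                    "valid": (~blink).astype(int).ravel(),
                }
            )
        )
    gaze = pd.concat(gaze_parts, ignore_index=True)
    gaze["participant_id"] = gaze["participant_id"].astype("category")
    gaze["video_id"] = gaze["video_id"].astype("category")

    items = np.empty((cfg.n_participants, 9), dtype=int)
    scores = np.arange(1, 8)
    for i, p in enumerate(pids):
        probs = np.asarray(cfg.gacs_params[group_of[p]], dtype=float)
        items[i] = rng.choice(scores, size=9, p=probs)
    questionnaire = pd.DataFrame(
        {"participant_id": pids, **{f"item{j + 1}": items[:, j] for j in range(9)}}
    )
    manifest = pd.DataFrame(
        {
            "video_id": cfg.videos,
            "category": [cfg.categories[v] for v in cfg.videos],
            "duration_s": cfg.duration_s,
        }
    )
    has_signal = cfg.dispersion_ratio != 1.0 or cfg.offset_px != 0.0
    truth = CohortTruth(
        group_of=group_of,
        signal_videos=sorted(cfg.signal_videos) if has_signal else [],
        signal_frames=signal_frames if has_signal else {},
        offset_direction=offset_direction,
        dispersion_ratio=cfg.dispersion_ratio,
        offset_px=cfg.offset_px,
        seed=cfg.seed,
    )
    return Cohort(gaze=gaze, questionnaire=questionnaire, manifest=manifest, truth=truth, config=cfg)


def generate_null_cohort(cfg: SimConfig = SimConfig()) -> Cohort:
    """Cohort with no planted gaze difference (both groups one distribution)."""
    return generate_cohort(replace(cfg, dispersion_ratio=1.0, offset_px=0.0))


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write gaze.csv, questionnaire.csv, manifest.csv and truth.json."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gaze = cohort.gaze.copy()
    # full-precision t_ms so frame binning survives the CSV round-trip;
    # sub-millipixel coordinate digits carry no information
    gaze["x_px"] = gaze["x_px"].round(3)
    gaze["y_px"] = gaze["y_px"].round(3)
    gaze.to_csv(out / "gaze.csv", index=False)
    cohort.questionnaire.to_csv(out / "questionnaire.csv", index=False)
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    cohort.truth.to_json(out / "truth.json")
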