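"""Reading, writing and frame-binning of raw gaze-sample streams.

Gaze data arrive as timestamped (x, y) screen positions per participant and
video, sampled by a remote eye tracker (60 Hz by default) with blinks and
track losses coded as invalid samples.  The analysis operates on video
frames, so sample streams are binned into half-open frame windows
[f/fps, (f+1)/fps) and averaged; a frame with no valid sample is missing.

Coordinates are screen pixels, origin top-left, y increasing downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Default display resolution in pixels (width, height).
DEFAULT_SCREEN: tuple[float, float] = (1280.0, 900.0)

#: Default eye-tracker sampling rate in Hz.
DEFAULT_SAMPLING_RATE_HZ: float = 60.0

#: Default video frame rate in frames per second.
DEFAULT_FPS: float = 30.0

GAZE_CSV_COLUMNS = ["participant_id", "video_id", "t_ms", "x_px", "y_px", "valid"]


class GazeParseError(ValueError):
    """Raised when a gaze CSV file cannot be parsed."""


class GazeValidationError(ValueError):
    """Raised when gaze data violate screen-bound or ordering invariants."""


class GazeSample(NamedTuple):
    """One timestamped gaze sample; coordinates are NaN when invalid."""

    participant_id: str
    video_id: str
    t_ms: float
    x_px: float
    y_px: float
    valid: bool


@dataclass
class GazeRecording:
    """One participant's gaze samples for one video.

    Samples are stored as parallel numpy arrays sorted by time; blinks and
    track losses keep their timestamp but carry NaN coordinates and
    ``valid=False``.
    """

    participant_id: str
    video_id: str
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise GazeValidationError("sample arrays must have equal length")
        if self.sampling_rate_hz <= 0:
            raise GazeValidationError("sampling_rate_hz must be positive")
        if n and (np.any(self.t_ms < 0) or np.any(np.diff(self.t_ms) < 0)):
            raise GazeValidationError(
                f"timestamps of {self.participant_id}/{self.video_id} must be "
                "non-negative and sorted"
            )

    def __len__(self) -> int:
        return len(self.t_ms)

    def samples(self) -> Iterator[GazeSample]:
        """Yield samples as :class:`GazeSample` records."""
        for i in range(len(self)):
            yield GazeSample(
                self.participant_id,
                self.video_id,
                float(self.t_ms[i]),
                float(self.x_px[i]),
                float(self.y_px[i]),
                bool(self.valid[i]),
            )


@dataclass
class FrameGazeMatrix:
    """Frame x participant grid of 2-D gaze positions for one video.

    ``positions`` has shape (n_frames, n_participants, 2); a missing cell
    (no valid sample in the frame window) is NaN in both coordinates.
    Participants are kept in sorted order so the column layout is
    deterministic.
    """

    video_id: str
    fps: float
    participants: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise GazeValidationError("positions must have shape (frames, participants, 2)")
        if self.positions.shape[1] != len(self.participants):
            raise GazeValidationError("participant count does not match positions")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_participants(self) -> int:
        return self.positions.shape[1]

    def present(self) -> np.ndarray:
        """Boolean (frames, participants) mask of non-missing cells."""
        return ~np.isnan(self.positions[:, :, 0])

    def subset(self, participants: Sequence[str]) -> "FrameGazeMatrix":
        """Column subset for the given participants (order preserved)."""
        index = {p: j for j, p in enumerate(self.participants)}
        cols = [index[p] for p in participants]
        return FrameGazeMatrix(
            self.video_id, self.fps, list(participants), self.positions[:, cols, :]
        )


def _n_frames_for(t_max_ms: float, fps: float) -> int:
    """Number of frame windows needed to cover a sample at ``t_max_ms``.

    Equals ceil(t_max / frame_duration) except when t_max falls exactly on
    a window boundary, where the sample belongs to the next window.
    """
    return int(math.floor(t_max_ms * fps / 1000.0)) + 1


def read_gaze_csv(
    path,
    screen: tuple[float, float] = DEFAULT_SCREEN,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> list[GazeRecording]:
    """Read a gaze-sample CSV into one :class:`GazeRecording` per (participant, video).

    The dialect is a plain UTF-8 CSV with header
    ``participant_id,video_id,t_ms,x_px,y_px,valid``; ``valid`` is 0/1 and
    invalid rows (blinks) have empty coordinate fields.  Valid rows with
    coordinates off-screen, or rows that cannot be parsed, raise errors
    naming the offending line.
    """
    try:
        # round_trip parsing keeps timestamps exact so samples on a frame
        # boundary land in the same frame as they would in memory
        df = pd.read_csv(
            path,
            dtype={"participant_id": str, "video_id": str},
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise GazeParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in GAZE_CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise GazeParseError(f"{path}: missing columns {missing_cols}")

    # header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2
    for col in ("t_ms", "x_px", "y_px", "valid"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["t_ms"].isna() | df["valid"].isna() | ~df["valid"].isin((0, 1))
    if bad.any():
        raise GazeParseError(f"{path}: malformed row at line {lines[bad.to_numpy()][0]}")
    valid = df["valid"].to_numpy() == 1
    x = df["x_px"].to_numpy(dtype=float)
    y = df["y_px"].to_numpy(dtype=float)
    width, height = screen
    off = valid & ~(
        np.isfinite(x) & np.isfinite(y) & (x >= 0) & (x <= width) & (y >= 0) & (y <= height)
    )
    if off.any():
        raise GazeValidationError(
            f"{path}: valid sample off-screen at line {lines[off][0]}"
        )
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)

    out: list[GazeRecording] = []
    t = df["t_ms"].to_numpy(dtype=float)
    keys = df["participant_id"].astype(str) + "\x00" + df["video_id"].astype(str)
    codes, _ = pd.factorize(keys)
    order = np.lexsort((t, codes))
    boundaries = np.flatnonzero(np.diff(codes[order])) + 1
    for chunk in np.split(order, boundaries):
        i0 = chunk[0]
        out.append(
            GazeRecording(
                participant_id=str(df["participant_id"].iloc[i0]),
                video_id=str(df["video_id"].iloc[i0]),
                t_ms=t[chunk],
                x_px=x[chunk],
                y_px=y[chunk],
                valid=valid[chunk],
                sampling_rate_hz=sampling_rate_hz,
            )
        )
    out.sort(key=lambda r: (r.participant_id, r.video_id))
    return out


def write_gaze_csv(recordings: Iterable[GazeRecording], path) -> None:
    """Write recordings in the CSV dialect read by :func:`read_gaze_csv`."""
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "video_id": rec.video_id,
                    "t_ms": rec.t_ms,
                    "x_px": rec.x_px,
                    "y_px": rec.y_px,
                    "valid": rec.valid.astype(int),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    # keep t_ms at full precision: samples can sit exactly on frame
    # boundaries and must bin identically after a round-trip
    table["x_px"] = table["x_px"].round(3)
    table["y_px"] = table["y_px"].round(3)
    table.to_csv(path, index=False)


def resample_to_frames(
    recording: GazeRecording,
    fps: float = DEFAULT_FPS,
    screen: tuple[float, float] | None = None,
) -> np.ndarray:
    """Bin one recording into frame windows; returns (n_frames, 2) positions.

    Frame f covers [f/fps, (f+1)/fps) seconds from video onset; the frame's
    position is the arithmetic mean of the valid samples in the window and
    NaN when the window holds none.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if len(recording) == 0:
        raise ValueError("recording has no samples")
    n_frames = _n_frames_for(float(recording.t_ms[-1]), fps)
    frame_idx = np.floor(recording.t_ms * fps / 1000.0).astype(np.intp)
    ok = recording.valid & np.isfinite(recording.x_px) & np.isfinite(recording.y_px)
    sums = np.zeros((n_frames, 2))
    counts = np.zeros(n_frames)
    np.add.at(sums[:, 0], frame_idx[ok], recording.x_px[ok])
    np.add.at(sums[:, 1], frame_idx[ok], recording.y_px[ok])
    np.add.at(counts, frame_idx[ok], 1.0)
    with np.errstate(invalid="ignore"):
        positions = sums / counts[:, None]
    positions[counts == 0] = np.nan
    return positions


def assemble_matrix(
    columns: Mapping[str, np.ndarray] | Iterable[tuple[str, np.ndarray]],
    video_id: str,
    fps: float = DEFAULT_FPS,
) -> FrameGazeMatrix:
    """Assemble per-participant frame series into a :class:`FrameGazeMatrix`.

    The frame count is the maximum over participants; shorter series are
    padded with missing frames.  Participants are ordered by sorted id.
    """
    items = list(columns.items()) if isinstance(columns, Mapping) else list(columns)
    ids = [pid for pid, _ in items]
    if len(set(ids)) != len(ids):
        dup = sorted({p for p in ids if ids.count(p) > 1})
        raise GazeValidationError(f"duplicate participant(s) for video {video_id}: {dup}")
    if not items:
        raise GazeValidationError("no participant columns to assemble")
    items.sort(key=lambda kv: kv[0])
    n_frames = max(np.asarray(col).shape[0] for _, col in items)
    positions = np.full((n_frames, len(items), 2), np.nan)
    for j, (_, col) in enumerate(items):
        col = np.asarray(col, dtype=float)
        positions[: col.shape[0], j, :] = col
    return FrameGazeMatrix(video_id, fps, [pid for pid, _ in items], positions)


def frame_matrices_from_table(
    table: pd.DataFrame,
    fps: float = DEFAULT_FPS,
) -> dict[str, FrameGazeMatrix]:
    """Vectorised sample-to-frame binning for a whole gaze table.

    Equivalent to :func:`resample_to_frames` + :func:`assemble_matrix` per
    video but binned in one pass; used by the pipeline on cohort-sized data
    (millions of samples).  ``table`` uses the gaze CSV column layout.
    """
    out: dict[str, FrameGazeMatrix] = {}
    t_all = table["t_ms"].to_numpy(dtype=float)
    valid_all = table["valid"].to_numpy() == 1
    x_all = table["x_px"].to_numpy(dtype=float)
    y_all = table["y_px"].to_numpy(dtype=float)
    video_codes, videos = pd.factorize(table["video_id"], sort=True)
    pid_codes_all, pids = pd.factorize(table["participant_id"], sort=True)
    participants = [str(p) for p in pids]
    n_p = len(participants)
    for v_code, video in enumerate(videos):
        rows = video_codes == v_code
        t = t_all[rows]
        n_frames = _n_frames_for(float(t.max()), fps)
        frame_idx = np.floor(t * fps / 1000.0).astype(np.intp)
        pid_codes = pid_codes_all[rows]
        ok = valid_all[rows] & np.isfinite(x_all[rows]) & np.isfinite(y_all[rows])
        flat = frame_idx[ok] * n_p + pid_codes[ok]
        sums_x = np.bincount(flat, weights=x_all[rows][ok], minlength=n_frames * n_p)
        sums_y = np.bincount(flat, weights=y_all[rows][ok], minlength=n_frames * n_p)
        counts = np.bincount(flat, minlength=n_frames * n_p).astype(float)
        with np.errstate(invalid="ignore"):
            px = (sums_x / counts).reshape(n_frames, n_p)
            py = (sums_y / counts).reshape(n_frames, n_p)
        out[str(video)] = FrameGazeMatrix(
            str(video), fps, participants, np.stack([px, py], axis=-1)
        )
    return out


def read_video_manifest(path) -> pd.DataFrame:
    """Read the video manifest CSV (video_id, category, duration_s)."""
    df = pd.read_csv(path, dtype={"video_id": str, "category": str})
    for col in ("video_id", "category", "duration_s"):
        if col not in df.columns:
            raise GazeParseError(f"{path}: missing manifest column {col}")
    return df
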