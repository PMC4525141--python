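"""Trajectory data model: arena geometry, tracked frames, CSV round-trip.

Coordinate convention (world frame, cm): origin at the arena corner farthest
from the stimulus wall, x-axis pointing away from the stimulus, y-axis
completing a right-handed top-view frame.  The stimulus wall therefore lies at
x = 0 and the stimulus direction is exactly 180 deg.  Angles are degrees in
[0, 360), counter-clockwise from +x.

Pixel (image) convention: x = column, y = row, row increasing downward, with
the stimulus wall on the left image edge.  ``convert_px_to_cm`` maps between
the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, ValidationError

#: relative tolerance (fraction of arena width) for clamping wall jitter
CLAMP_FRACTION = 0.02

CSV_COLUMNS = [
    "index",
    "head_x",
    "head_y",
    "cent_x",
    "cent_y",
    "tail_x",
    "tail_y",
    "detected",
]


@dataclass(frozen=True)
class ArenaGeometry:
    """Square test-arena geometry with a stimulus-adjacent region of interest.

    The ROI is the full-width strip of depth ``roi_depth`` adjoining the
    stimulus wall (x in [0, roi_depth]); with the 12x12 cm arena and 3 cm
    depth it covers 25% of the arena, the chance expectation for occupancy.
    """

    width: float = 12.0
    height: float = 12.0
    roi_depth: float = 3.0
    stimulus_direction: float = 180.0
    fps: float = 29.0
    px_per_cm: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("arena dimensions must be positive")
        if not 0 < self.roi_depth <= self.width:
            raise ValidationError("roi must lie inside the arena")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.px_per_cm is not None and self.px_per_cm <= 0:
            raise ValidationError("px_per_cm must be positive when present")

    @property
    def roi_area_fraction(self) -> float:
        return self.roi_depth / self.width

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 2) inside the arena rectangle."""
        p = np.asarray(points, dtype=float)
        return (
            (p[..., 0] >= 0)
            & (p[..., 0] <= self.width)
            & (p[..., 1] >= 0)
            & (p[..., 1] <= self.height)
        )

    def in_roi(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the stimulus-adjacent ROI strip."""
        p = np.asarray(points, dtype=float)
        return (
            (p[..., 0] >= 0)
            & (p[..., 0] <= self.roi_depth)
            & (p[..., 1] >= 0)
            & (p[..., 1] <= self.height)
        )


def load_arena_config(path: str | Path) -> ArenaGeometry:
    """Read an ArenaGeometry from a YAML config.

    Recognised keys: width_cm, height_cm, roi_depth_cm, fps, px_per_cm.
    Missing keys fall back to the defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"arena config {path} is not a key/value mapping")
    known = {"width_cm", "height_cm", "roi_depth_cm", "fps", "px_per_cm"}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown arena config keys: {sorted(unknown)}")
    kwargs = {}
    if "width_cm" in raw:
        kwargs["width"] = float(raw["width_cm"])
    if "height_cm" in raw:
        kwargs["height"] = float(raw["height_cm"])
    if "roi_depth_cm" in raw:
        kwargs["roi_depth"] = float(raw["roi_depth_cm"])
    if "fps" in raw:
        kwargs["fps"] = float(raw["fps"])
    if "px_per_cm" in raw and raw["px_per_cm"] is not None:
        kwargs["px_per_cm"] = float(raw["px_per_cm"])
    return ArenaGeometry(**kwargs)


def save_arena_config(arena: ArenaGeometry, path: str | Path) -> None:
    cfg = {
        "width_cm": arena.width,
        "height_cm": arena.height,
        "roi_depth_cm": arena.roi_depth,
        "fps": arena.fps,
        "px_per_cm": arena.px_per_cm,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


@dataclass
class TrackedTrajectory:
    """Per-frame head/centroid/tail positions of one fish at a fixed rate.

    Coordinate arrays are (n, 2) float in cm (world frame); rows for
    undetected frames hold NaN.  ``detected`` is a boolean mask.
    """

    head: np.ndarray
    centroid: np.ndarray
    tail: np.ndarray
    detected: np.ndarray
    arena: ArenaGeometry
    subject_id: str = "fish"
    treatment: str = ""
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head, dtype=float).reshape(-1, 2)
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(-1, 2)
        self.tail = np.asarray(self.tail, dtype=float).reshape(-1, 2)
        self.detected = np.asarray(self.detected, dtype=bool).reshape(-1)
        n = len(self.detected)
        if not (len(self.head) == len(self.centroid) == len(self.tail) == n):
            raise ValidationError("coordinate arrays and detected mask disagree in length")
        if self.validate:
            self._validate_and_clamp()

    def _validate_and_clamp(self) -> None:
        det = self.detected
        tol = CLAMP_FRACTION * self.arena.width
        hi = np.array([self.arena.width, self.arena.height])
        for arr in (self.head, self.centroid, self.tail):
            pts = arr[det]
            if np.isnan(pts).any():
                raise ValidationError("detected frames must carry coordinates")
            if (pts < -tol).any() or (pts > hi + tol).any():
                raise ValidationError(
                    "coordinates lie further than the clamping tolerance "
                    f"({tol:.3g} cm) outside the arena"
                )
            arr[det] = np.clip(pts, 0.0, hi)
        for arr in (self.head, self.centroid, self.tail):
            arr[~det] = np.nan

    @property
    def n_frames(self) -> int:
        return len(self.detected)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.arena.fps

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.arena.fps

    def slice_time(self, t0: float, t1: float) -> "TrackedTrajectory":
        """Sub-trajectory covering [t0, t1) seconds."""
        if not 0 <= t0 < t1:
            raise ValidationError("need 0 <= t0 < t1")
        i0 = int(round(t0 * self.arena.fps))
        i1 = min(int(round(t1 * self.arena.fps)), self.n_frames)
        if i0 >= i1:
            raise ValidationError("time window outside trajectory")
        return replace(
            self,
            head=self.head[i0:i1].copy(),
            centroid=self.centroid[i0:i1].copy(),
            tail=self.tail[i0:i1].copy(),
            detected=self.detected[i0:i1].copy(),
            validate=False,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.n_frames, dtype=int),
                "head_x": self.head[:, 0],
                "head_y": self.head[:, 1],
                "cent_x": self.centroid[:, 0],
                "cent_y": self.centroid[:, 1],
                "tail_x": self.tail[:, 0],
                "tail_y": self.tail[:, 1],
                "detected": self.detected.astype(int),
            }
        )


def detected_fraction(traj: TrackedTrajectory) -> float:
    """Fraction of frames in which the fish was detected."""
    if traj.n_frames == 0:
        raise ValidationError("empty trajectory")
    return float(traj.detected.sum()) / traj.n_frames


def write_trajectory(traj: TrackedTrajectory, path: str | Path) -> None:
    """Serialise to the trajectory CSV schema (6-decimal fixed precision)."""
    df = traj.to_frame()
    df.to_csv(path, index=False, float_format="%.6f", na_rep="")


def read_trajectory(
    path: str | Path,
    arena: ArenaGeometry,
    subject_id: str = "fish",
    treatment: str = "",
) -> TrackedTrajectory:
    """Read and validate a trajectory CSV (schema in CSV_COLUMNS)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if list(df.columns) != CSV_COLUMNS:
        raise FormatError(
            f"bad trajectory header in {path}: expected {CSV_COLUMNS}, got {list(df.columns)}"
        )
    idx = df["index"].to_numpy()
    if len(idx) and not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
        raise ValidationError(f"frame indices in {path} are not contiguous")
    det = df["detected"].to_numpy()
    if not np.isin(det, [0, 1]).all():
        raise FormatError("detected flag must be encoded 0/1")
    return TrackedTrajectory(
        head=df[["head_x", "head_y"]].to_numpy(float),
        centroid=df[["cent_x", "cent_y"]].to_numpy(float),
        tail=df[["tail_x", "tail_y"]].to_numpy(float),
        detected=det.astype(bool),
        arena=arena,
        subject_id=subject_id,
        treatment=treatment,
    )


def convert_px_to_cm(traj_px: TrackedTrajectory, arena: ArenaGeometry) -> TrackedTrajectory:
    """Convert a pixel-frame trajectory (image convention) to cm world frame.

    Assumes the camera is axis-aligned with the arena and the stimulus wall is
    on the left image edge: x_cm = col / px_per_cm, y_cm = height - row / px_per_cm.
    """
    if arena.px_per_cm is None:
        raise ConfigurationError("px_per_cm calibration required for conversion")
    ppc = arena.px_per_cm

    def conv(pts: np.ndarray) -> np.ndarray:
        out = np.empty_like(pts)
        out[:, 0] = pts[:, 0] / ppc
        out[:, 1] = arena.height - pts[:, 1] / ppc
        return out

    return TrackedTrajectory(
        head=conv(traj_px.head),
        centroid=conv(traj_px.centroid),
        tail=conv(traj_px.tail),
        detected=traj_px.detected.copy(),
        arena=arena,
        subject_id=traj_px.subject_id,
        treatment=traj_px.treatment,
    )


def trajectory_from_points(
    centroid: Sequence,
    arena: ArenaGeometry,
    head: Sequence | None = None,
    tail: Sequence | None = None,
    detected: Sequence | None = None,
    **kwargs,
) -> TrackedTrajectory:
    """Convenience constructor: centroid-only trajectories reuse the centroid
    for head/tail (orientation-free metrics still work)."""
    c = np.asarray(centroid, dtype=float).reshape(-1, 2)
    h = c.copy() if head is None else np.asarray(head, float).reshape(-1, 2)
    t = c.copy() if tail is None else np.asarray(tail, float).reshape(-1, 2)
    d = np.ones(len(c), bool) if detected is None else np.asarray(detected, bool)
    return TrackedTrajectory(head=h, centroid=c, tail=t, detected=d, arena=arena, **kwargs)
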