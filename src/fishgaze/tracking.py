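"""Blob-based single-fish pose tracking from top-view greyscale video.

Deterministic classical pipeline: temporal-median background model, Otsu
threshold on the absolute difference image, largest connected component,
principal-axis pose with the head assigned to the wider body half (falling
back on heading continuity, then motion direction, when the width asymmetry
is ambiguous).  Frames whose best blob falls outside the plausible area range
are recorded as not detected; gaps are never interpolated here (the distance
correction downstream accounts for them).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import ConfigurationError, DegenerateInputError, InsufficientDataError
from .trajectory import ArenaGeometry, TrackedTrajectory

log = logging.getLogger(__name__)

#: minimum |frame - background| peak for a frame to contain anything at all
MIN_CONTRAST = 0.02
#: relative width-asymmetry below which the head call falls back on continuity
HEAD_AMBIGUITY = 0.05
#: default area gate relative to the median blob area of early frames
AREA_GATE = (0.2, 3.0)


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pixel temporal-median reference image."""

    image: np.ndarray
    method: str = "temporal_median"


@dataclass
class PoseEstimate:
    """Head/centroid/tail in pixel coordinates (col, row); ok=False marks a
    frame with no acceptable blob."""

    head: tuple[float, float] | None
    centroid: tuple[float, float] | None
    tail: tuple[float, float] | None
    blob_area: float
    ok: bool


def as_grey(frame: np.ndarray) -> np.ndarray:
    """Luminance greyscale in [0, 1] from uint8 or float input."""
    f = np.asarray(frame)
    if f.ndim == 3:
        f = f.mean(axis=-1)
    if f.dtype == np.uint8:
        return f.astype(float) / 255.0
    return f.astype(float)


def estimate_background(frames, sample_every: int = 1) -> BackgroundModel:
    """Per-pixel temporal median over every ``sample_every``-th frame.

    A moving fish occupying a small fraction of pixels leaves the median at
    the empty-scene intensity.
    """
    if sample_every < 1:
        raise ConfigurationError("sample_every must be >= 1")
    sampled = [as_grey(f) for f in frames[::sample_every]]
    if len(sampled) < 25:
        raise InsufficientDataError(
            f"background model needs >= 25 sampled frames, got {len(sampled)}"
        )
    return BackgroundModel(image=np.median(np.stack(sampled), axis=0))


def segment_fish(
    frame: np.ndarray,
    bg: BackgroundModel,
    arena_px: tuple[float, float, float, float] | None = None,
    min_area: float | None = None,
    max_area: float | None = None,
):
    """Largest foreground blob of |frame - background|, or None ("missing").

    Otsu's threshold is computed on the difference image restricted to
    ``arena_px`` (col0, row0, col1, row1); a blob whose area falls outside
    [min_area, max_area] is rejected.
    Returns (coords, area): coords is an (m, 2) array of (row, col) pixels.
    """
    f = as_grey(frame)
    if f.shape != bg.image.shape:
        raise ConfigurationError("frame and background sizes disagree")
    diff = np.abs(f - bg.image)
    if arena_px is not None:
        c0, r0, c1, r1 = (int(round(v)) for v in arena_px)
        window = np.zeros_like(diff, dtype=bool)
        window[r0:r1, c0:c1] = True
        diff = np.where(window, diff, 0.0)
    if diff.max() < MIN_CONTRAST:
        return None
    mask = diff > threshold_otsu(diff)
    if not mask.any():
        return None
    lab = label(mask)
    regions = regionprops(lab)
    best = max(regions, key=lambda r: r.area)
    area = float(best.area)
    if min_area is not None and area < min_area:
        return None
    if max_area is not None and area > max_area:
        return None
    return best.coords, area


def extract_pose(blob_coords: np.ndarray, prev: PoseEstimate | None = None) -> PoseEstimate:
    """Principal-axis pose from a blob pixel set.

    Centroid is the pixel mean; the body axis is the first principal
    component; head and tail are the extremal blob pixels along the axis.
    The head end is the half with the larger mean perpendicular spread; if
    the asymmetry is below 5% the choice preserving heading continuity with
    ``prev`` (turn <= 90 deg) wins, else the motion direction decides.
    """
    coords = np.asarray(blob_coords)
    if len(coords) < 3:
        raise DegenerateInputError("blob of fewer than 3 pixels")
    # (x, y) = (col, row) pixel coordinates
    pts = coords[:, ::-1].astype(float)
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    proj = centred @ axis
    perp = centred @ np.array([-axis[1], axis[0]])
    end_pos = pts[int(np.argmax(proj))]
    end_neg = pts[int(np.argmin(proj))]

    pos_half, neg_half = proj > 0, proj < 0
    w_pos = float(np.abs(perp[pos_half]).mean()) if pos_half.any() else 0.0
    w_neg = float(np.abs(perp[neg_half]).mean()) if neg_half.any() else 0.0
    wmax = max(w_pos, w_neg)
    head_positive: bool | None = None
    if wmax > 0 and abs(w_pos - w_neg) >= HEAD_AMBIGUITY * wmax:
        head_positive = w_pos > w_neg
    if head_positive is None and prev is not None and prev.ok and prev.head is not None:
        prev_heading = math.atan2(
            prev.head[1] - prev.centroid[1], prev.head[0] - prev.centroid[0]
        )
        cand = math.atan2(end_pos[1] - centroid[1], end_pos[0] - centroid[0])
        turn = abs((cand - prev_heading + math.pi) % (2 * math.pi) - math.pi)
        head_positive = turn <= math.pi / 2.0
    if head_positive is None and prev is not None and prev.ok and prev.centroid is not None:
        motion = centroid - np.asarray(prev.centroid)
        if np.hypot(*motion) > 1e-9:
            head_positive = float(motion @ axis) >= 0.0
    if head_positive is None:
        head_positive = True  # arbitrary but deterministic

    head, tail = (end_pos, end_neg) if head_positive else (end_neg, end_pos)
    return PoseEstimate(
        head=tuple(head), centroid=tuple(centroid), tail=tuple(tail),
        blob_area=float(len(pts)), ok=True,
    )


def track_video(
    frames,
    arena: ArenaGeometry,
    arena_px: tuple[float, float, float, float] | None = None,
    search_px: tuple[float, float, float, float] | None = None,
    sample_every: int | None = None,
    subject_id: str = "fish",
    treatment: str = "",
) -> TrackedTrajectory:
    """Track one fish through an image sequence; output in cm, arena frame.

    ``arena_px`` is the pixel rectangle the arena maps onto (defaults to the
    full frame); ``search_px`` optionally restricts segmentation (defaults to
    the full frame so fish bodies at the arena edge are not clipped).  The
    area gate is [0.2x, 3x] the median blob area of the first 100 detected
    frames.  Deterministic: same frames, same output.
    """
    frames = list(frames)
    if len(frames) == 0:
        raise InsufficientDataError("empty frame sequence")
    if arena.px_per_cm is None and arena_px is None:
        raise ConfigurationError("need px_per_cm calibration or an arena_px rectangle")
    h, w = as_grey(frames[0]).shape
    if arena_px is None:
        arena_px = (0.0, 0.0, float(w), float(h))

    if sample_every is None:
        sample_every = max(1, len(frames) // 100)
    bg = estimate_background(frames, sample_every=sample_every)

    # pass 1: segment everything (unbounded), collect blobs
    blobs = [segment_fish(f, bg, arena_px=search_px) for f in frames]
    early_areas = [area for b in blobs if b is not None for _, area in [b]][:100]
    if early_areas:
        med = float(np.median(early_areas))
        min_area, max_area = AREA_GATE[0] * med, AREA_GATE[1] * med
    else:
        min_area = max_area = None

    c0, r0, c1, r1 = arena_px
    sx = arena.width / (c1 - c0)
    sy = arena.height / (r1 - r0)

    def to_cm(p):
        return ((p[0] - c0) * sx, arena.height - (p[1] - r0) * sy)

    n = len(frames)
    head = np.full((n, 2), np.nan)
    cent = np.full((n, 2), np.nan)
    tail = np.full((n, 2), np.nan)
    detected = np.zeros(n, dtype=bool)
    prev: PoseEstimate | None = None
    for i, b in enumerate(blobs):
        if b is None:
            continue
        coords, area = b
        if min_area is not None and not (min_area <= area <= max_area):
            continue
        try:
            pose = extract_pose(coords, prev)
        except DegenerateInputError:
            continue
        prev = pose
        detected[i] = True
        head[i] = to_cm(pose.head)
        cent[i] = to_cm(pose.centroid)
        tail[i] = to_cm(pose.tail)

    # tracker output is clamped into the arena (body pixels may overhang the
    # arena rectangle when the fish hugs a wall)
    for arr in (head, cent, tail):
        arr[detected, 0] = np.clip(arr[detected, 0], 0.0, arena.width)
        arr[detected, 1] = np.clip(arr[detected, 1], 0.0, arena.height)

    frac = detected.sum() / n
    log.info("tracked %d frames: %.1f%% detected", n, 100 * frac)
    return TrackedTrajectory(
        head=head, centroid=cent, tail=tail, detected=detected, arena=arena,
        subject_id=subject_id, treatment=treatment,
    )


def read_video(path) -> list[np.ndarray]:
    """Read a video file into a list of greyscale frames via imageio."""
    import imageio.v3 as iio

    try:
        frames = iio.imread(path, index=None)
    except Exception as exc:
        raise IOError(f"cannot read video {path}: {exc}") from exc
    return [as_grey(f) for f in frames]
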