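"""Stimulus-video manipulation and dyad activity analytics.

To dissociate motion from form in a playback stimulus, the two fighting fish
in a dyad clip are replaced, frame by frame, with flat dots of the same mean
area, colour and contrast placed at the tracked centroid positions over the
fish-free background.  Motion is preserved exactly (the dot centres are the
source centroids); body form is removed.  The dyad's on-screen activity is
profiled as the mean speed of the two fish in fixed time bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .metrics import BinnedSeries
from .trajectory import ArenaGeometry

log = logging.getLogger(__name__)


@dataclass
class DyadTrajectory:
    """Two fighters' centroid tracks plus per-fish appearance summaries.

    Positions are cm in the arena frame; both fish are present every frame.
    ``resolution_time_s`` marks the moment a dominant/subordinate emerged.
    Areas are blob areas in px^2 (appearance lives in pixel space); colours
    and contrasts are mean greyscale values in [0, 1].
    """

    pos_a: np.ndarray
    pos_b: np.ndarray
    fps: float
    resolution_time_s: float
    area_a_px2: float = 150.0
    area_b_px2: float = 150.0
    colour_a: float = 0.25
    colour_b: float = 0.30
    contrast_a: float = 0.65
    contrast_b: float = 0.60
    arena: ArenaGeometry | None = None

    def __post_init__(self):
        self.pos_a = np.asarray(self.pos_a, float).reshape(-1, 2)
        self.pos_b = np.asarray(self.pos_b, float).reshape(-1, 2)
        if len(self.pos_a) != len(self.pos_b):
            raise ValidationError("both fish must be present in every frame")
        if np.isnan(self.pos_a).any() or np.isnan(self.pos_b).any():
            raise ValidationError("dyad tracks admit no missing frames")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if not 0 <= self.resolution_time_s <= self.duration_s:
            raise ValidationError("resolution time must lie within the clip")

    @property
    def n_frames(self) -> int:
        return len(self.pos_a)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def swapped(self) -> "DyadTrajectory":
        """Fish labels exchanged (activity profiling must not care)."""
        return DyadTrajectory(
            pos_a=self.pos_b.copy(), pos_b=self.pos_a.copy(), fps=self.fps,
            resolution_time_s=self.resolution_time_s,
            area_a_px2=self.area_b_px2, area_b_px2=self.area_a_px2,
            colour_a=self.colour_b, colour_b=self.colour_a,
            contrast_a=self.contrast_b, contrast_b=self.contrast_a,
            arena=self.arena,
        )


@dataclass(frozen=True)
class DotSpec:
    radius_px: float
    colour: float
    contrast: float


def dyad_activity_profile(dyad: DyadTrajectory, bin_s: float = 30.0) -> BinnedSeries:
    """Mean speed of the fighting dyad (cm/s) in fixed time bins.

    Per bin, the mean over both fish of frame-to-frame centroid speeds (a step
    belongs to the bin of its starting frame).  Bins with fewer than two
    frames and the final partial bin are dropped.
    """
    if dyad.n_frames < 2:
        raise ValidationError("need at least 2 frames")
    frames_per_bin = int(round(bin_s * dyad.fps))
    if frames_per_bin < 2:
        raise ValidationError("bin too narrow for the frame rate")
    n_bins = dyad.n_frames // frames_per_bin
    if n_bins == 0:
        raise ValidationError("clip shorter than one bin")
    speeds = []
    for pos in (dyad.pos_a, dyad.pos_b):
        d = pos[1:] - pos[:-1]
        speeds.append(np.hypot(d[:, 0], d[:, 1]) * dyad.fps)
    values = np.empty(n_bins)
    for b in range(n_bins):
        lo, hi = b * frames_per_bin, (b + 1) * frames_per_bin
        hi = min(hi, dyad.n_frames - 1)  # steps indexed by starting frame
        values[b] = float(np.mean([s[lo:hi].mean() for s in speeds]))
    edges = np.arange(n_bins + 1) * bin_s
    return BinnedSeries(bin_edges_s=edges, values=values, metric="dyad_speed")


def dot_parameters(dyad: DyadTrajectory) -> tuple[DotSpec, DotSpec]:
    """Dot radius/colour/contrast per fish: radius = sqrt(mean_area / pi)."""
    specs = []
    for area, colour, contrast in (
        (dyad.area_a_px2, dyad.colour_a, dyad.contrast_a),
        (dyad.area_b_px2, dyad.colour_b, dyad.contrast_b),
    ):
        if area <= 0:
            raise DegenerateInputError("mean blob area must be positive")
        specs.append(DotSpec(radius_px=math.sqrt(area / math.pi), colour=colour, contrast=contrast))
    return tuple(specs)


def _draw_disc(img: np.ndarray, col: float, row: float, radius: float, value: float) -> None:
    """Compose one anti-aliased filled disc into ``img`` (in place)."""
    h, w = img.shape
    c0 = max(int(math.floor(col - radius - 1)), 0)
    c1 = min(int(math.ceil(col + radius + 2)), w)
    r0 = max(int(math.floor(row - radius - 1)), 0)
    r1 = min(int(math.ceil(row + radius + 2)), h)
    if c0 >= c1 or r0 >= r1:
        return
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    dist = np.hypot(cc - col, rr - row)
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    patch = img[r0:r1, c0:c1]
    patch[...] = patch * (1.0 - cov) + value * cov


def cm_to_px(points_cm: np.ndarray, arena: ArenaGeometry, arena_px: tuple[float, float, float, float]) -> np.ndarray:
    """World cm -> image (col, row); ``arena_px`` = (c0, r0, c1, r1) rectangle
    the arena maps onto (stimulus wall on the left edge, row down)."""
    c0, r0, c1, r1 = arena_px
    sx = (c1 - c0) / arena.width
    sy = (r1 - r0) / arena.height
    p = np.asarray(points_cm, float)
    out = np.empty_like(p)
    out[..., 0] = c0 + p[..., 0] * sx
    out[..., 1] = r0 + (arena.height - p[..., 1]) * sy
    return out


def replace_with_dots(
    frames: np.ndarray,
    dyad: DyadTrajectory,
    background: np.ndarray,
    arena: ArenaGeometry,
    arena_px: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Rebuild each frame as background + two dots at the fighters' centroids.

    ``frames`` is only used for shape/length checks: the output is composed
    over the fish-free ``background``, so edited frames differ from it only
    inside the dot discs.  Dots are anti-aliased; a dot whose centre falls
    outside the frame is clipped with a logged warning.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValidationError("frames must be a (n, rows, cols) stack")
    if frames.shape[0] != dyad.n_frames:
        raise ValidationError("frame count and dyad length disagree")
    if frames.shape[1:] != background.shape:
        raise ValidationError("frames and background sizes disagree")
    h, w = background.shape
    if arena_px is None:
        arena_px = (0.0, 0.0, float(w), float(h))
    spec_a, spec_b = dot_parameters(dyad)
    px_a = cm_to_px(dyad.pos_a, arena, arena_px)
    px_b = cm_to_px(dyad.pos_b, arena, arena_px)
    out = np.empty_like(frames, dtype=float)
    clipped = 0
    for i in range(dyad.n_frames):
        frame = background.astype(float).copy()
        for (col, row), spec in (((px_a[i]), spec_a), ((px_b[i]), spec_b)):
            if not (0 <= col < w and 0 <= row < h):
                clipped += 1
            _draw_disc(frame, float(col), float(row), spec.radius_px, spec.colour)
        out[i] = frame
    if clipped:
        log.warning("%d dot centres fell outside the frame and were clipped", clipped)
    return out


def track_dots(
    frames: np.ndarray,
    background: np.ndarray,
    n_dots: int = 2,
) -> np.ndarray:
    """Recover dot centroids (col, row) per frame from an edited sequence.

    Thresholds |frame - background| (Otsu), keeps the ``n_dots`` largest
    connected components and maintains dot identity by nearest-neighbour
    matching to the previous frame.  Returns an (n_frames, n_dots, 2) array.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    frames = np.asarray(frames, dtype=float)
    out = np.full((len(frames), n_dots, 2), np.nan)
    prev = None
    for i, frame in enumerate(frames):
        diff = np.abs(frame - background)
        if diff.max() < 1e-3:
            continue
        mask = diff > threshold_otsu(diff)
        props = sorted(regionprops(label(mask)), key=lambda r: r.area, reverse=True)[:n_dots]
        if len(props) < n_dots:
            continue
        cents = np.array([[p.centroid[1], p.centroid[0]] for p in props])  # (col, row)
        if prev is not None and n_dots == 2:
            direct = np.linalg.norm(cents - prev, axis=1).sum()
            swapped = np.linalg.norm(cents[::-1] - prev, axis=1).sum()
            if swapped < direct:
                cents = cents[::-1]
        out[i] = cents
        prev = cents
    return out
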