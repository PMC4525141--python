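"""Per-fish and group behavioural read-outs.

Attention toward the stimulus is read out from a tracked trajectory as
(1) percent time in the stimulus-adjacent ROI, (2) the per-frame body
orientation series and its mean resultant vector with projection onto the
stimulus direction, and (3) activity controls (total distance covered, with
the undetected-gap correction, and mean swimming speed inside the ROI).
Temporal dynamics use fixed-width time bins (30 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import (
    ResultantVector,
    group_mean_vector,
    mean_resultant_vector,
    project_onto_direction,
)
from .errors import ValidationError
from .trajectory import TrackedTrajectory

BIN_SECONDS_DEFAULT = 30.0


@dataclass
class OrientationSeries:
    """Centroid-to-head axis angle (deg, arena frame) per usable frame."""

    angles_deg: np.ndarray
    frame_index: np.ndarray  # frame of each angle
    n_skipped: int  # detected frames where head == centroid


@dataclass
class MetricsRecord:
    subject_id: str
    treatment: str
    time_in_roi_pct: float
    total_distance_m: float
    mean_speed_roi_m_s: float | None
    rv: ResultantVector
    r_proj: float


@dataclass
class OccupancyMap:
    """2D detected-centroid counts over the arena plus the 1D marginal along
    the stimulus axis (the 'linear histogram')."""

    counts: np.ndarray  # shape (nx, ny); axis 0 runs along the stimulus axis
    bin_cm: float
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def marginal_stimulus_axis(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def normalised(self) -> np.ndarray:
        """Counts scaled to the maximum cell (display convention)."""
        m = self.counts.max()
        return self.counts / m if m > 0 else self.counts.astype(float)


@dataclass
class BinnedSeries:
    """Fixed-width time-binned metric; NaN marks bins with no detected frames."""

    bin_edges_s: np.ndarray  # length n_bins + 1
    values: np.ndarray  # length n_bins
    metric: str

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])


def orientation_series(traj: TrackedTrajectory) -> OrientationSeries:
    """Per-frame body orientation: atan2(head - centroid) in degrees [0, 360).

    Frames where head coincides with the centroid carry no orientation and are
    skipped (counted in ``n_skipped``).
    """
    det = traj.detected
    if not det.any():
        raise ValidationError("no detected frames")
    d = traj.head[det] - traj.centroid[det]
    norms = np.hypot(d[:, 0], d[:, 1])
    ok = norms > 0
    angles = np.degrees(np.arctan2(d[ok, 1], d[ok, 0])) % 360.0
    return OrientationSeries(
        angles_deg=angles,
        frame_index=np.flatnonzero(det)[ok],
        n_skipped=int(np.count_nonzero(~ok)),
    )


def time_in_roi(traj: TrackedTrajectory) -> float:
    """Percent of detected frames with the centroid inside the ROI."""
    det = traj.detected
    if not det.any():
        raise ValidationError("no detected frames")
    inside = traj.arena.in_roi(traj.centroid[det])
    return 100.0 * float(inside.sum()) / int(det.sum())


def _detected_steps(traj: TrackedTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Step lengths (cm) over consecutive detected frame pairs and the mask of
    qualifying start frames."""
    det = traj.detected
    pair = det[:-1] & det[1:]
    d = traj.centroid[1:] - traj.centroid[:-1]
    steps = np.hypot(d[:, 0], d[:, 1])
    return steps[pair], pair


def total_distance(traj: TrackedTrajectory) -> float:
    """Total distance covered (metres), correcting for undetected gaps.

    Distance while undetected is estimated as proportional to the distance
    covered when detected: D_detected * (n_frames - 1) / n_detected_pairs.
    """
    steps, pair = _detected_steps(traj)
    n_pairs = int(pair.sum())
    if n_pairs < 1:
        raise ValidationError("need at least 2 consecutive detected frames")
    d_detected_cm = float(steps.sum())
    corrected = d_detected_cm * (traj.n_frames - 1) / n_pairs
    return corrected / 100.0


def mean_speed_in_roi(traj: TrackedTrajectory) -> float | None:
    """Mean speed (m/s) over steps whose starting centroid lies in the ROI.

    Steps spanning an undetected gap are excluded.  Returns None when no step
    qualifies.
    """
    det = traj.detected
    pair = det[:-1] & det[1:]
    start_in_roi = np.zeros(traj.n_frames - 1, dtype=bool)
    start_in_roi[pair] = traj.arena.in_roi(traj.centroid[:-1][pair])
    qual = pair & start_in_roi
    if not qual.any():
        return None
    d = traj.centroid[1:][qual] - traj.centroid[:-1][qual]
    speeds_cm_s = np.hypot(d[:, 0], d[:, 1]) * traj.arena.fps
    return float(speeds_cm_s.mean()) / 100.0


def occupancy_heatmap(traj: TrackedTrajectory, bin_cm: float = 0.5) -> OccupancyMap:
    """2D histogram of detected centroid positions (counts sum to n_detected)."""
    if bin_cm <= 0:
        raise ValidationError("bin size must be positive")
    det = traj.detected
    pts = traj.centroid[det]
    x_edges = np.arange(0.0, traj.arena.width + bin_cm * 0.999, bin_cm)
    if x_edges[-1] < traj.arena.width:
        x_edges = np.append(x_edges, traj.arena.width)
    y_edges = np.arange(0.0, traj.arena.height + bin_cm * 0.999, bin_cm)
    if y_edges[-1] < traj.arena.height:
        y_edges = np.append(y_edges, traj.arena.height)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
    return OccupancyMap(counts=counts, bin_cm=bin_cm, x_edges=x_edges, y_edges=y_edges)


def fish_metrics(traj: TrackedTrajectory, stimulus_direction: float | None = None) -> MetricsRecord:
    """All whole-session read-outs for one fish."""
    direction = traj.arena.stimulus_direction if stimulus_direction is None else stimulus_direction
    series = orientation_series(traj)
    rv = mean_resultant_vector(series.angles_deg)
    return MetricsRecord(
        subject_id=traj.subject_id,
        treatment=traj.treatment,
        time_in_roi_pct=time_in_roi(traj),
        total_distance_m=total_distance(traj),
        mean_speed_roi_m_s=mean_speed_in_roi(traj),
        rv=rv,
        r_proj=project_onto_direction(rv, direction),
    )


def binned_series(
    traj: TrackedTrajectory,
    metric: str,
    bin_s: float = BIN_SECONDS_DEFAULT,
) -> BinnedSeries:
    """Time-binned metric: 'roi_occupancy' (%), 'r_proj' ([-1,1]) or 'speed' (m/s).

    The bin width must be a whole number of frames; a final partial bin is
    dropped.  Bins with no usable frames are NaN.
    """
    fps = traj.arena.fps
    frames_per_bin_f = bin_s * fps
    frames_per_bin = int(round(frames_per_bin_f))
    if frames_per_bin < 1 or abs(frames_per_bin_f - frames_per_bin) > 1e-6 * frames_per_bin_f:
        raise ValidationError("bin width must be a whole number of frames")
    n_bins = traj.n_frames // frames_per_bin
    if n_bins == 0:
        raise ValidationError("trajectory shorter than one bin")
    values = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sub = slice(b * frames_per_bin, (b + 1) * frames_per_bin)
        det = traj.detected[sub]
        if metric == "roi_occupancy":
            if det.any():
                inside = traj.arena.in_roi(traj.centroid[sub][det])
                values[b] = 100.0 * inside.sum() / det.sum()
        elif metric == "r_proj":
            d = traj.head[sub][det] - traj.centroid[sub][det]
            norms = np.hypot(d[:, 0], d[:, 1])
            if (norms > 0).any():
                ang = np.degrees(np.arctan2(d[norms > 0, 1], d[norms > 0, 0])) % 360.0
                rv = mean_resultant_vector(ang)
                values[b] = project_onto_direction(rv, traj.arena.stimulus_direction)
        elif metric == "speed":
            pair = det[:-1] & det[1:]
            if pair.any():
                dd = traj.centroid[sub][1:][pair] - traj.centroid[sub][:-1][pair]
                values[b] = float(np.hypot(dd[:, 0], dd[:, 1]).mean()) * fps / 100.0
        else:
            raise ValidationError(f"unknown metric {metric!r}")
    edges = np.arange(n_bins + 1) * bin_s
    return BinnedSeries(bin_edges_s=edges, values=values, metric=metric)


def group_aggregate(records: list[MetricsRecord]) -> pd.DataFrame:
    """Group table: mean, SEM (SD/sqrt(n)) and n per scalar metric.

    Directional data additionally yield the length-weighted group vector
    (alpha_g, R_g) and the group mean of individual projections r_proj with
    its SEM — the form tabulated as mean +/- SEM in group reports.
    SEM is NaN-flagged for a single fish.
    """
    if len(records) == 0:
        raise ValidationError("no records")
    rows = {}
    scalars = {
        "time_in_roi_pct": [r.time_in_roi_pct for r in records],
        "total_distance_m": [r.total_distance_m for r in records],
        "mean_speed_roi_m_s": [
            r.mean_speed_roi_m_s for r in records if r.mean_speed_roi_m_s is not None
        ],
        "r_proj": [r.r_proj for r in records],
    }
    for name, vals in scalars.items():
        v = np.asarray(vals, dtype=float)
        n = v.size
        mean = float(v.mean()) if n else np.nan
        sem = float(v.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows[name] = {"mean": mean, "sem": sem, "n": n}
    gv = group_mean_vector([r.rv for r in records])
    rows["group_vector_alpha_g"] = {"mean": gv.alpha_g, "sem": np.nan, "n": gv.n_fish}
    rows["group_vector_R_g"] = {"mean": gv.R_g, "sem": np.nan, "n": gv.n_fish}
    return pd.DataFrame(rows).T


def aggregate_binned(series_list: list[BinnedSeries]) -> pd.DataFrame:
    """Across-fish mean +/- SEM per time bin (requires identical bin edges)."""
    if len(series_list) < 2:
        raise ValidationError("need at least 2 fish to aggregate")
    edges = series_list[0].bin_edges_s
    for s in series_list[1:]:
        if not np.array_equal(s.bin_edges_s, edges):
            raise ValidationError("bin edges differ across fish")
    mat = np.vstack([s.values for s in series_list])
    n = np.sum(~np.isnan(mat), axis=0)
    mean = np.nanmean(mat, axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame(
        {"bin_start_s": edges[:-1], "mean": mean, "sem": sem, "n": n}
    )
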