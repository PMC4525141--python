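"""Synthetic data: bystander random walks, fight dyads, rendered videos.

The bystander generator is a biased correlated random walk whose heading is,
each frame, either drawn toward the stimulus direction (von Mises around
180 deg with concentration ``kappa_att``, with probability ``p_att``) or a
heading-persistent wander step (von Mises increment around the previous
heading).  Step speeds are gamma distributed; an optional constant drift
pulls the fish toward the stimulus wall; boundaries reflect.  With
``kappa_att = 0`` and ``roi_drift = 0`` the agent is the unbiased null whose
long-run ROI occupancy is the 25% chance level.

The dyad generator produces a two-phase fight: a low-speed mutual-assessment
orbit before the resolution time, then chasing bouts alternating with pauses
(two-state Markov switch), the chaser steering straight at the evader.

The renderer rasterises fish as tapered dark teardrops (wider toward the
head) on a light background and returns exact per-frame ground truth, so the
tracker and the dot editor can be validated end to end without any real
video.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .stimulus import DyadTrajectory, _draw_disc
from .trajectory import ArenaGeometry, TrackedTrajectory

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class BystanderSimConfig:
    """Biased correlated random walk parameters for one bystander.

    Defaults describe an attentive (fight-observing) agent; ``null()`` gives
    the unbiased reference agent.  Speed defaults put a 30-min session in the
    90-130 m total-distance range typical of this assay.
    """

    kappa_att: float = 2.0  # von Mises concentration toward the stimulus
    p_att: float = 0.5  # per-frame probability of an attending orientation
    speed_mean: float = 9.0  # cm/s, gamma mean (hover-adjusted; see null())
    speed_shape: float = 3.0  # gamma shape
    attend_speed_factor: float = 0.25  # attending fish hover: step speed scale
    roi_drift: float = 0.0  # cm/s constant pull toward the stimulus wall
    persistence_kappa: float = 4.0  # wander-heading concentration
    duration_s: float = 1800.0
    fps: float = 29.0
    # detection loss happens along the three dark outer walls (the stimulus
    # side is high-contrast observation glass); defaults emulate the ~4% of
    # frames lost in real recordings
    miss_rate: float = 0.3  # P(undetected) within wall_margin of a dark wall
    wall_margin: float = 0.5  # cm
    body_length: float = 3.0  # cm, head-tail span
    attend_until_s: float | None = None  # attention switched off afterwards

    def __post_init__(self):
        if not 0.0 <= self.p_att <= 1.0 or not 0.0 <= self.miss_rate <= 1.0:
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.kappa_att < 0 or self.roi_drift < 0:
            raise ValidationError("kappa_att and roi_drift must be nonnegative")
        if self.speed_mean <= 0 or self.speed_shape <= 0:
            raise ValidationError("speed parameters must be positive")
        if not 0.0 < self.attend_speed_factor <= 1.0:
            raise ValidationError("attend_speed_factor must lie in (0, 1]")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValidationError("duration and fps must be positive")

    @classmethod
    def null(cls, **overrides) -> "BystanderSimConfig":
        """The unbiased (isolated-control-like) agent.

        Its lower speed_mean compensates for the attentive preset's hovering
        so both condition presets cover ~100 m in 30 min (activity levels do
        not differ between conditions in this assay).
        """
        overrides.setdefault("kappa_att", 0.0)
        overrides.setdefault("roi_drift", 0.0)
        overrides.setdefault("p_att", 0.0)
        overrides.setdefault("speed_mean", 5.5)
        return cls(**overrides)


def simulate_bystander(
    cfg: BystanderSimConfig,
    arena: ArenaGeometry | None = None,
    seed: int = 0,
    subject_id: str = "sim",
    treatment: str = "",
    return_truth: bool = False,
):
    """Simulate one bystander trajectory (fully seeded, deterministic).

    Returns a TrackedTrajectory; with ``return_truth=True`` additionally a
    DataFrame carrying the exact per-frame orientation (``true_alpha_deg``)
    and position including frames marked undetected.
    """
    if arena is None:
        arena = ArenaGeometry(fps=cfg.fps)
    if abs(arena.fps - cfg.fps) > 1e-9:
        raise ConfigurationError("arena fps and simulation fps disagree")
    W, H = arena.width, arena.height
    if cfg.body_length >= min(W, H):
        raise ConfigurationError("fish longer than the arena")
    n = int(round(cfg.duration_s * cfg.fps))
    rng = np.random.default_rng(seed)

    mu_att = math.radians(arena.stimulus_direction)
    att_draw = rng.vonmises(mu_att, cfg.kappa_att, size=n) if cfg.kappa_att > 0 else rng.uniform(
        -math.pi, math.pi, size=n
    )
    wander = rng.vonmises(0.0, cfg.persistence_kappa, size=n)
    speeds = rng.gamma(cfg.speed_shape, cfg.speed_mean / cfg.speed_shape, size=n)
    u_att = rng.random(n)
    u_miss = rng.random(n)

    att_off = n if cfg.attend_until_s is None else int(round(cfg.attend_until_s * cfg.fps))
    half = cfg.body_length / 2.0
    drift = cfg.roi_drift / cfg.fps
    dt = 1.0 / cfg.fps

    # python-scalar loop: the state update is inherently sequential
    att_draw_l = att_draw.tolist()
    wander_l = wander.tolist()
    speeds_l = speeds.tolist()
    u_att_l = u_att.tolist()
    u_miss_l = u_miss.tolist()

    x = rng.uniform(0.0, W)
    y = rng.uniform(0.0, H)
    theta = rng.uniform(-math.pi, math.pi)

    head = np.empty((n, 2))
    cent = np.empty((n, 2))
    tail = np.empty((n, 2))
    detected = np.ones(n, dtype=bool)
    true_alpha = np.empty(n)

    p_att = cfg.p_att
    miss_rate = cfg.miss_rate
    margin = cfg.wall_margin
    for t in range(n):
        attending = t < att_off and u_att_l[t] < p_att
        if attending:
            # gaze toward the stimulus; hover slowly along it.  The wander
            # heading is NOT re-anchored, so attention biases orientation and
            # proximity without turning the walk into a pure taxis.
            alpha = att_draw_l[t]
            ac, as_ = math.cos(alpha), math.sin(alpha)
            step = speeds_l[t] * dt * cfg.attend_speed_factor
            x += step * ac - drift
            y += step * as_
        else:
            theta = theta + wander_l[t]
            ac, as_ = math.cos(theta), math.sin(theta)
            step = speeds_l[t] * dt
            x += step * ac - drift
            y += step * as_
        # reflective boundaries (steps are small; one reflection suffices)
        if x < 0.0:
            x = -x
            theta = math.pi - theta
        elif x > W:
            x = 2.0 * W - x
            theta = math.pi - theta
        if y < 0.0:
            y = -y
            theta = -theta
        elif y > H:
            y = 2.0 * H - y
            theta = -theta
        if not attending:
            # a wandering fish's body aligns with its (reflected) motion
            alpha = theta
            ac, as_ = math.cos(theta), math.sin(theta)
        # head/tail offset, shrunk so both stay inside (angle-preserving)
        lam = 1.0
        adx, ady = abs(half * ac), abs(half * as_)
        if adx > 1e-12:
            lam = min(lam, min(x, W - x) / adx)
        if ady > 1e-12:
            lam = min(lam, min(y, H - y) / ady)
        if lam < 0.0:
            lam = 0.0
        hx, hy = lam * half * ac, lam * half * as_
        cent[t, 0] = x
        cent[t, 1] = y
        head[t, 0] = x + hx
        head[t, 1] = y + hy
        tail[t, 0] = x - hx
        tail[t, 1] = y - hy
        true_alpha[t] = math.degrees(alpha) % 360.0
        if miss_rate > 0.0 and min(W - x, y, H - y) < margin and u_miss_l[t] < miss_rate:
            detected[t] = False

    traj = TrackedTrajectory(
        head=head.copy(), centroid=cent.copy(), tail=tail.copy(), detected=detected,
        arena=arena, subject_id=subject_id, treatment=treatment,
    )
    if not return_truth:
        return traj
    truth = pd.DataFrame(
        {
            "index": np.arange(n),
            "head_x": head[:, 0], "head_y": head[:, 1],
            "cent_x": cent[:, 0], "cent_y": cent[:, 1],
            "tail_x": tail[:, 0], "tail_y": tail[:, 1],
            "detected": detected.astype(int),
            "true_alpha_deg": true_alpha,
        }
    )
    return traj, truth


def simulate_cohort(
    cfg: BystanderSimConfig,
    n_fish: int,
    seed: int = 0,
    arena: ArenaGeometry | None = None,
    treatment: str = "",
    p_att_sd: float = 0.0,
) -> list[TrackedTrajectory]:
    """Simulate a treatment cohort with per-fish seeds.

    ``p_att_sd`` adds between-fish heterogeneity in attentiveness (per-fish
    p_att drawn normal and clipped to [0, 1]), which is what spreads a
    cohort's time-in-ROI the way real groups spread.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_fish):
        fish_cfg = cfg
        if p_att_sd > 0:
            from dataclasses import replace as dc_replace

            p = float(np.clip(rng.normal(cfg.p_att, p_att_sd), 0.0, 1.0))
            fish_cfg = dc_replace(cfg, p_att=p)
        fish_seed = int(rng.integers(0, 2**31 - 1))
        out.append(
            simulate_bystander(
                fish_cfg, arena=arena, seed=fish_seed,
                subject_id=f"{treatment or 'fish'}_{i:02d}", treatment=treatment,
            )
        )
    return out


@dataclass(frozen=True)
class DyadSimConfig:
    """Two-phase fight dyad: assessment orbit, then chase bouts and pauses."""

    duration_s: float = 1800.0
    resolution_time_s: float = 210.0  # 3.5 min
    fps: float = 25.0
    pre_speed: float = 1.5  # cm/s, orbiting speed during assessment
    orbit_radius: float = 1.5  # cm, half distance between displaying fish
    chase_speed: float = 8.0  # cm/s, dominant during bouts
    evade_speed: float = 7.0  # cm/s, subordinate during bouts
    bout_on_rate: float = 0.3  # 1/s, pause -> bout
    bout_off_rate: float = 0.15  # 1/s, bout -> pause
    pause_speed: float = 0.3  # cm/s jitter while paused
    area_a_px2: float = 160.0
    area_b_px2: float = 150.0
    colour_a: float = 0.25
    colour_b: float = 0.30

    def __post_init__(self):
        if self.resolution_time_s >= self.duration_s:
            raise ConfigurationError("resolution time must precede the end of the clip")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValidationError("duration and fps must be positive")
        pre_level = self.pre_speed
        post_level = self.chase_speed * self.bout_on_rate / (self.bout_on_rate + self.bout_off_rate)
        if post_level < pre_level or (post_level == pre_level > 0):
            raise ConfigurationError("post-resolution speed level must exceed the pre level")


def simulate_dyad(cfg: DyadSimConfig, arena: ArenaGeometry | None = None, seed: int = 0) -> DyadTrajectory:
    """Simulate a fight dyad (seeded).

    Pre-resolution the two fish circle a drifting centre on opposite sides
    (facing each other); post-resolution a two-state Markov switch alternates
    pauses with chases in which fish A steers straight at fish B ("heat
    seeking") and B flees along the A->B bearing.
    """
    if arena is None:
        arena = ArenaGeometry(fps=cfg.fps)
    W, H = arena.width, arena.height
    n = int(round(cfg.duration_s * cfg.fps))
    n_res = int(round(cfg.resolution_time_s * cfg.fps))
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.fps

    pos_a = np.empty((n, 2))
    pos_b = np.empty((n, 2))

    # assessment phase: opposed orbit around a slowly wandering centre
    # (noise scales with pre_speed so a zero-speed dyad is truly stationary)
    cx, cy = W / 2.0, H / 2.0
    phi = rng.uniform(0.0, TWO_PI)
    omega = cfg.pre_speed / max(cfg.orbit_radius, 1e-6)
    centre_step = rng.normal(0.0, 0.1 * cfg.pre_speed * dt, size=(n_res, 2)) if n_res else np.empty((0, 2))
    phi_noise = rng.normal(0.0, 0.2 * omega * dt, size=n_res) if n_res else np.empty(0)
    r = cfg.orbit_radius
    for t in range(n_res):
        cx = min(max(cx + centre_step[t, 0], r), W - r)
        cy = min(max(cy + centre_step[t, 1], r), H - r)
        phi += omega * dt + phi_noise[t]
        dx, dy = r * math.cos(phi), r * math.sin(phi)
        pos_a[t] = (cx + dx, cy + dy)
        pos_b[t] = (cx - dx, cy - dy)

    # post-resolution: Markov bout/pause chasing
    if n_res > 0:
        ax, ay = pos_a[n_res - 1]
        bx, by = pos_b[n_res - 1]
    else:
        ax, ay = cx + r, cy
        bx, by = cx - r, cy
    bout = False
    p_on = cfg.bout_on_rate * dt
    p_off = cfg.bout_off_rate * dt
    u_switch = rng.random(n - n_res)
    jitter = rng.normal(0.0, 1.0, size=(n - n_res, 4))
    flee_noise = rng.normal(0.0, 0.3, size=n - n_res)
    for i, t in enumerate(range(n_res, n)):
        if bout:
            if u_switch[i] < p_off:
                bout = False
        else:
            if u_switch[i] < p_on:
                bout = True
        if bout:
            dx, dy = bx - ax, by - ay
            dist = math.hypot(dx, dy)
            if dist < 1e-9:
                dx, dy, dist = 1.0, 0.0, 1.0
            ux, uy = dx / dist, dy / dist
            ax += cfg.chase_speed * dt * ux
            ay += cfg.chase_speed * dt * uy
            ang = math.atan2(uy, ux) + flee_noise[i]
            bx += cfg.evade_speed * dt * math.cos(ang)
            by += cfg.evade_speed * dt * math.sin(ang)
        else:
            ax += cfg.pause_speed * dt * jitter[i, 0]
            ay += cfg.pause_speed * dt * jitter[i, 1]
            bx += cfg.pause_speed * dt * jitter[i, 2]
            by += cfg.pause_speed * dt * jitter[i, 3]
        ax = min(max(ax, 0.0), W)
        ay = min(max(ay, 0.0), H)
        bx = min(max(bx, 0.0), W)
        by = min(max(by, 0.0), H)
        pos_a[t] = (ax, ay)
        pos_b[t] = (bx, by)

    return DyadTrajectory(
        pos_a=pos_a, pos_b=pos_b, fps=cfg.fps, resolution_time_s=cfg.resolution_time_s,
        area_a_px2=cfg.area_a_px2, area_b_px2=cfg.area_b_px2,
        colour_a=cfg.colour_a, colour_b=cfg.colour_b, arena=arena,
    )


# ---------------------------------------------------------------------------
# rendering

#: canonical teardrop: disc offsets s in [0, 1] tail->head and radius profile
N_DISCS = 15
_PROFILE_P, _PROFILE_Q = 0.45, 0.25  # beta-like taper, peak toward the head


def _radius_profile(u: np.ndarray) -> np.ndarray:
    f = u**_PROFILE_P * (1.0 - u) ** _PROFILE_Q
    u0 = _PROFILE_P / (_PROFILE_P + _PROFILE_Q)
    return f / (u0**_PROFILE_P * (1.0 - u0) ** _PROFILE_Q)


@lru_cache(maxsize=8)
def _shape_centroid_offset(length_px: float, width_px: float) -> float:
    """Axial offset (px, toward the head) of the rendered blob's centroid
    relative to the head-tail midpoint, computed on a fine canonical raster."""
    ss = 4  # supersampling
    L = length_px * ss
    rmax = width_px * ss / 2.0
    size = int(math.ceil(L + 2 * rmax + 8))
    img = np.zeros((size, size))
    cy = size / 2.0
    u = np.linspace(0.0, 1.0, N_DISCS)
    radii = _radius_profile(u) * rmax
    x0 = (size - L) / 2.0
    for ui, ri in zip(u, radii):
        _draw_disc(img, x0 + ui * L, cy, max(ri, 0.5), 1.0)
    total = img.sum()
    cols = np.arange(size)
    cx = float((img.sum(axis=0) * cols).sum() / total)
    mid = x0 + L / 2.0
    return (cx - mid) / ss


def _fit_segment_inside(c, u, length, W, H):
    """Slide a length-``length`` segment centred at ``c`` along its axis ``u``
    by the smallest shift that brings both endpoints inside [0,W]x[0,H]
    (a fish nosing a wall keeps its full body, extending backward)."""
    e1 = c + 0.5 * length * u
    e2 = c - 0.5 * length * u
    lo, hi = -math.inf, math.inf
    for axis, bound in ((0, W), (1, H)):
        ua = u[axis]
        if abs(ua) < 1e-12:
            continue
        mn = min(e1[axis], e2[axis])
        mx = max(e1[axis], e2[axis])
        # s*ua in [-mn, bound - mx]
        a, b = -mn / ua, (bound - mx) / ua
        lo = max(lo, min(a, b))
        hi = min(hi, max(a, b))
    if lo > hi:  # cannot fit (never for a 3 cm fish in a 12 cm arena)
        s = 0.0
    else:
        s = min(max(0.0, lo), hi)
    return e1 + s * u, e2 + s * u, c + s * u


@dataclass
class RenderResult:
    """Rendered greyscale frames plus the exact ground truth.

    ``frames`` is (n, rows, cols) float in [0, 1]; ``arena_px`` the pixel
    rectangle the arena maps onto (there is a ``pad_cm`` margin around it so
    fish at the walls are never clipped); ``truth`` the per-frame ground-truth
    table in cm (trajectory schema + true_alpha_deg where applicable).
    """

    frames: np.ndarray
    truth: pd.DataFrame
    background: np.ndarray
    arena_px: tuple[float, float, float, float]
    px_per_cm: float


def _frame_geometry(arena: ArenaGeometry, pad_cm: float) -> tuple[int, int, tuple[float, float, float, float], float]:
    if arena.px_per_cm is None:
        raise ConfigurationError("px_per_cm calibration required to render")
    ppc = arena.px_per_cm
    wpx = int(round((arena.width + 2 * pad_cm) * ppc))
    hpx = int(round((arena.height + 2 * pad_cm) * ppc))
    pad_px = pad_cm * ppc
    arena_px = (pad_px, pad_px, pad_px + arena.width * ppc, pad_px + arena.height * ppc)
    return wpx, hpx, arena_px, ppc


def _world_to_px(x: float, y: float, arena: ArenaGeometry, arena_px) -> tuple[float, float]:
    c0, r0, _, r1 = arena_px
    ppc = arena.px_per_cm
    return (c0 + x * ppc, r0 + (arena.height - y) * ppc)


def _render_fish(
    img: np.ndarray,
    head_cm: np.ndarray,
    tail_cm: np.ndarray,
    arena: ArenaGeometry,
    arena_px,
    width_cm: float,
    value: float,
) -> None:
    """Rasterise one teardrop from tail to head; blob centroid lands on the
    head-tail midpoint (the chain is shifted by the cached shape offset)."""
    ppc = arena.px_per_cm
    hx, hy = head_cm
    tx, ty = tail_cm
    L_cm = math.hypot(hx - tx, hy - ty)
    if L_cm < 1e-9:
        return
    ux, uy = (hx - tx) / L_cm, (hy - ty) / L_cm
    delta = _shape_centroid_offset(round(L_cm * ppc, 2), round(width_cm * ppc, 2)) / ppc
    # shift so the pixel centroid coincides with the midpoint of head/tail
    sx, sy = -delta * ux, -delta * uy
    u = np.linspace(0.0, 1.0, N_DISCS)
    radii = _radius_profile(u) * width_cm * ppc / 2.0
    for ui, ri in zip(u, radii):
        px_ = tx + ui * L_cm * ux + sx
        py_ = ty + ui * L_cm * uy + sy
        col, row = _world_to_px(px_, py_, arena, arena_px)
        _draw_disc(img, col, row, max(float(ri), 0.5), value)


def render_video(
    traj,
    arena: ArenaGeometry,
    noise_sd: float = 0.0,
    pad_cm: float = 2.0,
    background_level: float = 0.9,
    fish_value: float = 0.2,
    body_width_cm: float = 0.6,
    render_body_length_cm: float | None = 3.0,
    occlude_frames=(),
    seed: int = 0,
) -> RenderResult:
    """Render a bystander or dyad trajectory as a top-view greyscale video.

    Fish are dark tapered teardrops (wider head half) on a light background;
    ``noise_sd`` adds Gaussian pixel noise; frames listed in
    ``occlude_frames`` (and undetected frames) are rendered without the fish.
    The exact ground truth accompanies the frames.

    Bystander frames are rasterised at the full ``render_body_length_cm``
    along the head-tail axis (overhanging the ``pad_cm`` margin at walls),
    so the blob's orientation stays well defined everywhere; pass None to
    render exactly the possibly wall-shortened head-tail segment instead.
    """
    wpx, hpx, arena_px, ppc = _frame_geometry(arena, pad_cm)
    bg = np.full((hpx, wpx), background_level, dtype=float)
    occ = set(int(i) for i in occlude_frames)
    rng = np.random.default_rng(seed)

    if isinstance(traj, TrackedTrajectory):
        n = traj.n_frames
        if traj.arena.width != arena.width or traj.arena.height != arena.height:
            raise ConfigurationError("trajectory arena and rendering arena disagree")
        frames = np.empty((n, hpx, wpx), dtype=float)
        r_head = traj.head.copy()
        r_cent = traj.centroid.copy()
        r_tail = traj.tail.copy()
        for i in range(n):
            img = bg.copy()
            if i not in occ and traj.detected[i]:
                head, tail = traj.head[i], traj.tail[i]
                if render_body_length_cm is not None:
                    span = math.hypot(head[0] - tail[0], head[1] - tail[1])
                    u = (head - tail) / span if span > 1e-9 else np.array([1.0, 0.0])
                    head, tail, mid = _fit_segment_inside(
                        traj.centroid[i], u, render_body_length_cm, arena.width, arena.height
                    )
                    r_head[i], r_cent[i], r_tail[i] = head, mid, tail
                _render_fish(img, head, tail, arena, arena_px, body_width_cm, fish_value)
            frames[i] = img
        truth = pd.DataFrame(
            {
                "index": np.arange(n),
                "head_x": r_head[:, 0], "head_y": r_head[:, 1],
                "cent_x": r_cent[:, 0], "cent_y": r_cent[:, 1],
                "tail_x": r_tail[:, 0], "tail_y": r_tail[:, 1],
                "detected": traj.detected.astype(int),
                "occluded": [int(i in occ) for i in range(n)],
            }
        )
    elif isinstance(traj, DyadTrajectory):
        n = traj.n_frames
        frames = np.empty((n, hpx, wpx), dtype=float)
        # dyad tracks are centroid-only: render heading along motion direction
        def headings(pos):
            d = np.diff(pos, axis=0, append=pos[-1:] + (pos[-1:] - pos[-2:-1]))
            ang = np.arctan2(d[:, 1], d[:, 0])
            keep = np.hypot(d[:, 0], d[:, 1]) > 1e-6
            for i in range(1, len(ang)):
                if not keep[i]:
                    ang[i] = ang[i - 1]
            return ang
        ang_a, ang_b = headings(traj.pos_a), headings(traj.pos_b)
        half = 1.0  # cm: stimulus fish rendered slightly smaller than bystanders
        for i in range(n):
            img = bg.copy()
            if i not in occ:
                for pos, ang, val in (
                    (traj.pos_a[i], ang_a[i], traj.colour_a),
                    (traj.pos_b[i], ang_b[i], traj.colour_b),
                ):
                    u = np.array([math.cos(ang), math.sin(ang)])
                    _render_fish(img, pos + half * u, pos - half * u, arena, arena_px, body_width_cm, val)
            frames[i] = img
        truth = pd.DataFrame(
            {
                "index": np.arange(n),
                "a_x": traj.pos_a[:, 0], "a_y": traj.pos_a[:, 1],
                "b_x": traj.pos_b[:, 0], "b_y": traj.pos_b[:, 1],
            }
        )
    else:
        raise ValidationError("traj must be a TrackedTrajectory or DyadTrajectory")

    if noise_sd > 0:
        frames = np.clip(frames + rng.normal(0.0, noise_sd, size=frames.shape), 0.0, 1.0)
    return RenderResult(frames=frames, truth=truth, background=bg, arena_px=arena_px, px_per_cm=ppc)
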