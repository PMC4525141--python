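import numpy as np
import pytest

from fishgaze.trajectory import ArenaGeometry, TrackedTrajectory


@pytest.fixture
def arena() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture
def arena_px() -> ArenaGeometry:
    return ArenaGeometry(px_per_cm=10.0)


def make_traj(
    centroid,
    arena,
    head=None,
    tail=None,
    detected=None,
    **kwargs,
) -> TrackedTrajectory:
    """Build a trajectory from raw arrays; head/tail default to the centroid
    (orientation-free) — pass them explicitly where orientation matters."""
    c = np.asarray(centroid, dtype=float).reshape(-1, 2)
    if head is None:
        head = c.copy()
    if tail is None:
        tail = c.copy()
    if detected is None:
        detected = np.ones(len(c), dtype=bool)
    return TrackedTrajectory(
        head=np.asarray(head, float),
        centroid=c,
        tail=np.asarray(tail, float),
        detected=np.asarray(detected, bool),
        arena=arena,
        **kwargs,
    )
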