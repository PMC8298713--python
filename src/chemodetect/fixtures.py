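"""Tiny deterministic observation tables for tests and demonstrations.

Every fixture is generated programmatically (no bundled data files) and is
small enough to reason about by hand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import IMMUNE, TARGET, ObservationTable


def _table(rows, frame_interval=1.0) -> ObservationTable:
    df = pd.DataFrame(rows, columns=["t", "x", "y", "z", "id", "class"])
    return ObservationTable(df, frame_interval=frame_interval)


def straight_runner() -> ObservationTable:
    """One immune cell running straight (+x at 5 µm/frame) past one fixed
    target at (75, 40).  All turning angles are zero, so the fitted kappa
    saturates at the clamp and every p-value follows from the approach-cone
    geometry alone — hand-checkable against direct quadrature."""
    rows = []
    for t in range(30):
        rows.append((t, 5.0 * t, 0.0, 0.0, 0, IMMUNE))
        rows.append((t, 75.0, 40.0, 0.0, 1, TARGET))
    return _table(rows)


def gap_track() -> ObservationTable:
    """One immune cell observed at frames 0,1,2,4,5,6 (gap at t=3) wiggling
    deterministically, plus one nearby target; exercises the triplet gap
    rules (centers 2 and 4 are suppressed)."""
    ts = [0, 1, 2, 4, 5, 6]
    rows = []
    for k, t in enumerate(ts):
        x = 3.0 * t
        y = 1.5 * ((-1) ** k)
        rows.append((t, x, y, 0.0, 0, IMMUNE))
    for t in range(7):
        rows.append((t, 10.0, 12.0, 0.0, 1, TARGET))
    return _table(rows)


def two_class() -> ObservationTable:
    """Four immune cells and three targets on deterministic pseudo-random
    walks over 40 frames inside a 200 µm box; exercises the within-class
    (immune-immune) versus cross-class pairing modes."""
    rng = np.random.default_rng(20210722)
    rows = []
    n_frames = 40
    for cid in range(4):
        pos = rng.random(2) * 200.0
        heading = rng.uniform(-np.pi, np.pi)
        for t in range(n_frames):
            rows.append((t, pos[0], pos[1], 0.0, cid, IMMUNE))
            heading += rng.vonmises(0.0, 2.0)
            pos = pos + rng.rayleigh(4.0) * np.array(
                [np.cos(heading), np.sin(heading)])
    for j in range(3):
        pos = rng.random(2) * 200.0
        for t in range(n_frames):
            rows.append((t, pos[0], pos[1], 0.0, 10 + j, TARGET))
    return _table(rows)


FIXTURES = {
    "straight-runner": straight_runner,
    "gap-track": gap_track,
    "two-class": two_class,
}


def make_fixture(name: str) -> ObservationTable:
    """Build a registered fixture table by name."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    return builder()
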