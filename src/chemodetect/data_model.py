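"""Observation tables, cell trajectories, triplets, and distance gating.

The universal input is a *tracked-cell observation table*: one row per cell
detection, with an integer frame index ``t``, coordinates ``x, y, z`` in
micrometres, an integer cell ``id`` and a ``class`` label (0 = immune /
searcher cell, 1 = target cell).  From such a table we assemble per-cell
trajectories and extract *triplets* — three positions of one immune cell at
frames ``t-n, t, t+n`` — which are the elementary units of the analysis.
Tracking gaps are handled by simply not emitting triplets whose three frames
are not all observed; the sub-sampling factor ``n`` trades time resolution
for an effectively longer recording interval.

Angles are always computed in the x-y plane; the z coordinate enters only
through the 3-D immune-target distance gate ``r_max``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConsistencyError, FormatError

#: class label of immune (searcher) cells
IMMUNE = 0
#: class label of target cells
TARGET = 1

#: steps shorter than this (in µm) have no usable heading; triplets
#: containing one are dropped
EPS_STEP = 1e-6

REQUIRED_COLUMNS = ("t", "x", "y", "z", "id", "class")
VALID_CLASSES = (IMMUNE, TARGET)


# ---------------------------------------------------------------------------
# observation tables
# ---------------------------------------------------------------------------

@dataclass
class ObservationTable:
    """A validated detection matrix plus the recording interval.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``t, x, y, z, id, class``; one row per detection.
    frame_interval : float
        Time between successive frames (minutes by convention); carried as
        metadata, never stored inside the table itself.
    """

    data: pd.DataFrame
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.data = _validate_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.unique(self.data["id"].to_numpy())

    @property
    def frames(self) -> np.ndarray:
        return np.unique(self.data["t"].to_numpy())

    def subset(self, cell_class: int) -> pd.DataFrame:
        return self.data[self.data["class"] == cell_class]


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() | ~np.isfinite(vals.to_numpy()))
        if bad.size:
            raise FormatError(
                f"non-numeric or non-finite value in column {col!r} at row {bad[0]}"
            )
        df[col] = vals.astype(float)
    for col in ("t", "id", "class"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise FormatError(
                f"non-numeric value in column {col!r} at row {bad[0]}"
            )
        if not np.allclose(vals.to_numpy(float) % 1.0, 0.0):
            raise FormatError(f"column {col!r} must be integer-valued")
        df[col] = vals.astype(int)
    bad_class = set(df["class"].unique()) - set(VALID_CLASSES)
    if bad_class:
        raise FormatError(f"unknown class label(s): {sorted(bad_class)}")
    dup = df.duplicated(subset=["t", "id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ConsistencyError(
            f"duplicate observation for cell id {row['id']} at frame t={row['t']}"
        )
    return df.reset_index(drop=True)


def load_observations(path, sep: str = ",", frame_interval: float = 1.0) -> ObservationTable:
    """Read a delimited observation table (header ``t,x,y,z,id,class``)."""
    df = pd.read_csv(path, sep=sep)
    return ObservationTable(df, frame_interval=frame_interval)


def write_observations(table: ObservationTable, path, sep: str = ",") -> None:
    """Write ``table`` as delimited text; round-trips losslessly."""
    table.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ordered positions of one cell; ``t`` strictly increasing, gaps allowed."""

    cell_id: int
    cell_class: int
    t: np.ndarray          # (L,) int frame indices
    xyz: np.ndarray        # (L, 3) float positions in µm

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return self.xyz[:, :2]

    @property
    def missing_frames(self) -> np.ndarray:
        """Frames inside the observed span at which the cell was not detected."""
        if len(self.t) == 0:
            return np.empty(0, dtype=int)
        full = np.arange(self.t[0], self.t[-1] + 1)
        return np.setdiff1d(full, self.t)

    def step_widths(self, n: int = 1) -> np.ndarray:
        """In-plane step widths between frames ``t`` and ``t+n`` (gaps skipped)."""
        index = {int(tt): k for k, tt in enumerate(self.t)}
        out = []
        for k, tt in enumerate(self.t):
            kn = index.get(int(tt) + n)
            if kn is not None:
                out.append(float(np.hypot(*(self.xyz[kn, :2] - self.xyz[k, :2]))))
        return np.asarray(out)


def build_trajectories(table: ObservationTable) -> list[Trajectory]:
    """Assemble one :class:`Trajectory` per cell id, sorted by frame."""
    out: list[Trajectory] = []
    for cell_id, sub in table.data.groupby("id", sort=True):
        classes = sub["class"].unique()
        if len(classes) > 1:
            raise ConsistencyError(
                f"cell id {cell_id} appears with multiple class labels {sorted(classes)}"
            )
        sub = sub.sort_values("t")
        out.append(
            Trajectory(
                cell_id=int(cell_id),
                cell_class=int(classes[0]),
                t=sub["t"].to_numpy(int),
                xyz=sub[["x", "y", "z"]].to_numpy(float),
            )
        )
    return out


# ---------------------------------------------------------------------------
# triplets
# ---------------------------------------------------------------------------

@dataclass
class Triplet:
    """Three in-plane positions of one immune cell at frames t-n, t, t+n.

    ``center`` keeps the full 3-D position at the central frame for the
    distance gate; the angles downstream use only ``r_prev, r_mid, r_next``.
    """

    cell_id: int
    t: int
    r_prev: np.ndarray     # (2,)
    r_mid: np.ndarray      # (2,)
    r_next: np.ndarray     # (2,)
    center: np.ndarray     # (3,) 3-D position at the central frame
    n: int = 1


def extract_triplets(traj: Trajectory, n: int = 1,
                     eps_step: float = EPS_STEP) -> list[Triplet]:
    """Extract all overlapping triplets at sub-sampling factor ``n``.

    A triplet is emitted for every frame ``t`` at which the cell was also
    observed at exactly ``t-n`` and ``t+n``; tracking gaps therefore
    suppress the affected triplets automatically.  Triplets in which either
    step is shorter than ``eps_step`` carry no heading and are dropped.
    """
    if n < 1:
        raise ValueError("sub-sampling factor n must be >= 1")
    index = {int(tt): k for k, tt in enumerate(traj.t)}
    out: list[Triplet] = []
    for k, tt in enumerate(traj.t):
        tt = int(tt)
        kp = index.get(tt - n)
        kn = index.get(tt + n)
        if kp is None or kn is None:
            continue
        r_prev = traj.xyz[kp, :2]
        r_mid = traj.xyz[k, :2]
        r_next = traj.xyz[kn, :2]
        if (np.hypot(*(r_mid - r_prev)) <= eps_step
                or np.hypot(*(r_next - r_mid)) <= eps_step):
            continue
        out.append(Triplet(traj.cell_id, tt, r_prev.copy(), r_mid.copy(),
                           r_next.copy(), traj.xyz[k].copy(), n))
    return out


def count_triplet_candidates(traj: Trajectory, n: int = 1) -> int:
    """Number of frames with both neighbours observed (before the step filter)."""
    ts = set(int(t) for t in traj.t)
    return sum(1 for t in ts if (t - n) in ts and (t + n) in ts)


def filter_min_triplets(by_cell: Mapping[int, Sequence[Triplet]],
                        n_tr_min: int) -> dict[int, list[Triplet]]:
    """Drop cells contributing fewer than ``n_tr_min`` triplets.

    Cells with very few triplets do not support a reliable estimate of
    their migration parameters and are excluded entirely.
    """
    if n_tr_min < 1:
        raise ValueError("n_tr_min must be >= 1")
    return {cid: list(trs) for cid, trs in by_cell.items() if len(trs) >= n_tr_min}


# ---------------------------------------------------------------------------
# immune-target pairing
# ---------------------------------------------------------------------------

@dataclass
class TripletTargetPair:
    """One triplet together with one in-range target at the central frame."""

    triplet: Triplet
    target_id: int
    target_xy: np.ndarray  # (2,) target in-plane position at the central frame
    distance: float        # 3-D immune-target distance (µm)


def pair_with_targets(triplets: Iterable[Triplet], table: ObservationTable,
                      r_max: float, immune_class: int = IMMUNE,
                      target_class: int = TARGET,
                      use_z: bool = True) -> list[TripletTargetPair]:
    """Pair every triplet with every target within ``r_max`` at its central frame.

    The gate uses the 3-D Euclidean distance between the triplet's central
    immune position and the target (set ``use_z=False`` for strictly planar
    data).  A cell is never paired with itself, which makes
    ``immune_class == target_class`` (within-class analysis) well defined.
    Triplets without any in-range target contribute nothing.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    if immune_class not in VALID_CLASSES or target_class not in VALID_CLASSES:
        raise ValueError("class labels must be 0 (immune) or 1 (target)")

    tgt = table.subset(target_class)
    by_frame = {int(t): sub for t, sub in tgt.groupby("t")}
    trips_by_frame: dict[int, list[Triplet]] = defaultdict(list)
    for trip in triplets:
        trips_by_frame[int(trip.t)].append(trip)

    pairs: list[TripletTargetPair] = []
    for t, trips in sorted(trips_by_frame.items()):
        sub = by_frame.get(t)
        if sub is None or len(sub) == 0:
            continue
        coords = sub[["x", "y", "z"]].to_numpy(float)
        gate_coords = coords.copy()
        if not use_z:
            gate_coords[:, 2] = 0.0
        ids = sub["id"].to_numpy(int)
        tree = cKDTree(gate_coords)
        centers = np.array([trip.center for trip in trips], dtype=float)
        if not use_z:
            centers[:, 2] = 0.0
        hits = tree.query_ball_point(centers, r_max)
        for trip, center, idxs in zip(trips, centers, hits):
            for idx in idxs:
                if ids[idx] == trip.cell_id:
                    continue
                d = float(np.linalg.norm(gate_coords[idx] - center))
                pairs.append(TripletTargetPair(trip, int(ids[idx]),
                                               coords[idx, :2].copy(), d))
    return pairs
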