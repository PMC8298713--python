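"""Approach-cone geometry and per-step p-values.

For a triplet (r_{t-n}, r_t, r_{t+n}) of an immune cell and the position of
a nearby target at the central frame, the *optimal* shift vector
``s_opt = r_target - r_t`` points straight at the target, and the optimal
turning angle ``theta_star`` is its angle relative to the incoming
direction r_t - r_{t-n}.  The actually performed step ``s1 = r_{t+n} - r_t``
encloses the angle ``delta_theta`` with s_opt.  The *approach cone* is the
interval of turning angles [theta_star - delta_theta, theta_star +
delta_theta] — exactly the moves at least as target-directed as the
observed one.  Integrating the cell's von-Mises turning-angle distribution
over this cone yields the p-value

    p_hat = P(move at least as target-directed | blind migration),

so small p-values flag attraction and large p-values flag repulsion.
p-values are pooled over all (triplet, target) pairs of a recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import EPS_STEP, Triplet, TripletTargetPair
from .errors import ConfigurationError
from .migration import MigrationParams, signed_angle, vonmises_arc_integral


@dataclass
class ApproachGeometry:
    """Approach-cone geometry of one (triplet, target) pair."""

    theta_star: float     # optimal turning angle toward the target, (-pi, pi]
    delta_theta: float    # half-width of the approach cone, [0, pi]
    theta_actual: float   # realized turning angle


def approach_geometry(triplet: Triplet, target_xy) -> ApproachGeometry:
    """Compute the approach cone for one triplet and one target position."""
    target_xy = np.asarray(target_xy, float)[:2]
    u = triplet.r_mid - triplet.r_prev
    s1 = triplet.r_next - triplet.r_mid
    s_opt = target_xy - triplet.r_mid
    if np.hypot(*s_opt) <= EPS_STEP:
        raise ConfigurationError(
            "target coincides with the immune cell position; pair is degenerate")
    theta_star = signed_angle(u, s_opt)
    theta_actual = signed_angle(u, s1)
    cosd = np.dot(s1, s_opt) / (np.hypot(*s1) * np.hypot(*s_opt))
    delta = float(np.arccos(np.clip(cosd, -1.0, 1.0)))
    return ApproachGeometry(theta_star, delta, theta_actual)


def pvalue(kappa: float, geom: ApproachGeometry) -> float:
    """Integrate the von-Mises turning-angle law over the approach cone.

    The integral is taken on the circle: when the cone crosses the +-pi
    branch cut the two sub-arcs are summed, and a cone of full width 2 pi
    gives exactly 1.
    """
    return float(vonmises_arc_integral(
        kappa, geom.theta_star - geom.delta_theta,
        geom.theta_star + geom.delta_theta))


# ---------------------------------------------------------------------------
# vectorized internals (shared with the randomized-reference machinery)
# ---------------------------------------------------------------------------

def _geometry_pvalues(kappa: np.ndarray, u: np.ndarray, s1: np.ndarray,
                      s_opt: np.ndarray, eps: float = EPS_STEP):
    """p-values for arrays of incoming, outgoing and optimal shift vectors.

    Returns ``(p, valid)`` where ``valid`` flags pairs whose optimal shift
    is non-degenerate; ``p`` is computed only where valid (0 elsewhere).
    """
    n_opt = np.hypot(s_opt[:, 0], s_opt[:, 1])
    valid = n_opt > eps
    cross = u[:, 0] * s_opt[:, 1] - u[:, 1] * s_opt[:, 0]
    dot = u[:, 0] * s_opt[:, 0] + u[:, 1] * s_opt[:, 1]
    theta_star = np.arctan2(cross, dot)
    n1 = np.hypot(s1[:, 0], s1[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosd = (s1 * s_opt).sum(axis=1) / (n1 * n_opt)
    delta = np.arccos(np.clip(np.where(valid, cosd, 0.0), -1.0, 1.0))
    p = np.zeros(len(u))
    if valid.any():
        p[valid] = vonmises_arc_integral(
            kappa[valid], theta_star[valid] - delta[valid],
            theta_star[valid] + delta[valid])
    return p, valid


def pair_arrays(pairs: Sequence[TripletTargetPair],
                params: Mapping[int, MigrationParams] | Mapping[int, float]) -> dict:
    """Flatten pairs into numpy arrays for bulk p-value work.

    ``params`` maps immune cell id to either a :class:`MigrationParams` or a
    bare kappa; a pair whose cell lacks fitted parameters is a
    configuration error.
    """
    m = len(pairs)
    u = np.empty((m, 2))
    s1 = np.empty((m, 2))
    center = np.empty((m, 3))
    target_xy = np.empty((m, 2))
    kappa = np.empty(m)
    cell_id = np.empty(m, dtype=int)
    target_id = np.empty(m, dtype=int)
    t = np.empty(m, dtype=int)
    distance = np.empty(m)
    for i, pr in enumerate(pairs):
        trip = pr.triplet
        try:
            par = params[trip.cell_id]
        except KeyError:
            raise ConfigurationError(
                f"no fitted migration parameters for cell id {trip.cell_id}")
        kappa[i] = par.kappa if isinstance(par, MigrationParams) else float(par)
        u[i] = trip.r_mid - trip.r_prev
        s1[i] = trip.r_next - trip.r_mid
        center[i] = trip.center
        target_xy[i] = pr.target_xy
        cell_id[i] = trip.cell_id
        target_id[i] = pr.target_id
        t[i] = trip.t
        distance[i] = pr.distance
    return dict(u=u, s1=s1, center=center, target_xy=target_xy, kappa=kappa,
                cell_id=cell_id, target_id=target_id, t=t, distance=distance)


# ---------------------------------------------------------------------------
# pooled p-value sets
# ---------------------------------------------------------------------------

@dataclass
class PValueRecord:
    cell_id: int
    target_id: int
    t: int
    p: float
    kappa: float
    distance: float


@dataclass
class PValueSet:
    """Pooled p-values over all (triplet, target) pairs of one analysis.

    Stored column-wise for efficiency; iterate for per-pair records.
    ``provenance`` carries the analysis parameters and bookkeeping counts
    (e.g. degenerate pairs dropped).
    """

    cell_id: np.ndarray
    target_id: np.ndarray
    t: np.ndarray
    p: np.ndarray
    kappa: np.ndarray
    distance: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.p)

    def __iter__(self) -> Iterator[PValueRecord]:
        for i in range(len(self.p)):
            yield PValueRecord(int(self.cell_id[i]), int(self.target_id[i]),
                               int(self.t[i]), float(self.p[i]),
                               float(self.kappa[i]), float(self.distance[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_id, "target_id": self.target_id, "t": self.t,
            "p": self.p, "kappa": self.kappa, "distance": self.distance,
        })

    def write(self, path, provenance_path=None, sep: str = ",") -> None:
        """Write the table ``cell_id,target_id,t,p,kappa,distance`` (and the
        JSON provenance block alongside, if a path is given)."""
        self.to_frame().to_csv(path, sep=sep, index=False)
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                json.dump(self.provenance, fh, indent=2, default=str)


def pooled_pvalues(pairs: Sequence[TripletTargetPair],
                   params: Mapping[int, MigrationParams] | Mapping[int, float],
                   provenance: dict | None = None) -> PValueSet:
    """One p-value per (triplet, target) pair, using each cell's own kappa.

    Degenerate pairs (target exactly at the immune position) are dropped and
    counted in the provenance, never assigned a p-value.
    """
    pa = pair_arrays(pairs, params)
    s_opt = pa["target_xy"] - pa["center"][:, :2]
    p, valid = _geometry_pvalues(pa["kappa"], pa["u"], pa["s1"], s_opt)
    prov = dict(provenance or {})
    prov["n_pairs_in"] = len(pairs)
    prov["n_degenerate_pairs_dropped"] = int((~valid).sum())
    return PValueSet(pa["cell_id"][valid], pa["target_id"][valid],
                     pa["t"][valid], p[valid], pa["kappa"][valid],
                     pa["distance"][valid], prov)
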