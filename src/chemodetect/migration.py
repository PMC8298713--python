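"""The blind-migration null model and its circular-statistics machinery.

A target-blind cell is modelled as a directionally persistent discrete-time
random walk in the plane: step widths ``w`` follow a Rayleigh distribution
with per-cell speed parameter ``sigma``,

    p(w) = (w / sigma^2) exp(-w^2 / (2 sigma^2)),

and turning angles ``theta`` (the signed angle between successive shift
vectors) follow a von-Mises distribution centred at zero with per-cell
persistence parameter ``kappa``,

    p(theta) = exp(kappa cos(theta)) / (2 pi I0(kappa)).

Both parameters are estimated per cell by maximum likelihood from the cell's
complete recorded time series.  The von-Mises arc integral implemented here
is the probability mass of a turning-angle interval under blind migration —
the quantity at the heart of the p-value construction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0e, i1e, ive

from .data_model import EPS_STEP, Trajectory
from .errors import DegenerateCellError

#: clamp for the von-Mises MLE; the estimator diverges for perfectly
#: straight tracks, and kappa = 100 is already effectively deterministic
#: motion at any realistic angular resolution
KAPPA_MAX = 100.0

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# elementary kinematics
# ---------------------------------------------------------------------------

def step_width(r_a, r_b) -> float:
    """In-plane Euclidean step width |r_b - r_a| in µm."""
    r_a = np.asarray(r_a, float)[:2]
    r_b = np.asarray(r_b, float)[:2]
    return float(np.hypot(*(r_b - r_a)))


def signed_angle(u, v) -> float:
    """Signed angle from vector ``u`` to vector ``v``, counter-clockwise
    positive, in (-pi, pi].  Uses atan2 of cross and dot products, which is
    numerically stable for near-collinear input."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return float(np.arctan2(cross, dot))


def turning_angle(r_prev, r_mid, r_next) -> float:
    """Signed turning angle between the incoming and outgoing shift vectors."""
    r_prev = np.asarray(r_prev, float)[:2]
    r_mid = np.asarray(r_mid, float)[:2]
    r_next = np.asarray(r_next, float)[:2]
    u = r_mid - r_prev
    v = r_next - r_mid
    if np.hypot(*u) <= EPS_STEP or np.hypot(*v) <= EPS_STEP:
        raise DegenerateCellError("turning angle undefined for zero-length shift")
    return signed_angle(u, v)


def wrap_angle(x):
    """Wrap angle(s) into [-pi, pi)."""
    return np.mod(np.asarray(x, float) + np.pi, TWO_PI) - np.pi


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def estimate_sigma(widths: Sequence[float]) -> float:
    """Maximum-likelihood Rayleigh speed parameter, sqrt(sum(w^2) / 2n)."""
    w = np.asarray(list(widths), float)
    if w.size == 0:
        raise ValueError("cannot estimate sigma from an empty sample")
    if np.all(w == 0):
        raise DegenerateCellError("all step widths are zero")
    return float(np.sqrt(np.sum(w * w) / (2.0 * w.size)))


def _bessel_ratio(kappa: float) -> float:
    """A(kappa) = I1(kappa) / I0(kappa), computed with scaled Bessels."""
    return i1e(kappa) / i0e(kappa)


def estimate_kappa(angles: Sequence[float], kappa_max: float = KAPPA_MAX,
                   tol: float = 1e-8) -> float:
    """Maximum-likelihood von-Mises persistence parameter.

    With the mean direction pinned at zero (the null model has no location
    parameter), the MLE solves I1(kappa)/I0(kappa) = mean(cos(theta)).
    A negative mean cosine (anti-persistent wiggling) is clamped to 0 and a
    mean cosine at or beyond A(kappa_max) is clamped to ``kappa_max``.
    """
    th = np.asarray(list(angles), float)
    if th.size == 0:
        raise ValueError("cannot estimate kappa from an empty sample")
    r = float(np.mean(np.cos(th)))
    if r <= 0.0:
        return 0.0
    if r >= _bessel_ratio(kappa_max):
        return float(kappa_max)
    return float(brentq(lambda k: _bessel_ratio(k) - r, 0.0, kappa_max,
                        xtol=tol))


@dataclass
class MigrationParams:
    """Fitted per-cell null model of blind migration."""

    cell_id: int
    sigma: float   # Rayleigh speed parameter, µm per frame step
    kappa: float   # von-Mises persistence parameter, dimensionless
    n_steps: int   # sample size used for the fit

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.kappa <= KAPPA_MAX:
            raise ValueError("kappa must lie in [0, KAPPA_MAX]")


def params_to_frame(params: Iterable[MigrationParams]) -> pd.DataFrame:
    """Export fitted parameters as a table ``id,sigma,kappa,n_steps``."""
    rows = [(p.cell_id, p.sigma, p.kappa, p.n_steps) for p in params]
    return pd.DataFrame(rows, columns=["id", "sigma", "kappa", "n_steps"])


# ---------------------------------------------------------------------------
# von-Mises arc integrals
# ---------------------------------------------------------------------------

def _n_terms(kappa_max_val: float) -> int:
    # I_j(k)/I_0(k) < exp(-j^2 / (2k)) for j >> k; this truncation keeps the
    # series remainder below ~1e-13 across kappa in [0, KAPPA_MAX]
    return int(np.ceil(kappa_max_val + 6.0 * np.sqrt(kappa_max_val + 1.0) + 25.0))


def vonmises_cdf(x, kappa):
    """CDF at ``x`` in [-pi, pi] of the zero-centred von-Mises distribution.

    Evaluated through the Fourier-Bessel series

        F(x) = 1/2 + x/(2 pi) + (1/pi) sum_j I_j(kappa)/(j I_0(kappa)) sin(j x),

    truncated once the Bessel ratio falls below machine precision.  Exact for
    ``kappa = 0`` (uniform) and vectorized over both arguments; distinct
    kappa values are grouped so the Bessel functions are evaluated once per
    group.
    """
    x = np.asarray(x, float)
    kappa = np.asarray(kappa, float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    x_b, kappa_b = np.broadcast_arrays(x, kappa)
    shape = x_b.shape
    xf = x_b.reshape(-1)
    kf = kappa_b.reshape(-1)

    uniq, inv = np.unique(kf, return_inverse=True)
    nj = _n_terms(float(uniq.max(initial=0.0)))
    j = np.arange(1, nj + 1, dtype=float)
    # scaled Bessels cancel the exp(kappa) factor: ive(j,k)/ive(0,k) = I_j/I_0
    coef = ive(j[None, :], uniq[:, None]) / ive(0, uniq)[:, None]
    coef /= j[None, :]                                  # (U, J)

    out = 0.5 + xf / TWO_PI
    chunk = 1 << 15
    for lo in range(0, xf.size, chunk):
        sl = slice(lo, lo + chunk)
        sins = np.sin(xf[sl, None] * j[None, :])        # (m, J)
        out[sl] += np.einsum("mj,mj->m", sins, coef[inv[sl]]) / np.pi
    return np.clip(out, 0.0, 1.0).reshape(shape) if shape else float(np.clip(out[0], 0.0, 1.0))


def vonmises_arc_integral(kappa, a, b):
    """Probability mass of the zero-centred von-Mises law on the arc a -> b.

    ``a`` and ``b`` are arc endpoints with ``b >= a``; the arc may wrap past
    +-pi (sub-arcs on either side of the branch cut are summed), and an arc
    of total length 2 pi returns exactly 1.  Vectorized over all arguments.
    """
    kappa = np.asarray(kappa, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    length = b - a
    if np.any(length < 0):
        raise ValueError("arc endpoints must satisfy b >= a")
    scalar = (np.ndim(kappa) == 0 and np.ndim(a) == 0 and np.ndim(b) == 0)
    kappa, a, b = np.atleast_1d(*np.broadcast_arrays(kappa, a, b))
    length = np.minimum(b - a, TWO_PI)
    a0 = wrap_angle(a)
    b0 = a0 + length
    wraps = b0 > np.pi
    hi = np.where(wraps, np.pi, b0)
    # F(pi) = 1 and F(-pi) = 0 exactly in the series, so the wrapped arc
    # needs only one extra CDF evaluation on the wrapped subset
    res = vonmises_cdf(hi, kappa) - vonmises_cdf(a0, kappa)
    if wraps.any():
        res[wraps] += vonmises_cdf(b0[wraps] - TWO_PI, kappa[wraps])
    res = np.where(length >= TWO_PI, 1.0, np.clip(res, 0.0, 1.0))
    return float(res[0]) if scalar else res


def persistence_cone_halfwidth(kappa: float, p_ord: float = 0.95) -> float:
    """Half-width of the symmetric turning-angle interval holding mass ``p_ord``.

    Solves for the threshold angle such that a target-blind cell makes an
    'ordinary' move (|theta| <= threshold) with probability ``p_ord``.  The
    cone is illustrative only — it plays no role in the p-value itself.
    """
    if not 0.0 < p_ord < 1.0:
        raise ValueError("p_ord must lie strictly between 0 and 1")
    return float(brentq(
        lambda th: vonmises_arc_integral(kappa, -th, th) - p_ord,
        0.0, np.pi, xtol=1e-12))


# ---------------------------------------------------------------------------
# momentary persistence / speed statistics
# ---------------------------------------------------------------------------

@dataclass
class MomentaryStep:
    """Instantaneous (cos(theta), v) pair of one cell at one frame."""

    cell_id: int
    t: int
    speed: float       # µm per minute: step width / frame interval
    cos_theta: float   # persistence measure in [-1, 1]


def momentary_params(traj: Trajectory, frame_interval: float,
                     eps_step: float = EPS_STEP) -> list[MomentaryStep]:
    """Per-frame momentary persistence and speed of one trajectory.

    Each interior frame with both neighbours observed and non-degenerate
    steps yields one pair (cos(theta_t), v_t), with the speed taken from the
    outgoing step.  The joint distribution of these pairs over all cells
    summarizes the spectrum of available movement steps.
    """
    index = {int(tt): k for k, tt in enumerate(traj.t)}
    out: list[MomentaryStep] = []
    for k, tt in enumerate(traj.t):
        tt = int(tt)
        kp = index.get(tt - 1)
        kn = index.get(tt + 1)
        if kp is None or kn is None:
            continue
        u = traj.xyz[k, :2] - traj.xyz[kp, :2]
        v = traj.xyz[kn, :2] - traj.xyz[k, :2]
        if np.hypot(*u) <= eps_step or np.hypot(*v) <= eps_step:
            continue
        theta = signed_angle(u, v)
        w = float(np.hypot(*v))
        out.append(MomentaryStep(traj.cell_id, tt, w / frame_interval,
                                 float(np.cos(theta))))
    return out
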