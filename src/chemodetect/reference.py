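"""Randomized reference distributions, confidence bands, and verdicts.

The observed p-value histogram ``q_obs`` by itself does not reveal whether
targets influence the immune cells: even blind walkers occasionally make
'suspiciously' target-directed turns.  The decision is therefore made
against an ensemble of *reference* datasets in which each pair's target is
re-placed at an independent uniformly random position within the
interaction radius ``r_max`` around the triplet's central immune position,
while the immune trajectories are left untouched.  Repeating the
randomization ``n_replicates`` times yields a per-bin mean and standard
deviation of the reference histogram, from which a confidence band
``mu_k -+ z * sd_k`` is formed (z = 1.645 for a one-sided 5% level under
normality).  Excess observed mass at small p-values above the band signals
attraction; a deficit below the band signals repulsion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import TripletTargetPair
from .errors import ConfigurationError
from .migration import MigrationParams
from .pvalues import PValueSet, _geometry_pvalues, pair_arrays

#: z-multiplier for a one-sided exceedance probability of 0.05 under normality
Z_05 = 1.645
#: z-multiplier for a one-sided exceedance probability of 0.01
Z_01 = 2.325


def _uniform_in_ball(rng: np.random.Generator, n: int, radius: float,
                     dim: int) -> np.ndarray:
    """Draw ``n`` points uniformly from a ``dim``-ball of given radius."""
    direc = rng.standard_normal((n, dim))
    norms = np.linalg.norm(direc, axis=1)
    norms[norms == 0] = 1.0
    r = radius * rng.random(n) ** (1.0 / dim)
    return direc * (r / norms)[:, None]


def randomize_targets(pairs: Sequence[TripletTargetPair], r_max: float,
                      rng: np.random.Generator | int | None = None,
                      use_z: bool = True) -> list[TripletTargetPair]:
    """Replace every pair's target by a uniform random position in the
    ``r_max``-ball (disk when ``use_z=False``) around its triplet's central
    immune position.  Immune triplets are untouched and the pair count is
    preserved; the draw is deterministic for a given seed/generator."""
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dim = 3 if use_z else 2
    offsets = _uniform_in_ball(rng, len(pairs), r_max, dim)
    out = []
    for pr, off in zip(pairs, offsets):
        new_xy = pr.triplet.center[:2] + off[:2]
        out.append(replace(pr, target_xy=new_xy,
                           distance=float(np.linalg.norm(off))))
    return out


# ---------------------------------------------------------------------------
# histograms and bands
# ---------------------------------------------------------------------------

def histogram(pvals, k: int) -> np.ndarray:
    """Per-bin probabilities of p-values on ``k`` uniform bins of [0, 1].

    Bins are half-open [a, b) except the last, which is closed, so p = 0.5
    with two bins falls in the upper bin.  Probabilities sum to 1.
    """
    if k < 2:
        raise ValueError("need at least 2 histogram bins")
    p = pvals.p if isinstance(pvals, PValueSet) else np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("cannot histogram an empty p-value set")
    counts, _ = np.histogram(p, bins=np.linspace(0.0, 1.0, k + 1))
    return counts / p.size


@dataclass
class BandedHistogram:
    """Binned reference statistics with confidence limits (the decision object)."""

    edges: np.ndarray          # (K+1,) uniform bin edges on [0, 1]
    mu: np.ndarray             # (K,) per-bin reference mean
    sd: np.ndarray             # (K,) per-bin reference SD over replicates
    z: float                   # band half-width multiplier
    n_replicates: int
    q_obs: np.ndarray | None = None   # observed per-bin probabilities

    @property
    def lo(self) -> np.ndarray:
        return self.mu - self.z * self.sd

    @property
    def hi(self) -> np.ndarray:
        return self.mu + self.z * self.sd

    @property
    def k(self) -> int:
        return len(self.mu)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "bin_lo": self.edges[:-1], "bin_hi": self.edges[1:],
            "q_obs": self.q_obs if self.q_obs is not None else np.nan,
            "mu_ref": self.mu, "sd_ref": self.sd,
            "lo": self.lo, "hi": self.hi,
        })
        return out

    def write(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def reference_band(pairs: Sequence[TripletTargetPair],
                   params: Mapping[int, MigrationParams] | Mapping[int, float],
                   r_max: float, k: int = 10, n_replicates: int = 100,
                   z: float = Z_05,
                   rng: np.random.Generator | int | None = None,
                   use_z: bool = True) -> BandedHistogram:
    """Confidence band of the p-value histogram under target randomization.

    Each of the ``n_replicates`` reference datasets redraws every pair's
    target uniformly within the ``r_max``-ball and recomputes the full
    p-value histogram at the same sample size as the observed set; the band
    is ``mu_k -+ z * sd_k`` over replicates (sample SD).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 reference replicates")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pa = pair_arrays(pairs, params)
    m = len(pairs)
    dim = 3 if use_z else 2
    edges = np.linspace(0.0, 1.0, k + 1)
    hists = np.empty((n_replicates, k))
    for s in range(n_replicates):
        offsets = _uniform_in_ball(rng, m, r_max, dim)
        s_opt = offsets[:, :2]
        p, valid = _geometry_pvalues(pa["kappa"], pa["u"], pa["s1"], s_opt)
        counts, _ = np.histogram(p[valid], bins=edges)
        hists[s] = counts / max(int(valid.sum()), 1)
    return BandedHistogram(edges=edges, mu=hists.mean(axis=0),
                           sd=hists.std(axis=0, ddof=1), z=z,
                           n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# verdicts
# ---------------------------------------------------------------------------

@dataclass
class Verdict:
    """Attraction/repulsion call plus every out-of-band bin."""

    classification: str                 # 'attractive' | 'repulsive' | 'none'
    excursions: list = field(default_factory=list)  # [(bin index, 'above'|'below')]

    def to_json(self) -> str:
        return json.dumps({"classification": self.classification,
                           "excursions": [list(e) for e in self.excursions]},
                          indent=2)


def classify_interaction(q_obs, band: BandedHistogram) -> Verdict:
    """Decide attraction/repulsion from the lowest-p histogram bin.

    Attraction piles extra mass onto small p-values, so the call is
    'attractive' when the lowest bin exceeds its upper limit and 'repulsive'
    when it falls below its lower limit; otherwise 'none'.  All out-of-band
    bins are reported so users can apply their own multiplicity handling —
    no correction across bins is applied here.
    """
    q_obs = np.asarray(q_obs, float)
    if len(q_obs) != band.k:
        raise ConfigurationError(
            f"observed histogram has {len(q_obs)} bins, band has {band.k}")
    lo, hi = band.lo, band.hi
    excursions = []
    for kk in range(band.k):
        if q_obs[kk] > hi[kk]:
            excursions.append((kk, "above"))
        elif q_obs[kk] < lo[kk]:
            excursions.append((kk, "below"))
    if q_obs[0] > hi[0]:
        cls = "attractive"
    elif q_obs[0] < lo[0]:
        cls = "repulsive"
    else:
        cls = "none"
    return Verdict(cls, excursions)
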