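"""Agent-based chemotaxis simulator for validating the detection pipeline.

Immune cells perform a correlated random walk in a square field: each step
draws a width from Rayleigh(sigma_i) and a turning angle from a von-Mises
law, while stationary targets emit a quasi-stationary chemoattractant field

    C(r) = sum_j 1 / (d_j + r0)

(summed over surviving targets at planar distance d_j).  Four scenarios
differ only in how the walk reacts to the field:

* ``BLS`` (blind search): no reaction; per-cell (sigma_i, kappa_i) constant.
* ``RMS`` (random mode switching): blind, but cells toggle between a
  persistent fast mode (sigma_fast, kappa_high) and a diffusive slow mode
  (sigma_slow, kappa_low) at random, with probability ``p_switch`` per step.
* ``TGS`` (temporal gradient sensing): the same two modes, but a cell stays
  persistent while the concentration at its position is increasing over
  time and tumbles (diffusive mode) when it decreases — run-and-tumble.
* ``SGS`` (spatial gradient sensing): as BLS, but the von-Mises centre is
  tilted toward the local concentration gradient: the preferred direction
  is the unit heading vector plus ``c`` times the relative gradient
  (grad C) / C — fold-change sensing — so ``c = 0`` reduces exactly to BLS
  (same random draw sequence), positive ``c`` attracts and negative ``c``
  repels.

Targets within the killing radius of any immune cell are removed and never
reappear; boundaries reflect.  ``simulate`` emits a standard observation
table (class 0 immune, class 1 targets, z = 0).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import IMMUNE, TARGET, ObservationTable

SCENARIOS = ("BLS", "RMS", "TGS", "SGS")


@dataclass
class ScenarioConfig:
    """Simulation settings; defaults give the standard validation system of
    100 immune cells hunting 50 targets for 500 one-minute steps in a
    5000 µm x 5000 µm field."""

    scenario: str = "BLS"
    field_size: float = 5000.0       # µm, square side length
    n_immune: int = 100
    n_targets: int = 50
    n_steps: int = 500
    dt: float = 1.0                  # minutes per step
    c: float = 500.0                 # chemotaxis response coefficient (SGS)
    sigma_slow: float = 1.0          # µm/step, diffusive mode
    sigma_fast: float = 5.0          # µm/step, persistent mode
    kappa_low: float = 0.0           # diffusive mode persistence
    kappa_high: float = 5.0          # persistent mode persistence
    p_switch: float = 0.05           # RMS per-step mode toggle probability
    r_kill: float = 20.0             # µm, killing radius
    r0: float = 10.0                 # µm, concentration length scale
    sigma_range: tuple = (1.0, 5.0)  # per-cell sigma_i, log-uniform (BLS/SGS)
    kappa_range: tuple = (0.0, 5.0)  # per-cell kappa_i, uniform (BLS/SGS)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose one of {SCENARIOS}")
        if min(self.n_immune, self.n_targets) < 0 or self.n_steps < 0:
            raise ValueError("counts must be non-negative")
        if self.field_size <= 0:
            raise ValueError("field_size must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class SimState:
    """Mutable state of one running simulation."""

    pos: np.ndarray          # (N, 2) immune positions
    heading: np.ndarray      # (N,) heading angles
    sigma: np.ndarray        # (N,) per-cell speed parameters
    kappa: np.ndarray        # (N,) per-cell persistence parameters
    persistent: np.ndarray   # (N,) bool mode flags (RMS/TGS)
    prev_conc: np.ndarray    # (N,) concentration at the previous frame (TGS)
    targets: np.ndarray      # (M0, 2) target positions (fixed)
    alive: np.ndarray        # (M0,) bool survival flags
    t: int = 0


def concentration_and_gradient(targets: np.ndarray, pos: np.ndarray,
                               r0: float = 10.0):
    """Chemoattractant concentration and its gradient at ``pos``.

    ``targets`` is (M, 2); ``pos`` may be a single point (2,) or a batch
    (N, 2).  With no surviving targets both outputs are zero.  The analytic
    gradient of 1/(d + r0) points toward each target with magnitude
    1/(d + r0)^2.
    """
    pos = np.asarray(pos, float)
    single = pos.ndim == 1
    pts = pos[None, :] if single else pos
    if len(targets) == 0:
        c = np.zeros(len(pts))
        g = np.zeros((len(pts), 2))
    else:
        diff = targets[None, :, :] - pts[:, None, :]        # (N, M, 2)
        d = np.linalg.norm(diff, axis=2)                    # (N, M)
        inv = 1.0 / (d + r0)
        c = inv.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = diff / d[:, :, None]
        unit = np.nan_to_num(unit)                          # cell on top of target
        g = (inv[:, :, None] ** 2 * unit).sum(axis=1)
    if single:
        return float(c[0]), g[0]
    return c, g


def _init_state(config: ScenarioConfig, rng: np.random.Generator) -> SimState:
    L = config.field_size
    pos = rng.random((config.n_immune, 2)) * L
    heading = rng.uniform(-np.pi, np.pi, config.n_immune)
    lo, hi = config.sigma_range
    sigma = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_immune))
    kappa = rng.uniform(*config.kappa_range, config.n_immune)
    targets = rng.random((config.n_targets, 2)) * L
    if config.scenario == "RMS":
        persistent = rng.random(config.n_immune) < 0.5
    else:
        persistent = np.ones(config.n_immune, dtype=bool)
    alive = np.ones(config.n_targets, dtype=bool)
    conc, _ = concentration_and_gradient(targets, pos, config.r0) \
        if config.n_immune else (np.zeros(0), None)
    return SimState(pos=pos, heading=heading, sigma=sigma, kappa=kappa,
                    persistent=persistent, prev_conc=np.asarray(conc),
                    targets=targets, alive=alive, t=0)


def step(state: SimState, config: ScenarioConfig,
         rng: np.random.Generator) -> SimState:
    """Advance the simulation by one frame (in place) and return the state."""
    n = len(state.pos)
    live_targets = state.targets[state.alive]
    scenario = config.scenario

    center = np.zeros(n)
    if scenario in ("BLS", "SGS"):
        kappa_step = state.kappa
        sigma_step = state.sigma
        if scenario == "SGS" and config.c != 0.0:
            conc, grad = concentration_and_gradient(live_targets, state.pos,
                                                    config.r0)
            # fold-change (logarithmic) sensing: the chemotactic torque
            # follows the relative gradient grad C / C, giving the response
            # the same spatial range as the concentration field itself
            rel = grad / np.maximum(conc, 1e-300)[:, None]
            pref = np.stack([np.cos(state.heading), np.sin(state.heading)],
                            axis=1) + config.c * rel
            norm = np.hypot(pref[:, 0], pref[:, 1])
            ang = np.arctan2(pref[:, 1], pref[:, 0])
            # preferred turn relative to the current heading; degenerate
            # preference vector falls back to straight ahead
            rel = np.mod(ang - state.heading + np.pi, 2 * np.pi) - np.pi
            center = np.where(norm > 1e-12, rel, 0.0)
    else:
        if scenario == "RMS":
            toggle = rng.random(n) < config.p_switch
            state.persistent = np.where(toggle, ~state.persistent,
                                        state.persistent)
        else:  # TGS: run while the concentration grows, tumble when it drops
            conc, _ = concentration_and_gradient(live_targets, state.pos,
                                                 config.r0)
            state.persistent = conc >= state.prev_conc
            state.prev_conc = conc
        kappa_step = np.where(state.persistent, config.kappa_high,
                              config.kappa_low)
        sigma_step = np.where(state.persistent, config.sigma_fast,
                              config.sigma_slow)

    theta = rng.vonmises(center, np.maximum(kappa_step, 1e-12))
    w = rng.rayleigh(sigma_step)
    new_heading = state.heading + theta
    old_pos = state.pos.copy()
    new_pos = old_pos + w[:, None] * np.stack(
        [np.cos(new_heading), np.sin(new_heading)], axis=1)

    # reflecting boundaries (step widths are tiny relative to the field,
    # so a single reflection per axis suffices)
    L = config.field_size
    new_pos = np.where(new_pos < 0, -new_pos, new_pos)
    new_pos = np.where(new_pos > L, 2 * L - new_pos, new_pos)

    disp = new_pos - old_pos
    moved = np.hypot(disp[:, 0], disp[:, 1]) > 0
    state.heading = np.where(moved, np.arctan2(disp[:, 1], disp[:, 0]),
                             new_heading)
    state.pos = new_pos

    # killing: any target within r_kill of any immune cell is removed
    if state.alive.any() and n > 0:
        live_idx = np.flatnonzero(state.alive)
        d = np.linalg.norm(
            state.targets[live_idx][:, None, :] - state.pos[None, :, :],
            axis=2)
        killed = live_idx[d.min(axis=1) < config.r_kill]
        state.alive[killed] = False
    state.t += 1
    return state


def simulate(config: ScenarioConfig) -> ObservationTable:
    """Run a scenario and return the observation table (deterministic per seed).

    Immune cells appear in every frame with class 0; targets appear with
    class 1 only while alive (killed targets vanish from their death frame
    onward).  Immune ids run from 0, target ids follow.
    """
    rng = np.random.default_rng(config.seed)
    state = _init_state(config, rng)
    rows = []

    def record(s: SimState) -> None:
        for i in range(len(s.pos)):
            rows.append((s.t, s.pos[i, 0], s.pos[i, 1], 0.0, i, IMMUNE))
        for j in np.flatnonzero(s.alive):
            rows.append((s.t, s.targets[j, 0], s.targets[j, 1], 0.0,
                         config.n_immune + j, TARGET))

    record(state)
    for _ in range(config.n_steps):
        step(state, config, rng)
        record(state)
    df = pd.DataFrame(rows, columns=["t", "x", "y", "z", "id", "class"])
    return ObservationTable(df, frame_interval=config.dt)
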