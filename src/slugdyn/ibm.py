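"""Individual-based simulation of two-layer slug movement.

The population lives on two coupled planar layers: overground (z = 0),
where movement is a density-dependent correlated random walk, and
underground (a single depth z*), where movement is isotropic Brownian
motion with a smaller step scale.  Each tick consists of

1. marking overground slugs that will go down (probability ``p_d`` each),
2. marking underground slugs that will come up (probability ``p_u`` each),
3. swapping the marked slugs between layers (planar positions unchanged),
4. a horizontal step for every slug in the *new* overground population,
   with regime (sparse/dense) chosen from the local density within the
   perception radius,
5. a horizontal step for every slug in the new underground population,
6. advancing time.

The total population is conserved: no births, deaths or emigration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

from ._neighbors import count_neighbors
from .kernels import (
    DENSE,
    SPARSE,
    UNDERGROUND,
    MovementParams,
    decide_move,
    sample_step_length,
    sample_turning_angle,
    wrap_angle,
)

__all__ = [
    "SlugPopulationState",
    "SimulationConfig",
    "SimulationResult",
    "init_uniform",
    "local_density",
    "classify_regime",
    "vertical_transition",
    "horizontal_step_overground",
    "horizontal_step_underground",
    "simulate",
    "write_snapshot_csv",
    "write_timeseries_csv",
]

BOUNDARIES = ("reflect", "periodic")


@dataclass
class SlugPopulationState:
    """Positions, layer membership and headings of all slugs at one time.

    ``over`` is a boolean mask: True for slugs currently on the surface.
    Coordinates are metres within the square domain [0, L] x [0, L].
    """

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    over: np.ndarray
    t: int = 0
    L: float = 10.0

    @property
    def size(self) -> int:
        return self.x.size

    @property
    def n_over(self) -> int:
        return int(np.count_nonzero(self.over))

    @property
    def n_under(self) -> int:
        return self.size - self.n_over

    def copy(self) -> "SlugPopulationState":
        return SlugPopulationState(
            self.x.copy(), self.y.copy(), self.heading.copy(),
            self.over.copy(), self.t, self.L,
        )

    def validate(self) -> None:
        n = self.x.size
        if not (self.y.size == self.heading.size == self.over.size == n):
            raise ValueError("state arrays have mismatched lengths")
        if n and (self.x.min() < 0 or self.x.max() > self.L
                  or self.y.min() < 0 or self.y.max() > self.L):
            raise ValueError("slug coordinates outside the domain [0, L]^2")


@dataclass
class SimulationConfig:
    """Full configuration of one simulation run.

    ``p_u``/``p_d`` are the per-step probabilities of an underground slug
    surfacing and of an overground slug burrowing; ``alpha``/``beta`` the
    initial overground/underground fractions (alpha + beta = 1); ``Pi`` the
    constant total population; ``T`` the number of ticks.
    """

    params: MovementParams = field(default_factory=MovementParams)
    p_u: float = 0.5
    p_d: float = 0.5
    Pi: int = 10_000
    alpha: float = 0.5
    beta: float = 0.5
    T: int = 100
    L: float = 10.0
    seed: int = 0
    boundary: str = "reflect"
    record_every: int = 0  # 0: keep only the final snapshot

    def __post_init__(self) -> None:
        for name in ("p_u", "p_d", "alpha", "beta"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")
        if self.Pi < 0:
            raise ValueError(f"population size must be >= 0, got {self.Pi}")
        if self.T < 0:
            raise ValueError(f"run length must be >= 0, got {self.T}")
        if self.L <= 0:
            raise ValueError(f"domain side must be > 0, got {self.L}")
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}")
        if self.record_every < 0:
            raise ValueError("record_every must be >= 0")


@dataclass
class SimulationResult:
    """Time series of layer sizes, recorded snapshots and the final state."""

    N: np.ndarray  # overground count at t = 0..T
    P: np.ndarray  # underground count at t = 0..T
    snapshots: list  # list of (t, SlugPopulationState)
    final_state: SlugPopulationState
    config: SimulationConfig


def init_uniform(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Statistically uniform initial condition.

    Exactly round(alpha * Pi) slugs start overground, the rest underground;
    coordinates are i.i.d. U(0, L) and headings i.i.d. uniform on the
    circle (the model defines turning relative to a persistent heading but
    not the initial heading; an isotropic draw keeps the start uniform).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(config.Pi)
    n_over = int(round(config.alpha * n))
    over = np.zeros(n, dtype=bool)
    over[:n_over] = True
    state = SlugPopulationState(
        x=rng.uniform(0.0, config.L, n),
        y=rng.uniform(0.0, config.L, n),
        heading=wrap_angle(rng.uniform(-np.pi, np.pi, n)),
        over=over,
        t=0,
        L=config.L,
    )
    state.validate()
    return state


def local_density(state: SlugPopulationState, R: float) -> np.ndarray:
    """Local overground density (slugs per m^2) seen by each surface slug.

    For each overground slug, the number of *other* overground slugs within
    Euclidean distance ``R``, divided by the full circle area pi R^2 (no
    truncation correction near the domain boundary; see docs).  Underground
    slugs are invisible.  Returns one density per overground slug, aligned
    with ``state.x[state.over]``.
    """
    if R <= 0:
        raise ValueError(f"perception radius must be > 0, got {R}")
    counts = count_neighbors(state.x[state.over], state.y[state.over],
                             R, max(state.L, R))
    return counts / (np.pi * R * R)


def classify_regime(D_l, d: float):
    """Sparse iff D_l < d, dense iff D_l >= d (threshold itself is dense)."""
    dense = np.asarray(D_l) >= d
    out = np.where(dense, DENSE, SPARSE)
    return out if out.ndim else out[()]


def vertical_transition(
    state: SlugPopulationState, p_u: float, p_d: float, rng: np.random.Generator
) -> SlugPopulationState:
    """Exchange slugs between layers (in place); positions are unchanged.

    Both layers are marked against the pre-transition membership, then the
    marked slugs are swapped simultaneously, so a slug cannot move down and
    immediately back up within one tick.
    """
    for name, p in (("p_u", p_u), ("p_d", p_d)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    over = state.over
    idx_over = np.flatnonzero(over)
    idx_under = np.flatnonzero(~over)
    going_down = idx_over[decide_move(p_d, rng, idx_over.size)]
    going_up = idx_under[decide_move(p_u, rng, idx_under.size)]
    over[going_down] = False
    over[going_up] = True
    return state


def _apply_boundary(pos: np.ndarray, L: float, boundary: str):
    """Map raw coordinates back into [0, L]; returns (pos, mirrored mask).

    Reflection folds the overshoot back specularly (triangle wave of period
    2L); ``mirrored`` flags coordinates whose axis direction was reversed,
    so the caller can mirror the heading.  Periodic wrapping never mirrors.
    """
    if boundary == "reflect":
        m = np.mod(pos, 2.0 * L)
        mirrored = m > L
        return np.where(mirrored, 2.0 * L - m, m), mirrored
    if boundary == "periodic":
        return np.mod(pos, L), np.zeros(pos.shape, dtype=bool)
    raise ValueError(f"boundary must be one of {BOUNDARIES}")


def _mirror_heading(heading: np.ndarray, flip_x: np.ndarray, flip_y: np.ndarray):
    # reflection off a vertical wall negates the x-component of the
    # direction, off a horizontal wall the y-component
    sx = np.where(flip_x, -1.0, 1.0)
    sy = np.where(flip_y, -1.0, 1.0)
    return np.arctan2(sy * np.sin(heading), sx * np.cos(heading))


def _step_subset(state, idx, theta, dr, boundary):
    """Displace the slugs in ``idx`` and re-impose the domain boundary."""
    heading = wrap_angle(state.heading[idx] + theta)
    x_raw = state.x[idx] + dr * np.cos(heading)
    y_raw = state.y[idx] + dr * np.sin(heading)
    x_new, flip_x = _apply_boundary(x_raw, state.L, boundary)
    y_new, flip_y = _apply_boundary(y_raw, state.L, boundary)
    if boundary == "reflect":
        heading = wrap_angle(_mirror_heading(heading, flip_x, flip_y))
    state.x[idx] = x_new
    state.y[idx] = y_new
    state.heading[idx] = heading


def horizontal_step_overground(
    state: SlugPopulationState,
    params: MovementParams,
    rng: np.random.Generator,
    boundary: str = "reflect",
) -> SlugPopulationState:
    """Density-dependent correlated-random-walk step for surface slugs.

    Each overground slug evaluates the local density within its perception
    radius against the threshold ``d``; the regime sets the movement
    frequency (p_ms or p_md), the turning-angle law (Von Mises or uniform)
    and the step-length scale (sigma_s or sigma_d).  Resting slugs keep
    position and heading.
    """
    idx_over = np.flatnonzero(state.over)
    if idx_over.size == 0:
        return state
    D_l = local_density(state, params.R)
    dense = classify_regime(D_l, params.d) == DENSE
    p_m = np.where(dense, params.p_md, params.p_ms)
    moving = rng.random(idx_over.size) < p_m

    theta = np.zeros(idx_over.size)
    dr = np.zeros(idx_over.size)
    sparse_movers = moving & ~dense
    dense_movers = moving & dense
    ns, nd = int(sparse_movers.sum()), int(dense_movers.sum())
    if ns:
        theta[sparse_movers] = sample_turning_angle(SPARSE, params, rng, ns)
        dr[sparse_movers] = sample_step_length(params.sigma_s, rng, ns)
    if nd:
        theta[dense_movers] = sample_turning_angle(DENSE, params, rng, nd)
        dr[dense_movers] = sample_step_length(params.sigma_d, rng, nd)

    movers = idx_over[moving]
    _step_subset(state, movers, theta[moving], dr[moving], boundary)
    return state


def horizontal_step_underground(
    state: SlugPopulationState,
    params: MovementParams,
    rng: np.random.Generator,
    boundary: str = "reflect",
) -> SlugPopulationState:
    """Brownian step for buried slugs: uniform angle, half-normal length.

    No density dependence and no rest state; every underground slug moves
    every tick with the (hypothetical, slower) scale ``sigma_under``.
    """
    idx_under = np.flatnonzero(~state.over)
    if idx_under.size == 0:
        return state
    theta = sample_turning_angle(UNDERGROUND, params, rng, idx_under.size)
    dr = sample_step_length(params.sigma_under, rng, idx_under.size)
    _step_subset(state, idx_under, theta, dr, boundary)
    return state


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full two-layer IBM for ``config.T`` ticks.

    Records the layer sizes N_t, P_t at every tick (including t = 0) and
    state snapshots at the configured cadence plus the final state.
    Identical configurations produce identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    state = init_uniform(config, rng)
    Pi = state.size
    N = np.empty(config.T + 1, dtype=np.int64)
    P = np.empty(config.T + 1, dtype=np.int64)
    N[0], P[0] = state.n_over, state.n_under
    snapshots = []
    if config.record_every:
        snapshots.append((0, state.copy()))
    for t in range(1, config.T + 1):
        vertical_transition(state, config.p_u, config.p_d, rng)
        horizontal_step_overground(state, config.params, rng, config.boundary)
        horizontal_step_underground(state, config.params, rng, config.boundary)
        state.t = t
        N[t], P[t] = state.n_over, state.n_under
        if N[t] + P[t] != Pi:  # conservation law; cannot fail by construction
            raise AssertionError("population conservation violated")
        if config.record_every and t % config.record_every == 0:
            snapshots.append((t, state.copy()))
    if config.record_every and (not snapshots or snapshots[-1][0] != config.T):
        snapshots.append((config.T, state.copy()))
    state.validate()
    return SimulationResult(N=N, P=P, snapshots=snapshots,
                            final_state=state, config=config)


def write_snapshot_csv(state: SlugPopulationState, path) -> None:
    """Write one snapshot as CSV rows (t, slug_id, x, y, layer)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "slug_id", "x", "y", "layer"])
        for i in range(state.size):
            w.writerow([state.t, i, repr(float(state.x[i])),
                        repr(float(state.y[i])),
                        "over" if state.over[i] else "under"])


def write_timeseries_csv(result: SimulationResult, path) -> None:
    """Write the layer-size time series as CSV rows (t, N_t, P_t)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "N_t", "P_t"])
        for t in range(result.N.size):
            w.writerow([t, int(result.N[t]), int(result.P[t])])
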