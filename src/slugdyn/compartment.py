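"""Analytic two-compartment model of vertical slug movement.

For a large population the random exchange between the surface layer (size
N_t) and the buried layer (size P_t) is replaced by its expectation, giving
the linear recurrence

    N_{t+1} = (1 - p_d) N_t + p_u P_t,
    P_{t+1} = (1 - p_u) P_t + p_d N_t,

with N_t + P_t = Pi conserved.  The imbalance variable
W_t = p_d N_t - p_u P_t satisfies W_{t+1} = C W_t with C = 1 - p_d - p_u,
so W_t decays geometrically to the single (always stable) steady state
W* = 0, monotonically for 0 < C < 1 and with alternating sign for
-1 < C < 0.  All quantities here are continuous expectations; rounding to
whole slugs belongs to the simulation and reporting layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CompartmentState",
    "CompartmentParams",
    "iterate",
    "closed_form",
    "steady_state",
    "transition_time",
    "equilibrium_flux",
    "population_ratio",
]


@dataclass(frozen=True)
class CompartmentState:
    """Aggregate layer populations (N_t overground, P_t underground)."""

    N: float
    P: float
    t: int = 0


@dataclass(frozen=True)
class CompartmentParams:
    """Vertical-transition probabilities and initial layer split.

    ``alpha``/``beta`` are the initial overground/underground fractions of
    the total population ``Pi``; derived quantities: the contraction factor
    ``C = 1 - p_d - p_u`` and the initial imbalance
    ``W0 = (alpha p_d - beta p_u) Pi``.
    """

    p_u: float
    p_d: float
    Pi: float = 10_000.0
    alpha: float = 1.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_u", "p_d", "alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")
        if self.Pi < 0:
            raise ValueError("total population must be >= 0")

    @property
    def C(self) -> float:
        return 1.0 - self.p_d - self.p_u

    @property
    def W0(self) -> float:
        return (self.alpha * self.p_d - self.beta * self.p_u) * self.Pi


def iterate(state: CompartmentState, p_u: float, p_d: float) -> CompartmentState:
    """One exact step of the linear recurrence; the total is conserved."""
    for name, p in (("p_u", p_u), ("p_d", p_d)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    N_new = (1.0 - p_d) * state.N + p_u * state.P
    return CompartmentState(N=N_new, P=(state.N + state.P) - N_new, t=state.t + 1)


def closed_form(t, params: CompartmentParams):
    """Closed-form (N_t, P_t) from the geometric decay of W_t.

    N_t = [p_u + (alpha p_d - beta p_u) C^t] / (p_u + p_d) * Pi and
    P_t = Pi - N_t; equals the t-fold iteration of the recurrence from
    (alpha Pi, beta Pi).  Vectorised over ``t``.
    """
    s = params.p_u + params.p_d
    if s == 0:
        raise ZeroDivisionError("p_u + p_d must be > 0")
    t = np.asarray(t)
    decay = (params.alpha * params.p_d - params.beta * params.p_u) * params.C ** t
    N = (params.p_u + decay) / s * params.Pi
    return N, params.Pi - N


def steady_state(p_u: float, p_d: float, Pi: float):
    """Equilibrium layer split N* = Pi p_u/(p_u+p_d), P* = Pi p_d/(p_u+p_d)."""
    s = p_u + p_d
    if s == 0:
        raise ZeroDivisionError("p_u + p_d must be > 0")
    return Pi * p_u / s, Pi * p_d / s


def transition_time(params: CompartmentParams, eps: float = 1e-4) -> int:
    """Steps needed for the layer imbalance |W_t| to decay below ``eps``.

    Solves |W0| |C|^t = eps for real t and returns the largest integer
    strictly below it, i.e. the last step at which |W_t| still exceeds eps
    (for a non-integer solution this is simply the floor).  The degenerate
    case C = 0 (p_u + p_d = 1) reaches the steady state in a single step;
    W0 = 0 means the system starts at the steady state.
    """
    if eps <= 0:
        raise ValueError(f"tolerance must be > 0, got {eps}")
    W0 = abs(params.W0)
    if W0 == 0.0:
        return 0
    # p_u + p_d = 1 given as decimals can leave ~1e-17 residue in C
    if abs(params.C) < 1e-9:
        return 1
    s = math.log(eps / W0) / math.log(abs(params.C))
    return max(math.ceil(s) - 1, 0)


def equilibrium_flux(p_u: float, p_d: float, Pi: float):
    """Slugs exchanged per step at equilibrium.

    Returns (N_f, f): the expected number N_f = Pi p_u p_d / (p_u + p_d)
    moving each way per step once the layers are balanced, and the scaled
    fraction f = N_f / Pi.
    """
    s = p_u + p_d
    if s == 0:
        raise ZeroDivisionError("p_u + p_d must be > 0")
    f = p_u * p_d / s
    return Pi * f, f


def population_ratio(p_u: float, p_d: float) -> float:
    """Equilibrium ratio r = N*/P* = p_u/p_d of surface to buried slugs."""
    if p_d == 0:
        raise ZeroDivisionError("p_d must be > 0")
    return p_u / p_d
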