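"""Pesticide application as a perturbation of the layer equilibrium.

A spray leaves fractions omega_o of the surface population and omega_u of
the buried population alive (typically omega_o < omega_u: pesticide mostly
kills overground).  The culled state (N~, P~) is not an equilibrium; under
unchanged transition probabilities the population relaxes within the usual
transition time to the steady state of the reduced total Pi_1.  Comparing
the immediate surface kill with the re-equilibrated surface count separates
the actual efficiency e_a from the apparent efficiency e_f a practitioner
would infer from a later count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .compartment import steady_state
from .ibm import SlugPopulationState

__all__ = [
    "PesticideScenario",
    "apply_cull",
    "post_cull_steady_state",
    "efficiency_actual",
    "efficiency_apparent",
    "apply_cull_ibm",
]


def _check_fractions(omega_o: float, omega_u: float) -> None:
    for name, w in (("omega_o", omega_o), ("omega_u", omega_u)):
        if not 0.0 < w <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {w}")
    if omega_o >= omega_u:
        warnings.warn(
            "expected omega_o < omega_u (pesticide mostly kills overground); "
            f"got omega_o={omega_o}, omega_u={omega_u}",
            stacklevel=3,
        )


def apply_cull(N_star: float, P_star: float, omega_o: float, omega_u: float):
    """Cull the equilibrium populations; returns (N~, P~, Pi_1).

    N~ = omega_o N*, P~ = omega_u P*, Pi_1 = N~ + P~ < Pi whenever any
    culling occurs.
    """
    _check_fractions(omega_o, omega_u)
    if N_star < 0 or P_star < 0:
        raise ValueError("populations must be >= 0")
    N_tilde = omega_o * N_star
    P_tilde = omega_u * P_star
    return N_tilde, P_tilde, N_tilde + P_tilde


def post_cull_steady_state(p_u: float, p_d: float,
                           omega_o: float, omega_u: float, Pi: float):
    """New equilibrium (N1*, P1*) after culling the old equilibrium.

    Equals the ordinary steady state evaluated at the reduced total Pi_1 =
    omega_o N* + omega_u P*.
    """
    N_star, P_star = steady_state(p_u, p_d, Pi)
    _, _, Pi_1 = apply_cull(N_star, P_star, omega_o, omega_u)
    return steady_state(p_u, p_d, Pi_1)


def efficiency_actual(N_star: float, N_tilde: float) -> float:
    """Actual efficiency e_a = 100 (N* - N~)/N*, in percent."""
    if N_star <= 0:
        raise ValueError("N* must be > 0")
    return 100.0 * (N_star - N_tilde) / N_star


def efficiency_apparent(N_star: float, N1_star: float) -> float:
    """Apparent efficiency e_f = 100 (N* - N1*)/N*, in percent.

    What a monitoring protocol sees once the population has re-equilibrated
    and the surface has been partially refilled from underground.
    """
    if N_star <= 0:
        raise ValueError("N* must be > 0")
    return 100.0 * (N_star - N1_star) / N_star


@dataclass(frozen=True)
class PesticideScenario:
    """One culling scenario and all its derived equilibrium quantities."""

    p_u: float
    p_d: float
    omega_o: float
    omega_u: float
    Pi: float
    N_star: float
    P_star: float
    N_tilde: float
    P_tilde: float
    Pi_1: float
    N1_star: float
    P1_star: float
    e_a: float
    e_f: float

    @classmethod
    def from_params(cls, p_u, p_d, omega_o, omega_u, Pi):
        N_star, P_star = steady_state(p_u, p_d, Pi)
        N_tilde, P_tilde, Pi_1 = apply_cull(N_star, P_star, omega_o, omega_u)
        N1_star, P1_star = steady_state(p_u, p_d, Pi_1)
        return cls(
            p_u=p_u, p_d=p_d, omega_o=omega_o, omega_u=omega_u, Pi=Pi,
            N_star=N_star, P_star=P_star,
            N_tilde=N_tilde, P_tilde=P_tilde, Pi_1=Pi_1,
            N1_star=N1_star, P1_star=P1_star,
            e_a=efficiency_actual(N_star, N_tilde),
            e_f=efficiency_apparent(N_star, N1_star),
        )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "p_u", "p_d", "omega_o", "omega_u", "Pi",
            "N_tilde", "P_tilde", "Pi_1", "N1_star", "P1_star", "e_a", "e_f",
        )}


def apply_cull_ibm(
    state: SlugPopulationState,
    omega_o: float,
    omega_u: float,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> SlugPopulationState:
    """Individual-level cull: independent Bernoulli survival per slug.

    Overground slugs survive with probability omega_o, underground slugs
    with omega_u; survivors keep position, layer and heading.  An optional
    boolean ``mask`` restricts the treated area (slugs outside it always
    survive), e.g. for patch-targeted application; the aggregate theory
    above assumes a spatially uniform cull.
    """
    _check_fractions(omega_o, omega_u)
    p_survive = np.where(state.over, omega_o, omega_u)
    survives = rng.random(state.size) < p_survive
    if mask is not None:
        survives = survives | ~np.asarray(mask, dtype=bool)
    return SlugPopulationState(
        x=state.x[survives], y=state.y[survives],
        heading=state.heading[survives], over=state.over[survives],
        t=state.t, L=state.L,
    )
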