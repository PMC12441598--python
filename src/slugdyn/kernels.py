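"""Per-step movement primitives for a single slug.

A slug's step is built from three stochastic ingredients: a move/rest
decision (Bernoulli with a regime-dependent movement frequency), a turning
angle (Von Mises for sparse overground movement, uniform on the circle for
dense overground movement and for underground Brownian motion), and a step
length (half-normal with a regime-dependent scale).  The displacement is
obtained by rotating the persistent heading by the turning angle and
advancing by the step length.

All samplers accept a :class:`numpy.random.Generator` and an optional
``size`` so they can be used scalar-wise in examples and vectorised inside
the simulation loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPARSE",
    "DENSE",
    "UNDERGROUND",
    "MovementParams",
    "wrap_angle",
    "decide_move",
    "sample_turning_angle",
    "sample_step_length",
    "displacement",
]

#: Movement regime tags.
SPARSE = "sparse"
DENSE = "dense"
UNDERGROUND = "underground"

_REGIMES = (SPARSE, DENSE, UNDERGROUND)


@dataclass(frozen=True)
class MovementParams:
    """Constants of the per-step movement model.

    Defaults are the field-parametrised values for the grey field slug
    (*Deroceras reticulatum*): movement frequencies ``p_ms`` (sparse) and
    ``p_md`` (dense), Von Mises turning-angle parameters ``kappa`` and
    ``mu`` for sparse movement, half-normal step-length scales ``sigma_s``
    (sparse), ``sigma_d`` (dense) and ``sigma_under`` (underground, a
    hypothetical slower scale), perception radius ``R`` within which a slug
    senses conspecific density, and density threshold ``d`` separating the
    sparse from the dense regime.  One time step corresponds to
    ``dt_minutes`` of real time.
    """

    p_ms: float = 0.5
    p_md: float = 0.25
    kappa: float = 0.8
    mu: float = 0.0
    sigma_s: float = 0.105  # metres per 30-min step
    sigma_d: float = 0.113
    sigma_under: float = 0.05
    R: float = 1.0  # metres
    d: float = 50.0  # slugs per square metre
    dt_minutes: float = 30.0

    def __post_init__(self) -> None:
        for name in ("p_ms", "p_md"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        for name in ("sigma_s", "sigma_d", "sigma_under", "R", "d", "dt_minutes"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")


def wrap_angle(theta):
    """Wrap an angle (radians) into the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(theta), 2.0 * np.pi)


def decide_move(p_m: float, rng: np.random.Generator, size=None):
    """Bernoulli move/rest decision: draw u ~ U(0,1), move iff u < p_m."""
    if not 0.0 <= p_m <= 1.0:
        raise ValueError(f"movement probability must lie in [0, 1], got {p_m}")
    u = rng.random(size)
    return u < p_m


def sample_turning_angle(
    regime: str, params: MovementParams, rng: np.random.Generator, size=None
):
    """Sample a turning angle in (-pi, pi] for the given movement regime.

    Sparse overground movement draws from a Von Mises distribution with
    mean ``mu`` and concentration ``kappa``; dense overground movement and
    underground Brownian motion draw from the uniform distribution on the
    circle, the kappa -> 0 limit of the Von Mises.
    """
    if regime == SPARSE:
        return wrap_angle(rng.vonmises(params.mu, params.kappa, size))
    if regime in (DENSE, UNDERGROUND):
        # exact uniform limit rather than Von Mises with tiny kappa
        return wrap_angle(rng.uniform(-np.pi, np.pi, size))
    raise ValueError(f"unknown movement regime {regime!r}; expected one of {_REGIMES}")


def sample_step_length(sigma: float, rng: np.random.Generator, size=None):
    """Sample a half-normal step length (metres) with scale ``sigma``."""
    if sigma <= 0:
        raise ValueError(f"step-length scale must be > 0, got {sigma}")
    return np.abs(rng.normal(0.0, sigma, size))


def displacement(heading_prev, theta, dr):
    """Advance a heading by a turning angle and step forward.

    Returns ``(dx, dy, heading_new)`` with
    ``heading_new = wrap(heading_prev + theta)`` and the Cartesian step
    ``(dr cos heading_new, dr sin heading_new)``, so that the displacement
    magnitude equals ``dr`` exactly.
    """
    dr = np.asarray(dr)
    if np.any(dr < 0):
        raise ValueError("step length must be non-negative")
    heading_new = wrap_angle(np.asarray(heading_prev) + np.asarray(theta))
    return dr * np.cos(heading_new), dr * np.sin(heading_new), heading_new
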