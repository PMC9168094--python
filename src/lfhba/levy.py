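"""Levy-flight update operator: Mantegna heavy-tailed steps plus spiral terms.

A Levy flight is a random walk whose step lengths follow a heavy-tailed
power-law distribution, producing occasional long jumps that help a
population search escape local optima.  Steps are sampled with the Mantegna
algorithm; the update also carries a slowly tightening spiral (the
"contour flight with glide" geometry borrowed from the Aquila optimizer
family) and a pull toward a randomly chosen population member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

__all__ = ["LevyParams", "mantegna_sigma", "levy_step", "spiral_coords", "levy_update"]

#: Floor on |r| in the Mantegna denominator.
EPS_DENOM = 1e-12


@dataclass(frozen=True)
class LevyParams:
    """Parameters of the Levy-flight operator.

    scale
        Overall step scale ``s`` (default 0.01).
    tail_exponent
        Stability index ``beta`` of the heavy tail, in (0, 2] (default 1.5).
        Not the honey badger "ability" parameter, which lives in HbaConfig.
    spiral_u, spiral_w
        Small increments of the spiral radius and angle per dimension
        (defaults 0.00565 and 0.005).
    theta1
        Spiral phase offset, ``3*pi/2``.
    cycle_count
        Base spiral radius ``r1``, a fixed integer in [1, 20] (default 10).
    mantegna_exponent
        If True (default), sigma is the Mantegna bracket raised to
        ``1/beta``; if False, the bracket alone is used.
    """

    scale: float = 0.01
    tail_exponent: float = 1.5
    spiral_u: float = 0.00565
    spiral_w: float = 0.005
    theta1: float = 3.0 * np.pi / 2.0
    cycle_count: int = 10
    mantegna_exponent: bool = True

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if not 0 < self.tail_exponent <= 2:
            raise ValueError("tail_exponent must be in (0, 2]")
        if not 1 <= self.cycle_count <= 20:
            raise ValueError("cycle_count must be in [1, 20]")


def mantegna_sigma(beta: float, with_exponent: bool = True) -> float:
    """Mantegna scale sigma for tail exponent ``beta``.

    sigma = [Gamma(1+beta) * sin(pi*beta/2)
             / (Gamma((1+beta)/2) * beta * 2^((beta-1)/2))] ** (1/beta)

    With ``with_exponent=False`` the bracket is returned without the
    ``1/beta`` power (a printed variant occasionally seen in the
    literature); the exponentiated form is what makes sigma a valid normal
    scale in the Mantegna scheme.
    """
    if not 0 < beta <= 2:
        raise ValueError(f"beta must be in (0, 2], got {beta}")
    bracket = (
        _gamma(1 + beta)
        * np.sin(np.pi * beta / 2)
        / (_gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    )
    return float(bracket ** (1.0 / beta)) if with_exponent else float(bracket)


def levy_step(
    dim: int,
    params: LevyParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one heavy-tailed step vector of length ``dim``.

    Per coordinate: ``s * u * sigma / |r|^(1/beta)`` with
    ``u ~ N(0, sigma^2)`` and ``r ~ N(0, 1)`` drawn fresh; ``|r|`` is
    floored to avoid the singularity at zero.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    beta = params.tail_exponent
    sigma = mantegna_sigma(beta, params.mantegna_exponent)
    u = rng.normal(0.0, sigma, size=dim)
    r = rng.normal(0.0, 1.0, size=dim)
    denom = np.maximum(np.abs(r), EPS_DENOM) ** (1.0 / beta)
    return params.scale * u * sigma / denom


def spiral_coords(dim: int, params: LevyParams) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic spiral terms ``(y, x)`` over dimensions 1..dim.

    For D1 = 1..dim: ``r = r1 + U*D1``, ``theta = -w*D1 + theta1``,
    ``y = r*cos(theta)``, ``x = r*sin(theta)``.  With the default
    ``theta1 = 3*pi/2`` the spiral starts pointing along -x and tightens by
    ``w`` per dimension.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    d1 = np.arange(1, dim + 1, dtype=float)
    r = params.cycle_count + params.spiral_u * d1
    theta = -params.spiral_w * d1 + params.theta1
    return r * np.cos(theta), r * np.sin(theta)


def levy_update(
    prey: np.ndarray,
    positions: np.ndarray,
    params: LevyParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Levy-flight move: ``x_new = prey * Levy(D) + X_R + (y - x) * rand``.

    ``Levy(D)`` multiplies the prey element-wise, ``X_R`` is a uniformly
    chosen population member, and ``rand`` is a single scalar uniform
    scaling the spiral difference.  The caller clamps the result to bounds.
    """
    positions = np.atleast_2d(positions)
    if positions.shape[0] < 1:
        raise ValueError("population must be non-empty")
    dim = prey.shape[0]
    step = levy_step(dim, params, rng)
    idx = int(rng.integers(positions.shape[0]))
    x_r = positions[idx]
    y, x = spiral_coords(dim, params)
    rand = rng.uniform()
    return prey * step + x_r + (y - x) * rand
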