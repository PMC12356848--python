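"""Deterministic tumour growth laws.

The Gompertz law describes decelerating tumour growth

    V(t) = V0 * exp[K * (1 - exp(-beta * t))],   K = ln(Vinf / V0),

where ``V0`` is the initiating volume (a single cell, 1e-9 cm^3 by
convention), ``Vinf`` the carrying capacity and ``beta`` the decay
constant of the specific growth rate (1/V) dV/dt = beta * K * exp(-beta*t).
Time ``t`` is measured in months from lesion initiation.

The module also provides the exponential law V(t) = V0 * exp(alpha * t)
and the observation transforms that make both laws *linear* in time:

    Gompertz:     y = -ln(1 - ln(V/V0) / K)  =  beta * t
    exponential:  y =  ln(V/V0)              =  alpha * t

These transforms are the backbone of the population (mixed-effects) fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SINGLE_CELL_CM3",
    "DAYS_PER_MONTH",
    "GompertzParams",
    "ExponentialParams",
    "volume_at",
    "time_to_volume",
    "gompertz_y",
    "exponential_y",
    "specific_growth_rate",
]

#: Volume of a single cell in cm^3 — the conventional initiating volume.
SINGLE_CELL_CM3 = 1e-9

#: Days per month (365.25 / 12); all rates are per month internally.
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of one Gompertz trajectory.

    Parameters
    ----------
    vinf : float
        Carrying capacity in cm^3 (asymptotic maximal volume).
    beta : float
        Decay constant of the specific growth rate, per month.
    v0 : float, optional
        Initiating volume in cm^3; defaults to a single cell.
    """

    vinf: float
    beta: float
    v0: float = SINGLE_CELL_CM3

    def __post_init__(self) -> None:
        if not (0.0 < self.v0 < self.vinf):
            raise ValueError(f"require 0 < v0 < vinf, got v0={self.v0}, vinf={self.vinf}")
        if not (self.beta > 0.0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be positive and finite, got {self.beta}")

    @property
    def k(self) -> float:
        """Dimensionless growth span K = ln(vinf / v0)."""
        return math.log(self.vinf / self.v0)


@dataclass(frozen=True)
class ExponentialParams:
    """Parameters of one exponential trajectory: V(t) = v0 * exp(alpha * t)."""

    alpha: float
    v0: float = SINGLE_CELL_CM3

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError(f"v0 must be positive, got {self.v0}")


def volume_at(p: GompertzParams, t: float) -> float:
    """Gompertz volume (cm^3) at time ``t`` months after initiation.

    Strictly increasing in ``t``, bounded in (v0, vinf).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0 (t=0 is initiation), got {t}")
    return p.v0 * math.exp(p.k * (1.0 - math.exp(-p.beta * t)))


def time_to_volume(p: GompertzParams, volume: float) -> float:
    """Months from initiation until the trajectory reaches ``volume``.

    Inverse of :func:`volume_at`:  t = -(1/beta) * ln(1 - ln(V/v0)/K).
    ``volume`` must lie in [v0, vinf).
    """
    if not (p.v0 <= volume < p.vinf):
        raise ValueError(
            f"volume {volume} outside the reachable range [{p.v0}, {p.vinf})"
        )
    return -math.log1p(-math.log(volume / p.v0) / p.k) / p.beta


def gompertz_y(volume: float, p: GompertzParams) -> float:
    """Gompertz observation transform y = -ln(1 - ln(V/v0)/K).

    On a noiseless trajectory, y equals ``beta * t`` exactly, turning the
    growth law into a line through the origin with slope beta.
    """
    if not (0.0 < volume < p.vinf):
        raise ValueError(f"volume {volume} outside the transform domain (0, {p.vinf})")
    return -math.log1p(-math.log(volume / p.v0) / p.k)


def exponential_y(volume: float, p: ExponentialParams) -> float:
    """Exponential observation transform y = ln(V/v0) = alpha * t."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return math.log(volume / p.v0)


def specific_growth_rate(p: GompertzParams, t: float) -> float:
    """Specific growth rate (1/V) dV/dt = beta * K * exp(-beta*t), per month."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return p.beta * p.k * math.exp(-p.beta * t)
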