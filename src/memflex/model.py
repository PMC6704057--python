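"""Core signaling model: two parallel first-order processes with saturation.

An experience drives a step input ``u`` into a fast memory-strengthening
pathway (time constant ``tau1``) and a slow memory-weakening pathway
(``tau2``).  Each pathway is a first-order linear process

    tau * dx/dt = -x + K * u(t)

whose step response is the familiar ``K*u*(1 - exp(-(t - t_on)/tau))``.
The saturated difference of the two signals, ``sat(x1 - x2, 0, 1)``,
is the *Pathway Activity* — the net short-term learning capacity an
event engages — and ``1 - Pathway Activity`` is the fraction of a finite
pool of downstream effectors still available for encoding new events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ParameterSet",
    "ExperienceEvent",
    "PathwayState",
    "CONTROL",
    "KNOCKDOWN",
    "DEFAULT_GENOTYPES",
    "first_order_step",
    "integrate_first_order",
    "saturate",
    "pathway_activity",
    "effectors_available",
    "activity_difference",
    "peak_activity_time",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    """A model parameter violates its domain (e.g. nonpositive time constant)."""


@dataclass(frozen=True)
class ParameterSet:
    """Genotype-specific model constants.

    Parameters
    ----------
    tau1, tau2 : float
        Time constants (hours) of the memory-strengthening and
        memory-weakening pathways.  Both must be positive.
    K1, K2 : float
        Dimensionless steady-state gains of the two pathways.
    u_nominal : float
        Default step-input magnitude applied by an experience.
    label : str
        Genotype name (e.g. ``"control"`` or ``"wt1d"``).
    """

    tau1: float
    tau2: float
    K1: float
    K2: float
    u_nominal: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise InvalidParameterError(
                f"time constants must be positive, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.K1 <= 0 or self.K2 <= 0:
            raise InvalidParameterError(
                f"gains must be positive, got K1={self.K1}, K2={self.K2}"
            )
        if self.u_nominal < 0:
            raise InvalidParameterError(f"u_nominal must be >= 0, got {self.u_nominal}")

    def with_overrides(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


#: Default parameter sets.  The strengthening pathway is fast (0.5 h) in both
#: genotypes; loss of functional WT1 slows the weakening pathway (36 -> 144 h)
#: and amplifies both gains ~2.4-fold (3 -> 7.2).
CONTROL = ParameterSet(tau1=0.5, tau2=36.0, K1=3.0, K2=3.0, u_nominal=0.125, label="control")
KNOCKDOWN = ParameterSet(tau1=0.5, tau2=144.0, K1=7.2, K2=7.2, u_nominal=0.125, label="wt1d")

DEFAULT_GENOTYPES = {"control": CONTROL, "wt1d": KNOCKDOWN}

#: Input-magnitude range explored by the default parameter-variation sweep.
U_SWEEP_RANGE = (0.025, 0.15)


@dataclass(frozen=True)
class ExperienceEvent:
    """One learning experience: a step input of magnitude ``u`` at ``t_on`` hours."""

    label: str
    t_on: float = 0.0
    u: float | None = None  # None -> use ParameterSet.u_nominal

    def __post_init__(self) -> None:
        if self.t_on < 0:
            raise InvalidParameterError(f"event onset must be >= 0, got {self.t_on}")
        if self.u is not None and self.u < 0:
            raise InvalidParameterError(f"event input must be >= 0, got {self.u}")

    def magnitude(self, params: ParameterSet) -> float:
        return params.u_nominal if self.u is None else self.u


@dataclass(frozen=True)
class PathwayState:
    """Strengthening and weakening signal levels at one time point."""

    x1: float
    x2: float
    t: float


def first_order_step(t, t_on: float, tau: float, K: float, u: float):
    """Closed-form step response of ``tau dx/dt = -x + K*u(t)``.

    Returns 0 before onset and ``K*u*(1 - exp(-(t - t_on)/tau))`` after;
    monotone nondecreasing with limit ``K*u``.  ``t`` may be a scalar or
    array (hours).
    """
    if tau <= 0:
        raise InvalidParameterError(f"tau must be positive, got {tau}")
    t = np.asarray(t, dtype=float)
    dt = t - t_on
    out = np.where(dt > 0, K * u * -np.expm1(-np.maximum(dt, 0.0) / tau), 0.0)
    return float(out) if out.ndim == 0 else out


def integrate_first_order(
    input_fn: Callable[[float], float],
    tau: float,
    K: float,
    grid: Sequence[float],
    max_step: float = 0.01,
    jumps: Sequence[float] = (),
) -> np.ndarray:
    """Numerically solve ``tau dx/dt = -x + K*u(t)`` from x(grid[0]) = 0.

    Classical fixed-step RK4; each grid interval is subdivided so no
    internal step exceeds ``max_step`` hours.  For step inputs this agrees
    with :func:`first_order_step` to better than 1e-6 at max_step <= 0.01 h.

    Known input discontinuities may be declared via ``jumps``: integration
    restarts at each jump and the input is sampled just inside every
    smooth segment, so RK4 never averages across a jump.  ``input_fn`` is
    taken right-continuous at its jumps.
    """
    if tau <= 0:
        raise InvalidParameterError(f"tau must be positive, got {tau}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a non-empty 1-D sequence")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    jump_times = sorted(t for t in set(float(j) for j in jumps) if grid[0] < t < grid[-1])

    def segment_deriv(seg_end: float | None):
        def deriv(t: float, x: float) -> float:
            # left-limit sampling at a segment's terminal jump
            if seg_end is not None and t >= seg_end:
                t = seg_end - 1e-9 * max(1.0, abs(seg_end))
            return (-x + K * input_fn(t)) / tau

        return deriv

    traj = np.empty_like(grid)
    traj[0] = 0.0
    x = 0.0
    for i in range(1, grid.size):
        t0, t1 = grid[i - 1], grid[i]
        cuts = [t0] + [j for j in jump_times if t0 < j < t1] + [t1]
        for s0, s1 in zip(cuts, cuts[1:]):
            deriv = segment_deriv(s1 if s1 in jump_times else None)
            nsub = max(1, int(math.ceil((s1 - s0) / max_step)))
            h = (s1 - s0) / nsub
            t = s0
            for _ in range(nsub):
                k1 = deriv(t, x)
                k2 = deriv(t + h / 2, x + h / 2 * k1)
                k3 = deriv(t + h / 2, x + h / 2 * k2)
                k4 = deriv(t + h, x + h * k3)
                x += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += h
        traj[i] = x
    return traj


def saturate(v, lo: float = 0.0, hi: float = 1.0):
    """Clip ``v`` to the interval [lo, hi]."""
    if lo > hi:
        raise ValueError(f"saturation bounds out of order: lo={lo} > hi={hi}")
    out = np.clip(np.asarray(v, dtype=float), lo, hi)
    return float(out) if out.ndim == 0 else out


def activity_difference(t, event: ExperienceEvent, params: ParameterSet):
    """Raw (unsaturated) x1 - x2 elicited by a single event at time(s) ``t``."""
    u = event.magnitude(params)
    x1 = first_order_step(t, event.t_on, params.tau1, params.K1, u)
    x2 = first_order_step(t, event.t_on, params.tau2, params.K2, u)
    return x1 - x2


def pathway_activity(x1, x2):
    """Pathway Activity = sat(x1 - x2, 0, 1)."""
    return saturate(np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float), 0.0, 1.0)


def effectors_available(aggregate_activity):
    """Fraction of the finite effector pool left: 1 - aggregate Pathway Activity."""
    a = np.asarray(aggregate_activity, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("aggregate activity must lie in [0, 1]")
    out = 1.0 - a
    return float(out) if out.ndim == 0 else out


def peak_activity_time(params: ParameterSet) -> float:
    """Analytic time (hours after onset) at which x1 - x2 peaks for a step.

    For equal gains, x1 - x2 = K*u*(exp(-t/tau2) - exp(-t/tau1)) which is
    maximal at t* = ln(tau2/tau1) / (1/tau1 - 1/tau2).
    """
    t1, t2 = params.tau1, params.tau2
    if t1 == t2:
        raise InvalidParameterError("peak time undefined for tau1 == tau2")
    return math.log(t2 / t1) / (1.0 / t1 - 1.0 / t2)
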