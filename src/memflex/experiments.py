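"""Protocol simulation: per-event Memory under finite effector capacity.

Each event in a schedule drives its own (x1, x2) pair.  The *need* of an
event is the peak Pathway Activity it would reach in isolation with
unlimited effectors; its *have* is the effector fraction left at its
stimulus onset after accounting for all earlier events.  Memory for event
i at time t is

    Memory_i(t) = PA_i(t) / max(PA_i)  *  min(have_i / need_i, 1)

in ``limiting`` effector mode, and just the normalised activity trace in
``excess`` mode (the capacity weight is 1).  The weight is capped at 1:
surplus effectors never amplify memory above full learning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import (
    ExperienceEvent,
    ParameterSet,
    activity_difference,
    first_order_step,
    peak_activity_time,
    saturate,
)

__all__ = [
    "Protocol",
    "SimulationResult",
    "MemoryUndefinedError",
    "peak_activity",
    "have_at_event",
    "memory_trajectory",
    "run_protocol",
    "sweep_input",
    "builtin_protocol",
    "BUILTIN_PROTOCOLS",
]

EffectorMode = Literal["limiting", "excess"]
HaveMode = Literal["onset", "time_varying"]

#: Default grid resolution (hours).  tau1 = 0.5 h must be resolved.
GRID_STEP = 0.01


class MemoryUndefinedError(ValueError):
    """Memory is undefined because the event's need is zero (u = 0)."""


@dataclass(frozen=True)
class Protocol:
    """An ordered event schedule plus the read-out times after each event.

    ``test_offsets`` gives, per event, the delay (hours) after onset at
    which memory_at_test is read; a single float applies to every event.
    """

    events: tuple[ExperienceEvent, ...]
    test_offsets: tuple[float, ...] | float = 24.0
    effector_mode: EffectorMode = "limiting"
    name: str = "custom"

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if self.effector_mode not in ("limiting", "excess"):
            raise ValueError(f"effector_mode must be 'limiting' or 'excess', got {self.effector_mode!r}")
        labels = [e.label for e in events]
        if len(set(labels)) != len(labels):
            raise ValueError(f"event labels must be unique, got {labels}")
        if any(b.t_on < a.t_on for a, b in zip(events, events[1:])):
            raise ValueError("events must be sorted by onset time")
        if len({e.t_on for e in events}) != len(events):
            warnings.warn("protocol contains events with identical onsets", stacklevel=2)
        offs = self.test_offsets
        offs = tuple(float(o) for o in (offs if isinstance(offs, (tuple, list)) else [offs] * len(events)))
        if events and len(offs) != len(events):
            raise ValueError("test_offsets must be scalar or one per event")
        if any(o <= 0 for o in offs):
            raise ValueError("test offsets must be positive")
        object.__setattr__(self, "test_offsets", offs)

    @property
    def test_times(self) -> tuple[float, ...]:
        return tuple(e.t_on + o for e, o in zip(self.events, self.test_offsets))


def builtin_protocol(name: str, effector_mode: EffectorMode = "limiting") -> Protocol:
    """Shipped training schedules.

    ``single``            task1 at 0 h, test +24 h.
    ``sequential-short``  task1 (object-location) at 0 h, task2 (fear
                          conditioning) at 48 h — train day 0, test day 1,
                          retrain the next day; tests +24 h.
    ``sequential-long``   as above with task2 at 240 h (ten-day interval).
    """
    t2_onset = {"single": None, "sequential-short": 48.0, "sequential-long": 240.0}
    if name not in t2_onset:
        raise ValueError(f"unknown protocol {name!r}; choose from {sorted(t2_onset)}")
    events = [ExperienceEvent("task1", 0.0)]
    if t2_onset[name] is not None:
        events.append(ExperienceEvent("task2", t2_onset[name]))
    return Protocol(tuple(events), test_offsets=24.0, effector_mode=effector_mode, name=name)


BUILTIN_PROTOCOLS = ("single", "sequential-short", "sequential-long")


@dataclass
class SimulationResult:
    """Full trajectory bundle for one protocol run under one parameter set."""

    grid: np.ndarray
    protocol: Protocol
    params: ParameterSet
    per_event_x1: dict[str, np.ndarray]
    per_event_x2: dict[str, np.ndarray]
    per_event_pa: dict[str, np.ndarray]
    aggregate_activity: np.ndarray
    need: dict[str, float]
    have: dict[str, float]
    memory: dict[str, np.ndarray]
    memory_at_test: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format trajectories: t, event, x1, x2, pathway_activity, memory."""
        frames = []
        for label in self.per_event_x1:
            frames.append(
                pd.DataFrame(
                    {
                        "t": self.grid,
                        "event": label,
                        "x1": self.per_event_x1[label],
                        "x2": self.per_event_x2[label],
                        "pathway_activity": self.per_event_pa[label],
                        "memory": self.memory[label],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        rows = []
        for ev, off in zip(self.protocol.events, self.protocol.test_offsets):
            rows.append(
                {
                    "event": ev.label,
                    "genotype": self.params.label,
                    "t_on": ev.t_on,
                    "test_time": ev.t_on + off,
                    "need": self.need[ev.label],
                    "have": self.have[ev.label],
                    "memory_at_test": self.memory_at_test[ev.label],
                }
            )
        return pd.DataFrame(rows)


def peak_activity(event: ExperienceEvent, params: ParameterSet) -> float:
    """Peak Pathway Activity of an event alone with unlimited effectors (need).

    Evaluated at the analytic peak time of x1 - x2 and passed through the
    [0, 1] saturation.  Zero-input events have zero need (memory undefined).
    """
    if event.magnitude(params) == 0:
        return 0.0
    t_star = event.t_on + peak_activity_time(params)
    return saturate(activity_difference(t_star, event, params), 0.0, 1.0)


def _prior_difference(t, events: Sequence[ExperienceEvent], upto: int, params: ParameterSet):
    """Summed raw x1 - x2 of events before index ``upto`` at time(s) t."""
    total = np.zeros_like(np.asarray(t, dtype=float))
    for ev in events[:upto]:
        total = total + activity_difference(t, ev, params)
    return total


def have_at_event(event_index: int, events: Sequence[ExperienceEvent], params: ParameterSet) -> float:
    """Effectors available at an event's onset, from prior events only.

    have = 1 - sat(sum_{j<i} (x1_j - x2_j)(t_on_i), 0, 1); 1 for the first
    event.  Prior activities are summed *then* saturated, mirroring the
    single saturation applied to aggregate activity.
    """
    events = list(events)
    t_on = events[event_index].t_on
    prior = float(np.asarray(_prior_difference(np.asarray(t_on), events, event_index, params)))
    return 1.0 - saturate(prior, 0.0, 1.0)


def memory_trajectory(
    event_index: int,
    events: Sequence[ExperienceEvent],
    params: ParameterSet,
    grid: np.ndarray,
    effector_mode: EffectorMode = "limiting",
    have_mode: HaveMode = "onset",
) -> np.ndarray:
    """Memory time series for one event of a schedule on ``grid``.

    Limiting mode weights the normalised activity trace by the capped
    capacity ratio min(have/need, 1); excess mode uses weight 1.  With
    ``have_mode="time_varying"`` the weight is recomputed pointwise from
    the prior events' activity at each time instead of at onset.
    """
    events = list(events)
    ev = events[event_index]
    need = peak_activity(ev, params)
    if need == 0:
        raise MemoryUndefinedError(
            f"event {ev.label!r} has zero input (need = 0); Memory is undefined"
        )
    pa = saturate(activity_difference(grid, ev, params), 0.0, 1.0)
    shape = pa / need
    if effector_mode == "excess":
        return np.minimum(shape, 1.0)
    if have_mode == "time_varying":
        prior = _prior_difference(grid, events, event_index, params)
        have = 1.0 - saturate(prior, 0.0, 1.0)
        weight = np.minimum(have / need, 1.0)
    else:
        have = have_at_event(event_index, events, params)
        weight = min(have / need, 1.0)
    return np.minimum(shape, 1.0) * weight


def run_protocol(
    protocol: Protocol,
    params: ParameterSet,
    grid_step: float = GRID_STEP,
    horizon: float | None = None,
    have_mode: HaveMode = "onset",
) -> SimulationResult:
    """Simulate a full protocol: trajectories, need/have accounting, Memory.

    The grid spans [0, horizon] at ``grid_step`` resolution; by default the
    horizon is the last test time plus 24 h.  An empty protocol yields an
    empty result.
    """
    events = list(protocol.events)
    if horizon is None:
        horizon = (max(protocol.test_times) if events else 0.0) + 24.0
    grid = np.arange(0.0, horizon + grid_step / 2, grid_step)

    x1, x2, pa, memory = {}, {}, {}, {}
    need, have, mem_at_test = {}, {}, {}
    total_diff = np.zeros_like(grid)
    for i, ev in enumerate(events):
        u = ev.magnitude(params)
        x1[ev.label] = first_order_step(grid, ev.t_on, params.tau1, params.K1, u)
        x2[ev.label] = first_order_step(grid, ev.t_on, params.tau2, params.K2, u)
        diff = x1[ev.label] - x2[ev.label]
        total_diff += diff
        pa[ev.label] = saturate(diff, 0.0, 1.0)
        need[ev.label] = peak_activity(ev, params)
        have[ev.label] = have_at_event(i, events, params)
        if need[ev.label] == 0:
            memory[ev.label] = np.full_like(grid, np.nan)
            mem_at_test[ev.label] = np.nan
        else:
            memory[ev.label] = memory_trajectory(
                i, events, params, grid, protocol.effector_mode, have_mode
            )
            t_test = ev.t_on + protocol.test_offsets[i]
            idx = int(round((t_test - grid[0]) / grid_step))
            idx = min(idx, grid.size - 1)
            mem_at_test[ev.label] = float(memory[ev.label][idx])

    return SimulationResult(
        grid=grid,
        protocol=protocol,
        params=params,
        per_event_x1=x1,
        per_event_x2=x2,
        per_event_pa=pa,
        aggregate_activity=saturate(total_diff, 0.0, 1.0),
        need=need,
        have=have,
        memory=memory,
        memory_at_test=mem_at_test,
    )


def sweep_input(
    protocol: Protocol,
    params: ParameterSet,
    u_values: Sequence[float],
    have_mode: HaveMode = "onset",
) -> pd.DataFrame:
    """Recompute memory_at_test across input magnitudes.

    Every event's input is set to each u in turn (both tasks share one u).
    Rows where u = 0 carry NaN memory and a ``memory_defined=False`` flag.
    A warning is issued for u above the saturation onset 1/max(K1, K2).
    """
    u_values = list(u_values)
    if not u_values:
        raise ValueError("u_values must be non-empty")
    u_sat = 1.0 / max(params.K1, params.K2)
    rows = []
    for u in u_values:
        if u < 0:
            raise ValueError(f"input magnitude must be >= 0, got {u}")
        if u > u_sat:
            warnings.warn(
                f"u={u} exceeds saturation onset 1/K={u_sat:.4g}; Pathway Activity will clip",
                stacklevel=2,
            )
        events = tuple(
            ExperienceEvent(ev.label, ev.t_on, u) for ev in protocol.events
        )
        proto_u = Protocol(events, protocol.test_offsets, protocol.effector_mode, protocol.name)
        if u == 0:
            for ev in proto_u.events:
                rows.append(
                    {
                        "u": u,
                        "event": ev.label,
                        "genotype": params.label,
                        "memory_at_test": np.nan,
                        "memory_defined": False,
                    }
                )
            continue
        res = run_protocol(proto_u, params, have_mode=have_mode)
        for ev in proto_u.events:
            rows.append(
                {
                    "u": u,
                    "event": ev.label,
                    "genotype": params.label,
                    "memory_at_test": res.memory_at_test[ev.label],
                    "memory_defined": True,
                }
            )
    return pd.DataFrame(rows)
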