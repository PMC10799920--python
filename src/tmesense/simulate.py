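"""Time-course and dose-response simulation of biosensor circuits.

Integration uses scipy's LSODA (stiff-capable) with piecewise restarts at
environment-schedule breakpoints, so piecewise-constant inputs never cross
a solver step discontinuously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .circuit import observed_outputs, rhs
from .params import CircuitState, EnvironmentSignal, ParameterError, StrainSpec

__all__ = [
    "IntegrationError",
    "EnvironmentSchedule",
    "Trajectory",
    "DoseResponseCurve",
    "TrajectorySummary",
    "ConsortiumTrajectory",
    "simulate_time_course",
    "dose_response",
    "summarize",
    "simulate_consortium",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """The ODE solver failed to converge on some schedule interval."""


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Piecewise-constant environment: (start_time_h, EnvironmentSignal) pairs.

    The first segment must start at t = 0 and start times must be strictly
    increasing. Each signal holds until the next breakpoint.
    """

    segments: tuple

    def __post_init__(self):
        segs = tuple((float(t), env) for t, env in self.segments)
        if not segs:
            raise ParameterError("schedule must contain at least one segment")
        if segs[0][0] != 0.0:
            raise ParameterError(f"first segment must start at t=0, got {segs[0][0]}")
        times = [t for t, _ in segs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterError("segment start times must be strictly increasing")
        for _, env in segs:
            if not isinstance(env, EnvironmentSignal):
                raise ParameterError("schedule entries must be EnvironmentSignal instances")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, env: EnvironmentSignal) -> "EnvironmentSchedule":
        return cls(segments=((0.0, env),))

    def at(self, t: float) -> EnvironmentSignal:
        env = self.segments[0][1]
        for start, e in self.segments:
            if start <= t:
                env = e
            else:
                break
        return env

    def breakpoints(self, horizon: float) -> list:
        """Interval edges [0, ..., horizon] clipped to the horizon."""
        edges = [t for t, _ in self.segments if t < horizon]
        return edges + [horizon]


@dataclass
class Trajectory:
    """Simulated time course of one strain: states and plate observables."""

    time: np.ndarray
    states: np.ndarray          # (n_times, 5) in CircuitState order
    od600: np.ndarray
    total_fluor: np.ndarray
    normalized_fluor: np.ndarray
    strain: StrainSpec

    def __post_init__(self):
        n = len(self.time)
        if not (self.states.shape[0] == len(self.od600) == len(self.total_fluor)
                == len(self.normalized_fluor) == n):
            raise ParameterError("trajectory grids are not aligned")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("trajectory time grid must be strictly increasing")

    def state_at(self, idx: int) -> CircuitState:
        return CircuitState.from_array(self.states[idx], clip_tol=1e-6)

    def value_at(self, t: float, column: str = "normalized_fluor") -> float:
        """Observable at grid time t (must lie on the output grid)."""
        idx = np.flatnonzero(np.isclose(self.time, t, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise ParameterError(f"time {t} h is not on the output grid")
        return float(getattr(self, column)[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_h": self.time,
            "od600": self.od600,
            "total_fluor_au": self.total_fluor,
            "normalized_fluor_au": self.normalized_fluor,
            "n_unflipped": self.states[:, 0],
            "n_flipped": self.states[:, 1],
            "reporter_per_cell": self.states[:, 2],
            "lysis_protein_per_cell": self.states[:, 3],
            "debris": self.states[:, 4],
        })
        df["strain_id"] = self.strain.strain_id
        df["topology"] = self.strain.topology
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DoseResponseCurve:
    """End-point readout across a grid of one signal channel."""

    channel: str
    signal: np.ndarray
    read_time: float
    normalized_fluor: np.ndarray
    od600: np.ndarray
    strain: StrainSpec

    def __post_init__(self):
        if not (len(self.signal) == len(self.normalized_fluor) == len(self.od600)):
            raise ParameterError("dose-response grids are not aligned")

    def value_at(self, signal_value: float) -> float:
        idx = np.flatnonzero(np.isclose(self.signal, signal_value))
        if idx.size == 0:
            raise ParameterError(f"signal value {signal_value} not on the grid")
        return float(self.normalized_fluor[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "signal": self.signal,
            "od600": self.od600,
            "normalized_fluor_au": self.normalized_fluor,
        })
        df["channel"] = self.channel
        df["read_time_h"] = self.read_time
        df["strain_id"] = self.strain.strain_id
        df["topology"] = self.strain.topology
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class TrajectorySummary:
    """Peak and persistence summary of a normalized-fluorescence trace."""

    peak_time: float
    peak_value: float
    persistence_time: float
    final_od600: float


def _integrate_segment(y0, t0, t1, strain, env, rtol, atol):
    def fun(t, y):
        return rhs(t, y, strain, env)
    sol = solve_ivp(fun, (t0, t1), y0, method="LSODA", rtol=rtol, atol=atol,
                    dense_output=True)
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed on interval [{t0}, {t1}] h: {sol.message}")
    return sol


def simulate_time_course(strain: StrainSpec,
                         schedule: EnvironmentSchedule | EnvironmentSignal,
                         horizon: float,
                         output_step: float = 0.5,
                         rtol: float = DEFAULT_RTOL,
                         atol: float = DEFAULT_ATOL,
                         initial_state: Optional[CircuitState] = None) -> Trajectory:
    """Integrate one strain over a (piecewise-constant) environment schedule.

    Parameters
    ----------
    strain : StrainSpec
    schedule : EnvironmentSchedule or EnvironmentSignal
        A bare signal is treated as a constant schedule.
    horizon : float
        End time in hours, > 0.
    output_step : float
        Spacing of the output grid in hours.
    rtol, atol : float
        Solver tolerances.
    initial_state : CircuitState, optional
        Defaults to the all-unflipped inoculum at ``growth.initial_density``
        with zero protein and debris.
    """
    if isinstance(schedule, EnvironmentSignal):
        schedule = EnvironmentSchedule.constant(schedule)
    horizon = float(horizon)
    if horizon <= 0:
        raise ParameterError(f"horizon must be > 0, got {horizon}")
    if output_step <= 0:
        raise ParameterError(f"output_step must be > 0, got {output_step}")

    if initial_state is None:
        initial_state = CircuitState(n_unflipped=strain.growth.initial_density)
    y = initial_state.to_array()

    n_out = int(round(horizon / output_step))
    t_grid = np.linspace(0.0, horizon, n_out + 1)

    edges = schedule.breakpoints(horizon)
    times_out = [0.0]
    ys_out = [y.copy()]
    for t0, t1 in zip(edges, edges[1:]):
        env = schedule.at(t0)
        sol = _integrate_segment(y, t0, t1, strain, env, rtol, atol)
        interior = t_grid[(t_grid > t0 + 1e-12) & (t_grid <= t1 + 1e-12)]
        if interior.size:
            seg_y = sol.sol(interior)
            times_out.extend(interior.tolist())
            ys_out.extend(seg_y.T.copy())
        y = sol.y[:, -1]

    times = np.array(times_out)
    states = np.clip(np.array(ys_out), 0.0, None)
    obs = [observed_outputs(CircuitState.from_array(s, clip_tol=np.inf), strain)
           for s in states]
    return Trajectory(
        time=times,
        states=states,
        od600=np.array([o["od600"] for o in obs]),
        total_fluor=np.array([o["total_fluor"] for o in obs]),
        normalized_fluor=np.array([o["normalized_fluor"] for o in obs]),
        strain=strain,
    )


def dose_response(strain: StrainSpec, channel: str, grid: Sequence[float],
                  read_time: float = 48.0, output_step: float = 0.5,
                  rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                  base_env: Optional[EnvironmentSignal] = None) -> DoseResponseCurve:
    """End-point dose-response over a grid of one signal channel.

    Each grid point is simulated as an independent constant-environment
    culture and read at ``read_time`` (48 h by default, the end-point used
    for the printed dose-response characterizations).
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("signal grid must be non-empty")
    if base_env is None:
        base_env = EnvironmentSignal()
    norm, od = [], []
    for value in grid:
        if channel == "lactate":
            env = EnvironmentSignal(lactate=value, pH=base_env.pH, oxygen=base_env.oxygen)
        elif channel == "pH":
            env = EnvironmentSignal(lactate=base_env.lactate, pH=value, oxygen=base_env.oxygen)
        elif channel == "oxygen":
            env = EnvironmentSignal(lactate=base_env.lactate, pH=base_env.pH, oxygen=value)
        else:
            raise ParameterError(f"unknown dose channel {channel!r}")
        traj = simulate_time_course(strain, env, horizon=read_time,
                                    output_step=output_step, rtol=rtol, atol=atol)
        norm.append(traj.normalized_fluor[-1])
        od.append(traj.od600[-1])
    return DoseResponseCurve(channel=channel, signal=np.asarray(grid, dtype=float),
                             read_time=float(read_time),
                             normalized_fluor=np.array(norm), od600=np.array(od),
                             strain=strain)


def summarize(traj: Trajectory, detection_threshold: Optional[float] = None) -> TrajectorySummary:
    """Peak time/value and persistence of the normalized-fluorescence trace.

    ``persistence_time`` is the last output-grid time at which the signal is
    at or above the detection threshold (0 if it never is); no interpolation
    between grid points is attempted.
    """
    if detection_threshold is None:
        detection_threshold = traj.strain.measurement.detection_threshold
    sig = traj.normalized_fluor
    peak_idx = int(np.argmax(sig))
    above = np.flatnonzero(sig >= detection_threshold)
    persistence = float(traj.time[above[-1]]) if above.size else 0.0
    return TrajectorySummary(
        peak_time=float(traj.time[peak_idx]),
        peak_value=float(sig[peak_idx]),
        persistence_time=persistence,
        final_od600=float(traj.od600[-1]),
    )


@dataclass
class ConsortiumTrajectory:
    """Coupled simulation of several strains sharing one carrying capacity."""

    trajectories: list
    total_od600: np.ndarray = field(init=False)

    def __post_init__(self):
        self.total_od600 = np.sum([t.od600 for t in self.trajectories], axis=0)

    @property
    def time(self) -> np.ndarray:
        return self.trajectories[0].time

    def member_fractions(self) -> np.ndarray:
        """Live-density share of each member over time, shape (n_strains, n_times)."""
        live = np.array([t.states[:, 0] + t.states[:, 1] for t in self.trajectories])
        return live / live.sum(axis=0, keepdims=True)


def simulate_consortium(strains: Sequence[StrainSpec],
                        schedule: EnvironmentSchedule | EnvironmentSignal,
                        horizon: float, output_step: float = 0.5,
                        rtol: float = DEFAULT_RTOL,
                        atol: float = DEFAULT_ATOL) -> ConsortiumTrajectory:
    """Simulate a consortium: members interact only through shared capacity.

    Each member's crowding term sees the summed biomass (live cells plus
    debris) of every member; all strains must declare the same carrying
    capacity. A consortium of one reduces exactly to
    :func:`simulate_time_course`.
    """
    strains = list(strains)
    if not strains:
        raise ParameterError("consortium must contain at least one strain")
    caps = {s.growth.carrying_capacity for s in strains}
    if len(caps) != 1:
        raise ParameterError("all consortium members must share one carrying capacity")
    if isinstance(schedule, EnvironmentSignal):
        schedule = EnvironmentSchedule.constant(schedule)
    horizon = float(horizon)
    if horizon <= 0:
        raise ParameterError(f"horizon must be > 0, got {horizon}")

    n = len(strains)
    y0 = np.concatenate([CircuitState(n_unflipped=s.growth.initial_density).to_array()
                         for s in strains])

    def coupled_rhs(t, y, env):
        blocks = y.reshape(n, 5)
        biomass = np.clip(blocks[:, 0], 0, None) + np.clip(blocks[:, 1], 0, None) \
            + np.clip(blocks[:, 4], 0, None)
        total = float(biomass.sum())
        out = np.empty_like(blocks)
        for i, s in enumerate(strains):
            out[i] = rhs(t, blocks[i], s, env, external_biomass=total - biomass[i])
        return out.ravel()

    n_out = int(round(horizon / output_step))
    t_grid = np.linspace(0.0, horizon, n_out + 1)
    edges = schedule.breakpoints(horizon)
    times_out = [0.0]
    ys_out = [y0.copy()]
    y = y0
    for t0, t1 in zip(edges, edges[1:]):
        env = schedule.at(t0)
        sol = solve_ivp(lambda t, yy: coupled_rhs(t, yy, env), (t0, t1), y,
                        method="LSODA", rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise IntegrationError(
                f"consortium integration failed on [{t0}, {t1}] h: {sol.message}")
        interior = t_grid[(t_grid > t0 + 1e-12) & (t_grid <= t1 + 1e-12)]
        if interior.size:
            times_out.extend(interior.tolist())
            ys_out.extend(sol.sol(interior).T.copy())
        y = sol.y[:, -1]

    times = np.array(times_out)
    all_states = np.clip(np.array(ys_out), 0.0, None)
    trajs = []
    for i, s in enumerate(strains):
        states = all_states[:, 5 * i:5 * (i + 1)]
        obs = [observed_outputs(CircuitState.from_array(st, clip_tol=np.inf), s)
               for st in states]
        trajs.append(Trajectory(
            time=times, states=states,
            od600=np.array([o["od600"] for o in obs]),
            total_fluor=np.array([o["total_fluor"] for o in obs]),
            normalized_fluor=np.array([o["normalized_fluor"] for o in obs]),
            strain=s,
        ))
    return ConsortiumTrajectory(trajectories=trajs)
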