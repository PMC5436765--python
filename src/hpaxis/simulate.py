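"""Stiff integration of the HPA-axis network under control/sham/kindling scenarios.

Scenarios differ in two knobs only: a multiplier on the CRH production
constant k2 (1.0 for control, 1.1765 for sham and kindled animals, absorbing
the surgical-stress elevation) and a schedule of instantaneous additive CRH
pulses emulating lateral-hypothalamic kindling (LHK).  A pulse is applied by
the stop-and-restart rule: integration halts at the event time, the CRH
concentration is incremented, every other species keeps its attained value,
and integration resumes from the modified state.

The system is stiff (rate constants span 17 orders of magnitude), so only
implicit/stiff methods are offered.  The strict tolerance preset
(atol 3e-20, rtol 1e-14) is the default; the documented fast preset
(atol 1e-9, rtol 3e-6) pairs the relaxed tolerances with the Radau scheme,
which tracks oscillation phase at relaxed tolerances much better than the
multistep methods do.  scipy refuses relative tolerances below 100*eps
(~2.22e-14), so the strict rtol is clamped to that floor at solve time.

Simulations start at t = 0 (00:00 of day 1) from the shared standard initial
condition; day 1 is a transient and is excluded from all analyses by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .forcing import DEFAULT_FORCING, ForcingParams, circadian_drive
from .network import (
    RATE_CONSTANTS,
    SPECIES,
    SpeciesState,
    _IDX,
    _jac_raw,
    _kvec,
    _rhs_raw,
    initial_state,
)

__all__ = [
    "PulseEvent",
    "PerturbationSchedule",
    "ScenarioConfig",
    "Trajectory",
    "SHAM_K2_MULTIPLIER",
    "LHK_PULSE_INTENSITY",
    "STRICT_TOLERANCES",
    "FAST_TOLERANCES",
    "apply_pulse",
    "kindling_schedule",
    "integrate",
    "find_fixed_point_and_stability",
    "control_scenario",
    "sham_scenario",
    "lhk_scenario",
    "clock_to_minutes",
    "minutes_to_clock",
]

#: Sham stress elevation of CRH production.
SHAM_K2_MULTIPLIER = 1.1765
#: Fitted intensity of a single kindling CRH pulse (M).
LHK_PULSE_INTENSITY = 5e-8
#: Default kindling clock window: starts 21:12, lasts 50 min.
KINDLE_START_CLOCK = "21:12"
KINDLE_DURATION_MIN = 50.0
KINDLE_INTERVAL_S = 40.0

#: (atol, rtol, method) presets.
STRICT_TOLERANCES = (3e-20, 1e-14, "LSODA")
FAST_TOLERANCES = (1e-9, 3e-6, "Radau")

_RTOL_FLOOR = 100 * np.finfo(float).eps  # scipy's hard floor


def clock_to_minutes(clock: str, day: int = 1) -> float:
    """'HH:MM' on simulation day `day` (1-based) -> minutes since 00:00 day 1."""
    hh, mm = clock.split(":")
    h, m = int(hh), int(mm)
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"invalid clock time {clock!r}")
    return (day - 1) * 1440.0 + 60.0 * h + m


def minutes_to_clock(t: float) -> str:
    """Minutes since 00:00 day 1 -> 'HH:MM' wall-clock label."""
    m = int(round(t)) % 1440
    return f"{m // 60:02d}:{m % 60:02d}"


@dataclass(frozen=True)
class PulseEvent:
    time: float
    species: str
    increment: float

    def __post_init__(self) -> None:
        if self.species not in _IDX:
            raise ValueError(f"unknown species {self.species!r}")
        if self.increment < 0:
            raise ValueError("pulse increment must be nonnegative")


@dataclass(frozen=True)
class PerturbationSchedule:
    """Ordered additive species pulses; times strictly increasing."""

    events: tuple[PulseEvent, ...] = ()

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])


def kindling_schedule(
    start: float,
    pulse_interval_s: float = KINDLE_INTERVAL_S,
    duration_min: float = KINDLE_DURATION_MIN,
    intensity: float = LHK_PULSE_INTENSITY,
    species: str = "CRH",
) -> PerturbationSchedule:
    """Pulse train emulating an LHK sequence.

    First pulse at `start`, one pulse every `pulse_interval_s` seconds, no
    pulse at or after start + duration_min.  Defaults give 75 pulses spanning
    the 50-min kindling window.
    """
    if pulse_interval_s <= 0:
        raise ValueError("pulse interval must be positive")
    if duration_min < 0:
        raise ValueError("duration must be nonnegative")
    step = pulse_interval_s / 60.0
    n = int(np.ceil(duration_min / step - 1e-12))  # endpoint excluded
    events = tuple(
        PulseEvent(time=start + i * step, species=species, increment=intensity)
        for i in range(n)
    )
    return PerturbationSchedule(events=events)


@dataclass(frozen=True)
class ScenarioConfig:
    """A runnable experiment: condition preset + solver options."""

    condition: str = "control"
    k2_multiplier: float = 1.0
    schedule: PerturbationSchedule = field(default_factory=PerturbationSchedule)
    initial_state: SpeciesState = field(default_factory=initial_state)
    t_start: float = 0.0
    t_end: float = 5 * 1440.0
    atol: float = STRICT_TOLERANCES[0]
    rtol: float = STRICT_TOLERANCES[1]
    method: str = "LSODA"
    output_dt: float = 1.0
    rate_constants: Mapping[str, float] | None = None
    forcing: ForcingParams = DEFAULT_FORCING

    def __post_init__(self) -> None:
        if self.condition not in {"control", "sham", "lhk", "custom"}:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.atol <= 0 or self.rtol <= 0:
            raise ValueError("tolerances must be positive")
        if self.k2_multiplier <= 0:
            raise ValueError("k2_multiplier must be positive")
        if self.method not in {"LSODA", "BDF", "Radau"}:
            raise ValueError("a stiff method (LSODA, BDF or Radau) is required")
        if self.output_dt <= 0 or self.output_dt > 1.0:
            raise ValueError("output spacing must be in (0, 1] min")

    def with_tolerances(self, preset: str) -> "ScenarioConfig":
        atol, rtol, method = {"strict": STRICT_TOLERANCES, "fast": FAST_TOLERANCES}[preset]
        return replace(self, atol=atol, rtol=rtol, method=method)


def control_scenario(days: float = 5.0, **kw) -> ScenarioConfig:
    return ScenarioConfig(condition="control", t_end=days * 1440.0, **kw)


def sham_scenario(days: float = 5.0, **kw) -> ScenarioConfig:
    kw.setdefault("k2_multiplier", SHAM_K2_MULTIPLIER)
    return ScenarioConfig(condition="sham", t_end=days * 1440.0, **kw)


def lhk_scenario(
    days: float = 3.0,
    intensity: float = LHK_PULSE_INTENSITY,
    kindle_start: float | None = None,
    kindle_duration_min: float = KINDLE_DURATION_MIN,
    pulse_interval_s: float = KINDLE_INTERVAL_S,
    **kw,
) -> ScenarioConfig:
    """Sham background plus a kindling pulse train (default 21:12 on day 2)."""
    if kindle_start is None:
        kindle_start = clock_to_minutes(KINDLE_START_CLOCK, day=2)
    schedule = kindling_schedule(
        kindle_start, pulse_interval_s, kindle_duration_min, intensity
    )
    kw.setdefault("k2_multiplier", SHAM_K2_MULTIPLIER)
    return ScenarioConfig(
        condition="lhk",
        schedule=schedule,
        t_end=days * 1440.0,
        **kw,
    )


def apply_pulse(state: SpeciesState, species: str, increment: float) -> SpeciesState:
    """Add `increment` (M) to one species; all other species bit-identical."""
    if species not in _IDX:
        raise KeyError(f"unknown species {species!r}")
    if increment < 0:
        raise ValueError("pulse increment must be nonnegative")
    c = state.concentrations.copy()
    c[_IDX[species]] += increment
    return replace(state, concentrations=c)


@dataclass(frozen=True)
class PulseRecord:
    """Bookkeeping for one applied pulse (pre/post values of the pulsed species)."""

    time: float
    species: str
    increment: float
    pre_value: float
    post_value: float


@dataclass
class Trajectory:
    """Dense simulated time course of all species (M), minutes since 00:00 day 1."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    scenario: ScenarioConfig
    pulse_records: tuple[PulseRecord, ...] = ()
    solver_stats: dict = field(default_factory=dict)

    @property
    def pulse_times(self) -> np.ndarray:
        return np.array([p.time for p in self.pulse_records])

    def series(self, species: str) -> np.ndarray:
        return self.states[:, _IDX[species]]

    def window(self, t0: float, t1: float, species: str = "CTS"):
        """(times, values) with t0 <= t < t1."""
        m = (self.times >= t0) & (self.times < t1)
        return self.times[m], self.series(species)[m]

    def day_mean(self, day: int, species: str = "CTS") -> float:
        """Mean concentration over simulation day `day` (1-based)."""
        _, v = self.window((day - 1) * 1440.0, day * 1440.0, species)
        if v.size == 0:
            raise ValueError(f"day {day} not covered by trajectory")
        return float(v.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_min": self.times})
        df["clock"] = [minutes_to_clock(t) for t in self.times]
        for name in SPECIES:
            df[name] = self.series(name)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, scenario: ScenarioConfig | None = None) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        times = df["time_min"].to_numpy(float)
        states = np.column_stack([df[name].to_numpy(float) for name in SPECIES])
        if scenario is None:
            scenario = ScenarioConfig(
                condition="custom", t_start=float(times[0]), t_end=float(times[-1]) + 1e-9
            )
        return cls(times=times, states=states, scenario=scenario)


class SolverError(RuntimeError):
    """Integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:.6g} min)")
        self.last_time = last_time


def _segment_grid(t0: float, t1: float, dt: float) -> np.ndarray:
    """Output times in (t0, t1]: the multiples of dt plus the segment end."""
    first = np.floor(t0 / dt + 1e-9) + 1
    pts = np.arange(first, t1 / dt - 1e-9, 1.0) * dt
    return np.concatenate([pts, [t1]])


def integrate(scenario: ScenarioConfig) -> Trajectory:
    """Integrate a scenario, applying scheduled pulses by stop-and-restart.

    Output is dense (<= `output_dt` minute spacing plus all event times).
    The state recorded at an event time is the pre-pulse state; the post-pulse
    values are kept in the trajectory's pulse records.
    """
    sc = scenario
    k = dict(RATE_CONSTANTS)
    if sc.rate_constants:
        k.update(sc.rate_constants)
    kvec = _kvec(k)
    kvec[2] *= sc.k2_multiplier  # forcing factor supplied per-call below
    forcing = sc.forcing

    def f(t, y):
        return _rhs_raw(y, kvec, circadian_drive(t, forcing))

    def jac(t, y):
        return _jac_raw(y, kvec)

    rtol = max(sc.rtol, _RTOL_FLOOR)
    # events outside the integration span are simply not applied
    events = [e for e in sc.schedule.events if sc.t_start < e.time < sc.t_end]
    bounds: list[tuple[float, PulseEvent | None]] = [(e.time, e) for e in events]
    bounds.append((sc.t_end, None))

    times: list[float] = [sc.t_start]
    states: list[np.ndarray] = [sc.initial_state.concentrations.copy()]
    records: list[PulseRecord] = []
    y = sc.initial_state.concentrations.copy()
    tcur = sc.t_start
    nfev = 0
    for t_stop, event in bounds:
        t_eval = _segment_grid(tcur, t_stop, sc.output_dt)
        sol = solve_ivp(
            f, (tcur, t_stop), y, method=sc.method, rtol=rtol, atol=sc.atol,
            t_eval=t_eval, jac=jac,
        )
        if not sol.success:
            raise SolverError(f"solver failed: {sol.message}", tcur)
        if not np.all(np.isfinite(sol.y)):
            raise SolverError("non-finite state encountered", tcur)
        nfev += sol.nfev
        times.extend(sol.t.tolist())
        seg = sol.y.T
        states.extend(seg)
        y = seg[-1].copy()
        tcur = t_stop
        if event is not None:
            i = _IDX[event.species]
            pre = y[i]
            y[i] += event.increment
            records.append(
                PulseRecord(event.time, event.species, event.increment, pre, y[i])
            )

    T = np.array(times)
    Y = np.array(states)
    Y[np.abs(Y) < 1e-30] = 0.0  # floor solver dust at exact zero
    return Trajectory(
        times=T,
        states=Y,
        scenario=sc,
        pulse_records=tuple(records),
        solver_stats={"nfev": nfev, "n_pulses": len(records), "rtol_used": rtol},
    )


def find_fixed_point_and_stability(
    rate_constants: Mapping[str, float] | None = None,
    frozen_D: float | None = None,
    guess: SpeciesState | np.ndarray | None = None,
    k2_multiplier: float = 1.0,
):
    """Steady state of the autonomous system with the forcing frozen at `frozen_D`.

    Returns (steady_state: SpeciesState, eigenvalues of the analytic Jacobian
    at the root).  With the default rate constants and the period-mean drive the root
    is an unstable focus, which is what sustains the ultradian oscillations.
    Default `frozen_D` is the mean of D over one period; default guess is the
    standard initial condition relaxed for two days.
    """
    k = dict(RATE_CONSTANTS)
    if rate_constants:
        k.update(rate_constants)
    if frozen_D is None:
        frozen_D = float(np.mean(circadian_drive(np.arange(1440.0))))
    if frozen_D <= 0:
        raise ValueError("frozen_D must be positive")
    kvec = _kvec(k)
    kvec[2] *= k2_multiplier * frozen_D

    if guess is None:
        relax = replace(
            ScenarioConfig(condition="custom", t_end=2 * 1440.0, k2_multiplier=k2_multiplier),
            atol=FAST_TOLERANCES[0], rtol=FAST_TOLERANCES[1], method=FAST_TOLERANCES[2],
        )
        # freeze the forcing for the relaxation run too
        frozen = ForcingParams(d1=frozen_D + DEFAULT_FORCING.offset_coefficient
                               * DEFAULT_FORCING.d2, d2=DEFAULT_FORCING.d2,
                               sine_amplitude=0.0, rectified_amplitude=0.0)
        relax = replace(relax, forcing=frozen, k2_multiplier=1.0,
                        rate_constants={**k, "k2": k["k2"] * k2_multiplier})
        g = integrate(relax).states[-1]
    else:
        g = guess.concentrations if isinstance(guess, SpeciesState) else np.asarray(guess, float)

    fun = lambda y: _rhs_raw(y, kvec, 1.0)
    jac = lambda y: _jac_raw(y, kvec)
    sol = root(fun, g, jac=jac, method="hybr", tol=1e-30)
    y = sol.x
    # Newton polish to push the residual to rounding level
    for _ in range(5):
        y = y - np.linalg.solve(jac(y), fun(y))
    resid = np.abs(fun(y)).max()
    if resid > 1e-18:
        raise RuntimeError(f"fixed-point search did not converge (residual {resid:.3e})")
    eigvals = np.linalg.eigvals(jac(y))
    return SpeciesState(concentrations=np.maximum(y, 0.0)), eigvals
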