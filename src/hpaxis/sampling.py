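"""Synthetic blood-sampling and ELISA measurement emulator.

Generates "animal" corticosterone series from simulated trajectories using
the in-vivo sampling protocol: 31 samples of 50 uL over ~24 h in one of two
interval schedules anchored to the kindling window, assay noise as a
multiplicative log-normal with median 1 and a 4.1% coefficient of variation
(the inter-assay CV of the ELISA), and optional independent sample loss.
Log-normal noise keeps synthetic assay values positive and median-unbiased.

Schedule variant A: samples 1-23 hourly before kindling, 24-29 every 10 min
through the kindling window, 30-31 at 30-min intervals after.  Variant B:
sample 1 at 50 min before kindling, 2-7 every 10 min through kindling,
8-31 hourly after.  The kindling window defaults to 21:12-22:02 on day 2.
The clock anchor of variant A's first sample is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import CORTICOSTERONE_MOLAR_MASS, molar_to_ng_per_ml
from .simulate import Trajectory, clock_to_minutes, minutes_to_clock

__all__ = [
    "SamplingSchedule",
    "NoiseModel",
    "SampledSeries",
    "make_schedule",
    "sample_trajectory",
    "make_cohort",
    "cohort_to_frame",
]

SAMPLE_VOLUME_UL = 50.0
N_SAMPLES = 31


@dataclass(frozen=True)
class SamplingSchedule:
    """Blood-draw times (minutes since 00:00 day 1) for one 24 h experiment."""

    variant: str
    sample_times: np.ndarray
    kindle_start: float
    per_sample_volume_ul: float = SAMPLE_VOLUME_UL

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.variant in {"A", "B"} and t.size != N_SAMPLES:
            raise ValueError(f"standard variants contain exactly {N_SAMPLES} samples")
        object.__setattr__(self, "sample_times", t)

    def __len__(self) -> int:
        return len(self.sample_times)

    @property
    def total_volume_ul(self) -> float:
        return len(self) * self.per_sample_volume_ul

    def relative_times(self) -> np.ndarray:
        """Times relative to kindling start (min)."""
        return self.sample_times - self.kindle_start


def make_schedule(
    variant: str,
    kindle_start_clock: str = "21:12",
    kindle_day: int = 2,
    kindle_duration_min: float = 50.0,
) -> SamplingSchedule:
    """Build one of the two standard 31-sample schedules around the kindling window."""
    ks = clock_to_minutes(kindle_start_clock, day=kindle_day)
    during = ks + np.arange(0.0, kindle_duration_min + 1e-9, 10.0)  # 6 samples
    if variant == "A":
        before = ks + np.arange(-23.0, 0.0) * 60.0  # samples 1-23, hourly
        after = during[-1] + np.array([30.0, 60.0])  # samples 30-31
        times = np.concatenate([before, during, after])
    elif variant == "B":
        first = np.array([ks - 50.0])  # sample 1
        after = during[-1] + 60.0 * np.arange(1.0, 25.0)  # samples 8-31, hourly
        times = np.concatenate([first, during, after])
    else:
        raise ValueError(f"unknown schedule variant {variant!r} (use 'A' or 'B')")
    return SamplingSchedule(variant=variant, sample_times=times, kindle_start=ks)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal assay noise, median 1, CV = cv."""

    cv: float = 0.041
    seed: int = 0
    missingness_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if not (0 <= self.missingness_prob < 1):
            raise ValueError("missingness_prob must be in [0, 1)")

    @property
    def sigma(self) -> float:
        """Log-scale SD giving the requested CV: cv^2 = exp(sigma^2) - 1."""
        return float(np.sqrt(np.log1p(self.cv**2)))

    def draw_factors(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.ones(n)
        return rng.lognormal(mean=0.0, sigma=self.sigma, size=n)


@dataclass(frozen=True)
class SampledSeries:
    """One synthetic animal's corticosterone measurements (ng/mL).

    Lost samples keep their schedule slot with value NaN, so the schedule
    length is invariant under missingness.
    """

    animal_id: str
    group: str
    times: np.ndarray
    values: np.ndarray  # ng/mL; NaN where the sample was lost
    schedule: SamplingSchedule
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if np.any(v[~np.isnan(v)] < 0):
            raise ValueError("present values must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def present(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~np.isnan(self.values)
        return self.times[m], self.values[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal_id": self.animal_id,
            "group": self.group,
            "time_min": self.times,
            "clock": [minutes_to_clock(t) for t in self.times],
            "value_ng_ml": self.values,
            "missing": np.isnan(self.values),
        })


def sample_trajectory(
    traj: Trajectory,
    schedule: SamplingSchedule,
    noise: NoiseModel,
    molar_mass: float = CORTICOSTERONE_MOLAR_MASS,
    animal_id: str = "animal-0",
    group: str = "control",
    rng: np.random.Generator | None = None,
) -> SampledSeries:
    """Measure simulated corticosterone through the sampling + assay model.

    value_i = CTS(t_i) converted to ng/mL, times an i.i.d. log-normal factor
    (median 1, CV = noise.cv); each sample is lost independently with
    probability noise.missingness_prob.  Deterministic given noise.seed.
    """
    t = schedule.sample_times
    lo, hi = traj.times[0], traj.times[-1]
    bad = t[(t < lo) | (t > hi)]
    if bad.size:
        raise ValueError(
            f"schedule time {bad[0]:.6g} min outside trajectory span [{lo:.6g}, {hi:.6g}]"
        )
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    true_ng_ml = molar_to_ng_per_ml(
        np.interp(t, traj.times, traj.series("CTS")), molar_mass
    )
    values = true_ng_ml * noise.draw_factors(t.size, rng)
    if noise.missingness_prob > 0:
        lost = rng.random(t.size) < noise.missingness_prob
        values = np.where(lost, np.nan, values)
    return SampledSeries(
        animal_id=animal_id, group=group, times=t.copy(), values=values,
        schedule=schedule, seed=noise.seed,
    )


def make_cohort(
    trajectories: Mapping[str, Trajectory],
    n_per_group: Mapping[str, int] | int = 4,
    schedule: SamplingSchedule | Mapping[str, SamplingSchedule] | None = None,
    noise: NoiseModel = NoiseModel(),
    master_seed: int = 0,
    molar_mass: float = CORTICOSTERONE_MOLAR_MASS,
) -> list[SampledSeries]:
    """Sample a multi-animal cohort from per-group trajectories.

    `trajectories` maps group name (e.g. control/sham/kindled) to the
    simulated trajectory for that condition.  Per-animal seeds are spawned
    deterministically from `master_seed`, so cohort regeneration with the
    same master seed is bit-identical.  Inter-animal variability comes from
    the assay noise; systematic inter-individual differences can be emulated
    upstream by jittering k2_multiplier between the input trajectories.
    """
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in trajectories}
    if schedule is None:
        schedule = make_schedule("B")
    series: list[SampledSeries] = []
    ss = np.random.SeedSequence(master_seed)
    for group in trajectories:  # insertion order: deterministic
        n = n_per_group.get(group, 0)
        if n < 1:
            raise ValueError(f"need at least one animal in group {group!r}")
        sched = schedule[group] if isinstance(schedule, Mapping) else schedule
        for i, child in enumerate(ss.spawn(n)):
            seed = int(child.generate_state(1)[0] % (2**31))
            series.append(
                sample_trajectory(
                    trajectories[group], sched, replace(noise, seed=seed),
                    molar_mass=molar_mass,
                    animal_id=f"{group}-{i + 1}", group=group,
                )
            )
    return series


def cohort_to_frame(cohort: Sequence[SampledSeries]) -> pd.DataFrame:
    """Tidy long-format table of a cohort (round-trips via CSV)."""
    return pd.concat([s.to_frame() for s in cohort], ignore_index=True)
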