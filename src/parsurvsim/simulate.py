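"""Synthetic single-arm trial simulation with staggered accrual.

The data-generating process emulates an event-driven oncology-style trial:

* a ground-truth population of ``pop_size`` individuals, each with an
  enrollment time drawn uniformly on [1, T1] days (staggered accrual) and
  an event time drawn from an exponential distribution with constant
  hazard ``lambda12`` per day, measured from enrollment;
* study samples of size ``n_obs`` drawn without replacement from the
  population, independently for each Monte-Carlo repetition;
* administrative censoring of each sample at the calendar time when a
  target proportion ``p_e`` of the sample has had its event.  Individuals
  not yet enrolled at that calendar time are excluded, everyone else is
  either observed (event before the cut) or censored at the cut, and the
  clock is reset to enrollment for analysis.

Reproducibility: all randomness flows from a single master seed through
per-repetition ``numpy`` seed sequences, so any repetition can be
regenerated in isolation and results do not depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np
import yaml

__all__ = [
    "ScenarioConfig",
    "Population",
    "CensoredDataset",
    "SCENARIO_PRESETS",
    "scenario_preset",
    "generate_population",
    "draw_sample",
    "censor_time_for_proportion",
    "apply_administrative_censoring",
    "build_dataset_grid",
    "population_rng",
    "repetition_rng",
]

_DEFAULT_N_OBS = (30, 60, 90, 120, 250, 500)
_DEFAULT_PE = tuple(round(0.1 * i, 1) for i in range(1, 11))

#: days per month used to convert the accrual window; the generating
#: process itself works purely in days.
DAYS_PER_MONTH = 30


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation scenario.

    Parameters
    ----------
    lambda12 : float
        Constant event hazard per day (transition healthy -> dead).
    t1_max : float
        Maximum accrual time in days; enrollment is Uniform(1, t1_max).
    pop_size : int
        Number of individuals in the ground-truth population.
    n_sim : int
        Number of Monte-Carlo repetitions.
    n_obs_levels : tuple of int
        Sample sizes drawn from the population, strictly increasing.
    pe_levels : tuple of float
        Event-proportion levels in (0, 1] at which each sample is
        administratively censored; strictly increasing, last equal to 1.
    seed : int
        Master RNG seed.
    b_ci : int
        Number of multivariate-normal parameter draws for interval
        estimates and plausibility checks.
    truth_source : {"population_fit", "theoretical"}
        Whether population truth values come from an exponential fit to
        the complete population or from the closed forms at ``lambda12``.
    """

    lambda12: float = 0.0025
    t1_max: float = 9 * DAYS_PER_MONTH
    pop_size: int = 50_000
    n_sim: int = 5_000
    n_obs_levels: tuple = _DEFAULT_N_OBS
    pe_levels: tuple = _DEFAULT_PE
    seed: int = 20211218
    b_ci: int = 1000
    truth_source: str = "population_fit"

    def __post_init__(self):
        if self.lambda12 <= 0:
            raise ValueError("lambda12 must be positive")
        if self.t1_max < 1:
            raise ValueError("t1_max must be at least 1 day")
        n_obs = tuple(int(n) for n in self.n_obs_levels)
        pe = tuple(float(p) for p in self.pe_levels)
        if any(b <= a for a, b in zip(n_obs, n_obs[1:])) or not n_obs:
            raise ValueError("n_obs_levels must be non-empty, strictly increasing")
        if any(b <= a for a, b in zip(pe, pe[1:])) or not pe:
            raise ValueError("pe_levels must be non-empty, strictly increasing")
        if not 0 < pe[0] or abs(pe[-1] - 1.0) > 1e-12:
            raise ValueError("pe_levels must lie in (0, 1] with last level 1.0")
        if self.pop_size < n_obs[-1]:
            raise ValueError("pop_size must be at least max(n_obs_levels)")
        if self.n_sim < 1:
            raise ValueError("n_sim must be positive")
        if self.truth_source not in ("population_fit", "theoretical"):
            raise ValueError("truth_source must be population_fit or theoretical")
        object.__setattr__(self, "n_obs_levels", n_obs)
        object.__setattr__(self, "pe_levels", pe)

    @property
    def n_datasets(self) -> int:
        return self.n_sim * len(self.n_obs_levels) * len(self.pe_levels)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


#: the four study scenarios: short/long accrual x high/low event rate
SCENARIO_PRESETS = {
    1: dict(lambda12=0.0025, t1_max=9 * DAYS_PER_MONTH),
    2: dict(lambda12=0.0025, t1_max=30 * DAYS_PER_MONTH),
    3: dict(lambda12=0.00075, t1_max=9 * DAYS_PER_MONTH),
    4: dict(lambda12=0.00075, t1_max=30 * DAYS_PER_MONTH),
}


def scenario_preset(scenario: int, **overrides) -> ScenarioConfig:
    """One of the four bundled scenario configurations."""
    if scenario not in SCENARIO_PRESETS:
        raise ValueError(f"scenario must be one of {sorted(SCENARIO_PRESETS)}")
    kw = dict(SCENARIO_PRESETS[scenario])
    kw.update(overrides)
    return ScenarioConfig(**kw)


@dataclass
class Population:
    """Ground-truth cohort with known enrollment and event times (days)."""

    enroll_times: np.ndarray  # days from study start
    event_times: np.ndarray  # days from enrollment
    true_rate: float  # hazard per day

    @property
    def size(self) -> int:
        return self.enroll_times.size

    @property
    def calendar_event_times(self) -> np.ndarray:
        return self.enroll_times + self.event_times

    @property
    def max_event_calendar_time(self) -> float:
        return float(np.max(self.calendar_event_times))

    @property
    def max_event_time(self) -> float:
        """Largest event time (from enrollment) in the population."""
        return float(np.max(self.event_times))


@dataclass
class CensoredDataset:
    """One analyzable sample: times from enrollment plus event indicators."""

    times: np.ndarray
    events: np.ndarray
    rep: int
    n_obs: int
    pe: float
    censor_calendar_time: float

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(np.sum(self.events))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "time": self.times,
                "event": self.events.astype(int),
                "rep": self.rep,
                "n_obs": self.n_obs,
                "pe": self.pe,
            }
        )


def population_rng(config: ScenarioConfig) -> np.random.Generator:
    """Dedicated stream for the ground-truth population."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0,))
    )


def repetition_rng(config: ScenarioConfig, rep: int) -> np.random.Generator:
    """Stream for repetition ``rep``, reproducible in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, rep))
    )


def generate_population(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> Population:
    """Draw the ground-truth cohort for a scenario.

    Enrollment times are continuous Uniform(1, t1_max) days from study
    start; event times are Exponential(rate=lambda12) days from
    enrollment.
    """
    if rng is None:
        rng = population_rng(config)
    enroll = rng.uniform(1.0, config.t1_max, size=config.pop_size)
    event = rng.exponential(1.0 / config.lambda12, size=config.pop_size)
    return Population(
        enroll_times=enroll, event_times=event, true_rate=config.lambda12
    )


def draw_sample(
    pop: Population, n_obs: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a uniform without-replacement sample of size ``n_obs``."""
    if n_obs > pop.size:
        raise ValueError(f"n_obs={n_obs} exceeds population size {pop.size}")
    return rng.choice(pop.size, size=n_obs, replace=False)


def censor_time_for_proportion(
    enrolls: np.ndarray, events: np.ndarray, pe: float
) -> float:
    """Calendar time at which a proportion ``pe`` of the sample has events.

    Returns the calendar time (enrollment + event time) of the
    ``ceil(pe * n)``-th smallest calendar event; ties resolve to the value
    of that order statistic.
    """
    enrolls = np.asarray(enrolls, dtype=float)
    events = np.asarray(events, dtype=float)
    if enrolls.size == 0:
        raise ValueError("empty sample")
    if not 0 < pe <= 1:
        raise ValueError("pe must lie in (0, 1]")
    n = enrolls.size
    rank = math.ceil(pe * n)  # 1-based
    calendar = np.sort(enrolls + events)
    return float(calendar[rank - 1])


def apply_administrative_censoring(
    enrolls: np.ndarray,
    events: np.ndarray,
    censor_calendar_time: float,
    rep: int = 0,
    n_obs: int | None = None,
    pe: float = float("nan"),
) -> CensoredDataset:
    """Truncate a complete sample at a calendar cut-off.

    Individuals enrolled at or after the cut-off have not entered the
    study and are excluded (analyses early in accrual can therefore use
    fewer than ``n_obs`` subjects).  For the rest, the event is observed
    if it falls before the cut-off, otherwise follow-up is censored at
    ``cut - enrollment``.  Times are measured from enrollment.
    """
    enrolls = np.asarray(enrolls, dtype=float)
    events = np.asarray(events, dtype=float)
    c = float(censor_calendar_time)
    accrued = enrolls < c
    if not accrued.any():
        raise ValueError("censoring time precedes every enrollment")
    enr, ev = enrolls[accrued], events[accrued]
    observed = enr + ev <= c
    times = np.where(observed, ev, c - enr)
    return CensoredDataset(
        times=times,
        events=observed.astype(np.int8),
        rep=rep,
        n_obs=n_obs if n_obs is not None else enrolls.size,
        pe=pe,
        censor_calendar_time=c,
    )


def build_dataset_grid(pop: Population, config: ScenarioConfig):
    """Yield all censored datasets of the simulation grid.

    For each repetition and sample size one complete sample is drawn; the
    ten follow-up levels are nested artificial censorings of that same
    sample, so increasing ``p_e`` never shortens any individual's
    follow-up.
    """
    for rep in range(config.n_sim):
        rng = repetition_rng(config, rep)
        for n_obs in config.n_obs_levels:
            idx = draw_sample(pop, n_obs, rng)
            enr = pop.enroll_times[idx]
            ev = pop.event_times[idx]
            for pe in config.pe_levels:
                c = censor_time_for_proportion(enr, ev, pe)
                yield apply_administrative_censoring(
                    enr, ev, c, rep=rep, n_obs=n_obs, pe=pe
                )
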