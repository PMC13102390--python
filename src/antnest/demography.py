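"""Colony demography: ant records, colony timelines, and synthetic generators.

A colony is a single queen plus workers that eclose (emerge from pupae) over
time. Two kinds of timeline mirror the two experimental designs the model is
meant for:

* ``maturation`` -- a colony founded by a lone queen whose worker population
  grows logistically and saturates at a carrying capacity of 5-20 workers
  over roughly 190 days.
* ``fixed`` -- a group of fixed size (5, 10 or 15 ants including the queen)
  whose workers all belong to one age cohort, either "young"
  (40 +/- 16 days) or "old" (171.56 +/- 20 days).

Ages are measured in days since eclosion; a negative ``eclosion_day`` means
the ant emerged before the experiment started (all workers of a fixed group,
and every queen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

QUEEN = "queen"
WORKER = "worker"

#: Age threshold separating functionally "young" from "old" workers, in days.
#: Defined as mean + sd of the young cohort age distribution: 40 + 16 = 56.
YOUNG_COHORT = (40.0, 16.0)
OLD_COHORT = (171.56, 20.0)


@dataclass(frozen=True)
class AntRecord:
    """One ant. ``death_day`` of ``None`` means alive for the whole record."""

    id: str
    caste: str
    eclosion_day: float
    death_day: float | None = None

    def __post_init__(self) -> None:
        if self.caste not in (QUEEN, WORKER):
            raise ValueError(f"unknown caste {self.caste!r}")
        if self.death_day is not None and self.death_day <= self.eclosion_day:
            raise ValueError("death_day must be after eclosion_day")

    def age(self, day: float) -> float:
        return day - self.eclosion_day

    def present(self, day: float) -> bool:
        """Counted in the colony on ``day``: already eclosed, not yet dead."""
        if day < self.eclosion_day:
            return False
        return self.death_day is None or day < self.death_day


@dataclass(frozen=True)
class PopulationParams:
    """Logistic worker-population growth.

    N(t) = K / (1 + ((K - N0)/N0) exp(-rho (t - t_first))) for t >= t_first,
    and 0 workers before the first emergence day ``t_first``.
    """

    K: float
    rho: float = 0.05
    t_first: float = 30.0
    N0: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("carrying capacity K must be >= 1")
        if self.rho <= 0:
            raise ValueError("growth rate rho must be > 0")
        if not 0 < self.N0 <= self.K:
            raise ValueError("N0 must be in (0, K]")


def logistic_population(t, p: PopulationParams):
    """Expected worker count at day(s) ``t``; 0 before ``p.t_first``."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        n = p.K / (1.0 + ((p.K - p.N0) / p.N0) * np.exp(-p.rho * (t - p.t_first)))
    n = np.where(t < p.t_first, 0.0, n)
    return n if n.ndim else float(n)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-colony generators.

    The defaults are the study conditions: worker saturation between 5 and 20
    ants over ~190 days, 5% multiplicative observation noise on measured
    areas, photography every 1-3 days, young cohort 40 +/- 16 d and old
    cohort 171.56 +/- 20 d, and a 10-day maturation delay before a newly
    eclosed worker starts digging.
    """

    seed: int = 0
    K_range: tuple[int, int] = (5, 20)
    obs_noise_sd_frac: float = 0.05
    young_age: tuple[float, float] = YOUNG_COHORT
    old_age: tuple[float, float] = OLD_COHORT
    maturation_delay: float = 10.0
    rho: float = 0.05
    t_first: float = 30.0
    N0: float = 1.0
    queen_eclosion_day: float = -365.0
    duration_days: float = 190.0
    fixed_duration_days: float = 45.0
    sampling_gaps: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if self.obs_noise_sd_frac < 0:
            raise ValueError("noise sd must be >= 0")
        for mean, sd in (self.young_age, self.old_age):
            if sd < 0:
                raise ValueError("cohort age sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ColonyTimeline:
    """Colony membership over an experiment, plus its observation schedule."""

    ants: list[AntRecord]
    duration_days: float
    kind: str  # "maturation" | "fixed"
    sampling_days: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.kind not in ("maturation", "fixed"):
            raise ValueError(f"unknown timeline kind {self.kind!r}")
        self.sampling_days = np.asarray(self.sampling_days, dtype=float)
        if self.sampling_days.size:
            if np.any(np.diff(self.sampling_days) <= 0):
                raise ValueError("sampling_days must be strictly increasing")
            if self.sampling_days[0] < 0 or self.sampling_days[-1] > self.duration_days:
                raise ValueError("sampling_days outside [0, duration_days]")
        if sum(1 for a in self.ants if a.caste == QUEEN) > 1:
            raise ValueError("at most one queen per colony")

    @property
    def queen(self) -> AntRecord | None:
        for a in self.ants:
            if a.caste == QUEEN:
                return a
        return None

    @property
    def workers(self) -> list[AntRecord]:
        return [a for a in self.ants if a.caste == WORKER]

    @property
    def first_worker_day(self) -> float:
        """Day the first worker is present (0 if workers predate the start)."""
        if not self.workers:
            raise ValueError("timeline has no workers")
        return max(0.0, min(w.eclosion_day for w in self.workers))

    def population(self, day) -> np.ndarray | int:
        """Number of ants (queen included) present on ``day``."""
        day = np.asarray(day, dtype=float)
        counts = np.zeros(day.shape, dtype=int)
        for a in self.ants:
            alive = day >= a.eclosion_day
            if a.death_day is not None:
                alive &= day < a.death_day
            counts += alive
        return counts if counts.ndim else int(counts)


def ages_at(timeline: ColonyTimeline, day: float) -> list[tuple[str, float, str]]:
    """(id, age, caste) for every ant present on ``day``."""
    if not 0 <= day <= timeline.duration_days:
        raise ValueError("day outside timeline duration")
    return [(a.id, a.age(day), a.caste) for a in timeline.ants if a.present(day)]


def young_old_threshold(mean_age: float, sd_age: float) -> float:
    """Age threshold between young and old workers: cohort mean + sd (days)."""
    if sd_age < 0:
        raise ValueError("sd must be >= 0")
    return mean_age + sd_age


def sampling_schedule(duration: float, rng: np.random.Generator,
                      gaps: tuple[int, int] = (1, 3)) -> np.ndarray:
    """Observation days 0, ... with gaps drawn uniformly from ``gaps`` (days)."""
    days = [0.0]
    while days[-1] < duration:
        days.append(days[-1] + rng.integers(gaps[0], gaps[1] + 1))
    if days[-1] > duration:
        days[-1] = float(duration)
        if days[-1] - days[-2] < 1:  # keep strictly increasing, sane gap
            days.pop(-2)
    return np.array(days)


def worker_emergence_days(p: PopulationParams, duration: float) -> list[int]:
    """Days (integer grid) on which the rounded logistic expectation increments.

    Deterministic given the parameters; the j-th worker emerges on the first
    day where round(N(t)) >= j.
    """
    days: list[int] = []
    prev = 0
    for t in range(0, int(math.ceil(duration)) + 1):
        n = int(np.rint(logistic_population(float(t), p)))
        days.extend([t] * (n - prev))
        prev = max(prev, n)
    return days


def synth_maturation_colony(config: GeneratorConfig, K: int | None = None,
                            rng: np.random.Generator | None = None) -> ColonyTimeline:
    """Synthesize a colony-maturation timeline.

    The queen predates the experiment (``config.queen_eclosion_day``); workers
    emerge deterministically on the days the rounded logistic expectation
    increments, saturating at a carrying capacity ``K`` drawn uniformly from
    ``config.K_range`` when not given.
    """
    rng = config.rng() if rng is None else rng
    lo, hi = config.K_range
    if K is None:
        K = int(rng.integers(lo, hi + 1))
    elif not lo <= K <= hi:
        raise ValueError(f"K={K} outside configured range {config.K_range}")
    p = PopulationParams(K=K, rho=config.rho, t_first=config.t_first, N0=config.N0)
    ants = [AntRecord("queen", QUEEN, config.queen_eclosion_day)]
    for j, day in enumerate(worker_emergence_days(p, config.duration_days), start=1):
        ants.append(AntRecord(f"w{j:03d}", WORKER, float(day)))
    days = sampling_schedule(config.duration_days, rng, config.sampling_gaps)
    return ColonyTimeline(ants, config.duration_days, "maturation", days)


def _truncated_normal(mean: float, sd: float, n: int, rng: np.random.Generator,
                      lower: float = 1.0) -> np.ndarray:
    """Normal draws truncated (by rejection) at ``lower``; degenerate sd=0 ok."""
    if sd == 0:
        if mean < lower:
            raise ValueError("degenerate cohort age below truncation bound")
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[draw >= lower]
        take = min(draw.size, n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def synth_fixed_colony(group_size: int, cohort: str,
                       config: GeneratorConfig,
                       rng: np.random.Generator | None = None,
                       age_sd: float | None = None) -> ColonyTimeline:
    """Synthesize a fixed-demographics group: queen + (group_size - 1) workers
    of one age cohort ("young" or "old"), all present from day 0.
    """
    if group_size < 2:
        raise ValueError("group_size must include the queen and >= 1 worker")
    if cohort == "young":
        mean, sd = config.young_age
    elif cohort == "old":
        mean, sd = config.old_age
    else:
        raise ValueError(f"unknown cohort {cohort!r} (use 'young' or 'old')")
    if age_sd is not None:
        sd = age_sd
    rng = config.rng() if rng is None else rng
    ages = _truncated_normal(mean, sd, group_size - 1, rng)
    ants = [AntRecord("queen", QUEEN, config.queen_eclosion_day)]
    ants += [AntRecord(f"w{j:03d}", WORKER, -float(a)) for j, a in enumerate(ages, 1)]
    days = sampling_schedule(config.fixed_duration_days, rng, config.sampling_gaps)
    return ColonyTimeline(ants, config.fixed_duration_days, "fixed", days)


# ---------------------------------------------------------------------------
# File formats

def write_timeline_csv(timeline: ColonyTimeline, path) -> None:
    df = pd.DataFrame(
        {
            "ant_id": [a.id for a in timeline.ants],
            "caste": [a.caste for a in timeline.ants],
            "eclosion_day": [a.eclosion_day for a in timeline.ants],
            "death_day": [a.death_day for a in timeline.ants],
        }
    )
    df.to_csv(path, index=False)


def read_timeline_csv(path, duration_days: float | None = None,
                      kind: str = "maturation") -> ColonyTimeline:
    """Read ``ant_id, caste, eclosion_day, death_day`` (blank = alive)."""
    df = pd.read_csv(path)
    required = {"ant_id", "caste", "eclosion_day"}
    if not required.issubset(df.columns):
        raise ValueError(f"timeline file missing columns {required - set(df.columns)}")
    ants = []
    for row in df.itertuples(index=False):
        death = getattr(row, "death_day", None)
        death = None if death is None or pd.isna(death) else float(death)
        ants.append(AntRecord(str(row.ant_id), str(row.caste),
                              float(row.eclosion_day), death))
    if duration_days is None:
        duration_days = max(190.0, max(a.eclosion_day for a in ants))
    return ColonyTimeline(ants, duration_days, kind)


def with_sampling(timeline: ColonyTimeline, days) -> ColonyTimeline:
    return replace(timeline, sampling_days=np.asarray(days, dtype=float))
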