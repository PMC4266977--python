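"""Seeded generators of complete synthetic decay experiments.

The generator emulates the structure of a destructive-sampling decay
experiment on a velvet-worm-like animal: each specimen decays in its own
sealed container and is dissected once, at a day drawn from a
logarithmically spaced schedule.  For each specimen x character pair two
latent times are drawn — onset of decay T1 and complete loss T2 = T1 +
duration — from region-specific lognormal distributions, scaled by a
specimen-level multiplicative frailty.  The observed 3-state condition at
the specimen's sampling day d is then

    pristine  if d < T1,    decaying  if T1 <= d < T2,    lost  if d >= T2.

Internal organs get the fastest defaults (onset within the first couple of
days, total loss by roughly day 8-12), cuticular regions are slower, and
sclerotised characters (jaws, terminal claws) are immune and stay pristine
at every day.  Morphometric drift is generated as a saturating linear trend
in percent change (trunk dimensions drifting 10-30%, limbs 10-25%) with
Gaussian measurement noise.  All generators are deterministic under a fixed
seed and return a truth record alongside the observable tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import (
    DECAYING,
    LOST,
    METRICS,
    PRISTINE,
    CharacterDefinition,
    DecayScoreMatrix,
    MeasurementTable,
    SamplingSchedule,
    ValidationError,
)

__all__ = [
    "RegionTiming",
    "MetricDrift",
    "DecaySimConfig",
    "MorphoSimConfig",
    "default_characters",
    "simulate_experiment",
    "simulate_measurements",
    "simulate_rank_pairs",
    "DEFAULT_SCHEDULE",
]

#: 14-point logarithmically spaced schedule: dense early sampling captures
#: the rapid initial decay, sparse late sampling the slow tail.
DEFAULT_SCHEDULE = SamplingSchedule((0, 1, 2, 3, 5, 8, 12, 19, 30, 47, 73, 113, 176, 273))


def default_characters() -> list[CharacterDefinition]:
    """A velvet-worm-like character set spanning the five body regions."""
    spec = [
        # internal organs: fastest decay
        ("gut", "gut and gut contents", "internal"),
        ("slime_glands", "slime glands", "internal"),
        ("salivary_glands", "salivary glands", "internal"),
        ("nerve_cords", "ventral nerve cords", "internal"),
        ("musculature", "body-wall musculature", "internal"),
        ("reproductive_organs", "reproductive organs", "internal"),
        # anterior
        ("antennae", "antennae", "anterior"),
        ("eyes", "eyes", "anterior"),
        ("mouth", "mouth position and shape", "anterior"),
        ("slime_papillae", "slime papillae", "anterior"),
        ("jaws", "sclerotised jaws", "anterior"),
        ("head_outline", "head outline", "anterior"),
        # trunk
        ("outer_cuticle", "outer cuticle", "trunk"),
        ("epidermis", "epidermis", "trunk"),
        ("pigment", "pigment granules", "trunk"),
        ("dermal_papillae", "dermal papillae", "trunk"),
        ("body_outline", "trunk outline", "trunk"),
        # limbs
        ("limb_outline", "lobopod outline", "limbs"),
        ("terminal_claws", "terminal claws", "limbs"),
        ("foot_pads", "foot pads", "limbs"),
        ("limb_spines", "limb spines", "limbs"),
        # posterior
        ("anal_cone", "anal cone", "posterior"),
        ("genital_pad", "genital pad", "posterior"),
        ("posterior_outline", "posterior outline", "posterior"),
    ]
    return [CharacterDefinition(*row) for row in spec]


@dataclass(frozen=True)
class RegionTiming:
    """Lognormal parameters for one region's decay timing (days).

    ``median_onset`` is the median day of onset of decay; ``median_duration``
    the median decaying-to-lost interval; sigmas are lognormal shape
    parameters (log-scale standard deviations).
    """

    median_onset: float
    sigma_onset: float
    median_duration: float
    sigma_duration: float

    def __post_init__(self) -> None:
        if min(self.median_onset, self.median_duration) <= 0:
            raise ValidationError("timing medians must be > 0")
        if min(self.sigma_onset, self.sigma_duration) < 0:
            raise ValidationError("sigmas must be >= 0")


#: Region timing defaults reproduce the canonical ordering of decay:
#: internal organs first (onset within days, total loss by ~day 8-12),
#: then anterior/trunk cuticular characters, with limbs and posterior
#: slowest among the decaying regions.
DEFAULT_REGION_TIMING: dict[str, RegionTiming] = {
    "internal": RegionTiming(1.5, 0.45, 6.0, 0.35),
    "anterior": RegionTiming(12.0, 0.45, 95.0, 0.45),
    "trunk": RegionTiming(14.0, 0.45, 110.0, 0.45),
    "limbs": RegionTiming(20.0, 0.45, 125.0, 0.45),
    "posterior": RegionTiming(18.0, 0.45, 115.0, 0.45),
}

#: Characters that never decay within the experiment (sclerotised parts).
DEFAULT_IMMUNE = frozenset({"jaws", "terminal_claws"})


@dataclass
class DecaySimConfig:
    """Configuration of a synthetic destructive-sampling decay experiment."""

    seed: int = 0
    n_specimens: int = 54
    schedule: SamplingSchedule = DEFAULT_SCHEDULE
    characters: list[CharacterDefinition] = field(default_factory=default_characters)
    region_timing: dict[str, RegionTiming] = field(
        default_factory=lambda: dict(DEFAULT_REGION_TIMING)
    )
    immune_characters: frozenset[str] = DEFAULT_IMMUNE
    frailty_sigma: float = 0.25  # lognormal sd of the specimen-level multiplier

    def __post_init__(self) -> None:
        if self.n_specimens < len(self.schedule):
            raise ValidationError(
                "need at least one specimen per sampling day "
                f"({self.n_specimens} specimens, {len(self.schedule)} days)"
            )
        regions = {c.body_region for c in self.characters}
        missing = regions - set(self.region_timing)
        if missing:
            raise ValidationError(f"no timing parameters for regions {sorted(missing)}")
        if self.frailty_sigma < 0:
            raise ValidationError("frailty_sigma must be >= 0")


@dataclass(frozen=True)
class MetricDrift:
    """True drift of one metric: slope (% per day) saturating at an asymptote."""

    slope: float  # % per day
    asymptote: float  # %


#: Drift defaults: trunk dimensions drift toward 10-30% change, limb
#: dimensions toward 10-25%, with saturation after the first few weeks.
DEFAULT_METRIC_DRIFT: dict[str, MetricDrift] = {
    "body_length": MetricDrift(0.9, 20.0),
    "body_width_outer": MetricDrift(1.1, 24.0),
    "body_width_inner": MetricDrift(0.7, 13.0),
    "limb_length": MetricDrift(0.8, 17.0),
    "limb_width_outer": MetricDrift(0.7, 13.0),
    "limb_width_inner": MetricDrift(0.9, 20.0),
}

#: Nominal adult dimensions (mm) used as values at death.
_BASE_VALUE = {
    "body_length": 40.0,
    "body_width_outer": 5.0,
    "body_width_inner": 4.2,
    "limb_length": 3.0,
    "limb_width_outer": 1.2,
    "limb_width_inner": 1.0,
}


@dataclass
class MorphoSimConfig:
    """Configuration of synthetic morphometric drift measurements."""

    seed: int = 0
    drift: dict[str, MetricDrift] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_DRIFT)
    )
    noise_sd: float = 4.0  # Gaussian measurement noise, percent points
    n_per_day: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        unknown = set(self.drift) - set(METRICS)
        if unknown:
            raise ValidationError(f"unknown metrics in drift config: {sorted(unknown)}")


def _assign_days(n_specimens: int, schedule: SamplingSchedule) -> list[int]:
    """Spread specimens evenly across the schedule, round-robin."""
    days = list(schedule.days)
    return [days[i % len(days)] for i in range(n_specimens)]


def simulate_experiment(
    config: DecaySimConfig,
) -> tuple[DecayScoreMatrix, pd.DataFrame]:
    """Draw one synthetic experiment; returns (score matrix, truth record).

    The truth record retains, per specimen x character, the latent onset and
    loss times and the specimen frailty, so tests can verify that observed
    conditions are consistent with the latent process.
    """
    rng = np.random.default_rng(config.seed)
    region_of = {c.character_id: c.body_region for c in config.characters}
    sample_day = _assign_days(config.n_specimens, config.schedule)
    rows, truth = [], []
    for i in range(config.n_specimens):
        specimen = f"sp{i + 1:03d}"
        day = sample_day[i]
        frailty = float(np.exp(rng.normal(0.0, config.frailty_sigma)))
        for char in config.characters:
            cid = char.character_id
            if cid in config.immune_characters:
                t1 = t2 = math.inf
                condition = PRISTINE
            else:
                timing = config.region_timing[region_of[cid]]
                t1 = frailty * float(
                    rng.lognormal(math.log(timing.median_onset), timing.sigma_onset)
                )
                dur = frailty * float(
                    rng.lognormal(
                        math.log(timing.median_duration), timing.sigma_duration
                    )
                )
                t2 = t1 + dur
                condition = (
                    PRISTINE if day < t1 else DECAYING if day < t2 else LOST
                )
            rows.append(
                {
                    "specimen_id": specimen,
                    "character_id": cid,
                    "day": day,
                    "condition": condition,
                }
            )
            truth.append(
                {
                    "specimen_id": specimen,
                    "character_id": cid,
                    "day": day,
                    "frailty": frailty,
                    "t_onset": t1,
                    "t_loss": t2,
                }
            )
    matrix = DecayScoreMatrix(
        schedule=config.schedule,
        characters=list(config.characters),
        records=pd.DataFrame(rows),
    )
    return matrix, pd.DataFrame(truth)


def simulate_measurements(
    config: MorphoSimConfig, schedule: SamplingSchedule = DEFAULT_SCHEDULE
) -> tuple[MeasurementTable, pd.DataFrame]:
    """Synthetic morphometric table; returns (table, truth record).

    For each metric and day, ``n_per_day`` specimens are measured with true
    change min(slope * day, asymptote) percent plus Gaussian noise:
    value_at_day = value_at_death * (1 + (change + noise)/100).
    """
    rng = np.random.default_rng(config.seed)
    rows, truth = [], []
    counter = 0
    for metric in METRICS:
        if metric not in config.drift:
            continue
        d = config.drift[metric]
        base = _BASE_VALUE[metric]
        for day in schedule.days:
            true_change = min(d.slope * day, d.asymptote)
            for _ in range(config.n_per_day):
                counter += 1
                specimen = f"m{counter:04d}"
                value_at_death = base * float(np.exp(rng.normal(0.0, 0.10)))
                noise = float(rng.normal(0.0, config.noise_sd))
                value_at_day = value_at_death * (1.0 + (true_change + noise) / 100.0)
                rows.append(
                    {
                        "specimen_id": specimen,
                        "day": day,
                        "metric": metric,
                        "value_at_death": value_at_death,
                        "value_at_day": value_at_day,
                    }
                )
                truth.append(
                    {
                        "specimen_id": specimen,
                        "day": day,
                        "metric": metric,
                        "true_change": true_change,
                        "noise": noise,
                    }
                )
    return MeasurementTable(records=pd.DataFrame(rows)), pd.DataFrame(truth)


def simulate_rank_pairs(
    n: int, rho: float, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rank pair with a given latent (Gaussian) correlation, for calibration.

    Draws a bivariate normal sample with correlation ``rho`` and returns the
    midranks of each margin — a null (rho=0) or power (rho!=0) testbed for
    the slippage correlation test.
    """
    if n < 3:
        raise ValidationError(f"need n >= 3, got {n}")
    if not -1 <= rho <= 1:
        raise ValidationError(f"rho must lie in [-1, 1], got {rho}")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    if abs(rho) == 1.0:
        y = rho * x
    else:
        y = rho * x + math.sqrt(1.0 - rho * rho) * rng.normal(size=n)
    return rankdata(x), rankdata(y)
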