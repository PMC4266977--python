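"""Aggregation of specimen scores into ordinal decay trajectories and ranks.

Specimen-level 3-state condition codes are pooled across the specimens
sampled on one day into a 5-state ordinal character condition:

    0 = pristine           (all specimens pristine)
    1 = onset of decay     (some decaying, none lost, some still pristine)
    2 = complete decay     (all decaying-or-worse, none lost)
    3 = onset of loss      (some but not all lost)
    4 = complete loss      (all lost)

Milestones are the first sampled day at which a character's aggregated
series reaches each ordinal state, and the decay-rank table orders
characters from most decay-prone (rank 1) to most decay-resistant using a
four-key tie-break: time of complete loss, then onset of loss, then complete
decay, then onset of decay, with never-reached milestones (censored) sorting
after every finite day.  Residual full-tuple ties receive midranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .datamodel import (
    CENSORED,
    DECAYING,
    LOST,
    NOT_SCORED,
    PRISTINE,
    DecayScoreMatrix,
    DecayStageScheme,
    ValidationError,
)

__all__ = [
    "AggregatedStateSeries",
    "MilestoneTimes",
    "DecayRankTable",
    "aggregate_character_state",
    "aggregate_series",
    "milestone_times",
    "decay_rank_table",
    "assign_decay_stage",
]


@dataclass(frozen=True)
class AggregatedStateSeries:
    """Per-character ordinal (0-4) decay state at each sampled day."""

    character_id: str
    days: tuple[int, ...]
    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.states):
            raise ValidationError("days and states must be parallel")
        if any(s not in (0, 1, 2, 3, 4) for s in self.states):
            raise ValidationError("aggregated states must lie in 0..4")

    @property
    def is_monotone(self) -> bool:
        """Destructive sampling can yield non-monotone series; flag those."""
        return all(b >= a for a, b in zip(self.states, self.states[1:]))


@dataclass(frozen=True)
class MilestoneTimes:
    """First sampled day at which each ordinal state is reached (or censored).

    ``CENSORED`` (+inf) marks a milestone never reached within the
    experiment's duration.
    """

    character_id: str
    t_onset_decay: float
    t_complete_decay: float
    t_onset_loss: float
    t_complete_loss: float

    def key(self) -> tuple[float, float, float, float]:
        """Ranking key: complete loss, onset of loss, complete decay, onset."""
        return (
            self.t_complete_loss,
            self.t_onset_loss,
            self.t_complete_decay,
            self.t_onset_decay,
        )


@dataclass(frozen=True)
class DecayRankTable:
    """Characters ordered most decay-prone (rank 1) to most resistant.

    ``ranks`` holds midranks of the total preorder induced by the milestone
    key tuples; ``tie_groups`` numbers the groups of exactly tied characters
    (1 = most decay-prone group).
    """

    ranks: dict[str, float]
    tie_groups: dict[str, int] = field(default_factory=dict)

    @property
    def character_ids(self) -> list[str]:
        return sorted(self.ranks, key=lambda c: (self.ranks[c], c))


def aggregate_character_state(
    matrix: DecayScoreMatrix, character_id: str, day: int
) -> int | None:
    """Pool specimen conditions for one character on one day into state 0-4.

    Returns ``None`` when no specimen was scored for that character on that
    day (the day is then omitted from the series).
    """
    rec = matrix.records
    sub = rec.loc[
        (rec["character_id"] == character_id)
        & (rec["day"] == int(day))
        & (rec["condition"] != NOT_SCORED),
        "condition",
    ]
    return _pool_conditions(sub.to_numpy())


def _pool_conditions(conditions: np.ndarray) -> int | None:
    if conditions.size == 0:
        return None
    n_lost = int((conditions == LOST).sum())
    n_pristine = int((conditions == PRISTINE).sum())
    if n_lost == conditions.size:
        return 4
    if n_lost > 0:
        return 3
    if n_pristine == conditions.size:
        return 0
    if n_pristine == 0:
        return 2
    return 1


def aggregate_series(matrix: DecayScoreMatrix) -> list[AggregatedStateSeries]:
    """Build the aggregated 0-4 series for every character in the matrix."""
    rec = matrix.records.loc[matrix.records["condition"] != NOT_SCORED]
    pooled = (
        rec.groupby(["character_id", "day"])["condition"]
        .agg(lambda s: _pool_conditions(s.to_numpy()))
        .reset_index()
    )
    out = []
    for char in matrix.character_ids:
        sub = pooled.loc[pooled["character_id"] == char].sort_values("day")
        if not len(sub):
            continue
        out.append(
            AggregatedStateSeries(
                character_id=char,
                days=tuple(int(d) for d in sub["day"]),
                states=tuple(int(s) for s in sub["condition"]),
            )
        )
    return out


def milestone_times(series: AggregatedStateSeries) -> MilestoneTimes:
    """First attainment time of each ordinal state (``>=`` the state).

    Using first attainment of *at least* the state means a series that jumps
    over a state between samplings (e.g. 1 -> 3) still yields the skipped
    milestone.  Non-monotone series (possible under destructive sampling) are
    scanned as-is; first attainment is well defined regardless.
    """
    if not series.days:
        raise ValidationError(f"empty series for character {series.character_id!r}")
    times = []
    for threshold in (1, 2, 3, 4):
        t = CENSORED
        for day, state in zip(series.days, series.states):
            if state >= threshold:
                t = float(day)
                break
        times.append(t)
    return MilestoneTimes(series.character_id, *times)


def decay_rank_table(milestones: list[MilestoneTimes]) -> DecayRankTable:
    """Rank characters by the four-key milestone tuple, midranking full ties.

    Censored milestones (+inf) sort after all finite days at every tie-break
    level; a censored-vs-censored comparison at one level falls through to
    the next key.  Ranks are invariant to the input order of characters.
    """
    if len(milestones) < 2:
        raise ValidationError("need at least 2 characters to rank")
    chars = [m.character_id for m in milestones]
    if len(set(chars)) != len(chars):
        raise ValidationError("duplicate character ids in milestone list")
    keys = [m.key() for m in milestones]
    # midranks over the lexicographic total preorder: rank each key column and
    # combine via a stable encoding of the distinct sorted tuples
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    codes = np.empty(len(keys), dtype=float)
    code = 0
    prev = None
    for idx in order:
        if keys[idx] != prev:
            code += 1
            prev = keys[idx]
        codes[idx] = code
    ranks = rankdata(codes, method="average")
    tie_group = {chars[i]: int(codes[i]) for i in range(len(chars))}
    return DecayRankTable(
        ranks={chars[i]: float(ranks[i]) for i in range(len(chars))},
        tie_groups=tie_group,
    )


def assign_decay_stage(day: float, scheme: DecayStageScheme | None = None) -> str:
    """Classify a day into a decay stage (half-open intervals, last open-ended)."""
    if scheme is None:
        scheme = DecayStageScheme()
    if day < 0:
        raise ValidationError(f"day must be non-negative, got {day}")
    b = scheme.boundaries
    for s in range(scheme.n_stages):
        if day < b[s + 1] or s == scheme.n_stages - 1:
            return scheme.stage_labels[s]
    raise AssertionError("unreachable")  # pragma: no cover
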