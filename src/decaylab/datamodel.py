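"""Domain types shared by every stage of the decay-analysis pipeline.

The central objects model a destructive-sampling decay experiment: each
specimen is dissected once, at a single sampling day, and every anatomical
character is scored with a three-state condition code (pristine / decaying /
lost).  Characters carry a body-region label (anterior, trunk, limbs,
posterior, internal) used by the trajectory statistics, and phylogenetic
hypotheses assign characters to nodes on the root-to-focal-terminal path of
a rooted tree for the stemward-slippage tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "BODY_REGIONS",
    "PRISTINE",
    "DECAYING",
    "LOST",
    "NOT_SCORED",
    "CONDITION_TOKENS",
    "CONDITION_NAMES",
    "METRICS",
    "CENSORED",
    "CharacterDefinition",
    "SamplingSchedule",
    "DecayScoreMatrix",
    "MeasurementTable",
    "PhyloHypothesis",
    "DecayStageScheme",
    "ValidationError",
]

#: Closed set of body-region labels used to categorise characters.
BODY_REGIONS = ("anterior", "trunk", "limbs", "posterior", "internal")

#: Specimen-level condition codes.
PRISTINE, DECAYING, LOST = 0, 1, 2

#: Marker for a character that could not be assessed on a given specimen;
#: such records are excluded from aggregation.
NOT_SCORED = -1

CONDITION_TOKENS = {
    "pristine": PRISTINE,
    "decaying": DECAYING,
    "lost": LOST,
    "not_scored": NOT_SCORED,
    "0": PRISTINE,
    "1": DECAYING,
    "2": LOST,
    "-1": NOT_SCORED,
}

CONDITION_NAMES = {
    PRISTINE: "pristine",
    DECAYING: "decaying",
    LOST: "lost",
    NOT_SCORED: "not_scored",
}

#: The six morphometric metrics (body and limb; lengths and inner/outer widths).
METRICS = (
    "body_length",
    "body_width_outer",
    "body_width_inner",
    "limb_length",
    "limb_width_outer",
    "limb_width_inner",
)

#: Sentinel for a decay milestone never reached within the experiment.
#: Sorts after every finite day, which is exactly the ranking semantics.
CENSORED = math.inf


class ValidationError(ValueError):
    """Raised when an input table or tree violates a domain invariant."""


@dataclass(frozen=True)
class CharacterDefinition:
    """One anatomical character: a short id, free-text label, body region."""

    character_id: str
    label: str
    body_region: str

    def __post_init__(self) -> None:
        if not self.character_id:
            raise ValidationError("character_id must be a non-empty token")
        if self.body_region not in BODY_REGIONS:
            raise ValidationError(
                f"character {self.character_id!r}: body_region {self.body_region!r} "
                f"not in {BODY_REGIONS}"
            )


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered sampling days of a destructive-sampling design (day 0 = death)."""

    days: tuple[int, ...]

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        object.__setattr__(self, "days", days)
        if not days:
            raise ValidationError("schedule must contain at least one day")
        if any(d < 0 for d in days):
            raise ValidationError("sampling days must be non-negative")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("sampling days must be strictly increasing")
        if days[0] > 2:
            raise ValidationError(
                "schedule must start at day 0 or within the first 2 days "
                f"(got first day {days[0]})"
            )

    def __len__(self) -> int:
        return len(self.days)

    def __iter__(self):
        return iter(self.days)


@dataclass
class DecayScoreMatrix:
    """Specimen-level condition codes over characters and sampling days.

    ``records`` is a tidy table with columns ``specimen_id``, ``character_id``,
    ``day`` and ``condition``; validation enforces the destructive-sampling
    design (each specimen appears at exactly one day), known character ids,
    condition codes from the closed set, and that within a sampling day every
    specimen was scored for the same character set.
    """

    schedule: SamplingSchedule
    characters: list[CharacterDefinition]
    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"specimen_id", "character_id", "day", "condition"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValidationError(f"records table missing columns: {sorted(missing)}")
        rec = self.records.copy()
        rec["specimen_id"] = rec["specimen_id"].astype(str)
        rec["character_id"] = rec["character_id"].astype(str)
        rec["day"] = rec["day"].astype(int)
        rec["condition"] = rec["condition"].astype(int)
        self.records = rec.reset_index(drop=True)

        ids = [c.character_id for c in self.characters]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate character ids: {dupes}")
        known = set(ids)
        bad_chars = rec.loc[~rec["character_id"].isin(known)]
        if len(bad_chars):
            row = bad_chars.iloc[0]
            raise ValidationError(
                f"unknown character_id {row['character_id']!r} "
                f"(specimen {row['specimen_id']!r}, day {row['day']})"
            )

        bad_cond = rec.loc[~rec["condition"].isin([PRISTINE, DECAYING, LOST, NOT_SCORED])]
        if len(bad_cond):
            row = bad_cond.iloc[0]
            raise ValidationError(
                f"condition code {row['condition']} outside the allowed set "
                f"(specimen {row['specimen_id']!r}, character {row['character_id']!r})"
            )

        days_per_specimen = rec.groupby("specimen_id")["day"].nunique()
        multi = days_per_specimen[days_per_specimen > 1]
        if len(multi):
            raise ValidationError(
                f"specimen {multi.index[0]!r} scored at {multi.iloc[0]} different days; "
                "destructive sampling allows exactly one sampling day per specimen"
            )

        sched_days = set(self.schedule.days)
        off = set(rec["day"].unique()) - sched_days
        if off:
            raise ValidationError(f"days {sorted(off)} not in the sampling schedule")

        dup = rec.duplicated(subset=["specimen_id", "character_id"])
        if dup.any():
            row = rec.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicate record for specimen {row['specimen_id']!r}, "
                f"character {row['character_id']!r}"
            )

        # within a day, all specimens must cover the same character set
        for day, sub in rec.groupby("day"):
            sets = sub.groupby("specimen_id")["character_id"].agg(frozenset)
            if sets.nunique() > 1:
                raise ValidationError(
                    f"day {day}: specimens scored for differing character sets"
                )

    @property
    def character_ids(self) -> list[str]:
        return [c.character_id for c in self.characters]

    @property
    def characters_by_id(self) -> dict[str, CharacterDefinition]:
        return {c.character_id: c for c in self.characters}

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(sorted(self.records["day"].unique()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, DecayScoreMatrix):
            return NotImplemented
        key = ["specimen_id", "character_id"]
        a = self.records.sort_values(key).reset_index(drop=True)
        b = other.records.sort_values(key).reset_index(drop=True)
        return (
            self.schedule == other.schedule
            and self.characters == other.characters
            and a.equals(b[a.columns])
        )


@dataclass
class MeasurementTable:
    """Per-specimen morphometric values at death and at the sampling day."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"specimen_id", "day", "metric", "value_at_death", "value_at_day"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValidationError(f"measurement table missing columns: {sorted(missing)}")
        rec = self.records.copy()
        rec["specimen_id"] = rec["specimen_id"].astype(str)
        rec["day"] = rec["day"].astype(int)
        rec["metric"] = rec["metric"].astype(str)
        for col in ("value_at_death", "value_at_day"):
            rec[col] = rec[col].astype(float)
        self.records = rec.reset_index(drop=True)

        bad_metric = rec.loc[~rec["metric"].isin(METRICS)]
        if len(bad_metric):
            raise ValidationError(
                f"unknown metric {bad_metric.iloc[0]['metric']!r}; "
                f"expected one of {METRICS}"
            )
        nonpos = rec.loc[(rec["value_at_death"] <= 0) | (rec["value_at_day"] <= 0)]
        if len(nonpos):
            row = nonpos.iloc[0]
            raise ValidationError(
                f"non-positive measurement for specimen {row['specimen_id']!r}, "
                f"metric {row['metric']!r}"
            )
        if (rec["day"] < 0).any():
            raise ValidationError("measurement days must be non-negative")


@dataclass
class PhyloHypothesis:
    """A rooted tree with a focal terminal plus character-to-clade assignments.

    ``assignments`` maps each character to a labelled internal node that must
    lie on the root-to-focal-terminal path; ``contested`` supplies the
    alternative node used when a character of disputed homology is treated as
    a homoplasy rather than a homology.
    """

    hypothesis_id: str
    tree: dendropy.Tree
    focal_terminal: str
    assignments: dict[str, str]
    contested: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._path_nodes = self._focal_path_labels()
        on_path = set(self._path_nodes)
        for char, node in self.assignments.items():
            if node not in on_path:
                raise ValidationError(
                    f"hypothesis {self.hypothesis_id!r}: character {char!r} assigned "
                    f"to node {node!r}, which is not on the root-to-"
                    f"{self.focal_terminal!r} path"
                )
        extra = set(self.contested) - set(self.assignments)
        if extra:
            raise ValidationError(
                f"contested characters {sorted(extra)} lack a primary assignment"
            )
        for char, node in self.contested.items():
            if node not in on_path:
                raise ValidationError(
                    f"hypothesis {self.hypothesis_id!r}: alternative node {node!r} "
                    f"for character {char!r} is not on the focal path"
                )

    def _focal_path_labels(self) -> list[str]:
        """Labels of ancestors of the focal terminal, tip-ward to root-ward."""
        leaf = None
        for node in self.tree.leaf_node_iter():
            if node.taxon is not None and node.taxon.label == self.focal_terminal:
                leaf = node
                break
        if leaf is None:
            raise ValidationError(
                f"focal terminal {self.focal_terminal!r} not found in tree "
                f"{self.hypothesis_id!r}"
            )
        labels: list[str] = []
        node = leaf.parent_node
        while node is not None:
            label = node.label if node.label else (
                node.taxon.label if node.taxon else None
            )
            if label:
                labels.append(label)
            node = node.parent_node
        return labels

    def path_depths(self) -> dict[str, int]:
        """Edge distance from each labelled on-path node down to the focal tip.

        The parent of the focal terminal (the least-inclusive clade containing
        it) has depth 1; depths increase root-ward.  Unlabelled on-path nodes
        are not assignable and are skipped without consuming a depth.
        """
        return {label: i + 1 for i, label in enumerate(self._path_nodes)}

    def node_depth(self, node_label: str) -> int:
        return self.path_depths()[node_label]


@dataclass(frozen=True)
class DecayStageScheme:
    """Day boundaries delimiting ordinal decay stages; last stage open-ended.

    The default reproduces the five-stage scheme for *Euperipatoides rowelli*
    (stage 1: days 0-2, ..., stage 5: days 109-220+), with half-open
    ``[start, end)`` intervals and stage 5 extending beyond the nominal end.
    """

    boundaries: tuple[float, ...] = (0, 2, 8, 34, 109, 220)
    stage_labels: tuple[str, ...] = ("1", "2", "3", "4", "5")

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.boundaries, self.boundaries[1:])):
            raise ValidationError("stage boundaries must be strictly increasing")
        if len(self.stage_labels) != len(self.boundaries) - 1:
            raise ValidationError(
                "need exactly one stage label per boundary interval "
                f"({len(self.boundaries) - 1} intervals, "
                f"{len(self.stage_labels)} labels)"
            )
        if self.boundaries[0] != 0:
            raise ValidationError("first stage must start at day 0")

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)
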