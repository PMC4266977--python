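"""Readers and writers for score tables, measurement tables and hypothesis files.

Tables are plain delimited text (CSV or TSV, chosen by file extension) with a
header row; trees are Newick with labelled internal nodes.  Downstream result
objects can be serialised to JSON or TSV via :func:`write_json` /
:func:`write_tsv`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Iterable, Mapping

import dendropy
import pandas as pd

from .datamodel import (
    CONDITION_NAMES,
    CONDITION_TOKENS,
    CharacterDefinition,
    DecayScoreMatrix,
    MeasurementTable,
    PhyloHypothesis,
    SamplingSchedule,
    ValidationError,
)

__all__ = [
    "read_characters",
    "write_characters",
    "read_decay_scores",
    "write_decay_scores",
    "read_measurements",
    "write_measurements",
    "read_hypothesis",
    "write_hypothesis",
    "write_json",
    "write_tsv",
]


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_characters(path: str | Path) -> list[CharacterDefinition]:
    """Read character metadata (``character_id``, ``label``, ``body_region``)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    req = {"character_id", "body_region"}
    missing = req - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if "label" not in df.columns:
        df["label"] = df["character_id"]
    return [
        CharacterDefinition(
            character_id=row["character_id"],
            label=row.get("label") or row["character_id"],
            body_region=str(row["body_region"]).strip().lower(),
        )
        for _, row in df.iterrows()
    ]


def write_characters(characters: Iterable[CharacterDefinition], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(c) for c in characters])
    df.to_csv(path, sep=_sep_for(path), index=False)


def _parse_condition(token: Any, line_no: int, path: str | Path) -> int:
    key = str(token).strip().lower()
    if key not in CONDITION_TOKENS:
        raise ValidationError(
            f"{path}, data row {line_no}: condition token {token!r} is not one of "
            f"{sorted(set(CONDITION_TOKENS))}"
        )
    return CONDITION_TOKENS[key]


def read_decay_scores(path: str | Path, characters_path: str | Path) -> DecayScoreMatrix:
    """Read a specimen-level score table plus its character metadata.

    The score table needs columns ``specimen_id``, ``character_id``, ``day``
    and ``condition``; condition accepts numeric codes {0,1,2} or the tokens
    pristine/decaying/lost (case-insensitive), plus ``not_scored`` for
    characters that could not be assessed.  The sampling schedule is inferred
    from the distinct days present.
    """
    characters = read_characters(characters_path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    req = {"specimen_id", "character_id", "day", "condition"}
    missing = req - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    df = df.copy()
    df["condition"] = [
        _parse_condition(tok, i + 2, path)  # +2: header is line 1
        for i, tok in enumerate(df["condition"])
    ]
    df["day"] = df["day"].astype(int)
    schedule = SamplingSchedule(tuple(sorted(df["day"].unique())))
    return DecayScoreMatrix(schedule=schedule, characters=characters, records=df)


def write_decay_scores(
    matrix: DecayScoreMatrix,
    path: str | Path,
    characters_path: str | Path | None = None,
    numeric: bool = False,
) -> None:
    """Write a score table (and optionally its character metadata)."""
    rec = matrix.records.copy()
    if not numeric:
        rec["condition"] = rec["condition"].map(CONDITION_NAMES)
    rec.to_csv(path, sep=_sep_for(path), index=False)
    if characters_path is not None:
        write_characters(matrix.characters, characters_path)


def read_measurements(path: str | Path) -> MeasurementTable:
    df = pd.read_csv(path, sep=_sep_for(path))
    return MeasurementTable(records=df)


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    table.records.to_csv(path, sep=_sep_for(path), index=False)


def read_hypothesis(
    tree_path: str | Path,
    assignment_path: str | Path,
    focal_terminal: str,
    hypothesis_id: str | None = None,
) -> PhyloHypothesis:
    """Read a rooted Newick tree and a character-to-node assignment table.

    The assignment table has columns ``character_id``, ``node_id`` and an
    optional ``alternative_node_id`` giving the node used under the
    homoplasy treatment for contested characters.  All referenced nodes must
    be labelled internal nodes on the root-to-focal-terminal path.
    """
    tree = dendropy.Tree.get(
        path=str(tree_path),
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="default-rooted",
    )
    df = pd.read_csv(assignment_path, sep=_sep_for(assignment_path), dtype=str)
    req = {"character_id", "node_id"}
    missing = req - set(df.columns)
    if missing:
        raise ValidationError(f"{assignment_path}: missing columns {sorted(missing)}")
    assignments = dict(zip(df["character_id"], df["node_id"]))
    contested: dict[str, str] = {}
    if "alternative_node_id" in df.columns:
        for _, row in df.iterrows():
            alt = row["alternative_node_id"]
            if isinstance(alt, str) and alt.strip():
                contested[row["character_id"]] = alt.strip()
    return PhyloHypothesis(
        hypothesis_id=hypothesis_id or Path(tree_path).stem,
        tree=tree,
        focal_terminal=focal_terminal,
        assignments=assignments,
        contested=contested,
    )


def write_hypothesis(
    hypothesis: PhyloHypothesis, tree_path: str | Path, assignment_path: str | Path
) -> None:
    hypothesis.tree.write(
        path=str(tree_path), schema="newick", suppress_rooting=True
    )
    rows = []
    for char, node in hypothesis.assignments.items():
        rows.append(
            {
                "character_id": char,
                "node_id": node,
                "alternative_node_id": hypothesis.contested.get(char, ""),
            }
        )
    pd.DataFrame(rows).to_csv(assignment_path, sep=_sep_for(assignment_path), index=False)


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float):
        if math.isinf(obj):
            return "censored" if obj > 0 else "-inf"
        if math.isnan(obj):
            return None
        return obj
    if hasattr(obj, "item"):  # numpy scalar
        return _jsonify(obj.item())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    """Serialise a result object (dataclass, mapping, frame) to pretty JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tsv(records: Iterable[Mapping[str, Any]] | pd.DataFrame, path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)
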