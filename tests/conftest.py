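"""Shared fixtures: tiny hand-built experiments and toy trees."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import decaylab as dl
from decaylab.datamodel import CharacterDefinition, DecayScoreMatrix, SamplingSchedule
from decaylab.simulate import RegionTiming


@pytest.fixture
def toy_characters() -> list[CharacterDefinition]:
    return [
        CharacterDefinition("gut", "gut", "internal"),
        CharacterDefinition("cuticle", "outer cuticle", "trunk"),
        CharacterDefinition("jaws", "sclerotised jaws", "anterior"),
    ]


@pytest.fixture
def toy_matrix(toy_characters) -> DecayScoreMatrix:
    """Two specimens per day at days 2 and 8; gut decays fast, jaws never."""
    rows = []
    conditions = {
        # (character, day) -> conditions of the two specimens sampled that day
        ("gut", 2): (1, 2),
        ("gut", 8): (2, 2),
        ("cuticle", 2): (0, 1),
        ("cuticle", 8): (1, 1),
        ("jaws", 2): (0, 0),
        ("jaws", 8): (0, 0),
    }
    for day, specimens in ((2, ("s1", "s2")), (8, ("s3", "s4"))):
        for char in ("gut", "cuticle", "jaws"):
            for i, sp in enumerate(specimens):
                rows.append(
                    {
                        "specimen_id": sp,
                        "character_id": char,
                        "day": day,
                        "condition": conditions[(char, day)][i],
                    }
                )
    return DecayScoreMatrix(
        schedule=SamplingSchedule((2, 8)),
        characters=toy_characters,
        records=pd.DataFrame(rows),
    )


def write_ladder_tree(tmp_path, name="hyp", n_internal=4, contested=None):
    """A ladder tree with n_internal labelled nodes on the root-focal path.

    Characters c1..c{n_internal} are assigned one per node, tip-ward to
    root-ward; ``contested`` maps character -> alternative node label.
    """
    labels = [f"n{i}" for i in range(1, n_internal + 1)]  # n1 tip-ward
    newick = "Focal"
    for i, lab in enumerate(labels):
        newick = f"({newick},T{i + 1}){lab}"
    tree_path = tmp_path / f"{name}.nwk"
    tree_path.write_text(newick + ";\n")
    rows = ["character_id,node_id,alternative_node_id"]
    contested = contested or {}
    for i, lab in enumerate(labels):
        char = f"c{i + 1}"
        rows.append(f"{char},{lab},{contested.get(char, '')}")
    assign_path = tmp_path / f"{name}_assign.csv"
    assign_path.write_text("\n".join(rows) + "\n")
    return tree_path, assign_path


@pytest.fixture
def calibration_timing() -> dict[str, RegionTiming]:
    """Internal organs far faster than all else; external regions identical."""
    external = RegionTiming(15.0, 0.45, 110.0, 0.45)
    return {
        "internal": RegionTiming(1.5, 0.45, 6.0, 0.35),
        "anterior": external,
        "trunk": external,
        "limbs": external,
        "posterior": external,
    }


def spearman_oracle(x, y):
    """Independent brute-force Spearman: midrank both, then Pearson."""
    from scipy.stats import pearsonr, rankdata

    return float(pearsonr(rankdata(x), rankdata(y))[0])
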