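"""Plain-text readers and writers for the pipeline's exchange formats.

Everything is TSV or Newick: a tip->family table (``tip_id\\tfamily``), a
halophyte name list (one name per line), a tip-state table
(``tip_id\\tstate``), and the family table consumed by the diversity
stage (``family\\torder\\tn_species\\tn_halophytes``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .diversity import FamilyRecord
from .phylo import tree_from_newick

__all__ = [
    "read_tree",
    "write_tree",
    "read_tip_family_table",
    "read_name_list",
    "read_states",
    "write_states",
    "write_family_table",
]


def read_tree(path) -> dendropy.Tree:
    return tree_from_newick(Path(path).read_text())


def write_tree(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", unquoted_underscores=True)
    )


def read_tip_family_table(path) -> dict:
    """tip_id -> family mapping from a two-column TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "tip_id" in cols and "family" in cols:
        df.columns = cols
    else:  # headerless
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["tip_id", "family"])
    return dict(zip(df["tip_id"], df["family"]))


def read_name_list(path) -> list[str]:
    """One name per line; blank lines and '#' comments ignored."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return names


def read_states(path) -> dict:
    """tip_id -> {0,1} from a TSV with columns tip_id, state."""
    df = pd.read_csv(path, sep="\t")
    if not {"tip_id", "state"}.issubset(df.columns):
        raise ValueError("states table needs columns tip_id, state")
    return {str(t): int(s) for t, s in zip(df["tip_id"], df["state"])}


def write_states(states: dict, path) -> None:
    pd.DataFrame(
        {"tip_id": list(states), "state": [int(v) for v in states.values()]}
    ).to_csv(path, sep="\t", index=False)


def write_family_table(records: Sequence[FamilyRecord] | Iterable[FamilyRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "family": r.family,
                "order": r.order,
                "n_species": r.n_species,
                "n_halophytes": r.k_halophytes,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
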