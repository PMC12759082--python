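"""Readers and writers for cell tables and lineage trees.

The cell table is UTF-8 tab-delimited with one header row and a fixed
column set; the canonical tree interchange format is a JSON document that
encodes every node field losslessly.  Newick is export-only, with the
per-node annotations (cell type, generation, theoretical intensity) carried
in bracketed comment blocks, because Newick cannot natively hold typed
per-node fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .types import (
    CellRecord,
    CellType,
    Clone,
    DivisionPattern,
    LineageNode,
    LineageTree,
)

__all__ = [
    "CELL_TABLE_COLUMNS",
    "read_cell_table",
    "write_cell_table",
    "read_tree",
    "write_tree",
    "tree_to_newick",
]

CELL_TABLE_COLUMNS = (
    "clone_id",
    "cell_id",
    "intensity",
    "x",
    "y",
    "z",
    "rel_radial_pos",
    "layer",
    "satb2",
    "ctip2",
    "fog2",
    "neuron_class",
    "apoptotic",
    "region",
)


class SchemaError(ValueError):
    """The file does not match the documented column schema."""


class IntegrityError(ValueError):
    """The file violates a content invariant (duplicates, bad values)."""


def read_cell_table(path: Union[str, Path]) -> list[Clone]:
    """Read a tab-delimited cell table into one Clone per clone id.

    Rows with nonpositive intensity are rejected with the offending row
    named; duplicate (clone_id, cell_id) pairs are an integrity error;
    unknown markers stay unknown.
    """

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    dupes = df.duplicated(subset=["clone_id", "cell_id"])
    if dupes.any():
        rows = (df.index[dupes] + 2).tolist()  # 1-based incl. header
        raise IntegrityError(f"{path}: duplicate (clone_id, cell_id) at rows {rows}")
    clones: dict[str, list[CellRecord]] = {}
    regions: dict[str, str] = {}
    for i, row in df.iterrows():
        try:
            intensity = float(row["intensity"])
        except ValueError as exc:
            raise IntegrityError(f"{path}: row {i + 2}: bad intensity") from exc
        if intensity <= 0:
            raise IntegrityError(
                f"{path}: row {i + 2} (cell {row['cell_id']}): "
                f"nonpositive intensity {intensity}"
            )
        pos_fields = [row["x"], row["y"], row["z"]]
        position = (
            np.array([float(v) for v in pos_fields])
            if all(v != "" for v in pos_fields)
            else None
        )
        record = CellRecord(
            clone_id=row["clone_id"],
            cell_id=row["cell_id"],
            intensity=intensity,
            position=position,
            rel_radial_pos=float(row["rel_radial_pos"])
            if row["rel_radial_pos"] != ""
            else float("nan"),
            layer=row["layer"] or "unknown",
            satb2=row["satb2"] or "?",
            ctip2=row["ctip2"] or "?",
            fog2=row["fog2"] or "?",
            neuron_class=row["neuron_class"] or "unknown",
            apoptotic=row["apoptotic"].lower() in ("true", "1", "yes"),
            region=row["region"] or "unknown",
        )
        clones.setdefault(record.clone_id, []).append(record)
        regions.setdefault(record.clone_id, record.region)
    return [
        Clone(clone_id=cid, cells=cells, region=regions[cid])
        for cid, cells in clones.items()
    ]


def write_cell_table(clones: Iterable[Clone], path: Union[str, Path]) -> None:
    """Write clones to the tab-delimited cell-table format."""

    rows = []
    for clone in clones:
        for c in clone.cells:
            pos = c.position if c.position is not None else ("", "", "")
            rows.append(
                {
                    "clone_id": c.clone_id,
                    "cell_id": c.cell_id,
                    "intensity": repr(float(c.intensity)),
                    "x": repr(float(pos[0])) if c.position is not None else "",
                    "y": repr(float(pos[1])) if c.position is not None else "",
                    "z": repr(float(pos[2])) if c.position is not None else "",
                    "rel_radial_pos": repr(float(c.rel_radial_pos))
                    if np.isfinite(c.rel_radial_pos)
                    else "",
                    "layer": c.layer,
                    "satb2": c.satb2,
                    "ctip2": c.ctip2,
                    "fog2": c.fog2,
                    "neuron_class": c.neuron_class,
                    "apoptotic": str(bool(c.apoptotic)),
                    "region": c.region,
                }
            )
    pd.DataFrame(rows, columns=list(CELL_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# tree formats
# ---------------------------------------------------------------------------


def _node_to_dict(node: LineageNode) -> dict:
    d = {
        "cell_type": node.cell_type.value,
        "theoretical_intensity": node.theoretical_intensity,
    }
    for name in ("hierarchy_index", "intensity", "generation"):
        value = getattr(node, name)
        if value is not None:
            d[name] = value
    for name in ("implicit_exit", "exit", "nn_terminal", "constrained"):
        if getattr(node, name):
            d[name] = True
    if node.source_pattern is not None:
        d["source_pattern"] = node.source_pattern.value
    if node.observed_cell is not None:
        d["observed_cell_id"] = node.observed_cell.cell_id
    if node.children:
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def _node_from_dict(d: dict) -> LineageNode:
    node = LineageNode(
        cell_type=CellType(d["cell_type"]),
        children=[_node_from_dict(c) for c in d.get("children", [])],
        hierarchy_index=d.get("hierarchy_index"),
        theoretical_intensity=d.get("theoretical_intensity", 1.0),
        intensity=d.get("intensity"),
        generation=d.get("generation"),
        implicit_exit=d.get("implicit_exit", False),
        exit=d.get("exit", False),
        nn_terminal=d.get("nn_terminal", False),
        constrained=d.get("constrained", False),
        source_pattern=DivisionPattern(d["source_pattern"])
        if "source_pattern" in d
        else None,
    )
    if "observed_cell_id" in d:
        node.observed_cell = CellRecord(
            clone_id="", cell_id=d["observed_cell_id"], intensity=1.0
        )
        node.observed_cell.clone_id = ""
    return node


def write_tree(
    tree: LineageTree, path: Union[str, Path], format: str = "json"
) -> None:
    """Write a lineage tree: lossless JSON (canonical) or annotated Newick."""

    tree.validate()
    path = Path(path)
    if format == "json":
        doc = {
            "clone_id": tree.clone_id,
            "generations": [
                [g, pat.value] for g, pat in tree.generations
            ],
            "root": _node_to_dict(tree.root),
        }
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    elif format == "newick":
        path.write_text(tree_to_newick(tree) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown tree format {format!r}")


def read_tree(path: Union[str, Path]) -> LineageTree:
    """Read a lineage tree from the canonical JSON format.

    Observed cells round-trip by id only; rejoin them to a cell table via
    the clone id when full records are needed.
    """

    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return LineageTree(
        root=_node_from_dict(doc["root"]),
        clone_id=doc.get("clone_id", ""),
        generations=[
            (int(g), DivisionPattern(p)) for g, p in doc.get("generations", [])
        ],
    )


def _newick_label(node: LineageNode) -> str:
    fields = [f"type={node.cell_type.value}"]
    if node.generation is not None:
        fields.append(f"generation={node.generation}")
    fields.append(f"theoretical_intensity={node.theoretical_intensity:g}")
    if node.observed_cell is not None:
        fields.append(f"cell={node.observed_cell.cell_id}")
    if node.exit:
        fields.append("exit=1")
    name = node.observed_cell.cell_id if node.observed_cell else node.cell_type.value
    # annotations ride in a bracketed comment block
    return f"{name}[&&{','.join(fields)}]"


def _newick_node(node: LineageNode) -> str:
    if node.is_leaf:
        return _newick_label(node)
    inner = ",".join(_newick_node(c) for c in node.children)
    return f"({inner}){_newick_label(node)}"


def tree_to_newick(tree: LineageTree) -> str:
    """Newick string with node annotations in comment blocks (export only)."""

    tree.validate()
    return _newick_node(tree.root) + ";"
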