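"""Shared domain types for clonal lineage analysis.

The vocabulary follows the dye-dilution lineage-tracing literature: radial
glial progenitors (RGP, symbol gamma) self-renew while producing either a
neuron directly (N division), a neurogenic intermediate progenitor (IP,
beta) that divides once into two neurons, or a proliferative intermediate
progenitor (IPP, alpha) that yields two IPs and hence four neurons.  A
lineage is stored as a binary tree whose internal nodes are progenitors and
whose observed leaves are neurons (kappa); dye intensity halves at every
division, so each node also carries a theoretical intensity expressed as a
fraction of the root intensity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "CellType",
    "DivisionPattern",
    "CellRecord",
    "Clone",
    "LineageNode",
    "LineageTree",
    "LAYERS",
    "NEURON_CLASSES",
    "MARKER_STATES",
]

#: Cortical layers recognised in cell tables (plus subplate and unknown).
LAYERS = ("L2/3", "L4", "L5", "L6", "SP", "unknown")

#: Excitatory projection-neuron classes callable from Satb2/Ctip2/Fog2.
NEURON_CLASSES = ("CPN", "SCPN", "CThPN", "HPN", "SPN", "unknown")

#: Ternary marker encoding used in cell tables.
MARKER_STATES = ("+", "-", "?")


class CellType(str, Enum):
    """The four node types of a lineage tree (field symbols in parens)."""

    RGP = "RGP"      # gamma: self-renewing radial glial progenitor
    IPP = "IPP"      # alpha: proliferative intermediate progenitor
    IP = "IP"        # beta: neurogenic intermediate progenitor
    NEURON = "NEURON"  # kappa: postmitotic pyramidal neuron

    @property
    def symbol(self) -> str:
        return {"RGP": "γ", "IPP": "α", "IP": "β", "NEURON": "κ"}[self.value]


class DivisionPattern(str, Enum):
    """What an RGP produced (besides its self-renewed copy) in one generation.

    N/IP/IPP are the three modelled asymmetric patterns.  NN_TERMINAL marks a
    self-consuming final division into two neurons, SYMMETRIC a
    progenitor-doubling division, and EXIT the RGP leaving the cell cycle.
    """

    N = "N"
    IP = "IP"
    IPP = "IPP"
    NN_TERMINAL = "NN_TERMINAL"
    SYMMETRIC = "SYMMETRIC"
    EXIT = "EXIT"


#: Patterns that appear in the 3-state transition matrix, in matrix order.
MARKOV_PATTERNS = (DivisionPattern.IPP, DivisionPattern.IP, DivisionPattern.N)

#: Neurons added to the clone by each asymmetric pattern.
PATTERN_NEURONS = {
    DivisionPattern.N: 1,
    DivisionPattern.IP: 2,
    DivisionPattern.IPP: 4,
    DivisionPattern.NN_TERMINAL: 2,
}


@dataclass
class CellRecord:
    """One observed labelled cell (a row of the cell table)."""

    clone_id: str
    cell_id: str
    intensity: float
    position: Optional[np.ndarray] = None  # (x, y, z) in micrometres
    rel_radial_pos: float = float("nan")   # 0 = pia, 1 = subplate
    layer: str = "unknown"
    satb2: str = "?"
    ctip2: str = "?"
    fog2: str = "?"
    neuron_class: str = "unknown"
    apoptotic: bool = False  # synthetic ground truth only
    region: str = "unknown"

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError(
                f"cell {self.clone_id}/{self.cell_id}: intensity must be "
                f"positive, got {self.intensity}"
            )
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        for name in ("satb2", "ctip2", "fog2"):
            if getattr(self, name) not in MARKER_STATES:
                raise ValueError(f"marker {name} must be one of {MARKER_STATES}")
        if self.neuron_class not in NEURON_CLASSES:
            raise ValueError(f"unknown neuron class {self.neuron_class!r}")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if self.position.shape != (3,):
                raise ValueError("position must be a 3-vector")


@dataclass
class Clone:
    """All observed cells sharing one clone id."""

    clone_id: str
    cells: list[CellRecord]
    region: str = "unknown"

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError(f"clone {self.clone_id}: needs at least one cell")
        for c in self.cells:
            if c.clone_id != self.clone_id:
                raise ValueError(
                    f"cell {c.cell_id} has clone_id {c.clone_id!r}, "
                    f"expected {self.clone_id!r}"
                )

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([c.intensity for c in self.cells])


_node_counter = itertools.count()


@dataclass
class LineageNode:
    """A node of a binary lineage tree.

    ``theoretical_intensity`` is the noiseless dye fraction (root = 1);
    ``intensity`` is the noisy synthetic measurement when assigned.
    ``exit`` marks the placeholder leaf for an RGP leaving the cycle;
    ``implicit_exit`` marks a progenitor inferred by singleton promotion
    during reconstruction (its unobserved sibling is the exiting RGP).
    """

    cell_type: CellType
    children: list["LineageNode"] = field(default_factory=list)
    node_id: int = field(default_factory=lambda: next(_node_counter))
    hierarchy_index: Optional[int] = None
    theoretical_intensity: float = 1.0
    intensity: Optional[float] = None
    generation: Optional[int] = None
    observed_cell: Optional[CellRecord] = None
    implicit_exit: bool = False
    exit: bool = False
    nn_terminal: bool = False
    # simulator ground truth:
    source_pattern: Optional[DivisionPattern] = None
    constrained: bool = False
    # synthetic observation annotations (neuron leaves only):
    position: Optional[np.ndarray] = None
    rel_radial_pos: Optional[float] = None
    layer: str = "unknown"
    neuron_class: str = "unknown"
    markers: tuple[str, str, str] = ("?", "?", "?")

    def __post_init__(self) -> None:
        if len(self.children) not in (0, 2):
            raise ValueError("lineage nodes have zero or exactly two children")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self) -> Iterator["LineageNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def copy(self) -> "LineageNode":
        new = replace(self, node_id=next(_node_counter))
        new.children = [c.copy() for c in self.children]
        return new


@dataclass
class LineageTree:
    """A clonal lineage: a binary tree plus its per-generation patterns.

    ``generations`` lists ``(generation index, DivisionPattern)`` along the
    RGP chain; the first labelled RGP's division is generation 1 and a final
    EXIT entry marks cycle exit (absent for self-consuming NN_TERMINAL ends).
    """

    root: LineageNode
    clone_id: str = ""
    generations: list[tuple[int, DivisionPattern]] = field(default_factory=list)

    @property
    def root_type(self) -> CellType:
        return self.root.cell_type

    def iter_nodes(self) -> Iterator[LineageNode]:
        return self.root.iter_nodes()

    def leaves(self) -> list[LineageNode]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    def neuron_leaves(self) -> list[LineageNode]:
        return [n for n in self.leaves() if n.cell_type is CellType.NEURON]

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_leaves())

    @property
    def n_generations(self) -> int:
        """Number of actual RGP-chain divisions (EXIT entry excluded)."""
        return sum(1 for _, p in self.generations if p is not DivisionPattern.EXIT)

    def copy(self) -> "LineageTree":
        return LineageTree(
            root=self.root.copy(),
            clone_id=self.clone_id,
            generations=list(self.generations),
        )

    def validate(self) -> None:
        """Check binary structure, acyclicity and intensity halving."""
        seen: set[int] = set()
        stack: list[LineageNode] = [self.root]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                raise ValueError("cyclic lineage tree structure")
            seen.add(id(node))
            for child in node.children:
                if not np.isclose(
                    child.theoretical_intensity,
                    node.theoretical_intensity / 2.0,
                ):
                    raise ValueError(
                        "child theoretical intensity must be half its parent's"
                    )
                stack.append(child)


def intensity_by_generation(tree: LineageTree) -> list[float]:
    """Total theoretical intensity of all cells extant after each generation.

    After generation g the extant cells are the self-renewed RGP (or the
    final daughters for a terminal division), every neuron born in
    generations 1..g, and the fully expanded progeny of the intermediate
    progenitors produced so far.  Because each division splits the parental
    dye exactly in half, every entry equals the root intensity; this function
    recomputes the sums explicitly so that conservation can be verified.
    """

    sums: list[float] = []
    # frontier: cells extant at the current stage
    frontier: list[LineageNode] = [tree.root]
    while True:
        # advance every progenitor in the frontier by one round of division
        nxt: list[LineageNode] = []
        divided = False
        for node in frontier:
            if node.cell_type is CellType.NEURON or node.is_leaf:
                nxt.append(node)
            else:
                nxt.extend(node.children)
                divided = True
        if not divided:
            break
        frontier = nxt
        sums.append(sum(n.theoretical_intensity for n in frontier))
    return sums
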