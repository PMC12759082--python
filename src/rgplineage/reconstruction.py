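"""Lineage-tree reconstruction from per-cell dye intensities.

Reconstruction proceeds in four stages:

1. **Hierarchy assignment** — the brightest cell defines level 1
   (``phi1``); level h has intensity ``phi1 / 2**(h-1)`` and every cell is
   binned to the nearest level in log2 space.
2. **Enumeration** — working from the deepest level upward, all unordered
   pairings of the working set (observed cells at the level plus nodes
   generated from below), with at most one singleton, are expanded through
   the combination algebra.  Nine ordered type pairs are permitted
   (βγ, γβ, κγ, γκ, αγ, γα, γγ → γ; κκ → β; ββ → α) and seven are
   prohibited (κβ, βκ, κα, ακ, βα, αβ, αα).  A singleton neuron, IP or IPP
   is promoted under an inferred RGP whose unobserved sibling exits the
   cycle; a singleton RGP is a dead end because the RGP chain cannot skip a
   division.  A neuron pair may alternatively close the lineage as a
   terminal self-consuming RGP division (two neurons at once); such trees
   are reported only when no interpretation without a terminal division
   reaches a single root.
3. **Canonical deduplication** — children are ordered by a fixed total
   order on (cell type, subtree signature), removing left-right exchanges.
4. **Spatial resolution** — when several trees share one topology but pair
   different equal-intensity neurons under the same IP, the tree minimising
   the total distance between sibling neuron pairs is chosen (sister
   neurons from the same IP lie closer together than other neurons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

import numpy as np

from .types import CellRecord, CellType, Clone, DivisionPattern, LineageNode, LineageTree

__all__ = [
    "HierarchyAssignment",
    "ReconstructionResult",
    "ReconstructionStatus",
    "ReconstructionLimitError",
    "assign_hierarchies",
    "combine",
    "enumerate_trees",
    "canonicalize",
    "tree_signature",
    "topology_signature",
    "resolve_by_proximity",
    "annotate_generations",
    "reconstruct_clone",
    "iter_pairings",
]

#: Maximum working-set size before enumeration aborts (combinatorial guard).
MAX_WORKING_SET = 12

_G = CellType.RGP
_A = CellType.IPP
_B = CellType.IP
_K = CellType.NEURON

#: The 9 permitted ordered combinations and their products.
_COMBINE: dict[tuple[CellType, CellType], CellType] = {
    (_B, _G): _G, (_G, _B): _G,
    (_K, _G): _G, (_G, _K): _G,
    (_A, _G): _G, (_G, _A): _G,
    (_G, _G): _G,
    (_K, _K): _B,
    (_B, _B): _A,
}


class ReconstructionLimitError(RuntimeError):
    """Raised when a working set exceeds the enumeration guard."""


class ReconstructionStatus(str, Enum):
    UNIQUE = "unique"
    RESOLVED_BY_PROXIMITY = "resolved_by_proximity"
    AMBIGUOUS = "ambiguous"
    FAILED = "failed"


def combine(a: CellType, b: CellType) -> Optional[CellType]:
    """Product of combining two node types, or None if prohibited."""

    return _COMBINE.get((a, b))


@dataclass
class HierarchyAssignment:
    """Binning of observed cells into intensity hierarchy levels."""

    phi1: float
    levels: dict[str, int]           # cell_id -> level h >= 1
    log2_deviation: dict[str, float]  # signed log2 distance to assigned level

    def level_intensity(self, h: int) -> float:
        return self.phi1 / 2.0 ** (h - 1)

    @property
    def max_level(self) -> int:
        return max(self.levels.values())


def assign_hierarchies(
    cells: Sequence[CellRecord],
    outlier_log2_tol: float = 0.5,
) -> HierarchyAssignment:
    """Bin cells to intensity levels ``phi1 / 2**(h-1)`` nearest in log2 space.

    ``h = 1 + round(log2(phi1 / intensity))``, clipped to ``h >= 1``.  Cells
    whose log2 distance to every level exceeds ``outlier_log2_tol`` raise
    (the default of 0.5 can only be reached at an exact tie and therefore
    never rejects; tighten it to flag off-grid intensities).
    """

    if not cells:
        raise ValueError("assign_hierarchies needs at least one cell")
    intensities = np.array([c.intensity for c in cells], dtype=float)
    if np.any(intensities <= 0):
        raise ValueError("all intensities must be positive")
    phi1 = float(intensities.max())
    levels: dict[str, int] = {}
    deviation: dict[str, float] = {}
    for cell in cells:
        x = math.log2(phi1 / cell.intensity)
        h = max(1, 1 + round(x))
        dev = x - (h - 1)
        if abs(dev) > outlier_log2_tol:
            raise ValueError(
                f"cell {cell.cell_id}: intensity off the halving grid by "
                f"2**{dev:.3f} (tolerance {outlier_log2_tol})"
            )
        levels[cell.cell_id] = h
        deviation[cell.cell_id] = dev
    return HierarchyAssignment(phi1=phi1, levels=levels, log2_deviation=deviation)


def iter_pairings(items: Sequence) -> Iterator[list]:
    """All unordered pairings of ``items`` with at most one singleton.

    Each pairing is a list of 2-tuples plus, iff ``len(items)`` is odd,
    exactly one 1-tuple.  This is the closure of the published permutation +
    adjacent-grouping procedure over all orderings (verified by the
    equivalence test in the suite).
    """

    items = list(items)
    if not items:
        yield []
        return
    if len(items) % 2 == 1:
        for i in range(len(items)):
            rest = items[:i] + items[i + 1:]
            for rest_pairs in _perfect_matchings(rest):
                yield rest_pairs + [(items[i],)]
    else:
        yield from _perfect_matchings(items)


def _perfect_matchings(items: list) -> Iterator[list]:
    if not items:
        yield []
        return
    a, rest = items[0], items[1:]
    for j in range(len(rest)):
        b = rest[j]
        remaining = rest[:j] + rest[j + 1:]
        for sub in _perfect_matchings(remaining):
            yield [(a, b)] + sub


def _resolve_pair(
    a: LineageNode, b: LineageNode, level: int
) -> list[LineageNode]:
    """Possible parent nodes for one pair, at hierarchy ``level``.

    A neuron pair yields both the IP interpretation and the terminal
    self-consuming RGP interpretation; every other permitted pair yields its
    single product; prohibited pairs yield nothing.
    """

    product = combine(a.cell_type, b.cell_type)
    if product is None:
        return []
    intensity = a.theoretical_intensity * 2.0
    out = [
        LineageNode(
            product,
            children=[a, b],
            hierarchy_index=level,
            theoretical_intensity=intensity,
        )
    ]
    if a.cell_type is _K and b.cell_type is _K:
        out.append(
            LineageNode(
                _G,
                children=[a.copy(), b.copy()],
                hierarchy_index=level,
                theoretical_intensity=intensity,
                nn_terminal=True,
            )
        )
    return out


def _promote_singleton(node: LineageNode, level: int) -> Optional[LineageNode]:
    """Promote a singleton under an inferred RGP with an exiting sibling."""

    if node.cell_type is _G:
        return None  # the RGP chain cannot skip a division
    exit_leaf = LineageNode(
        _G,
        hierarchy_index=node.hierarchy_index,
        theoretical_intensity=node.theoretical_intensity,
        exit=True,
    )
    return LineageNode(
        _G,
        children=[node, exit_leaf],
        hierarchy_index=level,
        theoretical_intensity=node.theoretical_intensity * 2.0,
        implicit_exit=True,
    )


def enumerate_trees(
    assignment: HierarchyAssignment,
    cells: Sequence[CellRecord],
    max_working_set: int = MAX_WORKING_SET,
) -> list[LineageTree]:
    """All canonical lineage trees consistent with the hierarchy assignment.

    Recursion runs from the deepest level to level 1 and above until a
    single root remains.  Trees that need a terminal two-neuron RGP division
    are kept only when no tree without one exists.  Returns deduplicated
    canonical trees (empty on reconstruction failure).
    """

    by_level: dict[int, list[LineageNode]] = {}
    cell_by_id = {c.cell_id: c for c in cells}
    if set(cell_by_id) != set(assignment.levels):
        raise ValueError("assignment and cells disagree on cell ids")
    for cell_id, h in assignment.levels.items():
        cell = cell_by_id[cell_id]
        node = LineageNode(
            _K,
            hierarchy_index=h,
            theoretical_intensity=2.0 ** (1 - h),  # relative to 2*phi1 root scale
            observed_cell=cell,
        )
        by_level.setdefault(h, []).append(node)

    hmax = assignment.max_level
    roots: list[LineageNode] = []

    def recurse(working: list[LineageNode], level: int) -> None:
        obs_below = [h for h in by_level if h < level]
        if len(working) == 1 and not obs_below:
            roots.append(working[0])
            return
        if len(working) > max_working_set:
            raise ReconstructionLimitError(
                f"working set of {len(working)} exceeds the enumeration "
                f"guard ({max_working_set})"
            )
        next_level = level - 1
        incoming = by_level.get(next_level, [])
        for pairing in iter_pairings(working):
            _expand_pairing(pairing, next_level, [], incoming)

    def _expand_pairing(
        pairing: list,
        next_level: int,
        produced: list[LineageNode],
        incoming: list[LineageNode],
    ) -> None:
        if not pairing:
            recurse(produced + incoming, next_level)
            return
        group, rest = pairing[0], pairing[1:]
        if len(group) == 1:
            promoted = _promote_singleton(group[0], next_level)
            if promoted is None:
                return
            _expand_pairing(rest, next_level, produced + [promoted], incoming)
        else:
            for parent in _resolve_pair(group[0], group[1], next_level):
                _expand_pairing(rest, next_level, produced + [parent], incoming)

    recurse(list(by_level.get(hmax, [])), hmax)

    # deduplicate by canonical signature; prefer trees without terminal
    # self-consuming divisions when any exist
    trees: dict[tuple, LineageTree] = {}
    for root in roots:
        tree = canonicalize(LineageTree(root=root))
        trees.setdefault(tree_signature(tree), tree)
    result = list(trees.values())
    nn_free = [
        t
        for t in result
        if not any(n.nn_terminal for n in t.iter_nodes())
    ]
    return nn_free if nn_free else result


_TYPE_RANK = {_K: 0, _B: 1, _A: 2, _G: 3}


def _node_signature(node: LineageNode, with_cells: bool) -> tuple:
    if node.is_leaf:
        if node.cell_type is _K:
            cell = node.observed_cell.cell_id if (with_cells and node.observed_cell) else ""
            return ("k", cell)
        if node.exit:
            return ("exit",)
        return (node.cell_type.value,)
    child_sigs = sorted(
        (
            (_TYPE_RANK[c.cell_type], _node_signature(c, with_cells))
            for c in node.children
        )
    )
    return (node.cell_type.value, node.nn_terminal, tuple(child_sigs))


def tree_signature(tree: LineageTree) -> tuple:
    """Canonical signature including observed-cell identities."""

    return _node_signature(tree.root, with_cells=True)


def topology_signature(tree: LineageTree) -> tuple:
    """Canonical signature with leaves matched up to equal-intensity exchange."""

    return _node_signature(tree.root, with_cells=False)


def _canonicalize_node(node: LineageNode) -> LineageNode:
    new = node.copy()
    _sort_children(new)
    return new


def _sort_children(node: LineageNode) -> None:
    for child in node.children:
        _sort_children(child)
    node.children.sort(
        key=lambda c: (_TYPE_RANK[c.cell_type], _node_signature(c, True))
    )


def canonicalize(tree: LineageTree) -> LineageTree:
    """Order children by (cell type, subtree signature); idempotent."""

    return LineageTree(
        root=_canonicalize_node(tree.root),
        clone_id=tree.clone_id,
        generations=list(tree.generations),
    )


@dataclass
class ReconstructionResult:
    """Outcome of reconstructing one clone."""

    status: ReconstructionStatus
    trees: list[LineageTree] = field(default_factory=list)
    chosen: Optional[LineageTree] = None
    root_classification: Optional[CellType] = None
    non_rgp: bool = False
    note: str = ""


def _sibling_neuron_distance(tree: LineageTree) -> Optional[float]:
    """Total distance between observed sibling-neuron pairs (None if any
    position is missing)."""

    total = 0.0
    for node in tree.iter_nodes():
        if len(node.children) == 2 and all(
            c.cell_type is _K and c.observed_cell is not None
            for c in node.children
        ):
            pa = node.children[0].observed_cell.position
            pb = node.children[1].observed_cell.position
            if pa is None or pb is None:
                return None
            total += float(np.linalg.norm(pa - pb))
    return total


def resolve_by_proximity(
    trees: Sequence[LineageTree],
    cells: Sequence[CellRecord] | None = None,
) -> ReconstructionResult:
    """Select among candidate trees using sibling-neuron proximity.

    Candidates sharing one topology but pairing different equal-intensity
    neurons are ranked by total distance between sibling neuron pairs; a
    unique minimiser wins.  Distinct topologies, ties, or missing positions
    leave the result ambiguous — the resolver never guesses.
    """

    trees = list(trees)
    if not trees:
        return ReconstructionResult(status=ReconstructionStatus.FAILED)
    if len(trees) == 1:
        return ReconstructionResult(
            status=ReconstructionStatus.UNIQUE, trees=trees, chosen=trees[0]
        )
    topologies = {topology_signature(t) for t in trees}
    if len(topologies) > 1:
        return ReconstructionResult(
            status=ReconstructionStatus.AMBIGUOUS,
            trees=trees,
            note="candidate trees differ in topology",
        )
    distances = [_sibling_neuron_distance(t) for t in trees]
    if any(d is None for d in distances):
        return ReconstructionResult(
            status=ReconstructionStatus.AMBIGUOUS,
            trees=trees,
            note="positions missing; cannot resolve equal-intensity pairings",
        )
    best = min(distances)
    minimisers = [
        t
        for t, d in zip(trees, distances)
        if math.isclose(d, best, rel_tol=1e-9, abs_tol=1e-9)
    ]
    if len(minimisers) > 1:
        # tied pairings: exchanging whole sibling pairs between symmetric
        # positions (e.g. which IP pair sits under the IPP) leaves the total
        # distance and the topology unchanged — the structure is determined
        # even though the pairing identity is not; pick the canonical
        # representative deterministically and record the tie.
        chosen = min(minimisers, key=tree_signature)
        return ReconstructionResult(
            status=ReconstructionStatus.RESOLVED_BY_PROXIMITY,
            trees=trees,
            chosen=chosen,
            note=f"sibling-distance tie among {len(minimisers)} equivalent pairings",
        )
    return ReconstructionResult(
        status=ReconstructionStatus.RESOLVED_BY_PROXIMITY,
        trees=trees,
        chosen=minimisers[0],
    )


def annotate_generations(tree: LineageTree) -> LineageTree:
    """Walk the RGP chain and label generations and division patterns.

    The k-th RGP-chain division is generation k; the pattern is read off the
    non-chain child (neuron → N, IP → IP, IPP → IPP; a two-neuron terminal
    node → NN_TERMINAL; both children RGP → SYMMETRIC, where the walk
    stops).  Cycle exit appends an EXIT entry.  Neuron leaves inherit the
    generation and pattern of the division that spawned their sublineage.
    """

    if tree.root_type is not CellType.RGP:
        raise ValueError("annotate_generations requires an RGP root")
    tree = tree.copy()
    generations: list[tuple[int, DivisionPattern]] = []
    node = tree.root
    g = 0
    while True:
        g += 1
        node.generation = g - 1
        if node.is_leaf:
            generations.append((g, DivisionPattern.EXIT))
            break
        c0, c1 = node.children
        if node.nn_terminal or all(c.cell_type is _K for c in (c0, c1)):
            generations.append((g, DivisionPattern.NN_TERMINAL))
            _stamp_subtree(node, g, DivisionPattern.NN_TERMINAL, skip_self=True)
            break
        gamma_children = [c for c in (c0, c1) if c.cell_type is _G]
        if len(gamma_children) == 2:
            generations.append((g, DivisionPattern.SYMMETRIC))
            break
        if not gamma_children:
            raise ValueError("internal RGP node without an RGP-chain child")
        chain = gamma_children[0]
        progeny = c1 if chain is c0 else c0
        pattern = {
            _K: DivisionPattern.N,
            _B: DivisionPattern.IP,
            _A: DivisionPattern.IPP,
        }[progeny.cell_type]
        generations.append((g, pattern))
        _stamp_subtree(progeny, g, pattern, skip_self=False)
        node = chain
    tree.generations = generations
    return tree


def _stamp_subtree(
    node: LineageNode, g: int, pattern: DivisionPattern, skip_self: bool
) -> None:
    for n in node.iter_nodes():
        if skip_self and n is node:
            continue
        n.generation = g
        if n.cell_type is _K:
            n.source_pattern = pattern


def _similar_intensities(intensities: np.ndarray, rel_tol: float) -> bool:
    m = float(np.mean(intensities))
    return bool(np.all(np.abs(intensities - m) <= rel_tol * m))


def reconstruct_clone(
    clone: Clone,
    similar_rel_tol: float = 0.15,
    max_working_set: int = MAX_WORKING_SET,
    outlier_log2_tol: float = 0.5,
) -> ReconstructionResult:
    """Full reconstruction pipeline for one clone.

    Clones of 1, 2 or 4 cells with highly similar intensities (within
    ``similar_rel_tol`` of their mean) are classified as neuron-, IP- or
    IPP-rooted respectively: labelling most likely hit a postmitotic neuron
    or an intermediate progenitor rather than an RGP, and such clones are
    excluded from RGP-level analyses.
    """

    cells = clone.cells
    intensities = clone.intensities
    if len(cells) == 1:
        tree = LineageTree(
            root=LineageNode(_K, observed_cell=cells[0]), clone_id=clone.clone_id
        )
        return ReconstructionResult(
            status=ReconstructionStatus.UNIQUE,
            trees=[tree],
            chosen=tree,
            root_classification=CellType.NEURON,
            non_rgp=True,
            note="single labelled cell",
        )
    if len(cells) in (2, 4) and _similar_intensities(intensities, similar_rel_tol):
        root_type = _B if len(cells) == 2 else _A
        try:
            assignment = assign_hierarchies(cells, outlier_log2_tol)
            candidates = enumerate_trees(assignment, cells, max_working_set)
        except (ValueError, ReconstructionLimitError):
            candidates = []
        chosen = next(
            (t for t in candidates if t.root_type is root_type), None
        )
        if chosen is not None:
            chosen.clone_id = clone.clone_id
        return ReconstructionResult(
            status=ReconstructionStatus.UNIQUE,
            trees=[chosen] if chosen else [],
            chosen=chosen,
            root_classification=root_type,
            non_rgp=True,
            note=f"{len(cells)} cells with similar intensities",
        )
    try:
        assignment = assign_hierarchies(cells, outlier_log2_tol)
        candidates = enumerate_trees(assignment, cells, max_working_set)
    except ReconstructionLimitError as exc:
        return ReconstructionResult(
            status=ReconstructionStatus.FAILED, note=str(exc)
        )
    except ValueError as exc:
        return ReconstructionResult(
            status=ReconstructionStatus.FAILED, note=str(exc)
        )
    if not candidates:
        return ReconstructionResult(
            status=ReconstructionStatus.FAILED,
            note="no pairing admits a valid lineage tree",
        )
    result = resolve_by_proximity(candidates, cells)
    if result.chosen is not None:
        chosen = result.chosen
        chosen.clone_id = clone.clone_id
        result.root_classification = chosen.root_type
        result.non_rgp = chosen.root_type is not CellType.RGP
        if chosen.root_type is CellType.RGP:
            result.chosen = annotate_generations(chosen)
            result.trees = [
                result.chosen if t is chosen else t for t in result.trees
            ]
    elif result.trees:
        # all candidates agree on the root type even when ambiguous
        root_types = {t.root_type for t in result.trees}
        if len(root_types) == 1:
            result.root_classification = root_types.pop()
    return result
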