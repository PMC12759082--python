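"""Synthetic observation tables from simulated lineage trees.

Turns ground-truth lineages into the kind of per-cell table an imaging
experiment yields: noisy dye intensities (unequal partitioning between
daughters), 3D positions with inside-out radial layering and tight
clustering of same-IP siblings, marker-consistent neuron classes, ~7%
apoptotic dropout, and a detection threshold at twice background.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .simulator import (
    CloneSizeModel,
    TransitionMatrix,
    simulate_lineage,
)
from .types import (
    CellRecord,
    Clone,
    DivisionPattern,
    LineageNode,
    LineageTree,
)

__all__ = [
    "NoiseModel",
    "SpatialModel",
    "DEFAULT_LAYER_CUTS",
    "MARKERS_BY_CLASS",
    "assign_noisy_intensities",
    "assign_positions",
    "assign_classes_and_markers",
    "apply_dropout_and_threshold",
    "make_observed_clone",
    "make_archetype_population",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement/process noise applied to a ground-truth lineage.

    ``daughter_fraction_sd`` is the s.d. of the fraction of parental dye one
    daughter inherits (mean 0.5, truncated to ``fraction_bounds``); the
    default of 0.03 keeps adjacent halving levels separable and stands in
    for the experiment's unpublished fitted deviation.  Cells are removed
    with probability ``dropout_rate`` (developmental apoptosis, ~7%) and
    cells dimmer than ``detection_factor x background_level`` go undetected.
    """

    daughter_fraction_sd: float = 0.03
    fraction_bounds: tuple[float, float] = (0.1, 0.9)
    background_level: float = 5e-4
    detection_factor: float = 2.0
    dropout_rate: float = 0.07
    root_intensity: float = 1.0
    # optional one-time multiplicative root loss for process-localised dye
    # (~9.8% measured on radial fibres); off by default.
    process_loss: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.fraction_bounds
        if not (lo < 0.5 < hi):
            raise ValueError("fraction bounds must contain 0.5")
        if self.daughter_fraction_sd < 0:
            raise ValueError("daughter_fraction_sd must be >= 0")
        if self.daughter_fraction_sd >= (hi - lo) / 2:
            raise ValueError("daughter_fraction_sd too large for the bounds")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.detection_factor < 1:
            raise ValueError("detection_factor must be >= 1")
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")


@dataclass(frozen=True)
class SpatialModel:
    """Spatial layout of clone neurons in a cortical column.

    Radial position (0 = pia, 1 = subplate) decreases with later effective
    birth order — the inside-out rule — with Gaussian jitter; same-IP
    siblings scatter within ``sibling_cluster_scale`` (micrometres) around a
    shared centre while the clone as a whole spreads laterally over
    ``clone_column_scale``.
    """

    inside_out_strength: float = 1.0
    sibling_cluster_scale: float = 15.0
    clone_column_scale: float = 60.0
    radial_jitter_sd: float = 0.03
    cortical_thickness: float = 1000.0

    def __post_init__(self) -> None:
        if not self.sibling_cluster_scale < self.clone_column_scale:
            raise ValueError(
                "sibling_cluster_scale must be smaller than clone_column_scale"
            )


#: Layer cut points on relative radial depth (upper bound, exclusive except last).
DEFAULT_LAYER_CUTS: tuple[tuple[str, float], ...] = (
    ("L2/3", 0.35),
    ("L4", 0.50),
    ("L5", 0.75),
    ("L6", 1.001),
)

#: Defining Satb2/Ctip2/Fog2 staining pattern of each class.
MARKERS_BY_CLASS = {
    "CPN": ("+", "-", "-"),
    "SCPN": ("-", "+", "-"),
    "CThPN": ("-", "-", "+"),
    "HPN": ("+", "+", "-"),
    "SPN": ("-", "-", "-"),
}

#: Classes compatible with each layer (laminar constraints: SCPN/HPN in L5,
#: CThPN mainly L6).
CLASSES_BY_LAYER = {
    "L2/3": ("CPN",),
    "L4": ("CPN",),
    "L5": ("CPN", "SCPN", "HPN"),
    "L6": ("CPN", "CThPN"),
    "SP": ("SPN",),
}


def layer_for_depth(rel: float, cuts=DEFAULT_LAYER_CUTS) -> str:
    for layer, upper in cuts:
        if rel < upper:
            return layer
    return cuts[-1][0]


def _truncated_fraction(noise: NoiseModel, rng: np.random.Generator) -> float:
    if noise.daughter_fraction_sd == 0:
        return 0.5
    lo, hi = noise.fraction_bounds
    while True:
        f = rng.normal(0.5, noise.daughter_fraction_sd)
        if lo < f < hi:
            return f


def assign_noisy_intensities(
    tree: LineageTree, noise: NoiseModel, rng: np.random.Generator
) -> LineageTree:
    """Assign measured intensities: unequal but conservative partitioning.

    At each division one daughter inherits fraction ``f`` of the parental
    intensity (truncated normal around equal splitting) and the other
    ``1 - f``, so the parental dye amount is conserved exactly.
    """

    tree = tree.copy()
    tree.root.intensity = noise.root_intensity * (1.0 - noise.process_loss)
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.children:
            f = _truncated_fraction(noise, rng)
            node.children[0].intensity = node.intensity * f
            node.children[1].intensity = node.intensity * (1.0 - f)
            stack.extend(node.children)
    return tree


def _effective_birth_order(leaf: LineageNode) -> int:
    """Generation plus the extra division rounds of the progenitor route."""

    offset = {
        DivisionPattern.N: 0,
        DivisionPattern.NN_TERMINAL: 0,
        DivisionPattern.IP: 1,
        DivisionPattern.IPP: 2,
        None: 0,
    }[leaf.source_pattern]
    return (leaf.generation or 1) + offset


def assign_positions(
    tree: LineageTree,
    spatial: SpatialModel,
    rng: np.random.Generator,
    layer_cuts=DEFAULT_LAYER_CUTS,
) -> LineageTree:
    """Position neuron leaves in a cortical column, inside-out by birth order.

    Requires an annotated tree (generations and source patterns on leaves).
    Mutates a copy: each neuron leaf receives ``position`` (x, y lateral;
    z depth from the pia) and a relative radial position mapped to a layer.
    """

    tree = tree.copy()
    leaves = tree.neuron_leaves()
    if not leaves:
        return tree
    orders = [_effective_birth_order(n) for n in leaves]
    # deepest-possible order range mapped onto [0.08, 0.92]: order 1 sits deep
    bmax = max(max(orders), 2)
    slope = 0.84 / (bmax - 1) * spatial.inside_out_strength

    # same-IP siblings share a cluster centre; use the parent node id
    centres: dict[int, np.ndarray] = {}

    def lateral_centre(leaf: LineageNode, parent_id: int) -> np.ndarray:
        if parent_id not in centres:
            centres[parent_id] = rng.normal(0.0, spatial.clone_column_scale, 2)
        return centres[parent_id]

    parent_of = {
        id(c): p for p in tree.iter_nodes() for c in p.children
    }
    for leaf, b in zip(leaves, orders):
        rel = 0.92 - slope * (b - 1)
        rel = float(np.clip(rel + rng.normal(0, spatial.radial_jitter_sd), 0.01, 0.999))
        parent = parent_of.get(id(leaf))
        key = id(parent) if parent is not None else id(leaf)
        xy = lateral_centre(leaf, key) + rng.normal(
            0.0, spatial.sibling_cluster_scale, 2
        )
        z = rel * spatial.cortical_thickness
        leaf.position = np.array([xy[0], xy[1], z])
        leaf.rel_radial_pos = rel
        leaf.layer = layer_for_depth(rel, layer_cuts)
    return tree


def assign_classes_and_markers(
    tree: LineageTree,
    class_table: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> LineageTree:
    """Draw a projection class per neuron and set its defining marker triple.

    ``class_table`` maps ``(division pattern value, layer)`` to a mapping of
    class probabilities; rows must sum to 1 and respect laminar constraints.
    The default is uniform over the classes compatible with each layer.
    """

    rng = rng if rng is not None else np.random.default_rng()
    tree = tree.copy()
    for leaf in tree.neuron_leaves():
        layer = leaf.layer
        if layer == "unknown":
            continue
        pattern = leaf.source_pattern.value if leaf.source_pattern else "N"
        if class_table is not None and (pattern, layer) in class_table:
            probs = class_table[(pattern, layer)]
            classes = list(probs)
            weights = np.array([probs[c] for c in classes], dtype=float)
            if not np.isclose(weights.sum(), 1.0):
                raise ValueError(
                    f"class probabilities for ({pattern}, {layer}) must sum to 1"
                )
            bad = [c for c in classes if c not in CLASSES_BY_LAYER[layer] and probs[c] > 0]
            if bad:
                raise ValueError(f"classes {bad} incompatible with layer {layer}")
        else:
            classes = list(CLASSES_BY_LAYER[layer])
            weights = np.full(len(classes), 1.0 / len(classes))
        cls = classes[int(rng.choice(len(classes), p=weights))]
        leaf.neuron_class = cls
        leaf.markers = MARKERS_BY_CLASS[cls]
    return tree


_clone_counter = itertools.count(1)


def apply_dropout_and_threshold(
    tree: LineageTree,
    noise: NoiseModel,
    rng: np.random.Generator,
    clone_id: Optional[str] = None,
) -> tuple[Optional[Clone], list[CellRecord]]:
    """Emit the observed cell table for one synthetic lineage.

    Each neuron is removed with probability ``dropout_rate`` (apoptosis;
    flagged in the ground-truth records) and surviving cells dimmer than
    ``detection_factor x background_level`` are dropped as undetected.
    Returns ``(observed clone or None, ground-truth records)`` — the
    ground-truth list contains every neuron with its apoptotic flag.
    """

    clone_id = clone_id or tree.clone_id or f"clone{next(_clone_counter)}"
    truth: list[CellRecord] = []
    observed: list[CellRecord] = []
    threshold = noise.detection_factor * noise.background_level
    for i, leaf in enumerate(tree.neuron_leaves(), start=1):
        intensity = leaf.intensity
        if intensity is None:
            raise ValueError("assign_noisy_intensities must run first")
        apoptotic = bool(rng.random() < noise.dropout_rate)
        markers = leaf.markers
        record = CellRecord(
            clone_id=clone_id,
            cell_id=f"{clone_id}.n{i}",
            intensity=float(intensity),
            position=leaf.position,
            rel_radial_pos=float(leaf.rel_radial_pos)
            if leaf.rel_radial_pos is not None
            else float("nan"),
            layer=leaf.layer,
            satb2=markers[0],
            ctip2=markers[1],
            fog2=markers[2],
            neuron_class=leaf.neuron_class,
            apoptotic=apoptotic,
        )
        truth.append(record)
        if not apoptotic and intensity >= threshold:
            observed.append(record)
    clone = Clone(clone_id=clone_id, cells=observed) if observed else None
    return clone, truth


def make_observed_clone(
    tree: LineageTree,
    rng: np.random.Generator,
    noise: Optional[NoiseModel] = None,
    spatial: Optional[SpatialModel] = None,
    class_table: Optional[dict] = None,
    clone_id: Optional[str] = None,
) -> tuple[Optional[Clone], LineageTree]:
    """Full generator pipeline: noise, positions, classes, dropout, threshold.

    Returns the observed clone (None if nothing survives detection) and the
    decorated ground-truth tree.
    """

    noise = noise or NoiseModel()
    spatial = spatial or SpatialModel()
    tree = assign_noisy_intensities(tree, noise, rng)
    tree = assign_positions(tree, spatial, rng)
    tree = assign_classes_and_markers(tree, class_table, rng)
    clone, truth = apply_dropout_and_threshold(tree, noise, rng, clone_id)
    tree.clone_id = clone.clone_id if clone else (clone_id or tree.clone_id)
    # attach the matching observed records to the ground-truth leaves
    by_id = {r.cell_id: r for r in truth}
    for leaf, record in zip(tree.neuron_leaves(), truth):
        leaf.observed_cell = record
    return clone, tree


# ---------------------------------------------------------------------------
# archetype populations for clustering studies
# ---------------------------------------------------------------------------

def _uniform_rows(row: Sequence[float]) -> list[list[float]]:
    return [list(row)] * 3


def _class_table(by_layer: dict[str, dict[str, float]]) -> dict:
    return {
        (pat, layer): probs
        for pat in ("N", "IP", "IPP", "NN_TERMINAL")
        for layer, probs in by_layer.items()
    }


#: Five clone archetypes with strongly contrasting division behaviour,
#: laminar placement and class composition, used to benchmark clustering.
#: Each archetype fixes its own transition matrix, size law, radial band and
#: class table, so the 20 features separate along all three feature families.
ARCHETYPES: dict[str, dict] = {
    # balanced translaminar, direct-neurogenesis-heavy, mixed classes
    "balanced_direct": dict(
        p=_uniform_rows([0.05, 0.15, 0.80]),
        sizes=(10.0, 12.0), depth_band=(0.15, 0.95),
        classes=_class_table(
            {
                "L2/3": {"CPN": 1.0}, "L4": {"CPN": 1.0},
                "L5": {"SCPN": 1.0}, "L6": {"CThPN": 1.0},
            }
        ),
    ),
    # deep-layer restricted, CThPN-dominated
    "deep_cthpn": dict(
        p=_uniform_rows([0.05, 0.25, 0.70]),
        sizes=(5.0, 7.0), depth_band=(0.76, 0.99),
        classes=_class_table({"L6": {"CThPN": 1.0}}),
    ),
    # deep-layer, IPP-amplified, subcerebral/heterogeneous output
    "deep_ipp": dict(
        p=_uniform_rows([0.70, 0.20, 0.10]),
        sizes=(7.0, 10.0), depth_band=(0.52, 0.74),
        classes=_class_table({"L5": {"SCPN": 0.5, "HPN": 0.5}}),
    ),
    # superficial-layer, IPP-amplified CPN producer
    "superficial_ipp": dict(
        p=_uniform_rows([0.70, 0.20, 0.10]),
        sizes=(7.0, 10.0), depth_band=(0.02, 0.34),
        classes=_class_table({"L2/3": {"CPN": 1.0}, "L4": {"CPN": 1.0}}),
    ),
    # superficial-restricted, IP-heavy small clones
    "superficial_ip": dict(
        p=_uniform_rows([0.02, 0.78, 0.20]),
        sizes=(6.0, 8.0), depth_band=(0.36, 0.49),
        classes=_class_table({"L4": {"CPN": 1.0}}),
    ),
}


def make_archetype_population(
    n_per_archetype: int,
    seed: int,
    noise: Optional[NoiseModel] = None,
) -> tuple[list[Clone], list[LineageTree], list[int]]:
    """Generate clones from five parameterised archetypes.

    Each archetype fixes its own transition matrix, clone-size law and
    radial band (which drives layer and class composition).  Returns
    observed clones, their ground-truth trees and integer archetype labels.
    Clones are generated without dropout so every tree is represented.
    """

    noise = noise or NoiseModel(dropout_rate=0.0)
    rng = np.random.default_rng(seed)
    clones: list[Clone] = []
    trees: list[LineageTree] = []
    labels: list[int] = []
    for label, (name, params) in enumerate(ARCHETYPES.items()):
        p = TransitionMatrix(params["p"])
        model = CloneSizeModel(weights=(0.5, 0.5), rates=params["sizes"])
        lo, hi = params["depth_band"]
        spatial = SpatialModel(radial_jitter_sd=0.0)
        for i in range(n_per_archetype):
            tree = simulate_lineage(model, p, rng, clone_id=f"{name}{i}")
            tree = assign_noisy_intensities(tree, noise, rng)
            tree = assign_positions(tree, spatial, rng)
            # squeeze the clone into its archetype's radial band
            for leaf in tree.neuron_leaves():
                rel = lo + (hi - lo) * leaf.rel_radial_pos
                leaf.rel_radial_pos = rel
                leaf.layer = layer_for_depth(rel)
                leaf.position[2] = rel * spatial.cortical_thickness
            tree = assign_classes_and_markers(tree, params["classes"], rng)
            clone, _ = apply_dropout_and_threshold(
                tree, noise, rng, clone_id=tree.clone_id
            )
            if clone is None:
                continue
            clones.append(clone)
            trees.append(tree)
            labels.append(label)
    return clones, trees, labels
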