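"""Per-clone cell-type calling, laminar classes, features and Ward clustering.

Neuron classes are called from Satb2/Ctip2/Fog2 staining plus layer; clones
are classified into seven laminar classes (three translaminar, four
layer-restricted); twenty per-clone features spanning division patterns,
laminar distribution and excitatory neuron types feed Ward hierarchical
clustering into (by default) five clonal clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as scipy_hierarchy
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering

from .types import Clone, DivisionPattern, LineageTree

__all__ = [
    "FEATURE_NAMES",
    "classify_cell_type",
    "laminar_class",
    "LaminarCloneClass",
    "extract_features",
    "CloneWardClustering",
    "ClusterResult",
    "cluster_clones",
    "cluster_summaries",
]

DL_LAYERS = ("L5", "L6")
SL_LAYERS = ("L2/3", "L4")

#: The twenty per-clone features, in fixed order.
FEATURE_NAMES = (
    "clone_size",
    "n_generations",
    "frac_div_N",
    "frac_div_IP",
    "frac_div_IPP",
    "frac_neurons_N",
    "frac_neurons_IP",
    "frac_neurons_IPP",
    "frac_L2/3",
    "frac_L4",
    "frac_L5",
    "frac_L6",
    "frac_DL",
    "frac_SL",
    "frac_CPN",
    "frac_CThPN",
    "frac_SCPN",
    "frac_HPN",
    "translaminar",
    "mean_rel_radial_pos",
)


def classify_cell_type(
    satb2: str, ctip2: str, fog2: str, layer: str = "unknown"
) -> str:
    """Call the projection-neuron class from the marker triple and layer.

    Precedence: Fog2+ → CThPN; Satb2+ and Ctip2+ → HPN; Ctip2+ → SCPN;
    Satb2+ → CPN; subplate location → SPN; otherwise unknown.
    """

    if fog2 == "+":
        return "CThPN"
    if satb2 == "+" and ctip2 == "+":
        return "HPN"
    if ctip2 == "+":
        return "SCPN"
    if satb2 == "+":
        return "CPN"
    if layer == "SP":
        return "SPN"
    return "unknown"


@dataclass(frozen=True)
class LaminarCloneClass:
    """One of the seven laminar clone classes.

    Translaminar clones span deep (L5/L6) and superficial (L2/3, L4) layers
    and subdivide by which deep layers are occupied; restricted clones
    occupy a single layer.
    """

    label: str
    translaminar: bool
    flagged: bool = False  # multi-layer same-side clone mapped to deepest layer


TRANSLAMINAR_CLASSES = ("SL+L5", "SL+L6", "SL+L5+L6")
RESTRICTED_CLASSES = ("L2/3-only", "L4-only", "L5-only", "L6-only")


def laminar_class(clone: Clone) -> LaminarCloneClass:
    """Classify a clone by its occupied cortical layers."""

    layers = {c.layer for c in clone.cells if c.layer in DL_LAYERS + SL_LAYERS}
    if not layers:
        raise ValueError(f"clone {clone.clone_id}: no layer-classified neurons")
    dl = layers & set(DL_LAYERS)
    sl = layers & set(SL_LAYERS)
    if dl and sl:
        label = "SL+L5+L6" if dl == {"L5", "L6"} else f"SL+{next(iter(dl))}"
        return LaminarCloneClass(label=label, translaminar=True)
    occupied = sorted(layers)
    if len(occupied) == 1:
        return LaminarCloneClass(label=f"{occupied[0]}-only", translaminar=False)
    # same-side multi-layer clone: map to the deepest occupied layer, flagged
    deepest = occupied[-1]  # lexicographic order matches depth within a side
    return LaminarCloneClass(
        label=f"{deepest}-only", translaminar=False, flagged=True
    )


def extract_features(clone: Clone, tree: Optional[LineageTree]) -> np.ndarray:
    """The 20-dimensional feature vector for one clone.

    Division-derived components need an annotated RGP tree; for non-RGP or
    failed clones they are imputed as 0.  Fractions over layers/classes are
    over the classified cells only.
    """

    f = dict.fromkeys(FEATURE_NAMES, 0.0)
    f["clone_size"] = float(len(clone))
    divisions = []
    if tree is not None and tree.generations:
        divisions = [
            DivisionPattern.N if p is DivisionPattern.NN_TERMINAL else p
            for _, p in tree.generations
            if p not in (DivisionPattern.EXIT, DivisionPattern.SYMMETRIC)
        ]
    if divisions:
        n_div = len(divisions)
        f["n_generations"] = float(n_div)
        neurons_by = {DivisionPattern.N: 1, DivisionPattern.IP: 2, DivisionPattern.IPP: 4}
        total_neurons = sum(neurons_by[p] for p in divisions)
        for key, pat in (
            ("N", DivisionPattern.N),
            ("IP", DivisionPattern.IP),
            ("IPP", DivisionPattern.IPP),
        ):
            k = sum(p is pat for p in divisions)
            f[f"frac_div_{key}"] = k / n_div
            f[f"frac_neurons_{key}"] = k * neurons_by[pat] / total_neurons
    layered = [c for c in clone.cells if c.layer in DL_LAYERS + SL_LAYERS]
    if layered:
        n = len(layered)
        for layer in ("L2/3", "L4", "L5", "L6"):
            f[f"frac_{layer}"] = sum(c.layer == layer for c in layered) / n
        f["frac_DL"] = sum(c.layer in DL_LAYERS for c in layered) / n
        f["frac_SL"] = sum(c.layer in SL_LAYERS for c in layered) / n
        f["translaminar"] = float(laminar_class(clone).translaminar)
    classed = [
        c for c in clone.cells
        if classify_cell_type(c.satb2, c.ctip2, c.fog2, c.layer)
        in ("CPN", "CThPN", "SCPN", "HPN")
    ]
    if classed:
        n = len(classed)
        for cls in ("CPN", "CThPN", "SCPN", "HPN"):
            f[f"frac_{cls}"] = (
                sum(
                    classify_cell_type(c.satb2, c.ctip2, c.fog2, c.layer) == cls
                    for c in classed
                )
                / n
            )
    rels = [c.rel_radial_pos for c in clone.cells if np.isfinite(c.rel_radial_pos)]
    if rels:
        f["mean_rel_radial_pos"] = float(np.mean(rels))
    return np.array([f[name] for name in FEATURE_NAMES])


class CloneWardClustering(BaseEstimator, ClusterMixin):
    """Ward hierarchical clustering of standardised clone features.

    Features are standardised per dimension (constant dimensions dropped),
    Ward linkage on Euclidean distances is cut at ``n_clusters``.  The
    procedure is deterministic and invariant to input order.  Fitted
    attributes: ``labels_``, ``linkage_``, ``kept_features_``.
    """

    def __init__(self, n_clusters: int = 5):
        self.n_clusters = n_clusters

    def fit(self, X: Sequence[Sequence[float]], y=None) -> "CloneWardClustering":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.n_clusters > X.shape[0]:
            raise ValueError(
                f"k={self.n_clusters} exceeds the number of clones {X.shape[0]}"
            )
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.any():
            raise ValueError("all features are constant")
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        model = AgglomerativeClustering(
            n_clusters=self.n_clusters, linkage="ward"
        ).fit(Z)
        self.labels_ = model.labels_ + 1  # clusters numbered 1..k
        self.linkage_ = scipy_hierarchy.linkage(Z, method="ward")
        self.kept_features_ = np.flatnonzero(keep)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass
class ClusterResult:
    labels: np.ndarray          # 1..k per clone
    linkage: np.ndarray
    n_clusters: int
    feature_names: tuple[str, ...] = FEATURE_NAMES


def cluster_clones(
    features: Sequence[Sequence[float]], k: int = 5
) -> ClusterResult:
    """Ward-cluster clone feature vectors into k clonal clusters."""

    model = CloneWardClustering(n_clusters=k).fit(features)
    return ClusterResult(
        labels=model.labels_, linkage=model.linkage_, n_clusters=k
    )


def _dominant_combination(class_counts: dict[str, int]) -> str:
    present = {c for c, n in class_counts.items() if n > 0}
    if present <= {"CPN"}:
        return "only CPN"
    if present <= {"CPN", "CThPN"}:
        return "CThPN+CPN"
    return "CThPN+SCPN/HPN+CPN"


def cluster_summaries(
    result: ClusterResult,
    clones: Sequence[Clone],
    trees: Sequence[Optional[LineageTree]],
) -> pd.DataFrame:
    """Per-cluster composition: layers, classes and IPP-derived neuron share."""

    if len(clones) != len(result.labels):
        raise ValueError("labels and clones must align")
    rows = {}
    for k in range(1, result.n_clusters + 1):
        members = [
            (c, t)
            for c, t, lab in zip(clones, trees, result.labels)
            if lab == k
        ]
        dl = sl = 0
        class_counts = {c: 0 for c in ("CPN", "CThPN", "SCPN", "HPN")}
        ipp_neurons = total_attr = 0
        for clone, tree in members:
            for cell in clone.cells:
                if cell.layer in DL_LAYERS:
                    dl += 1
                elif cell.layer in SL_LAYERS:
                    sl += 1
                cls = classify_cell_type(cell.satb2, cell.ctip2, cell.fog2, cell.layer)
                if cls in class_counts:
                    class_counts[cls] += 1
            if tree is not None and tree.generations:
                for _, pat in tree.generations:
                    n = {
                        DivisionPattern.N: 1,
                        DivisionPattern.NN_TERMINAL: 2,
                        DivisionPattern.IP: 2,
                        DivisionPattern.IPP: 4,
                    }.get(pat, 0)
                    total_attr += n
                    if pat is DivisionPattern.IPP:
                        ipp_neurons += n
        n_classed = sum(class_counts.values())
        rows[k] = {
            "n_clones": len(members),
            "n_DL": dl,
            "n_SL": sl,
            **{
                f"frac_{c}": (v / n_classed if n_classed else np.nan)
                for c, v in class_counts.items()
            },
            "combination": _dominant_combination(class_counts),
            "frac_neurons_IPP": (ipp_neurons / total_attr) if total_attr else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
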