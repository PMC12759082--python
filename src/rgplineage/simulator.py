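"""Stochastic branching-process simulator of direct/indirect neurogenesis.

An in silico RGP lineage is generated under four rules:

1. the clone size (total neuron output, PyN) is drawn from a two-component
   zero-truncated Poisson mixture, ``0.35 tPois(4.09) + 0.65 tPois(7.62)``;
2. the first division pattern is uniform over the feasible patterns;
3. subsequent patterns follow a stationary Markov chain with a 3x3
   row-stochastic transition matrix over (IPP, IP, N);
4. when fewer than four neurons remain to be produced, the matrix is
   renormalised so that the clone-size law is met exactly: with
   2 <= remaining < 4 the IPP column is zeroed and rows renormalised; with
   remaining = 1 every row becomes (0, 0, 1).

Each division appends a progeny subtree (N: one neuron; IP: one IP dividing
into two neurons; IPP: one IPP dividing into two IPs into four neurons) and
the RGP self-renews until the drawn size is reached, then exits the cycle.
Theoretical dye intensities halve with every division (root = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    MARKOV_PATTERNS,
    PATTERN_NEURONS,
    CellType,
    DivisionPattern,
    LineageNode,
    LineageTree,
)

__all__ = [
    "CloneSizeModel",
    "TransitionMatrix",
    "DEFAULT_TRANSITION_MATRIX",
    "draw_clone_size",
    "constrained_matrix",
    "first_pattern",
    "simulate_pattern_sequence",
    "simulate_lineage",
    "simulate_batch",
]


@dataclass(frozen=True)
class CloneSizeModel:
    """Two-component zero-truncated Poisson mixture for clone size."""

    weights: tuple[float, float] = (0.35, 0.65)
    rates: tuple[float, float] = (4.09, 7.62)

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be nonnegative")
        if any(r <= 0 for r in self.rates):
            raise ValueError("mixture rates must be positive")

    @property
    def mean(self) -> float:
        """Closed-form mean: sum_c w_c * lambda_c / (1 - exp(-lambda_c))."""
        return sum(
            w * r / (1.0 - math.exp(-r))
            for w, r in zip(self.weights, self.rates)
        )


class TransitionMatrix:
    """Row-stochastic 3x3 matrix over division patterns (IPP, IP, N)."""

    PATTERNS = MARKOV_PATTERNS

    def __init__(self, p: Sequence[Sequence[float]]):
        p = np.asarray(p, dtype=float)
        if p.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0):
            raise ValueError("each transition-matrix row must sum to 1")
        self.p = p

    def __repr__(self) -> str:
        return f"TransitionMatrix({self.p.tolist()})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TransitionMatrix) and np.allclose(self.p, other.p)

    def row(self, pattern: DivisionPattern) -> np.ndarray:
        return self.p[self.PATTERNS.index(pattern)]


#: Illustrative default transition matrix.  The published analysis estimates
#: its matrix from experimental lineages and reports it only graphically, so
#: no numeric default can claim to be that estimate; this one is qualitatively
#: shaped like typical estimates (IPP rarest, N commonest, modest persistence).
DEFAULT_TRANSITION_MATRIX = TransitionMatrix(
    [
        [0.20, 0.35, 0.45],  # from IPP
        [0.12, 0.40, 0.48],  # from IP
        [0.10, 0.28, 0.62],  # from N
    ]
)


def draw_clone_size(
    model: CloneSizeModel,
    rng: np.random.Generator,
    max_size: Optional[int] = None,
) -> int:
    """Draw one clone size (>= 1) from the zero-truncated mixture.

    Uses inverse-CDF sampling of the truncated Poisson conditional on the
    mixture component.  ``max_size``, when given, truncates the distribution
    from above by rejection (used for bounded reconstruction studies).
    """

    while True:
        comp = int(rng.random() >= model.weights[0])
        lam = model.rates[comp]
        # zero-truncated inverse CDF: map U(0,1) into the (P(X=0), 1] tail
        p0 = math.exp(-lam)
        u = p0 + rng.random() * (1.0 - p0)
        size = int(stats.poisson.ppf(u, lam))
        size = max(size, 1)
        if max_size is None or size <= max_size:
            return size


def constrained_matrix(p: TransitionMatrix, pyn_remain: int) -> TransitionMatrix:
    """Apply the boundary renormalisation for the remaining neuron budget."""

    if pyn_remain < 1:
        raise ValueError("pyn_remain must be >= 1")
    if pyn_remain >= 4:
        return p
    if pyn_remain == 1:
        return TransitionMatrix(np.tile([0.0, 0.0, 1.0], (3, 1)))
    # 2 <= pyn_remain < 4: IPP divisions are no longer feasible
    q = p.p.copy()
    denom = q[:, 1] + q[:, 2]
    if np.any(denom <= 0):
        raise ValueError(
            "degenerate row: p_i1 = 1 leaves no feasible pattern for "
            f"pyn_remain={pyn_remain}"
        )
    q[:, 0] = 0.0
    q[:, 1] /= denom
    q[:, 2] /= denom
    return TransitionMatrix(q)


def _feasible_patterns(pyn_remain: int) -> list[DivisionPattern]:
    if pyn_remain >= 4:
        return [DivisionPattern.IPP, DivisionPattern.IP, DivisionPattern.N]
    if pyn_remain >= 2:
        return [DivisionPattern.IP, DivisionPattern.N]
    return [DivisionPattern.N]


def first_pattern(pyn_target: int, rng: np.random.Generator) -> DivisionPattern:
    """Uniform first-generation fate over the patterns feasible for the size."""

    if pyn_target < 1:
        raise ValueError("pyn_target must be >= 1")
    feasible = _feasible_patterns(pyn_target)
    return feasible[int(rng.integers(len(feasible)))]


def simulate_pattern_sequence(
    pyn_target: int,
    p: TransitionMatrix,
    rng: np.random.Generator,
) -> list[tuple[DivisionPattern, bool]]:
    """Division patterns of one lineage, with per-division constraint flags.

    Returns ``[(pattern, constrained), ...]`` where ``constrained`` is True
    when the boundary renormalisation (Rule 4) was in force for that draw.
    This is the simulator's fast path; :func:`simulate_lineage` builds the
    full tree on top of it.
    """

    patterns: list[tuple[DivisionPattern, bool]] = []
    remain = pyn_target
    pat = first_pattern(pyn_target, rng)
    patterns.append((pat, remain < 4))
    remain -= PATTERN_NEURONS[pat]
    while remain > 0:
        q = constrained_matrix(p, remain)
        row = q.row(pat)
        u = rng.random()
        j = 0 if u < row[0] else (1 if u < row[0] + row[1] else 2)
        pat = MARKOV_PATTERNS[j]
        patterns.append((pat, remain < 4))
        remain -= PATTERN_NEURONS[pat]
    if remain != 0:
        raise AssertionError("clone-size accounting violated")
    return patterns


def _progeny_subtree(
    pattern: DivisionPattern, intensity: float, generation: int
) -> LineageNode:
    """Build the non-RGP child produced by one division (atomic expansion)."""

    def neuron(i: float) -> LineageNode:
        return LineageNode(
            CellType.NEURON,
            theoretical_intensity=i,
            generation=generation,
            source_pattern=pattern,
        )

    if pattern is DivisionPattern.N:
        return neuron(intensity)
    if pattern is DivisionPattern.IP:
        return LineageNode(
            CellType.IP,
            children=[neuron(intensity / 2), neuron(intensity / 2)],
            theoretical_intensity=intensity,
            generation=generation,
        )
    if pattern is DivisionPattern.IPP:
        betas = [
            LineageNode(
                CellType.IP,
                children=[neuron(intensity / 4), neuron(intensity / 4)],
                theoretical_intensity=intensity / 2,
                generation=generation,
            )
            for _ in range(2)
        ]
        return LineageNode(
            CellType.IPP,
            children=betas,
            theoretical_intensity=intensity,
            generation=generation,
        )
    raise ValueError(f"cannot expand pattern {pattern}")


def tree_from_patterns(
    patterns: Sequence[tuple[DivisionPattern, bool]],
    clone_id: str = "",
) -> LineageTree:
    """Assemble the annotated binary tree for a simulated pattern sequence."""

    root = LineageNode(CellType.RGP, theoretical_intensity=1.0, generation=0)
    current = root
    for g, (pat, constrained) in enumerate(patterns, start=1):
        half = current.theoretical_intensity / 2.0
        progeny = _progeny_subtree(pat, half, g)
        renewed = LineageNode(
            CellType.RGP, theoretical_intensity=half, generation=g,
            constrained=constrained,
        )
        current.children = [progeny, renewed]
        current = renewed
    current.exit = True
    generations = [(g, pat) for g, (pat, _) in enumerate(patterns, start=1)]
    generations.append((len(patterns) + 1, DivisionPattern.EXIT))
    return LineageTree(root=root, clone_id=clone_id, generations=generations)


def simulate_lineage(
    model: CloneSizeModel,
    p: TransitionMatrix,
    rng: np.random.Generator,
    max_size: Optional[int] = None,
    clone_id: str = "",
) -> LineageTree:
    """Simulate one lineage tree under the four rules."""

    pyn = draw_clone_size(model, rng, max_size=max_size)
    patterns = simulate_pattern_sequence(pyn, p, rng)
    return tree_from_patterns(patterns, clone_id=clone_id)


def simulate_batch(
    model: CloneSizeModel,
    p: TransitionMatrix,
    seed: int,
    batch_size: int = 258,
    n_batches: int = 100,
    max_size: Optional[int] = None,
) -> list[list[LineageTree]]:
    """Simulate ``n_batches`` reproducible batches of ``batch_size`` lineages.

    Each batch runs on its own substream spawned from the master seed, so a
    batch's content depends only on (seed, batch index).  The published batch
    geometry is 258 lineages x 100 repeats.
    """

    seeds = np.random.SeedSequence(seed).spawn(n_batches)
    batches: list[list[LineageTree]] = []
    for b, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        batches.append(
            [
                simulate_lineage(
                    model, p, rng, max_size=max_size, clone_id=f"b{b}c{i}"
                )
                for i in range(batch_size)
            ]
        )
    return batches
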