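"""Reconstruction: hierarchy binning, combination algebra, enumeration,
canonical deduplication, spatial resolution and the composed pipeline."""

import itertools

import numpy as np
import pytest

from rgplineage import (
    CloneSizeModel,
    DEFAULT_TRANSITION_MATRIX,
    NoiseModel,
    ReconstructionStatus,
    annotate_generations,
    assign_hierarchies,
    canonicalize,
    combine,
    enumerate_trees,
    make_observed_clone,
    reconstruct_clone,
    resolve_by_proximity,
    simulate_lineage,
    topology_signature,
    tree_signature,
)
from rgplineage.reconstruction import (
    MAX_WORKING_SET,
    ReconstructionLimitError,
    iter_pairings,
)
from rgplineage.types import CellType, DivisionPattern

from conftest import make_clone

G, A, B, K = CellType.RGP, CellType.IPP, CellType.IP, CellType.NEURON


class TestCombine:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (K, K, B),
            (B, B, A),
            (B, G, G), (G, B, G),
            (K, G, G), (G, K, G),
            (A, G, G), (G, A, G),
            (G, G, G),
            (K, B, None), (B, K, None),
            (K, A, None), (A, K, None),
            (B, A, None), (A, B, None),
            (A, A, None),
        ],
    )
    def test_combination_table(self, a, b, expected):
        assert combine(a, b) == expected

    def test_nine_permitted_seven_prohibited(self):
        results = [combine(a, b) for a, b in itertools.product(CellType, repeat=2)]
        assert sum(r is not None for r in results) == 9
        assert sum(r is None for r in results) == 7


class TestHierarchies:
    @pytest.mark.parametrize(
        "intensities,expected",
        [
            ([1.0, 0.5, 0.5], [1, 2, 2]),
            ([0.98, 0.52, 0.24], [1, 2, 3]),
            ([0.7], [1]),
        ],
    )
    def test_binning(self, intensities, expected):
        clone = make_clone(intensities)
        assignment = assign_hierarchies(clone.cells)
        got = [assignment.levels[c.cell_id] for c in clone.cells]
        assert got == expected
        assert assignment.phi1 == max(intensities)

    def test_level_values_halve(self):
        assignment = assign_hierarchies(make_clone([0.8, 0.2]).cells)
        assert assignment.level_intensity(1) == 0.8
        assert assignment.level_intensity(3) == pytest.approx(0.2)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            assign_hierarchies([])
        with pytest.raises(ValueError):
            make_clone([-1.0])

    def test_outlier_tolerance_flags_off_grid_cells(self):
        clone = make_clone([1.0, 0.7])  # 0.7 is ~0.51 in log2 off both levels
        with pytest.raises(ValueError):
            assign_hierarchies(clone.cells, outlier_log2_tol=0.3)


def _pairings_by_permutation(n):
    """Literal permutation + adjacent-grouping enumeration (reference oracle)."""

    out = set()
    for perm in itertools.permutations(range(n)):
        groups = []
        i = 0
        while i < n:
            if i + 1 < n:
                groups.append(frozenset(perm[i:i + 2]))
                i += 2
            else:
                groups.append(frozenset(perm[i:i + 1]))
                i += 1
        out.add(frozenset(groups))
    return out


def _pairings_by_matching(n):
    return {
        frozenset(frozenset(group) for group in pairing)
        for pairing in iter_pairings(range(n))
    }


class TestPairings:
    @pytest.mark.parametrize("n", range(1, 7))
    def test_matches_literal_permutation_procedure(self, n):
        assert _pairings_by_matching(n) == _pairings_by_permutation(n)

    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 3), (5, 15), (6, 15)])
    def test_pairing_counts(self, n, count):
        assert len(list(iter_pairings(range(n)))) == count


class TestEnumerate:
    def _trees(self, intensities):
        clone = make_clone(intensities)
        return enumerate_trees(assign_hierarchies(clone.cells), clone.cells)

    def test_terminal_division_is_unique_interpretation(self):
        # one neuron at level 1, an equal pair at level 2: the pair can only
        # close the lineage as a terminal self-consuming division
        trees = self._trees([0.5, 0.25, 0.25])
        assert len(trees) == 1
        (tree,) = trees
        assert tree.root_type is G
        assert any(n.nn_terminal for n in tree.iter_nodes())

    def test_two_equal_cells_give_ip_root(self):
        trees = self._trees([0.25, 0.25])
        assert len(trees) == 1
        assert trees[0].root_type is B

    def test_singleton_promotion_chain(self):
        trees = self._trees([0.5, 0.25])
        assert len(trees) == 1
        (tree,) = trees
        assert tree.root_type is G
        assert any(n.implicit_exit for n in tree.iter_nodes())
        assert any(n.exit for n in tree.iter_nodes())

    def test_four_equal_cells_give_ipp_root(self):
        trees = self._trees([0.25] * 4)
        assert {t.root_type for t in trees} == {A}

    def test_working_set_guard(self):
        with pytest.raises(ReconstructionLimitError):
            self._trees([0.5] * (MAX_WORKING_SET + 1))

    def test_completeness_on_noiseless_simulations(self, rng):
        """Enumeration contains the generating tree for exact intensities."""

        noise = NoiseModel(
            daughter_fraction_sd=0.0, dropout_rate=0.0, background_level=1e-12
        )
        for i in range(25):
            tree = simulate_lineage(
                CloneSizeModel(), DEFAULT_TRANSITION_MATRIX, rng,
                max_size=12, clone_id=f"c{i}",
            )
            clone, truth = make_observed_clone(tree, rng, noise=noise)
            intensities = clone.intensities
            if len(clone) in (1, 2, 4) and np.allclose(
                intensities, intensities.mean(), rtol=0.15
            ):
                # degenerate clones are observationally equivalent to
                # IP/IPP/neuron labelling and reconstruct as non-RGP roots
                continue
            candidates = enumerate_trees(
                assign_hierarchies(clone.cells), clone.cells
            )
            target = tree_signature(canonicalize(truth))
            assert target in {tree_signature(t) for t in candidates}


class TestCanonicalize:
    def _random_swap(self, tree, rng):
        tree = tree.copy()
        for node in tree.iter_nodes():
            if node.children and rng.random() < 0.5:
                node.children.reverse()
        return tree

    def test_swap_invariance_and_idempotence(self, small_trees, rng):
        for tree in small_trees:
            base = canonicalize(tree)
            assert tree_signature(canonicalize(base)) == tree_signature(base)
            for _ in range(3):
                swapped = self._random_swap(tree, rng)
                assert tree_signature(canonicalize(swapped)) == tree_signature(base)

    def test_distinct_pairings_stay_distinct(self):
        # three equal-intensity neurons: same topology, three pairings
        clone = make_clone([0.25, 0.25, 0.25])
        trees = enumerate_trees(assign_hierarchies(clone.cells), clone.cells)
        sigs = {tree_signature(t) for t in trees}
        topos = {topology_signature(t) for t in trees}
        assert len(sigs) == 3
        assert len(topos) == 1


class TestProximity:
    def test_adjacent_pair_assigned_to_shared_ip(self):
        positions = [(0, 0, 0), (5, 0, 0), (200, 0, 0)]
        clone = make_clone([0.25, 0.25, 0.25], positions=positions)
        trees = enumerate_trees(assign_hierarchies(clone.cells), clone.cells)
        result = resolve_by_proximity(trees, clone.cells)
        assert result.status is ReconstructionStatus.RESOLVED_BY_PROXIMITY
        siblings = {
            frozenset(
                c.observed_cell.cell_id for c in node.children
            )
            for node in result.chosen.iter_nodes()
            if node.children
            and all(c.cell_type is K and c.observed_cell for c in node.children)
        }
        assert frozenset({"c.n1", "c.n2"}) in siblings

    def test_single_candidate_is_unique(self):
        clone = make_clone([0.5, 0.25])
        trees = enumerate_trees(assign_hierarchies(clone.cells), clone.cells)
        result = resolve_by_proximity(trees, clone.cells)
        assert result.status is ReconstructionStatus.UNIQUE
        assert result.chosen is trees[0]

    def test_missing_positions_never_guess(self):
        clone = make_clone([0.25, 0.25, 0.25])
        trees = enumerate_trees(assign_hierarchies(clone.cells), clone.cells)
        result = resolve_by_proximity(trees, clone.cells)
        assert result.status is ReconstructionStatus.AMBIGUOUS
        assert result.chosen is None


class TestAnnotate:
    def test_promoted_chain_patterns(self):
        clone = make_clone([0.5, 0.25])
        (tree,) = enumerate_trees(assign_hierarchies(clone.cells), clone.cells)
        annotated = annotate_generations(tree)
        assert [p for _, p in annotated.generations] == [
            DivisionPattern.N,
            DivisionPattern.N,
            DivisionPattern.EXIT,
        ]

    def test_simulated_tree_read_off(self, rng):
        tree = simulate_lineage(
            CloneSizeModel(), DEFAULT_TRANSITION_MATRIX, rng, max_size=10
        )
        annotated = annotate_generations(tree)
        assert annotated.generations == tree.generations

    def test_terminal_division_annotation(self):
        clone = make_clone([0.5, 0.25, 0.25])
        (tree,) = enumerate_trees(assign_hierarchies(clone.cells), clone.cells)
        annotated = annotate_generations(tree)
        assert [p for _, p in annotated.generations] == [
            DivisionPattern.N,
            DivisionPattern.NN_TERMINAL,
        ]

    def test_requires_rgp_root(self):
        clone = make_clone([0.25, 0.25])
        (tree,) = enumerate_trees(assign_hierarchies(clone.cells), clone.cells)
        with pytest.raises(ValueError):
            annotate_generations(tree)


class TestReconstructClone:
    def test_noiseless_simulations_recover_ground_truth(self, rng):
        noise = NoiseModel(
            daughter_fraction_sd=0.0, dropout_rate=0.0, background_level=1e-12
        )
        n_checked = 0
        for i in range(20):
            tree = simulate_lineage(
                CloneSizeModel(), DEFAULT_TRANSITION_MATRIX, rng,
                max_size=10, clone_id=f"c{i}",
            )
            clone, truth = make_observed_clone(tree, rng, noise=noise)
            result = reconstruct_clone(clone)
            if result.non_rgp:
                # degenerate 1/2/4-similar-cell clones are excluded by design
                continue
            assert result.status in (
                ReconstructionStatus.UNIQUE,
                ReconstructionStatus.RESOLVED_BY_PROXIMITY,
            )
            assert topology_signature(result.chosen) == topology_signature(
                canonicalize(truth)
            )
            n_checked += 1
        assert n_checked >= 10

    def test_single_cell_clone_is_neuron(self):
        result = reconstruct_clone(make_clone([0.7]))
        assert result.root_classification is CellType.NEURON
        assert result.non_rgp

    @pytest.mark.parametrize(
        "intensities,root",
        [([0.3, 0.31], B), ([0.25, 0.24, 0.26, 0.25], A)],
    )
    def test_similar_intensity_clones_flagged_non_rgp(self, intensities, root):
        result = reconstruct_clone(make_clone(intensities))
        assert result.root_classification is root
        assert result.non_rgp

    def test_deleted_mid_tree_neuron_fails(self):
        # ground truth N then IP: cells at 1/2 and two at 1/8; dropping one
        # IP sibling leaves {1/2, 1/8}, which admits no valid lineage
        result = reconstruct_clone(make_clone([0.5, 0.125]))
        assert result.status in (
            ReconstructionStatus.FAILED,
            ReconstructionStatus.AMBIGUOUS,
        )

    def test_oversized_clone_fails_cleanly(self):
        result = reconstruct_clone(make_clone([0.5] * 14))
        assert result.status is ReconstructionStatus.FAILED
        assert "guard" in result.note
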