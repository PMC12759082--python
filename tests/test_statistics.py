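"""Lineage statistics: generation summaries, decay fitting, transition
estimation, KL divergence, mixture EM and cumulative distance curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rgplineage import (
    CloneSizeModel,
    DEFAULT_TRANSITION_MATRIX,
    NoiseModel,
    ZeroTruncatedPoissonMixture,
    assign_hierarchies,
    cumulative_distance,
    draw_clone_size,
    estimate_transitions,
    fit_decay,
    fit_poisson_mixture,
    kl_divergence,
    make_observed_clone,
    simulate_lineage,
    summarize_generations,
)
from rgplineage.statistics import GenerationSummary, _chi2_contingency_safe
from rgplineage.types import DivisionPattern

from conftest import make_clone

N, IP, IPP = DivisionPattern.N, DivisionPattern.IP, DivisionPattern.IPP
EXIT = DivisionPattern.EXIT


def _summary_from_means(means):
    import pandas as pd

    g = np.arange(1, len(means) + 1)
    return GenerationSummary(
        table=pd.DataFrame(
            {
                "output_mean": means,
                "output_per_lineage": means,
                "n_dividing": np.ones_like(g),
            },
            index=g,
        )
    )


class TestSummaries:
    def test_single_tree_proportions(self):
        summary = summarize_generations([[IP, N, EXIT]])
        t = summary.table
        assert (t.loc[1, ["prop_IPP", "prop_IP", "prop_N"]] == [0, 1, 0]).all()
        assert (t.loc[2, ["prop_IPP", "prop_IP", "prop_N"]] == [0, 0, 1]).all()
        assert t.loc[3, "exit_fraction"] == 1.0

    def test_neuron_attribution_per_generation(self):
        summary = summarize_generations([[N, IPP, EXIT]])
        assert summary.table.loc[2, "output_mean"] == 4.0
        assert summary.table.loc[1, "output_mean"] == 1.0

    def test_switch_fraction(self):
        summary = summarize_generations([[N, N, IP, EXIT], [N, IP, IP, EXIT]])
        assert summary.table.loc[2, "switch_fraction"] == 0.5
        assert summary.table.loc[3, "switch_fraction"] == 0.5

    def test_g1_matches_feasibility_adjusted_uniform(self, rng):
        trees = [
            simulate_lineage(CloneSizeModel(), DEFAULT_TRANSITION_MATRIX, rng)
            for _ in range(6000)
        ]
        t = summarize_generations(trees).table
        # mixture mass with size >= 4 draws uniformly; smaller sizes shift
        # weight from IPP to IP/N, so IPP < 1/3 <= N
        assert t.loc[1, "prop_IPP"] < 1 / 3 < t.loc[1, "prop_N"]
        assert t.loc[1, ["prop_IPP", "prop_IP", "prop_N"]].sum() == pytest.approx(1.0)

    def test_unannotated_tree_rejected(self, small_trees):
        bare = small_trees[0].copy()
        bare.generations = []
        with pytest.raises(ValueError, match="unannotated"):
            summarize_generations([bare])


class TestDecay:
    def test_exact_geometric_series_recovers_ln2(self):
        fit = fit_decay(_summary_from_means([8.0, 4.0, 2.0, 1.0]))
        assert fit.rate == pytest.approx(-math.log(2), abs=1e-12)
        assert fit.amplitude == pytest.approx(16.0, rel=1e-9)

    def test_constant_series_gives_zero_rate(self):
        fit = fit_decay(_summary_from_means([3.0, 3.0, 3.0, 3.0]))
        assert fit.rate == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance_of_rate(self):
        a = fit_decay(_summary_from_means([8.0, 4.0, 2.0, 1.0]))
        b = fit_decay(_summary_from_means([80.0, 40.0, 20.0, 10.0]))
        assert a.rate == pytest.approx(b.rate, abs=1e-10)

    def test_too_few_generations_rejected(self):
        with pytest.raises(ValueError):
            fit_decay(_summary_from_means([4.0, 2.0]))


class TestTransitions:
    def test_single_lineage_counts(self):
        est = estimate_transitions([[N, N, N]])
        expected = np.zeros((3, 3))
        expected[2, 2] = 2
        np.testing.assert_array_equal(est.counts, expected)

    def test_exit_terminates_counting(self):
        est = estimate_transitions([[N, IP, EXIT]])
        assert est.n_pairs == 1
        assert est.counts[2, 1] == 1

    def test_max_generation_limits_pairs(self):
        est = estimate_transitions([[N] * 10], max_generation=4)
        assert est.n_pairs == 3

    def test_identical_rows_have_unit_homogeneity_p(self):
        table = np.array([[10, 20, 30], [10, 20, 30], [10, 20, 30]])
        chi2, p = _chi2_contingency_safe(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_recovery_from_annotated_trees(self, rng):
        model = CloneSizeModel(weights=(1.0, 0.0), rates=(25.0, 25.0))
        trees = [
            simulate_lineage(model, DEFAULT_TRANSITION_MATRIX, rng)
            for _ in range(3000)
        ]
        est = estimate_transitions(trees, unconstrained_only=True)
        assert np.nanmax(np.abs(est.matrix - DEFAULT_TRANSITION_MATRIX.p)) < 0.03

    def test_estimator_is_consistent(self, rng):
        from rgplineage.simulator import simulate_pattern_sequence

        model = CloneSizeModel(weights=(1.0, 0.0), rates=(25.0, 25.0))

        def err(n):
            seqs = [
                simulate_pattern_sequence(
                    draw_clone_size(model, rng), DEFAULT_TRANSITION_MATRIX, rng
                )
                for _ in range(n)
            ]
            est = estimate_transitions(seqs, unconstrained_only=True)
            return np.nanmax(np.abs(est.matrix - DEFAULT_TRANSITION_MATRIX.p))

        assert err(10000) < err(100)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_transitions([[N, EXIT]])  # no consecutive pairs


class TestKL:
    def test_identity_is_zero(self):
        assert kl_divergence([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == pytest.approx(0.0)

    def test_closed_form_example(self):
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        got = kl_divergence([0.5, 0.5], [0.25, 0.75], pseudocount=0.0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_asymmetry(self):
        a = kl_divergence([0.5, 0.5], [0.25, 0.75], pseudocount=0.0)
        b = kl_divergence([0.25, 0.75], [0.5, 0.5], pseudocount=0.0)
        assert a != pytest.approx(b)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence([0.5, 0.5], [1.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 10.0), min_size=2, max_size=8),
        st.data(),
    )
    def test_nonnegative_and_finite_with_pseudocount(self, p, data):
        q = data.draw(
            st.lists(
                st.floats(0.0, 10.0), min_size=len(p), max_size=len(p)
            )
        )
        value = kl_divergence(p, q, pseudocount=0.5)
        assert np.isfinite(value)
        assert value >= -1e-12


class TestMixture:
    def test_parameter_recovery(self, rng):
        model = CloneSizeModel()
        sizes = [draw_clone_size(model, rng) for _ in range(5000)]
        weights, rates, gof_p = fit_poisson_mixture(sizes)
        assert abs(rates[0] - 4.09) < 0.3
        assert abs(rates[1] - 7.62) < 0.3
        assert abs(weights[0] - 0.35) < 0.05
        assert gof_p > 0.01

    def test_single_component_truth_does_not_reject(self, rng):
        model = CloneSizeModel(weights=(1.0, 0.0), rates=(6.0, 6.0))
        sizes = [draw_clone_size(model, rng) for _ in range(3000)]
        fit = ZeroTruncatedPoissonMixture(n_components=2).fit(sizes)
        _, gof_p = fit.gof_chi2(sizes)
        merged = abs(fit.rates_[0] - fit.rates_[1]) < 0.5
        collapsed = fit.weights_.min() < 0.05
        assert merged or collapsed
        assert gof_p > 0.01

    def test_constant_sizes_flagged_degenerate(self):
        fit = ZeroTruncatedPoissonMixture().fit([5] * 40)
        assert fit.degenerate_

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ZeroTruncatedPoissonMixture().fit([3] * 10)


class TestCumulativeDistance:
    def test_within_level_pairs_are_tighter(self, rng):
        noise = NoiseModel(dropout_rate=0.0, background_level=1e-12)
        within_all, other_all = [], []
        for i in range(20):
            t = simulate_lineage(
                CloneSizeModel(), DEFAULT_TRANSITION_MATRIX, rng,
                max_size=10, clone_id=f"c{i}",
            )
            clone, _ = make_observed_clone(t, rng, noise=noise)
            if clone is None or len(clone) < 3:
                continue
            assignment = assign_hierarchies(clone.cells)
            result = cumulative_distance(clone, assignment)
            if result.defined:
                within_all.extend(result.within)
                other_all.extend(result.other)
        assert np.mean(within_all) < np.mean(other_all)

    def test_coincident_cells_give_zero_ks(self):
        clone = make_clone(
            [0.5, 0.25, 0.25], positions=[(0, 0, 0)] * 3
        )
        result = cumulative_distance(clone, assign_hierarchies(clone.cells))
        assert result.ks_statistic == 0.0

    def test_singleton_levels_flagged_undefined(self):
        clone = make_clone([0.5, 0.25], positions=[(0, 0, 0), (1, 1, 1)])
        result = cumulative_distance(clone, assign_hierarchies(clone.cells))
        assert not result.defined

    def test_ecdf_curves_are_valid(self):
        clone = make_clone(
            [0.25, 0.25, 0.5],
            positions=[(0, 0, 0), (5, 0, 0), (100, 0, 0)],
        )
        result = cumulative_distance(clone, assign_hierarchies(clone.cells))
        for which in ("within", "other"):
            d, f = result.ecdf(which)
            assert (np.diff(f) >= 0).all()
            assert f[-1] == pytest.approx(1.0)
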