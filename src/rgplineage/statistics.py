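"""Population-level statistics over collections of annotated lineage trees.

Covers generation summaries (pattern proportions, exits, switches, neuron
output), exponential decay of per-generation output, estimation and testing
of the division-pattern transition matrix, Kullback-Leibler comparison of
categorical distributions, EM fitting of the zero-truncated Poisson clone-
size mixture, and the cumulative pairwise-distance analysis of spatial
clustering.  The model-fitting operations are sklearn-style estimators;
module-level functions are thin wrappers kept for pipeline use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .reconstruction import HierarchyAssignment
from .types import (
    MARKOV_PATTERNS,
    PATTERN_NEURONS,
    Clone,
    DivisionPattern,
    LineageTree,
)

__all__ = [
    "GenerationSummary",
    "summarize_generations",
    "ExponentialDecayModel",
    "DecayFit",
    "fit_decay",
    "TransitionMatrixEstimator",
    "TransitionEstimate",
    "estimate_transitions",
    "kl_divergence",
    "ZeroTruncatedPoissonMixture",
    "fit_poisson_mixture",
    "CumulativeDistanceResult",
    "cumulative_distance",
]

PatternSeq = Sequence[tuple[DivisionPattern, bool]]
TreesOrSequences = Sequence[Union[LineageTree, PatternSeq]]


def _pattern_sequence(
    item: Union[LineageTree, PatternSeq]
) -> list[tuple[DivisionPattern, bool]]:
    """Normalise a tree or raw sequence into [(pattern, constrained), ...]."""

    if isinstance(item, LineageTree):
        if not item.generations:
            raise ValueError(
                f"tree {item.clone_id!r} is unannotated (empty generations)"
            )
        flags: dict[int, bool] = {
            n.generation: n.constrained
            for n in item.iter_nodes()
            if n.cell_type.value == "RGP" and n.generation is not None
        }
        return [
            (pat, flags.get(g, False)) for g, pat in item.generations
        ]
    out = []
    for entry in item:
        if isinstance(entry, DivisionPattern):
            out.append((entry, False))
        else:
            out.append((entry[0], entry[1]))
    return out


# ---------------------------------------------------------------------------
# generation summaries
# ---------------------------------------------------------------------------


@dataclass
class GenerationSummary:
    """Per-generation tallies over a lineage collection."""

    table: pd.DataFrame  # indexed by generation

    @property
    def generations(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def mean_output(self) -> np.ndarray:
        return self.table["output_mean"].to_numpy()


def summarize_generations(
    trees: TreesOrSequences, map_nn_to_n: bool = True
) -> GenerationSummary:
    """Tally division patterns, exits, switches and neuron output per generation.

    Neurons are attributed to the generation of the RGP division that
    spawned their sublineage (an IPP division at G2 contributes its four
    neurons to G2's output).  Pattern proportions are over lineages that
    divided at that generation; the exit fraction is over lineages alive
    entering it.
    """

    sequences = [_pattern_sequence(t) for t in trees]
    if not sequences:
        raise ValueError("no lineages to summarise")
    n_total = len(sequences)
    rows = {}
    gmax = max(len(seq) for seq in sequences)
    for g in range(1, gmax + 1):
        alive = [seq for seq in sequences if len(seq) >= g]
        pats = [seq[g - 1][0] for seq in alive]
        n_exit = sum(1 for p in pats if p is DivisionPattern.EXIT)
        dividing = [p for p in pats if p is not DivisionPattern.EXIT]
        outputs = [PATTERN_NEURONS.get(p, 0) for p in dividing]
        if map_nn_to_n:
            counted = [
                DivisionPattern.N if p is DivisionPattern.NN_TERMINAL else p
                for p in dividing
            ]
        else:
            counted = dividing
        switches = [
            seq[g - 1][0] != seq[g - 2][0]
            for seq in alive
            if g >= 2
            and seq[g - 1][0] is not DivisionPattern.EXIT
            and seq[g - 2][0] is not DivisionPattern.EXIT
        ]
        n_div = len(dividing)
        rows[g] = {
            "n_alive": len(alive),
            "n_dividing": n_div,
            "n_exit": n_exit,
            "exit_fraction": n_exit / len(alive) if alive else np.nan,
            "output_mean": float(np.mean(outputs)) if outputs else np.nan,
            "output_sd": float(np.std(outputs, ddof=1)) if len(outputs) > 1 else np.nan,
            "output_total": int(np.sum(outputs)),
            "output_per_lineage": float(np.sum(outputs)) / n_total,
            "prop_IPP": sum(p is DivisionPattern.IPP for p in counted) / n_div
            if n_div else np.nan,
            "prop_IP": sum(p is DivisionPattern.IP for p in counted) / n_div
            if n_div else np.nan,
            "prop_N": sum(p is DivisionPattern.N for p in counted) / n_div
            if n_div else np.nan,
            "switch_fraction": float(np.mean(switches)) if switches else np.nan,
        }
    return GenerationSummary(table=pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# exponential decay of per-generation output
# ---------------------------------------------------------------------------


@dataclass
class DecayFit:
    amplitude: float
    rate: float  # the decay index lambda in y = a * exp(lambda * g)
    residual_norm: float
    fallback_loglinear: bool = False

    def predict(self, g: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(self.rate * np.asarray(g, dtype=float))


class ExponentialDecayModel(BaseEstimator):
    """Least-squares fit of ``y = a * exp(lambda * g)``.

    Deterministic: the nonlinear fit is initialised from the log-linear
    regression on the positive observations.  If any observation is
    nonpositive the log-linear fit on the positive entries is returned and
    flagged.  Fitted attributes: ``amplitude_``, ``rate_``,
    ``residual_norm_``.
    """

    def fit(self, g: Sequence[float], y: Sequence[float]) -> "ExponentialDecayModel":
        g = np.asarray(g, dtype=float)
        y = np.asarray(y, dtype=float)
        mask = np.isfinite(y) & np.isfinite(g)
        g, y = g[mask], y[mask]
        if len(y) < 3:
            raise ValueError("decay fit needs at least three generations")
        pos = y > 0
        if not pos.any():
            raise ValueError("decay fit needs positive outputs")
        slope, intercept = np.polyfit(g[pos], np.log(y[pos]), 1)
        a0, lam0 = math.exp(intercept), slope
        self.fallback_ = not pos.all()
        if self.fallback_:
            a, lam = a0, lam0
        else:
            try:
                (a, lam), _ = optimize.curve_fit(
                    lambda x, a, lam: a * np.exp(lam * x), g, y,
                    p0=(a0, lam0), maxfev=10000,
                )
            except RuntimeError:
                a, lam = a0, lam0
                self.fallback_ = True
        self.amplitude_ = float(a)
        self.rate_ = float(lam)
        self.residual_norm_ = float(
            np.linalg.norm(y[pos] - a * np.exp(lam * g[pos]))
        )
        return self

    def predict(self, g: Sequence[float]) -> np.ndarray:
        check_is_fitted(self, "rate_")
        return self.amplitude_ * np.exp(self.rate_ * np.asarray(g, dtype=float))


def fit_decay(
    summary: GenerationSummary, column: str = "output_per_lineage"
) -> DecayFit:
    """Fit the exponential decay of neuron output across generations.

    By default the fitted series is the mean output per cohort lineage
    (exited lineages contribute zero), the quantity whose published decay
    indices are -0.4898 (experimental) and -0.3759 (in silico); pass
    ``column="output_mean"`` to fit the mean over still-dividing lineages
    instead.
    """

    tab = summary.table
    mask = (tab[column].to_numpy() > 0) & np.isfinite(tab[column].to_numpy())
    model = ExponentialDecayModel().fit(
        tab.index.to_numpy()[mask],
        tab[column].to_numpy()[mask],
    )
    return DecayFit(
        amplitude=model.amplitude_,
        rate=model.rate_,
        residual_norm=model.residual_norm_,
        fallback_loglinear=model.fallback_,
    )


# ---------------------------------------------------------------------------
# transition-matrix estimation and tests
# ---------------------------------------------------------------------------


@dataclass
class TransitionEstimate:
    counts: np.ndarray                 # pooled 3x3 counts over (IPP, IP, N)
    counts_by_step: list[np.ndarray]   # one 3x3 per intergeneration
    matrix: np.ndarray                 # row-normalised pooled counts
    undefined_rows: list[int]
    dependency_chi2: float
    dependency_p: float
    homogeneity: dict[str, tuple[float, float]]  # row pattern -> (chi2, p)
    n_pairs: int


class TransitionMatrixEstimator(BaseEstimator):
    """Estimate the division-pattern transition matrix from lineages.

    Counts consecutive-generation pattern pairs over (IPP, IP, N) for
    generations below ``max_generation``; EXIT entries terminate counting
    and terminal two-neuron divisions map to N when ``map_nn_to_n``.  With
    ``unconstrained_only`` transitions whose draw was boundary-renormalised
    (a simulator ground-truth flag) are excluded, which makes the estimator
    unbiased for the base matrix; trees without flags count everything.

    Fitted attributes: ``matrix_``, ``counts_``, ``dependency_p_``,
    ``homogeneity_``.
    """

    def __init__(
        self,
        max_generation: int = 4,
        map_nn_to_n: bool = True,
        unconstrained_only: bool = False,
    ):
        self.max_generation = max_generation
        self.map_nn_to_n = map_nn_to_n
        self.unconstrained_only = unconstrained_only

    def fit(self, trees: TreesOrSequences) -> "TransitionMatrixEstimator":
        idx = {p: i for i, p in enumerate(MARKOV_PATTERNS)}
        n_steps = self.max_generation - 1
        by_step = [np.zeros((3, 3), dtype=int) for _ in range(n_steps)]
        for item in trees:
            seq = _pattern_sequence(item)
            mapped: list[Optional[tuple[int, bool]]] = []
            for pat, constrained in seq:
                if pat is DivisionPattern.EXIT or pat is DivisionPattern.SYMMETRIC:
                    mapped.append(None)
                    continue
                if pat is DivisionPattern.NN_TERMINAL:
                    pat = DivisionPattern.N if self.map_nn_to_n else None
                    if pat is None:
                        mapped.append(None)
                        continue
                mapped.append((idx[pat], constrained))
            for g in range(min(n_steps, len(mapped) - 1)):
                a, b = mapped[g], mapped[g + 1]
                if a is None or b is None:
                    continue
                if self.unconstrained_only and b[1]:
                    continue
                by_step[g][a[0], b[0]] += 1
        counts = np.sum(by_step, axis=0)
        if counts.sum() == 0:
            raise ValueError("no consecutive-generation pattern pairs found")
        row_sums = counts.sum(axis=1)
        matrix = np.full((3, 3), np.nan)
        undefined = []
        for i in range(3):
            if row_sums[i] > 0:
                matrix[i] = counts[i] / row_sums[i]
            else:
                undefined.append(i)
        chi2, p = _chi2_contingency_safe(counts)
        homogeneity: dict[str, tuple[float, float]] = {}
        for i, pat in enumerate(MARKOV_PATTERNS):
            if i in undefined:
                continue
            table = np.array([step[i] for step in by_step])
            homogeneity[pat.value] = _chi2_contingency_safe(table)
        self.counts_ = counts
        self.counts_by_step_ = by_step
        self.matrix_ = matrix
        self.undefined_rows_ = undefined
        self.dependency_chi2_, self.dependency_p_ = chi2, p
        self.homogeneity_ = homogeneity
        self.n_pairs_ = int(counts.sum())
        return self


def _chi2_contingency_safe(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a contingency table, dropping empty rows/cols."""

    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(t)
    return float(chi2), float(p)


def estimate_transitions(
    trees: TreesOrSequences,
    max_generation: int = 4,
    map_nn_to_n: bool = True,
    unconstrained_only: bool = False,
) -> TransitionEstimate:
    """Pooled transition matrix with dependency and homogeneity tests."""

    est = TransitionMatrixEstimator(
        max_generation=max_generation,
        map_nn_to_n=map_nn_to_n,
        unconstrained_only=unconstrained_only,
    ).fit(trees)
    return TransitionEstimate(
        counts=est.counts_,
        counts_by_step=est.counts_by_step_,
        matrix=est.matrix_,
        undefined_rows=est.undefined_rows_,
        dependency_chi2=est.dependency_chi2_,
        dependency_p=est.dependency_p_,
        homogeneity=est.homogeneity_,
        n_pairs=est.n_pairs_,
    )


# ---------------------------------------------------------------------------
# Kullback-Leibler divergence
# ---------------------------------------------------------------------------


def kl_divergence(
    p: Sequence[float], q: Sequence[float], pseudocount: float = 0.5
) -> float:
    """KL(p || q) in nats with pseudocount regularisation.

    Both vectors are augmented by ``pseudocount`` per bin and renormalised.
    Nonnegative; zero iff the (regularised) distributions coincide.  With
    ``pseudocount=0`` empty q-bins facing nonzero p-bins give ``inf``.
    """

    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be equal-length vectors")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probability vectors must be nonnegative")
    p = p + pseudocount
    q = q + pseudocount
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("vectors must have positive mass")
    p = p / p.sum()
    q = q / q.sum()
    terms = np.zeros_like(p)
    nz = p > 0
    with np.errstate(divide="ignore"):
        terms[nz] = p[nz] * (np.log(p[nz]) - np.log(q[nz]))
    return float(terms.sum())


# ---------------------------------------------------------------------------
# zero-truncated Poisson mixture (EM)
# ---------------------------------------------------------------------------


def _ztp_logpmf(k: np.ndarray, lam: float) -> np.ndarray:
    return stats.poisson.logpmf(k, lam) - math.log1p(-math.exp(-lam))


def _ztp_mean(lam: float) -> float:
    return lam / (1.0 - math.exp(-lam))


def _solve_ztp_rate(mean: float) -> float:
    """Invert m = lambda / (1 - exp(-lambda)) for lambda (m > 1)."""

    if mean <= 1.0 + 1e-9:
        return 1e-6
    return float(
        optimize.brentq(lambda lam: _ztp_mean(lam) - mean, 1e-9, mean + 50.0)
    )


class ZeroTruncatedPoissonMixture(BaseEstimator):
    """EM fit of a k-component zero-truncated Poisson mixture to clone sizes.

    Initialisation is a deterministic quantile split; convergence when the
    log-likelihood improves by less than ``tol`` (default 1e-8), capped at
    ``max_iter`` iterations.  A component whose weight collapses below
    ``degenerate_weight`` flags the fit as reduced.  Fitted attributes:
    ``weights_``, ``rates_``, ``loglik_``, ``converged_``, ``degenerate_``.
    """

    def __init__(
        self,
        n_components: int = 2,
        tol: float = 1e-8,
        max_iter: int = 500,
        degenerate_weight: float = 1e-6,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.degenerate_weight = degenerate_weight

    def fit(self, sizes: Sequence[int]) -> "ZeroTruncatedPoissonMixture":
        x = np.asarray(sizes, dtype=float)
        if len(x) < 20:
            raise ValueError("mixture fit needs at least 20 observations")
        if np.any(x < 1) or np.any(x != np.round(x)):
            raise ValueError("clone sizes must be integers >= 1")
        k = self.n_components
        if np.ptp(x) == 0:
            # all sizes identical: nothing to separate
            self.weights_ = np.array([1.0] + [0.0] * (k - 1))
            self.rates_ = np.array([_solve_ztp_rate(float(x[0]))] * k)
            self.loglik_ = float(np.sum(_ztp_logpmf(x, self.rates_[0])))
            self.converged_ = True
            self.degenerate_ = True
            return self
        # deterministic initialisation: quantile split
        qs = np.quantile(x, np.linspace(0, 1, k + 1))
        rates = []
        for j in range(k):
            part = x[(x >= qs[j]) & (x <= qs[j + 1])]
            m = float(part.mean()) if len(part) else float(x.mean())
            rates.append(_solve_ztp_rate(max(m, 1.05)))
        rates = np.asarray(rates, dtype=float)
        weights = np.full(k, 1.0 / k)
        loglik = -np.inf
        for _ in range(self.max_iter):
            logp = np.stack(
                [np.log(weights[j]) + _ztp_logpmf(x, rates[j]) for j in range(k)]
            )
            lse = np.logaddexp.reduce(logp, axis=0)
            new_loglik = float(lse.sum())
            resp = np.exp(logp - lse)
            weights = resp.mean(axis=1)
            for j in range(k):
                wsum = resp[j].sum()
                if wsum > 0:
                    rates[j] = _solve_ztp_rate(float(resp[j] @ x / wsum))
            if new_loglik - loglik < self.tol:
                loglik = new_loglik
                self.converged_ = True
                break
            loglik = new_loglik
        else:
            self.converged_ = False
        order = np.argsort(rates)
        self.rates_ = rates[order]
        self.weights_ = weights[order]
        self.loglik_ = loglik
        self.degenerate_ = bool(np.any(self.weights_ < self.degenerate_weight))
        return self

    def pmf(self, k: Sequence[int]) -> np.ndarray:
        check_is_fitted(self, "rates_")
        k = np.asarray(k, dtype=float)
        return sum(
            w * np.exp(_ztp_logpmf(k, lam))
            for w, lam in zip(self.weights_, self.rates_)
        )

    def gof_chi2(self, sizes: Sequence[int]) -> tuple[float, float]:
        """Goodness-of-fit chi-square with tail pooling (expected >= 5).

        Degrees of freedom: pooled bins - 1 - free parameters
        (2k - 1 for a k-component mixture).
        """

        check_is_fitted(self, "rates_")
        x = np.asarray(sizes)
        n = len(x)
        kmax = int(x.max())
        support = np.arange(1, kmax + 1)
        expected = self.pmf(support) * n
        # tail mass above kmax folded into the last bin
        expected[-1] += n * max(0.0, 1.0 - self.pmf(support).sum())
        observed = np.array([(x == v).sum() for v in support], dtype=float)
        obs_b, exp_b = _pool_bins(observed, expected, min_expected=5.0)
        n_params = 2 * self.n_components - 1
        dof = len(obs_b) - 1 - n_params
        chi2 = float(np.sum((obs_b - exp_b) ** 2 / exp_b))
        if dof < 1:
            return chi2, float("nan")
        return chi2, float(stats.chi2.sf(chi2, dof))


def _pool_bins(
    observed: np.ndarray, expected: np.ndarray, min_expected: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pool adjacent bins from the tail until every expected count is large."""

    obs, exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp:
        obs[-1] += acc_o
        exp[-1] += acc_e
    return np.asarray(obs), np.asarray(exp)


def fit_poisson_mixture(
    sizes: Sequence[int], k: int = 2
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit a k-component zero-truncated Poisson mixture to clone sizes.

    Returns ``(weights, rates, goodness-of-fit p)``.
    """

    model = ZeroTruncatedPoissonMixture(n_components=k).fit(sizes)
    _, p = model.gof_chi2(sizes)
    return model.weights_, model.rates_, p


# ---------------------------------------------------------------------------
# cumulative distance analysis
# ---------------------------------------------------------------------------


@dataclass
class CumulativeDistanceResult:
    """Pairwise-distance comparison of same-level vs different-level neurons.

    ``within`` pools all distances between neurons sharing an intensity
    hierarchy level (levels with >= 2 cells); ``other`` holds the remaining
    pairs.  A stochastically smaller ``within`` curve reflects the spatial
    clustering of sibling neurons from shared intermediate progenitors.
    """

    within: np.ndarray
    other: np.ndarray
    ks_statistic: float
    ks_p: float
    defined: bool = True

    def ecdf(self, which: str = "within") -> tuple[np.ndarray, np.ndarray]:
        d = np.sort(self.within if which == "within" else self.other)
        return d, np.arange(1, len(d) + 1) / len(d)


def cumulative_distance(
    clone: Clone, assignment: HierarchyAssignment
) -> CumulativeDistanceResult:
    """Compare distances within vs across intensity levels in one clone."""

    cells = [c for c in clone.cells if c.position is not None]
    if len(cells) < 2:
        raise ValueError("cumulative distance needs >= 2 positioned cells")
    levels = [assignment.levels[c.cell_id] for c in cells]
    within, other = [], []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            d = float(np.linalg.norm(cells[i].position - cells[j].position))
            (within if levels[i] == levels[j] else other).append(d)
    if not within:
        return CumulativeDistanceResult(
            within=np.array([]), other=np.asarray(other),
            ks_statistic=float("nan"), ks_p=float("nan"), defined=False,
        )
    within_a, other_a = np.asarray(within), np.asarray(other)
    if not other:
        return CumulativeDistanceResult(
            within=within_a, other=other_a,
            ks_statistic=float("nan"), ks_p=float("nan"), defined=False,
        )
    if np.ptp(np.concatenate([within_a, other_a])) == 0:
        ks, p = 0.0, 1.0
    else:
        res = stats.ks_2samp(within_a, other_a)
        ks, p = float(res.statistic), float(res.pvalue)
    return CumulativeDistanceResult(
        within=within_a, other=other_a, ks_statistic=ks, ks_p=p,
    )
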