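"""Coalition games over network elements and Shapley-value estimation.

The characteristic function ``v(S)`` is the task performance of the network
with every element *outside* ``S`` lesioned; the grand coalition ``N`` is the
intact network.  An element's Shapley value

    gamma_i = (1/n!) * sum over orderings R of  Delta_i(S_i(R)),
    Delta_i(S) = v(S u {i}) - v(S),

is its marginal contribution averaged over all orderings (``S_i(R)`` is the
set preceding ``i`` in ``R``).  ``exact_shapley`` evaluates the equivalent
subset-weighted sum; ``sampled_shapley`` is the unbiased estimator that
samples uniform orderings and walks each one as a chain of nested coalitions,
memoising coalition values so shared prefixes are never re-evaluated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats as _stats
from .netmodel import (
    CapacityError,
    Genome,
    LesionMask,
    ValidationError,
    node_lesion_mask,
    prune_disabled,
)
from .toytask import TaskSpec, trial_scores

__all__ = [
    "CoalitionGame",
    "ShapleyTable",
    "SPAResult",
    "lesion_game",
    "marginal_contribution",
    "exact_shapley",
    "sampled_shapley",
    "spa",
    "shapley_fraction",
    "rank_table",
]

EXACT_LIMIT = 12  # largest n for exhaustive 2^n subset enumeration


class CoalitionGame:
    """A characteristic function v over subsets of elements, with memoisation.

    ``value_fn(subset, replicates)`` must return one worth per requested
    replicate index and be deterministic given ``(subset, replicate)``; the
    cache therefore never changes returned values, it only avoids recompute.
    ``eval_count`` counts underlying (cache-miss) evaluations and
    ``unique_coalitions`` the distinct subsets evaluated.
    """

    def __init__(
        self,
        elements: Sequence[Hashable],
        value_fn: Callable[[frozenset, tuple[int, ...]], np.ndarray],
        stochastic: bool = False,
        caching: bool = True,
    ):
        if len(set(elements)) != len(elements):
            raise ValidationError("duplicate elements")
        self.elements: tuple = tuple(elements)
        self._value_fn = value_fn
        self.stochastic = stochastic
        self.caching = caching
        self.eval_count = 0
        self._cache: dict[tuple[frozenset, int], float] = {}
        self._seen: set[frozenset] = set()

    @property
    def n(self) -> int:
        return len(self.elements)

    @property
    def grand(self) -> frozenset:
        return frozenset(self.elements)

    @property
    def unique_coalitions(self) -> int:
        return len(self._seen)

    @classmethod
    def from_function(
        cls, elements: Sequence[Hashable], fn: Callable[[frozenset], float]
    ) -> "CoalitionGame":
        """Wrap a deterministic subset -> worth function (replicates ignored)."""

        def value_fn(S: frozenset, reps: tuple[int, ...]) -> np.ndarray:
            return np.full(len(reps), float(fn(S)))

        return cls(elements, value_fn, stochastic=False)

    def _check(self, subset: Iterable) -> frozenset:
        S = frozenset(subset)
        extra = S - self.grand
        if extra:
            raise ValidationError(f"unknown elements {extra}")
        return S

    def values(self, subset: Iterable, replicates: Sequence[int]) -> np.ndarray:
        """Worth of ``subset`` for each replicate index (batched, cached)."""
        S = self._check(subset)
        self._seen.add(S)
        reps = [int(r) for r in replicates]
        missing = [r for r in reps if (S, r) not in self._cache]
        if missing or not self.caching:
            todo = reps if not self.caching else missing
            vals = np.asarray(self._value_fn(S, tuple(todo)), dtype=float)
            self.eval_count += len(todo)
            for r, v in zip(todo, vals):
                self._cache[(S, r)] = float(v)
        return np.array([self._cache[(S, r)] for r in reps])

    def value(self, subset: Iterable, replicate: int = 0) -> float:
        return float(self.values(subset, [replicate])[0])


def lesion_game(
    genome: Genome,
    task: TaskSpec,
    granularity: str = "connections",
    plays_per_eval: int = 16,
    seed: int = 0,
) -> CoalitionGame:
    """Coalition game whose worth is lesioned-network task performance.

    Elements are node ids (``granularity="nodes"``; node elements expand to
    full incoming+outgoing connection lesions) or enabled-connection keys
    (``granularity="connections"``).  ``v(S, replicate=r)`` is the mean score
    of ``plays_per_eval`` episodes of the network with every element not in
    ``S`` lesioned; the episode noise stream is derived from
    ``(seed, lesion mask, r)`` so a coalition's worth is reproducible and
    identical whenever it is revisited.
    """
    genome = prune_disabled(genome)
    if granularity == "nodes":
        elements = [n.id for n in genome.nodes]
        masks = {i: node_lesion_mask(genome, i) for i in elements}
    elif granularity == "connections":
        elements = list(genome.connection_keys())
        masks = {
            k: LesionMask(disabled_connections=frozenset({k})) for k in elements
        }
    else:
        raise ValidationError(f"unknown granularity {granularity!r}")

    def value_fn(S: frozenset, reps: tuple[int, ...]) -> np.ndarray:
        lesioned = [e for e in elements if e not in S]
        mask = LesionMask()
        for e in lesioned:
            mask = mask | masks[e]
        return trial_scores(genome, task, mask, plays_per_eval, reps, seed)

    return CoalitionGame(elements, value_fn, stochastic=task.noise_sd > 0)


def marginal_contribution(game: CoalitionGame, i: Hashable, S: Iterable) -> float:
    """``Delta_i(S) = v(S u {i}) - v(S)``; requires ``i`` not in ``S``."""
    S = frozenset(S)
    if i in S:
        raise ValidationError(f"element {i!r} already in coalition")
    return game.value(S | {i}) - game.value(S)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class ShapleyTable:
    """Per-element Shapley estimates with their contribution samples.

    ``contributions[e]`` holds the per-ordering marginal samples (sampled
    estimator) or the per-subset marginals with matching ``weights[e]``
    (exact computation); ``gamma`` is their (weighted) mean.
    """

    elements: tuple
    gamma: dict
    contributions: dict
    ci_low: dict
    ci_high: dict
    n_permutations: int
    weights: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "element": [str(e) for e in self.elements],
                "gamma": [self.gamma[e] for e in self.elements],
                "ci_low": [self.ci_low[e] for e in self.elements],
                "ci_high": [self.ci_high[e] for e in self.elements],
            }
        )
        df["n_permutations"] = self.n_permutations
        df["rank"] = df["gamma"].rank(ascending=False, method="first").astype(int)
        return df

    def total(self) -> float:
        return float(sum(self.gamma.values()))


@dataclass
class SPAResult:
    """Single-element perturbation analysis: one lesion at a time."""

    elements: tuple
    intact: np.ndarray  # (n_trials,) intact trial scores
    lesioned: dict  # element -> (n_trials,) lesioned trial scores
    effect: dict  # element -> mean(lesioned) - mean(intact)
    p_value: dict
    significant: dict
    alpha_corrected: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element": [str(e) for e in self.elements],
                "mean_intact": float(self.intact.mean()),
                "mean_lesioned": [self.lesioned[e].mean() for e in self.elements],
                "effect": [self.effect[e] for e in self.elements],
                "p": [self.p_value[e] for e in self.elements],
                "significant": [self.significant[e] for e in self.elements],
            }
        )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def exact_shapley(game: CoalitionGame, limit: int = EXACT_LIMIT) -> ShapleyTable:
    """Exact Shapley values by the subset-weighted sum over all 2^n coalitions.

    gamma_i = sum_{S subseteq N\\{i}} |S|! (n-|S|-1)! / n! * Delta_i(S),
    identical to averaging marginals over all n! orderings.  Stochastic games
    are evaluated at replicate 0 (their replicate-averaged worth).
    """
    n = game.n
    if n > limit:
        raise CapacityError(
            f"n={n} exceeds the exact enumeration limit {limit}; "
            "use sampled_shapley"
        )
    elems = game.elements
    # one pass caching every subset value
    v = {S: game.value(S) for k in range(n + 1) for S in map(frozenset, itertools.combinations(elems, k))}
    fact = [math.factorial(k) for k in range(n + 1)]
    gamma, contribs, weights = {}, {}, {}
    for i in elems:
        rest = [e for e in elems if e != i]
        deltas, w = [], []
        for k in range(n):
            wk = fact[k] * fact[n - k - 1] / fact[n]
            for S in map(frozenset, itertools.combinations(rest, k)):
                deltas.append(v[S | {i}] - v[S])
                w.append(wk)
        deltas, w = np.array(deltas), np.array(w)
        gamma[i] = float(np.sum(deltas * w))
        contribs[i], weights[i] = deltas, w
    return ShapleyTable(
        elements=elems,
        gamma=gamma,
        contributions=contribs,
        ci_low=dict(gamma),
        ci_high=dict(gamma),
        n_permutations=0,
        weights=weights,
    )


def sampled_shapley(
    game: CoalitionGame,
    n_permutations: int = 1000,
    seed: int = 0,
    n_boot: int = 10000,
    ci_level: float = 0.95,
) -> ShapleyTable:
    """Permutation-sampling Shapley estimator.

    Draws ``n_permutations`` uniform orderings (with replacement) of the
    elements; each ordering is walked from the empty coalition upward, so it
    costs at most n+1 coalition evaluations and every element receives one
    marginal-contribution sample per ordering.  ``gamma`` is the sample mean;
    confidence bounds are percentile-bootstrap intervals of that mean.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    elems = game.elements
    n = game.n
    contribs = {e: np.empty(n_permutations) for e in elems}
    for p in range(n_permutations):
        order = [elems[k] for k in rng.permutation(n)]
        S: frozenset = frozenset()
        v_prev = game.value(S)
        for e in order:
            S = S | {e}
            v_new = game.value(S)
            contribs[e][p] = v_new - v_prev
            v_prev = v_new
    gamma = {e: float(c.mean()) for e, c in contribs.items()}
    ci_low, ci_high = {}, {}
    ci_seed = np.random.SeedSequence(entropy=seed, spawn_key=(1,)).generate_state(1)[0]
    for e in elems:
        lo, hi = _stats.percentile_ci(
            contribs[e], level=ci_level, n_boot=n_boot, seed=int(ci_seed)
        )
        ci_low[e], ci_high[e] = lo, hi
    return ShapleyTable(
        elements=elems,
        gamma=gamma,
        contributions=contribs,
        ci_low=ci_low,
        ci_high=ci_high,
        n_permutations=n_permutations,
    )


def spa(
    game: CoalitionGame,
    n_trials: int = 512,
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SPAResult:
    """Single-element perturbation analysis over a coalition game.

    For each element ``i`` the worth ``v(N \\ {i})`` is replicated
    ``n_trials`` times and compared with the intact distribution ``v(N)``;
    the effect is the mean difference, tested against the intact mean with
    the mean-shifted bootstrap and a Bonferroni-corrected alpha.
    """
    reps = range(n_trials)
    intact = game.values(game.grand, reps)
    alpha_c = _stats.bonferroni_alpha(alpha, game.n)
    lesioned, effect, pval, signif = {}, {}, {}, {}
    for k, e in enumerate(game.elements):
        scores = game.values(game.grand - {e}, reps)
        lesioned[e] = scores
        effect[e] = float(scores.mean() - intact.mean())
        res = _stats.bootstrap_p(
            scores,
            h0_mean=float(intact.mean()),
            n_boot=n_boot,
            side="two_sided",
            seed=seed + k,
        )
        pval[e] = res.p_value
        signif[e] = bool(res.p_value < alpha_c)
    return SPAResult(
        elements=game.elements,
        intact=intact,
        lesioned=lesioned,
        effect=effect,
        p_value=pval,
        significant=signif,
        alpha_corrected=alpha_c,
    )


def shapley_fraction(gamma: float, v_total: float) -> int:
    """Integer percent share of total performance attributed to an element.

    Truncates ``100 * gamma / v_total`` toward zero, so a value of 80 out of
    a 337-point total accounts for 23 percent.
    """
    if v_total == 0:
        raise ZeroDivisionError("total performance is zero")
    return int(100.0 * gamma / v_total)


def rank_table(spa_result: SPAResult, table: ShapleyTable) -> pd.DataFrame:
    """Side-by-side element ranking under SPA (most damaging lesion first)
    and MSA (largest Shapley value first)."""
    if set(spa_result.elements) != set(table.elements):
        raise ValidationError("SPA and Shapley tables cover different elements")
    elems = list(table.elements)
    eff = np.array([spa_result.effect[e] for e in elems])
    gam = np.array([table.gamma[e] for e in elems])
    df = pd.DataFrame(
        {
            "element": [str(e) for e in elems],
            "spa_effect": eff,
            "gamma": gam,
        }
    )
    df["spa_rank"] = df["spa_effect"].rank(ascending=True, method="first").astype(int)
    df["msa_rank"] = df["gamma"].rank(ascending=False, method="first").astype(int)
    return df
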