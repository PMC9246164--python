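"""Pairwise Causal Interaction Analysis (PCIA) and paradoxical-lesion detection.

For a pair of elements (i, j) three Shapley values are estimated on the same
base game: the joint value gamma_(ij) of the fused compound element, and the
conditioned values gamma(i, j-bar) and gamma(j, i-bar) of each element in a
game where the other is permanently lesioned.  Their difference

    I_ij = gamma_(ij) - gamma(i, j-bar) - gamma(j, i-bar)

is the interaction term: positive means net-synergy (the pair contributes
more jointly than individually), negative net-redundancy.  A paradoxical
lesion (Sprague) effect from i to j is declared when

    gamma(i, j-bar) < 0   and   I_ij + gamma(i, j-bar) > 0,

i.e. i actively hurts performance once j is lesioned although the pair as a
whole is beneficial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

import numpy as np
import pandas as pd

from .netmodel import ValidationError
from .shapley import CoalitionGame, ShapleyTable, exact_shapley, sampled_shapley

__all__ = [
    "PairAnalysis",
    "InteractionMatrix",
    "SpragueEdge",
    "compound_game",
    "conditioned_game",
    "interaction_term",
    "pair_analysis",
    "interaction_matrix",
    "threshold_pairs",
    "detect_sprague",
]


def compound_game(game: CoalitionGame, pair: tuple) -> CoalitionGame:
    """Fuse ``pair = (i, j)`` into one compound element.

    The compound is intact iff both members are intact; worth is delegated to
    (and cached by) the base game.  The compound element is labelled by the
    frozenset ``{i, j}``.
    """
    i, j = pair
    if i == j:
        raise ValidationError("compound pair must be two distinct elements")
    if i not in game.elements or j not in game.elements:
        raise ValidationError("pair members must be elements of the game")
    label = frozenset({i, j})
    others = tuple(e for e in game.elements if e not in (i, j))

    def value_fn(S: frozenset, reps):
        base = set(S - {label})
        if label in S:
            base |= {i, j}
        return game.values(base, reps)

    return CoalitionGame(others + (label,), value_fn, stochastic=game.stochastic)


def conditioned_game(
    game: CoalitionGame,
    target_pool: Iterable,
    always_lesioned: Iterable = (),
) -> CoalitionGame:
    """Restrict the game to ``target_pool`` with ``always_lesioned`` held out.

    Elements outside both sets are intact in every evaluated coalition;
    members of ``always_lesioned`` are never intact.  Orderings range over
    the pool only.
    """
    pool = tuple(target_pool)
    out = frozenset(always_lesioned)
    if out & set(pool):
        raise ValidationError("target_pool and always_lesioned overlap")
    background = game.grand - set(pool) - out

    def value_fn(S: frozenset, reps):
        return game.values(S | background, reps)

    return CoalitionGame(pool, value_fn, stochastic=game.stochastic)


@dataclass(frozen=True)
class PairAnalysis:
    """Joint and conditioned Shapley values of one unordered pair."""

    i: Hashable
    j: Hashable
    gamma_joint: float
    gamma_i_given_j_lesioned: float
    gamma_j_given_i_lesioned: float

    @property
    def interaction(self) -> float:
        return (
            self.gamma_joint
            - self.gamma_i_given_j_lesioned
            - self.gamma_j_given_i_lesioned
        )

    def conditioned(self, stem: Hashable) -> float:
        """gamma(stem, other-bar): stem's value with the other member lesioned."""
        if stem == self.i:
            return self.gamma_i_given_j_lesioned
        if stem == self.j:
            return self.gamma_j_given_i_lesioned
        raise ValidationError(f"{stem!r} is not a member of this pair")


@dataclass(frozen=True)
class SpragueEdge:
    """Directed paradoxical-lesion edge: lesioning ``head`` reveals the
    disruptive role of ``stem`` (gamma(stem, head-bar) < 0 while the pair is
    jointly beneficial)."""

    stem: Hashable
    head: Hashable
    interaction: float
    gamma_conditioned: float


def interaction_term(
    gamma_joint: float, gamma_i_cond: float, gamma_j_cond: float
) -> float:
    """I_ij = gamma_(ij) - gamma(i, j-bar) - gamma(j, i-bar)."""
    return gamma_joint - gamma_i_cond - gamma_j_cond


def _gamma_of(game: CoalitionGame, element, n_permutations, seed, exact) -> float:
    if exact:
        return exact_shapley(game).gamma[element]
    # CIs are not consumed here; a token bootstrap keeps this call cheap
    t = sampled_shapley(game, n_permutations=n_permutations, seed=seed, n_boot=200)
    return t.gamma[element]


def pair_analysis(
    game: CoalitionGame,
    i: Hashable,
    j: Hashable,
    n_permutations: int = 100,
    seed: int = 0,
    exact: bool = False,
) -> PairAnalysis:
    """Estimate the three Shapley values of the pair on the shared base game."""
    label = frozenset({i, j})
    ss = np.random.SeedSequence(entropy=seed).generate_state(3)
    g_joint = _gamma_of(
        compound_game(game, (i, j)), label, n_permutations, int(ss[0]), exact
    )
    pool_i = [e for e in game.elements if e != j]
    g_i = _gamma_of(
        conditioned_game(game, pool_i, {j}), i, n_permutations, int(ss[1]), exact
    )
    pool_j = [e for e in game.elements if e != i]
    g_j = _gamma_of(
        conditioned_game(game, pool_j, {i}), j, n_permutations, int(ss[2]), exact
    )
    return PairAnalysis(i, j, g_joint, g_i, g_j)


@dataclass
class InteractionMatrix:
    """Symmetric matrix of interaction terms over all element pairs."""

    elements: tuple
    analyses: dict  # frozenset({i, j}) -> PairAnalysis
    n_permutations: int

    def interaction(self, i, j) -> float:
        return self.analyses[frozenset({i, j})].interaction

    @property
    def entries(self) -> np.ndarray:
        """Unique unordered off-diagonal interaction values."""
        return np.array([a.interaction for a in self.analyses.values()])

    @property
    def mean(self) -> float:
        return float(self.entries.mean())

    @property
    def sd(self) -> float:
        return float(self.entries.std(ddof=0))

    def to_frame(self) -> pd.DataFrame:
        n = len(self.elements)
        m = np.full((n, n), np.nan)
        for k, a in enumerate(self.elements):
            for l in range(k + 1, n):
                val = self.interaction(a, self.elements[l])
                m[k, l] = m[l, k] = val
        labels = [str(e) for e in self.elements]
        return pd.DataFrame(m, index=labels, columns=labels)


def interaction_matrix(
    game: CoalitionGame,
    n_permutations: int = 100,
    seed: int = 0,
    exact: bool = False,
) -> InteractionMatrix:
    """PairAnalysis for every unordered pair at the given permutation budget."""
    if game.n < 2:
        raise ValidationError("need at least 2 elements")
    elems = game.elements
    analyses = {}
    ss = np.random.SeedSequence(entropy=seed)
    pair_seeds = ss.generate_state(game.n * (game.n - 1) // 2)
    k = 0
    for a in range(game.n):
        for b in range(a + 1, game.n):
            i, j = elems[a], elems[b]
            analyses[frozenset({i, j})] = pair_analysis(
                game, i, j, n_permutations, int(pair_seeds[k]), exact
            )
            k += 1
    return InteractionMatrix(elems, analyses, n_permutations)


def threshold_pairs(matrix: InteractionMatrix, k_sd: float = 2.0) -> set:
    """Pairs whose interaction lies more than ``k_sd`` SDs from the mean.

    With zero spread (all entries equal) no pair survives.
    """
    sd = matrix.sd
    if sd == 0.0:
        return set()
    mean = matrix.mean
    return {
        pair
        for pair, a in matrix.analyses.items()
        if abs(a.interaction - mean) > k_sd * sd
    }


def detect_sprague(pairs: Iterable, matrix: InteractionMatrix) -> list[SpragueEdge]:
    """Test both ordered directions of each surviving pair for the Sprague
    condition; both directions may fire independently."""
    edges = []
    for pair in pairs:
        if pair not in matrix.analyses:
            raise ValidationError(f"pair {set(pair)} was not analysed")
        a = matrix.analyses[pair]
        for stem, head in ((a.i, a.j), (a.j, a.i)):
            g_cond = a.conditioned(stem)
            if g_cond < 0 and a.interaction + g_cond > 0:
                edges.append(SpragueEdge(stem, head, a.interaction, g_cond))
    return edges
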