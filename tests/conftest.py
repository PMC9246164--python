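import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netmsa import CoalitionGame, Genome, TaskSpec, make_motif_genome

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def motif() -> Genome:
    return make_motif_genome()


@pytest.fixture(scope="session")
def task() -> TaskSpec:
    return TaskSpec(seed=7)


def random_game(n: int, seed: int) -> CoalitionGame:
    """A random deterministic game on n elements (worths iid normal)."""
    rng = np.random.default_rng(seed)
    elems = list(range(n))
    table = {
        frozenset(c): float(rng.normal())
        for k in range(n + 1)
        for c in itertools.combinations(elems, k)
    }
    table[frozenset()] = 0.0
    return CoalitionGame.from_function(elems, lambda S: table[S])


def brute_force_shapley(game: CoalitionGame) -> dict:
    """Oracle: average marginals over every one of the n! orderings."""
    elems = game.elements
    v = {
        frozenset(c): game.value(c)
        for k in range(len(elems) + 1)
        for c in itertools.combinations(elems, k)
    }
    totals = {e: 0.0 for e in elems}
    count = 0
    for order in itertools.permutations(elems):
        S = frozenset()
        for e in order:
            S2 = S | {e}
            totals[e] += v[S2] - v[S]
            S = S2
        count += 1
    return {e: t / count for e, t in totals.items()}


@pytest.fixture(scope="session")
def small_game() -> CoalitionGame:
    return random_game(4, seed=5)
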