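import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netmsa import (
    CapacityError,
    CoalitionGame,
    TaskSpec,
    ValidationError,
    canonical_games,
    exact_shapley,
    lesion_game,
    marginal_contribution,
    rank_table,
    sampled_shapley,
    shapley_fraction,
    spa,
)
from .conftest import brute_force_shapley, random_game

GAMES = {g.name: g for g in canonical_games()}


def as_coalition_game(cg) -> CoalitionGame:
    return CoalitionGame.from_function(cg.elements, cg.value_fn)


# -- CoalitionGame mechanics ------------------------------------------------


def test_cache_counts_unique_evaluations():
    g = random_game(4, seed=5)
    before = g.eval_count
    g.value({0, 1})
    g.value({0, 1})
    g.value({1, 0})
    assert g.eval_count == before + 1
    assert frozenset({0, 1}) in {frozenset({0, 1})}  # sanity
    g.value({0})
    assert g.eval_count == before + 2
    assert g.unique_coalitions >= 2


def test_game_rejects_unknown_elements_and_duplicates(small_game):
    with pytest.raises(ValidationError):
        small_game.value({99})
    with pytest.raises(ValidationError):
        CoalitionGame.from_function([1, 1], lambda S: 0.0)


def test_values_batched_replicates():
    calls = []

    def fn(S, reps):
        calls.append((S, reps))
        return np.full(len(reps), float(len(S)))

    g = CoalitionGame(["a", "b"], fn, stochastic=True)
    v = g.values({"a"}, [0, 1, 2])
    np.testing.assert_array_equal(v, [1.0, 1.0, 1.0])
    v2 = g.values({"a"}, [1, 3])
    assert len(calls) == 2 and calls[1][1] == (3,)
    np.testing.assert_array_equal(v2, [1.0, 1.0])


def test_marginal_contribution():
    add = as_coalition_game(GAMES["additive"])
    assert marginal_contribution(add, "b", set()) == 2.0
    assert marginal_contribution(add, "b", {"a", "c"}) == 2.0
    una = as_coalition_game(GAMES["unanimity-pair"])
    assert marginal_contribution(una, "a", {"b"}) == 1.0
    assert marginal_contribution(una, "a", set()) == 0.0
    glove = as_coalition_game(GAMES["glove"])
    assert marginal_contribution(glove, "L", {"R1"}) == 1.0
    with pytest.raises(ValidationError):
        marginal_contribution(add, "a", {"a"})


# -- exact estimator --------------------------------------------------------


@pytest.mark.parametrize("name", list(GAMES))
def test_exact_recovers_closed_forms(name):
    cg = GAMES[name]
    table = exact_shapley(as_coalition_game(cg))
    if cg.closed_form_shapley is None:
        return
    for e, expected in cg.closed_form_shapley.items():
        assert table.gamma[e] == pytest.approx(expected, abs=1e-12)


def test_exact_capacity_error():
    g = CoalitionGame.from_function(range(13), lambda S: float(len(S)))
    with pytest.raises(CapacityError):
        exact_shapley(g)
    exact_shapley(g, limit=13)  # explicit limit overrides


def test_exact_matches_brute_force_small():
    for seed in range(5):
        g = random_game(4, seed)
        oracle = brute_force_shapley(g)
        table = exact_shapley(g)
        for e in g.elements:
            assert table.gamma[e] == pytest.approx(oracle[e], abs=1e-9)


def test_exact_efficiency_and_weights(small_game):
    table = exact_shapley(small_game)
    assert table.total() == pytest.approx(
        small_game.value(small_game.grand) - small_game.value(frozenset()), abs=1e-9
    )
    for e in small_game.elements:
        # gamma is the weighted mean of the stored marginals
        assert table.gamma[e] == pytest.approx(
            float(np.sum(table.contributions[e] * table.weights[e])), abs=1e-12
        )
        assert table.weights[e].sum() == pytest.approx(1.0)


# -- sampled estimator ------------------------------------------------------


def test_sampled_additive_is_exact_any_budget():
    g = as_coalition_game(GAMES["additive"])
    t = sampled_shapley(g, n_permutations=7, seed=0, n_boot=100)
    assert t.gamma == {"a": 1.0, "b": 2.0, "c": 3.0}


def test_sampled_glove_converges():
    g = as_coalition_game(GAMES["glove"])
    t = sampled_shapley(g, n_permutations=1000, seed=0, n_boot=200)
    assert t.gamma["L"] == pytest.approx(2.0 / 3.0, abs=0.05)


@given(st.integers(0, 2**31 - 1))
def test_sampled_telescoping_efficiency(seed):
    g = random_game(5, seed=3)
    t = sampled_shapley(g, n_permutations=20, seed=seed, n_boot=50)
    v_span = g.value(g.grand) - g.value(frozenset())
    # telescoping holds per permutation, hence exactly in the mean
    per_perm = np.sum([t.contributions[e] for e in g.elements], axis=0)
    np.testing.assert_allclose(per_perm, v_span, atol=1e-9)
    assert t.total() == pytest.approx(v_span, abs=1e-9)


def test_sampled_determinism_and_ci_order():
    g = random_game(5, seed=9)
    a = sampled_shapley(g, n_permutations=50, seed=4, n_boot=200)
    b = sampled_shapley(random_game(5, seed=9), n_permutations=50, seed=4, n_boot=200)
    assert a.gamma == b.gamma and a.ci_low == b.ci_low
    for e in g.elements:
        assert a.ci_low[e] <= a.gamma[e] <= a.ci_high[e]


def test_sampled_prefix_walk_cost_bound():
    g = random_game(5, seed=2)
    sampled_shapley(g, n_permutations=10, seed=0, n_boot=50)
    # each ordering costs at most n+1 coalition evaluations
    assert g.eval_count <= 10 * (g.n + 1)
    assert g.unique_coalitions <= g.eval_count


def test_sampled_validation():
    with pytest.raises(ValidationError):
        sampled_shapley(random_game(3, 0), n_permutations=0)


def test_null_player_zero_in_both_estimators():
    def fn(S):
        return float(2 * ("a" in S) + 3 * ("b" in S))

    g = CoalitionGame.from_function(["a", "b", "dummy"], fn)
    assert exact_shapley(g).gamma["dummy"] == 0.0
    g2 = CoalitionGame.from_function(["a", "b", "dummy"], fn)
    assert sampled_shapley(g2, n_permutations=40, seed=0, n_boot=50).gamma["dummy"] == 0.0


def test_symmetry_axiom_exact():
    t = exact_shapley(as_coalition_game(GAMES["or-pair"]))
    assert t.gamma["a"] == pytest.approx(t.gamma["b"], abs=1e-12)


def test_linearity_axiom_exact():
    g1, g2 = random_game(4, 21), random_game(4, 22)

    def combo(S):
        return 2.0 * g1.value(S) + 3.0 * g2.value(S)

    gc = CoalitionGame.from_function(g1.elements, combo)
    t1, t2, tc = exact_shapley(g1), exact_shapley(g2), exact_shapley(gc)
    for e in g1.elements:
        assert tc.gamma[e] == pytest.approx(2 * t1.gamma[e] + 3 * t2.gamma[e], abs=1e-9)


# -- lesion game ------------------------------------------------------------


@pytest.fixture(scope="module")
def motif_conn_game(motif, task):
    return lesion_game(motif, task, "connections", plays_per_eval=2, seed=13)


def test_lesion_game_elements(motif, motif_conn_game):
    enabled = [c.key for c in motif.connections if c.enabled]
    assert list(motif_conn_game.elements) == enabled
    with pytest.raises(ValidationError):
        lesion_game(motif, TaskSpec(), granularity="edges")


def test_lesion_game_intact_matches_protocol(motif, task, motif_conn_game):
    from netmsa.toytask import trial_scores

    v = motif_conn_game.value(motif_conn_game.grand)
    expected = trial_scores(motif, task, None, 2, [0], 13)[0]
    assert v == pytest.approx(expected)


def test_lesion_game_self_loop_deficit(task, motif_conn_game):
    v = motif_conn_game.value(motif_conn_game.grand - {(0, 0)})
    assert v <= 0.3 * task.max_score


def test_lesion_game_node_granularity(motif, task):
    g = lesion_game(motif, task, "nodes", plays_per_eval=2, seed=13)
    assert set(g.elements) == {n.id for n in motif.nodes}
    # lesioning node 0 leaves performance within 5% of intact
    v_all = g.value(g.grand)
    v_no0 = g.value(g.grand - {0})
    assert abs(v_no0 - v_all) < 0.05 * task.max_score


# -- SPA, fractions, rank table ---------------------------------------------


def test_spa_effects_and_significance(task, motif_conn_game):
    res = spa(motif_conn_game, n_trials=32, n_boot=500, seed=0)
    assert res.effect[(0, 0)] <= -0.5 * task.max_score
    assert res.significant[(0, 0)]
    assert abs(res.effect[(-4, 0)]) < 0.05 * task.max_score
    assert res.intact.shape == (32,)
    assert res.alpha_corrected == pytest.approx(0.05 / motif_conn_game.n)
    df = res.to_frame()
    assert len(df) == motif_conn_game.n


def test_shapley_fraction_examples():
    assert shapley_fraction(80, 337) == 23
    assert shapley_fraction(0, 337) == 0
    assert shapley_fraction(337, 337) == 100
    assert shapley_fraction(-80, 337) == -23  # truncation toward zero
    with pytest.raises(ZeroDivisionError):
        shapley_fraction(1.0, 0.0)


def test_rank_table_is_permutation(small_game):
    res = spa(small_game, n_trials=4, n_boot=100)
    table = exact_shapley(small_game)
    df = rank_table(res, table)
    assert sorted(df["spa_rank"]) == list(range(1, small_game.n + 1))
    assert sorted(df["msa_rank"]) == list(range(1, small_game.n + 1))
    with pytest.raises(ValidationError):
        rank_table(res, exact_shapley(random_game(3, 0)))


def test_shapley_table_to_frame(small_game):
    df = exact_shapley(small_game).to_frame()
    assert list(df.columns) == [
        "element",
        "gamma",
        "ci_low",
        "ci_high",
        "n_permutations",
        "rank",
    ]
    assert df["rank"].iloc[df["gamma"].idxmax()] == 1
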