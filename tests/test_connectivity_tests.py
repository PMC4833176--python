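"""Edge-weight statistics and permutation connectivity tests."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvnet.coexpression_network import CoexpressionNetwork
from cnvnet.connectivity_tests import (
    GeneSet,
    between_set_weight,
    cohesion_test,
    comparative_background_test,
    cross_set_test,
    empirical_p,
    within_set_weight,
)


def net_from_edges(edges, extra_nodes=()):
    g = nx.Graph()
    g.add_nodes_from(extra_nodes)
    g.add_weighted_edges_from(edges)
    return CoexpressionNetwork(graph=g)


def random_net(rng, n=50, p=0.1):
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(n)})
    for a, b in g.edges:
        g.edges[a, b]["weight"] = float(rng.uniform(0.7, 1.0))
    return CoexpressionNetwork(graph=g)


# ---------------------------------------------------------------------------
# statistics


def test_within_weight_of_a_triangle_is_the_hand_sum():
    net = net_from_edges([("a", "b", 0.7), ("b", "c", 0.8), ("a", "c", 0.9)])
    assert within_set_weight(net, GeneSet("t", frozenset("abc"))) == pytest.approx(2.4)


def test_set_with_no_internal_edges_scores_zero():
    net = net_from_edges([("a", "b", 0.9)], extra_nodes=["c", "d"])
    assert within_set_weight(net, GeneSet("t", frozenset("cd"))) == 0.0
    # absent genes contribute nothing
    assert within_set_weight(net, GeneSet("t", frozenset({"zz", "c"}))) == 0.0


@pytest.mark.parametrize("trial", range(3))
def test_weights_match_brute_force_enumeration_on_random_graphs(trial):
    rng = np.random.default_rng(100 + trial)
    net = random_net(rng, n=200, p=0.05)
    nodes = sorted(net.nodes)
    a = frozenset(rng.choice(nodes, size=8, replace=False))
    b = frozenset(rng.choice(sorted(set(nodes) - a), size=30, replace=False))
    within_oracle = sum(
        net.weight(x, y) for x, y in itertools.combinations(sorted(a), 2)
    )
    between_oracle = sum(net.weight(x, y) for x in a for y in b)
    assert within_set_weight(net, GeneSet("a", a)) == pytest.approx(within_oracle, rel=1e-12)
    assert between_set_weight(net, GeneSet("a", a), GeneSet("b", b)) == pytest.approx(
        between_oracle, rel=1e-12
    )


def test_between_weight_rejects_overlapping_sets():
    net = net_from_edges([("a", "b", 0.9)])
    with pytest.raises(ValueError, match="share"):
        between_set_weight(net, GeneSet("x", frozenset("ab")), GeneSet("y", frozenset("bc")))


def test_between_weight_zero_without_cross_edges():
    net = net_from_edges([("a", "b", 0.9), ("c", "d", 0.8)])
    assert between_set_weight(net, GeneSet("x", frozenset("ab")), GeneSet("y", frozenset("cd"))) == 0.0


# ---------------------------------------------------------------------------
# empirical p


def test_empirical_p_boundaries_and_tie_rule():
    res = empirical_p(5.0, [1.0] * 100)
    assert res.k_ge == 0 and res.p_emp == pytest.approx(1 / 101)
    res = empirical_p(0.5, [1.0] * 100)
    assert res.k_ge == 100 and res.p_emp == 1.0
    res = empirical_p(1.0, [1.0] * 100)  # ties count toward k
    assert res.k_ge == 100 and res.p_emp == 1.0


@given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=50),
       st.floats(0, 10, allow_nan=False))
def test_empirical_p_formula_invariants(null, observed):
    res = empirical_p(observed, null)
    assert res.k_ge == sum(1 for x in null if x >= observed)
    assert res.p_emp == (res.k_ge + 1) / (len(null) + 1)
    assert 1 / (len(null) + 1) <= res.p_emp <= 1.0


# ---------------------------------------------------------------------------
# cohesion test


def planted_module_net(rng, n=60, module=10):
    """Dense weighted clique on the first ``module`` nodes, sparse elsewhere."""
    g = nx.Graph()
    names = [f"g{i}" for i in range(n)]
    g.add_nodes_from(names)
    for i, j in itertools.combinations(range(module), 2):
        g.add_edge(names[i], names[j], weight=float(rng.uniform(0.8, 1.0)))
    for i, j in itertools.combinations(range(n), 2):
        if i >= module or j >= module:
            if rng.random() < 0.02:
                g.add_edge(names[i], names[j], weight=float(rng.uniform(0.7, 0.8)))
    return CoexpressionNetwork(graph=g), names


def test_cohesion_recovers_planted_clique(rng):
    net, names = planted_module_net(rng)
    res = cohesion_test(
        net,
        GeneSet("module", frozenset(names[:10])),
        GeneSet("all", frozenset(names)),
        n_perm=10_000,
        seed=5,
    )
    assert res.p_emp <= 0.01


def test_cohesion_preconditions():
    net = net_from_edges([("a", "b", 0.9)], extra_nodes=["c"])
    cand = GeneSet("c", frozenset("ab"))
    with pytest.raises(ValueError, match="subset"):
        cohesion_test(net, cand, GeneSet("bg", frozenset("ac")), n_perm=10)
    with pytest.raises(ValueError, match="larger"):
        cohesion_test(net, cand, GeneSet("bg", frozenset("ab")), n_perm=10)


def test_cohesion_is_reproducible_for_a_fixed_seed(rng):
    net, names = planted_module_net(rng)
    cand = GeneSet("m", frozenset(names[2:12]))
    bg = GeneSet("all", frozenset(names))
    r1 = cohesion_test(net, cand, bg, n_perm=2_000, seed=42)
    r2 = cohesion_test(net, cand, bg, n_perm=2_000, seed=42)
    assert (r1.k_ge, r1.p_emp, r1.observed) == (r2.k_ge, r2.p_emp, r2.observed)
    r3 = cohesion_test(net, cand, bg, n_perm=2_000, seed=43)
    assert r3.observed == r1.observed  # statistic is seed-independent


def test_cohesion_null_calibrated_on_uniform_draws(rng):
    """Candidates drawn uniformly from the background give p with mean ~0.5."""
    net, names = planted_module_net(rng, n=80, module=30)
    bg_members = frozenset(names)
    bg = GeneSet("all", bg_members)
    ps = []
    for rep in range(200):
        cand = frozenset(rng.choice(names, size=8, replace=False))
        res = cohesion_test(net, GeneSet("draw", cand), bg, n_perm=200, seed=rep)
        ps.append(res.p_emp)
    mean = float(np.mean(ps))
    assert 0.42 <= mean <= 0.58


def test_p_stable_when_scaling_up_permutations(rng):
    net, names = planted_module_net(rng, n=80, module=12)
    cand = GeneSet("m", frozenset(names[:8]))
    bg = GeneSet("all", frozenset(names))
    p_small = cohesion_test(net, cand, bg, n_perm=1_000, seed=1).p_emp
    p_big = cohesion_test(net, cand, bg, n_perm=100_000, seed=2).p_emp
    se = np.sqrt(max(p_big, 1e-5) * (1 - p_big) / 1_000)
    assert abs(p_small - p_big) <= 3 * se + 1 / 1_001


# ---------------------------------------------------------------------------
# cross-set and comparative tests


def test_cross_set_target_without_edges_gives_p_one(rng):
    net = net_from_edges([("a", "b", 0.9)], extra_nodes=["t1", "t2", "c", "d"])
    res = cross_set_test(
        net,
        GeneSet("cand", frozenset("ab")),
        GeneSet("target", frozenset({"t1", "t2"})),
        GeneSet("bg", frozenset("abcd")),
        n_perm=500,
        seed=0,
    )
    assert res.observed == 0.0 and res.p_emp == 1.0


def test_cross_set_rejects_unremoved_overlaps():
    net = net_from_edges([("a", "b", 0.9)], extra_nodes=["c"])
    cand = GeneSet("cand", frozenset("ab"))
    with pytest.raises(ValueError, match="overlap"):
        cross_set_test(net, cand, GeneSet("t", frozenset("bc")),
                       GeneSet("bg", frozenset("abc")), n_perm=10)


def test_cross_set_detects_planted_association(rng):
    # candidates wired to the target; background mostly disconnected
    edges = [(f"c{i}", f"t{j}", 0.9) for i in range(6) for j in range(4)]
    extra = [f"b{i}" for i in range(40)]
    net = net_from_edges(edges, extra_nodes=extra)
    cand = GeneSet("cand", frozenset(f"c{i}" for i in range(6)))
    target = GeneSet("target", frozenset(f"t{j}" for j in range(4)))
    bg = GeneSet("bg", cand.members | frozenset(extra))
    res = cross_set_test(net, cand, target, bg, n_perm=5_000, seed=3)
    assert res.p_emp < 0.01


def test_comparative_background_bookkeeping_and_asymmetry(rng):
    # candidates connect to the target; competitor genes are isolated
    edges = [(f"c{i}", f"t{j}", 0.8) for i in range(5) for j in range(3)]
    competitors = [f"k{i}" for i in range(20)]
    net = net_from_edges(edges, extra_nodes=competitors)
    cand = GeneSet("cand", frozenset(f"c{i}" for i in range(5)) | {"t0"})
    comp = GeneSet("comp", frozenset(competitors) | {"c0"})
    target = GeneSet("target", frozenset(f"t{j}" for j in range(3)))
    res = comparative_background_test(net, cand, comp, target, n_perm=5_000, seed=4)
    sizes = res.set_sizes
    # |composite| = |cand| + |comp| - |overlap| - removed target-annotated
    assert sizes["composite_background"] == len(cand) + len(comp) - 1 - 1
    assert sizes["candidates_after_exclusion"] == 5
    assert res.p_emp < 0.01


def test_comparative_with_identical_competitor_cannot_discriminate(rng):
    net, names = planted_module_net(rng, n=40, module=10)
    cand = GeneSet("cand", frozenset(names[:8]))
    target = GeneSet("target", frozenset(names[20:30]))
    # a competitor identical to the candidates leaves no composite background
    # larger than the candidate set -> explicit error
    with pytest.raises(ValueError, match="strictly larger"):
        comparative_background_test(net, cand, cand, target, n_perm=200, seed=6)
    # with candidates redrawn uniformly from the composite pool the test is
    # exchangeable, so p is calibrated: mean ~0.5 across replicates
    pool = names[:16]
    ps = []
    for rep in range(200):
        chosen = frozenset(rng.choice(pool, size=8, replace=False))
        c = GeneSet("cand", chosen)
        k = GeneSet("comp", frozenset(set(pool) - chosen))
        ps.append(
            comparative_background_test(net, c, k, target, n_perm=100, seed=rep).p_emp
        )
    ps = np.array(ps)
    # super-uniform: never anti-conservative (ties push p upward, never down)
    assert ps.mean() >= 0.4
    assert (ps <= 0.1).mean() <= 0.2
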