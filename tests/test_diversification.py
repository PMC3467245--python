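"""MPL ultrametricization, LTT curves and the gamma statistic."""

from __future__ import annotations

import math

import numpy as np
import pytest

from commphylo.diversification import (
    InternodeIntervals,
    gamma_rarefaction,
    gamma_statistic,
    geometric_sizes,
    induced_subtree,
    internode_intervals,
    ltt,
    mpl_ultrametricize,
    scale_root,
)
from commphylo.synthetic import apply_age_transform, simulate_yule
from commphylo.trees import (
    CommunityTable,
    is_ultrametric,
    node_depths,
    read_newick,
    tip_labels,
)

from conftest import gamma_oracle, gamma_tree_oracle


def _ages(tree):
    return {
        (nd.taxon.label if nd.is_leaf() else frozenset(
            l.taxon.label for l in nd.leaf_iter()
        )): nd.age
        for nd in tree.preorder_node_iter()
    }


def _jitter(tree, seed):
    rng = np.random.default_rng(seed)
    out = tree.clone(depth=1)
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length *= rng.uniform(0.5, 2.0)
    return out


# ---------------------------------------------------------------------------
# MPL


def test_mpl_on_ultrametric_tree_recovers_original_ages(balanced4):
    ut = mpl_ultrametricize(balanced4)
    ages = _ages(ut)
    assert ages[frozenset("ABCD")] == pytest.approx(2.0)
    assert ages[frozenset("AB")] == pytest.approx(1.0)
    assert ages[frozenset("CD")] == pytest.approx(1.0)


def test_mpl_mean_path_length_ages_by_hand(caterpillar):
    # ((A:2,B:4):1,C:5): (A,B) node age = mean(2,4) = 3;
    # root age = mean of per-tip root paths (3, 5, 5) = 13/3
    ut = mpl_ultrametricize(caterpillar)
    ages = _ages(ut)
    assert ages[frozenset("AB")] == pytest.approx(3.0)
    assert ages[frozenset("ABC")] == pytest.approx(13 / 3)
    assert is_ultrametric(ut)


def test_mpl_clamps_age_conflicts_to_parent():
    # (A,B) node raw age 10 exceeds the root's raw age mean(11,11,2) = 8
    tree = read_newick("((A:10,B:10):1,C:2);", is_string=True)
    ut = mpl_ultrametricize(tree)
    ages = _ages(ut)
    assert ages[frozenset("ABC")] == pytest.approx(8.0)
    assert ages[frozenset("AB")] == pytest.approx(8.0)  # clamped, zero branch
    assert is_ultrametric(ut)


def test_mpl_output_is_always_ultrametric_on_jittered_trees():
    for seed in range(20):
        tree = _jitter(simulate_yule(30, seed=seed), seed)
        ut = scale_root(mpl_ultrametricize(tree), 1.0)
        depths = node_depths(ut)
        tips = [depths[l] for l in ut.leaf_node_iter()]
        assert max(tips) - min(tips) <= 1e-9 * max(tips)
        assert ut.seed_node.age == 1.0


def test_mpl_rejects_degenerate_input():
    with pytest.raises(ValueError):
        mpl_ultrametricize(read_newick("(A:1);", is_string=True))
    with pytest.raises(ValueError):
        mpl_ultrametricize(read_newick("(A:0,B:0);", is_string=True))


# ---------------------------------------------------------------------------
# scale_root


def test_scale_root_exact_and_idempotent(caterpillar):
    ut = mpl_ultrametricize(caterpillar)
    s1 = scale_root(ut, 1.0)
    s2 = scale_root(s1, 1.0)
    assert s1.seed_node.age == 1.0
    assert _ages(s1) == _ages(s2)


def test_scale_root_preserves_age_ratios(caterpillar):
    ut = mpl_ultrametricize(caterpillar)
    before = _ages(ut)
    after = _ages(scale_root(ut, 1.0))
    ratio = before[frozenset("AB")] / before[frozenset("ABC")]
    assert after[frozenset("AB")] == pytest.approx(ratio)


def test_scale_root_rejects_zero_root_age(balanced4):
    ut = mpl_ultrametricize(balanced4)
    for nd in ut.preorder_node_iter():
        nd.age = 0.0
    with pytest.raises(ValueError):
        scale_root(ut, 1.0)


# ---------------------------------------------------------------------------
# internode intervals


def test_two_tip_tree_intervals():
    tree = read_newick("(A:1,B:1);", is_string=True)
    iv = internode_intervals(tree)
    assert iv.n == 2
    assert iv.g == [1.0]
    assert iv.T == pytest.approx(2.0)


def test_balanced_four_tip_intervals(balanced4):
    iv = internode_intervals(balanced4)
    assert iv.n == 4
    assert iv.g == pytest.approx([1.0, 0.0, 1.0])
    assert iv.T == pytest.approx(2 * 1 + 3 * 0 + 4 * 1)


def test_intervals_telescope_to_root_age():
    for seed in range(5):
        tree = simulate_yule(40, seed=seed)
        iv = internode_intervals(tree)
        assert sum(iv.g) == pytest.approx(tree.seed_node.age)
        # T recomputed independently
        assert iv.T == pytest.approx(
            sum(k * gk for k, gk in zip(range(2, iv.n + 1), iv.g))
        )


def test_multifurcation_counts_as_multiple_events():
    tree = read_newick("(A:1,B:1,C:1,D:1);", is_string=True)
    iv = internode_intervals(tree)
    assert iv.n == 4
    assert iv.g == pytest.approx([0.0, 0.0, 1.0])


def test_intervals_require_ultrametric_tree(caterpillar):
    with pytest.raises(ValueError):
        internode_intervals(caterpillar)


# ---------------------------------------------------------------------------
# gamma


def test_gamma_explicit_intervals_against_formula_oracle():
    iv = InternodeIntervals(n=4, g=[0.5, 0.0, 0.5])
    assert gamma_statistic(iv) == pytest.approx(gamma_oracle(4, [0.5, 0.0, 0.5]))
    # and by hand: (1/2)(T_2 + T_3) - T/2 = 1 - 1.5; denom = 3 sqrt(1/24)
    assert gamma_statistic(iv) == pytest.approx(-0.5 / (3 * math.sqrt(1 / 24)))


def test_gamma_matches_independent_implementation_on_simulated_trees():
    for seed in range(10):
        tree = simulate_yule(40, seed=seed)
        assert gamma_statistic(tree) == pytest.approx(
            gamma_tree_oracle(tree), rel=1e-10
        )


def test_gamma_needs_three_tips():
    tree = read_newick("(A:1,B:1);", is_string=True)
    with pytest.raises(ValueError):
        gamma_statistic(tree)


def test_gamma_invariant_under_time_rescaling():
    tree = simulate_yule(50, seed=3)
    g0 = gamma_statistic(tree)
    for root_age in (0.1, 1.0, 7.3):
        assert gamma_statistic(scale_root(tree, root_age)) == pytest.approx(g0)


def test_gamma_monotone_in_age_transform_exponent():
    for seed in range(5):
        tree = simulate_yule(60, seed=seed)
        gammas = [
            gamma_statistic(apply_age_transform(tree, beta))
            for beta in (0.25, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(g1 < g2 for g1, g2 in zip(gammas, gammas[1:]))


def test_gamma_near_zero_under_constant_rate_null():
    gs = [gamma_statistic(simulate_yule(80, seed=s)) for s in range(60)]
    se = np.std(gs) / math.sqrt(len(gs))
    assert abs(np.mean(gs)) < 3 * se + 0.15


# ---------------------------------------------------------------------------
# LTT


def test_ltt_final_count_is_tip_number():
    tree = simulate_yule(25, seed=1)
    curve = ltt(tree)
    assert curve.lineages[-1] == 25
    assert curve.lineages == list(range(2, 26))
    assert curve.times[0] == pytest.approx(1.0)


def test_ltt_two_tip_tree_single_step():
    tree = read_newick("(A:1,B:1);", is_string=True)
    curve = ltt(tree)
    assert curve.times == [1.0] and curve.lineages == [2]


def test_ltt_log_linear_under_yule():
    tree = simulate_yule(200, seed=5)
    curve = ltt(tree)
    x = 1.0 - np.array(curve.times)  # forward time from the root
    y = np.array(curve.log_lineages)
    r = np.corrcoef(x, y)[0, 1]
    assert r**2 > 0.9


# ---------------------------------------------------------------------------
# induced subtrees and gamma rarefaction


def test_induced_subtree_of_all_tips_is_identity():
    tree = simulate_yule(20, seed=2)
    sub = induced_subtree(tree, tip_labels(tree))
    assert sub.seed_node.age == pytest.approx(1.0)
    assert gamma_statistic(sub) == pytest.approx(gamma_statistic(tree))


def test_induced_subtree_preserves_ultrametricity_and_mrca_ages():
    # hand-built 8-tip tree; prune to 5 and check ages against the
    # MRCA-restricted oracle
    nwk = ("(((A:1,B:1):1,(C:1.5,D:1.5):0.5):2,"
           "((E:0.5,F:0.5):2.5,(G:2,H:2):1):1);")
    tree = read_newick(nwk, is_string=True)
    keep = ["A", "B", "C", "E", "G"]
    sub = induced_subtree(tree, keep)
    assert is_ultrametric(sub)
    assert sorted(tip_labels(sub)) == keep
    sub_ages = _ages(sub)
    # MRCA ages read off the original tree
    assert sub_ages[frozenset("AB")] == pytest.approx(1.0)
    assert sub_ages[frozenset("ABC")] == pytest.approx(2.0)
    assert sub_ages[frozenset("EG")] == pytest.approx(3.0)
    assert sub_ages[frozenset("ABCEG")] == pytest.approx(4.0)  # root = MRCA


def test_induced_subtree_root_is_mrca():
    tree = simulate_yule(20, seed=4)
    # restrict to one cathedral clade: the root of the restriction must be
    # that clade's MRCA, younger than the full tree's root
    some_internal = next(
        nd
        for nd in tree.preorder_internal_node_iter()
        if nd is not tree.seed_node and sum(1 for _ in nd.leaf_iter()) >= 4
    )
    clade_tips = [l.taxon.label for l in some_internal.leaf_iter()]
    sub = induced_subtree(tree, clade_tips)
    assert sub.seed_node.age == pytest.approx(some_internal.age)


def test_induced_subtree_needs_three_tips(balanced4):
    with pytest.raises(ValueError):
        induced_subtree(balanced4, {"A", "B"})


def test_gamma_rarefaction_full_size_degenerate():
    tree = simulate_yule(30, seed=6)
    tips = tip_labels(tree)
    table = CommunityTable({"all": set(tips)})
    curves = gamma_rarefaction(tree, table, [len(tips)], n_rand=5, seed=0)
    c = curves["all"]
    assert c.sd == [0.0]
    assert c.mean[0] == pytest.approx(gamma_statistic(tree))


def test_gamma_rarefaction_orders_acceleration_regimes():
    base = simulate_yule(60, seed=8)
    fast = apply_age_transform(base, 4.0)  # node ages toward the tips
    slow = apply_age_transform(base, 0.25)  # node ages toward the root
    tips = set(tip_labels(base))
    sizes = [5, 10, 20]
    fast_c = gamma_rarefaction(fast, CommunityTable({"h": tips}), sizes,
                               n_rand=30, seed=1)["h"]
    slow_c = gamma_rarefaction(slow, CommunityTable({"h": tips}), sizes,
                               n_rand=30, seed=1)["h"]
    assert all(f > s for f, s in zip(fast_c.mean, slow_c.mean))


def test_gamma_rarefaction_null_fluctuates_around_zero():
    tree = simulate_yule(60, seed=9)
    table = CommunityTable({"all": set(tip_labels(tree))})
    c = gamma_rarefaction(tree, table, [20], n_rand=60, seed=2)["all"]
    assert abs(c.mean[0]) < 3 * c.sd[0] / math.sqrt(c.n_rand) + 1.0


def test_geometric_size_grid():
    sizes = geometric_sizes(3, 48)
    assert sizes[0] == 3 and sizes[-1] == 48
    assert sizes == sorted(set(sizes))
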