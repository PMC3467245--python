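"""Relative-time diversification analysis: MPL ultrametricization, LTT
curves, and the constant-rate test statistic (gamma).

The raw phylogeny (branch lengths in substitutions/site) is transformed to
an ultrametric tree by the mean path length (MPL) rate-smoothing method:
each internal node's age is the mean path length from the node to its
descendant tips.  Age conflicts created by rate variation (a child dated
older than its parent) are resolved by clamping the child to its parent's
age, producing a zero-length branch.  The tree is then placed on a
relative time axis with the root at 1 and the present (all tips) at 0.

On an ultrametric tree, sorted internal-node ages define the internode
intervals g_2..g_n (g_k = time during which the reconstructed tree has
exactly k lineages).  The gamma statistic

    gamma = [ (1/(n-2)) * sum_{i=2}^{n-1} T_i  -  T/2 ]
            / ( T * sqrt(1 / (12 (n-2))) ),
    T_i = sum_{k=2}^{i} k * g_k,   T = T_n,

is approximately standard normal under constant-rate diversification;
gamma > 0 means internal nodes crowd toward the tips (accelerating
cladogenesis), gamma < 0 toward the root (deceleration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .community import RarefactionCurve
from .trees import (
    CommunityTable,
    is_ultrametric,
    node_depths,
    set_ages_from_depths,
    set_branch_lengths_from_ages,
)

__all__ = [
    "InternodeIntervals",
    "LTTCurve",
    "mpl_ultrametricize",
    "scale_root",
    "internode_intervals",
    "gamma_statistic",
    "ltt",
    "induced_subtree",
    "gamma_rarefaction",
]


def _require_ages(tree: dendropy.Tree) -> None:
    if not all(
        getattr(nd, "age", None) is not None for nd in tree.preorder_node_iter()
    ):
        if not is_ultrametric(tree):
            raise ValueError("tree is not ultrametric")
        set_ages_from_depths(tree)


def _clone_with_ages(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep-copy a tree, carrying node ages across (clone may not copy
    ad-hoc node attributes; traversal order is preserved by the copy)."""
    out = tree.clone(depth=1)
    out.is_rooted = True
    for orig, copy_ in zip(tree.preorder_node_iter(), out.preorder_node_iter()):
        copy_.age = getattr(orig, "age", None)
    return out


def mpl_ultrametricize(tree: dendropy.Tree) -> dendropy.Tree:
    """Mean-path-length ultrametricization (in place on a copy).

    Node ages are mean path lengths to descendant tips; parent/child age
    conflicts are clamped to zero-length branches.  The plain unweighted
    variant is used (every descendant tip contributes equally to the
    mean), which is deterministic and needs no error model.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 2:
        raise ValueError("MPL needs a rooted tree with at least two tips")
    out = tree.clone(depth=1)
    out.is_rooted = True
    # postorder: per node, (sum of node-to-tip path lengths, tip count)
    acc: dict[int, tuple[float, int]] = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            acc[id(node)] = (0.0, 1)
            continue
        total = 0.0
        count = 0
        for child in node.child_nodes():
            csum, cn = acc[id(child)]
            total += csum + cn * (child.edge.length or 0.0)
            count += cn
        acc[id(node)] = (total, count)
    root_sum, root_n = acc[id(out.seed_node)]
    if root_sum == 0.0:
        raise ValueError("tree has zero depth; MPL ages undefined")
    # preorder: raw age = mean path length, clamped to the parent's age
    for node in out.preorder_node_iter():
        if node.is_leaf():
            node.age = 0.0
            continue
        total, count = acc[id(node)]
        raw = total / count
        if node.parent_node is not None:
            raw = min(raw, node.parent_node.age)
        node.age = raw
    set_branch_lengths_from_ages(out)
    return out


def scale_root(tree: dendropy.Tree, root_age: float = 1.0) -> dendropy.Tree:
    """Rescale node ages so the root sits at ``root_age`` (default 1).

    Linear in time, so age ratios — and the gamma statistic — are
    unchanged.
    """
    _require_ages(tree)
    out = _clone_with_ages(tree)
    old_root = out.seed_node.age
    if old_root <= 0:
        raise ValueError("root age must be positive to rescale")
    factor = root_age / old_root
    for node in out.preorder_node_iter():
        node.age = node.age * factor
    out.seed_node.age = root_age  # exact, no roundoff
    set_branch_lengths_from_ages(out)
    return out


@dataclass
class InternodeIntervals:
    """Durations g_2..g_n during which the reconstructed tree has exactly
    k lineages, plus the weighted total T = sum k * g_k."""

    n: int
    g: list[float]  # g[0] is g_2, ..., g[-1] is g_n

    def __post_init__(self) -> None:
        if len(self.g) != self.n - 1:
            raise ValueError(f"expected {self.n - 1} intervals, got {len(self.g)}")
        if any(gk < -1e-12 for gk in self.g):
            raise ValueError("negative internode interval")

    @property
    def T(self) -> float:
        return sum(k * gk for k, gk in zip(range(2, self.n + 1), self.g))

    @property
    def root_age(self) -> float:
        return sum(self.g)


def _event_ages(tree: dendropy.Tree) -> list[float]:
    """Internal node ages, each repeated (out-degree - 1) times.

    Repeating a multifurcation's age is equivalent to resolving it into a
    ladder of zero-length branches: only interval durations enter the LTT
    and gamma computations, so the resolution order is immaterial.
    """
    _require_ages(tree)
    ages: list[float] = []
    for node in tree.preorder_internal_node_iter():
        ages.extend([node.age] * (len(node.child_nodes()) - 1))
    ages.sort(reverse=True)
    return ages


def internode_intervals(tree: dendropy.Tree) -> InternodeIntervals:
    """Internode intervals of an ultrametric tree (present at age 0)."""
    if not is_ultrametric(tree):
        raise ValueError("internode intervals require an ultrametric tree")
    ages = _event_ages(tree)
    n = len(ages) + 1  # tip count of the binary-resolved tree
    g = [ages[i - 1] - ages[i] for i in range(1, len(ages))]
    g.append(ages[-1])  # g_n closes at the present
    return InternodeIntervals(n=n, g=g)


def gamma_statistic(tree_or_intervals: dendropy.Tree | InternodeIntervals) -> float:
    """Constant-rate diversification test statistic.

    Approximately N(0, 1) under a constant-rate pure-birth process;
    positive when nodes crowd toward the tips, negative toward the root.
    Needs at least three tips.
    """
    if isinstance(tree_or_intervals, InternodeIntervals):
        iv = tree_or_intervals
    else:
        iv = internode_intervals(tree_or_intervals)
    n = iv.n
    if n < 3:
        raise ValueError("gamma statistic requires at least three tips")
    T = iv.T
    if T <= 0:
        raise ValueError("total weighted tree length is zero")
    # partial sums T_i = sum_{k=2}^{i} k * g_k for i = 2..n-1
    partial = 0.0
    acc = 0.0
    for i, gk in zip(range(2, n), iv.g[:-1]):
        partial += i * gk
        acc += partial
    return (acc / (n - 2) - T / 2.0) / (T * math.sqrt(1.0 / (12.0 * (n - 2))))


@dataclass
class LTTCurve:
    """Lineage-through-time step curve on the relative-time axis
    (present at 0, time increasing toward the root)."""

    times: list[float]  # event ages, sorted decreasing (root first)
    lineages: list[int]  # count after each event: 2, 3, ..., n

    @property
    def log_lineages(self) -> list[float]:
        return [math.log(k) for k in self.lineages]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time\tlineages\tlog_lineages\n")
            for t, k, lk in zip(self.times, self.lineages, self.log_lineages):
                fh.write(f"{t:.10g}\t{k}\t{lk:.10g}\n")


def ltt(tree: dendropy.Tree) -> LTTCurve:
    """Lineage-through-time curve of an ultrametric tree."""
    if not is_ultrametric(tree):
        raise ValueError("LTT requires an ultrametric tree")
    ages = _event_ages(tree)
    counts = list(range(2, len(ages) + 2))
    return LTTCurve(times=ages, lineages=counts)


def induced_subtree(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Restriction of an ultrametric tree to a tip subset.

    Prunes the other tips, suppresses the resulting unifurcations (branch
    lengths merge), and re-roots at the MRCA of the kept set.  Node ages
    are retained from the original tree, so the result is ultrametric
    with root age = the MRCA's original age.
    """
    taxa = set(taxa)
    if len(taxa) < 3:
        raise ValueError("induced subtree requires at least three tips")
    _require_ages(tree)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = taxa - tips
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)[:5]}")
    out = _clone_with_ages(tree)
    out.retain_taxa_with_labels(sorted(taxa))
    # re-root at the MRCA: walk past any single-child chain at the top
    seed = out.seed_node
    while len(seed.child_nodes()) == 1:
        seed = seed.child_nodes()[0]
    seed.parent_node = None
    out.seed_node = seed
    # ages survive pruning on retained nodes; rebuild branch lengths
    for node in out.preorder_node_iter():
        if node.is_leaf():
            node.age = 0.0
    set_branch_lengths_from_ages(out)
    return out


def gamma_rarefaction(
    tree: dendropy.Tree,
    communities: CommunityTable,
    sizes: Sequence[int],
    n_rand: int = 100,
    seed: int = 0,
) -> dict[str, RarefactionCurve]:
    """Per-habitat rarefaction of the gamma statistic.

    For each habitat and subsample size m, the mean and SD of gamma over
    ``n_rand`` random m-tip subsamples, each evaluated on the induced
    subtree rescaled to root age 1.
    """
    if min(sizes) < 3:
        raise ValueError("gamma rarefaction sizes must be >= 3")
    communities.validate_against_tree(tree)
    _require_ages(tree)
    curves: dict[str, RarefactionCurve] = {}
    for k, habitat in enumerate(communities.habitats):
        members = sorted(communities.membership[habitat])
        if max(sizes) > len(members):
            raise ValueError(
                f"size {max(sizes)} exceeds habitat {habitat!r} ({len(members)})"
            )
        rng = np.random.default_rng(seed + k)
        means, sds = [], []
        for m in sizes:
            if m == len(members):
                g = gamma_statistic(scale_root(induced_subtree(tree, members)))
                means.append(g)
                sds.append(0.0)
                continue
            vals = np.empty(n_rand)
            for i in range(n_rand):
                sub = rng.choice(members, size=m, replace=False)
                vals[i] = gamma_statistic(
                    scale_root(induced_subtree(tree, sub))
                )
            means.append(float(vals.mean()))
            sds.append(float(vals.std()))
        curves[habitat] = RarefactionCurve(list(sizes), means, sds, n_rand, seed + k)
    return curves


def geometric_sizes(lo: int, hi: int, n_points: int = 8) -> list[int]:
    """Geometric grid of subsample sizes from lo to hi, deduplicated."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    xs = np.unique(
        np.round(np.geomspace(lo, hi, n_points)).astype(int)
    )
    return [int(x) for x in xs if lo <= x <= hi]
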