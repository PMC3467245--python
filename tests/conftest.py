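"""Shared fixtures and independent brute-force oracles.

The oracles deliberately take different computational routes from the
package (edge-set unions, explicit per-edge classification, dendropy's
own statistics) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import math

import dendropy
import pytest

from commphylo.trees import node_depths, read_newick


@pytest.fixture
def caterpillar():
    return read_newick("((A:2,B:4):1,C:5);", is_string=True)


@pytest.fixture
def balanced4():
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);", is_string=True)


@pytest.fixture
def star10():
    labels = ",".join(f"T{i}:1" for i in range(10))
    return read_newick(f"({labels});", is_string=True)


@pytest.fixture
def six_tip():
    # overlapping clades on both sides of the root; used by UniFrac tests
    return read_newick(
        "(((A:1,B:1):1,C:2):1,((D:1,E:1):0.5,F:1.5):1.5);", is_string=True
    )


# ---------------------------------------------------------------------------
# oracles


def pd_oracle(tree: dendropy.Tree, taxa: set[str]) -> float:
    """Faith's PD by explicit union of root-to-tip edge sets."""
    leaf = {l.taxon.label: l for l in tree.leaf_node_iter()}
    edges = set()
    for label in taxa:
        node = leaf[label]
        while node.parent_node is not None:
            edges.add(node)
            node = node.parent_node
    return sum(n.edge.length or 0.0 for n in edges)


def psv_oracle(tree: dendropy.Tree, taxa: list[str]) -> float:
    """PSV from an explicitly assembled covariance matrix, with MRCAs
    found via dendropy's own mrca() rather than path intersection."""
    import numpy as np

    depths = node_depths(tree)
    leaf = {l.taxon.label: l for l in tree.leaf_node_iter()}
    labels = sorted(taxa)
    n = len(labels)
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depths[leaf[labels[i]]]
        for j in range(i + 1, n):
            mrca = tree.mrca(taxon_labels=[labels[i], labels[j]])
            V[i, j] = V[j, i] = depths[mrca]
    d = np.sqrt(np.diag(V))
    C = V / np.outer(d, d)
    return float((n * np.trace(C) - C.sum()) / (n * (n - 1)))


def unifrac_oracle(tree: dendropy.Tree, a: set[str], b: set[str]) -> float:
    """Unweighted UniFrac by labeling every edge shared/unique/absent from
    its full descendant tip set."""
    union = a | b
    unique = shared = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        in_a = bool(below & a)
        in_b = bool(below & b)
        if not (below & union):
            continue
        if in_a and in_b:
            shared += node.edge.length or 0.0
        elif in_a or in_b:
            unique += node.edge.length or 0.0
    total = unique + shared
    return unique / total if total else 0.0


def gamma_oracle(n: int, g: list[float]) -> float:
    """Spreadsheet-style evaluation of the constant-rate test statistic
    from explicit internode intervals g_2..g_n."""
    T = sum((k + 2) * gk for k, gk in enumerate(g))
    outer = 0.0
    for i in range(2, n):
        inner = sum((k + 2) * gk for k, gk in enumerate(g[: i - 1]))
        outer += inner
    num = outer / (n - 2) - T / 2.0
    return num / (T * math.sqrt(1.0 / (12 * (n - 2))))


def gamma_tree_oracle(tree: dendropy.Tree) -> float:
    """gamma via dendropy's independent implementation."""
    from dendropy.calculate import treemeasure

    return treemeasure.pybus_harvey_gamma(tree.clone(depth=1))
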