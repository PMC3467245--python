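"""Community phylogenetics on a fixed tree.

Given a rooted phylogeny with branch lengths and a habitat -> tips table,
computes:

* Faith's phylogenetic diversity (PD): total branch length of the minimal
  subtree connecting a community's tips and the root (rooted convention —
  the root path is included; set ``include_root=False`` for the unrooted
  variant).
* Phylogenetic species variability (PSV): 1 minus the mean off-diagonal
  phylogenetic correlation among the community's tips.  1 for a star
  phylogeny, toward 0 for tightly related communities.
* Unweighted UniFrac distance between two communities: the fraction of
  the joint spanning subtree's branch length leading exclusively to one
  of the communities.
* PD rarefaction curves (mean +/- SD over random subsamples at a grid of
  sizes) and the habitat similarity network, an undirected complete graph
  whose nodes carry PD and PSV and whose edge weights are 1 - UniFrac.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import networkx as nx
import numpy as np

from .trees import CommunityTable, node_depths, tip_labels

__all__ = [
    "RarefactionCurve",
    "faith_pd",
    "pd_rarefaction",
    "psv",
    "phylo_covariance",
    "unifrac",
    "unifrac_matrix",
    "habitat_network",
    "write_unifrac_matrix",
    "write_habitat_graph",
]


@dataclass
class RarefactionCurve:
    """Mean and SD of a statistic over random subsamples at each size."""

    sizes: list[int]
    mean: list[float]
    sd: list[float]
    n_rand: int
    seed: int

    def to_tsv(self, path: str | Path, stat: str = "stat") -> None:
        with open(path, "w") as fh:
            fh.write(f"size\tmean_{stat}\tsd_{stat}\n")
            for m, mu, sigma in zip(self.sizes, self.mean, self.sd):
                fh.write(f"{m}\t{mu:.10g}\t{sigma:.10g}\n")


def _leaf_index(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def _require_tips(tree: dendropy.Tree, taxa: Iterable[str]) -> list[dendropy.Node]:
    index = _leaf_index(tree)
    nodes = []
    for label in taxa:
        if label not in index:
            raise KeyError(f"tip id {label!r} not found in tree")
        nodes.append(index[label])
    return nodes


def faith_pd(
    tree: dendropy.Tree, taxa: Iterable[str], include_root: bool = True
) -> float:
    """Faith's PD of a tip set.

    Sum of branch lengths of the minimal spanning subtree connecting the
    tips; with ``include_root`` (default) the subtree is anchored at the
    root so even a single tip has positive PD (its root-to-tip path).
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("faith_pd requires at least one tip")
    leaves = _require_tips(tree, taxa)
    edges: set[int] = set()
    total = 0.0
    node_of: dict[int, dendropy.Node] = {}
    for leaf in leaves:
        node = leaf
        while node.parent_node is not None:
            key = id(node)
            if key in edges:
                break
            edges.add(key)
            node_of[key] = node
            total += node.edge.length or 0.0
            node = node.parent_node
    if not include_root:
        # subtract the path from the root down to the MRCA of the tip set
        mrca = tree.mrca(taxon_labels=list(taxa))
        node = mrca
        while node.parent_node is not None:
            total -= node.edge.length or 0.0
            node = node.parent_node
    return total


def pd_rarefaction(
    tree: dendropy.Tree,
    community: Iterable[str],
    sizes: Sequence[int],
    n_rand: int = 1000,
    seed: int = 0,
    include_root: bool = True,
) -> RarefactionCurve:
    """Mean +/- SD of Faith's PD over random subsamples without replacement."""
    members = sorted(set(community))
    if max(sizes) > len(members):
        raise ValueError(
            f"subsample size {max(sizes)} exceeds community size {len(members)}"
        )
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for m in sizes:
        if m == len(members):
            pd_full = faith_pd(tree, members, include_root)
            means.append(pd_full)
            sds.append(0.0)
            continue
        vals = np.empty(n_rand)
        for i in range(n_rand):
            sub = rng.choice(members, size=m, replace=False)
            vals[i] = faith_pd(tree, sub, include_root)
        means.append(float(vals.mean()))
        sds.append(float(vals.std()))
    return RarefactionCurve(list(sizes), means, sds, n_rand, seed)


def phylo_covariance(
    tree: dendropy.Tree, taxa: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic covariance matrix over a tip set.

    V[i, j] is the root-to-MRCA path length shared by tips i and j;
    V[i, i] is the root-to-tip path length.
    """
    labels = sorted(set(taxa))
    leaves = _require_tips(tree, labels)
    depths = node_depths(tree)
    # root-to-leaf ancestor paths (node id -> depth), leaf included
    paths: list[dict[int, float]] = []
    for leaf in leaves:
        path: dict[int, float] = {}
        node = leaf
        while node is not None:
            path[id(node)] = depths[node]
            node = node.parent_node
        paths.append(path)
    n = len(labels)
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depths[leaves[i]]
        for j in range(i + 1, n):
            shared = paths[i].keys() & paths[j].keys()
            V[i, j] = V[j, i] = max(paths[i][k] for k in shared)
    return V, labels


def psv(tree: dendropy.Tree, taxa: Iterable[str]) -> float:
    """Phylogenetic species variability of a tip set.

    PSV = (n tr(C) - sum(C)) / (n (n - 1)) where C is the phylogenetic
    correlation matrix; equivalently 1 minus the mean off-diagonal
    correlation.  Requires at least two tips.
    """
    taxa = set(taxa)
    if len(taxa) < 2:
        raise ValueError("psv requires at least two tips")
    V, _ = phylo_covariance(tree, sorted(taxa))
    d = np.sqrt(np.diag(V))
    if np.any(d == 0):
        raise ValueError("zero root-to-tip distance; correlation undefined")
    C = V / np.outer(d, d)
    n = len(C)
    return float((n * np.trace(C) - C.sum()) / (n * (n - 1)))


def psv_rarefaction(
    tree: dendropy.Tree,
    community: Iterable[str],
    size: int,
    n_rand: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of PSV over random subsamples of one community."""
    members = sorted(set(community))
    if size > len(members):
        raise ValueError("subsample size exceeds community size")
    if size < 2:
        raise ValueError("PSV subsample needs at least two tips")
    if size == len(members):
        return psv(tree, members), 0.0
    rng = np.random.default_rng(seed)
    vals = np.empty(n_rand)
    for i in range(n_rand):
        vals[i] = psv(tree, rng.choice(members, size=size, replace=False))
    return float(vals.mean()), float(vals.std())


def unifrac(
    tree: dendropy.Tree, taxa_a: Iterable[str], taxa_b: Iterable[str]
) -> float:
    """Unweighted (presence/absence) UniFrac distance between two tip sets.

    Over the spanning subtree of the union (anchored at the root), the
    branch length leading exclusively to one community divided by the
    subtree's total branch length.  0 for identical communities, 1 for
    communities on disjoint root subtrees.
    """
    set_a, set_b = set(taxa_a), set(taxa_b)
    if not set_a or not set_b:
        raise ValueError("unifrac requires two non-empty communities")
    _require_tips(tree, set_a | set_b)
    unique = shared = 0.0
    # postorder accumulation of which communities each edge leads to
    reach: dict[int, tuple[bool, bool]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            flags = (label in set_a, label in set_b)
        else:
            in_a = in_b = False
            for child in node.child_nodes():
                ca, cb = reach[id(child)]
                in_a |= ca
                in_b |= cb
            flags = (in_a, in_b)
        reach[id(node)] = flags
        if node.parent_node is None:
            continue
        bl = node.edge.length or 0.0
        if flags == (True, True):
            shared += bl
        elif flags[0] or flags[1]:
            unique += bl
    total = unique + shared
    if total == 0:
        return 0.0
    return unique / total


def unifrac_matrix(
    tree: dendropy.Tree, communities: CommunityTable
) -> tuple[np.ndarray, list[str]]:
    """Symmetric matrix of pairwise unweighted UniFrac distances."""
    habitats = communities.habitats
    if len(habitats) < 2:
        raise ValueError("need at least two habitats")
    communities.validate_against_tree(tree)
    n = len(habitats)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = unifrac(
                tree,
                communities.membership[habitats[i]],
                communities.membership[habitats[j]],
            )
            D[i, j] = D[j, i] = d
    return D, habitats


def habitat_network(
    tree: dendropy.Tree,
    communities: CommunityTable,
    psv_subsample: int | None = None,
    n_rand: int = 1000,
    seed: int = 0,
) -> nx.Graph:
    """Habitat similarity network.

    Complete undirected graph over habitats: node attributes ``pd`` and
    ``psv`` (rarefied means at a common subsample size when
    ``psv_subsample`` is given, correcting for unequal sample sizes),
    edge weights 1 - UniFrac distance.
    """
    habitats = communities.habitats
    communities.validate_against_tree(tree)
    graph = nx.Graph()
    for k, habitat in enumerate(habitats):
        members = communities.membership[habitat]
        if psv_subsample is not None:
            curve = pd_rarefaction(
                tree, members, [psv_subsample], n_rand, seed + 2 * k
            )
            pd_val = curve.mean[0]
            psv_val, _ = psv_rarefaction(
                tree, members, psv_subsample, n_rand, seed + 2 * k + 1
            )
        else:
            pd_val = faith_pd(tree, members)
            psv_val = psv(tree, members)
        graph.add_node(habitat, pd=pd_val, psv=psv_val)
    D, labels = unifrac_matrix(tree, communities)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            graph.add_edge(labels[i], labels[j], weight=1.0 - D[i, j])
    return graph


def write_unifrac_matrix(
    D: np.ndarray, habitats: Sequence[str], path: str | Path
) -> None:
    """Square TSV with a header row and a leading label column."""
    with open(path, "w") as fh:
        fh.write("habitat\t" + "\t".join(habitats) + "\n")
        for i, habitat in enumerate(habitats):
            row = "\t".join(f"{D[i, j]:.10g}" for j in range(len(habitats)))
            fh.write(f"{habitat}\t{row}\n")


def write_habitat_graph(graph: nx.Graph, graphml_path: str | Path,
                        edgelist_path: str | Path) -> None:
    nx.write_graphml(graph, str(graphml_path))
    with open(edgelist_path, "w") as fh:
        fh.write("habitat_a\thabitat_b\tweight\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']:.10g}\n")
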