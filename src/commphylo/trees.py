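"""Tree containers and helpers shared across the package.

Trees are :class:`dendropy.Tree` objects, always treated as rooted, with
finite non-negative branch lengths and unique tip labels.  Ultrametric
trees additionally carry a relative-time ``age`` on every node (present =
0 at the tips, root age typically rescaled to 1); branch lengths equal the
parent-child age difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

ULTRAMETRIC_RTOL = 1e-9


def read_newick(path_or_string: str | Path, *, is_string: bool = False) -> dendropy.Tree:
    """Read a rooted tree with branch lengths from Newick."""
    if is_string:
        tree = dendropy.Tree.get(data=str(path_or_string), schema="newick")
    else:
        tree = dendropy.Tree.get(path=str(path_or_string), schema="newick")
    tree.is_rooted = True
    validate_tree(tree)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )


def validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(lbl is None for lbl in labels):
        raise ValueError("all tips must be labeled")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length
        if bl is None or bl < 0 or bl != bl:
            raise ValueError(
                f"branch length of node {node} must be finite and >= 0, got {bl}"
            )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Distance from the root to every node, from branch lengths."""
    depths: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    depths = node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    hi = max(tip_depths)
    if hi == 0:
        return False
    return (hi - min(tip_depths)) <= rtol * hi


def set_ages_from_depths(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> None:
    """Annotate every node with its age (root depth minus node depth).

    Requires an ultrametric tree; tip ages are clamped to exactly 0.
    """
    if not is_ultrametric(tree, rtol):
        raise ValueError("tree is not ultrametric; cannot assign node ages")
    depths = node_depths(tree)
    height = max(depths[leaf] for leaf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        node.age = 0.0 if node.is_leaf() else height - depths[node]


def set_branch_lengths_from_ages(tree: dendropy.Tree) -> None:
    """Make branch lengths consistent with node ages (parent age - child age)."""
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = None
            continue
        bl = node.parent_node.age - node.age
        if bl < 0:
            raise ValueError(
                f"child age {node.age} exceeds parent age {node.parent_node.age}"
            )
        node.edge.length = bl


def internal_ages(tree: dendropy.Tree) -> list[float]:
    return [nd.age for nd in tree.preorder_internal_node_iter()]


@dataclass
class CommunityTable:
    """Habitat -> set-of-tip-ids incidence structure."""

    membership: dict[str, set[str]] = field(default_factory=dict)

    @property
    def habitats(self) -> list[str]:
        return sorted(self.membership)

    def size(self, habitat: str) -> int:
        return len(self.membership[habitat])

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for members in self.membership.values():
            out |= members
        return out

    def validate_against_tree(self, tree: dendropy.Tree) -> None:
        tips = set(tip_labels(tree))
        for habitat, members in self.membership.items():
            extra = members - tips
            if extra:
                raise KeyError(
                    f"habitat {habitat!r} members not in tree: {sorted(extra)[:5]}"
                )

    @classmethod
    def from_records(cls, records: Iterable) -> "CommunityTable":
        """Build from annotated SequenceRecords; unannotated records are skipped."""
        membership: dict[str, set[str]] = {}
        for r in records:
            if r.habitat:
                membership.setdefault(r.habitat, set()).add(r.id)
        return cls(membership)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CommunityTable":
        membership: dict[str, set[str]] = {}
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
            rows = [] if not first else [first]
            rows.extend(line.rstrip("\n") for line in fh)
        for row in rows:
            if not row or row.startswith("habitat\t"):
                continue
            habitat, tip_id = row.split("\t")
            membership.setdefault(habitat, set()).add(tip_id)
        return cls(membership)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("habitat\ttip_id\n")
            for habitat in self.habitats:
                for tip_id in sorted(self.membership[habitat]):
                    fh.write(f"{habitat}\t{tip_id}\n")
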