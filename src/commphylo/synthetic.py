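"""Synthetic fixtures with the statistical structure the analysis assumes.

Generates, under one seed:

* birth-death (default pure-birth/Yule) trees conditioned on a tip count,
  placed on relative time (root 1, present 0);
* a power age transform (age -> age^beta) that produces deceleration
  (beta < 1, gamma < 0) or acceleration (beta > 1, gamma > 0) regimes with
  known ground truth;
* habitat labelings with tunable phylogenetic clustering, from perfectly
  clade-faithful (clustering = 1) to independent of the tree
  (clustering = 0);
* nucleotide sequences evolved down the tree under the Jukes-Cantor
  substitution process, with controllable length, rate and ambiguity
  content, plus isolation-source strings drawn from the default habitat
  mapping so annotation round-trips with zero unmapped sources.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .ontology import DEFAULT_MAPPING, DEFAULT_MERGE_RULES, HabitatMapping
from .records import SequenceRecord, write_fasta, write_metadata
from .trees import (
    CommunityTable,
    set_branch_lengths_from_ages,
    write_newick,
)

__all__ = [
    "SimulationConfig",
    "simulate_yule",
    "simulate_birth_death",
    "apply_age_transform",
    "assign_habitats",
    "evolve_sequences",
    "make_fixture",
    "SyntheticBundle",
]

_BASES = np.array(list("ACGT"))

# habitat order used when picking n_habitats terms for a fixture
_HABITAT_ORDER = (
    "soil",
    "sediment",
    "marine plankton",
    "freshwater plankton",
    "wastewater",
    "sludge",
    "organism-associated",
    "biofilm",
    "hot spring",
    "hydrothermal vent",
    "cultured",
)

# isolation sources per habitat, reverse-engineered from the default
# keyword mapping (merge rules applied) so annotation always round-trips
_SOURCES_BY_HABITAT: dict[str, list[str]] = {}
for _src, _term in DEFAULT_MAPPING.items():
    _SOURCES_BY_HABITAT.setdefault(
        DEFAULT_MERGE_RULES.get(_term, _term), []
    ).append(_src)
for _v in _SOURCES_BY_HABITAT.values():
    _v.sort()


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one synthetic dataset.

    Defaults give a mid-sized marker-gene survey: ~120 sequences of 400 nt
    across 4 habitats, moderate phylogenetic clustering of habitats, a
    substitution rate placing typical within-habitat identities in the
    70-90% band, and enough ambiguity-bearing records that every filter
    has work to do.
    """

    n_tips: int = 120
    birth_rate: float = 1.0
    death_rate: float = 0.0
    age_transform_beta: float = 1.0
    n_habitats: int = 4
    clustering: float = 0.7
    seq_length: int = 400
    jc_rate: float = 0.25
    ambiguous_frac: float = 0.05
    ambiguous_record_frac: float = 0.1
    sources_per_habitat: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("birth_rate must be > 0 and death_rate >= 0")
        if self.age_transform_beta <= 0:
            raise ValueError("age_transform_beta must be > 0")
        if not 0.0 <= self.clustering <= 1.0:
            raise ValueError("clustering must lie in [0, 1]")
        if self.n_habitats > self.n_tips // 3:
            raise ValueError("n_habitats must be <= n_tips / 3")


def _build_tree(split_times: list[tuple[int, float]], present: float,
                rng: np.random.Generator) -> dendropy.Tree:
    """Assemble a dendropy tree from a forward birth process trace."""
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    root = tree.seed_node
    root.sim_time = 0.0
    active: list[dendropy.Node] = [root]
    # root's first split: replace root by two children at time 0
    for _ in range(2):
        child = dendropy.Node()
        child.sim_time = 0.0
        root.add_child(child)
        active = [c for c in root.child_nodes()]
    for idx, t in split_times:
        node = active.pop(idx)
        node.sim_time = t
        for _ in range(2):
            child = dendropy.Node()
            active.append(child)
        for child in active[-2:]:
            node.add_child(child)
    # label tips deterministically in traversal order
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            counter += 1
            node.taxon = taxon_namespace.new_taxon(label=f"t{counter}")
            node.sim_time = present
    # ages relative to the present
    for node in tree.preorder_node_iter():
        node.age = present - node.sim_time
        del node.sim_time
    set_branch_lengths_from_ages(tree)
    return tree


def simulate_yule(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Constant-rate pure-birth tree conditioned on a tip count.

    Forward simulation: starting from the root's split (two lineages),
    each of k extant lineages splits after an Exp(k * birth_rate) wait;
    after the (n-1)-th split a final Exp(n * birth_rate) interval runs to
    the present.  The tree is returned on relative time with root age 1.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    t = 0.0
    split_times: list[tuple[int, float]] = []
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (k * birth_rate))
        split_times.append((int(rng.integers(k)), t))
        k += 1
    present = t + rng.exponential(1.0 / (n_tips * birth_rate))
    tree = _build_tree(split_times, present, rng)
    from .diversification import scale_root

    return scale_root(tree, 1.0)


def simulate_birth_death(
    n_tips: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    max_tries: int = 1000,
) -> dendropy.Tree:
    """Birth-death tree conditioned on the extant tip count.

    Forward simulation from two lineages with per-lineage birth and death
    rates; runs restart on extinction or whenever the extant count fails
    to reach ``n_tips``.  The reconstructed (extinct lineages pruned)
    tree is rescaled to root age 1.  With ``death_rate = 0`` this is the
    Yule process.
    """
    if death_rate == 0:
        return simulate_yule(n_tips, birth_rate, seed)
    rng = np.random.default_rng(seed)
    total_rate = birth_rate + death_rate
    for _ in range(max_tries):
        # each extant lineage: list of (node placeholder index); we track
        # splits as a parent index tree in arrays, then build once
        parents: list[int] = [-1]  # node 0 is the root
        times: list[float] = [0.0]
        children: dict[int, list[int]] = {}
        alive: list[int] = []
        for _ in range(2):
            parents.append(0)
            times.append(math.nan)
            children.setdefault(0, []).append(len(parents) - 1)
            alive.append(len(parents) - 1)
        t = 0.0
        dead: set[int] = set()
        ok = False
        while alive:
            k = len(alive)
            if k >= n_tips:
                t += rng.exponential(1.0 / (k * total_rate))
                ok = True
                break
            t += rng.exponential(1.0 / (k * total_rate))
            idx = int(rng.integers(k))
            node = alive.pop(idx)
            times[node] = t
            if rng.random() < birth_rate / total_rate:
                for _ in range(2):
                    parents.append(node)
                    times.append(math.nan)
                    children.setdefault(node, []).append(len(parents) - 1)
                    alive.append(len(parents) - 1)
            else:
                dead.add(node)
        if not ok:
            continue
        present = t
        # build reconstructed tree over extant tips only
        extant = set(alive)
        tree = _assemble_reconstructed(parents, times, children, extant,
                                       present)
        if tree is not None:
            from .diversification import scale_root

            return scale_root(tree, 1.0)
    raise RuntimeError(
        f"birth-death simulation failed to reach {n_tips} extant tips in "
        f"{max_tries} tries"
    )


def _assemble_reconstructed(
    parents: list[int],
    times: list[float],
    children: dict[int, list[int]],
    extant: set[int],
    present: float,
) -> dendropy.Tree | None:
    """Prune extinct lineages and suppress unifurcations; None if fewer
    than two extant lineages survive under the root."""
    has_extant: dict[int, bool] = {}

    def mark(node: int) -> bool:
        if node in extant:
            has_extant[node] = True
            return True
        flag = False
        for c in children.get(node, []):
            if mark(c):  # evaluate every child; no short-circuit
                flag = True
        has_extant[node] = flag
        return flag

    mark(0)
    if not has_extant.get(0):
        return None

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    counter = [0]

    def build(node: int) -> dendropy.Node | None:
        if node in extant:
            nd = dendropy.Node()
            nd.age = 0.0
            counter[0] += 1
            nd.taxon = taxon_namespace.new_taxon(label=f"t{counter[0]}")
            return nd
        kept = [build(c) for c in children.get(node, []) if has_extant.get(c)]
        kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]  # unifurcation suppressed; child keeps its age
        nd = dendropy.Node()
        nd.age = present - times[node]
        for k in kept:
            nd.add_child(k)
        return nd

    root = build(0)
    if root is None or root.is_leaf():
        return None
    tree.seed_node = root
    set_branch_lengths_from_ages(tree)
    return tree


def apply_age_transform(tree: dendropy.Tree, beta: float) -> dendropy.Tree:
    """Power transform of relative node ages, age -> age**beta.

    Requires a tree on relative time (root age 1).  beta > 1 pushes
    internal nodes toward the present (gamma increases); beta < 1 pushes
    them toward the root (gamma decreases); beta = 1 is the identity.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    from .diversification import _clone_with_ages, _require_ages

    _require_ages(tree)
    if abs(tree.seed_node.age - 1.0) > 1e-9:
        raise ValueError("age transform expects a tree on relative time "
                         "(root age 1); apply scale_root first")
    out = _clone_with_ages(tree)
    for node in out.preorder_node_iter():
        if not node.is_leaf():
            node.age = node.age ** beta
    set_branch_lengths_from_ages(out)
    return out


def assign_habitats(
    tree: dendropy.Tree,
    n_habitats: int,
    clustering: float,
    seed: int = 0,
    habitat_names: Sequence[str] | None = None,
    max_tries: int = 1000,
) -> CommunityTable:
    """Habitat labels for the tips, with tunable phylogenetic clustering.

    The tree is decomposed into ``n_habitats`` disjoint clades covering
    all tips (repeatedly splitting the oldest frontier node).  Each tip
    then inherits its clade's habitat with probability ``clustering``,
    otherwise draws a habitat uniformly at random.  Resamples until every
    habitat is non-empty.
    """
    tips = [leaf for leaf in tree.leaf_node_iter()]
    if n_habitats > len(tips) // 3:
        raise ValueError("n_habitats must be <= n_tips / 3")
    if not 0.0 <= clustering <= 1.0:
        raise ValueError("clustering must lie in [0, 1]")
    if habitat_names is None:
        habitat_names = list(_HABITAT_ORDER[:n_habitats])
    if len(habitat_names) != n_habitats:
        raise ValueError("habitat_names length must equal n_habitats")
    from .trees import node_depths

    depths = node_depths(tree)

    def min_tip_label(node: dendropy.Node) -> str:
        return min(l.taxon.label for l in node.leaf_iter())

    frontier = [tree.seed_node]
    while len(frontier) < n_habitats:
        internals = [nd for nd in frontier if not nd.is_leaf()]
        if not internals:
            raise ValueError("tree cannot be split into that many clades")
        # split the shallowest (oldest) internal node; ties by tip label
        target = min(internals, key=lambda nd: (depths[nd], min_tip_label(nd)))
        frontier.remove(target)
        frontier.extend(target.child_nodes())
    frontier.sort(key=min_tip_label)
    clade_of: dict[str, int] = {}
    for ci, node in enumerate(frontier[:n_habitats]):
        for leaf in node.leaf_iter():
            clade_of[leaf.taxon.label] = ci
    # extra frontier nodes (when a split overshot) fold into the last clade
    for node in frontier[n_habitats:]:
        for leaf in node.leaf_iter():
            clade_of[leaf.taxon.label] = n_habitats - 1

    rng = np.random.default_rng(seed)
    labels = sorted(clade_of)
    for _ in range(max_tries):
        membership: dict[str, set[str]] = {h: set() for h in habitat_names}
        for label in labels:
            if rng.random() < clustering:
                hab = habitat_names[clade_of[label]]
            else:
                hab = habitat_names[int(rng.integers(n_habitats))]
            membership[hab].add(label)
        if all(membership.values()):
            return CommunityTable(membership)
    raise RuntimeError("could not produce a labeling with all habitats non-empty")


def evolve_sequences(
    tree: dendropy.Tree,
    seq_length: int,
    jc_rate: float,
    ambiguous_frac: float = 0.0,
    seed: int = 0,
    communities: CommunityTable | None = None,
    ambiguous_record_frac: float = 0.0,
    sources_per_habitat: int = 1,
) -> list[SequenceRecord]:
    """Evolve nucleotide sequences down the tree under Jukes-Cantor.

    The root sequence is uniform over ACGT; along each branch every site
    changes with probability (3/4)(1 - exp(-4 mu t / 3)) where t is the
    branch length and mu = ``jc_rate`` substitutions/site/unit time, and a
    changed site picks one of the three other bases uniformly.  When
    ``ambiguous_record_frac`` > 0, that fraction of records (chosen at
    random) has ``ambiguous_frac`` of its sites replaced by 'N'.  Records
    carry isolation-source strings derived from the habitat assignment
    (``communities``), cycling through ``sources_per_habitat`` known
    sources per habitat so the default mapping covers them all.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if jc_rate < 0:
        raise ValueError("jc_rate must be >= 0")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    tip_seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        t = node.edge.length or 0.0
        p_change = 0.75 * (1.0 - math.exp(-4.0 * jc_rate * t / 3.0))
        child_seq = parent_seq.copy()
        hits = rng.random(seq_length) < p_change
        n_hits = int(hits.sum())
        if n_hits:
            # shift by 1..3 mod 4: uniform over the three other bases
            child_seq[hits] = (child_seq[hits] + rng.integers(1, 4, n_hits)) % 4
        seqs[id(node)] = child_seq
        if node.is_leaf():
            tip_seqs[node.taxon.label] = child_seq

    habitat_of: dict[str, str] = {}
    if communities is not None:
        for habitat, members in communities.membership.items():
            for m in members:
                habitat_of[m] = habitat

    # deterministic source assignment: cycle sources within each habitat
    source_of: dict[str, str] = {}
    if communities is not None:
        for habitat in sorted(communities.membership):
            pool = _SOURCES_BY_HABITAT.get(habitat, [habitat])
            pool = pool[: max(1, sources_per_habitat)]
            for i, m in enumerate(sorted(communities.membership[habitat])):
                source_of[m] = pool[i % len(pool)]

    labels = sorted(tip_seqs)
    n_ambig_records = int(round(ambiguous_record_frac * len(labels)))
    ambig_ids = set(
        rng.choice(labels, size=n_ambig_records, replace=False)
    ) if n_ambig_records else set()

    records: list[SequenceRecord] = []
    for label in labels:
        arr = tip_seqs[label]
        seq_chars = _BASES[arr].copy()
        if label in ambig_ids and ambiguous_frac > 0:
            n_sites = int(round(ambiguous_frac * seq_length))
            pos = rng.choice(seq_length, size=n_sites, replace=False)
            seq_chars[pos] = "N"
        records.append(
            SequenceRecord(
                id=label,
                seq="".join(seq_chars),
                source=source_of.get(label, "unknown source"),
                habitat=habitat_of.get(label),
                domain_tag="unknown",
            )
        )
    return records


@dataclass
class SyntheticBundle:
    """One self-consistent synthetic dataset."""

    config: SimulationConfig
    tree: dendropy.Tree
    communities: CommunityTable
    records: list[SequenceRecord]
    mapping: HabitatMapping

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "sequences.fasta",
            "metadata": outdir / "metadata.tsv",
            "mapping": outdir / "mapping.tsv",
            "merge": outdir / "merge_rules.tsv",
            "newick": outdir / "tree.nwk",
            "communities": outdir / "communities.tsv",
        }
        write_fasta(self.records, paths["fasta"])
        write_metadata(self.records, paths["metadata"])
        self.mapping.write_tsv(paths["mapping"], paths["merge"])
        write_newick(self.tree, paths["newick"])
        self.communities.write_tsv(paths["communities"])
        return paths


def make_fixture(config: SimulationConfig) -> SyntheticBundle:
    """Generate one self-consistent tree + habitats + sequences bundle."""
    tree = simulate_birth_death(
        config.n_tips, config.birth_rate, config.death_rate, config.seed
    )
    if config.age_transform_beta != 1.0:
        tree = apply_age_transform(tree, config.age_transform_beta)
    communities = assign_habitats(
        tree, config.n_habitats, config.clustering, config.seed + 1
    )
    records = evolve_sequences(
        tree,
        config.seq_length,
        config.jc_rate,
        config.ambiguous_frac,
        config.seed + 2,
        communities=communities,
        ambiguous_record_frac=config.ambiguous_record_frac,
        sources_per_habitat=config.sources_per_habitat,
    )
    return SyntheticBundle(
        config=config,
        tree=tree,
        communities=communities,
        records=records,
        mapping=HabitatMapping(),
    )
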