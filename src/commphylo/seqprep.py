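"""Sequence quality filtering, redundancy reduction and identity profiles.

The preparation pipeline applies, in order:

1. ambiguity filter — drop records whose fraction of non-ACGT positions
   exceeds ``max_ambiguous_frac`` (strictly greater: a record exactly at
   the threshold is kept);
2. small-source filter — drop every record of an isolation source that has
   fewer than ``min_seqs_per_source`` records;
3. per-source greedy clustering at ``cluster_identity`` — one
   representative per cluster, clustered independently within each source
   so that identical sequences from different environments all survive;
4. length-outlier filter — within each domain group, drop records shorter
   than ``mean - length_sd_multiplier * SD`` of the group's lengths.

Pairwise identity is computed from an end-to-end (global) alignment under
match +1 / mismatch -1 / gap -2 scoring; identity is the number of
identical columns divided by the total number of alignment columns (gap
columns count in the denominator).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import Align

from .records import SequenceRecord
from .trees import CommunityTable

__all__ = [
    "FilterConfig",
    "FilterReport",
    "IdentityDistribution",
    "filter_ambiguous",
    "filter_small_sources",
    "filter_length_outliers",
    "greedy_cluster",
    "pairwise_identity",
    "identity_distributions",
    "prepare",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the preparation pipeline (defaults follow common
    practice for public marker-gene compilations)."""

    max_ambiguous_frac: float = 0.001
    min_seqs_per_source: int = 5
    cluster_identity: float = 0.98
    length_sd_multiplier: float = 2.0
    # global-alignment scoring used for percent identity
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_ambiguous_frac <= 1.0:
            raise ValueError("max_ambiguous_frac must lie in [0, 1]")
        if not 0.0 < self.cluster_identity <= 1.0:
            raise ValueError("cluster_identity must lie in (0, 1]")
        if self.min_seqs_per_source < 1:
            raise ValueError("min_seqs_per_source must be >= 1")
        if self.length_sd_multiplier < 0:
            raise ValueError("length_sd_multiplier must be >= 0")


@dataclass
class FilterReport:
    """Bookkeeping of the preparation pipeline.

    Invariant: ``n_output == n_input - (n_removed_ambiguous +
    n_removed_small_source + n_removed_short + n_removed_redundant)``.
    """

    n_input: int = 0
    n_removed_ambiguous: int = 0
    n_removed_small_source: int = 0
    n_removed_short: int = 0
    n_removed_redundant: int = 0
    n_output: int = 0
    per_source_counts: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        removed = (
            self.n_removed_ambiguous
            + self.n_removed_small_source
            + self.n_removed_short
            + self.n_removed_redundant
        )
        if self.n_output != self.n_input - removed:
            raise AssertionError(
                f"filter bookkeeping does not balance: {self.n_input} - "
                f"{removed} != {self.n_output}"
            )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            fh.write(f"input\t{self.n_input}\n")
            fh.write(f"removed_ambiguous\t{self.n_removed_ambiguous}\n")
            fh.write(f"removed_small_source\t{self.n_removed_small_source}\n")
            fh.write(f"removed_redundant\t{self.n_removed_redundant}\n")
            fh.write(f"removed_short\t{self.n_removed_short}\n")
            fh.write(f"output\t{self.n_output}\n")
            for source in sorted(self.per_source_counts):
                fh.write(f"source:{source}\t{self.per_source_counts[source]}\n")


@dataclass
class IdentityDistribution:
    """All-against-all pairwise identities within one habitat."""

    habitat: str
    identities: list[float]
    flagged: bool = False  # True when the habitat had < 2 records

    @property
    def summary(self) -> dict[str, float]:
        """Five-number boxplot summary (quartiles by linear interpolation)."""
        if not self.identities:
            return {}
        xs = sorted(self.identities)
        q1, med, q3 = (_quantile(xs, q) for q in (0.25, 0.5, 0.75))
        return {"min": xs[0], "q1": q1, "median": med, "q3": q3, "max": xs[-1]}


def _quantile(sorted_xs: Sequence[float], q: float) -> float:
    """Linear-interpolation quantile on pre-sorted data."""
    n = len(sorted_xs)
    if n == 1:
        return sorted_xs[0]
    pos = q * (n - 1)
    lo = int(pos)
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_xs[lo] * (1 - frac) + sorted_xs[hi] * frac


# ---------------------------------------------------------------------------
# individual filters


def filter_ambiguous(
    records: Sequence[SequenceRecord], cfg: FilterConfig
) -> tuple[list[SequenceRecord], int]:
    """Drop records with strictly more than ``max_ambiguous_frac`` non-ACGT
    positions."""
    kept = [r for r in records if r.ambiguous_frac <= cfg.max_ambiguous_frac]
    return kept, len(records) - len(kept)


def filter_small_sources(
    records: Sequence[SequenceRecord], cfg: FilterConfig
) -> tuple[list[SequenceRecord], int]:
    """Drop every record of an isolation source represented by fewer than
    ``min_seqs_per_source`` records."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.source] = counts.get(r.source, 0) + 1
    kept = [r for r in records if counts[r.source] >= cfg.min_seqs_per_source]
    return kept, len(records) - len(kept)


def filter_length_outliers(
    records: Sequence[SequenceRecord], cfg: FilterConfig
) -> tuple[list[SequenceRecord], int]:
    """Drop too-short records, per domain group, in a single pass.

    The cut is one-sided: a record is removed when its length is below
    ``mean - length_sd_multiplier * SD`` where mean and SD are taken over
    the group's lengths before any removal.  Groups of a single record are
    kept unchanged (the SD is undefined).
    """
    groups: dict[str, list[SequenceRecord]] = {}
    for r in records:
        groups.setdefault(r.domain_tag, []).append(r)
    kept: list[SequenceRecord] = []
    for group in groups.values():
        if len(group) < 2:
            kept.extend(group)
            continue
        lengths = [r.length for r in group]
        mean = statistics.fmean(lengths)
        sd = statistics.pstdev(lengths)
        cutoff = mean - cfg.length_sd_multiplier * sd
        kept.extend(r for r in group if r.length >= cutoff)
    order = {id(r): i for i, r in enumerate(records)}
    kept.sort(key=lambda r: order[id(r)])
    return kept, len(records) - len(kept)


# ---------------------------------------------------------------------------
# pairwise identity and clustering


def _make_aligner(cfg: FilterConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = cfg.match_score
    aligner.mismatch_score = cfg.mismatch_score
    aligner.open_gap_score = cfg.gap_score
    aligner.extend_gap_score = cfg.gap_score
    return aligner


_DEFAULT_ALIGNER = None


def pairwise_identity(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Global-alignment identity between two sequences.

    Identity = identical columns / total alignment columns, so terminal
    and internal gap columns lower the identity.  Symmetric by
    construction (the argument pair is canonically ordered before
    aligning, so co-optimal alignment ties cannot break symmetry).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    global _DEFAULT_ALIGNER
    if aligner is None:
        if _DEFAULT_ALIGNER is None:
            _DEFAULT_ALIGNER = _make_aligner(FilterConfig())
        aligner = _DEFAULT_ALIGNER
    x, y = sorted((a.upper(), b.upper()))
    aln = aligner.align(x, y)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def greedy_cluster(
    records: Sequence[SequenceRecord],
    cfg: FilterConfig,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy incremental clustering of one source's records.

    Records are processed in descending length order (ties broken by id);
    each joins the first existing cluster whose founder it matches at
    ``cluster_identity`` or better, else founds a new cluster.  Returns
    the founders (in founding order) and a record-id -> founder-id map.
    The ``seed`` argument is accepted for interface uniformity; the
    procedure is deterministic and does not use it.
    """
    if not records:
        return [], {}
    sources = {r.source for r in records}
    if len(sources) > 1:
        raise ValueError(
            f"greedy_cluster operates on a single source, got {sorted(sources)}"
        )
    aligner = _make_aligner(cfg)
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    founders: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    for rec in ordered:
        for rep in founders:
            if pairwise_identity(rec.seq, rep.seq, aligner) >= cfg.cluster_identity:
                assignment[rec.id] = rep.id
                break
        else:
            founders.append(rec)
            assignment[rec.id] = rec.id
    return founders, assignment


def cluster_by_source(
    records: Sequence[SequenceRecord],
    cfg: FilterConfig,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], int]:
    """Cluster each isolation source independently; keep one representative
    per cluster.  Identical sequences appearing in different sources all
    survive."""
    by_source: dict[str, list[SequenceRecord]] = {}
    for r in records:
        by_source.setdefault(r.source, []).append(r)
    reps: list[SequenceRecord] = []
    for source in sorted(by_source):
        founders, _ = greedy_cluster(by_source[source], cfg, seed)
        reps.extend(founders)
    order = {id(r): i for i, r in enumerate(records)}
    reps.sort(key=lambda r: order[id(r)])
    return reps, len(records) - len(reps)


# ---------------------------------------------------------------------------
# pipeline and identity profiles


def prepare(
    records: Sequence[SequenceRecord],
    cfg: FilterConfig | None = None,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Run the full preparation pipeline in its canonical order.

    Order: ambiguity -> small sources -> per-source clustering -> length
    outliers.  Re-running on the output is idempotent.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=len(records))
    recs, report.n_removed_ambiguous = filter_ambiguous(records, cfg)
    recs, report.n_removed_small_source = filter_small_sources(recs, cfg)
    recs, report.n_removed_redundant = cluster_by_source(recs, cfg, seed)
    recs, report.n_removed_short = filter_length_outliers(recs, cfg)
    report.n_output = len(recs)
    for r in recs:
        report.per_source_counts[r.source] = (
            report.per_source_counts.get(r.source, 0) + 1
        )
    report.check()
    return recs, report


def identity_distributions(
    records: Sequence[SequenceRecord],
    communities: CommunityTable,
    cfg: FilterConfig | None = None,
) -> list[IdentityDistribution]:
    """Within-habitat all-against-all pairwise identities.

    For each habitat, the identities of all unordered pairs of its
    members.  Habitats with fewer than two records yield an empty,
    flagged distribution.
    """
    cfg = cfg or FilterConfig()
    aligner = _make_aligner(cfg)
    by_id: Mapping[str, SequenceRecord] = {r.id: r for r in records}
    out: list[IdentityDistribution] = []
    for habitat in communities.habitats:
        members = sorted(communities.membership[habitat])
        missing = [m for m in members if m not in by_id]
        if missing:
            raise KeyError(
                f"habitat {habitat!r} members absent from records: {missing[:5]}"
            )
        if len(members) < 2:
            out.append(IdentityDistribution(habitat, [], flagged=True))
            continue
        idents = [
            pairwise_identity(by_id[members[i]].seq, by_id[members[j]].seq, aligner)
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        out.append(IdentityDistribution(habitat, idents))
    return out
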