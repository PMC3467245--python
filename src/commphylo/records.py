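"""Sequence records and their on-disk representation.

A dataset is a FASTA file of nucleotide sequences plus a tab-separated
metadata table keyed by the same ids (columns ``id``, ``source``,
``habitat``, ``domain_tag``).  The record carries the free-text isolation
source; the habitat slot is filled later by the ontology annotator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# IUPAC nucleotide one-letter codes; '-' and '.' are alignment characters,
# not residues, and are rejected when a record is validated.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")

DOMAIN_TAGS = ("AOA", "AOB", "unknown")

METADATA_COLUMNS = ("id", "source", "habitat", "domain_tag")


@dataclass
class SequenceRecord:
    """One nucleotide sequence with its isolation-source metadata."""

    id: str
    seq: str
    source: str = ""
    habitat: str | None = None
    domain_tag: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        self.seq = self.seq.upper()
        bad = set(self.seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.domain_tag not in DOMAIN_TAGS:
            raise ValueError(
                f"record {self.id!r}: domain_tag must be one of {DOMAIN_TAGS}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def n_ambiguous(self) -> int:
        """Count of positions that are not A, C, G or T."""
        return sum(1 for c in self.seq if c not in UNAMBIGUOUS)

    @property
    def ambiguous_frac(self) -> float:
        return self.n_ambiguous / len(self.seq)

    def with_habitat(self, habitat: str | None) -> "SequenceRecord":
        return replace(self, habitat=habitat)


def _check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_metadata(path: str | Path) -> list[dict[str, str]]:
    """Read the metadata TSV; returns one dict per row."""
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != METADATA_COLUMNS:
            raise ValueError(
                f"metadata header must be {METADATA_COLUMNS}, got {header}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(METADATA_COLUMNS):
                raise ValueError(f"malformed metadata row: {line!r}")
            rows.append(dict(zip(METADATA_COLUMNS, fields)))
    return rows


def write_metadata(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.id}\t{r.source}\t{r.habitat or ''}\t{r.domain_tag}\n"
            )


def load_dataset(
    fasta_path: str | Path, metadata_path: str | Path
) -> list[SequenceRecord]:
    """Join a FASTA file with its metadata table into SequenceRecords.

    Every metadata id must have a sequence and vice versa.
    """
    seqs = read_fasta(fasta_path)
    rows = read_metadata(metadata_path)
    meta_ids = {row["id"] for row in rows}
    missing_seq = meta_ids - seqs.keys()
    missing_meta = seqs.keys() - meta_ids
    if missing_seq:
        raise ValueError(f"metadata ids without sequences: {sorted(missing_seq)[:5]}")
    if missing_meta:
        raise ValueError(f"sequences without metadata: {sorted(missing_meta)[:5]}")
    records = [
        SequenceRecord(
            id=row["id"],
            seq=seqs[row["id"]],
            source=row["source"],
            habitat=row["habitat"] or None,
            domain_tag=row["domain_tag"] or "unknown",
        )
        for row in rows
    ]
    _check_unique_ids(records)
    return records
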