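"""Isolation-source -> habitat annotation with a reduced environment
ontology vocabulary.

Free-text isolation sources are mapped onto a small controlled vocabulary
of habitat terms (the EnvO-Lite style reduction), then fine-grained terms
are merged upward (animal-associated and plant-associated fold into
organism-associated).  Two conventions matter:

* "cultured" is reserved for engineered laboratory habitats — artificial
  biofilters and bioreactors; microbial strains isolated in the lab keep
  the habitat they originally came from.
* wastewater (adversely affected liquid water) and sludge (residual
  semi-solid material from treatment processes) stay distinct habitats.

The shipped default mapping is a keyword-based reconstruction intended to
cover common source descriptions and everything the synthetic fixture
generator emits; a user-supplied TSV extends or overrides it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .records import SequenceRecord
from .trees import CommunityTable

#: The coarse habitat vocabulary.
HABITATS = (
    "soil",
    "sediment",
    "marine plankton",
    "freshwater plankton",
    "organism-associated",
    "wastewater",
    "sludge",
    "biofilm",
    "hot spring",
    "hydrothermal vent",
    "cultured",
)

#: Fine terms allowed as mapping targets before merging.
FINE_TERMS = ("animal-associated", "plant-associated")

CONTROLLED_VOCABULARY = frozenset(HABITATS) | frozenset(FINE_TERMS)

DEFAULT_MERGE_RULES: dict[str, str] = {
    "animal-associated": "organism-associated",
    "plant-associated": "organism-associated",
}

# Reconstructed keyword mapping for common isolation-source phrasings.
DEFAULT_MAPPING: dict[str, str] = {
    # soils
    "agricultural soil": "soil",
    "forest soil": "soil",
    "paddy soil": "soil",
    "grassland soil": "soil",
    "alpine soil": "soil",
    "soil": "soil",
    # sediments
    "marine sediment": "sediment",
    "lake sediment": "sediment",
    "estuarine sediment": "sediment",
    "river sediment": "sediment",
    "sediment": "sediment",
    # water columns
    "open ocean water": "marine plankton",
    "coastal seawater": "marine plankton",
    "deep sea water": "marine plankton",
    "seawater": "marine plankton",
    "lake water": "freshwater plankton",
    "river water": "freshwater plankton",
    "alpine lake water": "freshwater plankton",
    "freshwater": "freshwater plankton",
    # host-associated (fine terms, merged upward)
    "sponge tissue": "animal-associated",
    "coral tissue": "animal-associated",
    "fish gill": "animal-associated",
    "rice rhizosphere": "plant-associated",
    "plant rhizosphere": "plant-associated",
    "macrophyte surface": "plant-associated",
    # engineered and treatment systems
    "wastewater treatment plant": "wastewater",
    "municipal wastewater": "wastewater",
    "wastewater": "wastewater",
    "activated sludge reactor": "sludge",
    "activated sludge": "sludge",
    "digester sludge": "sludge",
    # only biofilters/bioreactors count as "cultured"
    "aquarium biofilter": "cultured",
    "nitrifying bioreactor": "cultured",
    "laboratory bioreactor": "cultured",
    # surfaces and extreme habitats
    "stream biofilm": "biofilm",
    "pipe biofilm": "biofilm",
    "hot spring water": "hot spring",
    "geothermal spring": "hot spring",
    "hydrothermal vent fluid": "hydrothermal vent",
    "deep-sea vent chimney": "hydrothermal vent",
}


@dataclass
class HabitatMapping:
    """Isolation-source -> habitat-term lookup plus upward merge rules."""

    entries: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MAPPING))
    merge_rules: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MERGE_RULES)
    )
    min_sequences_per_habitat: int = 5

    def __post_init__(self) -> None:
        bad = {t for t in self.entries.values() if t not in CONTROLLED_VOCABULARY}
        if bad:
            raise ValueError(f"mapping targets outside the vocabulary: {sorted(bad)}")
        bad = {t for t in self.merge_rules.values() if t not in CONTROLLED_VOCABULARY}
        if bad:
            raise ValueError(f"merge targets outside the vocabulary: {sorted(bad)}")

    def resolve(self, source: str) -> str | None:
        """Habitat for one isolation source, with merge rules applied once."""
        term = self.entries.get(source.strip().lower())
        if term is None:
            return None
        return self.merge_rules.get(term, term)

    @classmethod
    def from_tsv(
        cls,
        mapping_path: str | Path,
        merge_path: str | Path | None = None,
        *,
        extend_default: bool = False,
    ) -> "HabitatMapping":
        entries = dict(DEFAULT_MAPPING) if extend_default else {}
        with open(mapping_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("source\t"):
                    continue
                source, term = line.split("\t")
                entries[source.strip().lower()] = term
        merge_rules = dict(DEFAULT_MERGE_RULES)
        if merge_path is not None:
            merge_rules = {}
            with open(merge_path) as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line or line.startswith("term\t"):
                        continue
                    term, parent = line.split("\t")
                    merge_rules[term] = parent
        return cls(entries=entries, merge_rules=merge_rules)

    def write_tsv(self, mapping_path: str | Path, merge_path: str | Path) -> None:
        with open(mapping_path, "w") as fh:
            fh.write("source\tenvo_lite_term\n")
            for source in sorted(self.entries):
                fh.write(f"{source}\t{self.entries[source]}\n")
        with open(merge_path, "w") as fh:
            fh.write("term\tparent_term\n")
            for term in sorted(self.merge_rules):
                fh.write(f"{term}\t{self.merge_rules[term]}\n")


def annotate(
    records: Sequence[SequenceRecord], mapping: HabitatMapping | None = None
) -> tuple[list[SequenceRecord], list[str]]:
    """Assign a habitat to every record whose source the mapping covers.

    Returns the annotated records (unmapped ones pass through with
    ``habitat=None``) and the sorted list of distinct unmapped sources.
    Annotation is idempotent: merge rules are applied exactly once inside
    :meth:`HabitatMapping.resolve`, never chained.
    """
    mapping = mapping or HabitatMapping()
    if not mapping.entries:
        raise ValueError("habitat mapping is empty")
    annotated: list[SequenceRecord] = []
    unmapped: set[str] = set()
    for r in records:
        habitat = mapping.resolve(r.source)
        if habitat is None:
            unmapped.add(r.source)
            annotated.append(r.with_habitat(None))
        else:
            annotated.append(r.with_habitat(habitat))
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} isolation source(s) not covered by the habitat "
            f"mapping; their records are excluded from community analyses",
            stacklevel=2,
        )
    return annotated, sorted(unmapped)


def drop_small_habitats(communities: CommunityTable, min_n: int) -> CommunityTable:
    """Remove habitats with fewer than ``min_n`` members."""
    kept = {
        habitat: set(members)
        for habitat, members in communities.membership.items()
        if len(members) >= min_n
    }
    if not kept:
        raise ValueError(
            f"no habitat has at least {min_n} members; nothing to analyze"
        )
    return CommunityTable(kept)
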