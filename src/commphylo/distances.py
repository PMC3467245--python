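"""Evolutionary distance estimators and the substitution-saturation check.

Works on pairs of equal-length, gap-containing nucleotide strings.  Sites
where either sequence has a gap or an ambiguous base are excluded pairwise
(pairwise deletion), which keeps as many sites usable as possible on the
ragged alignments typical of public-database compilations.

Saturation is diagnosed by comparing model-corrected distances (JC69,
Kimura two-parameter) against the raw proportion of differing sites: at
low divergence corrections barely inflate the raw distance (slope near 1);
saturated pairs fall outside the estimators' domain and are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class SaturatedDistanceError(ValueError):
    """Raised when divergence is outside a distance estimator's domain."""


@dataclass(frozen=True)
class AlignedPair:
    """Two rows of an alignment, compared at pairwise-deleted sites."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError(
                f"aligned sequences differ in length: {len(self.a)} vs {len(self.b)}"
            )
        object.__setattr__(self, "a", self.a.upper())
        object.__setattr__(self, "b", self.b.upper())

    def site_counts(self) -> tuple[int, int, int]:
        """(comparable sites, transitions, transversions).

        Comparable sites are columns where both characters are unambiguous
        bases.  Transitions are A<->G and C<->T; every other difference is
        a transversion.
        """
        comparable = transitions = transversions = 0
        for x, y in zip(self.a, self.b):
            if x not in _VALID or y not in _VALID:
                continue
            comparable += 1
            if x == y:
                continue
            if (x in PURINES) == (y in PURINES):
                transitions += 1
            else:
                transversions += 1
        return comparable, transitions, transversions

    @property
    def comparable_sites(self) -> int:
        return self.site_counts()[0]


def p_distance(pair: AlignedPair) -> float:
    """Raw distance: proportion of differing comparable sites."""
    comparable, ts, tv = pair.site_counts()
    if comparable == 0:
        raise ValueError("no comparable sites; p-distance undefined")
    return (ts + tv) / comparable


def jc69(pair: AlignedPair) -> float:
    """Jukes-Cantor distance, d = -(3/4) ln(1 - 4p/3).

    Undefined (saturated) once p >= 0.75.
    """
    p = p_distance(pair)
    return jc69_from_p(p)


def jc69_from_p(p: float) -> float:
    if p >= 0.75:
        raise SaturatedDistanceError(
            f"p = {p:.4f} >= 0.75: Jukes-Cantor distance undefined (saturated)"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k2p(pair: AlignedPair) -> float:
    """Kimura two-parameter distance,
    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q),
    with P and Q the transition and transversion proportions."""
    comparable, ts, tv = pair.site_counts()
    if comparable == 0:
        raise ValueError("no comparable sites; K2P distance undefined")
    return k2p_from_pq(ts / comparable, tv / comparable)


def k2p_from_pq(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistanceError(
            f"P = {P:.4f}, Q = {Q:.4f}: K2P log argument non-positive (saturated)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def saturation_table(
    alignment: Sequence[tuple[str, str]]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Distances for every unordered pair of an alignment plus a summary.

    ``alignment`` is a sequence of (id, aligned sequence) tuples of equal
    length.  The table has one row per pair with columns ``pair``, ``p``,
    ``jc69``, ``k2p`` and a ``saturated`` flag (NaN distances where an
    estimator's domain is violated).  The summary reports the fraction of
    saturated pairs and the slope of the corrected-vs-raw relation at
    small p (over pairs with p < 0.2; 1.0 in the no-divergence limit) —
    a numeric stand-in for the visual saturation-plot check.
    """
    if len(alignment) < 2:
        raise ValueError("saturation check needs at least two sequences")
    lengths = {len(seq) for _, seq in alignment}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    rows = []
    for (id_a, seq_a), (id_b, seq_b) in combinations(alignment, 2):
        pair = AlignedPair(seq_a, seq_b)
        p = p_distance(pair)
        saturated = False
        try:
            d_jc = jc69_from_p(p)
        except SaturatedDistanceError:
            d_jc, saturated = float("nan"), True
        comparable, ts, tv = pair.site_counts()
        try:
            d_k2p = k2p_from_pq(ts / comparable, tv / comparable)
        except SaturatedDistanceError:
            d_k2p, saturated = float("nan"), True
        rows.append(
            {
                "pair": f"{id_a}|{id_b}",
                "p": p,
                "jc69": d_jc,
                "k2p": d_k2p,
                "saturated": saturated,
            }
        )
    table = pd.DataFrame(rows)
    low = table[(table["p"] < 0.2) & (table["p"] > 0) & ~table["saturated"]]
    if len(low):
        # least-squares slope through the origin of jc69 vs p
        slope = float((low["jc69"] * low["p"]).sum() / (low["p"] ** 2).sum())
    else:
        slope = 1.0
    summary = {
        "fraction_saturated": float(table["saturated"].mean()),
        "low_divergence_slope": slope,
    }
    return table, summary


def write_saturation_table(
    table: pd.DataFrame, summary: dict[str, float], path: str | Path
) -> None:
    table.to_csv(path, sep="\t", index=False)
    summary_path = Path(path).with_suffix(".summary.tsv")
    with open(summary_path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
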