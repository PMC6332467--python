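"""Top-level mitochondrial haplogroup assignment by marker matching.

Each haplogroup label is represented by a flat set of defining variants
(position, alt).  A sample is assigned the label whose markers it matches at
the highest fraction; raw match count and then lexicographic label order
break ties, so that a label whose marker set is a superset of another
(e.g. K extending U) wins when all of its markers are present.

This is a deliberate simplification of full phylogeny-walking classifiers
such as Mitomaster/HaploGrep: only the top-level labels used in cohort-scale
association tables are distinguished, back-mutations are ignored, and private
variants carry no weight.  It is not expected to reproduce a full Phylotree
classifier on real-world data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .genome import MT_GENOME_LENGTH

UNCLASSIFIED = "unclassified"

Variant = tuple[int, str]  # (1-based position, alt base)


class MarkerTableError(ValueError):
    """Invalid or empty haplogroup marker configuration."""


@dataclass(frozen=True)
class HaplogroupCall:
    """Best-matching haplogroup for one sample."""

    haplogroup: str
    matched: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.matched <= max(self.total, 0):
            raise ValueError("matched marker count outside 0..total")

    @property
    def match_fraction(self) -> float:
        return self.matched / self.total if self.total else 0.0


def validate_markers(markers: Mapping[str, Iterable[Variant]]) -> dict[str, frozenset[Variant]]:
    """Validate and normalize a marker table."""
    if not markers:
        raise MarkerTableError("marker table is empty")
    table: dict[str, frozenset[Variant]] = {}
    for label, variants in markers.items():
        vset = frozenset((int(p), str(a).upper()) for p, a in variants)
        if not vset:
            raise MarkerTableError(f"haplogroup {label!r} has no markers")
        for pos, alt in vset:
            if not 1 <= pos <= MT_GENOME_LENGTH:
                raise MarkerTableError(f"haplogroup {label!r}: marker position {pos} out of range")
            if alt not in "ACGT":
                raise MarkerTableError(f"haplogroup {label!r}: invalid marker alt {alt!r}")
        table[label] = vset
    return table


def assign_haplogroup(
    variants: Iterable[Variant], markers: Mapping[str, Iterable[Variant]]
) -> HaplogroupCall:
    """Assign the best-matching haplogroup label to one sample.

    Parameters
    ----------
    variants:
        The sample's variants as (position, alt) pairs; order is irrelevant.
    markers:
        Mapping from haplogroup label to its defining (position, alt) set.

    Returns
    -------
    HaplogroupCall
        The label maximizing match fraction, ties broken by larger matched
        count and then lexicographic label order.  A sample matching no
        marker of any label gets the reserved label ``"unclassified"``.
    """
    table = validate_markers(markers)
    observed = {(int(p), str(a).upper()) for p, a in variants}
    best: HaplogroupCall | None = None
    for label in sorted(table):
        defining = table[label]
        matched = len(defining & observed)
        call = HaplogroupCall(label, matched, len(defining))
        if best is None or (call.match_fraction, call.matched) > (
            best.match_fraction,
            best.matched,
        ):
            best = call
    assert best is not None
    if best.matched == 0:
        return HaplogroupCall(UNCLASSIFIED, 0, 0)
    return best


def read_marker_table(path: str | Path) -> dict[str, frozenset[Variant]]:
    """Read a marker TSV with columns haplogroup, position, alt."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"haplogroup", "position", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise MarkerTableError(f"{path}: marker table missing columns {sorted(missing)}")
    grouped: dict[str, set[Variant]] = {}
    for _, row in df.iterrows():
        grouped.setdefault(str(row["haplogroup"]), set()).add(
            (int(row["position"]), str(row["alt"]).upper())
        )
    return validate_markers(grouped)
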