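"""Pathogenicity-score annotation and per-sample variant load.

The variant load of a sample is the sum of pathogenicity scores (MutPred-style
probabilities in [0, 1] that an amino-acid substitution is deleterious) over
its qualifying variants: non-synonymous, operationally homoplasmic
(allele fraction >= a configurable cutoff, default 0.95) and scored strictly
above a threshold (default 0.5; 0.7 for the high-confidence tier).  Scores are
inputs read from a table keyed by (position, alt) — the pathogenicity
predictor itself is out of scope here.

Population frequencies classify variants as rare (< 0.1%), common (> 1%) or
intermediate; variants without a frequency are "unknown".  Proven pathogenic
mutations (e.g. m.3243A>G, m.1555A>G) are screened separately at any allele
fraction, because even heteroplasmic carriers are clinically relevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import MT_GENOME_LENGTH, NON_SYNONYMOUS, ConsequenceCall
from .haplogroups import HaplogroupCall

# Rarity bands on population frequency.
RARE_MAX = 0.001  # rare:   f < 0.1%
COMMON_MIN = 0.01  # common: f > 1%

RARITY_RARE = "rare"
RARITY_INTERMEDIATE = "intermediate"
RARITY_COMMON = "common"
RARITY_UNKNOWN = "unknown"

CATEGORY_NONE = "0"
CATEGORY_ONE = "1"
CATEGORY_TWO_PLUS = "2+"

COMBO_NONE = "none"
COMBO_SINGLE = "single"
COMBO_COMMON_ONLY = "common-only"
COMBO_COMMON_RARE = "common+rare"
COMBO_RARE_ONLY = "rare-only"

DEFAULT_SCORE_THRESHOLD = 0.5
HIGH_SCORE_THRESHOLD = 0.7
DEFAULT_HOMOPLASMY_CUTOFF = 0.95


@dataclass(frozen=True)
class MtVariant:
    """One single-nucleotide variant against the mitochondrial reference."""

    position: int
    ref: str
    alt: str
    fraction: float = 1.0  # alternate allele fraction; 1.0 when unstated

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_GENOME_LENGTH:
            raise ValueError(f"position {self.position} outside 1..{MT_GENOME_LENGTH}")
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at position {self.position}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"allele fraction {self.fraction} outside [0, 1]")

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt)

    def __str__(self) -> str:
        return f"m.{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant with consequence calls, score, frequency and rarity class."""

    variant: MtVariant
    calls: tuple[ConsequenceCall, ...]
    score: float | None = None
    frequency: float | None = None
    rarity: str = RARITY_UNKNOWN

    @property
    def is_nonsynonymous(self) -> bool:
        """True if any protein-feature call is a plain amino-acid substitution."""
        return any(c.consequence == NON_SYNONYMOUS for c in self.calls)

    def qualifies(self, threshold: float, homoplasmy_cutoff: float) -> bool:
        """Counts toward the variant load at the given thresholds."""
        return (
            self.score is not None
            and self.score > threshold
            and self.variant.fraction >= homoplasmy_cutoff
        )


@dataclass
class SampleProfile:
    """One individual's annotated mtDNA variants plus derived summaries."""

    sample_id: str
    cohort: str
    variants: list[AnnotatedVariant] = field(default_factory=list)
    haplogroup: HaplogroupCall | None = None


def rarity_class(frequency: float | None) -> str:
    if frequency is None:
        return RARITY_UNKNOWN
    if not 0.0 <= frequency <= 1.0:
        raise ValueError(f"population frequency {frequency} outside [0, 1]")
    if frequency < RARE_MAX:
        return RARITY_RARE
    if frequency > COMMON_MIN:
        return RARITY_COMMON
    return RARITY_INTERMEDIATE


def _check_threshold(threshold: float) -> None:
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"score threshold {threshold} outside [0, 1]")


def attach_scores(
    variants: Iterable[AnnotatedVariant],
    scores: Mapping[tuple[int, str], float],
    frequencies: Mapping[tuple[int, str], float],
) -> list[AnnotatedVariant]:
    """Attach pathogenicity scores and population frequencies.

    A score is attached only when the variant has a non-synonymous
    protein-feature call (pathogenicity predictors score amino-acid
    substitutions only); frequency and rarity are attached regardless of
    consequence.  Variants absent from the tables keep score None and rarity
    "unknown".
    """
    out: list[AnnotatedVariant] = []
    for av in variants:
        key = av.variant.key
        score = scores.get(key) if av.is_nonsynonymous else None
        if score is not None and not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} for {av.variant} outside [0, 1]")
        freq = frequencies.get(key)
        out.append(replace(av, score=score, frequency=freq, rarity=rarity_class(freq)))
    return out


def qualifying_variants(
    profile: SampleProfile,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    homoplasmy_cutoff: float = DEFAULT_HOMOPLASMY_CUTOFF,
) -> list[AnnotatedVariant]:
    """Variants that count toward the load at the given thresholds."""
    _check_threshold(threshold)
    return [v for v in profile.variants if v.qualifies(threshold, homoplasmy_cutoff)]


def compute_variant_load(
    profile: SampleProfile,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    homoplasmy_cutoff: float = DEFAULT_HOMOPLASMY_CUTOFF,
) -> float:
    """Sum of scores over qualifying variants (strictly above ``threshold``)."""
    return float(sum(v.score for v in qualifying_variants(profile, threshold, homoplasmy_cutoff)))


def carrier_category(
    profile: SampleProfile,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    homoplasmy_cutoff: float = DEFAULT_HOMOPLASMY_CUTOFF,
) -> str:
    """Bin the number of qualifying variants into 0 / 1 / 2+."""
    n = len(qualifying_variants(profile, threshold, homoplasmy_cutoff))
    if n == 0:
        return CATEGORY_NONE
    if n == 1:
        return CATEGORY_ONE
    return CATEGORY_TWO_PLUS


def combination_class(
    profile: SampleProfile,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    homoplasmy_cutoff: float = DEFAULT_HOMOPLASMY_CUTOFF,
) -> tuple[str, bool]:
    """Classify the combination of qualifying variants by rarity.

    Returns ``(class, unknown_flag)`` where class is one of none / single /
    common-only / common+rare / rare-only and the flag marks profiles whose
    qualifying variants include unknown-rarity entries (classified using the
    known ones).  Intermediate-frequency variants are grouped with common for
    this classification.
    """
    quals = qualifying_variants(profile, threshold, homoplasmy_cutoff)
    if not quals:
        return COMBO_NONE, False
    if len(quals) == 1:
        return COMBO_SINGLE, quals[0].rarity == RARITY_UNKNOWN
    rarities = [v.rarity for v in quals]
    has_unknown = RARITY_UNKNOWN in rarities
    known = [r for r in rarities if r != RARITY_UNKNOWN]
    n_rare = sum(r == RARITY_RARE for r in known)
    # Intermediate grouped with common: anything known and not rare.
    n_commonish = len(known) - n_rare
    if n_rare and n_commonish:
        return COMBO_COMMON_RARE, has_unknown
    if n_rare:
        return COMBO_RARE_ONLY, has_unknown
    return COMBO_COMMON_ONLY, has_unknown


@dataclass(frozen=True)
class PathogenicFlag:
    """One sample variant matching a proven pathogenic mutation."""

    variant: MtVariant
    label: str
    heteroplasmic: bool


def screen_pathogenic(
    variants: Iterable[MtVariant],
    known: Sequence[tuple[int, str, str]],
    homoplasmy_cutoff: float = DEFAULT_HOMOPLASMY_CUTOFF,
) -> list[PathogenicFlag]:
    """Flag sample variants matching a proven-pathogenic list.

    Unlike the load computation, no allele-fraction filter applies: even a
    low-fraction heteroplasmic hit is reported (and marked heteroplasmic when
    below the homoplasmy cutoff).
    """
    lookup = {(int(p), a.upper()): label for p, a, label in known}
    flags: list[PathogenicFlag] = []
    for v in variants:
        label = lookup.get(v.key)
        if label is not None:
            flags.append(PathogenicFlag(v, label, heteroplasmic=v.fraction < homoplasmy_cutoff))
    return flags


def _read_keyed_table(path: str | Path, value_column: str) -> dict[tuple[int, str], float]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"position", "alt", value_column}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    table: dict[tuple[int, str], float] = {}
    for _, row in df.iterrows():
        key = (int(row["position"]), str(row["alt"]).upper())
        if key in table:
            raise ValueError(f"{path}: duplicate key {key}")
        value = float(row[value_column])
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{path}: {value_column} {value} for {key} outside [0, 1]")
        table[key] = value
    return table


def read_score_table(path: str | Path) -> dict[tuple[int, str], float]:
    """Read a pathogenicity score TSV (position, ref, alt, score)."""
    return _read_keyed_table(path, "score")


def read_frequency_table(path: str | Path) -> dict[tuple[int, str], float]:
    """Read a population frequency TSV (position, ref, alt, frequency)."""
    return _read_keyed_table(path, "frequency")


def read_pathogenic_table(path: str | Path) -> list[tuple[int, str, str]]:
    """Read a proven-pathogenic variant TSV (position, ref, alt, label)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        (int(row["position"]), str(row["alt"]).upper(), str(row["label"]))
        for _, row in df.iterrows()
    ]
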