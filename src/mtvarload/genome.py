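"""Mitochondrial genome model and SNV consequence annotation.

The human mitochondrial chromosome is a 16,569-bp circular genome carrying
13 protein-coding genes, 22 tRNAs and 2 rRNAs.  Protein genes are translated
with the vertebrate mitochondrial genetic code (NCBI translation table 2:
TGA=Trp, ATA=Met, AGA/AGG=Stop), and one gene (MT-ND6) lies on the light
strand and must be reverse-complemented before translation.  Several genes
end in an incomplete stop codon that is only completed by polyadenylation of
the transcript; the trailing one or two bases of such genes cannot be
translated from genomic sequence alone and are reported as untranslatable.

Coordinates are 1-based inclusive throughout, matching the ``m.4216T>C``
HGVS-style notation used for mtDNA variants.  Only single-nucleotide
substitutions are handled; indels and multi-nucleotide variants are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

MT_GENOME_LENGTH = 16569

HEAVY = "heavy"
LIGHT = "light"

_VALID_BASES = frozenset("ACGTN")
_SNV_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Full 64-entry vertebrate mitochondrial code, stops included as '*'.
_MT_TABLE = CodonTable.unambiguous_dna_by_id[2]
MITO_CODON_TO_AA: dict[str, str] = dict(_MT_TABLE.forward_table)
MITO_CODON_TO_AA.update({codon: "*" for codon in _MT_TABLE.stop_codons})

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non-synonymous"
STOP_GAIN = "stop-gain"
STOP_LOSS = "stop-loss"
TRNA = "tRNA"
RRNA = "rRNA"
NON_CODING = "non-coding"
UNTRANSLATABLE = "untranslatable"


class CoordinateError(ValueError):
    """Position outside the 1..genome-length range."""


class ReferenceMismatchError(ValueError):
    """Stated reference base disagrees with the genome sequence."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single mitochondrial genome sequence (uppercase A/C/G/T/N)."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(f"genome {self.name!r} contains invalid bases: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    def base_at(self, position: int) -> str:
        """Base at a 1-based coordinate."""
        if not 1 <= position <= len(self.bases):
            raise CoordinateError(
                f"position {position} outside 1..{len(self.bases)} for genome {self.name!r}"
            )
        return self.bases[position - 1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the mitochondrial genome (1-based inclusive)."""

    gene: str
    start: int
    end: int
    strand: str
    feature_class: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end <= MT_GENOME_LENGTH:
            raise ValueError(f"{self.gene}: invalid span {self.start}..{self.end}")
        if self.strand not in (HEAVY, LIGHT):
            raise ValueError(f"{self.gene}: strand must be 'heavy' or 'light'")
        if self.feature_class not in ("protein", "tRNA", "rRNA", "non-coding"):
            raise ValueError(f"{self.gene}: unknown feature class {self.feature_class!r}")
        if self.feature_class == "protein" and self.end - self.start + 1 < 3:
            raise ValueError(f"{self.gene}: protein feature shorter than one codon")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConsequenceCall:
    """Predicted consequence of one SNV in the context of one feature.

    ``codon_index`` is the 1-based codon number within the gene; amino acids
    are one-letter codes with ``*`` for stop.  Amino acids and codon index are
    defined only for translatable protein-feature calls.
    """

    gene: str | None
    codon_index: int | None
    ref_aa: str | None
    alt_aa: str | None
    consequence: str

    @property
    def is_protein_change(self) -> bool:
        return self.consequence in (NON_SYNONYMOUS, STOP_GAIN, STOP_LOSS)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def locate_features(position: int, gene_map: Sequence[GeneFeature]) -> list[GeneFeature]:
    """All features whose span contains ``position`` (1-based).

    mtDNA genes overlap (e.g. MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4), so more than
    one feature may be returned.  Control-region positions return an empty
    list.
    """
    if not 1 <= position <= MT_GENOME_LENGTH:
        raise CoordinateError(f"position {position} outside 1..{MT_GENOME_LENGTH}")
    return [f for f in gene_map if f.contains(position)]


def _codon_call(
    position: int, alt: str, genome: GenomeSequence, feature: GeneFeature
) -> ConsequenceCall:
    """Consequence of a substitution within one protein feature."""
    if feature.strand == HEAVY:
        offset = position - feature.start
        strand_alt = alt
    else:
        # Gene read 3'->5' on the reference: translate the reverse complement.
        offset = feature.end - position
        strand_alt = _COMPLEMENT[alt]
    codon_index = offset // 3
    codon_start = codon_index * 3
    if codon_start + 3 > len(feature):
        # Incomplete 3' stop codon completed by polyadenylation in vivo.
        return ConsequenceCall(feature.gene, None, None, None, UNTRANSLATABLE)
    if feature.strand == HEAVY:
        g0 = feature.start - 1 + codon_start
        codon = genome.bases[g0 : g0 + 3]
    else:
        g0 = feature.end - codon_start  # 1-based coordinate of codon base 1
        codon = reverse_complement(genome.bases[g0 - 3 : g0])
    within = offset - codon_start
    alt_codon = codon[:within] + strand_alt + codon[within + 1 :]
    if "N" in codon or "N" in alt_codon:
        return ConsequenceCall(feature.gene, codon_index + 1, None, None, UNTRANSLATABLE)
    ref_aa = MITO_CODON_TO_AA[codon]
    alt_aa = MITO_CODON_TO_AA[alt_codon]
    if ref_aa == alt_aa:
        cons = SYNONYMOUS
    elif alt_aa == "*":
        cons = STOP_GAIN
    elif ref_aa == "*":
        cons = STOP_LOSS
    else:
        cons = NON_SYNONYMOUS
    return ConsequenceCall(feature.gene, codon_index + 1, ref_aa, alt_aa, cons)


def classify_snv(
    position: int,
    ref: str,
    alt: str,
    genome: GenomeSequence,
    gene_map: Sequence[GeneFeature],
) -> list[ConsequenceCall]:
    """Classify one single-nucleotide substitution against every overlapping feature.

    Returns one :class:`ConsequenceCall` per overlapping feature; a variant in
    no feature yields a single non-coding call.

    Raises
    ------
    CoordinateError
        if ``position`` is outside the genome.
    ReferenceMismatchError
        if ``ref`` disagrees with the genome base at ``position``.
    ValueError
        for indels / multi-nucleotide alleles or non-ACGT bases.
    """
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(
            f"only single-nucleotide substitutions are supported, got {ref!r}>{alt!r}"
        )
    if ref not in _SNV_BASES or alt not in _SNV_BASES:
        raise ValueError(f"ref/alt must be A, C, G or T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical at position {position}")
    genome_base = genome.base_at(position)
    if genome_base != ref:
        raise ReferenceMismatchError(
            f"position {position}: stated ref {ref!r} does not match genome base {genome_base!r}"
        )
    features = locate_features(position, gene_map)
    if not features:
        return [ConsequenceCall(None, None, None, None, NON_CODING)]
    calls: list[ConsequenceCall] = []
    for feature in features:
        if feature.feature_class == "protein":
            calls.append(_codon_call(position, alt, genome, feature))
        elif feature.feature_class == "tRNA":
            calls.append(ConsequenceCall(feature.gene, None, None, None, TRNA))
        elif feature.feature_class == "rRNA":
            calls.append(ConsequenceCall(feature.gene, None, None, None, RRNA))
        else:
            calls.append(ConsequenceCall(feature.gene, None, None, None, NON_CODING))
    return calls


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a single-record FASTA (any line wrapping) into a GenomeSequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return GenomeSequence(name=rec.id, bases=str(rec.seq))


def read_gene_map(path: str | Path) -> list[GeneFeature]:
    """Read a gene map TSV with columns gene, start, end, strand, class."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "start", "end", "strand", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene map missing columns {sorted(missing)}")
    return [
        GeneFeature(
            gene=str(row["gene"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
            feature_class=str(row["class"]),
        )
        for _, row in df.iterrows()
    ]


def write_bed(gene_map: Iterable[GeneFeature], path: str | Path) -> None:
    """Export features as BED (0-based half-open coordinates, export only)."""
    with open(path, "w") as fh:
        for f in gene_map:
            strand = "+" if f.strand == HEAVY else "-"
            fh.write(f"MT\t{f.start - 1}\t{f.end}\t{f.gene}\t0\t{strand}\n")
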