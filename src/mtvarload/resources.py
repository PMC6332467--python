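"""Accessors for the packaged fixture data.

The packaged reference genome is a synthetic stand-in: it has the true
16,569-bp length, the real gene architecture (coordinates, strands,
overlaps, incomplete 3' stop codons) and real reference bases planted at
every fixture variant site, but the remaining sequence is pseudo-random.
It supports every computation in this package (consequence annotation,
haplogroup matching, load computation) without redistributing the actual
reference sequence; it is not the real rCRS sequence.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as importlib_resources
from pathlib import Path

import pandas as pd

from .genome import GeneFeature, GenomeSequence, read_fasta, read_gene_map
from .haplogroups import read_marker_table
from .scoring import (
    read_frequency_table,
    read_pathogenic_table,
    read_score_table,
)


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(importlib_resources.files("mtvarload") / "data" / name))


@lru_cache(maxsize=None)
def load_reference() -> GenomeSequence:
    """The packaged synthetic mitochondrial reference genome."""
    return read_fasta(data_path("mt_reference_synthetic.fasta"))


@lru_cache(maxsize=None)
def load_gene_map() -> tuple[GeneFeature, ...]:
    """The 37-gene mitochondrial gene map (13 protein, 22 tRNA, 2 rRNA)."""
    return tuple(read_gene_map(data_path("gene_map.tsv")))


@lru_cache(maxsize=None)
def load_score_table() -> dict[tuple[int, str], float]:
    """Pathogenicity scores for the thirteen fixture variants."""
    return read_score_table(data_path("pathogenicity_scores.tsv"))


@lru_cache(maxsize=None)
def load_frequency_table() -> dict[tuple[int, str], float]:
    """Population frequencies for the fixture variants."""
    return read_frequency_table(data_path("pathogenicity_scores.tsv").with_name(
        "population_frequencies.tsv"
    ))


@lru_cache(maxsize=None)
def load_marker_table() -> dict[str, frozenset[tuple[int, str]]]:
    """Simplified top-level haplogroup marker sets (15 labels)."""
    return read_marker_table(data_path("haplogroup_markers.tsv"))


@lru_cache(maxsize=None)
def load_associated_variants():
    """Per-haplogroup associated high-scoring common variants."""
    from .synthetic import ScoredVariant  # local import avoids a cycle

    df = pd.read_csv(data_path("haplogroup_associated_variants.tsv"), sep="\t", comment="#")
    out: dict[str, list[ScoredVariant]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["haplogroup"]), []).append(
            ScoredVariant(
                position=int(row["position"]),
                ref=str(row["ref"]).upper(),
                alt=str(row["alt"]).upper(),
                score=float(row["score"]),
                frequency=float(row["frequency"]),
            )
        )
    return out


@lru_cache(maxsize=None)
def load_pathogenic_list() -> tuple[tuple[int, str, str], ...]:
    """Proven pathogenic mtDNA mutations screened in every sample."""
    return tuple(read_pathogenic_table(data_path("pathogenic_variants.tsv")))


@lru_cache(maxsize=None)
def load_published_haplogroup_counts() -> pd.DataFrame:
    """Observed haplogroup counts per study cohort (rows: haplogroups)."""
    return pd.read_csv(
        data_path("cohort_haplogroup_counts.tsv"), sep="\t", comment="#", index_col=0
    )
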