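"""Shared fixtures: packaged resources, toy genomes, and a literal
codon-table oracle independent of the implementation."""

from __future__ import annotations

import numpy as np
import pytest

from mtvarload import resources
from mtvarload.genome import GeneFeature, GenomeSequence

# Independent 64-entry vertebrate mitochondrial code, written out literally
# (codon order: base1, base2, base3 each cycling T, C, A, G).
_MITO_AAS = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"
_ORDER = "TCAG"
LITERAL_MITO_CODE = {
    b1 + b2 + b3: _MITO_AAS[16 * i + 4 * j + k]
    for i, b1 in enumerate(_ORDER)
    for j, b2 in enumerate(_ORDER)
    for k, b3 in enumerate(_ORDER)
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def oracle_classify(position, alt, genome: GenomeSequence, gene_map):
    """Brute-force consequence oracle: mutate, rebuild each gene's coding
    sequence, translate both with the literal code table, compare proteins."""
    calls = []
    for f in gene_map:
        if not (f.start <= position <= f.end):
            continue
        if f.feature_class != "protein":
            calls.append((f.gene, f.feature_class if f.feature_class != "non-coding" else "non-coding"))
            continue
        mutated = genome.bases[: position - 1] + alt + genome.bases[position:]
        if f.strand == "heavy":
            cds_ref = genome.bases[f.start - 1 : f.end]
            cds_alt = mutated[f.start - 1 : f.end]
            cds_pos = position - f.start
        else:
            cds_ref = revcomp(genome.bases[f.start - 1 : f.end])
            cds_alt = revcomp(mutated[f.start - 1 : f.end])
            cds_pos = f.end - position
        n_codons = len(cds_ref) // 3
        if cds_pos >= 3 * n_codons:
            calls.append((f.gene, "untranslatable"))
            continue
        prot_ref = [LITERAL_MITO_CODE[cds_ref[3 * i : 3 * i + 3]] for i in range(n_codons)]
        prot_alt = [LITERAL_MITO_CODE[cds_alt[3 * i : 3 * i + 3]] for i in range(n_codons)]
        i = cds_pos // 3
        ra, aa = prot_ref[i], prot_alt[i]
        if ra == aa:
            calls.append((f.gene, "synonymous"))
        elif aa == "*":
            calls.append((f.gene, "stop-gain"))
        elif ra == "*":
            calls.append((f.gene, "stop-loss"))
        else:
            calls.append((f.gene, "non-synonymous"))
    if not calls:
        calls.append((None, "non-coding"))
    return calls


def dunnett_fwer_oracle(d: float, k: int, df: int) -> float:
    """Quadrature oracle for the balanced-design family-wise error
    P(max_j |T_j| >= d) of k treatments vs one shared control: integrate the
    conditional independence representation over the control normal (z in
    [-8, 8]) and the pooled chi-distributed scale (s in (0, 3]) on
    Gauss-Legendre grids."""
    import scipy.stats as sps

    zn, zw = np.polynomial.legendre.leggauss(240)
    z, wz = zn * 8.0, zw * 8.0
    sn, sw = np.polynomial.legendre.leggauss(240)
    s, ws = 0.5 * (sn * 3.0 + 3.0), sw * 1.5
    a = sps.norm.cdf(z[None, :] + np.sqrt(2) * d * s[:, None])
    b = sps.norm.cdf(z[None, :] - np.sqrt(2) * d * s[:, None])
    inner = ((a - b) ** k * sps.norm.pdf(z)[None, :]) @ wz
    val = float(np.sum(inner * sps.chi.pdf(s * np.sqrt(df), df) * np.sqrt(df) * ws))
    return 1 - val


def dunnett_critical_value(k: int, df: int, alpha: float = 0.05) -> float:
    """Two-sided balanced Dunnett critical value from the quadrature oracle."""
    from scipy import optimize

    return optimize.brentq(lambda d: dunnett_fwer_oracle(d, k, df) - alpha, 1.5, 4.0, xtol=1e-6)


@pytest.fixture(scope="session")
def reference():
    return resources.load_reference()


@pytest.fixture(scope="session")
def gene_map():
    return list(resources.load_gene_map())


@pytest.fixture(scope="session")
def marker_table():
    return resources.load_marker_table()


@pytest.fixture(scope="session")
def score_table():
    return resources.load_score_table()


@pytest.fixture(scope="session")
def frequency_table():
    return resources.load_frequency_table()


@pytest.fixture(scope="session")
def toy_genome():
    """60-bp toy genome: one heavy-strand and one light-strand gene.

    Heavy gene at 4..15 (4 codons), light gene at 31..44 (14 bases, so one
    trailing incomplete-codon base in gene orientation).
    """
    rng = np.random.default_rng(7)
    bases = "".join(rng.choice(list("ACGT"), size=60))
    genome = GenomeSequence("toy", bases)
    gm = [
        GeneFeature("toyH", 4, 15, "heavy", "protein"),
        GeneFeature("toyL", 31, 44, "light", "protein"),
        GeneFeature("toyT", 20, 28, "heavy", "tRNA"),
    ]
    return genome, gm
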