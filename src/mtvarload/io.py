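"""Readers and writers for per-sample variant lists.

Two input dialects are supported:

* a TSV with columns ``sample, position, ref, alt`` and an optional
  ``fraction`` column (allele fraction; 1.0 when absent), and
* a minimal single-sample VCF, where CHROM is ignored and POS/REF/ALT plus
  an optional ``AF`` INFO field are used.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .scoring import MtVariant


class VariantInputError(ValueError):
    """Malformed variant input; carries file and line context."""


def read_variants_tsv(path: str | Path) -> dict[str, list[MtVariant]]:
    """Read per-sample variants from a TSV; returns sample -> variant list."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "position", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise VariantInputError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[MtVariant]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            fraction = float(getattr(row, "fraction", 1.0) or 1.0)
            variant = MtVariant(
                position=int(row.position), ref=row.ref, alt=row.alt, fraction=fraction
            )
        except (TypeError, ValueError) as exc:
            raise VariantInputError(f"{path}: line {i}: {exc}") from exc
        out.setdefault(str(row.sample), []).append(variant)
    return out


def write_variants_tsv(
    variants: Mapping[str, Iterable[MtVariant]], path: str | Path
) -> None:
    """Write per-sample variants in the TSV dialect read_variants_tsv reads."""
    rows = [
        {
            "sample": sample,
            "position": v.position,
            "ref": v.ref,
            "alt": v.alt,
            "fraction": v.fraction,
        }
        for sample, vs in variants.items()
        for v in vs
    ]
    pd.DataFrame(rows, columns=["sample", "position", "ref", "alt", "fraction"]).to_csv(
        path, sep="\t", index=False
    )


def read_variants_vcf(path: str | Path, sample_id: str | None = None) -> dict[str, list[MtVariant]]:
    """Read a minimal single-sample VCF (POS/REF/ALT, optional AF INFO).

    Multi-allelic records are split; non-SNV alleles raise an error.  The
    sample id defaults to the VCF sample name, else the file stem.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else Path(path).stem
    variants: list[MtVariant] = []
    for rec in vcf:
        af = rec.INFO.get("AF")
        for j, alt in enumerate(rec.ALT):
            if len(rec.REF) != 1 or len(alt) != 1:
                raise VariantInputError(
                    f"{path}: position {rec.POS}: only single-nucleotide variants supported"
                )
            if af is None:
                fraction = 1.0
            elif isinstance(af, tuple):
                fraction = float(af[j])
            else:
                fraction = float(af)
            variants.append(MtVariant(rec.POS, rec.REF, alt, fraction))
    return {sample_id: variants}


def read_cohort_assignments(path: str | Path) -> dict[str, str]:
    """Read a sample -> cohort TSV with columns sample, cohort."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"sample", "cohort"} - set(df.columns)
    if missing:
        raise VariantInputError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["sample"], df["cohort"]))
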