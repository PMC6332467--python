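"""End-to-end case-control analysis: annotate, haplogroup, score, associate.

``annotate_samples`` turns raw per-sample variant lists into
:class:`~mtvarload.scoring.SampleProfile` objects (consequence calls,
scores, frequencies, haplogroup call).  ``analyze_cohorts`` runs the full
statistical battery on a set of profiles:

* haplogroup distribution tables per disease-vs-control pair with the
  Fisher-Freeman-Halton exact test and adjusted-standardized-residual
  post-hoc (Bonferroni-adjusted over the haplogroup cells);
* unique-variant rare/common 2x2 tables with Fisher's exact test;
* carrier 2x2 tables at the 0.5 and 0.7 score thresholds and 0/1/2+
  carrier-category tables with exact tests;
* per-cohort variant-load summaries with one-way ANOVA and Dunnett's
  two-tailed many-to-one post-hoc against the control cohort;
* combination-class frequencies and the proven-pathogenic screen.

``run_analysis`` wraps this behind a file-based :class:`RunConfig` so a
whole run is reproducible from one config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io, resources
from .genome import GeneFeature, GenomeSequence, classify_snv, read_fasta, read_gene_map
from .haplogroups import assign_haplogroup, read_marker_table
from .scoring import (
    CATEGORY_NONE,
    CATEGORY_ONE,
    CATEGORY_TWO_PLUS,
    DEFAULT_HOMOPLASMY_CUTOFF,
    DEFAULT_SCORE_THRESHOLD,
    HIGH_SCORE_THRESHOLD,
    RARITY_COMMON,
    RARITY_RARE,
    AnnotatedVariant,
    MtVariant,
    SampleProfile,
    attach_scores,
    carrier_category,
    combination_class,
    compute_variant_load,
    read_frequency_table,
    read_score_table,
    screen_pathogenic,
)
from .stats import (
    ContingencyTable,
    adjusted_residuals,
    anova_oneway_raw,
    bonferroni_adjust,
    dunnett_two_tailed,
    fisher_exact_2x2,
    freeman_halton_exact,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisSettings:
    """Thresholds and statistical settings for one analysis run."""

    score_threshold: float = DEFAULT_SCORE_THRESHOLD
    high_score_threshold: float = HIGH_SCORE_THRESHOLD
    homoplasmy_cutoff: float = DEFAULT_HOMOPLASMY_CUTOFF
    control_label: str = "control"
    mc_replicates: int = 100_000
    max_enumeration: int = 200_000
    seed: int = 0
    bonferroni_m: int | None = None  # None -> number of haplogroup rows


@dataclass(frozen=True)
class RunConfig:
    """File-based configuration of a full pipeline run."""

    variants: str
    cohorts: str
    genome: str | None = None
    gene_map: str | None = None
    scores: str | None = None
    frequencies: str | None = None
    markers: str | None = None
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)


def annotate_samples(
    variant_map: Mapping[str, Sequence[MtVariant]],
    cohort_map: Mapping[str, str],
    genome: GenomeSequence | None = None,
    gene_map: Sequence[GeneFeature] | None = None,
    scores: Mapping[tuple[int, str], float] | None = None,
    frequencies: Mapping[tuple[int, str], float] | None = None,
    markers: Mapping[str, frozenset[tuple[int, str]]] | None = None,
) -> list[SampleProfile]:
    """Annotate raw variant lists into SampleProfiles (packaged defaults).

    Consequence calls are memoized per (position, ref, alt) since cohort
    samples share haplogroup variants.  Counts of variants passing each
    stage are logged.
    """
    genome = genome if genome is not None else resources.load_reference()
    gene_map = list(gene_map) if gene_map is not None else list(resources.load_gene_map())
    scores = scores if scores is not None else resources.load_score_table()
    frequencies = (
        frequencies if frequencies is not None else resources.load_frequency_table()
    )
    markers = markers if markers is not None else resources.load_marker_table()
    call_cache: dict[tuple[int, str, str], tuple] = {}
    profiles: list[SampleProfile] = []
    n_in = n_nonsyn = n_homoplasmic = n_scored = 0
    for sample_id, variants in variant_map.items():
        if sample_id not in cohort_map:
            raise ValueError(f"sample {sample_id!r} has no cohort assignment")
        annotated: list[AnnotatedVariant] = []
        for v in variants:
            key = (v.position, v.ref, v.alt)
            calls = call_cache.get(key)
            if calls is None:
                calls = tuple(classify_snv(v.position, v.ref, v.alt, genome, gene_map))
                call_cache[key] = calls
            annotated.append(AnnotatedVariant(v, calls))
        annotated = attach_scores(annotated, scores, frequencies)
        n_in += len(annotated)
        n_nonsyn += sum(a.is_nonsynonymous for a in annotated)
        n_homoplasmic += sum(
            a.variant.fraction >= DEFAULT_HOMOPLASMY_CUTOFF for a in annotated
        )
        n_scored += sum(a.score is not None for a in annotated)
        hap = assign_haplogroup([v.key for v in variants], markers)
        profiles.append(
            SampleProfile(
                sample_id=sample_id,
                cohort=cohort_map[sample_id],
                variants=annotated,
                haplogroup=hap,
            )
        )
    logger.info(
        "annotated %d samples: %d variants in, %d non-synonymous, "
        "%d homoplasmic, %d scored",
        len(profiles), n_in, n_nonsyn, n_homoplasmic, n_scored,
    )
    return profiles


def _group_profiles(profiles: Sequence[SampleProfile]) -> dict[str, list[SampleProfile]]:
    grouped: dict[str, list[SampleProfile]] = {}
    for p in profiles:
        grouped.setdefault(p.cohort, []).append(p)
    return grouped


def haplogroup_count_table(
    profiles: Sequence[SampleProfile], cohort_order: Sequence[str]
) -> pd.DataFrame:
    """Haplogroup-by-cohort count table from called profiles."""
    grouped = _group_profiles(profiles)
    labels = sorted({p.haplogroup.haplogroup for p in profiles if p.haplogroup})
    data = {
        cohort: [
            sum(p.haplogroup.haplogroup == lab for p in grouped.get(cohort, []))
            for lab in labels
        ]
        for cohort in cohort_order
    }
    return pd.DataFrame(data, index=labels)


def build_unique_variant_tables(
    profiles: Sequence[SampleProfile],
    control_label: str = "control",
    homoplasmy_cutoff: float = DEFAULT_HOMOPLASMY_CUTOFF,
) -> dict[str, pd.DataFrame]:
    """Per-pair 2x2 rare/common count tables over cohort-unique variants.

    A variant (position, alt) is "unique" when, among homoplasmic
    non-synonymous variants, it occurs in exactly one of the studied cohorts
    (assessed against all cohorts, not just the compared pair).  For each
    disease-control pair the unique variants of the two cohorts are
    cross-tabulated rare (< 0.1%) versus common (> 1%); intermediate and
    unknown-frequency variants are dropped.
    """
    grouped = _group_profiles(profiles)
    if control_label not in grouped:
        raise ValueError(f"control cohort {control_label!r} absent from profiles")
    # Which cohorts contain each qualifying variant key, and its rarity.
    presence: dict[tuple[int, str], set[str]] = {}
    rarity: dict[tuple[int, str], str] = {}
    for cohort, members in grouped.items():
        for p in members:
            for av in p.variants:
                if not av.is_nonsynonymous:
                    continue
                if av.variant.fraction < homoplasmy_cutoff:
                    continue
                presence.setdefault(av.variant.key, set()).add(cohort)
                rarity[av.variant.key] = av.rarity
    unique_by_cohort: dict[str, dict[str, int]] = {
        cohort: {RARITY_RARE: 0, RARITY_COMMON: 0} for cohort in grouped
    }
    for key, cohorts in presence.items():
        if len(cohorts) != 1:
            continue
        r = rarity[key]
        if r in (RARITY_RARE, RARITY_COMMON):
            unique_by_cohort[next(iter(cohorts))][r] += 1
    tables: dict[str, pd.DataFrame] = {}
    for cohort in grouped:
        if cohort == control_label:
            continue
        tables[cohort] = pd.DataFrame(
            {
                cohort: [
                    unique_by_cohort[cohort][RARITY_RARE],
                    unique_by_cohort[cohort][RARITY_COMMON],
                ],
                control_label: [
                    unique_by_cohort[control_label][RARITY_RARE],
                    unique_by_cohort[control_label][RARITY_COMMON],
                ],
            },
            index=["rare", "common"],
        )
    return tables


def _carrier_table(
    disease: Sequence[SampleProfile],
    control: Sequence[SampleProfile],
    threshold: float,
    cutoff: float,
    labels: tuple[str, str],
) -> ContingencyTable:
    def split(members: Sequence[SampleProfile]) -> tuple[int, int]:
        carriers = sum(
            carrier_category(p, threshold, cutoff) != CATEGORY_NONE for p in members
        )
        return carriers, len(members) - carriers

    d_car, d_non = split(disease)
    c_car, c_non = split(control)
    return ContingencyTable.from_rows(
        [[d_car, c_car], [d_non, c_non]],
        row_labels=(f">{threshold}", f"<={threshold}"),
        col_labels=labels,
    )


def _category_table(
    disease: Sequence[SampleProfile],
    control: Sequence[SampleProfile],
    threshold: float,
    cutoff: float,
    labels: tuple[str, str],
) -> ContingencyTable:
    cats = (CATEGORY_NONE, CATEGORY_ONE, CATEGORY_TWO_PLUS)

    def hist(members: Sequence[SampleProfile]) -> list[int]:
        counts = {c: 0 for c in cats}
        for p in members:
            counts[carrier_category(p, threshold, cutoff)] += 1
        return [counts[c] for c in cats]

    d, c = hist(disease), hist(control)
    return ContingencyTable.from_rows(
        [[d[i], c[i]] for i in range(3)], row_labels=cats, col_labels=labels
    )


def analyze_cohorts(
    profiles: Sequence[SampleProfile],
    settings: AnalysisSettings = AnalysisSettings(),
) -> dict:
    """Run the full statistical battery; returns a JSON-serializable report."""
    grouped = _group_profiles(profiles)
    control = settings.control_label
    if control not in grouped:
        raise ValueError(f"control cohort {control!r} absent")
    for cohort, members in grouped.items():
        if not members:
            raise ValueError(f"cohort {cohort!r} is empty")
    diseases = [c for c in sorted(grouped) if c != control]
    thr, hi_thr, cut = (
        settings.score_threshold,
        settings.high_score_threshold,
        settings.homoplasmy_cutoff,
    )
    report: dict = {
        "settings": asdict(settings),
        "cohort_sizes": {c: len(m) for c, m in grouped.items()},
    }

    # Haplogroup distribution and post-hoc residuals.
    hap_counts = haplogroup_count_table(profiles, [*diseases, control])
    report["haplogroup_counts"] = hap_counts.to_dict()
    hap_section = {}
    for i, disease in enumerate(diseases):
        pair = hap_counts[[disease, control]]
        pair = pair.loc[pair.sum(axis=1) > 0]
        table = ContingencyTable(
            pair.to_numpy(), tuple(pair.index), (disease, control)
        )
        exact = freeman_halton_exact(
            table,
            max_enumeration=settings.max_enumeration,
            mc_replicates=settings.mc_replicates,
            seed=settings.seed + i,
        )
        resid = adjusted_residuals(table)
        m = settings.bonferroni_m or len(pair.index)
        cell_p = resid.p_values[disease]
        hap_section[disease] = {
            "table": pair.to_dict(),
            "exact_p": exact.p_value,
            "exact_method": exact.method,
            "exact_std_error": exact.std_error,
            "residuals": resid.residuals[disease].round(6).to_dict(),
            "cell_p": cell_p.round(8).to_dict(),
            "cell_p_bonferroni": dict(
                zip(cell_p.index, bonferroni_adjust(cell_p.fillna(1.0), max(m, len(cell_p))))
            ),
            "phi": resid.phi[disease].round(6).to_dict(),
        }
    report["haplogroup_association"] = hap_section

    # Unique-variant rare/common tables (a pair without any rare/common
    # unique variants gets no test).
    unique_tables = build_unique_variant_tables(profiles, control, cut)
    report["unique_variants"] = {}
    for disease, frame in unique_tables.items():
        if int(frame.to_numpy().sum()) > 0:
            p = fisher_exact_2x2(
                ContingencyTable(
                    frame.to_numpy(), tuple(frame.index), tuple(frame.columns)
                )
            ).p_value
        else:
            p = None
        report["unique_variants"][disease] = {"table": frame.to_dict(), "fisher_p": p}

    # Carrier prevalence at both thresholds, and 0/1/2+ categories.
    carriers = {}
    for disease in diseases:
        d, c = grouped[disease], grouped[control]
        entry = {}
        for name, t in (("0.5", thr), ("0.7", hi_thr)):
            tab = _carrier_table(d, c, t, cut, (disease, control))
            entry[f"carrier_{name}"] = {
                "table": tab.to_frame().to_dict(),
                "fisher_p": fisher_exact_2x2(tab).p_value,
            }
        cat_tab = _category_table(d, c, thr, cut, (disease, control))
        cat_exact = freeman_halton_exact(
            cat_tab,
            max_enumeration=settings.max_enumeration,
            mc_replicates=settings.mc_replicates,
            seed=settings.seed,
        )
        entry["categories"] = {
            "table": cat_tab.to_frame().to_dict(),
            "exact_p": cat_exact.p_value,
            "exact_method": cat_exact.method,
        }
        carriers[disease] = entry
    report["carriers"] = carriers

    # Variant loads: summaries, ANOVA, Dunnett vs control.
    order = [control, *diseases]
    loads = {
        cohort: [compute_variant_load(p, thr, cut) for p in grouped[cohort]]
        for cohort in order
    }
    report["loads"] = {
        cohort: {
            "n": len(vals),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)),
        }
        for cohort, vals in loads.items()
    }
    anova = anova_oneway_raw([loads[c] for c in order])
    report["anova"] = {
        "f": anova.f_statistic,
        "df": [anova.df_between, anova.df_within],
        "p": anova.p_value,
    }
    dunnett = dunnett_two_tailed(
        [loads[c] for c in order],
        control_index=0,
        mc_replicates=max(settings.mc_replicates, 100_000),
        seed=settings.seed,
        labels=order,
    )
    report["dunnett"] = {
        "comparisons": list(dunnett.comparisons),
        "t": list(dunnett.t_statistics),
        "p_adjusted": list(dunnett.p_adjusted),
        "std_errors": list(dunnett.std_errors),
        "replicates": dunnett.replicates,
        "seed": dunnett.seed,
    }

    # Combination classes per cohort.
    combos = {}
    for cohort in order:
        counts: dict[str, int] = {}
        for p in grouped[cohort]:
            cls, _ = combination_class(p, thr, cut)
            counts[cls] = counts.get(cls, 0) + 1
        combos[cohort] = counts
    report["combination_classes"] = combos

    # Proven-pathogenic screen (no homoplasmy filter).
    known = resources.load_pathogenic_list()
    flags = []
    for p in profiles:
        for flag in screen_pathogenic([av.variant for av in p.variants], known, cut):
            flags.append(
                {
                    "sample": p.sample_id,
                    "cohort": p.cohort,
                    "variant": str(flag.variant),
                    "label": flag.label,
                    "fraction": flag.variant.fraction,
                    "heteroplasmic": flag.heteroplasmic,
                }
            )
    report["pathogenic_screen"] = flags
    return report


def run_analysis(config: RunConfig) -> dict:
    """Read inputs per ``config``, annotate, and run the full battery."""
    variant_map = io.read_variants_tsv(config.variants)
    cohort_map = io.read_cohort_assignments(config.cohorts)
    genome = read_fasta(config.genome) if config.genome else None
    gene_map = read_gene_map(config.gene_map) if config.gene_map else None
    scores = read_score_table(config.scores) if config.scores else None
    freqs = read_frequency_table(config.frequencies) if config.frequencies else None
    markers = read_marker_table(config.markers) if config.markers else None
    profiles = annotate_samples(
        variant_map, cohort_map, genome, gene_map, scores, freqs, markers
    )
    return analyze_cohorts(profiles, config.settings)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
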