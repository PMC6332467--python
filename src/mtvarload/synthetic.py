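"""Synthetic case-control mtDNA cohort generator.

Generates cohorts with the structure the association analysis assumes:

* each sample draws a top-level haplogroup from a configurable frequency
  vector (default: the control-cohort proportions observed in the study
  population this package models — four cohorts of 100/100/100/115
  individuals spanning 15 haplogroup labels);
* the sample deterministically inherits its haplogroup's defining marker
  variants and that haplogroup's associated high-scoring common variants
  (the packaged fixture carries thirteen such variants with pathogenicity
  scores above 0.5 and population frequencies above 1%);
* a Poisson number (default lambda = 0.5) of rare private non-synonymous
  variants is added at unused protein-coding positions, with pathogenicity
  scores drawn from a Beta(2, 2) distribution rescaled to [0.3, 0.9] and
  population frequencies below 0.1%;
* an optional case effect adds, with probability pi per sample, one extra
  qualifying (score > 0.5) non-synonymous variant to selected cohorts.

Every draw derives from one global seed through per-sample substreams keyed
by (cohort index, sample index), so cohorts are reproducible and independent
of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import resources
from .genome import NON_SYNONYMOUS, GeneFeature, GenomeSequence, classify_snv
from .scoring import MtVariant

DEFAULT_COHORT_SIZES: dict[str, int] = {
    "t2dm": 100,
    "obesity": 100,
    "atherosclerosis": 100,
    "control": 115,
}

# Control-cohort haplogroup proportions (counts out of 115).
DEFAULT_HAPLOGROUP_COUNTS: dict[str, int] = {
    "C": 1, "D": 2, "G": 0, "H": 43, "HV": 2, "I": 1, "J": 7, "K": 6,
    "N": 0, "R": 2, "T": 8, "U": 30, "V": 8, "W": 3, "X": 2,
}

CONTROL_LABEL = "control"


@dataclass(frozen=True)
class ScoredVariant:
    """A (position, ref, alt) with its pathogenicity score and frequency."""

    position: int
    ref: str
    alt: str
    score: float
    frequency: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for cohort generation."""

    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES)
    )
    haplogroup_freqs: Mapping[str, float] | None = None  # None -> control defaults
    rare_lambda: float = 0.5
    rare_score_beta: tuple[float, float] = (2.0, 2.0)
    rare_score_range: tuple[float, float] = (0.3, 0.9)
    # Per-cohort probability of gaining one extra qualifying variant.
    effect_pi: Mapping[str, float] = field(default_factory=dict)
    # Constant score for injected effect variants; None draws from the rare
    # score distribution conditioned on score > 0.5.
    effect_score: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rare_lambda < 0:
            raise ValueError("rare_lambda must be >= 0")
        for cohort, pi in self.effect_pi.items():
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"effect pi for {cohort!r} outside [0, 1]")
        if self.haplogroup_freqs is not None:
            total = sum(self.haplogroup_freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"haplogroup frequencies sum to {total}, not 1")


@dataclass
class SyntheticSample:
    sample_id: str
    cohort: str
    true_haplogroup: str
    variants: list[MtVariant]
    true_load: float  # sum of scores > 0.5 among homoplasmic variants


@dataclass
class SyntheticCohorts:
    """Generated samples plus the score/frequency tables covering them."""

    samples: list[SyntheticSample]
    score_table: dict[tuple[int, str], float]
    frequency_table: dict[tuple[int, str], float]
    config: SyntheticConfig

    def by_cohort(self) -> dict[str, list[SyntheticSample]]:
        out: dict[str, list[SyntheticSample]] = {}
        for s in self.samples:
            out.setdefault(s.cohort, []).append(s)
        return out


def default_haplogroup_freqs() -> dict[str, float]:
    total = sum(DEFAULT_HAPLOGROUP_COUNTS.values())
    return {k: v / total for k, v in DEFAULT_HAPLOGROUP_COUNTS.items()}


def nonsynonymous_candidates(
    genome: GenomeSequence,
    gene_map: Sequence[GeneFeature],
    exclude_positions: frozenset[int],
) -> list[tuple[int, str, str]]:
    """All (position, ref, alt) giving a plain amino-acid substitution.

    Scans every protein-coding position outside ``exclude_positions`` and
    keeps substitutions whose consequence is non-synonymous (stop gains and
    losses are skipped: pathogenicity scores model missense changes).
    """
    candidates: list[tuple[int, str, str]] = []
    seen: set[int] = set()
    for feature in gene_map:
        if feature.feature_class != "protein":
            continue
        for pos in range(feature.start, feature.end + 1):
            if pos in seen or pos in exclude_positions:
                continue
            seen.add(pos)
            ref = genome.base_at(pos)
            if ref not in "ACGT":
                continue
            for alt in "ACGT":
                if alt == ref:
                    continue
                calls = classify_snv(pos, ref, alt, genome, gene_map)
                if any(c.consequence == NON_SYNONYMOUS for c in calls):
                    candidates.append((pos, ref, alt))
    return candidates


class CohortSimulator:
    """Reusable simulator bound to a reference genome and fixture tables.

    Holding the simulator across many :meth:`generate` calls amortizes the
    one-off scan for candidate rare-variant sites.
    """

    def __init__(
        self,
        genome: GenomeSequence | None = None,
        gene_map: Sequence[GeneFeature] | None = None,
        markers: Mapping[str, frozenset[tuple[int, str]]] | None = None,
        associated: Mapping[str, Sequence[ScoredVariant]] | None = None,
    ) -> None:
        self.genome = genome if genome is not None else resources.load_reference()
        self.gene_map = list(gene_map) if gene_map is not None else resources.load_gene_map()
        self.markers = dict(markers) if markers is not None else resources.load_marker_table()
        self.associated = (
            {k: list(v) for k, v in associated.items()}
            if associated is not None
            else resources.load_associated_variants()
        )
        fixture_positions = {p for vs in self.markers.values() for p, _ in vs}
        for variants in self.associated.values():
            fixture_positions.update(v.position for v in variants)
        self._fixture_scores = {
            (v.position, v.alt): v.score for vs in self.associated.values() for v in vs
        }
        self._rare_sites = nonsynonymous_candidates(
            self.genome, self.gene_map, frozenset(fixture_positions)
        )
        if not self._rare_sites:
            raise ValueError("no candidate protein-coding sites left for rare variants")

    # -- single-sample machinery -------------------------------------------

    def _marker_variants(self, haplogroup: str) -> list[MtVariant]:
        out = []
        for pos, alt in sorted(self.markers.get(haplogroup, frozenset())):
            ref = self.genome.base_at(pos)
            if ref == alt:  # marker matches the reference base: nothing to add
                continue
            out.append(MtVariant(pos, ref, alt, 1.0))
        return out

    def _rare_score(self, rng: np.random.Generator) -> float:
        a, b = self.config.rare_score_beta
        lo, hi = self.config.rare_score_range
        return float(lo + (hi - lo) * rng.beta(a, b))

    def _draw_rare(
        self,
        rng: np.random.Generator,
        used: set[int],
        min_score: float | None = None,
    ) -> ScoredVariant:
        # ``used`` holds the sample's own positions (no within-sample repeats).
        while True:
            pos, ref, alt = self._rare_sites[int(rng.integers(len(self._rare_sites)))]
            if pos not in used:
                break
        used.add(pos)
        score = self._rare_score(rng)
        if min_score is not None:
            while score <= min_score:
                score = self._rare_score(rng)
        frequency = float(rng.uniform(0.0, 0.00099))
        return ScoredVariant(pos, ref, alt, score, frequency)

    def _build_sample(
        self,
        cohort: str,
        cohort_idx: int,
        idx: int,
        labels: list[str],
        probs: np.ndarray,
        catalog: dict[tuple[int, str], ScoredVariant],
    ) -> tuple[SyntheticSample, list[ScoredVariant]]:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.config.seed, spawn_key=(cohort_idx, idx))
        )
        haplogroup = labels[int(rng.choice(len(labels), p=probs))]
        variants = self._marker_variants(haplogroup)
        used = {v.position for v in variants}
        extras: list[ScoredVariant] = []
        # Marker variants that coincide with scored fixture variants count
        # toward the load just like explicitly associated ones.
        load = sum(
            s for v in variants if (s := self._fixture_scores.get(v.key, 0.0)) > 0.5
        )
        for assoc in self.associated.get(haplogroup, []):
            if assoc.position in used:
                continue
            used.add(assoc.position)
            variants.append(MtVariant(assoc.position, assoc.ref, assoc.alt, 1.0))
            if assoc.score > 0.5:
                load += assoc.score
        n_rare = int(rng.poisson(self.config.rare_lambda))
        for _ in range(n_rare):
            rare = self._draw_rare(rng, used)
            # A rare variant seen before in this cohort set keeps its original
            # score and frequency (recurrent private variant).
            rare = catalog.setdefault((rare.position, rare.alt), rare)
            variants.append(MtVariant(rare.position, rare.ref, rare.alt, 1.0))
            extras.append(rare)
            if rare.score > 0.5:
                load += rare.score
        pi = self.config.effect_pi.get(cohort, 0.0)
        if pi > 0.0 and rng.random() < pi:
            while True:
                # effect variants must carry a fresh key so their score is
                # not overridden by an earlier catalog entry
                if self.config.effect_score is not None:
                    eff = self._draw_rare(rng, used)
                    eff = replace(eff, score=self.config.effect_score)
                else:
                    eff = self._draw_rare(rng, used, min_score=0.5)
                if (eff.position, eff.alt) not in catalog:
                    break
            catalog[(eff.position, eff.alt)] = eff
            variants.append(MtVariant(eff.position, eff.ref, eff.alt, 1.0))
            extras.append(eff)
            load += eff.score
        sample = SyntheticSample(
            sample_id=f"{cohort}_{idx:04d}",
            cohort=cohort,
            true_haplogroup=haplogroup,
            variants=variants,
            true_load=load,
        )
        return sample, extras

    # -- public API ---------------------------------------------------------

    def generate(self, config: SyntheticConfig) -> SyntheticCohorts:
        """Generate all cohorts described by ``config``."""
        self.config = config
        freqs = (
            dict(config.haplogroup_freqs)
            if config.haplogroup_freqs is not None
            else default_haplogroup_freqs()
        )
        labels = sorted(freqs)
        probs = np.asarray([freqs[l] for l in labels], dtype=float)
        probs = probs / probs.sum()
        score_table: dict[tuple[int, str], float] = {}
        freq_table: dict[tuple[int, str], float] = {}
        for assoc_list in self.associated.values():
            for v in assoc_list:
                score_table[(v.position, v.alt)] = v.score
                freq_table[(v.position, v.alt)] = v.frequency
        samples: list[SyntheticSample] = []
        catalog: dict[tuple[int, str], ScoredVariant] = {}
        for cohort_idx, (cohort, size) in enumerate(sorted(config.cohort_sizes.items())):
            for idx in range(size):
                sample, extras = self._build_sample(
                    cohort, cohort_idx, idx, labels, probs, catalog
                )
                samples.append(sample)
                for v in extras:
                    score_table[(v.position, v.alt)] = v.score
                    freq_table[(v.position, v.alt)] = v.frequency
        return SyntheticCohorts(samples, score_table, freq_table, config)


_DEFAULT_SIMULATOR: CohortSimulator | None = None


def default_simulator() -> CohortSimulator:
    """Package-fixture-backed simulator (built once per process)."""
    global _DEFAULT_SIMULATOR
    if _DEFAULT_SIMULATOR is None:
        _DEFAULT_SIMULATOR = CohortSimulator()
    return _DEFAULT_SIMULATOR


def generate_cohorts(config: SyntheticConfig) -> SyntheticCohorts:
    """Generate cohorts with the packaged reference and fixture tables."""
    return default_simulator().generate(config)


def inject_effect(
    cohorts: SyntheticCohorts,
    pi: float,
    score: float | None,
    seed: int,
    cohort_labels: Sequence[str] | None = None,
) -> SyntheticCohorts:
    """Add, with probability ``pi`` per sample, one extra qualifying variant.

    ``score`` fixes the injected variant's score; None draws from the rare
    score distribution conditioned on score > 0.5.  ``cohort_labels`` limits
    the effect to specific cohorts (default: all).  Returns a new
    SyntheticCohorts sharing nothing mutable with the input.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must be in [0, 1]")
    sim = default_simulator()
    sim.config = cohorts.config
    rng = np.random.default_rng(seed)
    score_table = dict(cohorts.score_table)
    freq_table = dict(cohorts.frequency_table)
    new_samples: list[SyntheticSample] = []
    targets = set(cohort_labels) if cohort_labels is not None else None
    for s in cohorts.samples:
        variants = list(s.variants)
        load = s.true_load
        if (targets is None or s.cohort in targets) and rng.random() < pi:
            used = {v.position for v in variants}
            while True:
                eff = sim._draw_rare(rng, used, min_score=0.5 if score is None else None)
                if (eff.position, eff.alt) not in score_table:
                    break
            if score is not None:
                eff = replace(eff, score=score)
            variants.append(MtVariant(eff.position, eff.ref, eff.alt, 1.0))
            score_table[(eff.position, eff.alt)] = eff.score
            freq_table[(eff.position, eff.alt)] = eff.frequency
            load += eff.score
        new_samples.append(
            SyntheticSample(s.sample_id, s.cohort, s.true_haplogroup, variants, load)
        )
    return SyntheticCohorts(new_samples, score_table, freq_table, cohorts.config)
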