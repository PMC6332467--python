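"""Score attachment, variant load, carrier categories, pathogenic screen."""

import numpy as np
import pytest

from mtvarload.genome import classify_snv
from mtvarload.scoring import (
    AnnotatedVariant,
    MtVariant,
    SampleProfile,
    attach_scores,
    carrier_category,
    combination_class,
    compute_variant_load,
    qualifying_variants,
    rarity_class,
    screen_pathogenic,
)


def annotate(variants, reference, gene_map, scores, freqs):
    annotated = [
        AnnotatedVariant(v, tuple(classify_snv(v.position, v.ref, v.alt, reference, gene_map)))
        for v in variants
    ]
    return attach_scores(annotated, scores, freqs)


@pytest.fixture
def profile_factory(reference, gene_map, score_table, frequency_table):
    def make(variants, extra_scores=None, extra_freqs=None, cohort="case"):
        scores = {**score_table, **(extra_scores or {})}
        freqs = {**frequency_table, **(extra_freqs or {})}
        return SampleProfile(
            "s1", cohort, annotate(variants, reference, gene_map, scores, freqs)
        )

    return make


def test_attach_known_scores(profile_factory, reference):
    p = profile_factory(
        [MtVariant(4216, "T", "C"), MtVariant(3394, "T", "C")]
    )
    by_pos = {av.variant.position: av for av in p.variants}
    assert by_pos[4216].score == pytest.approx(0.611)
    assert by_pos[4216].frequency == pytest.approx(0.1001)
    assert by_pos[4216].rarity == "common"
    assert by_pos[3394].score == pytest.approx(0.783)


def test_synonymous_variant_gets_no_score(reference, gene_map):
    # A synonymous change at a scored key must not receive the score: build
    # a fake score table keyed at a synonymous site of the packaged genome.
    from mtvarload.synthetic import default_simulator

    genome, gm = reference, gene_map
    # find a synonymous SNV in MT-CO1
    co1 = next(f for f in gm if f.gene == "MT-CO1")
    found = None
    for pos in range(co1.start, co1.end):
        ref = genome.base_at(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            (call,) = classify_snv(pos, ref, alt, genome, gm)
            if call.consequence == "synonymous":
                found = MtVariant(pos, ref, alt)
                break
        if found:
            break
    assert found is not None
    annotated = annotate([found], genome, gm, {found.key: 0.9}, {found.key: 0.5})
    assert annotated[0].score is None  # scores apply to amino-acid changes only
    assert annotated[0].frequency == 0.5  # frequency attaches regardless


def test_load_sums_scores_of_qualifying_variants(profile_factory):
    p = profile_factory([MtVariant(4216, "T", "C"), MtVariant(4917, "A", "G")])
    assert compute_variant_load(p) == pytest.approx(1.239)


def test_empty_profile_zero_load():
    assert compute_variant_load(SampleProfile("s", "c", [])) == 0.0


def test_threshold_is_strict(profile_factory):
    # m.5460G>A scores exactly 0.505: above 0.5 but not above 0.505.
    p = profile_factory([MtVariant(5460, "G", "A")])
    assert compute_variant_load(p, threshold=0.5) == pytest.approx(0.505)
    assert compute_variant_load(p, threshold=0.505) == 0.0


def test_heteroplasmic_variants_excluded_from_load(profile_factory):
    p = profile_factory([MtVariant(4216, "T", "C", fraction=0.5)])
    assert compute_variant_load(p) == 0.0
    assert carrier_category(p) == "0"


def test_invalid_threshold_rejected(profile_factory):
    p = profile_factory([MtVariant(4216, "T", "C")])
    with pytest.raises(ValueError):
        compute_variant_load(p, threshold=1.5)


def test_carrier_categories(profile_factory):
    two = profile_factory([MtVariant(4216, "T", "C"), MtVariant(4917, "A", "G")])
    assert carrier_category(two) == "2+"
    one = profile_factory([MtVariant(4216, "T", "C"), MtVariant(5460, "G", "A")])
    # at threshold 0.52 only 4216 (0.611) qualifies, 5460 (0.505) does not
    assert carrier_category(one, threshold=0.52) == "1"
    assert carrier_category(profile_factory([])) == "0"


def test_load_and_category_consistent(profile_factory):
    for variants in ([], [MtVariant(4216, "T", "C")], [MtVariant(5460, "G", "A")]):
        p = profile_factory(variants)
        assert (compute_variant_load(p) > 0) == (carrier_category(p) != "0")


def test_threshold_monotonicity(profile_factory):
    p = profile_factory([MtVariant(4216, "T", "C"), MtVariant(3394, "T", "C")])
    assert compute_variant_load(p, 0.7) <= compute_variant_load(p, 0.5)


class TestCombinationClass:
    def test_two_common(self, profile_factory):
        p = profile_factory([MtVariant(4216, "T", "C"), MtVariant(4917, "A", "G")])
        assert combination_class(p) == ("common-only", False)

    def test_common_plus_rare(self, profile_factory, reference, gene_map):
        # find a non-synonymous site to serve as the rare variant
        from mtvarload.synthetic import default_simulator

        pos, ref, alt = default_simulator()._rare_sites[0]
        v = MtVariant(pos, ref, alt)
        p = profile_factory(
            [MtVariant(4216, "T", "C"), v],
            extra_scores={v.key: 0.6},
            extra_freqs={v.key: 0.0005},
        )
        assert combination_class(p) == ("common+rare", False)
        only_rare = profile_factory(
            [v], extra_scores={v.key: 0.6}, extra_freqs={v.key: 0.0005}
        )
        assert combination_class(only_rare) == ("single", False)

    def test_empty(self):
        assert combination_class(SampleProfile("s", "c", [])) == ("none", False)

    def test_unknown_rarity_flagged(self, profile_factory, reference):
        from mtvarload.synthetic import default_simulator

        pos, ref, alt = default_simulator()._rare_sites[1]
        v = MtVariant(pos, ref, alt)
        p = profile_factory(
            [MtVariant(4216, "T", "C"), v], extra_scores={v.key: 0.8}
        )  # no frequency for v -> unknown rarity
        cls, flagged = combination_class(p)
        assert cls == "common-only"  # classified using the known variant
        assert flagged


def test_rarity_bands():
    assert rarity_class(0.0005) == "rare"
    assert rarity_class(0.005) == "intermediate"
    assert rarity_class(0.05) == "common"
    assert rarity_class(None) == "unknown"
    # band edges belong to the intermediate class
    assert rarity_class(0.001) == "intermediate"
    assert rarity_class(0.01) == "intermediate"


class TestPathogenicScreen:
    KNOWN = [(3243, "G", "MELAS/MIDD"), (1555, "G", "deafness")]

    def test_heteroplasmic_hit_flagged(self):
        flags = screen_pathogenic([MtVariant(1555, "A", "G", 0.1181)], self.KNOWN)
        assert len(flags) == 1
        assert flags[0].label == "deafness"
        assert flags[0].heteroplasmic

    def test_absent_mutation_no_flag(self):
        assert screen_pathogenic([MtVariant(4216, "T", "C")], self.KNOWN) == []

    def test_planted_carriers_in_cohort(self):
        """Exactly the planted carriers are flagged across a cohort."""
        rng = np.random.default_rng(5)
        flagged = 0
        for i in range(415):
            variants = [MtVariant(4216, "T", "C")]
            if i in (17, 230):
                variants.append(MtVariant(1555, "A", "G", 1.0 if i == 17 else 0.1181))
            flagged += len(screen_pathogenic(variants, self.KNOWN))
        assert flagged == 2


def test_load_matches_brute_force_recount(reference, gene_map):
    """Random profiles: load equals an independent recount of their list."""
    from mtvarload.synthetic import default_simulator

    sim = default_simulator()
    rng = np.random.default_rng(99)
    sites = sim._rare_sites
    for _ in range(25):
        picks = rng.choice(len(sites), size=rng.integers(0, 8), replace=False)
        variants, scores, freqs = [], {}, {}
        for k in picks:
            pos, ref, alt = sites[int(k)]
            frac = float(rng.choice([1.0, 0.9, 0.5]))
            variants.append(MtVariant(pos, ref, alt, frac))
            scores[(pos, alt)] = float(rng.uniform(0, 1))
            freqs[(pos, alt)] = float(rng.uniform(0, 0.2))
        annotated = annotate(variants, reference, gene_map, scores, freqs)
        p = SampleProfile("r", "c", annotated)
        expected = sum(
            scores[v.key]
            for v in variants
            if scores[v.key] > 0.5 and v.fraction >= 0.95
        )
        assert compute_variant_load(p) == pytest.approx(expected)
        n_qual = len(qualifying_variants(p))
        assert n_qual == sum(
            1 for v in variants if scores[v.key] > 0.5 and v.fraction >= 0.95
        )
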