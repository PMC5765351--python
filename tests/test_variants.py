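"""Clone clustering, the unreplicated-SNP filter, minimum-locus inference,
and the within- vs between-species similarity contrast."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silkgene import synth, variants
from silkgene.model import CloneRead
from silkgene.variants import (
    VariantSet,
    cluster_variants,
    diagnose_variants,
    estimate_loci,
    filter_and_call,
    min_loci,
    species_contrast,
)


def _clones(seqs, species="sp", region="five_prime"):
    return [CloneRead(clone_id=f"c{i}", species_label=species, region=region,
                      sequence=s) for i, s in enumerate(seqs)]


BASE = ("ACGTTGCA" * 63)[:500]


def _mutated(seq, positions, base="A"):
    chars = list(seq)
    for p in positions:
        chars[p] = "T" if chars[p] == base else base
    return "".join(chars)


# ---------------------------------------------------------------------------
# clustering


def test_single_source_single_cluster():
    clusters = cluster_variants(_clones([BASE] * 6))
    assert len(clusters) == 1 and len(clusters[0]) == 6


def test_distinct_haplotypes_stay_separate():
    h2 = _mutated(BASE, range(0, 500, 20))  # 25 diffs -> 95% identity
    clusters = cluster_variants(_clones([BASE] * 5 + [h2] * 5))
    assert sorted(len(c) for c in clusters) == [5, 5]


def test_998_identity_merges_under_gt99_rule():
    h2 = _mutated(BASE, [100])  # 1 diff in 500 nt = 99.8% > 99
    clusters = cluster_variants(_clones([BASE] * 3 + [h2] * 3))
    assert len(clusters) == 1


def test_exactly_99_identity_does_not_merge():
    h2 = _mutated(BASE, range(0, 500, 100))  # 5 diffs = 99.0%, not > 99
    clusters = cluster_variants(_clones([BASE] * 3 + [h2] * 3))
    assert len(clusters) == 2


def test_grossly_different_lengths_not_joined():
    short = BASE[:300]
    clusters = cluster_variants(_clones([BASE] * 3 + [short] * 3))
    assert len(clusters) == 2


def test_clusters_require_one_species_region():
    mixed = _clones([BASE] * 2) + _clones([BASE], species="other")
    with pytest.raises(ValueError):
        cluster_variants(mixed)


# ---------------------------------------------------------------------------
# the unreplicated-SNP filter


def test_identical_clones_clean_consensus():
    var = filter_and_call(_clones([BASE] * 10))
    assert var.consensus == BASE
    assert var.support == 10
    assert var.ignored_snp_positions == [] and var.flags == []


def test_single_unreplicated_snp_ignored():
    noisy = _mutated(BASE, [42])
    var = filter_and_call(_clones([BASE] * 9 + [noisy]))
    assert var.consensus == BASE  # majority base restored
    assert var.ignored_snp_positions == [43]  # 1-based
    assert var.support == 10  # nobody discarded


def test_multi_snp_clone_discarded():
    bad = _mutated(BASE, [10, 200, 400])
    var = filter_and_call(_clones([BASE] * 9 + [bad]))
    assert var.consensus == BASE
    assert var.support == 9
    assert any(flag.startswith("discarded:") for flag in var.flags)


def test_replicated_polymorphism_is_kept():
    h2 = _mutated(BASE, [42])
    # two clones share the SNP: it is a real polymorphic site, not Taq error
    var = filter_and_call(_clones([BASE] * 3 + [h2] * 2))
    assert var.ignored_snp_positions == []
    assert var.consensus == BASE  # majority over 5


def test_singleton_cluster_flagged():
    var = filter_and_call(_clones([BASE]))
    assert var.flags == ["unreplicated variant"]
    assert var.consensus == BASE


def test_every_reported_snp_supported_by_two_clones():
    """The diagnosis guarantee: after filtering, any column where retained
    clones disagree with the consensus is backed by >= 2 clones."""
    from collections import Counter

    h2 = _mutated(BASE, [7, 99])
    noisy = _mutated(BASE, [300])
    clones = _clones([BASE] * 4 + [h2] * 3 + [noisy])
    var = filter_and_call(clones)
    retained = [c.sequence for c in clones if c.clone_id in var.clone_ids]
    for col in range(len(BASE)):
        counts = Counter(seq[col] for seq in retained)
        for base, support in counts.items():
            if base != var.consensus[col]:
                assert support >= 2 or (col + 1) in var.ignored_snp_positions


def test_diagnose_bookkeeping_and_numbering():
    h2 = _mutated(BASE, range(0, 500, 20))
    bad = _mutated(BASE, [5, 250])
    clones = _clones([BASE] * 6 + [h2] * 3 + [bad])
    vs = diagnose_variants(clones)
    assert [v.variant_id for v in vs.variants] == ["v1", "v2"]
    assert vs.variants[0].support >= vs.variants[1].support
    assigned = sum(len(v.clone_ids) for v in vs.variants)
    assert assigned + len(vs.discarded_clones) == len(clones)


# ---------------------------------------------------------------------------
# minimum-locus inference


@pytest.mark.parametrize("n,ploidy,expected", [
    (3, 2, 2), (6, 2, 3), (4, 2, 2), (1, 2, 1), (0, 2, 0),
])
def test_min_loci_examples(n, ploidy, expected):
    assert min_loci(n, ploidy) == expected


@settings(derandomize=True, max_examples=60)
@given(st.integers(0, 40), st.integers(1, 8))
def test_min_loci_monotone(n, ploidy):
    assert min_loci(n + 1, ploidy) >= min_loci(n, ploidy)
    assert min_loci(n, ploidy + 1) <= min_loci(n, ploidy)
    if n:
        assert min_loci(n, ploidy) >= 1


def _variant_set(species, region, n, seq=BASE):
    return VariantSet(species_label=species, region=region, variants=[
        variants.Variant(variant_id=f"v{i+1}", consensus=seq, support=2)
        for i in range(n)
    ])


def test_estimate_loci_species_maximum_over_regions():
    sets = [
        _variant_set("trifasciata", "five_prime", 4),
        _variant_set("trifasciata", "three_prime", 6),
        _variant_set("argentata", "five_prime", 3),
        _variant_set("argentata", "three_prime", 3),
    ]
    by_species = {e.species_label: e for e in estimate_loci(sets)}
    assert by_species["trifasciata"].min_loci_per_region == {
        "five_prime": 2, "three_prime": 3}
    assert by_species["trifasciata"].min_loci == 3
    assert by_species["argentata"].min_loci == 2


def test_estimate_loci_empty():
    est = estimate_loci([_variant_set("sp", "five_prime", 0)])[0]
    assert est.min_loci == 0


# ---------------------------------------------------------------------------
# species contrast


def test_contrast_identical_sequences_zero():
    sets = [_variant_set("a", "five_prime", 2), _variant_set("b", "five_prime", 2)]
    c = species_contrast(sets, "five_prime")
    assert c.computable and c.difference == pytest.approx(0.0)


def test_contrast_single_species_not_computable():
    c = species_contrast([_variant_set("a", "five_prime", 3)], "five_prime")
    assert not c.computable and c.between_mean is None


def test_contrast_positive_for_homogenized_panel():
    panel = synth.make_species_panel(
        {"a": 2, "b": 2}, synth.SpidroinModel(
            n_repeats=3, repeat_len_nt=90, nterm_len_nt=300, cterm_len_nt=300),
        species_divergence=0.10, locus_divergence=0.02, allele_divergence=0.02,
        seed=5)
    sets = []
    for genome in panel.values():
        spec = synth.CloneSimSpec(region="five_prime", n_clones=16,
                                  taq_error_rate=0.0)
        clones = synth.simulate_clones(genome, spec, seed=77)
        sets.append(diagnose_variants(clones))
    c = species_contrast(sets, "five_prime")
    assert c.computable and c.difference > 0


# ---------------------------------------------------------------------------
# end-to-end recovery (small; the full 50-seed battery runs in acceptance)


def test_end_to_end_variant_recovery_small():
    model = synth.SpidroinModel(n_repeats=4, repeat_len_nt=150,
                                nterm_len_nt=462, cterm_len_nt=531,
                                intra_repeat_divergence=0.01)
    for seed in range(6):
        L = 1 + seed % 3
        genome = synth.make_diploid_genome("sp", model, n_loci=L, seed=seed)
        spec = synth.CloneSimSpec(region="five_prime", n_clones=16 * L,
                                  taq_error_rate=0.001)
        clones = synth.simulate_clones(genome, spec, seed=seed + 999)
        vs = diagnose_variants(clones)
        assert vs.n_variants == 2 * L
        assert estimate_loci([vs])[0].min_loci == L
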