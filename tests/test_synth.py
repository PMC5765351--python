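"""Generator invariants: architecture arithmetic, determinism, truth-tracking."""

import numpy as np
import pytest

from silkgene import synth
from silkgene.annotate import find_premature_stops


def test_full_architecture_length(full_scale_gene):
    # 15 x 540 + 375 + 993 = 9468
    assert full_scale_gene.cds_len == 9468
    assert full_scale_gene.cds.startswith("ATG")
    assert full_scale_gene.sequence[full_scale_gene.cds_end : full_scale_gene.cds_end + 3] == "TAA"


def test_cds_length_is_exact_sum_of_blocks():
    model = synth.SpidroinModel(n_repeats=3, repeat_len_nt=30,
                                nterm_len_nt=30, cterm_len_nt=30, seed=4)
    gene = synth.generate_gene(model)
    assert gene.cds_len == 30 + 3 * 30 + 30
    truth = gene.truth
    assert truth.repeat_intervals == [(31, 60), (61, 90), (91, 120)]


def test_zero_divergence_units_identical(small_model):
    from dataclasses import replace

    gene = synth.generate_gene(replace(small_model, intra_repeat_divergence=0.0))
    units = {gene.cds[lo - 1 : hi] for lo, hi in gene.truth.repeat_intervals}
    assert len(units) == 1


def test_functional_gene_has_no_internal_stops(full_scale_gene, small_gene):
    for gene in (full_scale_gene, small_gene):
        assert find_premature_stops(gene.cds) == []


def test_generator_deterministic(small_model):
    a = synth.generate_gene(small_model)
    b = synth.generate_gene(small_model)
    assert a.sequence == b.sequence and a.truth.repeat_intervals == b.truth.repeat_intervals


@pytest.mark.parametrize("field,value", [
    ("repeat_len_nt", 100),      # not divisible by 3
    ("intra_repeat_divergence", 1.5),
    ("n_repeats", 0),
])
def test_model_validation_rejects(field, value, small_model):
    from dataclasses import replace

    with pytest.raises(ValueError):
        synth.generate_gene(replace(small_model, **{field: value}))


def test_pseudogenize_identity_case():
    model = synth.SpidroinModel(n_repeats=1, repeat_len_nt=90,
                                nterm_len_nt=90, cterm_len_nt=90, seed=3)
    gene = synth.generate_gene(model)
    spec = synth.PseudogenizationSpec(
        retained_5prime_repeat_nt=90, retained_3prime_repeat_nt=0,
        n_frameshifts=0, terminal_divergence=0.0, drop_tata=False)
    psi = synth.pseudogenize(gene, spec, seed=9)
    assert psi.cds == gene.cds


def test_pseudogenize_rejects_over_retention(small_gene):
    spec = synth.PseudogenizationSpec(retained_5prime_repeat_nt=121)
    with pytest.raises(ValueError):
        synth.pseudogenize(small_gene, spec, seed=0)


def test_pseudogene_length_near_full_scale(full_scale_gene):
    spec = synth.PseudogenizationSpec(terminal_divergence=0.08,
                                      terminal_divergence_3prime=0.12)
    psi = synth.pseudogenize(full_scale_gene, spec, seed=5)
    # 993 + 286 + 84 = 1363, +- the two injected 1-nt indels
    assert 1300 <= psi.cds_len <= 1400
    assert psi.truth.is_pseudogene and len(psi.truth.frameshifts) == 2


def test_deletion_frameshift_creates_premature_stop(full_scale_gene):
    # brute-force oracle: a 1-nt deletion shifts frame, and the shifted frame
    # of spidroin-like sequence hits a stop well before the end
    spec = synth.PseudogenizationSpec(n_frameshifts=1, terminal_divergence=0.0)
    hits = 0
    for seed in range(10):
        psi = synth.pseudogenize(full_scale_gene, spec, seed=seed)
        stops = find_premature_stops(psi.cds)
        if stops:
            hits += 1
            assert stops[0][0] > synth.PseudogenizationSpec.FRAMESHIFT_EXCLUSION_NT
    # an indel landing very near the 3' end can run off without a stop,
    # so demand a clear majority rather than all ten
    assert hits >= 7


def test_clone_truth_tracking_error_free(small_model):
    genome = synth.make_diploid_genome("sp", small_model, n_loci=2, seed=8)
    spec = synth.CloneSimSpec(region="five_prime", n_clones=16, taq_error_rate=0.0)
    clones = synth.simulate_clones(genome, spec, seed=12)
    p5, p3 = synth.design_primers(genome, "five_prime")
    amplicons = {
        (locus.name, a): synth._amplicon(locus.alleles[a], p5, p3)
        for locus in genome.loci for a in range(2)
    }
    for clone in clones:
        assert clone.n_errors == 0
        assert clone.sequence == amplicons[(clone.source_locus, clone.source_allele)]
    assert len({c.clone_id for c in clones}) == len(clones)


def test_clone_error_injection_matches_truth_count(small_model):
    genome = synth.make_diploid_genome("sp", small_model, n_loci=1, seed=2)
    spec = synth.CloneSimSpec(region="five_prime", n_clones=30, taq_error_rate=0.005)
    clones = synth.simulate_clones(genome, spec, seed=3)
    p5, p3 = synth.design_primers(genome, "five_prime")
    amplicons = {
        (locus.name, a): synth._amplicon(locus.alleles[a], p5, p3)
        for locus in genome.loci for a in range(2)
    }
    total = 0
    for clone in clones:
        source = amplicons[(clone.source_locus, clone.source_allele)]
        diffs = sum(a != b for a, b in zip(clone.sequence, source))
        assert diffs == clone.n_errors
        total += diffs
    expected = spec.taq_error_rate * len(clones) * len(clones[0].sequence)
    assert 0.3 * expected <= total <= 2.5 * expected


def test_diploid_genome_invariants(small_model):
    genome = synth.make_diploid_genome("sp", small_model, n_loci=3, seed=1)
    assert len(genome.loci) == 3
    for locus in genome.loci:
        assert len(locus.alleles) == 2
        assert locus.alleles[0].sequence != locus.alleles[1].sequence


def test_promoter_motifs_exactly_as_flagged():
    from dataclasses import replace

    base = synth.SpidroinModel(n_repeats=3, repeat_len_nt=60, nterm_len_nt=60,
                               cterm_len_nt=60, upstream_len_nt=300, seed=6)
    with_tata = synth.generate_gene(replace(base, has_tata=True, has_cacg=False))
    assert "TATAAA" in with_tata.upstream and "CACG" not in with_tata.upstream
    with_both = synth.generate_gene(replace(base, has_tata=True, has_cacg=True))
    assert "TATAAA" in with_both.upstream and "CACG" in with_both.upstream
    bare = synth.generate_gene(replace(base, has_tata=False, has_cacg=False))
    assert "TATAAA" not in bare.upstream and "CACG" not in bare.upstream
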