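"""Gene-vs-pseudogene segment alignment, repeat-loss, and classification."""

import pytest

from silkgene import annotate, paralogs, synth
from silkgene.annotate import GeneAnnotation, MotifHit
from silkgene.repeats import detect_repeats


def test_self_comparison_two_perfect_segments(full_scale_gene, full_scale_decomposition):
    segs = paralogs.align_paralogs(full_scale_gene, full_scale_decomposition, full_scale_gene)
    assert [s.label for s in segs] == ["five_prime", "three_prime"]
    for seg in segs:
        assert seg.identity_pct == pytest.approx(100.0)
        assert seg.frameshift_gaps == 0
    assert paralogs.repeat_loss_fraction(full_scale_decomposition, segs) == pytest.approx(0.0)


def test_pseudogene_segments_and_frameshift_gaps(full_scale_gene, full_scale_decomposition):
    spec = synth.PseudogenizationSpec(n_frameshifts=2, terminal_divergence=0.0)
    psi = synth.pseudogenize(full_scale_gene, spec, seed=7)
    segs = paralogs.align_paralogs(full_scale_gene, full_scale_decomposition, psi)
    assert [s.label for s in segs] == ["five_prime", "three_prime"]
    assert sum(s.frameshift_gaps for s in segs) == 2
    for seg in segs:
        assert seg.identity_pct > 98.0  # only the 2 indels and junction noise
    # segments ordered and non-overlapping on the candidate
    assert segs[0].pseudo_interval[1] < segs[1].pseudo_interval[0] + 1


def test_full_scale_segment_identities(full_scale_gene, full_scale_decomposition):
    spec = synth.PseudogenizationSpec(terminal_divergence=0.08,
                                      terminal_divergence_3prime=0.12)
    psi = synth.pseudogenize(full_scale_gene, spec, seed=42)
    segs = paralogs.align_paralogs(full_scale_gene, full_scale_decomposition, psi)
    by_label = {s.label: s for s in segs}
    assert by_label["five_prime"].identity_pct == pytest.approx(92, abs=3)
    assert by_label["three_prime"].identity_pct == pytest.approx(88, abs=4)
    loss = paralogs.repeat_loss_fraction(full_scale_decomposition, segs)
    # (8475 - ~370) / 8475
    assert loss == pytest.approx(0.956, abs=0.02)


def test_unrelated_candidate_yields_no_segments(full_scale_gene, full_scale_decomposition):
    import numpy as np

    rng = np.random.default_rng(3)
    junk = "".join("ACGT"[i] for i in rng.integers(4, size=1400))
    from silkgene.model import Locus

    cand = Locus(name="junk", sequence=junk, cds_start=1, cds_end=len(junk))
    segs = paralogs.align_paralogs(full_scale_gene, full_scale_decomposition, cand)
    assert segs == []


def test_repeat_loss_single_unit(full_scale_gene, full_scale_decomposition):
    # candidate = gene minus one 540-nt unit: loss = 540 / 8475
    from silkgene.model import Locus

    lo, hi = full_scale_gene.truth.repeat_intervals[7]
    cds = full_scale_gene.cds[: lo - 1] + full_scale_gene.cds[hi:]
    cand = Locus(name="minus_one", sequence=cds, cds_start=1, cds_end=len(cds))
    segs = paralogs.align_paralogs(full_scale_gene, full_scale_decomposition, cand)
    loss = paralogs.repeat_loss_fraction(full_scale_decomposition, segs)
    assert loss == pytest.approx(540 / 8475, abs=0.02)


def _ann(stops):
    return GeneAnnotation(cds_start=1, cds_end=9, protein="***",
                          premature_stops=stops)


def test_classify_rules():
    tata = [MotifHit(motif="TATAAA", position_upstream=60)]
    assert paralogs.classify_locus(_ann([(421, 423)]), [], 0.9, 2).verdict == "pseudogene"
    assert paralogs.classify_locus(_ann([]), tata, 0.0, 0).verdict == "functional"
    assert paralogs.classify_locus(_ann([]), [], 0.0, 0).verdict == "ambiguous"
    # frameshifts alone are disqualifying even without a stop
    assert paralogs.classify_locus(_ann([]), tata, 0.0, 1).verdict == "pseudogene"


def test_classify_pseudogene_always_has_evidence():
    verdict = paralogs.classify_locus(_ann([(10, 12)]), [], 0.0, 0)
    assert verdict.verdict == "pseudogene" and verdict.evidence


def test_truth_label_recovery_across_divergence():
    """Gene/pseudogene pairs across terminal divergence 0-15%: the rule-based
    classifier should recover the generator's truth label almost always."""
    ok = n = 0
    for i in range(25):
        div = (i % 6) * 0.03  # 0 .. 0.15
        gene = synth.generate_gene(synth.SpidroinModel(
            n_repeats=5, repeat_len_nt=150, nterm_len_nt=150, cterm_len_nt=150,
            seed=300 + i))
        deco = detect_repeats(gene.cds)
        psi = synth.pseudogenize(gene, synth.PseudogenizationSpec(
            retained_5prime_repeat_nt=90, retained_3prime_repeat_nt=30,
            n_frameshifts=2, terminal_divergence=div), seed=600 + i)
        for locus, want in ((gene, "functional"), (psi, "pseudogene")):
            segs = paralogs.align_paralogs(gene, deco, locus)
            loss = paralogs.repeat_loss_fraction(deco, segs)
            ann = annotate.annotate_fixed_frame(locus.cds)
            tata = annotate.scan_promoter(locus.upstream, ["TATAAA"])
            got = paralogs.classify_locus(
                ann, tata, loss, sum(s.frameshift_gaps for s in segs))
            n += 1
            ok += got.verdict == want
    assert ok / n >= 0.95
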