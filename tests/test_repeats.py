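"""Tandem-repeat decomposition, identity statistics, consensus, and
frameshift-artifact resolution against planted generator truth."""

import numpy as np
import pytest

from silkgene import synth
from silkgene.repeats import (
    apply_events,
    consensus_repeat,
    detect_repeats,
    identity_matrix,
    resolve_frameshifts,
)

# ---------------------------------------------------------------------------
# brute-force affine-gap aligner: the independent identity oracle


def _oracle_identity(a, b, match=1, mismatch=-1, gap_open=-4, gap_extend=-1):
    """Gotoh global alignment with traceback; identity = matches / columns,
    terminal gap columns excluded.  Independent of the package's aligner."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i][j], X[i][j], Y[i][j]]))
    cols = []
    while i > 0 or j > 0:
        if state == 0:
            cols.append("M" if a[i - 1] == b[j - 1] else "X")
            i, j = i - 1, j - 1
            if i >= 0 and j >= 0:
                state = int(np.argmax([M[i][j], X[i][j], Y[i][j]])) if (i or j) else 0
        elif state == 1:
            cols.append("G")
            prev_from_open = M[i - 1][j] + (-4)
            state = 0 if prev_from_open >= X[i - 1][j] + (-1) else 1
            i -= 1
        else:
            cols.append("G")
            prev_from_open = M[i][j - 1] + (-4)
            state = 0 if prev_from_open >= Y[i][j - 1] + (-1) else 2
            j -= 1
    cols.reverse()
    lo, hi = 0, len(cols)
    while lo < hi and cols[lo] == "G":
        lo += 1
    while hi > lo and cols[hi - 1] == "G":
        hi -= 1
    inner = cols[lo:hi]
    if not inner:
        return 0.0
    return 100.0 * inner.count("M") / len(inner)


# ---------------------------------------------------------------------------
# detection


def test_planted_units_recovered_exactly_at_zero_divergence():
    model = synth.SpidroinModel(n_repeats=5, repeat_len_nt=60, nterm_len_nt=60,
                                cterm_len_nt=60, seed=2)
    gene = synth.generate_gene(model)
    deco = detect_repeats(gene.cds)
    assert deco is not None
    assert deco.units == gene.truth.repeat_intervals
    assert deco.unit_len_nt == 60


def test_full_scale_gene_decomposition(full_scale_gene, full_scale_decomposition):
    deco = full_scale_decomposition
    assert deco.n_units == 16
    lengths = [hi - lo + 1 for lo, hi in deco.units]
    assert lengths[:15] == [540] * 15
    assert lengths[15] == 375
    assert deco.mean_identity_nt == pytest.approx(100.0)
    assert deco.mean_identity_aa == pytest.approx(100.0)


def test_decomposition_round_trip(full_scale_gene, full_scale_decomposition):
    deco = full_scale_decomposition
    lo_n, hi_n = deco.nterm_interval
    lo_c, hi_c = deco.cterm_interval
    rebuilt = (full_scale_gene.cds[lo_n - 1 : hi_n]
               + "".join(deco.unit_seqs())
               + full_scale_gene.cds[lo_c - 1 : hi_c])
    assert rebuilt == full_scale_gene.cds


def test_no_repeat_region_in_random_sequence():
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(4, size=2000))
    assert detect_repeats(seq) is None


def test_detect_rejects_bad_bounds(small_gene):
    with pytest.raises(ValueError):
        detect_repeats(small_gene.cds, min_unit_nt=2)


# ---------------------------------------------------------------------------
# identity


@pytest.mark.parametrize("a,b,expected", [
    ("ACGTACGT", "ACGTACGT", 100.0),
    ("AAAA", "AAAT", 75.0),
])
def test_identity_examples(a, b, expected):
    mat, mean = identity_matrix([a, b])
    assert mat[0, 1] == pytest.approx(expected)
    assert mean == pytest.approx(expected)


def test_identity_matrix_symmetric_unit_diagonal(full_scale_decomposition):
    mat = full_scale_decomposition.identity_mat
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 100.0)


def test_identity_matches_brute_force_oracle():
    model = synth.SpidroinModel(n_repeats=6, repeat_len_nt=120,
                                intra_repeat_divergence=0.03,
                                nterm_len_nt=120, cterm_len_nt=120, seed=21)
    gene = synth.generate_gene(model)
    units = [gene.cds[lo - 1 : hi] for lo, hi in gene.truth.repeat_intervals]
    mat, _ = identity_matrix(units)
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            assert mat[i, j] == pytest.approx(
                _oracle_identity(units[i], units[j]), abs=0.35)


def test_identity_oracle_agreement_full_length_unit(full_scale_gene):
    # one pair at the full 540-nt unit scale, units made unequal by mutation
    u1 = full_scale_gene.cds[462:1002]
    rng = np.random.default_rng(5)
    chars = list(u1)
    for pos in rng.choice(540, size=12, replace=False):
        chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
    u2 = "".join(chars)
    mat, _ = identity_matrix([u1, u2])
    assert mat[0, 1] == pytest.approx(_oracle_identity(u1, u2), abs=0.35)


# ---------------------------------------------------------------------------
# consensus


def test_consensus_trivial_and_majority():
    assert consensus_repeat(["ACGT", "ACGT", "ACGT"]) == "ACGT"
    assert consensus_repeat(["AAAA", "AAAA", "AAGA"]) == "AAAA"


def test_consensus_tie_breaks_to_most_5prime_unit():
    assert consensus_repeat(["AAAA", "AAGA"]) == "AAAA"
    assert consensus_repeat(["AAGA", "AAAA"]) == "AAGA"


def test_consensus_requires_two_units():
    with pytest.raises(ValueError):
        consensus_repeat(["ACGT"])


# ---------------------------------------------------------------------------
# frameshift resolution


def test_resolve_planted_artifacts_bit_exact(full_scale_gene):
    raw, planted = synth.plant_frameshift_artifacts(
        full_scale_gene, n_deletions=2, n_insertions=3, seed=101)
    report = resolve_frameshifts(raw.cds)
    assert report.n_additions == 2
    assert report.n_deletions == 3
    assert report.corrected_sequence == full_scale_gene.cds
    assert apply_events(raw.cds, report.events) == report.corrected_sequence


def test_resolve_clean_sequence_empty_report(full_scale_gene):
    report = resolve_frameshifts(full_scale_gene.cds)
    assert report.events == []
    assert report.corrected_sequence == full_scale_gene.cds


def test_resolve_idempotent(full_scale_gene):
    raw, _ = synth.plant_frameshift_artifacts(full_scale_gene, 2, 3, seed=55)
    first = resolve_frameshifts(raw.cds)
    second = resolve_frameshifts(first.corrected_sequence)
    assert second.events == []


def test_whole_unit_deletion_is_not_corrected(full_scale_gene):
    # removing an entire 540-nt unit is biology (unequal crossing over),
    # not a sequencing artifact: the unit count drops instead
    lo, hi = full_scale_gene.truth.repeat_intervals[5]
    cds = full_scale_gene.cds[: lo - 1] + full_scale_gene.cds[hi:]
    report = resolve_frameshifts(cds)
    assert report.events == []
    deco = detect_repeats(cds)
    assert deco.n_units == 15


def test_resolution_recovers_original_across_seeds():
    model = synth.SpidroinModel(n_repeats=6, repeat_len_nt=120,
                                nterm_len_nt=120, cterm_len_nt=120)
    good = 0
    for seed in range(100):
        from dataclasses import replace

        gene = synth.generate_gene(replace(model, seed=seed))
        raw, _ = synth.plant_frameshift_artifacts(gene, 1, 1, seed=seed + 1)
        report = resolve_frameshifts(raw.cds)
        good += report.corrected_sequence == gene.cds
    assert good == 100
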