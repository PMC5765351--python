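"""Frameshift-tolerant comparison of a full-length spidroin gene with a
candidate paralog, and rule-based locus classification.

A recently pseudogenized spidroin copy typically retains the two terminal
segments of its parent — the N-terminal-coding block plus the start of the
first repeat, and the end of the last repeat plus the C-terminal-coding
block — while the repeat array between them has been deleted (unequal
crossing over collapses tandem arrays).  Segment discovery is therefore
anchored on the parent gene's known architecture rather than left to
unconstrained local alignment, which on a repeat array would produce
spurious repeat-to-repeat matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignmentStats, align_stats
from .annotate import GeneAnnotation, MotifHit
from .model import Locus
from .repeats import RepeatDecomposition

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass
class SegmentAlignment:
    label: str  # five_prime | three_prime
    gene_interval: tuple[int, int]  # 1-based inclusive, on the gene CDS
    pseudo_interval: tuple[int, int]  # on the candidate body
    identity_pct: float
    #: 1-2 nt gap events needed to align the segments (frame-restoring gaps)
    frameshift_gaps: int
    #: scoring parameters, reported alongside every identity
    params: str = "match=1,mismatch=-1,gap_open=-4,gap_extend=-1"


@dataclass
class LocusClassification:
    verdict: str  # 'functional' | 'pseudogene' | 'ambiguous'
    evidence: list[str] = field(default_factory=list)


def _segment_stats(gene_block: str, candidate: str) -> AlignmentStats:
    return align_stats(gene_block, candidate, mode="local")


def align_paralogs(gene: Locus, decomposition: RepeatDecomposition,
                   candidate: Locus, identity_floor: float = 60.0,
                   min_span_nt: int = 100) -> list[SegmentAlignment]:
    """Locally align the gene's terminal blocks (each extended one repeat
    into the array) against the candidate body.

    Returns the 5' and 3' segment alignments that reach ``identity_floor``;
    an empty list means the candidate shows no recognizable relationship.
    The candidate's middle — the lost repeat region — is whatever lies
    between the two reported ``pseudo_interval``s.
    """
    gene_cds = gene.cds
    cand = candidate.cds
    first_lo, first_hi = decomposition.units[0]
    last_lo, last_hi = decomposition.units[-1]

    blocks = (
        (FIVE_PRIME, (1, first_hi)),          # N-terminal block + repeat 1
        (THREE_PRIME, (last_lo, len(gene_cds))),  # last repeat + C-terminal block
    )
    # segments are located sequentially: the 3' block is aligned against the
    # candidate remainder after the 5' match, so near-identical repeat
    # sequence at the junction cannot pull both local alignments onto the
    # same candidate stretch
    out: list[SegmentAlignment] = []
    cand_offset = 0
    for label, (lo, hi) in blocks:
        block = gene_cds[lo - 1 : hi]
        remainder = cand[cand_offset:]
        if not remainder:
            break
        stats = _segment_stats(block, remainder)
        # a real terminal segment is hundreds of nt; short high-scoring
        # blips against unrelated sequence are noise
        if stats.columns < min_span_nt or stats.identity_pct < identity_floor:
            continue
        g0, g1 = stats.span_a
        p0, p1 = stats.span_b
        out.append(SegmentAlignment(
            label=label,
            gene_interval=(lo + g0 - 1, lo + g1 - 1),
            pseudo_interval=(cand_offset + p0, cand_offset + p1),
            identity_pct=stats.identity_pct,
            frameshift_gaps=stats.short_gap_events,
        ))
        cand_offset += p1
    return out


def repeat_loss_fraction(decomposition: RepeatDecomposition,
                         segments: list[SegmentAlignment]) -> float:
    """Fraction of the gene's repeat-region nucleotides with no counterpart
    in the candidate.

    Counterparts are the repeat nucleotides inside the aligned terminal
    segments, plus whatever the candidate carries between the two segments
    (its unaligned middle stands in for interior repeats, up to the length
    the gene actually has there).
    """
    rep_lo, rep_hi = decomposition.repeat_region
    total = rep_hi - rep_lo + 1
    covered = 0
    for seg in segments:
        lo, hi = seg.gene_interval
        covered += max(0, min(hi, rep_hi) - max(lo, rep_lo) + 1)
    middle_counterpart = 0
    if len(segments) == 2:
        cand_middle = max(0, segments[1].pseudo_interval[0]
                          - segments[0].pseudo_interval[1] - 1)
        middle_counterpart = min(cand_middle, total - covered)
    return max(0.0, (total - covered - middle_counterpart) / total)


def classify_locus(annotation: GeneAnnotation, motif_hits: list[MotifHit],
                   loss: float, frameshifts: int) -> LocusClassification:
    """Categorical diagnosis of one locus.

    Pseudogene iff it has a premature stop or requires frameshift gaps to
    align with the functional paralog — repeat loss and a missing TATA box
    are recorded as supporting evidence only.  Functional requires a clean
    translation, no frameshifts, and a TATA box.  Everything else is
    ambiguous.
    """
    has_tata = any(h.motif.upper() == "TATAAA" for h in motif_hits)
    evidence: list[str] = []
    if annotation.premature_stops:
        first = annotation.premature_stops[0]
        evidence.append(f"premature stop codon at {first[0]}-{first[1]}"
                        + (f" (+{len(annotation.premature_stops) - 1} more)"
                           if len(annotation.premature_stops) > 1 else ""))
    if frameshifts:
        evidence.append(f"{frameshifts} frameshift gap(s) required for paralog alignment")
    if loss > 0.5:
        evidence.append(f"{loss:.1%} of the repeat region lost")
    if not has_tata:
        evidence.append("no TATA box in the upstream region")

    if annotation.premature_stops or frameshifts:
        return LocusClassification(verdict="pseudogene", evidence=evidence)
    if has_tata:
        return LocusClassification(
            verdict="functional",
            evidence=evidence or ["intact ORF, TATA box present"])
    return LocusClassification(verdict="ambiguous", evidence=evidence or ["no disabling lesion, no promoter support"])
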