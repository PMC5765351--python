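"""Single-exon gene annotation: ORF finding, translation, premature-stop
detection, residue composition, molecular weight, and promoter-motif scanning.

Conventions, applied uniformly and reported everywhere:

* CDS length runs from the start codon through the last sense codon — the
  stop codon is excluded — so ``len(protein) == cds_len_nt / 3``.
* All reported coordinates are 1-based inclusive.
* ORF search is ATG-initiated, forward strand only (inputs are oriented);
  longest wins, ties broken by leftmost start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight as _bio_mw

from . import iupac

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MotifHit:
    motif: str
    #: nt between the motif's 3' end and the A of the start codon
    position_upstream: int
    strand: str = "+"


@dataclass
class GeneAnnotation:
    """Annotation of one single-exon coding sequence.

    ``cds_start``/``cds_end`` are 1-based inclusive on the input sequence and
    exclude the stop codon.  ``premature_stops`` lists in-frame stop codons
    occurring before the final stop, as 1-based CDS-relative (start, end)
    nucleotide intervals — empty for an ORF selected by ``annotate_cds``,
    which by construction ends at the first in-frame stop.
    """

    cds_start: int
    cds_end: int
    protein: str
    premature_stops: list[tuple[int, int]] = field(default_factory=list)
    composition: dict[str, float] = field(default_factory=dict)
    composition_int: dict[str, int] = field(default_factory=dict)
    mol_weight_kda: float = 0.0

    @property
    def cds_len_nt(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def found(self) -> bool:
        return self.cds_len_nt > 0


NO_ORF = GeneAnnotation(cds_start=0, cds_end=-1, protein="")


def translate(cds: str) -> str:
    """Standard-genetic-code translation; in-frame stops rendered as '*'."""
    if len(cds) % 3 != 0:
        raise ValueError(f"sequence length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate())


def find_premature_stops(sequence: str) -> list[tuple[int, int]]:
    """Every in-frame stop codon, reading frame 1 from the first base.

    Returns 1-based inclusive nucleotide intervals, earliest first.  A
    trailing partial codon is ignored.
    """
    seq = sequence.upper()
    return [
        (i + 1, i + 3)
        for i in range(0, len(seq) - 2, 3)
        if seq[i : i + 3] in STOP_CODONS
    ]


def composition(protein: str) -> tuple[dict[str, float], dict[str, int]]:
    """Percent of protein length per residue: full precision and
    round-half-up integers (the form composition tables print)."""
    if not protein:
        raise ValueError("empty protein")
    full = {
        aa: 100.0 * protein.count(aa) / len(protein)
        for aa in AMINO_ACIDS
        if aa in protein
    }
    rounded = {aa: int(pct + 0.5) for aa, pct in full.items()}
    return full, rounded


def protein_mass_kda(protein: str) -> float:
    """Predicted mass in kDa from average (not monoisotopic) residue masses,
    i.e. sum of residue masses plus one water."""
    if not protein:
        raise ValueError("empty protein")
    return _bio_mw(protein, seq_type="protein", monoisotopic=False) / 1000.0


# alias matching the operation name used in reports
molecular_weight = protein_mass_kda


def annotate_cds(sequence: str, min_len_nt: int = 300) -> GeneAnnotation:
    """Annotate the longest ATG-initiated forward-strand ORF.

    An ORF qualifies only if a stop codon terminates it within the sequence;
    length is counted start codon through last sense codon.  Returns the
    NO_ORF sentinel (``found`` is False) when nothing reaches ``min_len_nt``.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must contain only A/C/G/T/N")
    if min_len_nt < 3:
        raise ValueError("min_len_nt must be >= 3")

    # first in-frame stop at or after each position, per frame
    best: tuple[int, int] | None = None  # (cds_len, start_0based)
    stops_by_frame: dict[int, list[int]] = {f: [] for f in range(3)}
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    import bisect

    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        stops = stops_by_frame[i % 3]
        k = bisect.bisect_left(stops, i + 3)
        if k == len(stops):
            continue  # never terminated: not a complete ORF
        cds_len = stops[k] - i
        if cds_len >= min_len_nt and (best is None or cds_len > best[0]):
            best = (cds_len, i)
    if best is None:
        return NO_ORF

    cds_len, start = best
    cds = seq[start : start + cds_len]
    protein = translate(cds)
    full, rounded = composition(protein)
    return GeneAnnotation(
        cds_start=start + 1,
        cds_end=start + cds_len,
        protein=protein,
        premature_stops=[],  # ORF ends at its first in-frame stop
        composition=full,
        composition_int=rounded,
        mol_weight_kda=protein_mass_kda(protein),
    )


def annotate_fixed_frame(sequence: str) -> GeneAnnotation:
    """Annotate a sequence whose reading frame is known to start at base 1
    (e.g. a pseudogene body read from its inherited ATG).

    Unlike ``annotate_cds`` this does not re-select an ORF, so premature
    stops are reported rather than defining the CDS end.
    """
    seq = sequence.upper()
    usable = len(seq) - len(seq) % 3
    protein = translate(seq[:usable])
    stops = find_premature_stops(seq)
    premature = stops[:-1] if stops and stops[-1][1] == usable else stops
    full, rounded = composition(protein.replace("*", "") or protein)
    return GeneAnnotation(
        cds_start=1,
        cds_end=usable,
        protein=protein,
        premature_stops=premature,
        composition=full,
        composition_int=rounded,
        mol_weight_kda=0.0,
    )


def scan_promoter(upstream: str, motifs: list[str], window_nt: int | None = None) -> list[MotifHit]:
    """Exact degenerate (IUPAC) motif scan of an upstream region.

    ``upstream`` is given 5'->3' and ends immediately before the start codon.
    Only matches whose 3' end lies within ``window_nt`` of the start codon are
    reported.  An empty list for a motif means it is absent from the window.
    """
    seq = upstream.upper()
    window = len(seq) if window_nt is None else window_nt
    if window > len(seq):
        raise ValueError("window_nt exceeds the upstream sequence")
    hits = []
    for motif in motifs:
        for pos in iupac.find_all(motif, seq):
            dist = len(seq) - (pos + len(motif))
            if dist <= window:
                hits.append(MotifHit(motif=motif, position_upstream=dist))
    hits.sort(key=lambda h: (h.position_upstream, h.motif))
    return hits
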