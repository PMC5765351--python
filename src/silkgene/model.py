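"""Core record types shared across the pipeline.

Coordinates follow the reporting convention used throughout the package:
1-based, inclusive, forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class LocusTruth:
    """Generator-side ground truth attached to a synthetic locus.

    Intervals are CDS-relative, 1-based inclusive.  `frameshifts` records
    injected single-base indels as (cds_position, kind, base) where kind is
    'ins' (extra base present in the sequence) or 'del' (base removed).
    """

    nterm_len: int = 0
    cterm_len: int = 0
    unit_len: int = 0
    repeat_intervals: list[tuple[int, int]] = field(default_factory=list)
    frameshifts: list[tuple[int, str, str]] = field(default_factory=list)
    is_pseudogene: bool = False

    @property
    def repeat_region(self) -> tuple[int, int] | None:
        if not self.repeat_intervals:
            return None
        return (self.repeat_intervals[0][0], self.repeat_intervals[-1][1])


@dataclass
class Locus:
    """A genomic segment carrying one (possibly pseudogenized) gene copy.

    `sequence` is the full segment: upstream promoter region, then the
    coding body, then (for functional genes) the stop codon and a short
    downstream tail.  `cds_start`/`cds_end` delimit the body on `sequence`
    (1-based inclusive; the stop codon is excluded, matching the
    start-through-last-sense-codon length convention).
    """

    name: str
    sequence: str
    cds_start: int
    cds_end: int
    truth: LocusTruth | None = None

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start - 1 : self.cds_end]

    @property
    def upstream(self) -> str:
        """Sequence 5' of the start codon, ending immediately before the A of ATG."""
        return self.sequence[: self.cds_start - 1]

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start + 1


@dataclass
class DiploidLocus:
    name: str
    alleles: tuple[Locus, Locus]


@dataclass
class DiploidGenome:
    """One individual: a set of gene loci, each with `ploidy` allele copies."""

    species_label: str
    loci: list[DiploidLocus]
    ploidy: int = 2
    allele_divergence: float = 0.0

    def __post_init__(self) -> None:
        for locus in self.loci:
            if len(locus.alleles) != self.ploidy:
                raise ValueError(
                    f"locus {locus.name} has {len(locus.alleles)} alleles, expected {self.ploidy}"
                )


@dataclass
class CloneRead:
    """One sequenced cloned PCR amplicon."""

    clone_id: str
    species_label: str
    region: str  # 'five_prime' | 'three_prime'
    sequence: str
    # generator truth, absent for real data
    source_locus: str | None = None
    source_allele: int | None = None
    n_errors: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"clone {self.clone_id}: empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"clone {self.clone_id}: non-nucleotide characters {sorted(bad)}")
        if self.region not in ("five_prime", "three_prime"):
            raise ValueError(f"clone {self.clone_id}: unknown region {self.region!r}")
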