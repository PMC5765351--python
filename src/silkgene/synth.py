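"""Synthetic spidroin-like gene, genome, and clone-read generator.

Spidroin (spider silk protein) genes are long single-exon genes: a short
nonrepetitive N-terminal-coding block, a large central array of near-identical
in-frame tandem repeats (hundreds of nt each, homogenized by concerted
evolution), and a short C-terminal-coding block, with a TATA-box bearing
promoter region upstream.  This module generates such genes with known ground
truth, derives pseudogenes from them by repeat-block deletion plus frameshift
injection, assembles diploid multi-locus genomes, and simulates cloned PCR
amplicons with per-base polymerase error — so every downstream analysis stage
can be exercised against planted truth.

All generation is deterministic given the top-level seed; per-locus and
per-clone streams are split hierarchically with numpy SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import iupac
from .model import CloneRead, DiploidGenome, DiploidLocus, Locus, LocusTruth

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
BASES = "ACGT"

#: Residue frequencies used for coding-sequence sampling.  Concentrated on
#: alanine, serine and glutamine with little glycine, the hallmark tubuliform
#: spidroin composition; the remaining mass is spread over residues whose
#: average masses place the full-length predicted protein near the expected
#: ~93 Da mean residue mass.
RESIDUE_WEIGHTS: dict[str, float] = {
    "A": 0.26, "S": 0.28, "G": 0.08, "Q": 0.12, "T": 0.09,
    "L": 0.04, "V": 0.04, "F": 0.03, "Y": 0.02, "N": 0.02,
    "D": 0.01, "E": 0.01,
}

_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "S": ("TCT", "TCC", "TCA", "AGC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "Q": ("CAA", "CAG"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "L": ("CTT", "CTC", "CTA", "TTG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "F": ("TTT", "TTC"),
    "Y": ("TAT", "TAC"),
    "N": ("AAT", "AAC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
}

TATA_MOTIF = "TATAAA"
CACG_MOTIF = "CACG"
#: nt between the motif's 3' end and the A of ATG
TATA_OFFSET = 60
CACG_OFFSET = 80


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class SpidroinModel:
    """Architecture of one synthetic spidroin gene.

    Lengths are nucleotides; `repeat_len_nt`, `nterm_len_nt`, `cterm_len_nt`
    and `final_repeat_len_nt` must be divisible by 3 so the whole CDS stays in
    frame.  `intra_repeat_divergence` is the per-site substitution probability
    applied independently to each repeat copy relative to the master unit
    (0 = perfect homogenization).
    """

    n_repeats: int = 16
    repeat_len_nt: int = 540
    final_repeat_len_nt: int | None = None  # None = full-length last unit
    intra_repeat_divergence: float = 0.0
    nterm_len_nt: int = 462
    cterm_len_nt: int = 531
    residue_bias: dict[str, float] | None = None  # None = RESIDUE_WEIGHTS
    upstream_len_nt: int = 300
    has_tata: bool = True
    has_cacg: bool = False
    seed: int = 0

    def validate(self) -> None:
        for label, val in (("repeat_len_nt", self.repeat_len_nt),
                           ("nterm_len_nt", self.nterm_len_nt),
                           ("cterm_len_nt", self.cterm_len_nt)):
            if val % 3 != 0 or val <= 0:
                raise ValueError(f"{label} must be positive and divisible by 3, got {val}")
        if self.nterm_len_nt < 3:
            raise ValueError("nterm_len_nt must include the start codon")
        if not 0.0 <= self.intra_repeat_divergence <= 1.0:
            raise ValueError("intra_repeat_divergence must lie in [0, 1]")
        if self.n_repeats < 1:
            raise ValueError("model must produce at least one repeat unit")
        if self.final_repeat_len_nt is not None:
            if not 0 < self.final_repeat_len_nt <= self.repeat_len_nt:
                raise ValueError("final_repeat_len_nt must lie in (0, repeat_len_nt]")
            if self.final_repeat_len_nt % 3 != 0:
                raise ValueError("final_repeat_len_nt must be divisible by 3")
        if self.upstream_len_nt < TATA_OFFSET + len(TATA_MOTIF) and self.has_tata:
            raise ValueError("upstream too short to place the TATA box")
        if self.upstream_len_nt < CACG_OFFSET + len(CACG_MOTIF) and self.has_cacg:
            raise ValueError("upstream too short to place the CACG motif")


def full_scale_model(seed: int = 0, intra_repeat_divergence: float = 0.0) -> SpidroinModel:
    """The full-scale architecture: 16 repeats of 540 nt, the last truncated
    to 375 nt, with 993 nt of terminal-coding sequence (CDS = 9468 nt)."""
    return SpidroinModel(
        n_repeats=16, repeat_len_nt=540, final_repeat_len_nt=375,
        intra_repeat_divergence=intra_repeat_divergence,
        nterm_len_nt=462, cterm_len_nt=531, seed=seed,
    )


@dataclass(frozen=True)
class PseudogenizationSpec:
    """How to derive a pseudogene from a functional gene.

    The repeat array is collapsed to its edges — the 5' `retained_5prime_repeat_nt`
    of the first unit joined directly to the 3' `retained_3prime_repeat_nt` of
    the last — emulating repeat loss via unequal crossing over.  The retained
    sequence then diverges by substitution (`terminal_divergence` on the 5'
    side, `terminal_divergence_3prime` on the 3' side, defaulting to the same
    value) and acquires `n_frameshifts` single-base indels.
    """

    retained_5prime_repeat_nt: int = 286
    retained_3prime_repeat_nt: int = 84
    n_frameshifts: int = 2
    terminal_divergence: float = 0.0
    terminal_divergence_3prime: float | None = None
    drop_tata: bool = True

    #: frameshifts never land in the first nt of the body, so the start codon
    #: and early frame survive and the lesion looks like a recognizable
    #: pseudogene rather than a destroyed ORF
    FRAMESHIFT_EXCLUSION_NT = 30

    def validate(self, gene_truth: LocusTruth) -> None:
        if self.n_frameshifts < 0:
            raise ValueError("n_frameshifts must be >= 0")
        if self.retained_5prime_repeat_nt < 0 or self.retained_3prime_repeat_nt < 0:
            raise ValueError("retained repeat lengths must be >= 0")
        first = gene_truth.repeat_intervals[0]
        last = gene_truth.repeat_intervals[-1]
        first_len = first[1] - first[0] + 1
        last_len = last[1] - last[0] + 1
        if self.retained_5prime_repeat_nt > first_len:
            raise ValueError("retained_5prime_repeat_nt exceeds the first repeat")
        if self.retained_3prime_repeat_nt > last_len:
            raise ValueError("retained_3prime_repeat_nt exceeds the last repeat")
        if len(gene_truth.repeat_intervals) == 1:
            if self.retained_5prime_repeat_nt + self.retained_3prime_repeat_nt > first_len:
                raise ValueError("retained pieces overlap within the single repeat")


@dataclass(frozen=True)
class CloneSimSpec:
    """Parameters of one simulated clone-and-sequence survey."""

    region: str  # 'five_prime' | 'three_prime'
    n_clones: int = 20
    taq_error_rate: float = 0.001
    primer_5: str | None = None  # IUPAC; designed from the genome if None
    primer_3: str | None = None

    def validate(self) -> None:
        if self.region not in ("five_prime", "three_prime"):
            raise ValueError(f"unknown region {self.region!r}")
        if not 0.0 <= self.taq_error_rate <= 0.01:
            raise ValueError("taq_error_rate must lie in [0, 0.01]")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")


# ---------------------------------------------------------------------------
# low-level sequence sampling


def _spawn(seed_or_ss, n: int) -> list[np.random.Generator]:
    ss = seed_or_ss if isinstance(seed_or_ss, np.random.SeedSequence) else np.random.SeedSequence(seed_or_ss)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def _sample_codons(n: int, rng: np.random.Generator, weights: dict[str, float]) -> str:
    """n codons whose residue counts follow the weight table by quota
    (largest-remainder apportionment), in random order.

    Quota sampling keeps the realized composition at the table values even
    for short blocks — important because the repeat array amplifies its
    master unit's composition across the whole protein.
    """
    residues = list(weights)
    probs = np.asarray([weights[r] for r in residues], dtype=float)
    probs = probs / probs.sum()
    ideal = probs * n
    counts = np.floor(ideal).astype(int)
    short = n - counts.sum()
    for idx in np.argsort(-(ideal - counts))[:short]:
        counts[idx] += 1
    pool = [res for res, c in zip(residues, counts) for _ in range(c)]
    rng.shuffle(pool)
    out = []
    for res in pool:
        codons = _CODONS[res]
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def mutate_coding(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitutions that never create an in-frame stop codon.

    The sequence is read in frame from its first base.
    """
    if rate <= 0.0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for pos in hits:
        old = chars[pos]
        codon_start = (pos // 3) * 3
        candidates = []
        for base in BASES:
            if base == old:
                continue
            codon = chars[codon_start:codon_start + 3]
            codon[pos - codon_start] = base
            if codon_start + 3 <= len(chars) and "".join(codon) in STOP_CODONS:
                continue
            candidates.append(base)
        if candidates:
            chars[pos] = candidates[rng.integers(len(candidates))]
    return "".join(chars)


def mutate_plain(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Unconstrained per-site substitutions (noncoding or selection-free sequence)."""
    if rate <= 0.0 or not seq:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for pos in hits:
        others = [b for b in BASES if b != chars[pos]]
        chars[pos] = others[rng.integers(3)]
    return "".join(chars)


def _scrub_motifs(seq: str, rng: np.random.Generator,
                  keep: dict[str, int] | None = None) -> str:
    """Remove accidental promoter-motif occurrences by point mutation.

    `keep` maps motif -> 0-based start of the one planted occurrence to
    preserve.  Both TATAAA and CACG are scrubbed everywhere else so motif
    presence in the upstream region is exactly what the model flags say;
    ATG is scrubbed too so the planted start codon opens the longest ORF.
    """
    keep = keep or {}
    chars = list(seq)
    for _ in range(200):  # bounded; each pass fixes at least one occurrence
        dirty = False
        for motif in (TATA_MOTIF, CACG_MOTIF, "ATG"):
            for pos in iupac.find_all(motif, "".join(chars)):
                if keep.get(motif) == pos:
                    continue
                # also protect positions overlapping a kept motif
                if any(k <= pos < k + len(m) for m, k in keep.items()):
                    continue
                target = pos + int(rng.integers(len(motif)))
                others = [b for b in BASES if b != chars[target]]
                chars[target] = others[rng.integers(3)]
                dirty = True
        if not dirty:
            return "".join(chars)
    raise RuntimeError("failed to scrub accidental promoter motifs")


def _build_upstream(model: SpidroinModel, rng: np.random.Generator) -> str:
    seq = "".join(BASES[i] for i in rng.integers(4, size=model.upstream_len_nt))
    chars = list(seq)
    keep: dict[str, int] = {}
    L = model.upstream_len_nt
    if model.has_tata:
        start = L - TATA_OFFSET - len(TATA_MOTIF)
        chars[start:start + len(TATA_MOTIF)] = TATA_MOTIF
        keep[TATA_MOTIF] = start
    if model.has_cacg:
        start = L - CACG_OFFSET - len(CACG_MOTIF)
        chars[start:start + len(CACG_MOTIF)] = CACG_MOTIF
        keep[CACG_MOTIF] = start
    return _scrub_motifs("".join(chars), rng, keep=keep)


# ---------------------------------------------------------------------------
# gene generation


def generate_gene(model: SpidroinModel, name: str = "synthetic_gene",
                  downstream_len_nt: int = 60) -> Locus:
    """Build one functional spidroin-like locus with ground truth attached.

    The CDS is N-terminal block + tandem repeat array (last unit optionally
    3'-truncated) + C-terminal block; it begins with ATG, contains no internal
    in-frame stop, and is followed on the locus by a TAA stop codon and a
    short downstream tail.  Deterministic given ``model.seed``.
    """
    model.validate()
    weights = model.residue_bias or RESIDUE_WEIGHTS
    rng_up, rng_nterm, rng_unit, rng_copies, rng_cterm, rng_down = _spawn(model.seed, 6)

    upstream = _build_upstream(model, rng_up)
    nterm = "ATG" + _sample_codons(model.nterm_len_nt // 3 - 1, rng_nterm, weights)
    master = _sample_codons(model.repeat_len_nt // 3, rng_unit, weights)

    copy_rngs = _spawn(np.random.SeedSequence(model.seed).spawn(7)[6], model.n_repeats)
    units = [mutate_coding(master, model.intra_repeat_divergence, r) for r in copy_rngs]
    if model.final_repeat_len_nt is not None:
        units[-1] = units[-1][: model.final_repeat_len_nt]
    cterm = _sample_codons(model.cterm_len_nt // 3, rng_cterm, weights)

    cds = nterm + "".join(units) + cterm
    downstream = "".join(BASES[i] for i in rng_down.integers(4, size=downstream_len_nt))

    intervals = []
    pos = model.nterm_len_nt
    for unit in units:
        intervals.append((pos + 1, pos + len(unit)))
        pos += len(unit)
    truth = LocusTruth(
        nterm_len=model.nterm_len_nt,
        cterm_len=model.cterm_len_nt,
        unit_len=model.repeat_len_nt,
        repeat_intervals=intervals,
    )
    sequence = upstream + cds + "TAA" + downstream
    return Locus(
        name=name,
        sequence=sequence,
        cds_start=len(upstream) + 1,
        cds_end=len(upstream) + len(cds),
        truth=truth,
    )


def plant_frameshift_artifacts(gene: Locus, n_deletions: int, n_insertions: int,
                               seed: int) -> tuple[Locus, list[tuple[int, str, str]]]:
    """Inject isolated single-base indels into distinct repeat units.

    Emulates raw-assembly frameshift artifacts in the repetitive region: each
    event sits in its own unit, away from unit edges.  Returns the damaged
    locus plus the planted events as (cds_position_1based, kind, base), where
    kind 'del' means the base was removed and 'ins' means an extra base was
    inserted at that output position.
    """
    truth = gene.truth
    if truth is None or not truth.repeat_intervals:
        raise ValueError("gene must carry repeat ground truth")
    n_events = n_deletions + n_insertions
    full_units = [iv for iv in truth.repeat_intervals
                  if iv[1] - iv[0] + 1 == truth.unit_len]
    if n_events > len(full_units):
        raise ValueError("more events than full-length repeat units")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = rng.choice(len(full_units), size=n_events, replace=False)
    kinds = ["del"] * n_deletions + ["ins"] * n_insertions
    events = []
    margin = 20
    for unit_idx, kind in zip(chosen, kinds):
        lo, hi = full_units[unit_idx]
        pos = int(rng.integers(lo + margin, hi - margin))  # 1-based CDS position
        if kind == "ins":
            base = BASES[rng.integers(4)]
        else:
            base = gene.cds[pos - 1]
        events.append((pos, kind, base))
    events.sort()
    chars = list(gene.cds)
    for pos, kind, base in reversed(events):  # right-to-left keeps positions valid
        if kind == "del":
            del chars[pos - 1]
        else:
            chars.insert(pos - 1, base)
    damaged_cds = "".join(chars)
    sequence = gene.upstream + damaged_cds + gene.sequence[gene.cds_end:]
    damaged = Locus(
        name=gene.name + "_raw",
        sequence=sequence,
        cds_start=gene.cds_start,
        cds_end=gene.cds_start + len(damaged_cds) - 1,
        truth=replace(truth, frameshifts=list(events)),
    )
    return damaged, events


def pseudogenize(gene: Locus, spec: PseudogenizationSpec, seed: int) -> Locus:
    """Derive a pseudogene locus: repeat array collapsed to its edges,
    terminal segments diverged by substitution, frameshifts injected, and
    (optionally) the TATA box erased from the upstream region."""
    truth = gene.truth
    if truth is None or not truth.repeat_intervals:
        raise ValueError("gene must carry repeat ground truth")
    spec.validate(truth)
    rng5, rng3, rng_up, rng_fs, rng_down = _spawn(seed, 5)

    cds = gene.cds
    first = truth.repeat_intervals[0]
    last = truth.repeat_intervals[-1]
    r5 = cds[first[0] - 1 : first[0] - 1 + spec.retained_5prime_repeat_nt]
    r3 = cds[last[1] - spec.retained_3prime_repeat_nt : last[1]] if spec.retained_3prime_repeat_nt else ""
    nterm = cds[: truth.nterm_len]
    cterm = cds[last[1]:]

    d5 = spec.terminal_divergence
    d3 = spec.terminal_divergence_3prime if spec.terminal_divergence_3prime is not None else d5
    five_part = mutate_plain(nterm + r5, d5, rng5)
    three_part = mutate_plain(r3 + cterm, d3, rng3)
    body = five_part + three_part

    events: list[tuple[int, str, str]] = []
    if spec.n_frameshifts:
        lo = spec.FRAMESHIFT_EXCLUSION_NT
        if len(body) - lo <= spec.n_frameshifts:
            raise ValueError("body too short for requested frameshifts")
        positions = sorted(
            int(p) + lo + 1  # 1-based body positions
            for p in rng_fs.choice(len(body) - lo, size=spec.n_frameshifts, replace=False)
        )
        chars = list(body)
        for pos in reversed(positions):
            if rng_fs.random() < 0.5:
                events.append((pos, "del", chars[pos - 1]))
                del chars[pos - 1]
            else:
                base = BASES[rng_fs.integers(4)]
                events.append((pos, "ins", base))
                chars.insert(pos - 1, base)
        body = "".join(chars)
        events.sort()

    upstream = mutate_plain(gene.upstream, d5, rng_up)
    if spec.drop_tata:
        upstream = _scrub_motifs(upstream, rng_up)
    tail = mutate_plain(gene.sequence[gene.cds_end:], d3, rng_down)

    return Locus(
        name=gene.name + "_psi",
        sequence=upstream + body + tail,
        cds_start=len(upstream) + 1,
        cds_end=len(upstream) + len(body),
        truth=LocusTruth(
            nterm_len=truth.nterm_len,
            cterm_len=truth.cterm_len,
            unit_len=truth.unit_len,
            repeat_intervals=[],
            frameshifts=events,
            is_pseudogene=True,
        ),
    )


# ---------------------------------------------------------------------------
# diploid genomes and clone simulation


def make_diploid_genome(species_label: str, model: SpidroinModel, n_loci: int = 2,
                        locus_divergence: float = 0.05, allele_divergence: float = 0.03,
                        seed: int = 0) -> DiploidGenome:
    """A diploid individual carrying ``n_loci`` paralogous gene copies.

    Each locus diverges from a common base gene by coding-safe substitution at
    ``locus_divergence``; its second allele diverges from the first at
    ``allele_divergence``.  The allele default (3%) keeps haplotypes reliably
    below the 99%-identity variant-merging threshold over amplicon-sized
    windows — the clone survey can only count variants it can distinguish.
    Substitution-only divergence keeps coordinates identical across all
    copies, which is what guarantees the degenerate primers a unique binding
    site per allele.
    """
    if not 1 <= n_loci:
        raise ValueError("n_loci must be >= 1")
    ss = np.random.SeedSequence(seed)
    base_seed = int(ss.generate_state(1)[0] % (2**31))
    base = generate_gene(replace(model, seed=base_seed), name=f"{species_label}_base")
    loci = []
    locus_ss = ss.spawn(n_loci)
    for i in range(n_loci):
        rng_locus, rng_allele = (np.random.default_rng(c) for c in locus_ss[i].spawn(2))
        name = f"{species_label}_L{i + 1}"
        a0 = _derive_copy(base, locus_divergence, rng_locus, f"{name}_a1")
        a1 = _derive_copy(a0, allele_divergence, rng_allele, f"{name}_a2")
        loci.append(DiploidLocus(name=name, alleles=(a0, a1)))
    return DiploidGenome(species_label=species_label, loci=loci,
                         allele_divergence=allele_divergence)


def make_species_panel(species_plan: dict[str, int], model: SpidroinModel,
                       species_divergence: float = 0.08,
                       locus_divergence: float = 0.05,
                       allele_divergence: float = 0.03,
                       seed: int = 0) -> dict[str, DiploidGenome]:
    """Diploid genomes for several species descended from one ancestral gene.

    All species' gene copies are homologs of a single generated ancestor;
    each species' founder diverges from it at ``species_divergence``, loci
    within a species at ``locus_divergence`` and alleles at
    ``allele_divergence`` — so gene copies are more similar within a species
    than between species, the concerted-evolution signature the
    species-contrast statistic measures.
    """
    ss = np.random.SeedSequence(seed)
    anc_seed = int(ss.generate_state(1)[0] % (2**31))
    ancestor = generate_gene(replace(model, seed=anc_seed), name="ancestor")
    panel: dict[str, DiploidGenome] = {}
    children = ss.spawn(len(species_plan))
    for child, (label, n_loci) in zip(children, species_plan.items()):
        rng_sp = np.random.default_rng(child)
        founder = _derive_copy(ancestor, species_divergence, rng_sp, f"{label}_founder")
        loci = []
        for i in range(n_loci):
            rng_locus = np.random.default_rng(child.spawn(1)[0])
            name = f"{label}_L{i + 1}"
            a0 = _derive_copy(founder, locus_divergence, rng_locus, f"{name}_a1")
            a1 = _derive_copy(a0, allele_divergence, rng_locus, f"{name}_a2")
            loci.append(DiploidLocus(name=name, alleles=(a0, a1)))
        panel[label] = DiploidGenome(species_label=label, loci=loci,
                                     allele_divergence=allele_divergence)
    return panel


def _derive_copy(locus: Locus, rate: float, rng: np.random.Generator, name: str) -> Locus:
    cds = mutate_coding(locus.cds, rate, rng)
    upstream = mutate_plain(locus.upstream, rate, rng)
    tail = mutate_plain(locus.sequence[locus.cds_end:], rate, rng)
    return Locus(
        name=name,
        sequence=upstream + cds + tail,
        cds_start=len(upstream) + 1,
        cds_end=len(upstream) + len(cds),
        truth=locus.truth,
    )


def design_primers(genome: DiploidGenome, region: str, primer_len: int = 20) -> tuple[str, str]:
    """Degenerate primer pair for a region, built from the genome itself.

    The binding sites are fixed coordinates anchored on nonrepetitive
    sequence: the 5' amplicon runs from the start codon across the N-terminal
    block into the first repeat; the 3' amplicon from the end of the last
    repeat through the C-terminal block.  Each column takes the IUPAC code of
    the union of bases observed across every allele of every locus, so each
    primer matches every allele exactly once by construction.
    """
    truth = genome.loci[0].alleles[0].truth
    if truth is None or not truth.repeat_intervals:
        raise ValueError("genome loci must carry repeat ground truth")
    junction_in = 12  # nt of repeat included in the junction-spanning site
    if region == "five_prime":
        site5 = (0, primer_len)
        j = truth.nterm_len
        site3 = (j - (primer_len - junction_in), j + junction_in)
    elif region == "three_prime":
        j = truth.repeat_intervals[-1][1]
        site5 = (j - junction_in, j + (primer_len - junction_in))
        cds_len = genome.loci[0].alleles[0].cds_len
        site3 = (cds_len - primer_len, cds_len)
    else:
        raise ValueError(f"unknown region {region!r}")

    def degenerate(start: int, end: int) -> str:
        cols = [set() for _ in range(end - start)]
        for locus in genome.loci:
            for allele in locus.alleles:
                window = allele.cds[start:end]
                for i, base in enumerate(window):
                    cols[i].add(base)
        return "".join(iupac.code_for(c) for c in cols)

    return degenerate(*site5), degenerate(*site3)


def _amplicon(allele: Locus, primer_5: str, primer_3: str) -> str:
    hits5 = iupac.find_all(primer_5, allele.sequence)
    hits3 = iupac.find_all(primer_3, allele.sequence)
    if len(hits5) != 1 or len(hits3) != 1:
        raise ValueError(
            f"primers must match allele {allele.name} exactly once "
            f"(got {len(hits5)} x {len(hits3)})"
        )
    start, end = hits5[0], hits3[0] + len(primer_3)
    if end <= start:
        raise ValueError(f"primer orientation inverted on allele {allele.name}")
    return allele.sequence[start:end]


def simulate_clones(genome: DiploidGenome, spec: CloneSimSpec, seed: int) -> list[CloneRead]:
    """Simulate cloned-and-sequenced PCR products from one individual.

    Each clone is the amplicon of one uniformly chosen (locus, allele) with
    independent per-base substitution errors at ``taq_error_rate``; the true
    source is recorded on the read for downstream oracles.
    """
    spec.validate()
    primer_5, primer_3 = (spec.primer_5, spec.primer_3)
    if primer_5 is None or primer_3 is None:
        primer_5, primer_3 = design_primers(genome, spec.region)
    amplicons = {
        (locus.name, a): _amplicon(locus.alleles[a], primer_5, primer_3)
        for locus in genome.loci for a in range(genome.ploidy)
    }
    clone_rngs = _spawn(seed, spec.n_clones)
    pick_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(spec.n_clones + 1)[-1])
    reads = []
    for i, rng in enumerate(clone_rngs):
        locus = genome.loci[pick_rng.integers(len(genome.loci))]
        allele = int(pick_rng.integers(genome.ploidy))
        template = amplicons[(locus.name, allele)]
        errs = np.flatnonzero(rng.random(len(template)) < spec.taq_error_rate)
        chars = list(template)
        for pos in errs:
            others = [b for b in BASES if b != chars[pos]]
            chars[pos] = others[rng.integers(3)]
        tag = "5p" if spec.region == "five_prime" else "3p"
        reads.append(CloneRead(
            clone_id=f"{genome.species_label}_{tag}_c{i + 1:03d}",
            species_label=genome.species_label,
            region=spec.region,
            sequence="".join(chars),
            source_locus=locus.name,
            source_allele=allele,
            n_errors=int(len(errs)),
        ))
    return reads
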