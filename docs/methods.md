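# Methods

`silkgene` re-implements, as a tested pipeline over synthetic data, the
sequence analyses used to characterize a tubuliform spidroin (TuSp1) gene
family: single-exon ORF annotation, tandem-repeat decomposition with
majority-rule consensus frameshift resolution, pseudogene diagnosis by
frameshift-tolerant paralog comparison, promoter-motif scanning, and
clone-based variant diagnosis with ploidy-aware minimum-locus inference.
This note records the models, parameter choices, numerical conventions and
known limitations.

## The synthetic gene model

Spidroin genes are long single-exon genes: a nonrepetitive N-terminal-coding
block, a central array of near-identical in-frame tandem repeats, and a
nonrepetitive C-terminal-coding block, with a TATA-box-bearing promoter
region upstream. The generator (`silkgene.synth`) builds such genes with
ground truth attached.

**Architecture defaults.** The full-scale model is 16 repeats of 540 nt with
the last truncated to 375 nt (a 3′ truncation of the final unit, not an
independent short unit), plus 993 nt of terminal-coding sequence, giving a
9468-nt CDS and a 3156-residue protein. The 993 nt terminal total is split
462 nt N-terminal / 531 nt C-terminal (154 and 177 codons, within the range
typical of spidroin terminal domains); the split is a free parameter of the
model. Reduced architectures (e.g. 5–6 repeats of 120–150 nt) are used
wherever full scale adds only runtime.

**Codon sampling.** Coding sequence is drawn codon-wise from a residue
weight table concentrated on alanine (26%), serine (28%) and glutamine
(12%) with little glycine (8%); the remaining residues are weighted so the
mean residue mass lands near 92.8 Da, i.e. a full-length predicted protein
of ≈293 kDa. Sampling is by quota (largest-remainder apportionment, then
shuffle) rather than i.i.d. draws: the repeat array amplifies its master
unit's composition 16-fold, so i.i.d. sampling of the 180-codon master unit
would make the realized whole-protein composition fluctuate by ±3
percentage points. Quota sampling pins it at the table values. Terminal
blocks use the same table — a simplification; real spidroin terminal
domains have their own composition.

**Repeat homogenization.** Each repeat copy is derived from one master unit
by independent per-site substitution at `intra_repeat_divergence`
(0 = perfect homogenization; the full-scale demonstrations use 0.005,
giving ≈99% mean pairwise unit identity). Substitutions in coding sequence
are resampled if they would create an in-frame stop. The generator does not
model the structured homogenization gradient seen in real arrays (e.g. a
block of perfectly identical 5′ units); every copy diverges independently.

**Promoter region.** TATAAA is planted with its 3′ end exactly 60 nt
upstream of the ATG when `has_tata` is set (fixed for testability; the
biological spacing is approximate), CACG 80 nt upstream when `has_cacg` is
set. Accidental occurrences of either motif — and of ATG, so the planted
start codon always opens the longest ORF — are scrubbed from the upstream
region by point mutation.

**Pseudogenization.** A pseudogene is derived by collapsing the repeat
array to its edges (defaults: 286 nt of the first repeat joined to 84 nt of
the last, emulating repeat loss through unequal crossing over), mutating
the retained sequence by substitution, and injecting 1-nt frameshift
indels at random positions outside the first 30 nt (so the start codon and
early frame survive and the lesion resembles a recognizable pseudogene).
The whole retained sequence is the two terminal segments, so
`terminal_divergence` applies to all of it; a separate
`terminal_divergence_3prime` (default mirrors the 5′ value) exists because
real paralog pairs diverge asymmetrically between the 5′ and 3′ segments.
Pseudogene mutation is unconstrained (stops allowed): the sequence is free
of selection.

**Diploid genomes and the species panel.** A genome carries 1–3 loci, each
with two alleles; loci diverge from a common base gene at 5% and alleles at
3%, substitution-only so coordinates stay identical across copies (which is
what lets degenerate primers match every allele exactly once by
construction). The 3% allele default keeps haplotypes reliably below the
99%-identity variant-merging threshold over amplicon-sized windows: the
clone survey can only count variants it can distinguish, so detectably
distinct alleles are part of the survey's design conditions. A multi-species
panel descends every genome from one ancestral gene (species founders at 8%
divergence), producing the within-species > between-species similarity
structure that the species-contrast statistic measures.

**Clone simulation.** Degenerate primers are designed from the genome
itself: each binding site is a fixed-coordinate window anchored on
nonrepetitive sequence (the 5′ amplicon runs from the start codon across
the N-terminal block 12 nt into the first repeat; the 3′ amplicon from
12 nt inside the last repeat's end through the C-terminal block), with each
column the IUPAC code of the union of bases across all alleles. Primer
sites anchored inside the repeat array would not be unique — every repeat
copy carries near-identical sequence — hence the junction anchoring. Each
clone is the amplicon of a uniformly chosen (locus, allele) with
independent per-base substitution errors at the polymerase error rate
(default 10⁻³/base); true sources are recorded for test oracles. Indel
polymerase errors and chromatogram-level artifacts are not modeled.

## Annotation conventions

* CDS length runs from the start codon through the last sense codon, stop
  excluded — the convention under which 9468 nt encodes exactly 3156
  residues. All reported coordinates are 1-based inclusive.
* ORF selection: longest ATG-initiated ORF, forward strand only (input
  contigs are oriented), ties to the leftmost start; an ORF must be
  terminated by a stop codon inside the sequence.
* Premature stops are reported for a *fixed-frame* reading (frame 1 from
  the first base), as used when reading a pseudogene body from its
  inherited ATG; coordinates are CDS-relative.
* Molecular weight uses average (not monoisotopic) residue masses — the
  convention behind conventional kDa predictions. Composition is reported
  at full precision and as round-half-up integers (the form composition
  tables print).
* Motif scanning is exact-degenerate IUPAC matching (no mismatches);
  `position_upstream` counts nucleotides between the motif's 3′ end and the
  A of ATG.

## Percent identity

One definition everywhere: matching columns / alignment columns × 100,
internal gap columns counting against identity, terminal (overhang) gap
columns excluded. Scored alignments use a fixed scheme — match +1, mismatch
−1, gap open −4, gap extend −1 — via Biopython's `PairwiseAligner`; for the
near-identical sequences this package compares, identity is insensitive to
the scheme, but fixing it guarantees determinism, and every report that
prints an identity also records the parameters. Equal-length near-identical
pairs take a Hamming fast path (the optimal global alignment of such pairs
is gapless; the fast path is only trusted when ≥90% of positions already
match). Edit-distance alignments (edlib) are used where unit-cost indel
placement is what matters: unit chaining and frameshift resolution.

## Repeat decomposition

`detect_repeats` works in stages:

1. **Period.** Modal spacing between recurrences of shared 12-mers,
   restricted to the allowed unit-length range.
2. **Coarse region.** The longest stretch where `seq[i] == seq[i+P]` at
   high smoothed density.
3. **Phase.** A representative unit (the medoid of rigid period-width
   slices) is anchored by infix edit alignment near the region start; a
   leftward walk then finds the array's true 5′ end. The walk crosses clean
   periods whole and recognizes artifact indels (a 1–2 nt shift after which
   the lattice resumes), so an indel inside the first repeat does not strand
   the boundary mid-array.
4. **Chaining.** Unit boundaries are walked 5′→3′ with a prefix edit
   alignment per unit, so a unit carrying an isolated indel keeps correct
   boundaries. When plain mismatch counting explains a unit as well as the
   edit alignment (no indel evidence), the chain steps exactly one period —
   this removes ±1 boundary wobble from edit-path ties at nonzero
   divergence.
5. **Truncated final unit.** The last unit may be 3′-truncated; its length
   maximizes `matches(T) − 0.75·T` against the consensus prefix, allowing a
   ±2 nt shift of the preceding chain end.
6. **Second pass.** The template is rebuilt as the majority consensus of
   the chained full-length units (cancelling the medoid copy's private
   mutations) and phase/chaining re-run once.

The boundary score penalty (0.75/base) sits between the chance per-base
match rate of repeat sequence against the similarly codon-biased flanks
(≈1/3) and the in-repeat match rate at the divergences handled (≥0.98).
Array edges remain intrinsically ambiguous at the ±1–2 nt scale whenever
flank sequence happens to continue the repeat pattern; on the benchmark
built into the acceptance checks (60 genes, divergence 0–2%, with and
without a truncated final unit) boundaries are recovered within ±3 nt in
≥95% of genes, exactly at zero divergence in most.

"Mean pairwise identity" averages over unordered pairs of full-length units
(the truncated unit is excluded from the modal-length estimate and the
matrix); a second statistic including the truncated unit over its aligned
span is also reported, since either reading of "average pairwise identity"
is defensible. Unit numbering is 1-based, 5′→3′.

**Consensus.** Column-wise majority over stacked units (equal lengths stack
directly; unequal ones are projected onto the first unit's coordinates
through an edit alignment); column ties break to the most 5′ unit's base,
making the consensus deterministic.

**Frameshift resolution.** Each unit is aligned to the consensus; indels of
≤2 nt are corrected to the consensus state (an *addition* inserts the
consensus base the unit lacks; a *deletion* removes the unit's extra base)
unless the same indel appears at the same consensus column in at least half
the units — then it is genuine sequence. Whole-unit loss is likewise left
alone (the unit count drops instead). Two spurious patterns cancel
pairwise: a chained boundary one base off (extra base in one unit, missing
base in its neighbor — a no-op pair), and two nearby substitutions inside
one unit that tie with an insertion+deletion edit path. Corrections are
reported with 1-based positions and are idempotent: resolving the corrected
sequence yields an empty report. Within a homopolymer the reinserted base's
position is ambiguous; the corrected sequence is exact regardless.

## Paralog comparison and classification

Segment discovery is anchored on the gene's known architecture — the
N-terminal block plus the first repeat, and the last repeat plus the
C-terminal block — rather than unconstrained local alignment, which on a
repeat array would produce spurious repeat-to-repeat matches. The two
blocks are locally aligned against the candidate sequentially (the 3′ block
against the remainder after the 5′ match, so near-identical repeat sequence
at the junction cannot pull both alignments onto the same stretch).
Segments must span ≥100 nt and reach 60% identity. Frameshift gaps are gap
events of 1–2 nt; longer gaps are ordinary indels. Because the retained
repeat stubs resemble every other repeat, a few tens of nt at the segment
junction can be attributed to either segment; reported identities carry
that much fuzz.

Repeat loss is the fraction of the gene's repeat-region nucleotides with no
counterpart in the candidate; counterparts are repeat nucleotides inside
the aligned segments plus whatever the candidate carries between the two
segments (bounded by the gene's own interior length), so a candidate that
still has its repeats scores zero loss.

Classification is rule-based and categorical: *pseudogene* iff ≥1 premature
stop or ≥1 frameshift gap required for alignment (repeat loss and a missing
TATA box are supporting evidence only); *functional* iff a clean fixed-frame
translation, no frameshifts, and a TATA box; otherwise *ambiguous*. No
retrotransposition diagnostics are attempted.

## Variant diagnosis and locus inference

* **Clustering:** single-linkage on pairwise global-alignment identity;
  clones join iff identity is strictly >99%. Single-linkage is the most
  permissive reading of a pairwise merging rule; the threshold and linkage
  are configurable. Pairs differing in length by >20% are never joined
  directly (different amplicons, not polymerase error). Indels between
  clones are handled by the package-wide identity convention.
* **Unreplicated-SNP filter:** within a cluster, a base carried by exactly
  one clone at a polymorphic column is attributed to polymerase error; the
  consensus takes the majority base and the position is recorded as
  ignored. A clone with ≥2 such positions is discarded before consensus
  calling (discarding happens within clusters, after clustering). The
  guarantee that follows — every reported polymorphic site is supported by
  ≥2 retained clones — is enforced as a tested post-condition. Column ties
  in the consensus resolve to IUPAC ambiguity codes rather than an
  arbitrary base. A singleton cluster's consensus is the clone itself,
  flagged "unreplicated variant".
* **Numbering:** v1 is the best-supported variant, descending; ties break
  by first-seen clone.
* **Minimum loci:** n variants of one region in a diploid imply at least
  ⌈n/2⌉ loci; the species-level minimum is the *maximum* over regions,
  because 5′ and 3′ fragments of one locus cannot be phased from these
  data. Zero variants give zero loci.
* **Species contrast:** mean pairwise identity among variant consensuses,
  within-species vs between-species pairs; a positive difference is the
  concerted-evolution-consistent signal. With a single species the between
  term is explicitly not computable rather than silently zero.

## Problem sizes and determinism

The bundled demonstrations and acceptance checks use: the full 9468-nt
architecture for annotation, decomposition and frameshift resolution; a
6-unit × 120-nt architecture for the 60-gene boundary-recovery benchmark;
4-unit genomes with full-length terminal blocks for the 50-seed variant
recovery battery (16 clones per locus, Taq error 10⁻³); and 25
gene/pseudogene pairs × 2 loci for classification recovery. Every stage is
deterministic given one top-level seed, hierarchically split per locus and
per clone with numpy `SeedSequence`.

## What passing tests do and do not show

The generator produces clean, substitution-dominated data with known truth:
no chimeric clones, no alignment-confounding microsatellites, no
heterogeneous repeat units, no sequencing-quality gradients. Passing the
recovery batteries shows the algorithms implement their stated rules and
are robust at the divergences and error rates modeled — not that those
rates describe any particular real dataset. Accession-based checks against
deposited sequences require downloads and are out of scope here; the
pipeline accepts real FASTA input through the same interfaces.
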