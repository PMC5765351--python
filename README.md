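# silkgene

Analysis pipeline for spidroin (spider silk protein) gene architecture:
tandem-repeat decomposition and homogenization statistics, majority-rule
consensus resolution of frameshift sequencing artifacts, pseudogene
diagnosis by frameshift-tolerant paralog comparison, promoter-motif
scanning, and diagnosis of gene-copy variants from cloned PCR products with
ploidy-aware minimum-locus inference. A synthetic spidroin-gene generator
with full ground truth drives every stage, so the whole pipeline runs and
is tested without external data; real FASTA input goes through the same
interfaces.

## The scientific problem

Tubuliform spidroin (TuSp1) genes — the silk genes behind egg-case silk —
are long single-exon genes: a nonrepetitive N-terminal-coding block, a
central array of tandem repeats hundreds of nt long and homogenized to
near-identity by concerted evolution, and a nonrepetitive C-terminal-coding
block. That architecture raises the analyses this package implements:

* **Repeat decomposition.** Find the unit period P and phase of the array
  by self-comparison, chain unit boundaries 5′→3′, and quantify
  homogenization as all-vs-all pairwise percent identity (matches /
  alignment columns × 100, terminal gaps excluded).
* **Frameshift resolution.** Raw assemblies of such arrays carry isolated
  1-nt indel artifacts. Because the units are near-identical, each unit can
  be aligned to the majority-rule consensus unit and an indel private to
  one unit reverted to the consensus state; indels shared by half the units
  are genuine sequence.
* **Pseudogene diagnosis.** A pseudogenized paralog typically keeps only
  the two terminal segments of its parent (unequal crossing over collapses
  the tandem array). Segments are aligned frameshift-tolerantly; a locus
  with premature stops or frameshifts is a pseudogene, with repeat loss and
  a missing TATA box as supporting evidence.
* **Variant diagnosis and locus counting.** Cloned amplicons from a
  degenerate-primer PCR survey cluster into variants at >99% identity;
  polymorphisms seen in exactly one clone are attributed to polymerase
  error and ignored (a clone with two or more is discarded). In a diploid,
  n variants of one region imply at least ⌈n/2⌉ loci; the species count is
  the maximum over the 5′ and 3′ regions. Comparing variant identities
  within vs between species tests for ongoing within-species
  homogenization of gene copies.

## Worked example

```python
from silkgene import synth, annotate
from silkgene.repeats import detect_repeats, resolve_frameshifts

gene = synth.generate_gene(synth.full_scale_model(seed=1), name="TuSp1_like")
ann = annotate.annotate_cds(gene.sequence)
print(ann.cds_len_nt, len(ann.protein), round(ann.mol_weight_kda))
# 9468 3156 294

deco = detect_repeats(gene.cds)
print(deco.n_units, deco.unit_len_nt, deco.units[-1])
# 16 540 (8563, 8937)

raw, _ = synth.plant_frameshift_artifacts(gene, n_deletions=2, n_insertions=3, seed=101)
report = resolve_frameshifts(raw.cds)
print(report.n_additions, report.n_deletions, report.corrected_sequence == gene.cds)
# 2 3 True
```

The 9468-nt CDS (start codon through last sense codon) encodes 3156
residues at ≈294 kDa; the array decomposes into 16 units — fifteen of
540 nt and a final unit truncated to 375 nt (positions 8563–8937 of the
CDS); and the five planted 1-nt artifacts are resolved as two additions and
three deletions against the consensus repeat, restoring the clean gene
exactly.

The numbered drivers under `analysis/` run the same stages as a narrative
(`python analysis/01_simulate.py --seed 1`, then `02`–`05`), writing tables
under `results/`: gene architecture and promoter motifs, the repeat
identity matrix and frameshift report, the pseudogene segment table and
classification, and the per-species variant tallies with minimum-locus
estimates. The `silkgene` CLI exposes the same stages as subcommands
(`simulate`, `annotate`, `repeats`, `compare`, `variants`, `run`) for FASTA
input from the shell.

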