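#!/usr/bin/env python
"""Generate the synthetic study inputs and write them under results/sim/.

One full-architecture tubuliform-spidroin-like gene (16 tandem repeats,
9468 nt CDS), a raw-assembly copy with five planted 1-nt frameshift
artifacts, a pseudogenized paralog, and diploid genomes for three species
carrying 2, 2 and 3 gene copies, surveyed by cloned PCR in the 5' and 3'
gene regions.  Later stages regenerate the same objects deterministically
from the seed, so this stage exists to inspect the data, not to feed them.
"""

import argparse

import pandas as pd

from silkgene import io_utils, synth
from silkgene.io_utils import load_config, run_header
from silkgene.pipeline import _model_from_config, _subseed


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", default="results/sim")
    args = parser.parse_args()
    config = load_config(None, seed=args.seed)
    header = run_header(seed=args.seed, stage="simulate")

    model = _model_from_config(config, _subseed(config.seed, 0))
    gene = synth.generate_gene(model, name="TuSp1_like")
    raw, planted = synth.plant_frameshift_artifacts(
        gene, n_deletions=2, n_insertions=3, seed=_subseed(config.seed, 1))
    psi = synth.pseudogenize(gene, synth.PseudogenizationSpec(
        terminal_divergence=config.terminal_divergence,
        terminal_divergence_3prime=config.terminal_divergence_3prime,
    ), seed=_subseed(config.seed, 2))

    io_utils.write_fasta(
        [(gene.name, gene.sequence), (raw.name, raw.sequence), (psi.name, psi.sequence)],
        f"{args.outdir}/loci.fasta")
    io_utils.write_tsv(
        pd.DataFrame(planted, columns=["cds_position", "kind", "base"]),
        f"{args.outdir}/planted_artifacts.tsv", header=header)

    from dataclasses import replace

    survey_model = replace(model, n_repeats=4, final_repeat_len_nt=None)
    panel = synth.make_species_panel(
        config.species_plan(), survey_model,
        species_divergence=config.species_divergence,
        locus_divergence=config.locus_divergence,
        allele_divergence=config.allele_divergence,
        seed=_subseed(config.seed, 10))
    all_clones = []
    for i, genome in enumerate(panel.values()):
        for j, region in enumerate(("five_prime", "three_prime")):
            spec = synth.CloneSimSpec(region=region, n_clones=config.n_clones,
                                      taq_error_rate=config.taq_error_rate)
            all_clones += synth.simulate_clones(
                genome, spec, seed=_subseed(config.seed, 20 + 2 * i + j))
    io_utils.write_clones_fasta(all_clones, f"{args.outdir}/clones.fasta")
    io_utils.write_tsv(
        pd.DataFrame([{"clone_id": c.clone_id, "species": c.species_label,
                       "region": c.region, "source_locus": c.source_locus,
                       "source_allele": c.source_allele,
                       "n_injected_errors": c.n_errors} for c in all_clones]),
        f"{args.outdir}/clone_truth.tsv", header=header)

    print(f"gene CDS {gene.cds_len} nt; raw with {len(planted)} planted artifacts; "
          f"pseudogene body {psi.cds_len} nt")
    print(f"{len(all_clones)} clones across {len(panel)} species x 2 regions "
          f"-> {args.outdir}/")


if __name__ == "__main__":
    main()
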