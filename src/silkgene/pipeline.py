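"""End-to-end driver: simulate -> annotate -> repeats -> paralogs -> variants.

``run_pipeline`` executes the whole study design on synthetic data: one
full-architecture gene (with a raw copy carrying planted frameshift
artifacts), a pseudogenized paralog, and a panel of diploid multi-locus
genomes surveyed by cloned PCR in both gene regions.  Everything is
deterministic given the configured seed, and every table written carries a
header with version, seed and parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, io_utils, paralogs, repeats, synth, variants
from .io_utils import RunConfig, run_header
from .model import DiploidGenome


def _model_from_config(config: RunConfig, seed: int) -> synth.SpidroinModel:
    return synth.SpidroinModel(
        n_repeats=config.n_repeats,
        repeat_len_nt=config.repeat_len_nt,
        final_repeat_len_nt=config.final_repeat_len_nt,
        intra_repeat_divergence=config.intra_repeat_divergence,
        nterm_len_nt=config.nterm_len_nt,
        cterm_len_nt=config.cterm_len_nt,
        upstream_len_nt=config.upstream_len_nt,
        has_tata=config.has_tata,
        has_cacg=config.has_cacg,
        seed=seed,
    )


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(k + 1)[k] % (2**31))


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Run every stage; return the summary dict (and write reports when
    ``write`` is set)."""
    config.validate()
    outdir = Path(config.outdir)
    summary: dict = {"seed": config.seed}

    # --- simulate the focal gene, a raw assembly, and the pseudogene
    model = _model_from_config(config, _subseed(config.seed, 0))
    gene = synth.generate_gene(model, name="TuSp1_like")
    raw, planted = synth.plant_frameshift_artifacts(
        gene, n_deletions=2, n_insertions=3, seed=_subseed(config.seed, 1))
    psi_spec = synth.PseudogenizationSpec(
        retained_5prime_repeat_nt=config.retained_5prime_repeat_nt,
        retained_3prime_repeat_nt=config.retained_3prime_repeat_nt,
        n_frameshifts=config.n_frameshifts,
        terminal_divergence=config.terminal_divergence,
        terminal_divergence_3prime=config.terminal_divergence_3prime,
        drop_tata=True,
    )
    pseudo = synth.pseudogenize(gene, psi_spec, seed=_subseed(config.seed, 2))

    # --- annotate (on the full locus: the ORF needs its stop codon)
    ann = annotate.annotate_cds(gene.sequence, min_len_nt=300)
    tata_hits = annotate.scan_promoter(gene.upstream, ["TATAAA"], window_nt=None)
    cacg_hits = annotate.scan_promoter(gene.upstream, ["CACG"], window_nt=None)
    summary["gene"] = {
        "cds_len_nt": ann.cds_len_nt,
        "protein_len_aa": len(ann.protein),
        "mol_weight_kda": round(ann.mol_weight_kda, 1),
        "composition_int": {aa: ann.composition_int.get(aa, 0) for aa in "ASG"},
        "tata_position_upstream": tata_hits[0].position_upstream if tata_hits else None,
        "cacg_found": bool(cacg_hits),
    }

    # --- repeats
    deco = repeats.detect_repeats(gene.cds, identity_floor=config.identity_floor)
    if deco is None:
        raise RuntimeError("repeats stage: no repeat region detected in the simulated gene")
    raw_deco = repeats.detect_repeats(raw.cds, identity_floor=config.identity_floor)
    report = repeats.resolve_frameshifts(raw.cds, raw_deco)
    summary["repeats"] = {
        "n_units": deco.n_units,
        "unit_len_nt": deco.unit_len_nt,
        "final_unit_len_nt": deco.units[-1][1] - deco.units[-1][0] + 1,
        "mean_identity_nt": round(deco.mean_identity_nt, 2),
        "mean_identity_aa": round(deco.mean_identity_aa, 2),
        "frameshift_corrections": {
            "n_additions": report.n_additions,
            "n_deletions": report.n_deletions,
            "restored_original": report.corrected_sequence == gene.cds,
        },
    }

    # --- paralog comparison and classification
    segments = paralogs.align_paralogs(gene, deco, pseudo)
    loss = paralogs.repeat_loss_fraction(deco, segments)
    psi_ann = annotate.annotate_fixed_frame(pseudo.cds)
    psi_tata = annotate.scan_promoter(pseudo.upstream, ["TATAAA"], window_nt=None)
    n_fs_gaps = sum(seg.frameshift_gaps for seg in segments)
    psi_class = paralogs.classify_locus(psi_ann, psi_tata, loss, n_fs_gaps)
    gene_class = paralogs.classify_locus(
        annotate.annotate_fixed_frame(gene.cds), tata_hits, 0.0, 0)
    summary["paralogs"] = {
        "pseudogene_len_nt": pseudo.cds_len,
        "segments": {
            seg.label: {"identity_pct": round(seg.identity_pct, 1),
                        "frameshift_gaps": seg.frameshift_gaps}
            for seg in segments
        },
        "repeat_loss_fraction": round(loss, 3),
        "first_premature_stop": (psi_ann.premature_stops[0]
                                 if psi_ann.premature_stops else None),
        "classification": {"gene": gene_class.verdict, "pseudogene": psi_class.verdict},
    }

    # --- clone survey across species
    genomes: dict[str, DiploidGenome] = {}
    clone_sets = []
    variant_sets = []
    # the clone survey runs on a reduced architecture so amplicons stay
    # Sanger-sized; divergence parameters come from the config
    survey_model = replace(
        model, n_repeats=max(3, min(model.n_repeats, 5)), final_repeat_len_nt=None)
    genomes = synth.make_species_panel(
        config.species_plan(), survey_model,
        species_divergence=config.species_divergence,
        locus_divergence=config.locus_divergence,
        allele_divergence=config.allele_divergence,
        seed=_subseed(config.seed, 10),
    )
    for i, (label, genome) in enumerate(genomes.items()):
        for j, region in enumerate(("five_prime", "three_prime")):
            spec = synth.CloneSimSpec(
                region=region, n_clones=config.n_clones,
                taq_error_rate=config.taq_error_rate)
            clones = synth.simulate_clones(genome, spec, seed=_subseed(config.seed, 20 + 2 * i + j))
            clone_sets.append(clones)
            variant_sets.append(
                variants.diagnose_variants(clones, identity_threshold=config.identity_threshold))
    estimates = variants.estimate_loci(variant_sets, ploidy=2)
    contrast = variants.species_contrast(variant_sets, region="five_prime")
    summary["variants"] = {
        "per_set": {
            f"{vs.species_label}/{vs.region}": {
                "n_variants": vs.n_variants,
                "n_discarded": len(vs.discarded_clones),
            }
            for vs in variant_sets
        },
        "min_loci": {e.species_label: e.min_loci for e in estimates},
        "species_contrast_5prime": {
            "within_mean": contrast.within_mean and round(contrast.within_mean, 2),
            "between_mean": contrast.between_mean and round(contrast.between_mean, 2),
            "difference": contrast.difference and round(contrast.difference, 2),
        },
    }

    if write:
        _write_reports(outdir, config, gene, raw, pseudo, ann, deco, report,
                       segments, psi_class, gene_class, clone_sets, variant_sets,
                       estimates, summary)
    return summary


def _write_reports(outdir: Path, config: RunConfig, gene, raw, pseudo, ann, deco,
                   report, segments, psi_class, gene_class, clone_sets,
                   variant_sets, estimates, summary) -> None:
    header = run_header(seed=config.seed, stage="pipeline")
    outdir.mkdir(parents=True, exist_ok=True)

    io_utils.write_fasta(
        [(gene.name, gene.sequence), (raw.name, raw.sequence), (pseudo.name, pseudo.sequence)],
        outdir / "loci.fasta")
    (outdir / "gene_annotation.gff3").write_text(
        io_utils.annotation_to_gff3(gene.name, ann))

    io_utils.write_tsv(io_utils.units_to_bed(deco.units, gene.name + "_cds"),
                       outdir / "repeat_units.bed.tsv", header=header)
    io_utils.write_fasta([("consensus_repeat", deco.consensus)],
                         outdir / "consensus_repeat.fasta")
    io_utils.write_tsv(
        pd.DataFrame(deco.identity_mat,
                     columns=[f"R{i + 1}" for i in deco.full_length_indices()]),
        outdir / "repeat_identity_matrix.tsv", header=header)
    io_utils.write_tsv(
        pd.DataFrame([dataclasses.asdict(e) for e in report.events]),
        outdir / "frameshift_report.tsv", header=header)

    io_utils.write_tsv(
        pd.DataFrame([dataclasses.asdict(s) for s in segments]),
        outdir / "paralog_segments.tsv", header=header)
    io_utils.write_json(
        {"gene": dataclasses.asdict(gene_class), "pseudogene": dataclasses.asdict(psi_class)},
        outdir / "classification.json", header=header)

    all_clones = [c for cs in clone_sets for c in cs]
    io_utils.write_clones_fasta(all_clones, outdir / "clones.fasta")
    io_utils.write_tsv(
        pd.DataFrame([
            {"clone_id": c.clone_id, "source_locus": c.source_locus,
             "source_allele": c.source_allele, "n_injected_errors": c.n_errors}
            for c in all_clones
        ]),
        outdir / "clone_truth.tsv", header=header)
    io_utils.write_fasta(
        [(f"{vs.species_label}_{vs.region}_{v.variant_id}", v.consensus)
         for vs in variant_sets for v in vs.variants],
        outdir / "variants.fasta")
    io_utils.write_tsv(
        pd.DataFrame([
            {"species": vs.species_label, "region": vs.region,
             "variant": v.variant_id, "support": v.support,
             "ignored_snps": len(v.ignored_snp_positions),
             "clones": ",".join(v.clone_ids)}
            for vs in variant_sets for v in vs.variants
        ]),
        outdir / "variant_table.tsv", header=header)
    io_utils.write_json(
        {e.species_label: dataclasses.asdict(e) for e in estimates},
        outdir / "loci_estimates.json", header=header)
    io_utils.write_json(summary, outdir / "summary.json", header=header)
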