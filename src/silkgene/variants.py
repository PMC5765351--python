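"""Variant diagnosis from cloned PCR products and minimum-locus inference.

Cloned amplicons from a degenerate-primer PCR survey of one individual mix
true allelic/paralogous variation with per-base polymerase error.  The
diagnosis rules implemented here:

* clones whose pairwise identity exceeds 99% represent the same variant
  (single-linkage clustering; the threshold is strictly greater-than);
* within a cluster, a polymorphism carried by exactly one clone (an
  *unreplicated SNP*) is attributed to Taq error and ignored — the consensus
  takes the majority base; a clone carrying two or more unreplicated SNPs is
  discarded outright;
* consequently every reported polymorphic site is supported by at least two
  retained clones;
* under diploidy, n distinct variants of one region imply at least
  ceil(n / 2) loci; the species-level minimum is the maximum over regions,
  since 5' and 3' fragments of one locus cannot be phased from these data.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from . import iupac
from .align import percent_identity
from .model import CloneRead

__all__ = [
    "Variant", "VariantSet", "LociEstimate", "SpeciesContrast",
    "cluster_variants", "filter_and_call", "diagnose_variants",
    "min_loci", "estimate_loci", "species_contrast",
]


@dataclass
class Variant:
    variant_id: str  # v1, v2, ...
    consensus: str
    support: int  # retained clones
    clone_ids: list[str] = field(default_factory=list)
    ignored_snp_positions: list[int] = field(default_factory=list)  # 1-based
    flags: list[str] = field(default_factory=list)


@dataclass
class VariantSet:
    species_label: str
    region: str
    variants: list[Variant] = field(default_factory=list)
    discarded_clones: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class LociEstimate:
    species_label: str
    min_loci_per_region: dict[str, int]
    min_loci: int
    ploidy: int = 2


@dataclass
class SpeciesContrast:
    region: str
    within_mean: float | None
    between_mean: float | None
    difference: float | None  # within - between; positive = homogenization signal

    @property
    def computable(self) -> bool:
        return self.difference is not None


# ---------------------------------------------------------------------------
# clustering


def cluster_variants(clones: list[CloneRead], identity_threshold: float = 99.0,
                     max_length_diff: float = 0.20) -> list[list[CloneRead]]:
    """Single-linkage clustering of clones: two clones fall in the same
    cluster iff some chain of pairwise identities strictly above
    ``identity_threshold`` connects them.

    Pairs differing in length by more than ``max_length_diff`` are never
    joined directly, whatever their aligned identity — grossly different
    lengths mean different amplicons, not polymerase error.
    Clusters are ordered by descending size, then by first-seen clone.
    """
    if not clones:
        return []
    species = {c.species_label for c in clones}
    regions = {c.region for c in clones}
    if len(species) > 1 or len(regions) > 1:
        raise ValueError("clones must come from a single species and region")

    n = len(clones)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i, j in combinations(range(n), 2):
        li, lj = len(clones[i].sequence), len(clones[j].sequence)
        if abs(li - lj) > max_length_diff * max(li, lj):
            continue
        if percent_identity(clones[i].sequence, clones[j].sequence) > identity_threshold:
            union(i, j)

    groups: dict[int, list[CloneRead]] = {}
    for i, clone in enumerate(clones):
        groups.setdefault(find(i), []).append(clone)
    # roots are the smallest member index, so sorting keys on (size desc,
    # root asc) implements "descending support then first-seen clone"
    return [groups[r] for r in sorted(groups, key=lambda r: (-len(groups[r]), r))]


# ---------------------------------------------------------------------------
# consensus calling with the unreplicated-SNP filter


def _stack(cluster: list[CloneRead]) -> list[str]:
    """Column-wise view of a cluster of near-identical clones.

    Equal-length clones (the usual case: substitution-only error) stack
    directly; otherwise each is projected onto the longest clone's
    coordinates through an edit-distance alignment, gaps as '-'.
    """
    seqs = [c.sequence for c in cluster]
    if len(set(map(len, seqs))) == 1:
        return seqs
    from .align import cigar_ops, edit_alignment

    anchor = max(seqs, key=len)
    rows = []
    for seq in seqs:
        if seq == anchor:
            rows.append(seq)
            continue
        res = edit_alignment(seq, anchor, mode="NW")
        row, qi = [], 0
        for length, op in cigar_ops(res["cigar"]):
            if op in "=X":
                row.append(seq[qi : qi + length])
                qi += length
            elif op == "D":
                row.append("-" * length)
            elif op == "I":
                qi += length
        rows.append("".join(row))
    return rows


def _unreplicated_positions(rows: list[str], active: list[int]) -> dict[int, list[int]]:
    """Per-row (clone) list of 1-based columns where that clone carries a
    base seen in no other active clone at a polymorphic column."""
    out: dict[int, list[int]] = {i: [] for i in active}
    if len(active) < 2:
        return out
    width = len(rows[active[0]])
    for col in range(width):
        counts = Counter(rows[i][col] for i in active)
        if len(counts) == 1:
            continue
        for i in active:
            if counts[rows[i][col]] == 1:
                out[i].append(col + 1)
    return out


def filter_and_call(cluster: list[CloneRead]) -> Variant:
    """Call one variant consensus from a cluster, applying the
    unreplicated-SNP filter.

    Clones carrying >= 2 unreplicated SNPs are discarded (recorded in
    ``flags`` as ``discarded:<id>``); remaining single unreplicated SNPs are
    ignored and listed; the consensus is the column-wise majority over
    retained clones, ties resolved with IUPAC ambiguity codes.
    """
    if not cluster:
        raise ValueError("empty cluster")
    if len(cluster) == 1:
        clone = cluster[0]
        return Variant(
            variant_id="", consensus=clone.sequence, support=1,
            clone_ids=[clone.clone_id], flags=["unreplicated variant"],
        )
    rows = _stack(cluster)
    active = list(range(len(cluster)))
    unrep = _unreplicated_positions(rows, active)
    discarded = [i for i in active if len(unrep[i]) >= 2]
    retained = [i for i in active if i not in discarded]
    if not retained:  # pathological: keep the first clone rather than nothing
        retained, discarded = [0], discarded[1:]
    unrep = _unreplicated_positions(rows, retained)
    ignored = sorted(pos for i in retained for pos in unrep[i])

    width = len(rows[0])
    out = []
    for col in range(width):
        counts = Counter(rows[i][col] for i in retained)
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        if len(winners) == 1:
            base = winners[0]
        else:
            real = [b for b in winners if b in "ACGT"]
            base = iupac.code_for(real) if real else "-"
        if base != "-":
            out.append(base)
    flags = [f"discarded:{cluster[i].clone_id}" for i in discarded]
    return Variant(
        variant_id="",
        consensus="".join(out),
        support=len(retained),
        clone_ids=[cluster[i].clone_id for i in retained],
        ignored_snp_positions=ignored,
        flags=flags,
    )


def diagnose_variants(clones: list[CloneRead], identity_threshold: float = 99.0) -> VariantSet:
    """Full diagnosis for one species-region clone set: cluster, filter,
    call consensuses, and number variants v1, v2, ... by descending support
    (ties by first-seen clone)."""
    if not clones:
        raise ValueError("no clones given")
    clusters = cluster_variants(clones, identity_threshold=identity_threshold)
    called = [filter_and_call(cluster) for cluster in clusters]
    order = sorted(
        range(len(called)),
        key=lambda k: (-called[k].support,
                       min(i for i, c in enumerate(clones)
                           if c.clone_id in set(called[k].clone_ids))),
    )
    variants, discarded = [], []
    for rank, k in enumerate(order, start=1):
        var = called[k]
        var.variant_id = f"v{rank}"
        for flag in var.flags:
            if flag.startswith("discarded:"):
                discarded.append((flag.split(":", 1)[1], "multiple unreplicated SNPs"))
        variants.append(var)
    return VariantSet(
        species_label=clones[0].species_label,
        region=clones[0].region,
        variants=variants,
        discarded_clones=discarded,
    )


# ---------------------------------------------------------------------------
# locus inference and the species contrast


def min_loci(n_variants: int, ploidy: int = 2) -> int:
    """Minimum locus count explaining ``n_variants`` distinct sequences in a
    genome of the given ploidy: ceil(n / ploidy)."""
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    return math.ceil(n_variants / ploidy)


def estimate_loci(variant_sets: list[VariantSet], ploidy: int = 2) -> list[LociEstimate]:
    """Per-species minimum locus counts: per-region ceil(n/ploidy), species
    total the maximum across regions."""
    by_species: dict[str, dict[str, int]] = {}
    for vs in variant_sets:
        by_species.setdefault(vs.species_label, {})[vs.region] = vs.n_variants
    return [
        LociEstimate(
            species_label=sp,
            min_loci_per_region={r: min_loci(n, ploidy) for r, n in regions.items()},
            min_loci=max((min_loci(n, ploidy) for n in regions.values()), default=0),
            ploidy=ploidy,
        )
        for sp, regions in by_species.items()
    ]


def species_contrast(variant_sets: list[VariantSet], region: str) -> SpeciesContrast:
    """Mean pairwise identity among variant consensuses, within species vs
    between species, for one gene region.

    A positive difference (within > between) is the signature of ongoing
    within-species homogenization of gene copies (concerted evolution).
    Returns an explicitly not-computable result when either partition has no
    pairs (e.g. a single-species input).
    """
    pool = [
        (vs.species_label, v.consensus)
        for vs in variant_sets if vs.region == region
        for v in vs.variants
    ]
    within, between = [], []
    for (sp_a, seq_a), (sp_b, seq_b) in combinations(pool, 2):
        (within if sp_a == sp_b else between).append(percent_identity(seq_a, seq_b))
    w = float(sum(within) / len(within)) if within else None
    b = float(sum(between) / len(between)) if between else None
    diff = (w - b) if (w is not None and b is not None) else None
    return SpeciesContrast(region=region, within_mean=w, between_mean=b, difference=diff)
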