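"""File formats and run configuration.

FASTA reading/writing goes through Biopython; tabular outputs are TSV with a
comment header recording version, seed and parameters so every report is
self-describing.  Clone FASTA headers follow ``cloneID|species|region``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import CloneRead

VALID_NT = set("ACGTN")


def read_fasta(path: str | Path, validate_nt: bool = True) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs.

    Raises on an empty file, duplicate ids, or (by default) characters
    outside A/C/G/T/N — each error names the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if validate_nt:
            bad = set(seq) - VALID_NT
            if bad:
                raise ValueError(
                    f"{path}: record {rec.id!r} contains non-nucleotide characters {sorted(bad)}")
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_clones_fasta(path: str | Path) -> list[CloneRead]:
    """Clone FASTA with ``cloneID|species|region`` headers."""
    clones = []
    for name, seq in read_fasta(path):
        parts = name.split("|")
        if len(parts) != 3:
            raise ValueError(f"{path}: clone header {name!r} is not 'cloneID|species|region'")
        clones.append(CloneRead(clone_id=parts[0], species_label=parts[1],
                                region=parts[2], sequence=seq))
    return clones


def write_clones_fasta(clones: list[CloneRead], path: str | Path) -> None:
    write_fasta(
        [(f"{c.clone_id}|{c.species_label}|{c.region}", c.sequence) for c in clones],
        path,
    )


def run_header(seed: int | None = None, **params) -> str:
    from . import __version__

    parts = [f"silkgene v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in params.items())
    return "# " + " ".join(parts)


def write_tsv(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_json(obj, path: str | Path, header: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = {"_meta": header} if header else {}
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def units_to_bed(units: list[tuple[int, int]], name: str) -> pd.DataFrame:
    """Repeat units as CDS-relative BED (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": name,
            "start": [lo - 1 for lo, _ in units],
            "end": [hi for _, hi in units],
            "name": [f"R{i + 1}" for i in range(len(units))],
        }
    )


def annotation_to_gff3(seq_id: str, ann, source: str = "silkgene") -> str:
    """One gene + CDS feature pair in GFF3 (coordinates on the input sequence)."""
    lines = ["##gff-version 3"]
    if ann.found:
        attrs = f"ID=gene1;protein_length={len(ann.protein)}"
        lines.append("\t".join(map(str, [seq_id, source, "gene", ann.cds_start,
                                         ann.cds_end, ".", "+", ".", attrs])))
        lines.append("\t".join(map(str, [seq_id, source, "CDS", ann.cds_start,
                                         ann.cds_end, ".", "+", "0", "ID=cds1;Parent=gene1"])))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# run configuration


_CONFIG_SCHEMA: dict[str, type] = {
    "seed": int,
    "outdir": str,
    "n_repeats": int,
    "repeat_len_nt": int,
    "final_repeat_len_nt": int,
    "intra_repeat_divergence": float,
    "nterm_len_nt": int,
    "cterm_len_nt": int,
    "upstream_len_nt": int,
    "has_tata": bool,
    "has_cacg": bool,
    "retained_5prime_repeat_nt": int,
    "retained_3prime_repeat_nt": int,
    "n_frameshifts": int,
    "terminal_divergence": float,
    "terminal_divergence_3prime": float,
    "species": str,  # comma-separated label:n_loci pairs
    "species_divergence": float,
    "n_clones": int,
    "taq_error_rate": float,
    "locus_divergence": float,
    "allele_divergence": float,
    "identity_threshold": float,
    "identity_floor": float,
    "verbosity": int,
}

_RANGES: dict[str, tuple[float, float]] = {
    "intra_repeat_divergence": (0.0, 1.0),
    "terminal_divergence": (0.0, 1.0),
    "terminal_divergence_3prime": (0.0, 1.0),
    "taq_error_rate": (0.0, 0.01),
    "species_divergence": (0.0, 1.0),
    "locus_divergence": (0.0, 1.0),
    "allele_divergence": (0.0, 1.0),
    "identity_threshold": (0.0, 100.0),
    "identity_floor": (0.0, 100.0),
}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "silkgene_out"
    n_repeats: int = 16
    repeat_len_nt: int = 540
    final_repeat_len_nt: int | None = 375
    intra_repeat_divergence: float = 0.005
    nterm_len_nt: int = 462
    cterm_len_nt: int = 531
    upstream_len_nt: int = 300
    has_tata: bool = True
    has_cacg: bool = False
    retained_5prime_repeat_nt: int = 286
    retained_3prime_repeat_nt: int = 84
    n_frameshifts: int = 2
    terminal_divergence: float = 0.08
    terminal_divergence_3prime: float | None = 0.12
    species: str = "argentata:2,aurantia:2,trifasciata:3"
    species_divergence: float = 0.08
    n_clones: int = 32
    taq_error_rate: float = 0.001
    locus_divergence: float = 0.05
    allele_divergence: float = 0.03
    identity_threshold: float = 99.0
    identity_floor: float = 80.0
    verbosity: int = 1

    def species_plan(self) -> dict[str, int]:
        plan = {}
        for chunk in self.species.split(","):
            label, _, n = chunk.strip().partition(":")
            plan[label] = int(n) if n else 1
        return plan

    def validate(self) -> None:
        for key, (lo, hi) in _RANGES.items():
            val = getattr(self, key)
            if val is not None and not lo <= val <= hi:
                raise ValueError(f"config {key}={val} outside [{lo}, {hi}]")


def _coerce(key: str, raw: str):
    typ = _CONFIG_SCHEMA[key]
    if typ is bool:
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"config {key}: expected a boolean, got {raw!r}")
    return typ(raw)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Plain key=value config file ('#' comments), with keyword overrides.

    Unknown keys are rejected by name.
    """
    values: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, raw = (part.strip() for part in line.partition("="))
            if key not in _CONFIG_SCHEMA:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _coerce(key, raw)
    for key, val in overrides.items():
        if val is None:
            continue
        if key not in _CONFIG_SCHEMA:
            raise ValueError(f"unknown config key {key!r}")
        values[key] = val
    config = RunConfig(**values)
    config.validate()
    return config
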