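"""File formats and configuration: FASTA, BED6, tabular inputs, YAML config.

Conventions: internal coordinates are 0-based half-open; BED output is
0-based half-open over the core; all other user-facing tables carry
1-based positions.  Tabular artifacts are tab-separated, UTF-8,
headered.  ``chr`` prefixes are tolerated and preserved.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .cohort import LocusRegistry, RegistryEntry, SampleRecord
from .genome_scan import CoreMotif, PalindromicLocus, ReferenceSequence, VariantSite

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fasta(path: str | Path):
    """Stream records of a (possibly gzipped) FASTA, preserving case.

    Yields :class:`ReferenceSequence` one record at a time so a
    genome-sized file never needs to be held in memory at once.  Record
    names are parsed to the first whitespace.  Alphabet violations are
    rejected with the record named.
    """
    with _open_text(path) as fh:
        n = 0
        for rec in SeqIO.parse(fh, "fasta"):
            n += 1
            try:
                yield ReferenceSequence(rec.id, str(rec.seq))
            except ValueError as e:
                raise ValueError(f"record {rec.id!r} in {path}: {e}") from e
        if n == 0:
            raise ValueError(f"no FASTA records found in {path}")


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read all records of a FASTA file (see :func:`iter_fasta`)."""
    return list(iter_fasta(path))


def write_fasta(sequences: list[ReferenceSequence], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.name}\n")
            for i in range(0, len(seq.bases), width):
                fh.write(seq.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------
# BED / locus tables
# ---------------------------------------------------------------------

def write_bed(loci: list[PalindromicLocus], path: str | Path) -> None:
    """BED6 over the core: chrom, start, end, <core>|arm=<k>, arm, strand."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.chrom}\t{l.core_start}\t{l.core_end}\t"
                f"{l.core.sequence}|arm={l.arm_length}\t{l.arm_length}\t{l.strand_label}\n"
            )


def read_bed(path: str | Path) -> list[PalindromicLocus]:
    """Read loci written by :func:`write_bed` (lossless round-trip of the
    coordinate/core/arm/strand fields; masked_fraction is not stored in BED)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED fields, got {len(parts)}")
            chrom, start, _end, name, score, strand = parts
            core_seq = name.split("|", 1)[0]
            out.append(PalindromicLocus(
                chrom=chrom, core_start=int(start), core=CoreMotif(core_seq),
                arm_length=int(score), strand_label=strand))
    return out


def write_locus_table(loci: list[PalindromicLocus], seqs: dict[str, ReferenceSequence],
                      path: str | Path) -> None:
    """TSV companion of the BED: adds masked fraction and homopolymer flag."""
    from .genome_scan import is_arm_homopolymer
    rows = []
    for l in loci:
        rows.append({
            "chrom": l.chrom, "core_start_0based": l.core_start,
            "core_end_0based": l.core_end, "core": l.core.sequence,
            "arm_length": l.arm_length, "strand": l.strand_label,
            "masked_fraction": round(l.masked_fraction, 6),
            "arm_homopolymer": is_arm_homopolymer(l, seqs[l.chrom]),
            "mutable_positions_1based": ",".join(str(p + 1) for p in l.mutable_positions),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------

def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample_id, chrom, pos (1-based), ref, alt."""
    tab = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str,
                                             "ref": str, "alt": str})
    missing = {"sample_id", "chrom", "pos", "ref", "alt"} - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: mutation table missing columns {sorted(missing)}")
    tab["pos"] = tab["pos"].astype(int)
    return tab


def read_variants(path: str | Path) -> list[VariantSite]:
    """Variant list for window-discovery mode: VCF (by extension) or TSV.

    The TSV needs columns chrom, pos (1-based), ref, alt.
    """
    path = Path(path)
    if path.suffix in {".vcf"} or path.name.endswith(".vcf.gz"):
        out = []
        with _open_text(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, pos, ref, alts = f[0], int(f[1]), f[3], f[4]
                for alt in alts.split(","):
                    if len(ref) == 1 and len(alt) == 1 and alt != ".":
                        out.append(VariantSite(chrom, pos, ref, alt))
        return out
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = {"chrom", "pos", "ref", "alt"} - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: variant table missing columns {sorted(missing)}")
    return [VariantSite(r.chrom, int(r.pos), r.ref, r.alt) for r in tab.itertuples()]


_COVARIATE_FIELDS = ("sex", "stage", "grade", "cohort", "history_of_nmibc",
                     "fgfr3", "pik3ca", "tert", "recurrence", "progression", "death")


def read_covariates(path: str | Path) -> list[SampleRecord]:
    """Headered TSV, one row per sample; unknown columns are ignored,
    missing cells become None."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in tab.columns:
        raise ValueError(f"{path}: covariate table needs a sample_id column")
    out = []
    for _, row in tab.iterrows():
        kwargs = {f: (row[f] if f in tab.columns and pd.notna(row[f]) else None)
                  for f in _COVARIATE_FIELDS}
        out.append(SampleRecord(sample_id=row["sample_id"], **kwargs))
    return out


def write_covariates(samples: list[SampleRecord], path: str | Path) -> None:
    rows = [{"sample_id": s.sample_id, **{f: getattr(s, f) for f in _COVARIATE_FIELDS}}
            for s in samples]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_registry(path: str | Path) -> LocusRegistry:
    """Registry TSV: locus_id, chrom, positions (comma-joined, 1-based), core."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"locus_id", "chrom", "positions", "core"} - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: registry missing columns {sorted(missing)}")
    entries = [
        RegistryEntry(r.locus_id, r.chrom,
                      tuple(int(p) for p in str(r.positions).split(",")), r.core)
        for r in tab.itertuples()
    ]
    return LocusRegistry(entries)


def write_registry(registry: LocusRegistry, path: str | Path) -> None:
    registry.to_frame().to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    missing = {"sample_id", "gene", "ct"} - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {sorted(missing)}")
    return tab


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Sample × locus binary matrix exported by CohortMatrix.to_frame."""
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated run configuration; every random stage derives from `seed`."""

    core: str = "TGAACA"
    min_arm: int = 9
    max_arm: int | None = 11
    homopolymer_filter: bool = True
    max_masked_fraction: float = 0.0
    window: int = 30
    window_min_arm: int = 8
    select_plain_min_expected: float = 5.0
    select_yates_min_expected: float = 3.0
    reference_gene: str = "TBP"
    normal_ids: list[str] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        import zlib
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys with a precise message."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}; valid: {sorted(valid)}")
    return PipelineConfig(**raw)
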