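"""Locus registry, cohort mutation matrix, burdens and signature groups.

The unit of analysis is a binary sample × locus matrix: a sample scores
1 at a locus when a somatic call hits either of the locus' two mutable
core positions.  Per-sample *burden* (number of mutated loci over a
subset) stratifies the cohort into three signature groups:

* G1 — no mutated locus,
* G2 — one or two mutated loci,
* G3 — three or more mutated loci.

Locus labels follow the field's short names (``GPR126``, ``PLEKHS1``,
``Intron ADM``, ``Chr7:11``, ``Chr15:96``, ``GABRG3``, ``CLVS2``,
``Chr3:82``, ``RAD51B``); genomic coordinates are registry data, not
hard-coded, since only some are printed in the literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ("G1", "G2", "G3")


def assign_signature_group(burden: int) -> str:
    """Map a per-sample mutated-locus count to its signature group."""
    if burden < 0:
        raise ValueError(f"burden must be non-negative, got {burden}")
    if burden == 0:
        return "G1"
    if burden <= 2:
        return "G2"
    return "G3"


@dataclass(frozen=True)
class RegistryEntry:
    """One locus: short label, chromosome, 1-based mutable positions, core."""

    locus_id: str
    chrom: str
    mutable_positions: tuple[int, ...]
    core: str = "TGAACA"

    def __post_init__(self) -> None:
        if not self.mutable_positions:
            raise ValueError(f"locus {self.locus_id}: no mutable positions")
        if any(p < 1 for p in self.mutable_positions):
            raise ValueError(f"locus {self.locus_id}: positions are 1-based, must be >= 1")


class LocusRegistry:
    """Ordered collection of loci, indexable by id and by (chrom, pos)."""

    def __init__(self, entries: list[RegistryEntry]):
        ids = [e.locus_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids in registry")
        self.entries = list(entries)
        self._by_id = {e.locus_id: e for e in entries}
        self._by_pos: dict[tuple[str, int], str] = {}
        for e in entries:
            for p in e.mutable_positions:
                key = (e.chrom, p)
                if key in self._by_pos:
                    raise ValueError(f"position {key} claimed by two loci")
                self._by_pos[key] = e.locus_id

    @property
    def locus_ids(self) -> list[str]:
        return [e.locus_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def __getitem__(self, locus_id: str) -> RegistryEntry:
        return self._by_id[locus_id]

    def locus_at(self, chrom: str, pos: int) -> str | None:
        """Locus id whose mutable positions include (chrom, 1-based pos)."""
        return self._by_pos.get((chrom, pos))

    def subset(self, locus_ids: list[str]) -> "LocusRegistry":
        return LocusRegistry([self._by_id[i] for i in locus_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": [e.locus_id for e in self.entries],
                "chrom": [e.chrom for e in self.entries],
                "positions": [",".join(map(str, e.mutable_positions)) for e in self.entries],
                "core": [e.core for e in self.entries],
            }
        )


#: Printed coordinates for the loci whose positions are public; the
#: remaining short-labelled loci carry registry-supplied coordinates
#: (see default_registry, which fills them with documented placeholders).
PRINTED_POSITIONS: dict[str, tuple[str, tuple[int, ...]]] = {
    "Chr3:82": ("chr3", (82807069,)),
    "Intron ADM": ("chr11", (10331381, 10331384)),
    "CLVS2": ("chr6", (123442661,)),
    "GABRG3": ("chr15", (27617168, 27617171)),
}


def default_registry() -> LocusRegistry:
    """Registry of the nine named loci used throughout the analyses.

    Coordinates are the printed ones where public.  For loci whose full
    coordinates are not printed (GPR126, PLEKHS1, Chr7:11, Chr15:96,
    RAD51B) synthetic placeholder positions are used — consistent
    pair spacing (3 bp, core offsets 1 and 4) on the stated chromosome —
    so that synthetic cohorts and fixtures are well-formed.  Supply a
    registry TSV to override with real coordinates.
    """
    entries = [
        RegistryEntry("GPR126", "chr6", (142706206, 142706209)),
        RegistryEntry("PLEKHS1", "chr10", (115511590, 115511593)),
        RegistryEntry("Intron ADM", "chr11", (10331381, 10331384)),
        RegistryEntry("Chr7:11", "chr7", (11000001, 11000004)),
        RegistryEntry("Chr15:96", "chr15", (96000001, 96000004)),
        RegistryEntry("GABRG3", "chr15", (27617168, 27617171)),
        RegistryEntry("CLVS2", "chr6", (123442661, 123442664)),
        RegistryEntry("Chr3:82", "chr3", (82807069, 82807072)),
        RegistryEntry("RAD51B", "chr14", (68000001, 68000004), core="AGATCA"),
    ]
    return LocusRegistry(entries)


@dataclass
class SampleRecord:
    """Per-sample clinical covariates; outcome fields carried, not modeled."""

    sample_id: str
    sex: str | None = None            # male / female
    stage: str | None = None          # Cis / Ta / T1 / T2 / >=T3
    grade: str | None = None          # low / high
    cohort: str | None = None         # NMIBC / MIBC
    history_of_nmibc: str | None = None  # yes / no
    fgfr3: str | None = None          # mutated / not_mutated
    pik3ca: str | None = None
    tert: str | None = None
    recurrence: str | None = None
    progression: str | None = None
    death: str | None = None


class CohortMatrix:
    """Binary sample × locus mutation matrix with covariates attached."""

    def __init__(self, samples: list[SampleRecord], registry: LocusRegistry,
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=int)
        if calls.shape != (len(samples), len(registry)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(samples)} samples x {len(registry)} loci"
            )
        if not np.isin(calls, (0, 1)).all():
            raise ValueError("calls must be binary")
        self.samples = list(samples)
        self.registry = registry
        self.calls = calls
        self._col = {lid: k for k, lid in enumerate(registry.locus_ids)}

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def locus_ids(self) -> list[str]:
        return self.registry.locus_ids

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def calls_for(self, locus_id: str) -> np.ndarray:
        if locus_id not in self._col:
            raise KeyError(f"unknown locus {locus_id!r}")
        return self.calls[:, self._col[locus_id]]

    def covariate(self, name: str) -> pd.Series:
        vals = [getattr(s, name) for s in self.samples]
        return pd.Series(vals, index=self.sample_ids, name=name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.locus_ids)

    # -- burden / groups ----------------------------------------------
    def _subset_cols(self, loci_subset: list[str] | None) -> np.ndarray:
        if loci_subset is None:
            return self.calls
        if not loci_subset:
            raise ValueError("loci subset must be non-empty")
        return self.calls[:, [self._col[l] for l in loci_subset]]

    def burden(self, loci_subset: list[str] | None = None) -> pd.Series:
        """Number of mutated loci per sample over a locus subset."""
        b = self._subset_cols(loci_subset).sum(axis=1)
        return pd.Series(b, index=self.sample_ids, name="burden")

    def signature_groups(self, loci_subset: list[str] | None = None) -> pd.Series:
        g = self.burden(loci_subset).map(assign_signature_group)
        return g.rename("group")

    def locus_frequency(self, locus_id: str) -> tuple[int, int, float]:
        """(mutated count, cohort size, fraction) for one locus."""
        calls = self.calls_for(locus_id)
        count = int(calls.sum())
        return count, self.n_samples, count / self.n_samples

    def signature_positive_fraction(self, loci_subset: list[str] | None = None) -> float:
        """Fraction of samples with at least one mutated locus in the subset."""
        return float((self._subset_cols(loci_subset).sum(axis=1) >= 1).mean())


def build_matrix(
    mutation_table: pd.DataFrame,
    registry: LocusRegistry,
    samples: list[SampleRecord],
) -> tuple[CohortMatrix, pd.DataFrame]:
    """Assemble the binary matrix from a per-sample SNV list.

    *mutation_table* has columns ``sample_id, chrom, pos, ref, alt``
    with 1-based positions.  Every row must land on a registry mutable
    position — unknown positions raise, listing the offenders, rather
    than being dropped silently.  A sample hit at both mutable positions
    of a locus still scores 1.  Duplicate (sample, chrom, pos, alt) rows
    are de-duplicated with a warning.  Returns the matrix and a side
    table of the retained calls with their locus assignment (alt alleles
    kept for context classification downstream).
    """
    known = {s.sample_id for s in samples}
    required = {"sample_id", "chrom", "pos", "ref", "alt"}
    missing = required - set(mutation_table.columns)
    if missing:
        raise ValueError(f"mutation table missing columns {sorted(missing)}")
    tab = mutation_table.copy()
    tab["pos"] = tab["pos"].astype(int)

    unknown_samples = sorted(set(tab["sample_id"]) - known)
    if unknown_samples:
        raise ValueError(f"samples in mutation table but not in sample list: {unknown_samples}")

    dup = tab.duplicated(subset=["sample_id", "chrom", "pos", "alt"])
    if dup.any():
        logger.warning("dropping %d duplicate mutation rows", int(dup.sum()))
        tab = tab[~dup]

    locus_of = [registry.locus_at(c, p) for c, p in zip(tab["chrom"], tab["pos"])]
    bad = tab.loc[[l is None for l in locus_of], ["sample_id", "chrom", "pos"]]
    if len(bad):
        listing = "; ".join(f"{r.sample_id} {r.chrom}:{r.pos}" for r in bad.itertuples())
        raise ValueError(f"{len(bad)} mutation(s) at positions not in the registry: {listing}")
    tab = tab.assign(locus_id=locus_of)

    row = {s.sample_id: k for k, s in enumerate(samples)}
    col = {lid: k for k, lid in enumerate(registry.locus_ids)}
    calls = np.zeros((len(samples), len(registry)), dtype=int)
    for rec in tab.itertuples():
        calls[row[rec.sample_id], col[rec.locus_id]] = 1
    return CohortMatrix(samples, registry, calls), tab.reset_index(drop=True)


def locus_frequency(matrix: CohortMatrix, locus_id: str) -> tuple[int, int, float]:
    """Module-level convenience wrapper; see :meth:`CohortMatrix.locus_frequency`."""
    return matrix.locus_frequency(locus_id)


def signature_positive_fraction(matrix: CohortMatrix,
                                loci_subset: list[str] | None = None) -> float:
    """Module-level convenience wrapper; see :meth:`CohortMatrix.signature_positive_fraction`."""
    return matrix.signature_positive_fraction(loci_subset)
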