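"""Trinucleotide context classification of single-base substitutions.

Substitutions are reported on the strand where the mutated base is a
pyrimidine (the field's convention for mutational signatures): a G>A
call is flipped to C>T with its trinucleotide context
reverse-complemented.  APOBEC cytidine deaminases act on TpC
dinucleotides in single-stranded DNA, preferring TCA, so contexts are
classified as:

* ``TCA_optimal``   — C>X in a TCA trinucleotide (or TGA on the other
  strand), the optimal APOBEC substrate;
* ``TCN_canonical`` — C>X in any other TCN trinucleotide;
* ``other``         — everything else (including T-centered changes and
  the ACA context of the second mutable core position).

For a TGAACA core the two recurrently mutated positions fall out
naturally: the G at core offset 1 sits in a forward TGA (= TCA on the
opposite strand, optimal), while the C at offset 4 sits in ACA (not a
TpC context at all).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_scan import ReferenceSequence, VariantSite, reverse_complement

PYRIMIDINES = {"C", "T"}
PURINES = {"A", "G"}


@dataclass(frozen=True)
class SubstitutionContext:
    """Pyrimidine-normalized context of one substitution."""

    chrom: str
    pos: int          # 1-based
    ref: str          # pyrimidine after normalization
    alt: str
    trinucleotide: str
    substitution: str  # e.g. "C>T"
    apobec_class: str  # TCA_optimal | TCN_canonical | other

    def __post_init__(self) -> None:
        if self.trinucleotide != "NNN" and self.trinucleotide[1] != self.ref:
            raise ValueError("trinucleotide center must equal the normalized ref base")


def classify_trinucleotide(trinucleotide: str, ref: str) -> str:
    """APOBEC class of a pyrimidine-normalized context."""
    if ref == "C" and trinucleotide.startswith("TC"):
        return "TCA_optimal" if trinucleotide == "TCA" else "TCN_canonical"
    return "other"


def pyrimidine_context(seq: ReferenceSequence, site: VariantSite) -> SubstitutionContext:
    """Pyrimidine-normalized trinucleotide context of one variant.

    The reference base at ``site.pos`` (1-based) must equal ``site.ref``.
    When the reference base is a purine, ref/alt are complemented and
    the trinucleotide reverse-complemented so the reported center is a
    pyrimidine; applying the operation to the already-normalized record
    is the identity.  Contexts at the first or last base of the
    sequence are reported with trinucleotide ``"NNN"`` and class
    ``other`` (excluded from summaries).
    """
    i = site.pos - 1
    if not 0 <= i < len(seq.bases):
        raise ValueError(f"position {site.chrom}:{site.pos} outside sequence {seq.name}")
    base = seq.bases[i].upper()
    ref, alt = site.ref.upper(), site.alt.upper()
    if base != ref:
        raise ValueError(
            f"reference mismatch at {site.chrom}:{site.pos}: expected {ref}, found {base}"
        )
    if i == 0 or i == len(seq.bases) - 1:
        ref_n, alt_n = (ref, alt) if ref in PYRIMIDINES else (
            reverse_complement(ref), reverse_complement(alt))
        return SubstitutionContext(site.chrom, site.pos, ref_n, alt_n, "NNN",
                                   f"{ref_n}>{alt_n}", "other")
    tri = seq.bases[i - 1 : i + 2].upper()
    if ref in PURINES:
        tri = reverse_complement(tri)
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    if "N" in tri:
        return SubstitutionContext(site.chrom, site.pos, ref, alt, "NNN",
                                   f"{ref}>{alt}", "other")
    return SubstitutionContext(
        site.chrom, site.pos, ref, alt, tri, f"{ref}>{alt}",
        classify_trinucleotide(tri, ref),
    )


def classify_cohort(mutations: pd.DataFrame,
                    sequences: dict[str, ReferenceSequence]) -> tuple[pd.DataFrame, dict]:
    """Classify every cohort mutation and summarize the spectrum.

    *mutations* columns: ``sample_id, chrom, pos, ref, alt`` (1-based
    positions).  Returns a tidy per-mutation table and a summary dict
    with the fraction of calls that are G>A / C>T on the forward strand
    (i.e. C>T after normalization) and the fraction in APOBEC-compatible
    (TCN) contexts; edge contexts (``NNN``) are excluded from the
    context denominators.
    """
    rows = []
    for rec in mutations.itertuples():
        seq = sequences.get(rec.chrom)
        if seq is None:
            raise KeyError(f"no reference sequence for {rec.chrom}")
        ctx = pyrimidine_context(seq, VariantSite(rec.chrom, int(rec.pos), rec.ref, rec.alt))
        rows.append(
            {"sample_id": rec.sample_id, "chrom": ctx.chrom, "pos": ctx.pos,
             "ref": ctx.ref, "alt": ctx.alt, "trinucleotide": ctx.trinucleotide,
             "substitution": ctx.substitution, "apobec_class": ctx.apobec_class}
        )
    table = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref", "alt",
                       "trinucleotide", "substitution", "apobec_class"])
    usable = table.loc[table["trinucleotide"] != "NNN"]
    n, n_usable = len(table), len(usable)
    summary = {
        "n_mutations": n,
        "fraction_c_to_t": float((table["substitution"] == "C>T").mean()) if n else float("nan"),
        "fraction_apobec_compatible": (
            float(usable["apobec_class"].isin(["TCA_optimal", "TCN_canonical"]).mean())
            if n_usable else float("nan")),
        "fraction_tca_optimal": (
            float((usable["apobec_class"] == "TCA_optimal").mean())
            if n_usable else float("nan")),
    }
    return table, summary
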