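"""Scan reference sequences for core motifs flanked by palindromic arms.

A *locus* here is an occurrence of a short core motif (e.g. ``TGAACA``)
whose flanks form a perfect inverted repeat: the ``k`` bases immediately
left of the core equal the reverse complement of the ``k`` bases
immediately right of it.  Such a construct can extrude as a DNA hairpin
with the core in the loop, exposing the core's cytosines to single-strand
mutagens (APOBEC deaminases in particular).  The arm length ``k`` is
always *maximal*: extending by one more base breaks complementarity or
runs off the sequence.

Two modes are provided:

* :func:`scan_core_motif` — fixed-core genome-wide search (both
  orientations of the core on the forward strand), with arm-length
  bounds, a homopolymer-arm filter and a soft-masking repeat filter.
* :func:`scan_variant_window` — discovery mode around a single variant:
  every 5–8 bp sub-pattern covering the variant is tried as a candidate
  core and kept when flanked by sufficiently long arms.

Coordinates are 0-based half-open internally; text I/O converts at the
boundary (see :mod:`palinsig.io`).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Mutable core offsets: positions within the core recurrently hit in
#: tumors.  For TGAACA these are the G at offset 1 and the C at offset 4
#: (3 bp apart); the AGATCA core mutates at the same two offsets.
DEFAULT_MUTABLE_OFFSETS = (1, 4)


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement, case-preserving, N maps to N.

    Raises ``ValueError`` naming the first offending position if *seq*
    contains a non-DNA character.
    """
    for i, ch in enumerate(seq):
        if ch not in "ACGTNacgtn":
            raise ValueError(f"non-DNA character {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """A named DNA sequence; lowercase bases mark soft-masked repeats."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        if not self.bases:
            raise ValueError(f"sequence {self.name!r} is empty")
        bad = set(self.bases) - set("ACGTNacgtn")
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains non-DNA characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class CoreMotif:
    """A candidate core pattern with its recurrently mutable offsets."""

    sequence: str
    mutable_offsets: tuple[int, ...] = DEFAULT_MUTABLE_OFFSETS

    def __post_init__(self) -> None:
        if not (5 <= len(self.sequence) <= 8):
            raise ValueError(
                f"core length must be 5-8, got {len(self.sequence)} ({self.sequence!r})"
            )
        if self.sequence != self.sequence.upper() or set(self.sequence) - set("ACGT"):
            raise ValueError(f"core must be uppercase ACGT, got {self.sequence!r}")
        for off in self.mutable_offsets:
            if not 0 <= off < len(self.sequence):
                raise ValueError(f"mutable offset {off} outside core of length {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PalindromicLocus:
    """One core-motif occurrence with its measured maximal arm.

    ``core_start`` is the 0-based forward-strand position of the first
    core base.  ``strand_label`` is ``"+"`` when the core motif itself
    matched the forward strand and ``"-"`` when its reverse complement
    did.  ``masked_fraction`` is the lowercase fraction over
    ``[core_start - arm_length, core_start + len(core) + arm_length)``.
    """

    chrom: str
    core_start: int
    core: CoreMotif
    arm_length: int
    strand_label: str
    masked_fraction: float = 0.0

    @property
    def core_end(self) -> int:
        return self.core_start + len(self.core)

    @property
    def mutable_positions(self) -> tuple[int, ...]:
        """0-based forward-strand genomic positions of the mutable bases."""
        return tuple(self.core_start + off for off in self.core.mutable_offsets)

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open span including both arms."""
        return (self.core_start - self.arm_length, self.core_end + self.arm_length)


@dataclass(frozen=True)
class VariantSite:
    """A single-nucleotide variant at a 1-based genomic position."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("ref and alt must be single bases")
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")


def max_arm_length(seq: ReferenceSequence | str, core_start: int, core_len: int) -> int:
    """Maximal perfect palindromic arm length around a core interval.

    Returns the largest ``k >= 0`` such that the ``k`` bases left of the
    core are the reverse complement of the ``k`` bases right of it.
    Comparison is case-insensitive; any ``N`` stops extension; the arm is
    bounded by the sequence ends.
    """
    bases = seq.bases if isinstance(seq, ReferenceSequence) else seq
    if core_start < 0 or core_start + core_len > len(bases):
        raise ValueError(
            f"core interval [{core_start}, {core_start + core_len}) outside sequence of length {len(bases)}"
        )
    up = bases.upper()
    right0 = core_start + core_len
    k = 0
    while core_start - k - 1 >= 0 and right0 + k < len(up):
        left = up[core_start - k - 1]
        right = up[right0 + k]
        if left == "N" or right == "N" or left != right.translate(_COMPLEMENT):
            break
        k += 1
    return k


def _masked_fraction(bases: str, start: int, end: int) -> float:
    window = bases[start:end]
    if not window:
        return 0.0
    return sum(ch.islower() for ch in window) / len(window)


def _is_homopolymer(s: str) -> bool:
    return len(set(s.upper())) == 1 if s else False


def is_arm_homopolymer(locus: PalindromicLocus, seq: ReferenceSequence) -> bool:
    """True iff either arm of *locus* is a single repeated base.

    A zero-length arm is vacuously not a homopolymer.  (For a perfect
    inverted repeat the two arms are homopolymers together — the left is
    the complement of the right — but both are checked for clarity.)
    """
    if locus.arm_length == 0:
        return False
    left = seq.bases[locus.core_start - locus.arm_length : locus.core_start]
    right = seq.bases[locus.core_end : locus.core_end + locus.arm_length]
    return _is_homopolymer(left) or _is_homopolymer(right)


def passes_repeat_filter(locus: PalindromicLocus, max_masked_fraction: float = 0.0) -> bool:
    """True iff the locus' soft-masked fraction is within the threshold."""
    return locus.masked_fraction <= max_masked_fraction


def scan_core_motif(
    seq: ReferenceSequence,
    core: CoreMotif,
    min_arm: int = 9,
    max_arm: int | None = 11,
    homopolymer_filter: bool = True,
) -> list[PalindromicLocus]:
    """Find all palindromic-arm occurrences of *core* in *seq*.

    Both the core and its reverse complement are searched on the forward
    strand, so loci on either genomic strand are reported with
    forward-strand coordinates.  Occurrences whose maximal arm length
    falls in ``[min_arm, max_arm]`` (``max_arm=None`` means unbounded
    above) are emitted, sorted by position.  Windows containing ``N``
    never match.  When the same interval matches in both orientations
    (self-complementary core) one record is kept.

    With ``homopolymer_filter`` (default on), loci whose arms are a
    single repeated base are dropped — mononucleotide runs satisfy the
    inverted-repeat definition trivially but are replication-slippage
    substrates, not hairpin-forming arms.
    """
    if min_arm < 1:
        raise ValueError("min_arm must be >= 1")
    up = seq.bases.upper()
    fwd = core.sequence
    rc = reverse_complement(fwd)
    hits: dict[tuple[int, int], PalindromicLocus] = {}
    for pattern, strand in ((fwd, "+"), (rc, "-")):
        start = up.find(pattern)
        while start != -1:
            key = (start, len(pattern))
            if key not in hits:
                arm = max_arm_length(seq, start, len(pattern))
                if arm >= min_arm and (max_arm is None or arm <= max_arm):
                    locus = PalindromicLocus(
                        chrom=seq.name,
                        core_start=start,
                        core=core,
                        arm_length=arm,
                        strand_label=strand,
                        masked_fraction=_masked_fraction(
                            seq.bases, start - arm, start + len(pattern) + arm
                        ),
                    )
                    if not (homopolymer_filter and is_arm_homopolymer(locus, seq)):
                        hits[key] = locus
                    else:
                        logger.debug(
                            "homopolymer-armed locus dropped at %s:%d", seq.name, start
                        )
            start = up.find(pattern, start + 1)
    return sorted(hits.values(), key=lambda l: (l.chrom, l.core_start))


def scan_genome(
    sequences: Iterable[ReferenceSequence],
    core: CoreMotif,
    min_arm: int = 9,
    max_arm: int | None = 11,
    homopolymer_filter: bool = True,
    max_masked_fraction: float | None = 0.0,
) -> list[PalindromicLocus]:
    """Scan every sequence of a (possibly large) reference, streaming.

    Applies :func:`scan_core_motif` per record and, when
    ``max_masked_fraction`` is not ``None``, keeps only loci passing the
    soft-masking repeat filter.  Suitable for a whole soft-masked genome:
    records are processed one at a time.
    """
    out: list[PalindromicLocus] = []
    for seq in sequences:
        for locus in scan_core_motif(seq, core, min_arm, max_arm, homopolymer_filter):
            if max_masked_fraction is None or passes_repeat_filter(locus, max_masked_fraction):
                out.append(locus)
    return out


@dataclass(frozen=True)
class WindowCandidate:
    """A candidate core found around a variant inside a search window."""

    core_start_in_window: int
    core_len: int
    arm_length: int

    @property
    def core_end_in_window(self) -> int:
        return self.core_start_in_window + self.core_len


def scan_variant_window(
    window: str,
    variant_offset: int = 30,
    core_len_range: tuple[int, int] = (5, 8),
    min_arm: int = 8,
) -> list[WindowCandidate]:
    """Discovery mode: enumerate candidate cores covering a variant.

    *window* is the reference context with the alternate allele already
    substituted at *variant_offset* (0-based within the window; the
    default matches a +/-30 bp extraction).  Every sub-pattern of length
    5–8 containing the variant is tried; a candidate is reported when its
    maximal flanking arms reach *min_arm* on each side, unless the
    pattern or either arm is a homopolymer.
    """
    if not 0 <= variant_offset < len(window):
        raise ValueError(f"variant offset {variant_offset} outside window of length {len(window)}")
    lo, hi = core_len_range
    if len(window) < 2 * min_arm + lo:
        logger.warning(
            "window of length %d too short for arms of %d around a %d bp core",
            len(window), min_arm, lo,
        )
        return []
    ref = ReferenceSequence("window", window)
    out: list[WindowCandidate] = []
    for core_len in range(lo, hi + 1):
        for start in range(variant_offset - core_len + 1, variant_offset + 1):
            if start < 0 or start + core_len > len(window):
                continue
            pattern = window[start : start + core_len]
            if "N" in pattern.upper() or _is_homopolymer(pattern):
                continue
            arm = max_arm_length(ref, start, core_len)
            if arm < min_arm:
                continue
            left = window[start - arm : start]
            right = window[start + core_len : start + core_len + arm]
            if _is_homopolymer(left) or _is_homopolymer(right):
                continue
            out.append(WindowCandidate(start, core_len, arm))
    return sorted(out, key=lambda c: (c.core_start_in_window, c.core_len))
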