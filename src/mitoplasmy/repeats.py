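"""Per-read repeat-length calling and multiplasmy classification.

Multiplasmy is heteroplasmy of repeat *length*: several repeat-unit counts
coexisting at a variable-length locus within one sample (e.g. a mixture of
(CA)5, (CA)6 and (CA)7 molecules at the D-loop dinucleotide repeat starting
at position 514). Lengths are read directly off individual reads that span
the locus between two exact-match flanking anchors; there is no alignment
and no stutter denoising — the raw length mixture is reported, and support
thresholds decide which lengths count as alleles.

The three default loci are the ones known to vary in the D-loop:

* 514 (CA)n dinucleotide repeat, reference (CA)5;
* D310, the poly-C tract 5' of the fixed T at 308 (CCCCCTCCCCC);
* D16189, the poly-C tract 5' of the fixed T at 16189 (CCCCCTCCCC).

For the two poly-C tracts the fixed T is the first base of the right
anchor, so a T->C substitution that fuses the tract makes reads
non-spanning rather than producing a spurious length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .reference import MitoReference


class RepeatError(ValueError):
    pass


NOT_SPANNING = None  # sentinel returned by extract_repeat_length


@dataclass(frozen=True)
class RepeatLocusSpec:
    """A repeat locus defined by its unit and exact flanking anchors."""

    name: str
    unit: str
    reference_units: int
    left_anchor: str
    right_anchor: str
    max_anchor_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.unit:
            raise RepeatError("repeat unit must be non-empty")
        for anchor, side in ((self.left_anchor, "left"), (self.right_anchor, "right")):
            if not anchor:
                raise RepeatError(f"{side} anchor must be non-empty")
        if self.left_anchor.upper().endswith(self.unit.upper()):
            raise RepeatError(
                f"{self.name}: left anchor ends with a full unit copy"
            )
        if self.right_anchor.upper().startswith(self.unit.upper()):
            raise RepeatError(
                f"{self.name}: right anchor starts with a full unit copy"
            )


@dataclass(frozen=True)
class RepeatLengthDistribution:
    locus: RepeatLocusSpec
    counts: dict[int, int]
    n_discarded: int

    @property
    def n_spanning(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MultiplasmyCall:
    locus_name: str
    alleles: tuple[int, ...]  # supported repeat lengths, ascending
    fractions: dict[int, float]
    is_multiplasmic: bool
    abstained: bool = False


def _matches(a: str, b: str, max_mismatches: int) -> bool:
    if len(a) != len(b):
        return False
    if max_mismatches == 0:
        return a == b
    return sum(x != y for x, y in zip(a, b)) <= max_mismatches


def extract_repeat_length(read_sequence: str, locus: RepeatLocusSpec) -> int | None:
    """Number of complete unit copies between the anchors, or not-spanning.

    Both anchors must match (within ``max_anchor_mismatches``, default
    exact) and only whole or partial copies of the unit may lie between
    them; anything else — including reads that end inside the locus —
    is not-spanning (``None``).
    """
    read = read_sequence.upper()
    unit = locus.unit.upper()
    left = locus.left_anchor.upper()
    right = locus.right_anchor.upper()
    start = read.find(left) if locus.max_anchor_mismatches == 0 else _fuzzy_find(
        read, left, locus.max_anchor_mismatches
    )
    if start < 0:
        return NOT_SPANNING
    i = start + len(left)
    n_units = 0
    u = len(unit)
    while read[i : i + u] == unit:
        n_units += 1
        i += u
    # optionally one partial unit copy (proper prefix of the unit)
    partial = 0
    while partial < u - 1 and i + partial < len(read) and read[i + partial] == unit[partial]:
        partial += 1
    for trail in (0, partial):
        j = i + trail
        if j + len(right) <= len(read) and _matches(
            read[j : j + len(right)], right, locus.max_anchor_mismatches
        ):
            return n_units
    return NOT_SPANNING


def _fuzzy_find(read: str, anchor: str, max_mismatches: int) -> int:
    best = -1
    for s in range(len(read) - len(anchor) + 1):
        if _matches(read[s : s + len(anchor)], anchor, max_mismatches):
            return s
    return best


def repeat_distribution(
    reads: Iterable[str], locus: RepeatLocusSpec
) -> RepeatLengthDistribution:
    """Tally per-read repeat lengths; non-spanning reads are counted, not used."""
    counts: Counter[int] = Counter()
    discarded = 0
    for read in reads:
        length = extract_repeat_length(read, locus)
        if length is NOT_SPANNING:
            discarded += 1
        else:
            counts[length] += 1
    return RepeatLengthDistribution(
        locus=locus, counts=dict(counts), n_discarded=discarded
    )


def call_multiplasmy(
    dist: RepeatLengthDistribution,
    min_fraction: float = 0.05,
    min_reads: int = 10,
) -> MultiplasmyCall:
    """Lengths with count >= min_reads and fraction >= min_fraction are
    alleles; two or more supported alleles is multiplasmy. With no
    spanning reads the call abstains rather than raising."""
    n = dist.n_spanning
    if n == 0:
        return MultiplasmyCall(
            locus_name=dist.locus.name,
            alleles=(),
            fractions={},
            is_multiplasmic=False,
            abstained=True,
        )
    supported = sorted(
        length
        for length, count in dist.counts.items()
        if count >= min_reads and count / n >= min_fraction
    )
    fractions = {length: dist.counts[length] / n for length in supported}
    return MultiplasmyCall(
        locus_name=dist.locus.name,
        alleles=tuple(supported),
        fractions=fractions,
        is_multiplasmic=len(supported) >= 2,
    )


@dataclass(frozen=True)
class DeletionRatio:
    ratio: float | None  # None when undefined (no reference-length reads)
    n_deleted: int
    n_reference: int


def deletion_ratio(
    dist: RepeatLengthDistribution, reference_units: int | None = None
) -> DeletionRatio:
    """Reads with fewer units than reference over reads at reference length."""
    ref_units = (
        reference_units if reference_units is not None else dist.locus.reference_units
    )
    n_del = sum(c for length, c in dist.counts.items() if length < ref_units)
    n_ref = dist.counts.get(ref_units, 0)
    if n_ref == 0:
        return DeletionRatio(ratio=None, n_deleted=n_del, n_reference=0)
    return DeletionRatio(ratio=n_del / n_ref, n_deleted=n_del, n_reference=n_ref)


# ---------------------------------------------------------------------------
# Default locus configuration
# ---------------------------------------------------------------------------

#: (name, unit, reference_units, locus start, locus end) — anchors are taken
#: from the reference immediately outside [start, end].
DEFAULT_LOCUS_LAYOUT: tuple[tuple[str, str, int, int, int], ...] = (
    ("CA514", "CA", 5, 514, 523),
    ("D310", "C", 5, 303, 307),
    ("D16189", "C", 5, 16184, 16188),
)


def default_repeat_loci(
    ref: MitoReference, anchor_len: int = 5
) -> dict[str, RepeatLocusSpec]:
    """The three D-loop repeat loci with anchors read off the reference."""
    loci = {}
    for name, unit, ref_units, start, end in DEFAULT_LOCUS_LAYOUT:
        loci[name] = RepeatLocusSpec(
            name=name,
            unit=unit,
            reference_units=ref_units,
            left_anchor=ref.slice(start - anchor_len, start - 1),
            right_anchor=ref.slice(end + 1, end + anchor_len),
        )
    return loci


def reads_from_fastq(path) -> list[str]:
    """Plain sequences from a FASTQ file (qualities are ignored)."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
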