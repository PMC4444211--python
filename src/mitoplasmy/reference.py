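"""Circular human mitochondrial reference model.

Holds the 16,569-base reference sequence, the NC_012920 gene model (13
protein-coding genes, 2 rRNAs, 22 tRNAs), the control-region map, and the
vertebrate mitochondrial genetic code, and provides the coordinate and codon
arithmetic every downstream stage relies on.

Conventions
-----------
* Positions are 1-based and inclusive, the universal convention for human
  mtDNA (rCRS numbering).
* The genome is circular: all index arithmetic wraps modulo the genome
  length. Wrap-around is handled here and nowhere else in the package.
* The rCRS carries an ``N`` placeholder at position 3107 (a historical
  artifact of the original Cambridge sequence); operations that touch an
  ``N`` report it explicitly instead of silently translating through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

RCRS_LENGTH = 16_569
RCRS_PLACEHOLDER_POSITION = 3107

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Vertebrate mitochondrial genetic code (NCBI translation table 2):
#: ATA=Met, TGA=Trp, and AGA/AGG are stops.
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


class ReferenceError(ValueError):
    """Raised for malformed reference input or out-of-contract coordinates."""


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid map for the vertebrate mitochondrial code."""

    forward: dict[str, str] = field(
        default_factory=lambda: dict(_MITO_TABLE.forward_table)
    )
    stop_codons: frozenset[str] = field(
        default_factory=lambda: frozenset(_MITO_TABLE.stop_codons)
    )

    def translate(self, codon: str) -> str | None:
        """One-letter amino acid for ``codon``, ``*`` for a stop.

        Returns ``None`` (untranslatable) when the codon contains an ``N``
        or any symbol outside {A,C,G,T}; this is a result, not an error,
        because rCRS position 3107 legitimately produces such codons.
        """
        codon = codon.upper()
        if len(codon) != 3:
            raise ReferenceError(f"codon must have 3 bases, got {codon!r}")
        if any(b not in "ACGT" for b in codon):
            return None
        if codon in self.stop_codons:
            return "*"
        return self.forward[codon]

    def translate3(self, codon: str) -> str | None:
        """Three-letter form (``Met``, ``Ter``) of :meth:`translate`."""
        aa = self.translate(codon)
        return None if aa is None else _AA3[aa]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons


VERTEBRATE_MITO_CODE = GeneticCode()


def translate(codon: str, code: GeneticCode = VERTEBRATE_MITO_CODE) -> str | None:
    """Module-level convenience wrapper around :meth:`GeneticCode.translate3`."""
    return code.translate3(codon)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MitoReference:
    """A circular mitochondrial reference sequence (1-based positions)."""

    sequence: str
    name: str = "rCRS"

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ReferenceError(f"non-ACGTN symbols in reference: {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_placeholder_n(self) -> bool:
        """True when position 3107 carries the rCRS 'N' placeholder."""
        return (
            len(self.sequence) >= RCRS_PLACEHOLDER_POSITION
            and self.sequence[RCRS_PLACEHOLDER_POSITION - 1] == "N"
        )

    def base(self, position: int) -> str:
        """Base at a 1-based position, wrapping circularly."""
        return self.sequence[(position - 1) % len(self.sequence)]

    def slice(self, start: int, end: int) -> str:
        """Bases from ``start`` to ``end`` inclusive (1-based), wrapping.

        ``end`` may be numerically smaller than ``start`` for intervals
        spanning the origin (e.g. the control region 16024..576).
        """
        n = len(self.sequence)
        start0 = (start - 1) % n
        end0 = (end - 1) % n
        if start0 <= end0:
            return self.sequence[start0 : end0 + 1]
        return self.sequence[start0:] + self.sequence[: end0 + 1]


def load_reference(
    fasta_path: str | Path,
    *,
    allow_any_length: bool = False,
) -> MitoReference:
    """Load a single-record FASTA as a :class:`MitoReference`.

    The loader enforces the rCRS length of 16,569 bases unless
    ``allow_any_length`` is set (non-human genomes are otherwise out of
    scope). Multi-record FASTA and non-ACGTN symbols are rejected.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ReferenceError(
            f"expected exactly one FASTA record in {fasta_path}, got {len(records)}"
        )
    record = records[0]
    seq = str(record.seq).upper()
    if len(seq) != RCRS_LENGTH and not allow_any_length:
        raise ReferenceError(
            f"reference length {len(seq)} != {RCRS_LENGTH}; "
            "pass allow_any_length=True to override"
        )
    return MitoReference(sequence=seq, name=record.id)


def default_reference() -> MitoReference:
    """The packaged reference (a synthetic rCRS stand-in; see its header)."""
    with resources.as_file(
        resources.files("mitoplasmy.data") / "synthetic_rcrs.fa"
    ) as p:
        return load_reference(p)


def context_window(ref: MitoReference, position: int, flank: int) -> str:
    """(2*flank+1)-base window centred on ``position``, wrapping circularly.

    The centre base is upper-case and the flanks lower-case, the convention
    used when printing error-hotspot contexts.
    """
    if flank < 0:
        raise ReferenceError("flank must be >= 0")
    if not 1 <= position <= len(ref):
        raise ReferenceError(f"position {position} outside 1..{len(ref)}")
    left = ref.slice(position - flank, position - 1).lower() if flank else ""
    right = ref.slice(position + 1, position + flank).lower() if flank else ""
    return left + ref.base(position).upper() + right


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature of the mitochondrial genome.

    ``strand`` is ``heavy`` or ``light``; the only light-strand protein
    gene is ND6, whose codons are read reverse-complemented from the
    heavy-strand sequence, 3' to 5' in heavy-strand coordinates.
    """

    name: str
    start: int
    end: int
    strand: str
    kind: str  # protein | tRNA | rRNA

    def __post_init__(self) -> None:
        if self.strand not in ("heavy", "light"):
            raise ReferenceError(f"bad strand {self.strand!r} for {self.name}")
        if self.kind not in ("protein", "tRNA", "rRNA"):
            raise ReferenceError(f"bad kind {self.kind!r} for {self.name}")
        if self.end < self.start:
            raise ReferenceError(f"{self.name}: end < start (origin-spanning genes unsupported)")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def incomplete_stop(self) -> bool:
        """True for genes whose terminal stop codon is completed by polyadenylation."""
        return self.kind == "protein" and self.length % 3 != 0

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def load_gene_model(path: str | Path | None = None) -> list[GeneFeature]:
    """Load the gene model TSV (columns: name, start, end, strand, kind).

    The packaged model is a versioned snapshot of the NC_012920 annotation;
    nothing is fetched at runtime.
    """
    if path is None:
        with resources.as_file(
            resources.files("mitoplasmy.data") / "gene_model.tsv"
        ) as p:
            return load_gene_model(p)
    genes: list[GeneFeature] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "name":  # header
            continue
        if len(fields) != 5:
            raise ReferenceError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        name, start, end, strand, kind = fields
        genes.append(GeneFeature(name, int(start), int(end), strand, kind))
    return genes


def genes_at(genes: Iterable[GeneFeature], position: int, kind: str | None = None) -> list[GeneFeature]:
    """All gene features containing ``position`` (overlaps give several)."""
    hits = [g for g in genes if g.contains(position)]
    if kind is not None:
        hits = [g for g in hits if g.kind == kind]
    return hits


def codon_at(
    ref: MitoReference, gene: GeneFeature, position: int
) -> tuple[int, int, str]:
    """Codon index, offset within codon, and coding-strand codon bases.

    Heavy strand: codon index of position p is ``(p - start)//3 + 1``.
    Light strand (ND6): codon index is ``(end - p)//3 + 1`` and the codon
    is read reverse-complemented. The trailing partial codon of genes with
    incomplete stops is returned padded with ``-``.
    """
    if gene.kind != "protein":
        raise ReferenceError(f"{gene.name} is not protein-coding")
    if not gene.contains(position):
        raise ReferenceError(
            f"position {position} outside {gene.name} ({gene.start}..{gene.end})"
        )
    if gene.strand == "heavy":
        idx0 = position - gene.start
        codon_index = idx0 // 3 + 1
        offset = idx0 % 3
        c_start = gene.start + 3 * (codon_index - 1)
        bases = "".join(
            ref.base(p) if p <= gene.end else "-" for p in range(c_start, c_start + 3)
        )
    else:
        idx0 = gene.end - position
        codon_index = idx0 // 3 + 1
        offset = idx0 % 3
        c_end = gene.end - 3 * (codon_index - 1)  # heavy-strand coordinate of codon base 1
        heavy = "".join(
            ref.base(p) if p >= gene.start else "-"
            for p in range(c_end - 2, c_end + 1)
        )
        bases = reverse_complement(heavy.replace("-", "N")).replace("N", "-") \
            if "-" in heavy else reverse_complement(heavy)
    return codon_index, offset, bases


# ---------------------------------------------------------------------------
# Region map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMap:
    """Maps every reference position to one primary region class.

    The control region (D-loop) spans the circular origin, 16024..576.
    The hypervariable poly-C tracts D310 and D16189 and the 514..523 (CA)n
    repeat are carried as named sub-intervals of the control region.
    """

    genes: tuple[GeneFeature, ...]
    genome_length: int = RCRS_LENGTH
    control_start: int = 16024
    control_end: int = 576
    d310: tuple[int, int] = (303, 315)
    d16189: tuple[int, int] = (16184, 16193)
    ca_repeat: tuple[int, int] = (514, 523)

    def in_control_region(self, position: int) -> bool:
        return position >= self.control_start or position <= self.control_end

    def region_class(self, position: int) -> str:
        """One of control, protein, tRNA, rRNA, intergenic.

        Priority order control > protein > tRNA > rRNA resolves the rare
        feature overlaps so the classification is a partition.
        """
        if not 1 <= position <= self.genome_length:
            raise ReferenceError(f"position {position} outside genome")
        if self.in_control_region(position):
            return "control"
        kinds = {g.kind for g in self.genes if g.contains(position)}
        for kind in ("protein", "tRNA", "rRNA"):
            if kind in kinds:
                return kind
        return "intergenic"


def default_region_map(genes: Iterable[GeneFeature] | None = None) -> RegionMap:
    return RegionMap(genes=tuple(genes if genes is not None else load_gene_model()))
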