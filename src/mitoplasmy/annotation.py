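"""Variant consequence annotation, novelty classification, haplogroup exclusion.

Consequences are computed under the vertebrate mitochondrial genetic code,
with light-strand genes (ND6) handled by reverse-complementing the codon.
Variants in gene overlaps (ATP8/ATP6, ND4L/ND4) receive one consequence per
overlapping gene; for burden counting a variant is non-synonymous if it is
non-synonymous in at least one of them. Damage-prediction labels are opaque
pass-through strings from an external predictor, never recomputed.

Novelty is judged against a user-supplied frequency catalog: *novel* means
never observed, *rare* means observed at a frequency below 0.1% of catalog
genomes, *known* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .calling import ThresholdConfig, VariantCall
from .reference import (
    GeneFeature,
    GeneticCode,
    MitoReference,
    RegionMap,
    ReferenceError,
    VERTEBRATE_MITO_CODE,
    codon_at,
    genes_at,
    reverse_complement,
)

#: Gene priority used by report writers when a variant hits an overlap; the
#: first overlapping gene in this order is the one printed.
GENE_PRIORITY = (
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneConsequence:
    gene: str
    codon_index: int
    ref_aa: str | None  # three-letter; None when untranslatable (N in codon)
    alt_aa: str | None
    synonymous: bool | None

    @property
    def aa_change(self) -> str | None:
        if self.ref_aa is None or self.alt_aa is None:
            return None
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


@dataclass(frozen=True)
class ConsequenceAnnotation:
    position: int
    ref: str
    alt: str
    genes: tuple[GeneConsequence, ...]
    region_class: str
    damage_label: str | None = None

    @property
    def primary(self) -> GeneConsequence | None:
        """The consequence in the highest-priority overlapping gene."""
        if not self.genes:
            return None
        order = {g: i for i, g in enumerate(GENE_PRIORITY)}
        return min(self.genes, key=lambda gc: order.get(gc.gene, len(order)))

    @property
    def is_nonsynonymous(self) -> bool:
        """Non-synonymous in at least one overlapping gene."""
        return any(gc.synonymous is False for gc in self.genes)

    @property
    def is_coding(self) -> bool:
        return bool(self.genes)


def annotate_variant(
    call: VariantCall | tuple[int, str, str],
    ref: MitoReference,
    genes: list[GeneFeature],
    region_map: RegionMap,
    code: GeneticCode = VERTEBRATE_MITO_CODE,
    damage_label: str | None = None,
) -> ConsequenceAnnotation:
    """Annotate a single-base substitution.

    Accepts a :class:`VariantCall` or a bare ``(position, ref, alt)``
    triple. The stated reference base must match the reference sequence
    (an ``N`` reference matches anything and yields untranslatable
    consequences, which burden tallies exclude).
    """
    if isinstance(call, VariantCall):
        position, ref_base, alt = call.position, call.ref_base, call.alt
    else:
        position, ref_base, alt = call
    ref_base, alt = ref_base.upper(), alt.upper()
    actual = ref.base(position)
    if actual != ref_base:
        raise AnnotationError(
            f"reference mismatch at {position}: call says {ref_base!r}, "
            f"reference has {actual!r}"
        )
    consequences: list[GeneConsequence] = []
    for gene in genes_at(genes, position, kind="protein"):
        codon_index, offset, codon = codon_at(ref, gene, position)
        if "-" in codon:  # incomplete terminal codon
            consequences.append(
                GeneConsequence(gene.name, codon_index, None, None, None)
            )
            continue
        if gene.strand == "heavy":
            alt_codon = codon[:offset] + alt + codon[offset + 1 :]
        else:
            alt_codon = (
                codon[:offset] + reverse_complement(alt) + codon[offset + 1 :]
            )
        ref_aa = code.translate3(codon)
        alt_aa = code.translate3(alt_codon)
        synonymous = None if ref_aa is None or alt_aa is None else ref_aa == alt_aa
        consequences.append(
            GeneConsequence(gene.name, codon_index, ref_aa, alt_aa, synonymous)
        )
    return ConsequenceAnnotation(
        position=position,
        ref=ref_base,
        alt=alt,
        genes=tuple(consequences),
        region_class=region_map.region_class(position),
        damage_label=damage_label,
    )


# ---------------------------------------------------------------------------
# Novelty / rarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogEntry:
    position: int
    alt: str
    observed_count: int
    catalog_size: int
    self_deposit: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.observed_count <= self.catalog_size:
            raise AnnotationError(
                f"catalog count {self.observed_count} outside 0..{self.catalog_size}"
            )


@dataclass(frozen=True)
class NoveltyStatus:
    status: str  # novel | rare | known | unknown
    frequency: float | None


def load_catalog(path: str | Path | None = None) -> dict[tuple[int, str], CatalogEntry]:
    """Catalog TSV (position, alt, count, catalog_size[, self])."""
    if path is None:
        with resources.as_file(resources.files("mitoplasmy.data") / "catalog.tsv") as p:
            return load_catalog(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    catalog = {}
    for _, row in df.iterrows():
        entry = CatalogEntry(
            position=int(row["position"]),
            alt=str(row["alt"]).upper(),
            observed_count=int(row["count"]),
            catalog_size=int(row["catalog_size"]),
            self_deposit=bool(row.get("self", 0)),
        )
        catalog[(entry.position, entry.alt)] = entry
    return catalog


def classify_novelty(
    call: VariantCall | tuple[int, str],
    catalog: dict[tuple[int, str], CatalogEntry] | None,
    thresholds: ThresholdConfig = ThresholdConfig(),
    discount_self: bool = False,
) -> NoveltyStatus:
    """novel (count 0) / rare (frequency < 0.1%) / known; unknown w/o catalog.

    With ``discount_self`` a single observation attributable to this
    cohort's own catalog deposit is subtracted before classifying.
    """
    if catalog is None:
        return NoveltyStatus("unknown", None)
    if isinstance(call, VariantCall):
        key = (call.position, call.alt)
    else:
        key = (call[0], call[1].upper())
    entry = catalog.get(key)
    if entry is None:
        return NoveltyStatus("novel", 0.0)
    count = entry.observed_count
    if discount_self and entry.self_deposit:
        count = max(count - 1, 0)
    freq = count / entry.catalog_size
    if count == 0:
        return NoveltyStatus("novel", 0.0)
    if freq < thresholds.rare_catalog_freq_max:
        return NoveltyStatus("rare", freq)
    return NoveltyStatus("known", freq)


# ---------------------------------------------------------------------------
# Haplogroup-defining variant exclusion
# ---------------------------------------------------------------------------

def load_haplogroup_table(path: str | Path) -> set[tuple[int, str]]:
    """Haplogroup-defining (position, alt) pairs, TSV columns position, alt."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {(int(r.position), str(r.alt).upper()) for r in df.itertuples(index=False)}


def exclude_haplogroup_defining(
    calls: list[VariantCall],
    haplogroup_table: set[tuple[int, str]],
) -> tuple[list[VariantCall], list[VariantCall]]:
    """(retained, excluded): calls matching a table (position, alt) pair move
    to excluded. A matching position with a different allele is retained."""
    retained, excluded = [], []
    for call in calls:
        if (call.position, call.alt) in haplogroup_table:
            excluded.append(call)
        else:
            retained.append(call)
    return retained, excluded
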