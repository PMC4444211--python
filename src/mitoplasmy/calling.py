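"""Homoplasmy / heteroplasmy classification from per-position allele counts.

The classification rule: a site is *heteroplasmic* when the major allele is
below 95% of the observed reads, a *homoplasmic variant* when the major
allele is at least 95% and differs from the reference, and *reference*
otherwise. Sites with fewer than 200 reads are filtered, not classified.
The 95% boundary is inclusive for homoplasmy (a major fraction of exactly
0.95 is homoplasmic), the only reading consistent with defining homoplasmy
as "95% to 100%" and heteroplasmy as "<95%".

Heteroplasmy level is reported as the fraction of reads supporting the
(largest) non-reference allele, so a site that is 90% C / 10% T with
reference T has level 0.90.

Deletions participate in depth but are never called as substitution
variants; length variation is handled at designated repeat loci by
:mod:`mitoplasmy.repeats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import MitoReference

BASES = ("A", "C", "G", "T")
COUNT_COLUMNS = ("pos", "A", "C", "G", "T", "del")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdConfig:
    """Classification thresholds.

    homoplasmy_major_min
        Minimum major-allele fraction for a homoplasmic call (default 0.95,
        inclusive); anything below is heteroplasmic.
    min_coverage
        Minimum read depth for a site to be classified at all (default 200).
    blood_detection_min
        Heteroplasmy level below which a variant counts as undetectable in
        blood (default 0.05).
    rare_catalog_freq_max
        Catalog frequency below which a known variant is "rare"
        (default 0.001, i.e. <0.1% of catalog genomes).
    """

    homoplasmy_major_min: float = 0.95
    min_coverage: int = 200
    blood_detection_min: float = 0.05
    rare_catalog_freq_max: float = 0.001

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise CallingError("min_coverage must be >= 1")
        if not 0 < self.blood_detection_min <= 1 - self.homoplasmy_major_min + 1e-12:
            raise CallingError(
                "blood_detection_min must lie in (0, 1 - homoplasmy_major_min]"
            )


@dataclass(frozen=True)
class AlleleCounts:
    """Read tallies for one reference position."""

    position: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for base, n in self.counts.items():
            if base not in BASES and base != "del":
                raise CallingError(f"unknown allele key {base!r}")
            if n < 0:
                raise CallingError(f"negative count at {self.position}")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def count(self, base: str) -> int:
        return self.counts.get(base, 0)


@dataclass(frozen=True)
class VariantCall:
    position: int
    ref_base: str
    major_allele: str
    major_fraction: float
    alleles: tuple[tuple[str, float], ...]  # (base, fraction), descending
    classification: str  # homoplasmic_variant | heteroplasmic | reference
    heteroplasmy_level: float  # fraction of the largest non-reference allele
    coverage: int
    tie_broken: bool = False

    @property
    def alt(self) -> str:
        """The (largest) non-reference allele this call reports."""
        if self.major_allele != self.ref_base:
            return self.major_allele
        for base, _ in self.alleles:
            if base != self.ref_base:
                return base
        return self.major_allele

    @property
    def is_variant(self) -> bool:
        return self.classification != "reference"


@dataclass(frozen=True)
class FilteredSite:
    position: int
    reason: str
    coverage: int


@dataclass
class SampleCalls:
    """Per-sample call set with counts at each filtering stage."""

    sample: str
    calls: list[VariantCall]
    filtered: list[FilteredSite]
    n_positions: int = 0

    @property
    def n_homoplasmic(self) -> int:
        return sum(c.classification == "homoplasmic_variant" for c in self.calls)

    @property
    def n_heteroplasmic(self) -> int:
        return sum(c.classification == "heteroplasmic" for c in self.calls)

    def summary(self) -> dict[str, int]:
        return {
            "positions": self.n_positions,
            "homoplasmic": self.n_homoplasmic,
            "heteroplasmic": self.n_heteroplasmic,
            "filtered": len(self.filtered),
        }


@dataclass(frozen=True)
class ConsensusSequence:
    sample: str
    bases: str
    mask: tuple[int, ...]  # 1-based positions failing min_coverage (carry 'N')


def classify_position(
    counts: AlleleCounts,
    ref_base: str,
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> VariantCall | FilteredSite:
    """Classify one site per the major-allele-fraction rule.

    Returns a :class:`FilteredSite` when depth < ``min_coverage``. The major
    allele is the most-supported base (A/C/G/T; deletions count toward depth
    only); ties are broken by base order A<C<G<T and flagged.
    """
    ref_base = ref_base.upper()
    if ref_base not in ("A", "C", "G", "T", "N"):
        raise CallingError(f"invalid reference base {ref_base!r}")
    depth = counts.depth
    if depth < thresholds.min_coverage:
        return FilteredSite(
            counts.position, f"coverage < {thresholds.min_coverage}", depth
        )
    base_counts = [(b, counts.count(b)) for b in BASES]
    top = max(n for _, n in base_counts)
    major = next(b for b, n in base_counts if n == top)  # A<C<G<T tie-break
    tie = sum(n == top for _, n in base_counts) > 1
    fractions = sorted(
        ((b, n / depth) for b, n in base_counts if n > 0),
        key=lambda bf: (-bf[1], bf[0]),
    )
    if counts.count("del"):
        fractions.append(("del", counts.count("del") / depth))
    major_fraction = top / depth
    het_level = max(
        (n / depth for b, n in base_counts if b != ref_base), default=0.0
    )
    if major_fraction < thresholds.homoplasmy_major_min:
        classification = "heteroplasmic"
    elif major != ref_base:
        classification = "homoplasmic_variant"
    else:
        classification = "reference"
    return VariantCall(
        position=counts.position,
        ref_base=ref_base,
        major_allele=major,
        major_fraction=major_fraction,
        alleles=tuple(fractions),
        classification=classification,
        heteroplasmy_level=het_level,
        coverage=depth,
        tie_broken=tie,
    )


def transition_or_transversion(ref_base: str, alt_base: str) -> str:
    """Purine<->purine or pyrimidine<->pyrimidine is a transition."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base == alt_base:
        raise CallingError("ref and alt bases are identical")
    for b in (ref_base, alt_base):
        if b not in BASES:
            raise CallingError(f"invalid base {b!r}")
    same_class = ({ref_base, alt_base} <= PURINES) or (
        {ref_base, alt_base} <= PYRIMIDINES
    )
    return "transition" if same_class else "transversion"


# ---------------------------------------------------------------------------
# Count tables (TSV with header "pos A C G T del")
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise CallingError(f"count table {path} missing columns {sorted(missing)}")
    return df[list(COUNT_COLUMNS)]


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _validate_table(count_table: pd.DataFrame) -> pd.DataFrame:
    df = count_table
    if df["pos"].duplicated().any():
        dup = df.loc[df["pos"].duplicated(), "pos"].iloc[0]
        raise CallingError(f"duplicate position {int(dup)} in count table")
    return df


def call_sample(
    count_table: pd.DataFrame,
    ref: MitoReference,
    thresholds: ThresholdConfig = ThresholdConfig(),
    sample: str = "sample",
) -> SampleCalls:
    """Classify every tabulated position; keep non-reference calls.

    The scan is vectorised: depth, major allele and fractions are computed
    across the whole table with numpy, and :func:`classify_position` is
    only invoked on the (few) sites that are not plain reference matches,
    so calling a full genome is cheap at any coverage.
    """
    df = _validate_table(count_table)
    mat = df[["A", "C", "G", "T"]].to_numpy(dtype=np.int64)
    dels = df["del"].to_numpy(dtype=np.int64)
    pos = df["pos"].to_numpy(dtype=np.int64)
    depth = mat.sum(axis=1) + dels
    ref_bases = np.array([ref.base(int(p)) for p in pos])
    base_idx = {b: i for i, b in enumerate(BASES)}

    low = depth < thresholds.min_coverage
    top = mat.max(axis=1)
    major = np.array(BASES)[mat.argmax(axis=1)]  # argmax ties -> lowest index = A<C<G<T
    with np.errstate(invalid="ignore", divide="ignore"):
        major_frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    is_het = ~low & (major_frac < thresholds.homoplasmy_major_min)
    is_hom_var = ~low & ~is_het & (major != ref_bases)
    interesting = np.flatnonzero(low | is_het | is_hom_var | (ref_bases == "N"))

    calls: list[VariantCall] = []
    filtered: list[FilteredSite] = []
    for i in interesting:
        counts = AlleleCounts(
            int(pos[i]),
            {**{b: int(mat[i, base_idx[b]]) for b in BASES}, "del": int(dels[i])},
        )
        result = classify_position(counts, str(ref_bases[i]), thresholds)
        if isinstance(result, FilteredSite):
            filtered.append(result)
        elif result.is_variant:
            calls.append(result)
    return SampleCalls(
        sample=sample, calls=calls, filtered=filtered, n_positions=len(df)
    )


def build_consensus(
    count_table: pd.DataFrame,
    thresholds: ThresholdConfig = ThresholdConfig(),
    sample: str = "sample",
    genome_length: int | None = None,
) -> ConsensusSequence:
    """Major allele at every passing position; 'N' where filtered or absent."""
    df = _validate_table(count_table)
    length = genome_length if genome_length is not None else int(df["pos"].max())
    bases = np.full(length, "N", dtype="<U1")
    mat = df[["A", "C", "G", "T"]].to_numpy(dtype=np.int64)
    depth = mat.sum(axis=1) + df["del"].to_numpy(dtype=np.int64)
    pos = df["pos"].to_numpy(dtype=np.int64)
    ok = depth >= thresholds.min_coverage
    bases[pos[ok] - 1] = np.array(BASES)[mat.argmax(axis=1)][ok]
    mask = tuple(int(p) for p in np.flatnonzero(bases == "N") + 1)
    return ConsensusSequence(sample=sample, bases="".join(bases), mask=mask)
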