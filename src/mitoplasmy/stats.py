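"""Case/control cohort statistics for mtDNA mutation burden.

The burden analysis counts, per diagnosis group, non-synonymous homoplasmic
variants observed *only* on one side of the case/control split (case-only
vs control-only loci), converts them to per-subject rates, and standardises
each group's rate against the pooled rate with a Poisson-rate z. Cases
default to {BD, MDD, SZ}; METH users are a separate group kept out of the
case/control partition. Artifact-flagged and haplogroup-defining calls are
excluded from burden by default; every inclusion criterion is a toggle.

A per-subject dichotomisation (>= 5 non-synonymous mutations or not) feeds
a one-sided Fisher exact test, and blood-brain comparisons report
homoplasmic concordance plus heteroplasmies detectable in brain (level >=
5%) but not in blood.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import ConsequenceAnnotation, NoveltyStatus
from .artifacts import HotspotFlag
from .calling import ThresholdConfig, VariantCall

DIAGNOSES = ("Control", "BD", "MDD", "SZ", "METH")
CASE_GROUPS_DEFAULT = frozenset({"BD", "MDD", "SZ"})
REGIONS = (
    "ACC", "AMY", "CAUN", "CB", "DLPFC", "HIPP",
    "NACC", "OFC", "PUT", "SN", "THAL", "blood",
)


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class ObservedVariant:
    """A called variant with its downstream annotations, as stats consume it."""

    call: VariantCall
    annotation: ConsequenceAnnotation | None = None
    novelty: NoveltyStatus | None = None
    artifact_flag: HotspotFlag | None = None
    haplogroup_defining: bool = False

    @property
    def locus(self) -> tuple[int, str]:
        return (self.call.position, self.call.alt)

    @property
    def is_nonsynonymous(self) -> bool:
        return self.annotation is not None and self.annotation.is_nonsynonymous


@dataclass
class SubjectRecord:
    subject: str
    diagnosis: str
    samples: dict[str, list[ObservedVariant]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise CohortError(
                f"unknown diagnosis {self.diagnosis!r}; expected one of {DIAGNOSES}"
            )
        for region in self.samples:
            if region not in REGIONS:
                raise CohortError(f"unknown region {region!r}")


@dataclass(frozen=True)
class BurdenConfig:
    """Which calls enter the exclusive-burden tallies (all default on)."""

    require_nonsynonymous: bool = True
    require_homoplasmic: bool = True
    exclude_artifact_flagged: bool = True
    exclude_haplogroup_defining: bool = True
    case_groups: frozenset[str] = CASE_GROUPS_DEFAULT

    def admits(self, variant: ObservedVariant) -> bool:
        if self.require_homoplasmic and (
            variant.call.classification != "homoplasmic_variant"
        ):
            return False
        if self.require_nonsynonymous and not variant.is_nonsynonymous:
            return False
        if self.exclude_artifact_flagged and variant.artifact_flag is not None:
            return False
        if self.exclude_haplogroup_defining and variant.haplogroup_defining:
            return False
        return True


@dataclass(frozen=True)
class PartitionResult:
    """Exclusive/shared loci with per-diagnosis subject observation counts."""

    case_only: dict[tuple[int, str], Counter]
    control_only: dict[tuple[int, str], Counter]
    shared: dict[tuple[int, str], Counter]

    def observations(self, side: str, diagnosis: str | None = None) -> int:
        loci = getattr(self, side)
        if diagnosis is None:
            return sum(sum(c.values()) for c in loci.values())
        return sum(c.get(diagnosis, 0) for c in loci.values())

    @property
    def n_loci(self) -> int:
        return len(self.case_only) + len(self.control_only) + len(self.shared)


@dataclass(frozen=True)
class BurdenSummary:
    group: str
    n_subjects: int
    exclusive_ns_mutations: int
    rate: float
    z: float


def partition_variants(
    cohort: list[SubjectRecord],
    case_groups: frozenset[str] | set[str] = CASE_GROUPS_DEFAULT,
    tissue: str = "DLPFC",
    config: BurdenConfig | None = None,
) -> PartitionResult:
    """Split observed loci into case-only / control-only / shared.

    A locus is (position, alt); it is case-only iff observed in at least
    one case subject and no control. METH subjects (any diagnosis outside
    ``case_groups`` and Control) are outside the partition. Observation
    counts tally subjects per diagnosis. The three sets are disjoint and
    cover every locus observed in partition subjects (asserted).
    """
    if not cohort:
        raise CohortError("empty cohort")
    config = config or BurdenConfig(case_groups=frozenset(case_groups))
    per_locus: dict[tuple[int, str], Counter] = defaultdict(Counter)
    for subject in cohort:
        if subject.diagnosis != "Control" and subject.diagnosis not in case_groups:
            continue
        if tissue not in subject.samples:
            raise CohortError(f"subject {subject.subject} lacks tissue {tissue}")
        seen: set[tuple[int, str]] = set()
        for variant in subject.samples[tissue]:
            if config.admits(variant) and variant.locus not in seen:
                per_locus[variant.locus][subject.diagnosis] += 1
                seen.add(variant.locus)
    case_only, control_only, shared = {}, {}, {}
    for locus, diag_counts in per_locus.items():
        in_control = diag_counts.get("Control", 0) > 0
        in_case = any(diag_counts.get(d, 0) > 0 for d in case_groups)
        if in_case and not in_control:
            case_only[locus] = diag_counts
        elif in_control and not in_case:
            control_only[locus] = diag_counts
        else:
            shared[locus] = diag_counts
    assert len(case_only) + len(control_only) + len(shared) == len(per_locus)
    assert not (set(case_only) & set(control_only))
    assert not (set(case_only) & set(shared))
    assert not (set(control_only) & set(shared))
    return PartitionResult(case_only, control_only, shared)


def group_rate_z(count: int, n: int, pooled_rate: float) -> float:
    """Poisson-rate standardisation: z = (count/n - pooled) / sqrt(pooled/n).

    Under a null where each subject contributes Poisson(pooled_rate)
    mutations, count/n has variance pooled_rate/n, so z is approximately
    standard normal for moderate counts.
    """
    if n <= 0:
        raise CohortError("n must be positive")
    if pooled_rate < 0:
        raise CohortError("pooled_rate must be >= 0")
    if pooled_rate == 0:
        return float("inf") if count > 0 else 0.0
    return (count / n - pooled_rate) / np.sqrt(pooled_rate / n)


def burden_table(
    partition: PartitionResult,
    group_sizes: dict[str, int],
) -> list[BurdenSummary]:
    """Per-group exclusive counts, per-subject rates, and rate z-scores.

    Case groups draw their counts from case-only loci, Controls from
    control-only loci; the pooled rate is total exclusive mutations over
    total subjects across the listed groups.
    """
    counts: dict[str, int] = {}
    for group, n in group_sizes.items():
        if n <= 0:
            raise CohortError(f"group size for {group} must be positive")
        side = "control_only" if group == "Control" else "case_only"
        counts[group] = partition.observations(side, group)
    total = sum(counts.values())
    total_n = sum(group_sizes.values())
    pooled = total / total_n if total_n else 0.0
    return [
        BurdenSummary(
            group=group,
            n_subjects=group_sizes[group],
            exclusive_ns_mutations=counts[group],
            rate=counts[group] / group_sizes[group],
            z=group_rate_z(counts[group], group_sizes[group], pooled),
        )
        for group in group_sizes
    ]


def two_group_rate_test(
    count1: int, n1: int, count0: int, n0: int
) -> tuple[float, float]:
    """Two-sample Poisson-rate z test with a pooled rate; two-tailed p.

    z = (r1 - r0) / sqrt(pooled * (1/n1 + 1/n0)) with pooled =
    (count1+count0)/(n1+n0); p from the standard normal. Two all-zero
    samples give (0, 1).
    """
    if n1 <= 0 or n0 <= 0:
        raise CohortError("group sizes must be positive")
    pooled = (count1 + count0) / (n1 + n0)
    if pooled == 0:
        return 0.0, 1.0
    z = (count1 / n1 - count0 / n0) / np.sqrt(pooled * (1 / n1 + 1 / n0))
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni-adjusted p-values (capped at 1).

    No correction is applied anywhere by default — the burden analysis
    reports raw p — but the adjustment is available for reuse when many
    loci or groups are tested.
    """
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


def subject_ns_counts(
    cohort: list[SubjectRecord],
    tissue: str = "DLPFC",
    config: BurdenConfig | None = None,
) -> dict[str, int]:
    """Per-subject count of admitted non-synonymous mutations in a tissue."""
    config = config or BurdenConfig()
    out = {}
    for subject in cohort:
        variants = subject.samples.get(tissue, [])
        out[subject.subject] = len(
            {v.locus for v in variants if config.admits(v)}
        )
    return out


def fisher_from_table(table: list[list[int]]) -> float:
    """One-sided (greater) Fisher exact p for a 2x2 table."""
    a, b = table[0]
    c, d = table[1]
    if min(a + b, c + d) == 0 or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def fisher_dichotomized(
    cohort: list[SubjectRecord],
    case_groups: frozenset[str] | set[str] = CASE_GROUPS_DEFAULT,
    cutoff: int = 5,
    tissue: str = "DLPFC",
    config: BurdenConfig | None = None,
) -> tuple[float, list[list[int]]]:
    """One-sided Fisher test of (case/control) x (>=cutoff / <cutoff mutations).

    Tests whether carrying ``cutoff`` or more non-synonymous mutations is
    over-represented among cases. Returns (p, table) with the table rows
    (cases, controls) and columns (>=cutoff, <cutoff).
    """
    counts = subject_ns_counts(cohort, tissue=tissue, config=config)
    table = [[0, 0], [0, 0]]
    for subject in cohort:
        if subject.diagnosis in case_groups:
            row = 0
        elif subject.diagnosis == "Control":
            row = 1
        else:
            continue
        col = 0 if counts[subject.subject] >= cutoff else 1
        table[row][col] += 1
    return fisher_from_table(table), table


# ---------------------------------------------------------------------------
# Blood-brain and region profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceReport:
    subject: str
    homoplasmic_concordance: float  # |shared| / |union| of homoplasmic loci
    n_homoplasmic_loci: int
    brain_only: tuple[tuple[int, str, str, float], ...]  # (pos, alt, region, level)


def blood_brain_concordance(
    subject: SubjectRecord,
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> ConcordanceReport:
    """Homoplasmic agreement between blood and brain, and heteroplasmies
    detectable in brain (level >= blood_detection_min) but not in blood."""
    if "blood" not in subject.samples:
        raise CohortError(f"subject {subject.subject} has no blood sample")
    brain_regions = [r for r in subject.samples if r != "blood"]
    if not brain_regions:
        raise CohortError(f"subject {subject.subject} has no brain region")

    def homoplasmic_loci(variants: list[ObservedVariant]) -> set[tuple[int, str]]:
        return {
            v.locus
            for v in variants
            if v.call.classification == "homoplasmic_variant"
        }

    blood_hom = homoplasmic_loci(subject.samples["blood"])
    brain_hom: set[tuple[int, str]] = set()
    for region in brain_regions:
        brain_hom |= homoplasmic_loci(subject.samples[region])
    union = blood_hom | brain_hom
    concordance = 1.0 if not union else len(blood_hom & brain_hom) / len(union)

    cutoff = thresholds.blood_detection_min
    blood_levels = {
        v.locus: v.call.heteroplasmy_level for v in subject.samples["blood"]
    }
    brain_only = []
    seen: set[tuple[int, str]] = set()
    for region in brain_regions:
        for v in subject.samples[region]:
            if v.call.classification != "heteroplasmic":
                continue
            if v.call.heteroplasmy_level < cutoff or v.locus in seen:
                continue
            if blood_levels.get(v.locus, 0.0) < cutoff:
                brain_only.append(
                    (v.locus[0], v.locus[1], region, v.call.heteroplasmy_level)
                )
                seen.add(v.locus)
    return ConcordanceReport(
        subject=subject.subject,
        homoplasmic_concordance=concordance,
        n_homoplasmic_loci=len(union),
        brain_only=tuple(brain_only),
    )


@dataclass(frozen=True)
class RegionProfile:
    subject: str
    position: int
    levels: dict[str, tuple[float, int]]  # region -> (level, coverage)
    filtered_regions: tuple[str, ...]

    @property
    def min_level(self) -> float:
        return min(lvl for lvl, _ in self.levels.values())

    @property
    def max_level(self) -> float:
        return max(lvl for lvl, _ in self.levels.values())

    @property
    def level_range(self) -> float:
        return self.max_level - self.min_level


def region_heteroplasmy_profile(
    subject: SubjectRecord, position: int
) -> RegionProfile:
    """Per-region heteroplasmy level at one position (e.g. 16086 across the
    11 brain regions of one subject). Regions where the position was
    filtered (or not called) are listed separately."""
    levels: dict[str, tuple[float, int]] = {}
    filtered: list[str] = []
    for region, variants in subject.samples.items():
        hit = next((v for v in variants if v.call.position == position), None)
        if hit is None:
            filtered.append(region)
        else:
            levels[region] = (hit.call.heteroplasmy_level, hit.call.coverage)
    if not levels:
        raise CohortError(f"position {position} not called in any region")
    return RegionProfile(
        subject=subject.subject,
        position=position,
        levels=levels,
        filtered_regions=tuple(filtered),
    )


# ---------------------------------------------------------------------------
# Fixture cohorts from published locus tables
# ---------------------------------------------------------------------------

def load_locus_table(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged case-only locus table (position, gene, per-diagnosis
    observation counts, ref, alt, amino-acid change, prediction, catalog N)."""
    if path is None:
        with resources.as_file(
            resources.files("mitoplasmy.data") / "case_only_loci.tsv"
        ) as p:
            return load_locus_table(p)
    return pd.read_csv(path, sep="\t", comment="#")


def load_novel_rare_table(path: str | Path | None = None) -> pd.DataFrame:
    if path is None:
        with resources.as_file(
            resources.files("mitoplasmy.data") / "novel_rare_variants.tsv"
        ) as p:
            return load_novel_rare_table(p)
    return pd.read_csv(path, sep="\t", comment="#")


def cohort_from_locus_table(
    table: pd.DataFrame,
    group_sizes: dict[str, int],
) -> list[SubjectRecord]:
    """Materialise a minimal DLPFC cohort realising a per-diagnosis locus
    count table: each observation is assigned round-robin to a pseudo-subject
    of that diagnosis, as a non-synonymous homoplasmic call.

    This reconstructs subject-level structure that a published locus table
    summarises away; it preserves exactly the per-diagnosis observation
    counts, which is what the partition and burden operations consume.
    """
    from .annotation import GeneConsequence

    subjects = {
        f"{group}-{i + 1}": SubjectRecord(
            subject=f"{group}-{i + 1}", diagnosis=group, samples={"DLPFC": []}
        )
        for group, n in group_sizes.items()
        for i in range(n)
    }
    rotation = {
        group: itertools.cycle(range(n)) for group, n in group_sizes.items()
    }
    col_for = {"BD": "bd", "MDD": "mdd", "SZ": "sz"}
    for _, row in table.iterrows():
        for group, col in col_for.items():
            if group not in group_sizes:
                continue
            for _ in range(int(row[col])):
                idx = next(rotation[group])
                call = VariantCall(
                    position=int(row["position"]),
                    ref_base=str(row["ref"]),
                    major_allele=str(row["alt"]),
                    major_fraction=1.0,
                    alleles=((str(row["alt"]), 1.0),),
                    classification="homoplasmic_variant",
                    heteroplasmy_level=1.0,
                    coverage=1000,
                )
                aa = str(row["aa_change"])
                codon_index = int("".join(ch for ch in aa if ch.isdigit()))
                annotation = ConsequenceAnnotation(
                    position=call.position,
                    ref=call.ref_base,
                    alt=call.alt,
                    genes=(
                        GeneConsequence(
                            gene=str(row["gene"]),
                            codon_index=codon_index,
                            ref_aa=aa[:3],
                            alt_aa=aa[-3:],
                            synonymous=False,
                        ),
                    ),
                    region_class="protein",
                    damage_label=str(row["prediction"]),
                )
                subjects[f"{group}-{idx + 1}"].samples["DLPFC"].append(
                    ObservedVariant(call=call, annotation=annotation)
                )
    return list(subjects.values())
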