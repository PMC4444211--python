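"""Synthetic data generation: reference stand-in, pileups, cohorts, reads.

Everything the pipeline consumes can be generated here with a known truth
set, so every stage is testable without any download:

* a synthetic 16,569-base reference standing in for the rCRS (see
  :func:`build_synthetic_reference`);
* per-position allele-count tables from a haplotype + heteroplasmy map,
  with negative-binomial coverage and uniform sequencing error;
* repeat-locus reads with configurable length mixtures and stutter;
* context-motif A>C artifact injection;
* whole cohorts with germline clades, private variants, planted
  case/control burden, and region-varying somatic heteroplasmy.

All randomness flows from a single seed; identical configs produce
bit-identical outputs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .artifacts import motif_positions
from .reference import (
    GeneFeature,
    MitoReference,
    RCRS_LENGTH,
    VERTEBRATE_MITO_CODE,
    codon_at,
    load_gene_model,
    reverse_complement,
)
from .repeats import RepeatLocusSpec

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Synthetic reference construction
# ---------------------------------------------------------------------------
#
# The true rCRS sequence is not redistributed with this package; instead a
# synthetic stand-in is constructed with the real NC_012920 gene
# coordinates and every sequence feature the analyses rely on planted at
# its documented location:
#
# * codons at all reported coding variant loci solved so that the printed
#   reference/alternate bases and amino-acid changes hold;
# * the A>C error-hotspot contexts at 302, 3492, 6419 and 10306;
# * the D310 and D16189 poly-C tracts and the (CA)5 repeat at 514;
# * the rCRS 'N' placeholder at 3107;
# * no internal stop codons in any protein gene (both strands).
#
# Everything else is deterministic random fill.

_BUILD_SEED = 20_120_920  # part of the artifact's identity, not a knob

#: Fixed base runs planted verbatim: {start position: bases}.
_PLANTED_RUNS: dict[int, str] = {
    # hotspot context at 302 + D310 tract C5 T C5, terminated at 314
    297: "ACCAAACCCCCTCCCCCA",
    # hotspot contexts (Table-style printed windows)
    3487: "CTAAAACCCGC",
    6414: "ATAAAACCCCC",
    10301: "AACTAACCTGC",
    # (CA)5 dinucleotide repeat at 514 with repeat-free anchors
    509: "TGTCTCACACACACATCTGG",
    # D16189 tract: anchor, C5 T C4, terminator
    16179: "AGGTACCCCCTCCCCA",
    # assorted reference bases behind reported non-coding variants
    16519: "T",
    16086: "T",
    16261: "C",
    16178: "T",
    1601: "C",
    1861: "T",
    9801: "G",
}

#: Coding variants whose printed ref/alt bases and amino-acid change pin a
#: codon: (gene, position, heavy ref, heavy alt, ref_aa3, alt_aa3).
_EXTRA_CODING_VARIANTS: tuple[tuple[str, int, str, str, str, str], ...] = (
    ("ND4", 11696, "G", "A", "Val", "Ile"),
)

_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})
_ALL_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)


def _coding_span(gene: GeneFeature, codon_index: int) -> tuple[int, int, int]:
    """Heavy-strand positions (b1, b2, b3) of a codon, in coding order."""
    if gene.strand == "heavy":
        s = gene.start + 3 * (codon_index - 1)
        return (s, s + 1, s + 2)
    e = gene.end - 3 * (codon_index - 1)
    return (e, e - 1, e - 2)


def _solve_codon(
    gene: GeneFeature,
    position: int,
    ref: str,
    alt: str,
    ref_aa3: str,
    alt_aa3: str,
    fixed: dict[int, str],
) -> tuple[int, str]:
    """Find the lexicographically first codon consistent with the printed
    variant (and with any already-planted bases); returns (codon_index,
    coding codon)."""
    if gene.strand == "heavy":
        idx0 = position - gene.start
    else:
        idx0 = gene.end - position
    codon_index = idx0 // 3 + 1
    offset = idx0 % 3
    span = _coding_span(gene, codon_index)
    coding_ref = ref if gene.strand == "heavy" else _COMPLEMENT[ref]
    coding_alt = alt if gene.strand == "heavy" else _COMPLEMENT[alt]
    code = VERTEBRATE_MITO_CODE
    for codon in _ALL_CODONS:
        if codon in _STOPS or codon[offset] != coding_ref:
            continue
        if code.translate3(codon) != ref_aa3:
            continue
        mutated = codon[:offset] + coding_alt + codon[offset + 1 :]
        if code.translate3(mutated) != alt_aa3:
            continue
        ok = True
        for i, pos in enumerate(span):
            coding_base = codon[i]
            heavy_base = (
                coding_base if gene.strand == "heavy" else _COMPLEMENT[coding_base]
            )
            if pos in fixed and fixed[pos] != heavy_base:
                ok = False
                break
        if ok:
            return codon_index, codon
    raise SimulationError(
        f"no codon satisfies {gene.name} {ref_aa3}{codon_index}{alt_aa3} "
        f"({ref}>{alt} at {position})"
    )


def _plant(fixed: dict[int, str], position: int, base: str) -> None:
    prev = fixed.get(position)
    if prev is not None and prev != base:
        raise SimulationError(
            f"conflicting plant at {position}: {prev} vs {base}"
        )
    fixed[position] = base


def _plant_codon(
    fixed: dict[int, str], gene: GeneFeature, codon_index: int, codon: str
) -> None:
    for i, pos in enumerate(_coding_span(gene, codon_index)):
        base = codon[i] if gene.strand == "heavy" else _COMPLEMENT[codon[i]]
        _plant(fixed, pos, base)


def _coding_variant_rows() -> list[tuple[str, int, str, str, str, str]]:
    """(gene, position, ref, alt, ref_aa3, alt_aa3) for every reported
    coding variant in the packaged locus tables."""
    from .stats import load_locus_table, load_novel_rare_table

    rows: list[tuple[str, int, str, str, str, str]] = []
    seen: set[int] = set()
    for table in (load_locus_table(), load_novel_rare_table()):
        for _, row in table.iterrows():
            aa = str(row["aa_change"])
            if aa in ("-", "nan") or str(row["gene"]) == "D-loop":
                continue
            position = int(row["position"])
            if position in seen:
                continue
            seen.add(position)
            rows.append(
                (
                    str(row["gene"]),
                    position,
                    str(row["ref"]),
                    str(row["alt"]),
                    aa[:3],
                    aa[-3:],
                )
            )
    rows.extend(_EXTRA_CODING_VARIANTS)
    return rows


def build_synthetic_reference(
    genes: list[GeneFeature] | None = None,
) -> MitoReference:
    """Deterministically build the synthetic rCRS stand-in (see module notes)."""
    genes = genes if genes is not None else load_gene_model()
    by_name = {g.name: g for g in genes}
    fixed: dict[int, str] = {}

    for start, run in _PLANTED_RUNS.items():
        for i, base in enumerate(run):
            _plant(fixed, start + i, base)

    # start and (complete) stop codons
    for gene in genes:
        if gene.kind != "protein":
            continue
        _plant_codon(fixed, gene, 1, "ATG")
        if not gene.incomplete_stop:
            _plant_codon(fixed, gene, gene.length // 3, "TAA")

    # codons pinned by the reported coding variants
    for gene_name, position, ref_b, alt_b, ref_aa, alt_aa in _coding_variant_rows():
        gene = by_name[gene_name]
        codon_index, codon = _solve_codon(
            gene, position, ref_b, alt_b, ref_aa, alt_aa, fixed
        )
        _plant_codon(fixed, gene, codon_index, codon)

    # deterministic random fill, then 'N' placeholder
    rng = np.random.default_rng(_BUILD_SEED)
    seq = list(rng.choice(list("ACGT"), size=RCRS_LENGTH))
    for position, base in fixed.items():
        seq[position - 1] = base
    seq[3106] = "N"

    _repair_stop_codons(seq, genes, fixed, rng)
    return MitoReference(sequence="".join(seq), name="synthetic_rCRS")


def _codon_of(seq: list[str], gene: GeneFeature, codon_index: int) -> str:
    span = _coding_span(gene, codon_index)
    bases = [seq[p - 1] for p in span]
    if gene.strand == "light":
        bases = [_COMPLEMENT.get(b, "N") for b in bases]
    return "".join(bases)


def _repair_stop_codons(
    seq: list[str],
    genes: list[GeneFeature],
    fixed: dict[int, str],
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> None:
    """Mutate free bases until no protein gene has an internal stop codon.

    Overlapping reading frames (ATP8/ATP6, ND4L/ND4) mean one fix can
    create a stop elsewhere, so iterate to a fixpoint."""
    protein = [g for g in genes if g.kind == "protein"]
    for _ in range(max_rounds):
        dirty = False
        for gene in protein:
            n_complete = gene.length // 3
            last_internal = n_complete if gene.incomplete_stop else n_complete - 1
            for ci in range(1, last_internal + 1):
                if _codon_of(seq, gene, ci) not in _STOPS:
                    continue
                span = _coding_span(gene, ci)
                free = [p for p in span if p not in fixed and p != 3107]
                if not free:
                    raise SimulationError(
                        f"stop codon pinned by constraints in {gene.name} codon {ci}"
                    )
                p = free[rng.integers(len(free))]
                seq[p - 1] = str(rng.choice(list("ACGT")))
                dirty = True
        if not dirty:
            return
    raise SimulationError("stop-codon repair did not converge")


def write_default_reference(path: str | Path) -> None:
    """Regenerate the packaged synthetic reference FASTA."""
    ref = build_synthetic_reference()
    lines = [
        ">synthetic_rCRS synthetic stand-in for NC_012920 "
        "(real gene coordinates, constructed sequence)"
    ]
    for i in range(0, len(ref.sequence), 70):
        lines.append(ref.sequence[i : i + 70])
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------

def simulate_coverage(
    n: int, mean: float, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial depths (wide spread, matching deep mtDNA data)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def simulate_pileup(
    true_haplotype: str,
    heteroplasmy: dict[int, tuple[str, float]] | None = None,
    coverage_mean: float = 8850.0,
    coverage_dispersion: float = 3.0,
    error_rate: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Count table for one sample.

    Depth per position is negative-binomial; at heteroplasmic positions
    the alternate allele draws Binomial(depth, fraction) reads; sequencing
    errors move reads uniformly onto the three non-template bases.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    heteroplasmy = heteroplasmy or {}
    for pos, (_, f) in heteroplasmy.items():
        if not 0 <= f <= 1:
            raise SimulationError(f"heteroplasmy fraction {f} at {pos} outside [0,1]")
    length = len(true_haplotype)
    depth = simulate_coverage(length, coverage_mean, coverage_dispersion, rng)
    counts = np.zeros((length, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(BASES)}
    template_idx = np.array(
        [base_idx.get(b, -1) for b in true_haplotype.upper()], dtype=np.int64
    )

    # reads supporting the planted heteroplasmic allele
    template_reads = depth.copy()
    for pos, (alt, f) in heteroplasmy.items():
        i = pos - 1
        alt_n = rng.binomial(depth[i], f)
        counts[i, base_idx[alt]] += alt_n
        template_reads[i] -= alt_n

    # sequencing errors, uniform over the three non-template bases
    if error_rate > 0:
        n_err = rng.binomial(template_reads, error_rate)
        template_reads = template_reads - n_err
        for t in range(4):
            sel = np.flatnonzero((template_idx == t) & (n_err > 0))
            if sel.size == 0:
                continue
            others = [i for i in range(4) if i != t]
            split = rng.multinomial(n_err[sel], [1 / 3] * 3)
            for j, o in enumerate(others):
                counts[sel, o] += split[:, j]

    known = template_idx >= 0
    counts[np.flatnonzero(known), template_idx[known]] += template_reads[known]
    # 'N' template positions: spread remaining reads on A (kept filtered low
    # only by classification; reference there is N so calls are flagged)
    counts[~known, 0] += template_reads[~known]

    return pd.DataFrame(
        {
            "pos": np.arange(1, length + 1),
            "A": counts[:, 0],
            "C": counts[:, 1],
            "G": counts[:, 2],
            "T": counts[:, 3],
            "del": np.zeros(length, dtype=np.int64),
        }
    )


def inject_ac_artifacts(
    count_table: pd.DataFrame,
    ref: MitoReference,
    artifact_fraction: float,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Inflate the C count at every motif-matching A position by
    Binomial(depth, artifact_fraction). Returns a new table."""
    if not 0 <= artifact_fraction <= 1:
        raise SimulationError("artifact_fraction outside [0,1]")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    df = count_table.copy()
    if artifact_fraction == 0:
        return df
    hot = set(motif_positions(ref))
    rows = df.index[df["pos"].isin(hot)]
    depth = df.loc[rows, ["A", "C", "G", "T", "del"]].sum(axis=1).to_numpy()
    df.loc[rows, "C"] = df.loc[rows, "C"].to_numpy() + rng.binomial(
        depth, artifact_fraction
    )
    return df


# ---------------------------------------------------------------------------
# Repeat-locus reads
# ---------------------------------------------------------------------------

def simulate_repeat_reads(
    mixture: dict[int, float],
    locus: RepeatLocusSpec,
    n_reads: int = 1000,
    stutter_rate: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> list[str]:
    """Reads spanning a repeat locus, lengths drawn from ``mixture``.

    With probability ``stutter_rate`` a read's length slips +-1 unit
    (direction fair, floor at zero), emulating polymerase slippage.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    lengths = np.array(sorted(mixture))
    probs = np.array([mixture[k] for k in lengths], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise SimulationError("mixture fractions must sum to 1")
    drawn = rng.choice(lengths, size=n_reads, p=probs)
    if stutter_rate > 0:
        slip = rng.random(n_reads) < stutter_rate
        direction = rng.choice([-1, 1], size=n_reads)
        drawn = np.maximum(drawn + slip * direction, 0)
    return [
        locus.left_anchor + locus.unit * int(k) + locus.right_anchor
        for k in drawn
    ]


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

BRAIN_REGIONS = (
    "ACC", "AMY", "CAUN", "CB", "DLPFC", "HIPP", "NACC", "OFC", "PUT", "SN", "THAL",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for cohort simulation.

    Group sizes mirror the cohort (20 controls, 14 BD, 15 MDD, 14 SZ,
    6 METH); every subject has the DLPFC, 11 subjects all brain regions,
    and 3 of those also blood. Coverage is negative-binomial around the
    combined platform mean; somatic heteroplasmy levels are uniform on
    5-35%, spanning the observed 6.3-32.5% regional spread. Planted
    exclusive non-synonymous burden rates per subject are the published
    per-group rates.
    """

    seed: int = 0
    n_subjects: dict[str, int] = field(
        default_factory=lambda: {
            "Control": 20, "BD": 14, "MDD": 15, "SZ": 14, "METH": 6,
        }
    )
    multiregion_subjects: int = 11
    blood_subjects: int = 3
    clade_variants: int = 5
    private_variant_mean: float = 2.0
    burden_rates: dict[str, float] = field(
        default_factory=lambda: {
            "Control": 0.55, "BD": 1.00, "MDD": 0.87, "SZ": 1.57, "METH": 0.55,
        }
    )
    somatic_site_mean: float = 1.0
    somatic_level_low: float = 0.05
    somatic_level_high: float = 0.35
    coverage_mean: float = 8850.0
    coverage_dispersion: float = 3.0
    base_error_rate: float = 1e-3
    ac_artifact_rate: float = 0.08
    repeat_stutter_rate: float = 0.02

    def __post_init__(self) -> None:
        for name, rate in (
            ("base_error_rate", self.base_error_rate),
            ("ac_artifact_rate", self.ac_artifact_rate),
            ("repeat_stutter_rate", self.repeat_stutter_rate),
        ):
            if not 0 <= rate <= 1:
                raise SimulationError(f"{name} outside [0,1]")
        for group in self.n_subjects:
            if group not in ("Control", "BD", "MDD", "SZ", "METH"):
                raise SimulationError(f"invalid group name {group!r}")


@dataclass
class TruthSet:
    """Ground truth paired with every simulated cohort."""

    clades: dict[str, dict[int, str]]
    germline: dict[str, dict[int, str]]  # subject -> {position: alt}
    subject_clade: dict[str, str]
    burden_extra: dict[str, dict[int, str]]  # case-burden NS variants
    somatic: dict[str, dict[str, dict[int, float]]]  # subject -> region -> pos -> f
    artifact_positions: list[int]

    def to_json(self) -> str:
        def _keys_to_str(d):
            if isinstance(d, dict):
                return {str(k): _keys_to_str(v) for k, v in d.items()}
            return d

        return json.dumps(
            {
                "clades": _keys_to_str(self.clades),
                "germline": _keys_to_str(self.germline),
                "subject_clade": self.subject_clade,
                "burden_extra": _keys_to_str(self.burden_extra),
                "somatic": _keys_to_str(self.somatic),
                "artifact_positions": self.artifact_positions,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    metadata: pd.DataFrame  # subject, diagnosis, region
    tables: dict[tuple[str, str], pd.DataFrame]  # (subject, region) -> counts
    truth: TruthSet


def _nonsyn_candidates(
    ref: MitoReference,
    genes: list[GeneFeature],
    rng: np.random.Generator,
    n: int,
    exclude: set[int],
) -> list[tuple[int, str]]:
    """Random non-synonymous substitution sites with verified consequence."""
    protein = [g for g in genes if g.kind == "protein"]
    out: list[tuple[int, str]] = []
    used = set(exclude)
    code = VERTEBRATE_MITO_CODE
    while len(out) < n:
        gene = protein[rng.integers(len(protein))]
        pos = int(rng.integers(gene.start, gene.end + 1))
        if pos in used or ref.base(pos) == "N":
            continue
        _, offset, codon = codon_at(ref, gene, pos)
        if "-" in codon or "N" in codon:
            continue
        alts = [b for b in BASES if b != ref.base(pos)]
        rng.shuffle(alts)
        for alt in alts:
            coding_alt = alt if gene.strand == "heavy" else _COMPLEMENT[alt]
            mutated = codon[:offset] + coding_alt + codon[offset + 1 :]
            if (
                code.translate3(mutated) != code.translate3(codon)
                and mutated not in _STOPS
            ):
                out.append((pos, alt))
                used.add(pos)
                break
    return out


def simulate_cohort(
    config: SimulationConfig,
    ref: MitoReference | None = None,
    genes: list[GeneFeature] | None = None,
) -> SimulatedCohort:
    """Generate count tables, metadata and a truth set for a whole cohort.

    Germline haplotypes come from a hand-built 3-clade toy tree (so
    haplogroup exclusion has a planted truth) plus private homoplasmic
    variants; case/control burden is planted by drawing per-subject extra
    non-synonymous variants at the per-group rates; somatic heteroplasmy
    varies by brain region and is absent from blood.
    """
    if ref is None:
        from .reference import default_reference

        ref = default_reference()
    genes = genes if genes is not None else load_gene_model()
    rng = np.random.default_rng(config.seed)
    length = len(ref)

    # three clades of haplogroup-defining variants on a toy tree
    clade_sites = _nonsyn_candidates(
        ref, genes, rng, 3 * config.clade_variants, exclude=set()
    )
    clades = {
        f"clade{i + 1}": dict(
            clade_sites[i * config.clade_variants : (i + 1) * config.clade_variants]
        )
        for i in range(3)
    }
    used_positions = {p for variants in clades.values() for p in variants}

    subjects: list[tuple[str, str]] = []
    for group, n in config.n_subjects.items():
        subjects.extend((f"{group}-{i + 1}", group) for i in range(n))

    germline: dict[str, dict[int, str]] = {}
    burden_extra: dict[str, dict[int, str]] = {}
    subject_clade: dict[str, str] = {}
    somatic: dict[str, dict[str, dict[int, float]]] = {}
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    meta_rows: list[dict[str, str]] = []

    multi = {s for s, _ in subjects[: config.multiregion_subjects]}
    blood = {s for s, _ in subjects[: config.blood_subjects]}

    for subject, group in subjects:
        clade = f"clade{rng.integers(1, 4)}"
        subject_clade[subject] = clade
        variants = dict(clades[clade])
        n_priv = rng.poisson(config.private_variant_mean)
        priv = _nonsyn_candidates(ref, genes, rng, n_priv, exclude=used_positions)
        variants.update(priv)
        n_extra = rng.poisson(config.burden_rates.get(group, 0.0))
        extra = _nonsyn_candidates(ref, genes, rng, n_extra, exclude=used_positions)
        burden_extra[subject] = dict(extra)
        variants.update(extra)
        germline[subject] = variants

        haplotype = list(ref.sequence)
        for pos, alt in variants.items():
            haplotype[pos - 1] = alt
        haplotype = "".join(haplotype)

        regions = list(BRAIN_REGIONS) if subject in multi else ["DLPFC"]
        if subject in blood:
            regions.append("blood")

        n_som = rng.poisson(config.somatic_site_mean)
        som_positions = [
            int(p)
            for p in rng.integers(1, length + 1, size=n_som)
            if p not in variants and ref.base(int(p)) != "N"
        ]
        somatic[subject] = {}
        for region in regions:
            het: dict[int, tuple[str, float]] = {}
            levels: dict[int, float] = {}
            if region != "blood":
                for pos in som_positions:
                    level = rng.uniform(
                        config.somatic_level_low, config.somatic_level_high
                    )
                    alt = str(
                        rng.choice([b for b in BASES if b != ref.base(pos)])
                    )
                    het[pos] = (alt, level)
                    levels[pos] = level
            somatic[subject][region] = levels
            table = simulate_pileup(
                haplotype,
                heteroplasmy=het,
                coverage_mean=config.coverage_mean,
                coverage_dispersion=config.coverage_dispersion,
                error_rate=config.base_error_rate,
                rng=rng,
            )
            if config.ac_artifact_rate > 0:
                table = inject_ac_artifacts(
                    table, ref, config.ac_artifact_rate, rng
                )
            tables[(subject, region)] = table
            meta_rows.append(
                {"subject": subject, "diagnosis": group, "region": region}
            )

    truth = TruthSet(
        clades=clades,
        germline=germline,
        subject_clade=subject_clade,
        burden_extra=burden_extra,
        somatic=somatic,
        artifact_positions=motif_positions(ref)
        if config.ac_artifact_rate > 0
        else [],
    )
    return SimulatedCohort(
        config=config,
        metadata=pd.DataFrame(meta_rows),
        tables=tables,
        truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> Path:
    """Write count tables, metadata TSV and truth-set JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (subject, region), table in cohort.tables.items():
        p = outdir / f"{subject}_{region}.counts.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths.append(str(p.name))
    meta = cohort.metadata.copy()
    meta["count_table"] = paths
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(cohort.truth.to_json())
    return outdir
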