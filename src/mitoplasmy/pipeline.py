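"""Pipeline orchestration and report writers.

Runs the stages in method order — classify, flag artifacts, annotate,
classify novelty, exclude haplogroup-defining variants, partition and
burden — over a cohort described by a metadata TSV (subject, diagnosis,
region, count_table[, fastq]), and writes:

* per-sample VCF 4.2 and consensus FASTA;
* a case-only locus table (per-diagnosis observation counts);
* a burden table (group, subjects, exclusive mutations, rate, z);
* a heteroplasmy/multiplasmy table;
* a flagged-hotspot table (position, context, variant, sample count);
* a machine-readable run manifest (version, config hash, counts at every
  filtering stage).

Any stage failure aborts with the stage name and the offending sample.
All thresholds live in the config; none are hard-coded in stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    annotate_variant,
    classify_novelty,
    exclude_haplogroup_defining,
    load_catalog,
    load_haplogroup_table,
)
from .artifacts import apply_blacklist, load_blacklist
from .calling import (
    ThresholdConfig,
    VariantCall,
    build_consensus,
    call_sample,
    read_count_table,
)
from .reference import default_reference, default_region_map, load_gene_model, load_reference
from .repeats import (
    call_multiplasmy,
    default_repeat_loci,
    deletion_ratio,
    reads_from_fastq,
    repeat_distribution,
)
from .stats import (
    BurdenConfig,
    ObservedVariant,
    SubjectRecord,
    burden_table,
    partition_variants,
)


class PipelineConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on sample {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample


@dataclass
class PipelineConfig:
    cohort_metadata: str
    output_dir: str
    reference_fasta: str | None = None  # None -> packaged synthetic reference
    gene_model: str | None = None
    catalog: str | None = "packaged"
    blacklist: str | None = "packaged"
    haplogroup_table: str | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    burden: BurdenConfig = field(default_factory=BurdenConfig)
    flag_artifacts: bool = True
    annotate: bool = True
    call_repeats: bool = True
    burden_tissue: str = "DLPFC"
    seed: int = 0

    def validate(self) -> None:
        """Reject unresolved paths before any stage runs."""
        for label, path in (
            ("cohort_metadata", self.cohort_metadata),
            ("reference_fasta", self.reference_fasta),
            ("gene_model", self.gene_model),
            ("catalog", self.catalog),
            ("blacklist", self.blacklist),
            ("haplogroup_table", self.haplogroup_table),
        ):
            if path is None or path == "packaged":
                continue
            if not Path(path).exists():
                raise PipelineConfigError(f"{label} path does not exist: {path}")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        d["burden"] = {**asdict(self.burden), "case_groups": sorted(self.burden.case_groups)}
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# VCF writer / reader
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mitoplasmy {version}
##contig=<ID={contig},length={length}>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AF,Number=1,Type=Float,Description="Non-reference allele fraction (heteroplasmy level)">
##INFO=<ID=CLS,Number=1,Type=String,Description="Classification: homoplasmic_variant or heteroplasmic">
##INFO=<ID=GENE,Number=.,Type=String,Description="Overlapping protein gene(s)">
##INFO=<ID=AAC,Number=.,Type=String,Description="Amino-acid change(s)">
##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">
##INFO=<ID=NOV,Number=1,Type=String,Description="Novelty status">
##FILTER=<ID=motif_AC,Description="A>C call in a >=2A-then->=2C error-hotspot context">
##FILTER=<ID=blacklist,Description="Position/substitution failed orthogonal validation">
##FILTER=<ID=min_coverage,Description="Coverage below the classification threshold">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(
    variants: list[ObservedVariant],
    path: str | Path,
    sample: str = "sample",
    contig: str = "chrM",
    length: int = 16569,
    filtered_sites=(),
) -> Path:
    """Write calls (and optionally coverage-filtered sites) as VCF 4.2."""
    lines = [_VCF_HEADER.format(version=__version__, contig=contig, length=length)]
    records = []
    for ov in variants:
        call = ov.call
        filt = "PASS" if ov.artifact_flag is None else ov.artifact_flag.reason
        info = [
            f"DP={call.coverage}",
            f"AF={call.heteroplasmy_level:.6g}",
            f"CLS={call.classification}",
        ]
        if ov.annotation is not None and ov.annotation.genes:
            info.append(
                "GENE=" + ",".join(gc.gene for gc in ov.annotation.genes)
            )
            changes = [gc.aa_change or "." for gc in ov.annotation.genes]
            info.append("AAC=" + ",".join(changes))
        if ov.annotation is not None:
            info.append(f"REGION={ov.annotation.region_class}")
        if ov.novelty is not None:
            info.append(f"NOV={ov.novelty.status}")
        records.append(
            (call.position, call.ref_base, call.alt, filt, ";".join(info))
        )
    for fs in filtered_sites:
        records.append((fs.position, "N", ".", "min_coverage", f"DP={fs.coverage}"))
    for pos, ref_b, alt, filt, info in sorted(records):
        lines.append(f"{contig}\t{pos}\t.\t{ref_b}\t{alt}\t.\t{filt}\t{info}\n")
    path = Path(path)
    path.write_text("".join(lines))
    return path


def read_vcf(path: str | Path) -> list[dict]:
    """Parse a VCF written by :func:`write_vcf` back into plain records."""
    records = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        chrom, pos, _id, ref_b, alt, _qual, filt, info = line.split("\t")
        fields = dict(
            kv.split("=", 1) for kv in info.split(";") if "=" in kv
        )
        records.append(
            {
                "position": int(pos),
                "ref": ref_b,
                "alt": alt,
                "filter": filt,
                "info": fields,
            }
        )
    return records


def write_consensus_fasta(consensus, path: str | Path) -> Path:
    path = Path(path)
    lines = [f">{consensus.sample} consensus"]
    for i in range(0, len(consensus.bases), 70):
        lines.append(consensus.bases[i : i + 70])
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    output_dir: Path
    subjects: list[SubjectRecord]
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    meta = pd.read_csv(config.cohort_metadata, sep="\t")
    if meta.empty:
        raise PipelineConfigError("empty cohort metadata")
    required = {"subject", "diagnosis", "region", "count_table"}
    if not required <= set(meta.columns):
        raise PipelineConfigError(
            f"metadata must have columns {sorted(required)}"
        )

    ref = (
        default_reference()
        if config.reference_fasta is None
        else load_reference(config.reference_fasta)
    )
    genes = load_gene_model(config.gene_model)
    region_map = default_region_map(genes)
    catalog = (
        load_catalog(None if config.catalog == "packaged" else config.catalog)
        if config.catalog
        else None
    )
    blacklist = (
        load_blacklist(None if config.blacklist == "packaged" else config.blacklist)
        if config.blacklist
        else []
    )
    haplo = (
        load_haplogroup_table(config.haplogroup_table)
        if config.haplogroup_table
        else set()
    )
    repeat_loci = default_repeat_loci(ref) if config.call_repeats else {}
    meta_dir = Path(config.cohort_metadata).parent

    subjects: dict[str, SubjectRecord] = {}
    stage_counts = {
        "samples": 0,
        "called": 0,
        "filtered_low_coverage": 0,
        "artifact_flagged": 0,
        "haplogroup_excluded": 0,
        "retained": 0,
    }
    hotspot_counter: dict[tuple[int, str, str], int] = {}
    het_rows: list[dict] = []
    repeat_rows: list[dict] = []

    for _, row in meta.iterrows():
        sample_id = f"{row['subject']}_{row['region']}"
        stage_counts["samples"] += 1
        table_path = Path(row["count_table"])
        if not table_path.is_absolute():
            table_path = meta_dir / table_path
        try:
            table = read_count_table(table_path)
            calls = call_sample(
                table, ref, config.thresholds, sample=sample_id
            )
            consensus = build_consensus(
                table, config.thresholds, sample=sample_id, genome_length=len(ref)
            )
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError("calling", sample_id, exc) from exc
        stage_counts["called"] += len(calls.calls)
        stage_counts["filtered_low_coverage"] += len(calls.filtered)

        try:
            if config.flag_artifacts:
                flagged, retained = apply_blacklist(calls.calls, ref, blacklist)
            else:
                flagged, retained = [], list(calls.calls)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("artifact_filter", sample_id, exc) from exc
        stage_counts["artifact_flagged"] += len(flagged)
        for call, flag in flagged:
            key = (call.position, call.ref_base, call.alt)
            hotspot_counter[key] = hotspot_counter.get(key, 0) + 1

        retained_kept, excluded = exclude_haplogroup_defining(retained, haplo)
        stage_counts["haplogroup_excluded"] += len(excluded)
        stage_counts["retained"] += len(retained_kept)

        observed: list[ObservedVariant] = []
        try:
            flag_by_pos = {c.position: f for c, f in flagged}
            for call in calls.calls:
                ann = (
                    annotate_variant(call, ref, genes, region_map)
                    if config.annotate and call.ref_base != "N"
                    else None
                )
                nov = classify_novelty(call, catalog, config.thresholds)
                observed.append(
                    ObservedVariant(
                        call=call,
                        annotation=ann,
                        novelty=nov,
                        artifact_flag=flag_by_pos.get(call.position),
                        haplogroup_defining=call in excluded,
                    )
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("annotation", sample_id, exc) from exc

        subject_id = str(row["subject"])
        rec = subjects.setdefault(
            subject_id,
            SubjectRecord(subject=subject_id, diagnosis=str(row["diagnosis"])),
        )
        rec.samples[str(row["region"])] = observed

        write_vcf(
            observed,
            outdir / f"{sample_id}.vcf",
            sample=sample_id,
            contig=ref.name,
            length=len(ref),
            filtered_sites=calls.filtered,
        )
        write_consensus_fasta(consensus, outdir / f"{sample_id}.consensus.fa")

        for ov in observed:
            if ov.call.classification == "heteroplasmic" and ov.artifact_flag is None:
                het_rows.append(
                    {
                        "subject": subject_id,
                        "region": row["region"],
                        "diagnosis": row["diagnosis"],
                        "position": ov.call.position,
                        "ref": ov.call.ref_base,
                        "alleles": f"{ov.call.ref_base}/{ov.call.alt}",
                        "heteroplasmy_pct": round(100 * ov.call.heteroplasmy_level, 1),
                        "region_class": ov.annotation.region_class if ov.annotation else ".",
                        "novelty": ov.novelty.status if ov.novelty else ".",
                    }
                )

        if config.call_repeats and "fastq" in meta.columns and pd.notna(row.get("fastq")):
            fq = Path(row["fastq"])
            if not fq.is_absolute():
                fq = meta_dir / fq
            try:
                reads = reads_from_fastq(fq)
                for name, locus in repeat_loci.items():
                    dist = repeat_distribution(reads, locus)
                    mcall = call_multiplasmy(dist)
                    ratio = deletion_ratio(dist)
                    repeat_rows.append(
                        {
                            "subject": subject_id,
                            "region": row["region"],
                            "locus": name,
                            "reference_units": locus.reference_units,
                            "n_spanning": dist.n_spanning,
                            "counts": json.dumps(dist.counts, sort_keys=True),
                            "alleles": ",".join(map(str, mcall.alleles)),
                            "multiplasmic": mcall.is_multiplasmic,
                            "deletion_ratio": ratio.ratio,
                        }
                    )
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("repeats", sample_id, exc) from exc

    cohort = list(subjects.values())

    # burden over subjects with the burden tissue
    burden_cohort = [s for s in cohort if config.burden_tissue in s.samples]
    burden_df = pd.DataFrame()
    partition_counts = {}
    if burden_cohort:
        partition = partition_variants(
            burden_cohort,
            case_groups=config.burden.case_groups,
            tissue=config.burden_tissue,
            config=config.burden,
        )
        group_sizes: dict[str, int] = {}
        for s in burden_cohort:
            if s.diagnosis == "Control" or s.diagnosis in config.burden.case_groups:
                group_sizes[s.diagnosis] = group_sizes.get(s.diagnosis, 0) + 1
        summaries = burden_table(partition, group_sizes)
        burden_df = pd.DataFrame(
            [
                {
                    "group": b.group,
                    "subjects": b.n_subjects,
                    "mutations": b.exclusive_ns_mutations,
                    "mutations_per_subject": round(b.rate, 2),
                    "z": round(b.z, 3),
                }
                for b in summaries
            ]
        )
        partition_counts = {
            "case_only_loci": len(partition.case_only),
            "case_only_observations": partition.observations("case_only"),
            "control_only_loci": len(partition.control_only),
            "control_only_observations": partition.observations("control_only"),
            "shared_loci": len(partition.shared),
        }
        case_rows = [
            {
                "position": pos,
                "alt": alt,
                **{g: counts.get(g, 0) for g in sorted(config.burden.case_groups)},
                "total": sum(counts.values()),
            }
            for (pos, alt), counts in sorted(partition.case_only.items())
        ]
        pd.DataFrame(case_rows).to_csv(
            outdir / "case_only_loci.tsv", sep="\t", index=False
        )
        burden_df.to_csv(outdir / "burden.tsv", sep="\t", index=False)

    pd.DataFrame(het_rows).to_csv(
        outdir / "heteroplasmy.tsv", sep="\t", index=False
    )
    if repeat_rows:
        pd.DataFrame(repeat_rows).to_csv(
            outdir / "multiplasmy.tsv", sep="\t", index=False
        )
    from .reference import context_window

    pd.DataFrame(
        [
            {
                "position": pos,
                "context": context_window(ref, pos, 5),
                "variant": f"{ref_b}/{alt}",
                "n_samples": n,
            }
            for (pos, ref_b, alt), n in sorted(hotspot_counter.items())
        ]
    ).to_csv(outdir / "flagged_hotspots.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "config": config.to_jsonable(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stage_counts": stage_counts,
        "partition": partition_counts,
        "n_subjects": len(cohort),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(output_dir=outdir, subjects=cohort, manifest=manifest)
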