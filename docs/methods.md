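# Methods

## Scope and data model

The package analyses deep-sequencing evidence for human mitochondrial DNA
as per-position allele-count tables (`pos A C G T del`), one per sample,
against a circular 16,569-base reference in rCRS numbering (1-based,
inclusive; index arithmetic wraps modulo the genome length, handled only
in the reference module). Read alignment is upstream and out of scope:
counts may be tallied by any standard aligner/pileup; when tallying from
alignments, sensible defaults are base quality ≥ 20 and mapping quality
≥ 20, which this package does not second-guess because pileup filtering
is not part of the classification model.

A cohort is a set of subjects (diagnosis ∈ {Control, BD, MDD, SZ, METH})
each with one or more regional samples (11 named brain regions and
blood). The dorsolateral prefrontal cortex (DLPFC) is the default tissue
for case/control comparisons.

## Classification model

With depth *n* (deletions included) and major-allele fraction *p̂* over
the four bases:

| rule | default | meaning |
|---|---|---|
| `min_coverage` | 200 reads | below this a site is *filtered*, reported with reason, never classified |
| `homoplasmy_major_min` | 0.95 | *p̂* ≥ 0.95 and major ≠ reference → homoplasmic variant; *p̂* < 0.95 → heteroplasmic |
| `blood_detection_min` | 0.05 | heteroplasmy level below which a variant counts as undetectable in blood |
| `rare_catalog_freq_max` | 0.001 | catalog frequency below which a known variant is *rare* |

Decisions that were genuinely open:

* **The 95% boundary is inclusive for homoplasmy.** Defining homoplasmy
  as "95% to 100%" and heteroplasmy as "<95%" is consistent only with
  this reading; a major fraction of exactly 0.95 is homoplasmic.
* **Heteroplasmy level is the non-reference-allele fraction**, not the
  minor-allele fraction: a 90% C / 10% T site with reference T has level
  0.90. This keeps the level interpretable as mutant load.
* **Ties for the major allele** are broken by base order A<C<G<T and
  flagged (`tie_broken`), purely for determinism.
* **Deletions** count toward depth but are never emitted as substitution
  calls; length variation is handled only at the designated repeat loci.
* **Reference position 3107 is `N`** (the historical rCRS placeholder).
  Calls there are reported with reference `N`, excluded from
  synonymous/non-synonymous tallies, and never silently translated.

## Repeat-length (multiplasmy) calling

Per-read lengths are extracted between exact-match flanking anchors
(default 5 bases each side, mismatch tolerance configurable, default 0);
between the anchors only whole or partial copies of the unit may occur,
otherwise the read is non-spanning. This is deterministic and testable,
and adequate at mtDNA coverage depths; alignment-based extraction was
deliberately not used. The three default loci are 514 (CA)ₙ (reference
(CA)₅), and the D310 / D16189 poly-C tracts, both modelled as the 5'
C-run before their fixed T (the T is the first base of the right anchor,
so a tract-fusing T→C substitution makes reads non-spanning rather than
mis-measured). A length is an allele when supported by ≥ `min_reads`
(10) spanning reads at ≥ `min_fraction` (5%); two or more alleles is
multiplasmy. These support thresholds are this package's choice — no published thresholds exist for this
call — and both are config keys. Stutter is not
denoised: raw length mixtures are reported, and a stutter-aware mode is
explicitly deferred. The deletion/wild-type ratio is (reads shorter than
reference length) / (reads at reference length).

## Artifact filtering

Recurrent spurious heteroplasmic A>C transversions on the Illumina
platform share a context motif: a run of ≥ 2 A's ending at the called
position (inclusive of it — the context `aactaAcctgc` requires this
reading), immediately followed by ≥ 2 C's. Calls matching the motif, or
a configurable blacklist of validation-failed substitutions (shipped
default: A302C, A3492C, A6419C, A10306C, T3488A, T6415A, G9801T), are
flagged, not removed; burden statistics exclude flagged calls by default
via a toggle. Flagging is idempotent and order-independent.

## Annotation

Consequences use the vertebrate mitochondrial genetic code (NCBI table
2, via Biopython: ATA=Met, TGA=Trp, AGA/AGG stop). Heavy-strand codon
index of position *p* in a gene starting at *s* is ⌊(p−s)/3⌋+1;
light-strand genes (ND6) use ⌊(end−p)/3⌋+1 with reverse-complemented
codons. Gene overlaps (ATP8/ATP6, ND4L/ND4) produce one consequence per
gene; "non-synonymous" for burden means non-synonymous in at least one.
Report writers print the first gene in a configurable priority order.
Incomplete terminal codons (genes whose stop is completed by
polyadenylation) are flagged and left untranslated. Damage-prediction
labels are opaque pass-through strings from an external predictor.

Novelty: *novel* = 0 catalog observations, *rare* = frequency < 0.1% of
catalog genomes, *known* otherwise; classification is monotone in the
observed count. The catalog is a user-supplied TSV (a small fixture is
packaged for tests) with an optional `self` flag so counts caused by a
cohort's own database deposit can be discounted. Haplogroup-defining
variants are excluded by exact (position, alt) match against a
user-supplied table; haplogroup *calling* is out of scope.

## Burden statistics

Only non-synonymous, homoplasmic, artifact-unflagged,
non-haplogroup-defining calls enter the exclusive-burden tallies; each
criterion is a toggle. Cases default to {BD, MDD, SZ}; METH is kept
outside the case/control partition (toggleable). A locus (position, alt)
is case-only iff observed in ≥ 1 case subject and no control; each
subject contributes at most one observation per locus.

The group z is the Poisson-rate standardisation
*z = (c/n − λ̂)/√(λ̂/n)* with λ̂ the pooled rate across the tabulated
groups. This formula is fixed and documented because no standard
candidate reproduces the previously reported z values for these group
counts, whose formula was never stated — so counts and rates, not z or p,
are the quantities this package treats as reproducible. The two-sample
version uses the pooled rate (c₁+c₀)/(n₁+n₀) and a two-tailed normal p.
The ≥5-mutation dichotomy uses scipy's one-sided Fisher exact test,
cross-checked in the tests against an exhaustive hypergeometric
enumeration oracle. No multiple-testing correction is applied by default
(the original analysis applied none); a Bonferroni toggle exists
for reuse.

Blood–brain concordance is |shared|/|union| over homoplasmic loci, plus
the list of heteroplasmic loci at level ≥ 5% in some brain region but
< 5% (or absent) in blood.

## Synthetic reference

The package does not redistribute the rCRS sequence; the shipped FASTA
(`synthetic_rcrs.fa`, labelled synthetic in name and header) is built
deterministically by `build_synthetic_reference` from a fixed internal
seed: real NC_012920 gene coordinates; start codons and complete stops
planted; the codon behind every reported amino-acid change solved from
its printed reference/alternate base and residue pair (lexicographically
first consistent codon, overlapping constraints merged); the four A>C
hotspot contexts, the D-loop repeat tracts, and an `N` at 3107 planted
verbatim; random fill elsewhere, iteratively repaired so no protein gene
contains an internal stop codon in either reading frame of the overlap
regions. The D310 tract is modelled as C₅TC₅ at 303–313, matching the
printed motif (whose stated end coordinate, 316, is inconsistent with
its own 11-base sequence); the region map labels 303..315 as D310.
Codon-index arithmetic is independent of the fill, so annotation
coordinates are exact; residue identities at unconstrained codons are
synthetic.

## Synthetic cohorts

`SimulationConfig` defaults are the study conditions: group sizes
20/14/15/14/6 (Control/BD/MDD/SZ/METH); DLPFC for every subject, all 11
brain regions for 11 subjects, blood for 3; negative-binomial coverage
(mean 8,850 — the combined platform average — dispersion 3, giving the
wide min-100-to-max-10⁵ spread a Poisson cannot; per-platform means of
3,766 and 9,775 can be set explicitly); base error 10⁻³ uniform over
non-template bases; per-subject somatic heteroplasmy (Poisson mean 1
site) with levels uniform on 5–35% per brain region — spanning the
observed 6.3–32.5% regional spread — and absent from blood; A>C
artifact injection at motif sites at an 8% read fraction (chosen so
injected artifacts present as clearly heteroplasmic calls, as the
reported hotspots did); repeat stutter 2%. Germline haplotypes come
from a hand-built 3-clade toy tree (5 defining variants each) plus
private variants (Poisson mean 2), so haplogroup exclusion has a planted
truth; case/control burden is planted by drawing per-subject extra
non-synonymous variants at the published per-group rates (0.55 / 1.00 /
0.87 / 1.57). All randomness flows from the single config seed; outputs
are bit-identical across runs.

What the generator does **not** emulate: read-level errors correlated
along reads, strand bias, NUMT contamination, indels outside the repeat
loci, and linkage between variants beyond the clade structure. Passing
tests therefore demonstrate correctness of the classification,
filtering and statistics under binomial/negative-binomial sampling, not
robustness to alignment pathology in real data.

## Problem sizes and numerical choices

Tests and the acceptance checks run at deliberately modest sizes chosen
as adequate for their tolerances: estimator recovery uses 500 replicates
per level at 1000× with a 4σ-style bound (bias < 0.005, RMSE ≤ 1.2×
binomial sd); artifact flagging uses 100 seeded replicates; null
calibration of the rate z uses 2,000 simulated null groups at λn = 100
(large enough that Poisson discreteness keeps the two-tailed 5% level
within ±0.02); end-to-end recovery uses 10 seeded small cohorts.
Fraction sums are checked to 1e-9; allele-fraction ties and all RNG use
numpy `default_rng` seeded from the config. Pipeline reports are
regenerable byte-identically from the manifest's config hash and seed.

## Known limitations

* Cohort-wide published totals (e.g. 3,670 variants across 121 samples,
  the 984/191 DLPFC homoplasmic/heteroplasmic split) depend on raw reads
  that are not shipped and are not asserted anywhere; property tests
  stand in for them.
* The repeat caller abstains rather than guessing when no read spans a
  locus, and treats tract-fusing substitutions as non-spanning.
* The synthetic reference reproduces documented features only; analyses
  keyed to undocumented sequence content require supplying the real
  rCRS FASTA, which every loader accepts.
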