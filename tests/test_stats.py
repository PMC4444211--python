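"""Cohort burden statistics: partition, rates, z, Fisher, concordance."""

import math

import numpy as np
import pytest

from mitoplasmy.annotation import ConsequenceAnnotation, GeneConsequence
from mitoplasmy.calling import ThresholdConfig, VariantCall
from mitoplasmy.stats import (
    BurdenConfig,
    CohortError,
    ObservedVariant,
    SubjectRecord,
    blood_brain_concordance,
    burden_table,
    cohort_from_locus_table,
    fisher_dichotomized,
    fisher_from_table,
    group_rate_z,
    partition_variants,
    region_heteroplasmy_profile,
    subject_ns_counts,
    two_group_rate_test,
)

GROUP_SIZES = {"Control": 20, "BD": 14, "MDD": 15, "SZ": 14}


def variant(position, alt="G", ref="A", classification="homoplasmic_variant",
            level=1.0, nonsyn=True, coverage=1000):
    call = VariantCall(
        position=position, ref_base=ref, major_allele=alt,
        major_fraction=max(level, 1 - level) if classification == "heteroplasmic" else 1.0,
        alleles=((alt, 1.0),), classification=classification,
        heteroplasmy_level=level, coverage=coverage,
    )
    ann = ConsequenceAnnotation(
        position=position, ref=ref, alt=alt,
        genes=(GeneConsequence("ND1", 1, "Met", "Val" if nonsyn else "Met",
                               not nonsyn),),
        region_class="protein",
    )
    return ObservedVariant(call=call, annotation=ann)


def subject(name, diagnosis, dlpfc):
    return SubjectRecord(subject=name, diagnosis=diagnosis, samples={"DLPFC": dlpfc})


class TestPartition:
    def test_fixture_cohort_counts(self, locus_table):
        cohort = cohort_from_locus_table(locus_table, GROUP_SIZES)
        part = partition_variants(cohort)
        assert len(part.case_only) == 37
        assert part.observations("case_only") == 49
        assert part.control_only == {} and part.shared == {}

    def test_variant_in_both_sides_is_shared(self):
        cohort = [
            subject("c1", "Control", [variant(100)]),
            subject("s1", "SZ", [variant(100)]),
        ]
        part = partition_variants(cohort)
        assert part.case_only == {} and part.control_only == {}
        assert list(part.shared) == [(100, "G")]

    def test_single_case_subject_all_case_only(self):
        cohort = [subject("s1", "SZ", [variant(100), variant(200)])]
        part = partition_variants(cohort)
        assert set(part.case_only) == {(100, "G"), (200, "G")}

    def test_empty_cohort_rejected(self):
        with pytest.raises(CohortError):
            partition_variants([])

    def test_meth_subjects_outside_partition(self):
        cohort = [
            subject("d1", "METH", [variant(100)]),
            subject("s1", "SZ", [variant(200)]),
            subject("c1", "Control", [variant(300)]),
        ]
        part = partition_variants(cohort)
        assert (100, "G") not in part.case_only
        assert (100, "G") not in part.control_only

    def test_partition_covers_all_loci_disjointly(self, ref):
        from mitoplasmy.simulate import SimulationConfig, simulate_cohort
        from mitoplasmy.calling import call_sample

        cfg = SimulationConfig(
            seed=3, n_subjects={"Control": 2, "SZ": 2}, multiregion_subjects=0,
            blood_subjects=0, coverage_mean=2000, ac_artifact_rate=0.0,
            base_error_rate=0.0, somatic_site_mean=0.0,
        )
        sim = simulate_cohort(cfg, ref=ref)
        cohort = []
        for (subj, region), table in sim.tables.items():
            calls = [
                variant(c.position, alt=c.alt, ref=c.ref_base)
                for c in call_sample(table, ref).calls
                if c.ref_base != "N"
            ]
            cohort.append(
                SubjectRecord(
                    subject=subj,
                    diagnosis=sim.metadata.loc[
                        sim.metadata.subject == subj, "diagnosis"
                    ].iloc[0],
                    samples={region: calls},
                )
            )
        part = partition_variants(cohort)
        all_loci = {
            v.locus for s in cohort for v in s.samples["DLPFC"]
        }
        covered = set(part.case_only) | set(part.control_only) | set(part.shared)
        assert covered == all_loci
        assert part.n_loci == len(all_loci)

    def test_burden_invariant_to_subject_order_and_duplication(self, locus_table):
        cohort = cohort_from_locus_table(locus_table, GROUP_SIZES)
        base = burden_table(partition_variants(cohort), GROUP_SIZES)
        reordered = burden_table(
            partition_variants(list(reversed(cohort))), GROUP_SIZES
        )
        assert base == reordered
        # duplicating a subject's sample list leaves per-subject loci unchanged
        cohort[5].samples["DLPFC"] = cohort[5].samples["DLPFC"] * 2
        assert burden_table(partition_variants(cohort), GROUP_SIZES) == base


class TestBurden:
    def test_fixture_rates(self, locus_table):
        cohort = cohort_from_locus_table(locus_table, GROUP_SIZES)
        rows = {
            b.group: b for b in burden_table(partition_variants(cohort), GROUP_SIZES)
        }
        assert rows["SZ"].exclusive_ns_mutations == 22
        assert rows["SZ"].rate == pytest.approx(22 / 14)
        assert rows["BD"].exclusive_ns_mutations == 14
        assert rows["MDD"].exclusive_ns_mutations == 13

    def test_all_zero_counts_give_zero_rates_and_z(self):
        cohort = [
            subject("c1", "Control", []),
            subject("s1", "SZ", []),
        ]
        rows = burden_table(
            partition_variants(cohort), {"Control": 1, "SZ": 1}
        )
        assert all(b.rate == 0 and b.z == 0 for b in rows)

    def test_group_rate_z_arithmetic(self):
        assert group_rate_z(10, 10, 1.0) == 0.0
        assert group_rate_z(20, 10, 1.0) == pytest.approx(1.0 / math.sqrt(0.1))
        assert group_rate_z(3, 10, 0.0) == math.inf

    def test_null_z_is_calibrated(self):
        """Type-I error of |z| > 1.96 over simulated null cohorts ~ 5%."""
        rng = np.random.default_rng(2024)
        n, lam, reps = 50, 2.0, 2000
        counts = rng.poisson(n * lam, size=reps)
        z = (counts / n - lam) / np.sqrt(lam / n)
        rate = np.mean(np.abs(z) > 1.96)
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_permuting_diagnoses_destroys_planted_signal(self, locus_table):
        """Mean SZ z over label permutations is ~0 despite the planted
        excess in the unpermuted cohort."""
        cohort = cohort_from_locus_table(locus_table, GROUP_SIZES)
        observed = {
            b.group: b.z
            for b in burden_table(partition_variants(cohort), GROUP_SIZES)
        }["SZ"]
        rng = np.random.default_rng(7)
        diagnoses = [s.diagnosis for s in cohort]
        zs = []
        for _ in range(200):
            perm = rng.permutation(diagnoses)
            permuted = [
                SubjectRecord(s.subject, d, s.samples)
                for s, d in zip(cohort, perm)
            ]
            rows = burden_table(partition_variants(permuted), GROUP_SIZES)
            zs.append({b.group: b.z for b in rows}["SZ"])
        assert observed > 1.0
        assert abs(np.mean(zs)) < 0.2


class TestTwoGroupRateTest:
    def test_identical_rates(self):
        z, p = two_group_rate_test(10, 10, 10, 10)
        assert z == 0.0 and p == 1.0

    def test_all_zero_counts(self):
        assert two_group_rate_test(0, 5, 0, 5) == (0.0, 1.0)

    def test_arithmetic_oracle(self):
        # independently computed pooled-rate z for (22,14) vs (11,20)
        c1, n1, c0, n0 = 22, 14, 11, 20
        pooled = (c1 + c0) / (n1 + n0)
        expect_z = (c1 / n1 - c0 / n0) / math.sqrt(pooled * (1 / n1 + 1 / n0))
        from scipy.stats import norm

        z, p = two_group_rate_test(c1, n1, c0, n0)
        assert z == pytest.approx(expect_z)
        assert p == pytest.approx(2 * norm.sf(abs(expect_z)))

    def test_power_matches_normal_approximation(self):
        """Planted 3x rate ratio, n=20 per arm: empirical power of the
        two-tailed 5% test matches the analytic normal approximation."""
        rng = np.random.default_rng(99)
        n, r0, r1, reps = 20, 0.5, 1.5, 1000
        rejections = 0
        for _ in range(reps):
            c1 = rng.poisson(n * r1)
            c0 = rng.poisson(n * r0)
            z, p = two_group_rate_test(c1, n, c0, n)
            rejections += p < 0.05
        from scipy.stats import norm

        pooled = (r0 + r1) / 2
        se_null = math.sqrt(pooled * 2 / n)
        se_alt = math.sqrt((r0 + r1) / n)
        delta = r1 - r0
        power = norm.sf((1.96 * se_null - delta) / se_alt) + norm.cdf(
            (-1.96 * se_null - delta) / se_alt
        )
        assert rejections / reps == pytest.approx(power, abs=0.05)


def hypergeom_tail(a, r1, r2, c1):
    """Enumeration oracle: P(X >= a) for X ~ Hypergeom with fixed margins
    (row sums r1, r2; first column sum c1)."""
    n = r1 + r2
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if x >= a:
            total += math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
    return total


class TestFisher:
    def test_matches_enumeration_oracle_exhaustively(self):
        for r1 in range(0, 9):
            for r2 in range(0, 9):
                for a in range(0, r1 + 1):
                    for c in range(0, r2 + 1):
                        table = [[a, r1 - a], [c, r2 - c]]
                        expect = (
                            1.0
                            if min(r1, r2) == 0 or a + c == 0 or (r1 - a) + (r2 - c) == 0
                            else hypergeom_tail(a, r1, r2, a + c)
                        )
                        assert fisher_from_table(table) == pytest.approx(expect), table

    def test_random_tables_with_margins_up_to_40(self):
        rng = np.random.default_rng(13)
        for _ in range(150):
            r1, r2 = rng.integers(1, 41, size=2)
            a = int(rng.integers(0, r1 + 1))
            c = int(rng.integers(0, r2 + 1))
            if a + c == 0 or (r1 - a) + (r2 - c) == 0:
                continue
            table = [[a, int(r1 - a)], [c, int(r2 - c)]]
            assert fisher_from_table(table) == pytest.approx(
                hypergeom_tail(a, int(r1), int(r2), a + c)
            )

    def test_dichotomized_no_subject_above_cutoff(self):
        cohort = [
            subject("c1", "Control", [variant(100)]),
            subject("s1", "SZ", [variant(200)]),
        ]
        p, table = fisher_dichotomized(cohort, cutoff=5)
        assert p == 1.0
        assert table == [[0, 1], [0, 1]]

    def test_dichotomized_perfect_separation_is_minimal_tail(self):
        cases = [
            subject(f"s{i}", "SZ", [variant(100 + j) for j in range(6)])
            for i in range(5)
        ]
        controls = [subject(f"c{i}", "Control", [variant(900)]) for i in range(5)]
        p, table = fisher_dichotomized(cases + controls, cutoff=5)
        assert table == [[5, 0], [0, 5]]
        assert p == pytest.approx(hypergeom_tail(5, 5, 5, 5))

    def test_example_table_against_oracle(self):
        assert fisher_from_table([[2, 8], [8, 2]]) == pytest.approx(
            hypergeom_tail(2, 10, 10, 10)
        )


class TestBloodBrain:
    def test_identical_call_sets_concordance_one(self):
        calls = [variant(100), variant(200)]
        s = SubjectRecord(
            "c1", "Control", {"DLPFC": list(calls), "blood": list(calls)}
        )
        report = blood_brain_concordance(s)
        assert report.homoplasmic_concordance == 1.0
        assert report.brain_only == ()

    def test_brain_8pct_blood_2pct_is_brain_only(self):
        brain = [variant(500, classification="heteroplasmic", level=0.08)]
        blood = [variant(500, classification="heteroplasmic", level=0.02)]
        s = SubjectRecord("c1", "Control", {"DLPFC": brain, "blood": blood})
        report = blood_brain_concordance(s)
        assert [(p, r) for p, _, r, _ in report.brain_only] == [(500, "DLPFC")]

    def test_planted_brain_only_heteroplasmies_recovered(self):
        brain = [
            variant(1000 + i, classification="heteroplasmic", level=0.10 + 0.02 * i)
            for i in range(5)
        ]
        s = SubjectRecord("c1", "Control", {"DLPFC": brain, "blood": []})
        report = blood_brain_concordance(s)
        assert len(report.brain_only) == 5

    def test_missing_blood_rejected(self):
        s = subject("c1", "Control", [variant(100)])
        with pytest.raises(CohortError):
            blood_brain_concordance(s)


class TestRegionProfile:
    def test_planted_levels_recovered(self):
        levels = {"NACC": 0.063, "THAL": 0.325, "DLPFC": 0.15}
        samples = {
            region: [variant(16086, ref="T", alt="C",
                             classification="heteroplasmic", level=lvl)]
            for region, lvl in levels.items()
        }
        samples["CB"] = []  # filtered / not called there
        s = SubjectRecord("c1", "Control", samples)
        profile = region_heteroplasmy_profile(s, 16086)
        assert profile.min_level == pytest.approx(0.063)
        assert profile.max_level == pytest.approx(0.325)
        assert profile.level_range == pytest.approx(0.262)
        assert profile.filtered_regions == ("CB",)

    def test_position_called_nowhere_rejected(self):
        s = subject("c1", "Control", [])
        with pytest.raises(CohortError):
            region_heteroplasmy_profile(s, 42)


def test_subject_ns_counts_respects_toggles():
    flagged = variant(100)
    flagged = ObservedVariant(
        call=flagged.call, annotation=flagged.annotation,
        artifact_flag=object.__new__(type("F", (), {})),  # placeholder flag
    )
    syn = variant(200, nonsyn=False)
    het = variant(300, classification="heteroplasmic", level=0.2)
    good = variant(400)
    s = subject("s1", "SZ", [flagged, syn, het, good])
    assert subject_ns_counts([s]) == {"s1": 1}
    loose = BurdenConfig(
        require_nonsynonymous=False, require_homoplasmic=False,
        exclude_artifact_flagged=False,
    )
    assert subject_ns_counts([s], config=loose) == {"s1": 4}
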