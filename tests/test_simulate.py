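"""Synthetic data generator: determinism, plants, recovery, artifacts."""

import numpy as np
import pandas as pd
import pytest

from mitoplasmy.calling import AlleleCounts, ThresholdConfig, classify_position, call_sample
from mitoplasmy.artifacts import apply_blacklist, motif_positions
from mitoplasmy.simulate import (
    SimulationConfig,
    SimulationError,
    inject_ac_artifacts,
    simulate_cohort,
    simulate_pileup,
    simulate_repeat_reads,
)

SMALL = dict(
    n_subjects={"Control": 2, "SZ": 2},
    multiregion_subjects=0,
    blood_subjects=0,
    coverage_mean=2000,
)


class TestDeterminism:
    def test_same_seed_bit_identical(self, ref):
        a = simulate_cohort(SimulationConfig(seed=5, **SMALL), ref=ref)
        b = simulate_cohort(SimulationConfig(seed=5, **SMALL), ref=ref)
        assert a.truth.to_json() == b.truth.to_json()
        for key in a.tables:
            pd.testing.assert_frame_equal(a.tables[key], b.tables[key])

    def test_different_seed_differs(self, ref):
        a = simulate_cohort(SimulationConfig(seed=5, **SMALL), ref=ref)
        b = simulate_cohort(SimulationConfig(seed=6, **SMALL), ref=ref)
        assert a.truth.to_json() != b.truth.to_json()


class TestSimulatePileup:
    def test_planted_fraction_recovered_within_binomial_error(self, ref):
        hap = ref.sequence.replace("N", "A")
        f, cov = 0.10, 10_000
        pos = 5000
        alt = next(b for b in "ACGT" if b != hap[pos - 1])
        df = simulate_pileup(
            hap, {pos: (alt, f)}, coverage_mean=cov,
            coverage_dispersion=1e6, error_rate=0.0, rng=4,
        )
        row = df.iloc[pos - 1]
        depth = row[["A", "C", "G", "T"]].sum()
        sd = (f * (1 - f) / depth) ** 0.5
        assert abs(row[alt] / depth - f) < 4 * sd

    def test_zero_fraction_zero_error_no_nontemplate_reads(self, ref):
        hap = ref.sequence.replace("N", "G")
        df = simulate_pileup(hap, coverage_mean=500, error_rate=0.0, rng=1)
        mat = df[["A", "C", "G", "T"]].to_numpy()
        for i, base in enumerate(hap):
            nontemplate = mat[i].sum() - mat[i]["ACGT".index(base)]
            assert nontemplate == 0

    def test_90pct_heteroplasmy_at_16519_called_at_90(self, ref):
        # the scenario where one region is ~90% non-reference
        assert ref.base(16519) == "T"
        hap = ref.sequence.replace("N", "A")
        df = simulate_pileup(
            hap, {16519: ("C", 0.90)}, coverage_mean=5000, error_rate=0.0, rng=2
        )
        row = df.iloc[16518]
        counts = AlleleCounts(16519, {b: int(row[b]) for b in "ACGT"})
        call = classify_position(counts, "T")
        assert call.classification == "heteroplasmic"
        assert call.heteroplasmy_level == pytest.approx(0.90, abs=0.02)

    def test_fraction_outside_unit_interval_rejected(self, ref):
        with pytest.raises(SimulationError):
            simulate_pileup(ref.sequence, {100: ("C", 1.5)}, rng=0)


class TestArtifactInjection:
    def test_zero_fraction_leaves_table_unchanged(self, ref):
        hap = ref.sequence.replace("N", "A")
        df = simulate_pileup(hap, coverage_mean=1000, error_rate=0.0, rng=9)
        out = inject_ac_artifacts(df, ref, 0.0, rng=9)
        pd.testing.assert_frame_equal(df, out)

    def test_motif_positions_acquire_flagged_het_calls(self, ref):
        hap = ref.sequence.replace("N", "A")
        df = simulate_pileup(hap, coverage_mean=3000, error_rate=0.0, rng=20)
        out = inject_ac_artifacts(df, ref, 0.08, rng=21)
        result = call_sample(out, ref)
        called = {c.position: c for c in result.calls}
        for pos in (3492, 6419, 10306):
            assert pos in called
            assert called[pos].classification == "heteroplasmic"
            assert called[pos].alt == "C"
        flagged, retained = apply_blacklist(
            [c for c in result.calls if c.ref_base != "N"], ref
        )
        assert retained == []  # artifacts are the only non-reference calls

    def test_non_motif_positions_unchanged(self, ref):
        hap = ref.sequence.replace("N", "A")
        df = simulate_pileup(hap, coverage_mean=1000, error_rate=0.0, rng=22)
        out = inject_ac_artifacts(df, ref, 0.10, rng=23)
        hot = set(motif_positions(ref))
        cold = ~out["pos"].isin(hot)
        pd.testing.assert_frame_equal(df.loc[cold], out.loc[cold])


class TestRepeatReads:
    def test_pure_mixture_no_stutter_single_length(self, repeat_loci):
        reads = simulate_repeat_reads(
            {5: 1.0}, repeat_loci["CA514"], n_reads=200, stutter_rate=0.0, rng=0
        )
        assert all("CA" * 5 in r and "CA" * 6 not in r for r in reads)

    def test_stutter_rate_within_binomial_bounds(self, repeat_loci):
        from mitoplasmy.repeats import repeat_distribution

        n, rate = 5000, 0.02
        reads = simulate_repeat_reads(
            {5: 1.0}, repeat_loci["CA514"], n_reads=n, stutter_rate=rate, rng=8
        )
        dist = repeat_distribution(reads, repeat_loci["CA514"])
        slipped = dist.n_spanning - dist.counts.get(5, 0)
        sd = (n * rate * (1 - rate)) ** 0.5
        assert abs(slipped - n * rate) < 4 * sd

    def test_low_stutter_stays_below_multiplasmy_threshold(self, repeat_loci):
        from mitoplasmy.repeats import call_multiplasmy, repeat_distribution

        reads = simulate_repeat_reads(
            {5: 1.0}, repeat_loci["CA514"], n_reads=2000, stutter_rate=0.02, rng=3
        )
        call = call_multiplasmy(repeat_distribution(reads, repeat_loci["CA514"]))
        assert call.alleles == (5,)
        assert not call.is_multiplasmic

    def test_mixture_must_sum_to_one(self, repeat_loci):
        with pytest.raises(SimulationError):
            simulate_repeat_reads({5: 0.5, 6: 0.4}, repeat_loci["CA514"], rng=0)


class TestCohort:
    def test_invalid_group_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_subjects={"XYZ": 3})

    def test_zero_somatic_rate_identical_region_consensus(self, ref):
        from mitoplasmy.calling import build_consensus

        cfg = SimulationConfig(
            seed=21, n_subjects={"Control": 1}, multiregion_subjects=1,
            blood_subjects=0, coverage_mean=2500, somatic_site_mean=0.0,
            ac_artifact_rate=0.0,
        )
        sim = simulate_cohort(cfg, ref=ref)
        # identical up to coverage masking: compare on jointly covered sites
        tables = list(sim.tables.values())
        assert len(tables) == 11  # all brain regions, no blood
        c0 = build_consensus(tables[0], genome_length=len(ref)).bases
        for t in tables[1:]:
            ci = build_consensus(t, genome_length=len(ref)).bases
            for a, b in zip(c0, ci):
                assert a == b or "N" in (a, b)

    def test_planted_group_burden_rates_realised(self, ref):
        """Mean number of planted extra non-synonymous variants per subject
        matches the configured per-group rates (Poisson means)."""
        totals = {"Control": 0, "SZ": 0}
        n = {"Control": 0, "SZ": 0}
        for seed in range(12):
            cfg = SimulationConfig(
                seed=seed, n_subjects={"Control": 6, "SZ": 6},
                multiregion_subjects=0, blood_subjects=0, coverage_mean=300,
                private_variant_mean=0.0, somatic_site_mean=0.0,
            )
            sim = simulate_cohort(cfg, ref=ref)
            for subject, extras in sim.truth.burden_extra.items():
                group = subject.split("-")[0]
                totals[group] += len(extras)
                n[group] += 1
        for group, rate in (("Control", 0.55), ("SZ", 1.57)):
            mean = totals[group] / n[group]
            se = (rate / n[group]) ** 0.5
            assert abs(mean - rate) < 4 * se

    def test_end_to_end_recovery_of_planted_truth(self, ref):
        """Planted homoplasmic germline variants are recovered (>=99%),
        heteroplasmies >=7% are detected, and no artifact call survives
        filtering, across seeded replicates."""
        total_planted = total_recovered = 0
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed, n_subjects={"Control": 1, "SZ": 1},
                multiregion_subjects=0, blood_subjects=0,
                coverage_mean=3000, somatic_site_mean=0.0,
            )
            sim = simulate_cohort(cfg, ref=ref)
            for (subject, region), table in sim.tables.items():
                calls = call_sample(table, ref)
                # a planted variant counts as recovered when called with the
                # right allele; an artifact landing on top of it can lower
                # the major fraction below 95%, which is still a detection
                found = {
                    c.position: c.alt for c in calls.calls if c.ref_base != "N"
                }
                planted = sim.truth.germline[subject]
                total_planted += len(planted)
                total_recovered += sum(
                    found.get(p) == alt for p, alt in planted.items()
                )
                # artifacts never survive the filter
                flagged, retained = apply_blacklist(
                    [c for c in calls.calls if c.ref_base != "N"], ref
                )
                survivors = {
                    c.position for c in retained
                    if c.classification == "heteroplasmic" and c.alt == "C"
                } & set(sim.truth.artifact_positions)
                assert survivors == set()
        assert total_recovered >= 0.99 * total_planted

    def test_heteroplasmy_sensitivity_at_coverage_1000(self, ref):
        """Planted heteroplasmies at >=7% with ~1000x coverage are detected
        with sensitivity >=0.95."""
        hap = ref.sequence.replace("N", "A")
        rng = np.random.default_rng(0)
        detected = trials = 0
        positions = rng.integers(600, 16000, size=100)
        for i, pos in enumerate(map(int, positions)):
            f = float(rng.uniform(0.07, 0.5))
            alt = next(b for b in "ACGT" if b != hap[pos - 1])
            df = simulate_pileup(
                hap, {pos: (alt, f)}, coverage_mean=1000,
                coverage_dispersion=1e6, error_rate=1e-3, rng=rng,
            )
            row = df.iloc[pos - 1]
            counts = AlleleCounts(pos, {b: int(row[b]) for b in "ACGT"})
            call = classify_position(counts, hap[pos - 1])
            trials += 1
            from mitoplasmy.calling import VariantCall

            detected += (
                isinstance(call, VariantCall)
                and call.classification == "heteroplasmic"
                and call.alt == alt
            )
        assert detected / trials >= 0.95

    def test_metadata_covers_all_tables(self, ref):
        sim = simulate_cohort(SimulationConfig(seed=1, **SMALL), ref=ref)
        meta_keys = {
            (r.subject, r.region) for r in sim.metadata.itertuples(index=False)
        }
        assert meta_keys == set(sim.tables)


def test_write_cohort_round_trip(tmp_path, ref):
    import json

    from mitoplasmy.calling import read_count_table
    from mitoplasmy.simulate import write_cohort

    sim = simulate_cohort(SimulationConfig(seed=2, **SMALL), ref=ref)
    out = write_cohort(sim, tmp_path / "sim")
    meta = pd.read_csv(out / "metadata.tsv", sep="\t")
    assert len(meta) == len(sim.tables)
    first = meta.iloc[0]
    table = read_count_table(out / first["count_table"])
    pd.testing.assert_frame_equal(
        table, sim.tables[(first["subject"], first["region"])]
    )
    truth = json.loads((out / "truth.json").read_text())
    assert set(truth["germline"]) == {s for s, _ in sim.tables}
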