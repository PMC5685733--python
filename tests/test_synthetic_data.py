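"""Generator self-consistency, determinism and ground-truth fidelity."""

import numpy as np
import pandas as pd
import pytest

from sermir import io
from sermir import survival as sv
from sermir import synthetic_data as sd


class TestToyReference:
    def test_loci_extracts_match_written_mature_fasta(self, toy_ref, tmp_path):
        paths = toy_ref.write(tmp_path)
        loaded = sd.load_reference(tmp_path)
        mature = io.read_fasta(paths["mature_fasta"])
        assert len(loaded.mirna_loci) == len(toy_ref.mirna_loci) >= 20
        for loc in loaded.mirna_loci:
            assert loaded.mature_sequence(loc) == mature[loc.mature_name]

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        for d in ("a", "b"):
            sd.build_toy_reference(seed=11).write(tmp_path / d)
        for name in ("genome.fa", "mirna.gff3", "mature.fa", "ncrna.fa", "calibrators.fa"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_ten_distinct_22nt_calibrators_absent_from_genome(self, toy_ref):
        seqs = [c.sequence for c in toy_ref.calibrators]
        assert len(seqs) == 10 == len(set(seqs))
        assert all(len(s) == 22 for s in seqs)
        genome = "".join(toy_ref.contigs.values())
        assert not any(s in genome for s in seqs)

    def test_ncrna_entries_at_least_30nt(self, toy_ref):
        assert all(len(e.sequence) >= 30 for e in toy_ref.ncrna_db)

    def test_calibrator_colliding_with_mature_rejected(self, toy_ref):
        mature = next(iter(toy_ref.mature_seqs.values()))
        cfg = sd.ReferenceConfig(calibrator_sequences=(mature,) + tuple(
            c.sequence for c in toy_ref.calibrators[:9]
        ))
        with pytest.raises(ValueError, match="collides"):
            sd.build_toy_reference(cfg, seed=1)

    def test_too_few_loci_rejected(self):
        with pytest.raises(ValueError):
            sd.build_toy_reference(sd.ReferenceConfig(n_mirna_loci=5), seed=0)


class TestCohort:
    def test_default_marginals_match_study_table(self, cohort):
        meta, _ = cohort
        assert len(meta) == 96
        assert (meta["m_stage"] == "M1").sum() == 21
        assert meta["stage_group"].value_counts().to_dict() == {
            "II": 38, "III": 23, "IV": 21, "I": 13, "0": 1
        }
        assert (meta["serum_timing"] == "before").sum() == 53
        assert (meta["sex"] == "male").sum() == 53
        assert meta.loc[meta["stage_group"] == "IV", "m_stage"].eq("M1").all()
        assert (meta["treatment"] == "crt").sum() == 34

    def test_zero_event_rate_censors_everyone(self):
        spec = sd.CohortSpec(five_year_survival={s: 1.0 for s in ("0", "I", "II", "III", "IV")})
        meta, _ = sd.simulate_cohort(spec, seed=0)
        assert (meta["os_event"] == 0).all()

    def test_km_five_year_gap_matches_configured_rates(self):
        # 1e4 patients, stage-IV hazard 5x stage I: closed-form exponential
        # 5-year survival is 0.9 and 0.9**5
        n = 10_000
        spec = sd.CohortSpec(
            n_patients=n,
            stage_counts={"I": n // 2, "IV": n - n // 2},
            n_before_treatment=n, n_after_treatment=0,
            sex_counts={"male": n // 2, "female": n - n // 2},
            after_treatments={},
            n_m1_before=n - n // 2, n_m1_after_crt=0,
            t_counts={"T3": n}, n_counts={"N0": n},
            age_bins=((50, 69, n),),
            five_year_survival={"I": 0.9, "IV": 0.9 ** 5},
            followup_months=(61.0, 120.0),
        )
        meta, _ = sd.simulate_cohort(spec, seed=4)
        curves, _ = sv.km_estimator(
            meta["os_months"], meta["os_event"], meta["stage_group"]
        )
        at60 = {
            g: grp.loc[grp["time"] <= 60, "survival"].iloc[-1]
            for g, grp in curves.groupby("group")
        }
        assert at60["I"] == pytest.approx(0.9, abs=0.03)
        assert at60["IV"] == pytest.approx(0.9 ** 5, abs=0.03)

    def test_determinism(self):
        a, _ = sd.simulate_cohort(seed=5)
        b, _ = sd.simulate_cohort(seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestSampleReads:
    def test_all_canonical_mix_reproduces_mature_sequences(self, toy_ref, cohort):
        meta, _ = cohort
        profile = sd.SampleProfile(
            library_size=2000,
            class_mixture={"miRNA": 1.0},
            isomir_mix={"canonical": 1.0, "3p-trim": 0.0, "nta": 0.0, "3p-tail": 0.0, "5p-mod": 0.0},
            calibrator_fraction=0.0,
        )
        _, truth = sd.simulate_sample_reads(toy_ref, profile, meta.iloc[0], seed=0)
        matures = toy_ref.mature_seqs
        assert (truth["rna_class"] == "miRNA").all()
        assert all(ins == matures[f] for ins, f in zip(truth["insert"], truth["feature"]))

    def test_read_level_nta_fraction_recovers_mix(self, toy_ref, cohort):
        meta, _ = cohort
        mix = {"canonical": 0.20, "3p-trim": 0.20, "nta": 0.39, "3p-tail": 0.11, "5p-mod": 0.10}
        profile = sd.SampleProfile(
            library_size=50_000, class_mixture={"miRNA": 1.0},
            isomir_mix=mix, calibrator_fraction=0.0,
        )
        _, truth = sd.simulate_sample_reads(toy_ref, profile, meta.iloc[0], seed=1)
        frac = (truth["itype"] == "nta").mean()
        assert frac == pytest.approx(0.39, abs=0.01)

    def test_planted_lfc_doubles_relative_abundance(self, toy_ref, cohort):
        meta, _ = cohort
        cat = sd.build_catalogue(toy_ref, sd.SampleProfile(), seed=2)
        eff = [sd.DEEffect("miR-sim-03", 1.0, "m1")]
        m1 = meta[meta["m_stage"] == "M1"].iloc[0]
        m0 = meta[meta["m_stage"] == "M0"].iloc[0]
        f1 = sd.expected_mirna_fractions(cat, eff, m1)
        f0 = sd.expected_mirna_fractions(cat, eff, m0)
        odds1 = f1["miR-sim-03"] / f1["miR-sim-10"]
        odds0 = f0["miR-sim-03"] / f0["miR-sim-10"]
        assert odds1 / odds0 == pytest.approx(2.0, rel=1e-12)

    def test_determinism_conservation_and_truth_coverage(self, toy_ref, cohort):
        meta, _ = cohort
        profile = sd.SampleProfile(library_size=3000)
        cat = sd.build_catalogue(toy_ref, profile, seed=2)
        r1, t1 = sd.simulate_sample_reads(toy_ref, profile, meta.iloc[0], catalogue=cat, seed=9)
        r2, t2 = sd.simulate_sample_reads(toy_ref, profile, meta.iloc[0], catalogue=cat, seed=9)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)
        assert len(r1) == profile.library_size            # conservation
        ids = [rid for rid, _ in r1]
        assert sorted(ids) == sorted(t1["read_id"])        # truth coverage
        assert t1["read_id"].is_unique
        assert all(len(s) == sd.READ_LENGTH for _, s in r1)

    def test_mixture_must_sum_to_one(self):
        profile = sd.SampleProfile(class_mixture={"miRNA": 0.5})
        with pytest.raises(ValueError, match="sum to 1"):
            profile.validate()


class TestFeatureLevelSimulators:
    def test_count_matrix_shapes_and_truth(self):
        counts, groups, truth = sd.simulate_count_matrix(
            n_features=100, group_sizes=(10, 5), n_de=8, seed=0
        )
        assert counts.shape == (100, 15)
        assert (counts.to_numpy() >= 0).all()
        assert len(truth) == 8
        assert groups.value_counts().to_dict() == {"A": 10, "B": 5}

    def test_survival_simulator_censoring_fraction(self):
        df = sd.simulate_survival_data(n=4000, hr=2.0, censoring=0.2, seed=0)
        assert 1 - df["event"].mean() == pytest.approx(0.2, abs=0.03)

    def test_ct_table_layout(self):
        ct = sd.simulate_ct_table(["t"], ["c1", "c2"], seed=0)
        assert set(ct.columns) == {"sample", "group", "gene", "replicate", "Ct"}
        assert set(ct["gene"]) == {"t", "c1", "c2"}
        assert ct.groupby(["sample", "gene"])["replicate"].count().eq(2).all()
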