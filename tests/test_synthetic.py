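"""Cohort generator: determinism, validity, truth recovery, noise model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from capmorph.annotation_io import GROUP_LABELS, validate_annotations
from capmorph.morphometry import compute_profile_metrics, profile_table
from capmorph.pipeline import PipelineConfig, run_pipeline
from capmorph.synthetic import (
    CohortConfig,
    GroupPhenotype,
    RaterNoise,
    default_study_config,
    generate_cohort,
    recovery_report,
    reference_group_table,
    sample_capillary,
    save_cohort,
)
from capmorph.annotation_io import annotations_to_json


def zero_sd_phenotype(**overrides):
    base = dict(
        label="endurance_pre", n_subjects=2, n_capillaries=5,
        lumen_radius_sd=0.0, ec_thickness_sd=0.0, bm_thickness_sd=0.0,
        pc_coverage_sd=0.0, nucleus_area_density_sd=0.0,
        luminal_enlargement_sd=0.0, disrupted_bm_sd=0.0,
        p_ec_socket_sd=0.0, p_empty_ec_socket_sd=0.0,
        p_pc_socket_sd=0.0, p_empty_pc_socket_sd=0.0,
        oblique_fraction=0.0, elongation_included=(1.0, 1.0),
        harmonic_amplitude=0.0, nucleus_presence_p=1.0,
    )
    base.update(overrides)
    return GroupPhenotype(**base)


def small_config(n_subjects=3, n_capillaries=6, labels=("endurance_pre",
                                                        "endurance_post"),
                 noise=None, **pheno_overrides):
    groups = {}
    for lbl in labels:
        base = default_study_config()[lbl]
        groups[lbl] = dataclasses.replace(
            base, n_subjects=n_subjects, n_capillaries=n_capillaries,
            **pheno_overrides)
    return CohortConfig(groups=groups, rater_noise=noise or RaterNoise())


class TestSampleCapillary:
    def test_zero_sd_phenotype_identical_metrics(self, rng):
        phen = zero_sd_phenotype()
        metrics = []
        for i in range(6):
            ann, _ = sample_capillary(phen, rng, micrograph_id=f"m{i}")
            m = compute_profile_metrics(ann)
            metrics.append((m.lumen_radius_nm, m.ec_thickness_nm,
                            m.bm_thickness_nm, m.pc_coverage,
                            m.nucleus_area_density_pct,
                            m.luminal_enlargement_pct))
        arr = np.asarray(metrics)
        # identical up to arc quantization of pericyte/nucleus footprints
        np.testing.assert_allclose(arr, np.broadcast_to(arr[0], arr.shape),
                                   rtol=2e-2)

    def test_circular_profiles_recover_generating_geometry(self, rng):
        phen = zero_sd_phenotype(pc_coverage_sd=0.0)
        errs = []
        for i in range(10):
            ann, truth = sample_capillary(phen, rng, micrograph_id=f"m{i}")
            m = compute_profile_metrics(ann)
            errs.append([
                m.lumen_radius_nm / truth.lumen_radius_nm - 1,
                m.ec_thickness_nm / truth.ec_thickness_nm - 1,
                m.bm_thickness_nm / truth.bm_thickness_nm - 1,
            ])
        assert np.max(np.abs(errs)) < 0.01

    def test_fixed_oblique_elongation_all_excluded(self, rng):
        phen = zero_sd_phenotype(oblique_fraction=1.0,
                                 elongation_oblique=(1.5, 1.5))
        for i in range(5):
            ann, truth = sample_capillary(phen, rng, micrograph_id=f"m{i}")
            m = compute_profile_metrics(ann)
            assert truth.oblique
            assert m.excluded and m.exclusion_reason == "oblique_section"

    def test_enlargement_realized_exactly(self, rng):
        from capmorph.morphometry import luminal_enlargement

        phen = zero_sd_phenotype(luminal_enlargement_pct=17.0)
        ann, truth = sample_capillary(phen, rng)
        assert truth.luminal_enlargement_pct == pytest.approx(17.0, rel=1e-9)
        assert luminal_enlargement(ann) == pytest.approx(17.0, rel=1e-9)

    def test_generated_annotations_valid(self, rng):
        phen = default_study_config()["diabetic_pre"]
        anns = [sample_capillary(phen, rng, micrograph_id=f"m{i}")[0]
                for i in range(30)]
        validate_annotations(anns)


class TestGenerateCohort:
    def test_same_seed_byte_identical(self):
        cfg = small_config()
        c1 = generate_cohort(cfg, master_seed=5)
        c2 = generate_cohort(cfg, master_seed=5)
        for rater in ("A", "B"):
            assert annotations_to_json(c1.annotations[rater]) == \
                annotations_to_json(c2.annotations[rater])
        pd.testing.assert_frame_equal(c1.truth_capillaries,
                                      c2.truth_capillaries)

    def test_different_seeds_differ(self):
        cfg = small_config()
        c1 = generate_cohort(cfg, master_seed=5)
        c2 = generate_cohort(cfg, master_seed=6)
        assert annotations_to_json(c1.annotations["A"]) != \
            annotations_to_json(c2.annotations["A"])

    def test_study_size_bookkeeping_with_default_config(self):
        # full study structure: 126 biopsies; 40 capillaries per biopsy
        cfg = CohortConfig()
        n_biopsies = sum(p.n_subjects for p in cfg.groups.values())
        assert n_biopsies == 126
        assert [cfg.groups[g].n_subjects for g in GROUP_LABELS] == \
            [10, 10, 6, 6, 6, 6, 10, 10, 9, 9, 10, 10, 10, 14]
        small = small_config(n_subjects=2, n_capillaries=3)
        cohort = generate_cohort(small, master_seed=0)
        assert cohort.manifest["n_biopsies"] == 4
        assert cohort.manifest["n_capillaries"] == 4 * 3
        assert len(cohort.annotations["A"]) == 12

    def test_zero_rater_noise_gives_identical_geometry(self):
        cfg = small_config(noise=RaterNoise(0.0, 0.0, 0.0))
        cohort = generate_cohort(cfg, master_seed=1)
        for a, b in zip(cohort.annotations["A"], cohort.annotations["B"]):
            assert a.lumen == b.lumen
            assert a.bm_outer == b.bm_outer
            assert a.projections == b.projections
            assert a.rater_id != b.rater_id

    def test_rater_noise_scales_length_indices_only(self):
        cfg = small_config(noise=RaterNoise(0.10, 0.0, 0.0,
                                            repeat_until_accepted=False))
        cohort = generate_cohort(cfg, master_seed=1)
        da = profile_table(cohort.annotations["A"])
        db = profile_table(cohort.annotations["B"])
        ratio = (db["lumen_radius_nm"] / da["lumen_radius_nm"]).to_numpy()
        assert np.std(np.log(ratio)) == pytest.approx(0.10 * np.sqrt(2), rel=0.2)
        # dimensionless indices are calibration-invariant
        np.testing.assert_allclose(db["pc_coverage"], da["pc_coverage"],
                                   rtol=1e-9)
        np.testing.assert_allclose(db["luminal_enlargement_pct"],
                                   da["luminal_enlargement_pct"], rtol=1e-9)
        # both layer thicknesses carry the same calibration factor
        np.testing.assert_allclose(
            db["ec_thickness_nm"] / da["ec_thickness_nm"], ratio, rtol=1e-6)

    def test_paired_groups_share_subjects(self):
        cohort = generate_cohort(small_config(), master_seed=2)
        subj = cohort.truth_subjects
        pre = set(subj.loc[subj.group == "endurance_pre", "subject_id"])
        post = set(subj.loc[subj.group == "endurance_post", "subject_id"])
        assert pre == post
        ages = subj.groupby("subject_id")["age_years"].nunique()
        assert (ages == 1).all()

    def test_subject_draws_stable_under_group_removal(self):
        both = generate_cohort(small_config(), master_seed=3)
        only_pre = generate_cohort(
            small_config(labels=("endurance_pre",)), master_seed=3)
        a = both.truth_subjects.query("group == 'endurance_pre'")
        b = only_pre.truth_subjects
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))

    def test_unknown_group_label_rejected(self):
        cfg = small_config(labels=("endurance_pre",))
        cfg.groups["made_up_group"] = dataclasses.replace(
            cfg.groups["endurance_pre"], label="made_up_group")
        with pytest.raises(ValueError, match="unknown study group"):
            generate_cohort(cfg, master_seed=0)

    def test_save_cohort_writes_files(self, tmp_path):
        cohort = generate_cohort(small_config(n_subjects=2, n_capillaries=2),
                                 master_seed=0)
        paths = save_cohort(cohort, tmp_path)
        for key in ("annotations_A", "annotations_B", "truth", "manifest"):
            assert key in paths


class TestRecovery:
    def test_noiseless_cohort_recovers_geometry_tightly(self):
        cfg = small_config(
            n_subjects=4, n_capillaries=10,
            noise=RaterNoise(0.0, 0.0, 0.0),
            lumen_radius_sd=0.0, ec_thickness_sd=0.0, bm_thickness_sd=0.0,
            pc_coverage_sd=0.0, oblique_fraction=0.0,
            elongation_included=(1.0, 1.0), harmonic_amplitude=0.0,
        )
        cohort = generate_cohort(cfg, master_seed=4)
        res = run_pipeline(cohort.annotations, PipelineConfig(),
                           run_stats=False)
        rep = recovery_report(cohort.truth_groups, res.subjects)
        geom = rep[rep.parameter.isin(["lumen_radius_nm", "ec_thickness_nm",
                                       "bm_thickness_nm", "pc_coverage"])]
        assert (np.abs(geom.recovered_value / geom.generating_value - 1)
                < 0.01).all()

    def test_zero_disruption_probability_recovers_zero(self, rng):
        cfg = small_config(disrupted_bm_p=0.0, disrupted_bm_sd=0.0)
        cohort = generate_cohort(cfg, master_seed=5)
        res = run_pipeline(cohort.annotations, PipelineConfig(),
                           run_stats=False)
        assert (res.subjects["pct_capillaries_bm_disrupted"] == 0).all()

    def test_enlargement_recovered_near_published_means(self):
        # moderate-size check; the full-size recovery runs in the acceptance
        # suite
        cfg = small_config(labels=("diabetic_pre",), n_subjects=8,
                           n_capillaries=30)
        cohort = generate_cohort(cfg, master_seed=6)
        res = run_pipeline(cohort.annotations, PipelineConfig(),
                           run_stats=False)
        rep = recovery_report(cohort.truth_groups, res.subjects)
        row = rep[(rep.parameter == "luminal_enlargement_pct")].iloc[0]
        assert row.generating_value == pytest.approx(10.2)
        assert abs(row.z) < 3

    def test_full_cohort_recovery_unbiased(self):
        # full study-size cohort: the recovered group means scatter around
        # the generating means like independent z-scores — bounded excursion
        # fraction and no outlier beyond heavy-tail expectation
        cohort = generate_cohort(CohortConfig(), master_seed=0)
        res = run_pipeline(cohort.annotations, PipelineConfig(),
                           ages=cohort.ages, run_stats=False)
        rep = recovery_report(cohort.truth_groups, res.subjects)
        z = rep["z"].to_numpy()
        assert np.isfinite(z).all()
        assert (np.abs(z) > 2).mean() < 0.25
        assert np.abs(z).max() < 4.5

    def test_reference_table_consistency(self):
        ref = reference_group_table()
        assert list(ref.group) == list(GROUP_LABELS)
        assert int(ref.n_capillaries.sum()) == 5000
        assert int(ref.n_subjects.sum()) == 126
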