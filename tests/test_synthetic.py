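"""Generator contracts: determinism, the generative formula, ground truth."""

import numpy as np
import pandas as pd
import pytest

import normvol as nv


class TestTrajectoryPresets:
    @pytest.mark.parametrize(
        "region,apr",
        [
            ("posterior_cingulate", -1.9),
            ("amygdala", -0.8),
            ("corticospinal_tract", 0.8),
            ("body_corpus_callosum", 0.5),
            ("genu_corpus_callosum", 0.1),
            ("global_grey", -17.0 / 12.0),
            ("global_white", 9.0 / 12.0),
        ],
    )
    def test_default_presets_carry_published_rates(self, region, apr):
        by_name = {p.region: p for p in nv.DEFAULT_PRESETS}
        assert by_name[region].apr == pytest.approx(apr)

    def test_invalid_presets_rejected(self):
        with pytest.raises(ValueError):
            nv.TrajectoryPreset("x", "grey", -0.1, 1.0)
        with pytest.raises(ValueError):
            nv.TrajectoryPreset("x", "grey", 0.1, 12.0)
        with pytest.raises(ValueError):
            # trajectory would cross zero before age 22
            nv.TrajectoryPreset("x", "grey", 0.1, -9.0)
        with pytest.raises(ValueError):
            nv.TrajectoryPreset("x", "bone", 0.1, 1.0)


class TestNormativeCohort:
    def test_zero_noise_values_sit_on_preset_line(self, clean_config, clean_presets):
        table = nv.generate_normative_cohort(clean_config, clean_presets)
        corrected = nv.correct_table(table)
        for p in clean_presets:
            expected = p.line(corrected["age_years"].to_numpy())
            np.testing.assert_allclose(corrected[p.region], expected, rtol=1e-12)

    def test_determinism_byte_identical(self):
        cfg = nv.GeneratorConfig(n_subjects=120, min_bin_n=5, seed=9)
        a = nv.generate_normative_cohort(cfg)
        b = nv.generate_normative_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_ticv_scale_equivariance(self):
        base = nv.GeneratorConfig(n_subjects=90, min_bin_n=5, seed=3)
        doubled = nv.GeneratorConfig(
            n_subjects=90, min_bin_n=5, seed=3, ticv_base_mm3=2 * base.ticv_base_mm3
        )
        ta, tb = nv.generate_normative_cohort(base), nv.generate_normative_cohort(doubled)
        regions = nv.region_columns(ta)
        for r in regions:
            np.testing.assert_allclose(
                tb[r + "_mm3"], 2.0 * ta[r + "_mm3"], rtol=1e-12
            )
        pd.testing.assert_frame_equal(
            nv.correct_table(ta)[regions], nv.correct_table(tb)[regions]
        )

    def test_every_age_bin_meets_minimum(self, default_cohort):
        counts = pd.Series(
            nv.age_bin(default_cohort["table"]["age_years"])
        ).value_counts()
        assert sorted(counts.index) == list(range(8, 23))
        assert (counts >= 45).all()

    def test_underfilled_bin_error_names_bin(self):
        with pytest.raises(ValueError, match=r"age bin.*min_bin_n"):
            nv.generate_normative_cohort(nv.GeneratorConfig(n_subjects=100, seed=0))

    def test_monte_carlo_means_match_generative_formula(self):
        # oracle: E[v | age] = line(age) * mean(offsets) * exp(noise_sd^2/2)
        cfg = nv.GeneratorConfig(
            n_subjects=5000, outlier_fraction=0.0, min_bin_n=5, seed=11
        )
        presets = nv.default_presets(noise_sd=0.05)
        table = nv.generate_normative_cohort(cfg, presets)
        corrected = nv.correct_table(table)
        bins = nv.age_bin(corrected["age_years"])
        mean_offset = np.mean(cfg.site_offsets)
        for p in presets:
            bias = np.exp(p.noise_sd**2 / 2)
            for b in (8, 14, 21):
                sel = bins == b
                v = corrected.loc[sel, p.region].to_numpy()
                oracle = (
                    p.line(corrected.loc[sel, "age_years"].to_numpy()).mean()
                    * mean_offset
                    * bias
                )
                mc_se = v.std(ddof=1) / np.sqrt(sel.sum())
                assert abs(v.mean() - oracle) < 3 * mc_se


class TestPatientCohort:
    def test_null_deficit_matches_healthy_generative_values(self):
        cfg = nv.GeneratorConfig(seed=21)
        zero = [nv.DeficitSpec(deficits={"amygdala": 0.0}, age=13.0)] * 4
        none = [nv.DeficitSpec(deficits={}, age=13.0)] * 4
        ta, truth_a = nv.generate_patient_cohort(cfg, None, zero)
        tb, truth_b = nv.generate_patient_cohort(cfg, None, none)
        pd.testing.assert_frame_equal(ta, tb)
        assert truth_a.empty and truth_b.empty

    def test_injected_deficit_shifts_by_sd_units_exactly(self):
        cfg = nv.GeneratorConfig(seed=33)
        preset = {p.region: p for p in nv.DEFAULT_PRESETS}["genu_corpus_callosum"]
        healthy, _ = nv.generate_patient_cohort(
            cfg, None, [nv.DeficitSpec(deficits={}, age=13.0)]
        )
        hurt, truth = nv.generate_patient_cohort(
            cfg, None, [nv.DeficitSpec(deficits={"genu_corpus_callosum": 5.0}, age=13.0)]
        )
        _, sigma = nv.corrected_moments(preset, cfg, 13.0)
        shift = (
            healthy["genu_corpus_callosum_mm3"][0] - hurt["genu_corpus_callosum_mm3"][0]
        ) / (sigma * healthy["ticv_mm3"][0])
        assert shift == pytest.approx(5.0, rel=1e-9)
        assert len(truth) == 1 and truth.loc[0, "deficit_sd"] == 5.0

    def test_ground_truth_bookkeeping_matches_requested_set(self):
        specs = [
            nv.DeficitSpec(deficits={"amygdala": 2.0, "global_grey": 1.0}, age=10.0),
            nv.DeficitSpec(deficits={}, age=15.0),
            nv.DeficitSpec(deficits={"corticospinal_tract": 3.0}, age=18.0),
        ]
        _, truth = nv.generate_patient_cohort(nv.GeneratorConfig(seed=2), None, specs)
        got = set(zip(truth["subject_id"], truth["region"]))
        assert got == {
            ("tbi0000", "amygdala"),
            ("tbi0000", "global_grey"),
            ("tbi0002", "corticospinal_tract"),
        }

    def test_unknown_region_and_negative_volume_errors(self):
        cfg = nv.GeneratorConfig(seed=1)
        with pytest.raises(KeyError, match="absent from presets"):
            nv.generate_patient_cohort(
                cfg, None, [nv.DeficitSpec(deficits={"nope": 1.0})]
            )
        with pytest.raises(ValueError, match="negative"):
            nv.generate_patient_cohort(
                cfg, None, [nv.DeficitSpec(deficits={"amygdala": 500.0}, age=12.0)]
            )


class TestPhantomGeneration:
    def test_round_trip_reproduces_tabular_volumes(self, toy_subject):
        layout = nv.cuboid_layout(["roi_a", "roi_b", "roi_c"], (16, 16, 16))
        ph = nv.generate_phantom(toy_subject, layout)
        for rv in nv.extract_roi_volumes(ph):
            assert rv.volume_mm3 == pytest.approx(
                float(toy_subject[rv.region + "_mm3"]), rel=1e-3
            )

    def test_full_occlusion_extracts_zero(self, toy_subject):
        layout = nv.cuboid_layout(["roi_a", "roi_b"], (8, 8, 8))
        ph = nv.generate_phantom(toy_subject[:-1], layout)
        lesion = layout["roi_a"].astype(np.uint8)  # covers roi_a exactly
        vols = {v.region: v for v in nv.extract_roi_volumes(ph.with_lesion(lesion))}
        assert vols["roi_a"].volume_mm3 == 0.0
        assert vols["roi_a"].masked_fraction == 1.0
        assert vols["roi_b"].masked_fraction == 0.0

    def test_half_coverage_halves_homogeneous_roi(self, toy_subject):
        # voxel-count oracle: uniform density, half the voxels masked
        layout = nv.cuboid_layout(["roi_a"], (8, 8, 8))
        ph = nv.generate_phantom(toy_subject[["roi_a_mm3"]], layout)
        lesion = np.zeros((8, 8, 8), dtype=np.uint8)
        lesion[:4] = 1  # half of every z-slab
        rv = nv.extract_roi_volumes(ph.with_lesion(lesion))[0]
        assert rv.masked_fraction == pytest.approx(0.5)
        assert rv.volume_mm3 == pytest.approx(0.5 * 1200.0, rel=1e-12)

    def test_overlapping_or_empty_layout_rejected(self, toy_subject):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            nv.generate_phantom(toy_subject, {"roi_a": mask, "roi_b": mask})
        with pytest.raises(ValueError, match="zero voxels"):
            nv.generate_phantom(
                toy_subject, {"roi_a": np.zeros((4, 4, 4), dtype=bool)}
            )

    def test_nifti_round_trip(self, toy_subject, tmp_path):
        layout = nv.cuboid_layout(["roi_a", "roi_b"], (8, 8, 8))
        ph = nv.generate_phantom(
            toy_subject[:-1], layout, lesion=nv.LesionSpec((4, 4, 4), 2.0),
            tissue_classes={"roi_a": "grey", "roi_b": "white"},
        )
        ph.save(tmp_path / "ph")
        back = nv.Phantom.load(tmp_path / "ph")
        np.testing.assert_allclose(back.tissue, ph.tissue, rtol=1e-6)
        np.testing.assert_array_equal(back.parcellation, ph.parcellation)
        np.testing.assert_array_equal(back.lesion, ph.lesion)
        assert back.labels == ph.labels


class TestCognitiveBattery:
    def test_block_correlations_exceed_between_block(self):
        model = nv.FactorModel(
            blocks={f"f{k}": [f"m{k}_{i}" for i in range(3)] for k in range(5)},
            loading=0.85,
        )
        t = nv.generate_cognitive_battery({"control": 2000}, model, seed=4)
        corr = t[model.measures].corr().to_numpy()
        within, between = [], []
        names = model.measures
        block_of = {m: f for f, ms in model.blocks.items() for m in ms}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                (within if block_of[names[i]] == block_of[names[j]] else between).append(
                    corr[i, j]
                )
        assert min(within) > max(between)

    def test_group_shift_scales_with_loading(self):
        model = nv.FactorModel(blocks={"f1": ["m1", "m2"]}, loading=0.8)
        t = nv.generate_cognitive_battery(
            {"control": 4000, "tbi_low": 4000},
            model,
            group_effects={"tbi_low": {"f1": -1.0}},
            seed=8,
            scale="z",
        )
        diff = (
            t.loc[t["group"] == "control", "m1"].mean()
            - t.loc[t["group"] == "tbi_low", "m1"].mean()
        )
        # linear-model expectation: shift on the measure = loading * 1 SD
        assert diff == pytest.approx(0.8, abs=0.06)

    def test_zero_loading_gives_independent_noise(self):
        model = nv.FactorModel(blocks={"f1": ["m1", "m2"]}, loading=0.0)
        t = nv.generate_cognitive_battery({"control": 3000}, model, seed=6)
        assert abs(t["m1"].corr(t["m2"])) < 0.05

    def test_more_factors_than_measures_rejected(self):
        with pytest.raises(ValueError, match="more factors"):
            nv.FactorModel(blocks={"f1": ["m1"], "f2": [], "f3": []})

    def test_determinism(self):
        model = nv.FactorModel(blocks={"f1": ["m1"]})
        a = nv.generate_cognitive_battery({"control": 50}, model, seed=3)
        b = nv.generate_cognitive_battery({"control": 50}, model, seed=3)
        pd.testing.assert_frame_equal(a, b)
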