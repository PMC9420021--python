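"""Z-scoring, BH FDR, low/normal labelling and lesion-matched norms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import normvol as nv


def bh_brute_force(p):
    """Literal BH definition: q_(i) = min over j >= i of m*p_(j)/(j+1)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(m * ps[j] / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def toy_norms(regions=("a", "b"), mean=1.0, sd=0.1, ages=range(8, 23), n=50):
    rows = [
        {"region": r, "age": a, "mean": mean, "sd": sd, "n": n}
        for r in regions
        for a in ages
    ]
    stats = pd.DataFrame(rows).set_index(["region", "age"]).sort_index()
    stats["usable"] = stats["n"] >= 45
    return nv.AgeNorms(stats=stats, min_bin_n=45)


class TestZscore:
    def test_trivial_deviations(self):
        norms = toy_norms()
        z, excluded = nv.zscore_subject({"a": 1.0, "b": 0.8}, norms, 12.3)
        assert z["a"] == pytest.approx(0.0)
        assert z["b"] == pytest.approx(-2.0)
        assert excluded == []

    def test_regions_missing_from_norms_excluded(self):
        z, excluded = nv.zscore_subject({"a": 1.0, "zz": 5.0}, toy_norms(), 12.0)
        assert excluded == ["zz"]
        assert list(z.index) == ["a"]

    def test_unusable_bin_error_names_nearest(self):
        norms = toy_norms()
        norms.stats.loc[("a", 12), "usable"] = False
        with pytest.raises(ValueError, match="nearest usable bin is 11"):
            nv.zscore_subject({"a": 1.0}, norms, 12.5)
        z, _ = nv.zscore_subject({"a": 1.0}, norms, 12.5, allow_nearest_bin=True)
        assert z["a"] == pytest.approx(0.0)

    def test_synthetic_five_sd_deficit_recovers_z_near_minus_five(
        self, default_cohort
    ):
        norms = default_cohort["norms"]
        cfg = nv.GeneratorConfig(seed=77)
        specs = [
            nv.DeficitSpec(deficits={"genu_corpus_callosum": 5.0}, age=13.5)
            for _ in range(40)
        ]
        patients, _ = nv.generate_patient_cohort(cfg, None, specs)
        corrected = nv.correct_table(patients)
        zs = []
        for _, row in corrected.iterrows():
            z, _ = nv.zscore_subject(
                row[nv.region_columns(patients)], norms, row["age_years"]
            )
            zs.append(z["genu_corpus_callosum"])
        assert np.mean(zs) == pytest.approx(-5.0, abs=0.6)


class TestPvalues:
    @pytest.mark.parametrize(
        "z,p", [(0.0, 0.5), (-2.0, 0.02275), (3.0, 0.99865)]
    )
    def test_lower_tail_values(self, z, p):
        assert nv.z_to_p(z) == pytest.approx(p, abs=5e-6)

    def test_two_sided_option(self):
        assert nv.z_to_p(-2.0, side="two") == pytest.approx(0.0455, abs=1e-4)
        assert nv.z_to_p(2.0, side="two") == nv.z_to_p(-2.0, side="two")

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            nv.z_to_p(np.inf)


class TestFdr:
    def test_single_test_unchanged(self):
        assert nv.fdr_adjust([0.031])[0] == pytest.approx(0.031)

    def test_textbook_vector_all_point_05(self):
        q = nv.fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, 0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nv.fdr_adjust([])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        p=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=12
        )
    )
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(
            nv.fdr_adjust(p), bh_brute_force(p), rtol=1e-12, atol=1e-12
        )

    def test_monotone_in_rank_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=12)
        q = nv.fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()


class TestClassification:
    def test_all_zero_z_is_normal(self):
        res = nv.classify_regions(pd.Series({"a": 0.0, "b": 0.0}))
        assert res.label == "normal volume"
        assert res.flagged_regions == []

    def test_strong_deficit_flagged_low(self):
        res = nv.classify_regions(pd.Series({"a": -6.0, "b": 0.5}))
        assert res.label == "low volume"
        assert res.flagged_regions == ["a"]
        t = res.table.set_index("region")
        assert (t["q"] >= t["p"] - 1e-15).all()

    def test_high_volume_never_flagged_low(self):
        res = nv.classify_regions(pd.Series({"a": 6.0, "b": 8.0}))
        assert res.label == "normal volume"

    def test_all_regions_excluded_is_untestable(self):
        res = nv.classify_regions(pd.Series(dtype=float), excluded=["a", "b"])
        assert res.label == "untestable"
        assert (res.table["excluded_reason"] != "").all()

    def test_separate_families_adjust_independently(self):
        z = pd.Series({"g1": -2.5, "g2": 0.0, "w1": -2.5, "w2": 0.0})
        joint = nv.classify_regions(z)
        split = nv.classify_regions(
            z, families={"grey": ["g1", "g2"], "white": ["w1", "w2"]}
        )
        jq = joint.table.set_index("region")["q"]
        sq = split.table.set_index("region")["q"]
        # within-family correction over 2 tests is never harsher than over 4
        assert sq["g1"] <= jq["g1"] + 1e-15

    def test_flags_monotone_in_deficit_size(self):
        base = pd.Series({"a": -2.2, "b": -1.0, "c": 0.3})
        small = nv.classify_regions(base)
        bigger = nv.classify_regions(base + pd.Series({"a": -2.0, "b": -2.0, "c": 0.0}))
        assert set(small.flagged_regions) <= set(bigger.flagged_regions)


class TestLesionMatchedNorms:
    @staticmethod
    def controls(n=45, noise_sd=0.0, seed=3):
        cfg = nv.GeneratorConfig(
            n_subjects=n,
            age_range=(12, 14),
            n_sites=1,
            site_offsets=(1.0,),
            outlier_fraction=0.0,
            min_bin_n=1,
            seed=seed,
        )
        presets = nv.default_presets(noise_sd)
        table = nv.generate_normative_cohort(cfg, presets)
        regions = nv.region_columns(table)
        layout = nv.cuboid_layout(regions, (16, 16, 32))
        phantoms = [
            nv.generate_phantom(row, layout) for _, row in table.iterrows()
        ]
        return table, phantoms, layout

    def test_empty_lesion_reproduces_standard_norms(self):
        table, phantoms, _ = self.controls()
        lesion = np.zeros((16, 16, 32), dtype=np.uint8)
        norms, untestable = nv.lesion_matched_norms(
            lesion, phantoms, table, min_bin_n=1
        )
        standard = nv.build_age_norms(
            nv.cap_outliers(nv.correct_table(table))[0], min_bin_n=1
        )
        assert untestable == []
        # identical up to the phantom's volume->density->volume float round trip
        np.testing.assert_allclose(
            norms.stats["mean"], standard.stats["mean"], rtol=1e-12
        )
        np.testing.assert_allclose(norms.stats["sd"], standard.stats["sd"],
                                   rtol=1e-9, atol=1e-18)

    def test_fully_occluded_region_untestable(self):
        table, phantoms, layout = self.controls()
        region = nv.region_columns(table)[0]
        lesion = layout[region].astype(np.uint8)
        _, untestable = nv.lesion_matched_norms(lesion, phantoms, table, min_bin_n=1)
        assert untestable == [region]

    def test_partial_lesion_scales_zero_noise_means(self):
        # voxel arithmetic: uniform-density ROI loses exactly the masked
        # density fraction, so the norm mean scales by (1 - fraction)
        table, phantoms, layout = self.controls()
        region = nv.region_columns(table)[0]
        lesion = layout[region].copy()
        lesion[8:, :, :] = False  # half the ROI
        lesion = lesion.astype(np.uint8)
        norms, untestable = nv.lesion_matched_norms(
            lesion, phantoms, table, min_bin_n=1
        )
        standard = nv.build_age_norms(
            nv.cap_outliers(nv.correct_table(table))[0], min_bin_n=1
        )
        assert region not in untestable
        for a in (12, 13, 14):
            assert norms.get(region, a)["mean"] == pytest.approx(
                0.5 * standard.get(region, a)["mean"], rel=1e-12
            )

    def test_geometry_mismatch_rejected(self):
        table, phantoms, _ = self.controls(n=4)
        with pytest.raises(ValueError, match="does not match"):
            nv.lesion_matched_norms(
                np.zeros((8, 8, 8), dtype=np.uint8), phantoms, table, min_bin_n=1
            )

    def test_lesion_matched_comparison_is_neutral_naive_is_biased(self):
        # a lesioned patient whose intact tissue is healthy should look
        # normal under lesion-matched norms but low under naive norms
        table, phantoms, layout = self.controls(n=45, noise_sd=0.02, seed=9)
        region = nv.region_columns(table)[0]
        lesion = layout[region].copy()
        lesion[8:, :, :] = False
        lesion = lesion.astype(np.uint8)
        matched, _ = nv.lesion_matched_norms(lesion, phantoms, table, min_bin_n=1)
        naive = nv.build_age_norms(
            nv.cap_outliers(nv.correct_table(table))[0], min_bin_n=1
        )
        # the patient: a healthy control seen through the same lesion
        pt_table, pt_phantoms, _ = self.controls(n=6, noise_sd=0.02, seed=31)
        z_matched, z_naive = [], []
        for (_, meta), ph in zip(pt_table.iterrows(), pt_phantoms):
            vol = {
                v.region: v.volume_mm3
                for v in nv.extract_roi_volumes(ph.with_lesion(lesion), [region])
            }
            corrected = vol[region] / meta["ticv_mm3"]
            z_matched.append(
                nv.zscore_subject({region: corrected}, matched, meta["age_years"])[0][region]
            )
            z_naive.append(
                nv.zscore_subject({region: corrected}, naive, meta["age_years"])[0][region]
            )
        assert np.mean(np.abs(z_matched)) < 3.0
        assert np.mean(z_naive) < -5.0
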