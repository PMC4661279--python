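"""Split-half confirmation machinery: matching, peaks, spheres, held-out tests."""

import numpy as np
import pytest

import ambicon as ac
from ambicon.roi import ROIError, _roi_pes, confirm_roi, subject_designs


class TestSplitMatched:
    def test_default_cohort_splits_16_16_with_equal_sexes(self, cohort):
        split = ac.split_matched(cohort, seed=0)
        assert len(split.group1) == len(split.group2) == 16
        for grp in (split.group1, split.group2):
            assert sum(cohort[i].params.sex == "M" for i in grp) == 8
        assert not set(split.group1) & set(split.group2)

    def test_same_seed_identical(self, cohort):
        assert ac.split_matched(cohort, seed=5) == ac.split_matched(cohort, seed=5)

    def test_groups_matched_on_standardized_variables(self):
        """Over replicate cohorts, group means of each matching variable differ
        by well under half a pooled SD."""
        import math

        diffs = {k: [] for k in ("age", "ln_gamma_a", "gamma_c")}
        for rep in range(20):
            cohort = ac.sample_population(ac.PopulationSpec(seed=100 + rep))
            split = ac.split_matched(cohort, seed=rep)
            for key, get in (
                ("age", lambda s: s.params.age),
                ("ln_gamma_a", lambda s: math.log(s.params.gamma_a)),
                ("gamma_c", lambda s: s.params.gamma_c),
            ):
                a = np.array([get(cohort[i]) for i in split.group1])
                b = np.array([get(cohort[i]) for i in split.group2])
                pooled_sd = np.concatenate([a, b]).std(ddof=1)
                diffs[key].append(abs(a.mean() - b.mean()) / pooled_sd)
        for key, vals in diffs.items():
            assert np.mean(vals) < 0.35, key   # typical imbalance well matched
            assert max(vals) < 1.0, key        # no grossly unbalanced split

    def test_single_sex_falls_back_to_random_split(self):
        cohort = ac.sample_population(ac.PopulationSpec(male_fraction=1 / 32, seed=0))
        split = ac.split_matched(cohort, seed=0)
        assert not split.paired
        assert abs(len(split.group1) - len(split.group2)) <= 1

    def test_too_small_cohort_rejected(self, cohort):
        with pytest.raises(ROIError):
            ac.split_matched(cohort[:3])


class TestSphereMask:
    def test_radius_zero_is_single_voxel(self):
        m = ac.sphere_mask((4, 4, 4), 0, (9, 9, 9))
        assert m.sum() == 1 and m[4, 4, 4]

    def test_radius_two_has_33_lattice_points(self):
        assert ac.sphere_mask((10, 10, 10), 2, (21, 21, 21)).sum() == 33

    @pytest.mark.parametrize("radius", [1, 3, 5, 10])
    def test_matches_lattice_enumeration_oracle(self, radius):
        dims = (25, 25, 25)
        center = (12, 12, 12)
        count = sum(
            (x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2 <= radius**2
            for x in range(25) for y in range(25) for z in range(25)
        )
        assert ac.sphere_mask(center, radius, dims).sum() == count

    def test_clipped_at_boundary(self):
        m = ac.sphere_mask((0, 0, 0), 2, (8, 8, 8))
        assert m.sum() < 33

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ROIError):
            ac.sphere_mask((9, 0, 0), 2, (8, 8, 8))


class TestFindCandidates:
    def test_single_blob_peak_at_center(self):
        stat = np.zeros((12, 12, 12))
        stat[5, 6, 7] = -8.0
        stat[5, 6, 6] = -6.0
        peaks = ac.find_candidate_rois(stat, threshold=3.0)
        assert peaks == [((5, 6, 7), -8.0)]

    def test_empty_map_gives_empty_list(self):
        assert ac.find_candidate_rois(np.zeros((6, 6, 6)), threshold=2.0) == []

    def test_nearby_peaks_pruned_to_strongest(self):
        stat = np.zeros((12, 12, 12))
        stat[3, 3, 3] = 5.0
        stat[4, 4, 4] = 7.0
        peaks = ac.find_candidate_rois(stat, threshold=3.0, min_separation=4.0)
        assert peaks == [((4, 4, 4), 7.0)]

    def test_distant_peaks_both_kept_ordered_by_strength(self):
        stat = np.zeros((12, 12, 12))
        stat[1, 1, 1] = 4.0
        stat[9, 9, 9] = -6.0
        peaks = ac.find_candidate_rois(stat, threshold=3.0)
        assert [p[0] for p in peaks] == [(9, 9, 9), (1, 1, 1)]


@pytest.fixture(scope="module")
def planted_dataset(cohort, session2):
    """Small dataset with one strongly planted negative A-level region."""
    pl = ac.PlantedEffects(
        regions=(ac.PlantedRegion("vmPFC", (3, 3, 3), 2.0, "A_level", -0.015),)
    )
    subs = cohort[:12]
    sessions = {s.params.subject_id: session2 for s in subs}
    return ac.simulate_bold(subs, sessions, {}, pl, grid=(10, 10, 10), seed=1)


class TestConfirmROI:
    def test_planted_effect_confirmed_in_held_out_half(self, planted_dataset):
        atts = ac.subject_attitudes(planted_dataset, "true")
        mask = ac.sphere_mask((3, 3, 3), 3, planted_dataset.grid)
        stat, p, ok, cross, pooled, n = confirm_roi(
            planted_dataset, mask, list(range(6, 12)), "A_level", -1, atts,
        )
        assert ok and stat < 0 and pooled < 0
        assert "C_level" in cross and cross["C_level"][1] > 0.05

    def test_empty_mask_rejected(self, planted_dataset):
        atts = ac.subject_attitudes(planted_dataset, "true")
        with pytest.raises(ROIError):
            confirm_roi(
                planted_dataset, np.zeros(planted_dataset.grid, bool),
                [6, 7, 8], "A_level", -1, atts,
            )

    def test_roi_average_fit_matches_region_amplitude(self, planted_dataset):
        mask = ac.sphere_mask((3, 3, 3), 2, planted_dataset.grid)
        pes = _roi_pes(planted_dataset, mask, list(range(12)))
        assert pes.loc["A_level"].mean() == pytest.approx(-0.015, abs=0.002)


class TestPipeline:
    def test_disjoint_groups_and_confirmed_planted_region(self, planted_dataset):
        res = ac.run_confirmation_pipeline(
            planted_dataset, ac.PipelineConfig(attitudes="true", seed=0)
        )
        assert not set(res.split.group1) & set(res.split.group2)
        tab = res.table()
        hits = tab[
            (tab.kind == "level") & (tab.target == "A_level") & tab.confirmed
        ]
        assert len(hits) >= 1
        best = hits.iloc[0]
        assert np.linalg.norm(np.array([best.x, best.y, best.z]) - 3) <= 2.0
        assert best.confirm_stat < 0

    def test_overfit_candidates_rejected_out_of_sample(self, cohort, session2):
        """An effect present only in the exploratory subjects' data does not
        survive held-out confirmation above chance."""
        pl_eff = ac.PlantedEffects(
            regions=(ac.PlantedRegion("fake", (6, 6, 6), 2.0, "A_level", -0.02),)
        )
        pl_null = ac.PlantedEffects(regions=())
        subs = cohort[:12]
        g1, g2 = subs[:6], subs[6:]
        sess = {s.params.subject_id: session2 for s in subs}
        ds_eff = ac.simulate_bold(g1, {k: sess[k] for k in list(sess)[:6]}, {},
                                  pl_eff, grid=(10, 10, 10), seed=3)
        ds_null = ac.simulate_bold(g2, {k: sess[k] for k in list(sess)[6:]}, {},
                                   pl_null, grid=(10, 10, 10), seed=4)
        # merge: exploratory half carries the effect, held-out half pure noise
        merged = ac.VoxelDataset(
            ds_eff.grid, ds_eff.tr,
            {**ds_eff.data, **ds_null.data},
            {**ds_eff.sessions, **ds_null.sessions},
            {}, list(g1) + list(g2), pl_eff, ds_eff.ground_truth,
        )
        maps = ac.first_level_pe_maps(merged, ("A_level",))
        from scipy import stats as sps

        t1, _ = sps.ttest_1samp(maps["A_level"][:6], 0.0, axis=0)
        peaks = ac.find_candidate_rois(t1, sps.t.isf(0.0025, 5), 4.0)
        assert peaks, "planted exploratory effect should surface"
        atts = ac.subject_attitudes(merged, "true")
        designs = subject_designs(merged)
        confirmed = 0
        for center, stat in peaks[:6]:
            mask = ac.sphere_mask(center, 3, merged.grid)
            _, p, ok, *_ = confirm_roi(
                merged, mask, list(range(6, 12)), "A_level",
                1 if stat >= 0 else -1, atts, designs=designs,
            )
            confirmed += ok
        assert confirmed <= 1
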