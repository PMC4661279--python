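"""GLM machinery: HRF, design construction, PSC, voxel fits, group maps."""

import numpy as np
import pytest
from scipy import stats

import ambicon as ac
from ambicon.glm import GLMError, TASK_REGRESSORS, _convolve_events


class TestHRF:
    def test_zero_at_origin_and_peak_at_5s(self):
        t = np.arange(0, 32, 0.01)
        h = ac.double_gamma_hrf(t)
        assert h[0] == 0.0
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.02)
        assert h.max() == pytest.approx(1.0)

    def test_undershoot_trough_near_15s(self):
        t = np.arange(0, 32, 0.01)
        h = ac.double_gamma_hrf(t)
        trough = t[np.argmin(h)]
        assert 14.0 < trough < 17.0
        assert h.min() < 0

    def test_invalid_parameters_rejected(self):
        t = np.arange(0, 32, 0.1)
        with pytest.raises(GLMError):
            ac.double_gamma_hrf(t, peak_shape=-1)
        with pytest.raises(GLMError):
            ac.double_gamma_hrf(np.array([3.0, 2.0, 1.0]))


@pytest.fixture(scope="module")
def choices2(cohort, session2):
    return ac.simulate_choices(cohort[0], session2, seed=0)


@pytest.fixture(scope="module")
def design2(session2, choices2):
    return ac.build_design_matrix(session2, choices2)


class TestDesignMatrix:
    def test_nine_task_regressors_plus_run_intercepts(self, design2):
        task = [c for c in design2.names if not c.startswith("const")]
        assert task == list(TASK_REGRESSORS)
        assert len(task) == 9
        assert sum(c.startswith("const") for c in design2.names) == 2

    def test_parametric_columns_center_within_runs(self, design2):
        for name in ("A_level", "C_level", "RT"):
            col = design2.frame[name].to_numpy()
            for sl in design2.run_slices:
                seg = col[sl]
                assert abs(seg.sum()) < 1e-8 * max(1.0, np.abs(seg).sum())

    def test_dummy_columns_are_boxcar_responses(self, design2):
        """Condition dummies are convolved 0/1 boxcars: dominated by the
        positive response, with any dip bounded by the undershoot ratio."""
        for name in ("R", "A", "C", "I"):
            col = design2.frame[name]
            assert col.max() > 0
            assert col.min() >= -0.25 * col.max()

    def test_full_rank(self, design2):
        assert not design2.rank_deficient

    def test_convolution_matches_brute_force_oracle(self):
        """A toy 2-trial boxcar convolved by direct summation."""
        dt = 0.1
        n_vols, tr = 40, 2.5
        onsets, durs, amps = [5.0, 30.0], [6.5, 6.5], [1.0, -2.0]
        got = _convolve_events(onsets, durs, amps, n_vols, tr, None, dt)
        t_fine = np.arange(0, n_vols * tr + dt / 2, dt)
        box = np.zeros_like(t_fine)
        for on, du, am in zip(onsets, durs, amps):
            box[(t_fine >= on) & (t_fine < on + du)] += am
        h = ac.double_gamma_hrf(np.arange(0, 32.0 + dt, dt))
        ref = np.array([
            sum(box[j] * h[i - j] for j in range(max(0, i - len(h) + 1), i + 1)) * dt
            for i in np.round(np.arange(n_vols) * tr / dt).astype(int)
        ])
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_misaligned_choices_rejected(self, session2, choices2):
        with pytest.raises(GLMError):
            ac.build_design_matrix(session2, choices2[:-3])


class TestSVDesignMatrix:
    def test_eight_regressors_plus_intercepts(self, session2, choices2, cohort):
        dm = ac.build_sv_design_matrix(session2, choices2, cohort[0].params)
        task = [c for c in dm.names if not c.startswith("const")]
        assert len(task) == 8
        assert {"R_sv", "A_sv", "C_sv", "I_sv"} <= set(task)

    def test_all_sure_subject_gives_zero_sv_columns(self, session2):
        recs = [ac.ChoiceRecord(t.gamble, "sure", 2.0, t.run, t.index_in_run)
                for t in session2.gamble_trials()]
        dm = ac.build_sv_design_matrix(session2, recs, ac.SubjectParameters())
        for name in ("R_sv", "A_sv", "C_sv", "I_sv"):
            assert np.allclose(dm.frame[name], 0.0)
        assert dm.rank_deficient

    def test_sv_amplitudes_match_subjective_value(self, session2, choices2, cohort):
        """The SV column equals the convolution of the per-trial subjective
        values (centered per run), reconstructed independently."""
        params = cohort[0].params
        dm = ac.build_sv_design_matrix(session2, choices2, params)
        gamble_trials = session2.gamble_trials()
        run = 0
        run_trials = [t for t in session2.run_trials(run) if t.trial_type == "ambiguity"]
        sv = np.array([
            ac.subjective_value(t.gamble, choices2[gamble_trials.index(t)].choice, params)
            for t in run_trials
        ])
        ref = _convolve_events(
            [t.onset for t in run_trials], [t.duration for t in run_trials],
            sv - sv.mean(), session2.volumes_per_run, session2.tr, None, 0.1,
        )
        ref -= ref.mean()      # per-run demeaning, as in the built column
        np.testing.assert_allclose(
            dm.frame["A_sv"].to_numpy()[dm.run_slices[run]], ref, atol=1e-10
        )


class TestHighpass:
    def test_removes_constant_and_slow_drift(self):
        t = np.linspace(0, 1, 120)
        slow = 5.0 + 2.0 * t + np.cos(2 * np.pi * 1.5 * t)   # < 3 cycles/run
        out = ac.highpass_filter(slow)
        assert np.abs(out).max() < 0.15 * np.abs(slow - slow.mean()).max()

    def test_preserves_fast_oscillation(self):
        t = np.linspace(0, 1, 120)
        fast = np.sin(2 * np.pi * 12 * t)                     # 12 cycles/run
        out = ac.highpass_filter(fast)
        assert np.corrcoef(out, fast)[0, 1] > 0.99


class TestPSC:
    def test_constant_series_is_zero(self):
        assert np.allclose(ac.to_percent_signal_change(np.full(10, 42.0)), 0.0)

    def test_hand_example(self):
        np.testing.assert_allclose(
            ac.to_percent_signal_change(np.array([90.0, 110.0])), [-10.0, 10.0]
        )

    def test_scale_invariance(self):
        y = np.random.default_rng(0).uniform(50, 150, 64)
        np.testing.assert_allclose(
            ac.to_percent_signal_change(y), ac.to_percent_signal_change(7 * y)
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(GLMError):
            ac.to_percent_signal_change(np.array([-1.0, -2.0]))


class TestFitGLM:
    def test_noiseless_recovery(self, design2):
        x = design2.values
        beta = np.linspace(-1, 1, x.shape[1])
        res = ac.fit_glm(x @ beta, design2)
        np.testing.assert_allclose(np.asarray(res.pe), beta, atol=1e-8)

    def test_matches_normal_equations_oracle(self, design2):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((5, design2.values.shape[0]))
        res = ac.fit_glm(y, design2)
        x = design2.values
        ref = np.linalg.solve(x.T @ x, x.T @ y.T).T
        np.testing.assert_allclose(res.pe.to_numpy().T, ref, atol=1e-8)

    def test_ar1_prewhitening_unbiased(self, design2):
        rng = np.random.default_rng(2)
        x = design2.values
        beta = np.zeros(x.shape[1])
        beta[design2.names.index("A_level")] = 0.01
        n_vox, T = 400, x.shape[0]
        eps = rng.standard_normal((n_vox, T))
        noise = np.empty_like(eps)
        noise[:, 0] = eps[:, 0]
        for t in range(1, T):
            noise[:, t] = 0.4 * noise[:, t - 1] + eps[:, t]
        res = ac.fit_glm(x @ beta + 0.3 * noise, design2, ar1=True)
        est = res.pe.loc["A_level"].to_numpy()
        assert abs(est.mean() - 0.01) < 3 * est.std() / np.sqrt(n_vox)
        assert res.ar1 > 0.2

    def test_rank_deficient_rejected(self, session2, design2):
        import pandas as pd

        bad = ac.DesignMatrix(
            pd.concat([design2.frame, design2.frame.iloc[:, :1].rename(
                columns={design2.names[0]: "dup"})], axis=1),
            design2.tr, design2.run_slices,
        )
        with pytest.raises(GLMError):
            ac.fit_glm(np.zeros(design2.values.shape[0]), bad)


class TestGroupMaps:
    def test_sign_flip_antisymmetry(self):
        pes = np.random.default_rng(0).standard_normal((8, 5, 5))
        t1, _ = ac.group_ttest_map(pes)
        t2, _ = ac.group_ttest_map(-pes)
        np.testing.assert_allclose(t1, -t2)

    def test_null_calibration(self):
        pes = np.random.default_rng(1).standard_normal((12, 4000))
        _, p = ac.group_ttest_map(pes)
        assert 0.035 < (p < 0.05).mean() < 0.065

    def test_brain_behavior_detects_planted_coupling(self):
        rng = np.random.default_rng(3)
        att = rng.standard_normal(32)
        pes = np.outer(att, np.ones(50)) + 0.3 * rng.standard_normal((32, 50))
        r, p = ac.brain_behavior_map(pes, att)
        assert (r > 0.8).all() and (p < 1e-6).all()

    def test_brain_behavior_permutation_control(self):
        rng = np.random.default_rng(4)
        att = rng.standard_normal(32)
        pes = np.outer(att, np.ones(200)) + 0.3 * rng.standard_normal((32, 200))
        perm = rng.permutation(att)
        r, p = ac.brain_behavior_map(pes, perm)
        assert (p < 0.05).mean() < 0.2   # coupling destroyed by permutation

    def test_brain_behavior_rejects_constant_attitudes(self):
        with pytest.raises(GLMError):
            ac.brain_behavior_map(np.random.rand(8, 10), np.ones(8))

    def test_contrast_map_antisymmetric_and_zero_on_equal(self):
        pes = np.random.default_rng(5).standard_normal((8, 20))
        t, _ = ac.contrast_map(pes, pes.copy())
        assert np.allclose(np.nan_to_num(t), 0.0)
        t_ab, _ = ac.contrast_map(pes, pes + 1.0)
        t_ba, _ = ac.contrast_map(pes + 1.0, pes)
        np.testing.assert_allclose(t_ab, -t_ba)

    def test_conjunction_identical_and_opposite(self):
        t = np.array([3.0, -3.0, 0.5])
        p = np.array([0.01, 0.01, 0.6])
        same = ac.conjunction_map(t, p, t, p, alpha=0.05)
        np.testing.assert_array_equal(same, [True, True, False])
        opposite = ac.conjunction_map(t, p, -t, p, alpha=0.05)
        assert not opposite.any()


class TestClusterThreshold:
    def test_nondecreasing_in_smoothness(self):
        k0 = ac.cluster_threshold((14, 14, 14), 0.005, 150, smooth_sigma=0.0, seed=0)
        k2 = ac.cluster_threshold((14, 14, 14), 0.005, 150, smooth_sigma=1.5, seed=0)
        assert k0 <= k2
        assert k0 <= 4   # unsmoothed suprathreshold voxels are nearly isolated

    def test_heldout_familywise_rate_controlled(self):
        shape, sigma = (12, 12, 12), 1.0
        k = ac.cluster_threshold(shape, 0.005, 300, smooth_sigma=sigma, seed=1)
        from scipy import ndimage

        rng = np.random.default_rng(99)
        zcrit = stats.norm.isf(0.0025)
        hits = 0
        n_fresh = 200
        for _ in range(n_fresh):
            z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
            z /= z.std()
            lab, nlab = ndimage.label(np.abs(z) > zcrit)
            if nlab and np.bincount(lab.ravel())[1:].max() >= k:
                hits += 1
        assert hits / n_fresh <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_fresh)

    def test_degenerate_smoothness_rejected(self):
        with pytest.raises(GLMError):
            ac.cluster_threshold((8, 8, 8), 0.005, 150, smooth_sigma=-1.0)
        with pytest.raises(GLMError):
            ac.cluster_threshold((8, 8, 8), 0.005, 50)
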