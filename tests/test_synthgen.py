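"""Generator-level oracles: planted structure must be recoverable by direct
computation, without any pipeline code."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from caudconn import pet_srtm, synthgen


class TestSubjectTable:
    def test_requires_seed_and_minimum_n(self):
        with pytest.raises(ValueError, match="seed"):
            synthgen.generate_subject_table(n=10)
        with pytest.raises(ValueError, match=">= 4"):
            synthgen.generate_subject_table(n=2, seed=1)

    def test_deterministic_for_fixed_seed(self):
        t1 = synthgen.generate_subject_table(n=40, seed=7)
        t2 = synthgen.generate_subject_table(n=40, seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_paths_decouple_age_and_binding(self):
        paths = synthgen.MediationPaths(a=0.0, b=0.0, c_prime=-0.3)
        t = synthgen.generate_subject_table(n=180, seed=3, mediation_rest=paths)
        r = np.corrcoef(t["age"], t["bp_caudate"])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(180)

    def test_planted_indirect_effect_recovered_by_ols(self):
        # independent oracle: two OLS fits on the generated table
        paths = synthgen.MediationPaths(a=-0.5, b=0.4, c_prime=-0.2)
        t = synthgen.generate_subject_table(n=2000, seed=11, mediation_rest=paths)
        xa = sm.add_constant(t[["age_z" if "age_z" in t else "age"]])
        age_z = (t["age"] - t["age"].mean()) / t["age"].std(ddof=1)
        a_hat = sm.OLS(t["bp_caudate_z"], sm.add_constant(age_z)).fit().params.iloc[1]
        xb = sm.add_constant(np.column_stack([age_z, t["bp_caudate_z"]]))
        b_hat = sm.OLS(t["d_rest_z"], xb).fit().params.iloc[2]
        assert a_hat * b_hat == pytest.approx(-0.20, abs=0.03)

    def test_age_groups_follow_bounds(self):
        t = synthgen.generate_subject_table(n=100, seed=5)
        assert (t.loc[t["age"] < 40, "age_group"] == "young").all()
        assert (t.loc[(t["age"] >= 40) & (t["age"] < 60), "age_group"] == "middle").all()
        assert (t.loc[t["age"] >= 60, "age_group"] == "old").all()
        assert t["bp_caudate"].min() >= 0
        assert t["age"].between(20, 79).all()


class TestToyAtlas:
    def test_every_network_owns_voting_pool(self, atlas):
        labels = atlas.labels
        for net in range(1, atlas.n_networks + 1):
            assert (labels == net).sum() >= 25

    def test_striatal_overlap_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            synthgen.make_toy_atlas(striatal_box=((0, 4), (0, 4), (0, 2)))

    def test_undersized_network_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            synthgen.make_toy_atlas(grid_dims=(8, 8, 8), cortical_slab=(0, 1),
                                    striatal_box=((2, 4), (2, 4), (4, 6)))

    def test_atlas_roundtrip(self, atlas, tmp_path):
        import nibabel as nib

        atlas.save(tmp_path)
        reread = nib.load(str(tmp_path / "atlas.nii"))
        assert np.array_equal(np.asarray(reread.dataobj), atlas.labels)


class TestLatentSignals:
    def test_band_limited_power(self, rng):
        sigs = synthgen.bandlimited_signals(350, 5, 2.0, rng)
        spec = np.abs(np.fft.rfft(sigs, axis=0)) ** 2
        freqs = np.fft.rfftfreq(350, d=2.0)
        inband = (freqs >= 0.009) & (freqs <= 0.09)
        share = spec[inband].sum(axis=0) / spec.sum(axis=0)
        assert (share >= 0.90).all()

    def test_exactly_orthonormal_unit_variance(self, rng):
        sigs = synthgen.bandlimited_signals(350, 5, 2.0, rng)
        gram = sigs.T @ sigs / 350
        assert np.allclose(gram, np.eye(5), atol=1e-10)


class TestRestBold:
    def test_noiseless_voxel_correlates_most_with_planted_network(
        self, atlas, noiseless_profile, noiseless_rest
    ):
        subj, run, motion, truth = noiseless_rest
        vox = noiseless_profile.voxels
        labels = atlas.labels
        for v in (0, 50, 150):
            series = run.data[vox[v, 0], vox[v, 1], vox[v, 2]]
            means = []
            for net in range(1, atlas.n_networks + 1):
                cvox = np.argwhere(labels == net)[0]
                c = run.data[cvox[0], cvox[1], cvox[2]]
                means.append(np.corrcoef(series, c)[0, 1])
            assert np.argmax(means) + 1 == truth["labels"][v]

    def test_age_slope_shifts_coupling_linearly(self, atlas):
        profile = synthgen.default_coupling_profile(atlas)
        w25 = profile.weights(25.0)
        w75 = profile.weights(75.0)
        grad = ~profile.seed_mask & (profile.age_slope[:, 0] != 0)
        unclipped = (w25[grad, 0] < 0.85) & (w75[grad, 0] > 0)
        delta = (w25[grad, 0] - w75[grad, 0])[unclipped]
        assert np.allclose(delta, 50 * 0.0022, atol=1e-12)

    def test_bit_identical_for_fixed_seed(self, atlas, profile, subjects):
        r1, m1, _ = synthgen.generate_rest_bold(subjects.iloc[1], atlas, profile, seed=9)
        r2, m2, _ = synthgen.generate_rest_bold(subjects.iloc[1], atlas, profile, seed=9)
        assert np.array_equal(r1.data, r2.data)
        pd.testing.assert_frame_equal(m1, m2)

    def test_input_validation(self, atlas, profile, subjects):
        with pytest.raises(ValueError):
            synthgen.generate_rest_bold(subjects.iloc[0], atlas, profile, tr=-1, seed=1)
        with pytest.raises(ValueError):
            synthgen.generate_rest_bold(subjects.iloc[0], atlas, profile, n_volumes=5, seed=1)
        with pytest.raises(ValueError, match="seed"):
            synthgen.generate_rest_bold(subjects.iloc[0], atlas, profile)


class TestTaskBold:
    def test_design_volume_count_and_labels(self):
        design = synthgen.TaskDesign()
        labels = design.labels()
        assert design.n_volumes == synthgen.TASK_VOLUMES == len(labels)
        for load in (1, 2, 3):
            assert (labels == f"{load}-back").sum() == 90
        assert (labels == "cue").sum() == 27

    def test_gain_ordering_in_within_block_coupling(self, atlas, subjects):
        # noiseless: higher load gain -> higher within-block seed-FPN corr.
        # Averaged over subjects because the per-load volume subsets of a
        # band-limited run carry finite-sample correlation noise.
        profile = synthgen.default_coupling_profile(atlas).noiseless()
        design = synthgen.TaskDesign()
        corrs = np.zeros(3)
        for s in range(8):
            run, labels_df, motion, truth = synthgen.generate_task_bold(
                subjects.iloc[s], atlas, profile, design, seed=77 + s
            )
            shift = truth["delay_volumes"]
            labels = labels_df["condition"].to_numpy()
            vox = profile.voxels[profile.seed_mask][0]
            seed_series = run.data[vox[0], vox[1], vox[2]]
            cvox = np.argwhere(atlas.labels == 1)[0]
            cort = run.data[cvox[0], cvox[1], cvox[2]]
            for li, load in enumerate((1, 2, 3)):
                idx = np.flatnonzero(labels == f"{load}-back") + shift
                idx = idx[idx < len(labels)]
                corrs[li] += np.corrcoef(seed_series[idx], cort[idx])[0, 1] / 8
        assert corrs[0] < corrs[1] < corrs[2]

    def test_planted_delay_beats_no_shift(self, atlas, subjects):
        profile = synthgen.default_coupling_profile(atlas).noiseless()
        design = synthgen.TaskDesign()
        run, labels_df, _, truth = synthgen.generate_task_bold(
            subjects.iloc[0], atlas, profile, design, seed=78
        )
        labels = labels_df["condition"].to_numpy()
        vox = profile.voxels[profile.seed_mask][0]
        seed_series = run.data[vox[0], vox[1], vox[2]]
        cvox = np.argwhere(atlas.labels == 1)[0]
        cort = run.data[cvox[0], cvox[1], cvox[2]]

        def mean_corr(shift):
            cs = []
            for load in (2, 3):
                idx = np.flatnonzero(labels == f"{load}-back") + shift
                idx = idx[idx < len(labels)]
                cs.append(np.corrcoef(seed_series[idx], cort[idx])[0, 1])
            return np.mean(cs)

        assert mean_corr(truth["delay_volumes"]) > mean_corr(0)


class TestTacGeneration:
    def test_identity_when_no_binding(self):
        tac = synthgen.generate_tac({"R1": 1.0, "k2": 0.15, "BP_ND": 0.0})
        assert np.allclose(tac.reference, tac.target, rtol=1e-10)

    def test_curves_start_at_zero(self):
        shape = synthgen.GammaVariate()
        assert shape(np.array([0.0]))[0] == 0.0
        ref = shape(np.linspace(0, 60, 100))
        fwd = pet_srtm.srtm_forward(1.0, 0.15, 2.0, ref * 0, np.linspace(0, 60, 100))
        assert np.allclose(fwd, 0)

    def test_forward_matches_fine_grid_convolution_oracle(self):
        # independent oracle: direct trapezoidal convolution at 0.1 s steps,
        # evaluated pointwise at every frame midpoint
        r1, k2, bp = 1.0, 0.15, 2.0
        dt = 0.1 / 60.0
        t = np.arange(0.0, 60.0 + 1e-9, dt)
        ref = synthgen.GammaVariate()(t)
        lam = k2 / (1.0 + bp)
        fwd = pet_srtm.srtm_forward(r1, k2, bp, ref, t)
        sched = pet_srtm.FrameSchedule.default_pet()
        mids = np.round(sched.midpoints_s / 0.1).astype(int)
        for i in mids:
            conv_i = np.trapezoid(
                ref[: i + 1] * np.exp(-lam * (t[i] - t[: i + 1])), dx=dt
            )
            expected = r1 * ref[i] + (k2 - r1 * k2 / (1 + bp)) * conv_i
            assert fwd[i] == pytest.approx(expected, rel=1e-3, abs=1e-9)

    def test_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            synthgen.generate_tac({"R1": -1.0, "k2": 0.15, "BP_ND": 1.0})
        with pytest.raises(ValueError):
            synthgen.generate_tac({"R1": 1.0, "k2": 0.15, "BP_ND": -0.5})


class TestBehavior:
    def test_rank_one_battery_dominated_by_first_component(self, subjects):
        t = synthgen.generate_behavior(
            subjects, loadings=(1.0,) * 6, noise=0.0, seed=5
        )
        cols = [f"memory_task_{j}" for j in range(1, 7)]
        z = (t[cols] - t[cols].mean()) / t[cols].std(ddof=1)
        vals = np.linalg.eigvalsh(np.corrcoef(z.to_numpy(), rowvar=False))
        assert vals[-1] / 6 > 0.97  # integer rounding leaves a little residue

    def test_null_link_gives_no_partial_association(self):
        t = synthgen.generate_subject_table(n=800, seed=21)
        t = synthgen.generate_behavior(t, link=0.0, link_x_age=0.0, seed=22)
        import statsmodels.formula.api as smf

        fit = smf.ols("memory_latent_true ~ d_rest_z + age", data=t).fit()
        assert abs(fit.params["d_rest_z"]) < 3 * fit.bse["d_rest_z"]

    def test_default_battery_first_component_share(self):
        # planted equal loadings 0.7 give an expected first-component share
        # of (1 + 5 * 0.49) / 6 ~ 57.5%; allow sampling + rounding slack
        t = synthgen.generate_subject_table(n=180, seed=31)
        t = synthgen.generate_behavior(t, seed=32)
        cols = [f"memory_task_{j}" for j in range(1, 7)]
        z = (t[cols] - t[cols].mean()) / t[cols].std(ddof=1)
        vals = np.linalg.eigvalsh(np.corrcoef(z.to_numpy(), rowvar=False))
        assert vals[-1] / 6 == pytest.approx(0.575, abs=0.05)

    def test_loading_count_mismatch_rejected(self, subjects):
        with pytest.raises(ValueError, match="loadings"):
            synthgen.generate_behavior(subjects, loadings=(0.7,) * 5, seed=1)

    def test_scores_respect_task_maxima(self, subjects):
        t = synthgen.generate_behavior(subjects, seed=40)
        for j, mx in enumerate(synthgen.MEMORY_TASK_MAXIMA, start=1):
            col = t[f"memory_task_{j}"]
            assert col.between(0, mx).all()


class TestMotion:
    def test_mean_fd_matches_target(self, rng):
        motion, spikes = synthgen.generate_motion(350, 0.15, rng, spike_rate=0.0)
        from caudconn.preprocess import compute_fd

        fd = compute_fd(motion)
        assert fd.mean() == pytest.approx(0.15, rel=0.05)

    def test_spikes_recorded_and_visible_in_fd(self, rng):
        motion, spikes = synthgen.generate_motion(
            200, 0.05, rng, spike_rate=3.0, spike_size_mm=0.8
        )
        from caudconn.preprocess import compute_fd

        fd = compute_fd(motion)
        for v in spikes:
            assert fd[v] > 0.5
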