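"""Synthetic cohort generator: ground-truth contracts."""

import numpy as np
import pytest

from sfcoupling.granger import spectral_gc, wilson_factorize
from sfcoupling.oracles import var_cross_covariance
from sfcoupling.spectral import (LOW_BETA, FrequencyBand, band_average,
                                 coherence, compute_csd)
from sfcoupling.synthetic import (CohortSpec, SourceSpec,
                                  generate_streamline_cohort,
                                  generate_subject_recording,
                                  make_symmetric_space, make_toy_leadfield,
                                  simulate_var_sources)


class TestSimulateVar:
    def test_white_noise_unit_variance(self):
        rec = simulate_var_sources(np.zeros((1, 1, 1)), np.eye(1), 20000,
                                   seed=0)
        v = rec.data.var()
        # sample variance of n iid normals: SE = sqrt(2/n)
        assert abs(v - 1.0) < 3 * np.sqrt(2.0 / 20000)

    def test_cross_correlation_matches_lyapunov_oracle(self, var_fixture):
        coeffs, noise, fs = var_fixture
        rec = simulate_var_sources(coeffs, noise, 200_000, seed=1, fs=fs)
        x = rec.data
        x = x - x.mean(axis=1, keepdims=True)
        n = x.shape[1]
        expected = var_cross_covariance(coeffs, noise, max_lag=3)
        for lag in range(4):
            got = x[:, lag:] @ x[:, : n - lag].T / (n - lag)
            assert np.allclose(got, expected[lag], atol=0.05)
        # driver->receiver: Cov(x2_t, x1_{t-1}) exceeds Cov(x1_t, x2_{t-1})
        assert expected[1][1, 0] > expected[1][0, 1] + 0.1

    def test_determinism(self, var_fixture):
        coeffs, noise, fs = var_fixture
        a = simulate_var_sources(coeffs, noise, 5000, seed=7, fs=fs)
        b = simulate_var_sources(coeffs, noise, 5000, seed=7, fs=fs)
        assert np.array_equal(a.data, b.data)

    def test_unstable_var_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            simulate_var_sources(np.array([[[1.05]]]), np.eye(1), 100, seed=0)

    def test_non_spd_noise_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError, match="positive definite"):
            simulate_var_sources(np.zeros((1, 2, 2)), bad, 100, seed=0)


class TestToyLeadfield:
    def test_rows_unit_norm_and_distinct(self):
        grid = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        sensors = np.stack([30 * np.cos(theta), 30 * np.sin(theta),
                            np.zeros(8)], axis=1)
        lf = make_toy_leadfield(grid, sensors)
        assert np.allclose(np.linalg.norm(lf, axis=1), 1.0, atol=1e-12)
        cos = lf[0] @ lf[1]
        assert cos < 1.0 - 1e-6

    def test_nearest_sensor_has_largest_gain(self, toy_grid, toy_leadfield):
        from sfcoupling.synthetic import make_sensor_shell
        sensors = make_sensor_shell(16, radius=45.0)
        d = np.linalg.norm(toy_grid.points[:, None] - sensors[None], axis=2)
        assert np.array_equal(np.argmax(toy_leadfield, axis=1),
                              np.argmin(d, axis=1))

    def test_coincident_grid_and_sensor_rejected(self):
        sensors = np.random.default_rng(0).normal(size=(8, 3)) * 30
        with pytest.raises(ValueError, match="coincides"):
            make_toy_leadfield(sensors[:2], sensors)


class TestSubjectRecording:
    def test_planted_coherence_visible_at_best_sensor(self, toy_leadfield):
        spec = SourceSpec(location=3, band=LOW_BETA, coherence_target=1.0,
                          coupling_lag=4)
        rec = generate_subject_recording(
            [spec], toy_leadfield, duration_s=180.0, fs=300.0,
            sensor_snr=np.inf, seed=0,
        )
        best = int(np.argmax(toy_leadfield[3]))
        csd = compute_csd(rec.pick([f"MEG{best:03d}", "LFP"]))
        coh = band_average(csd.freqs, coherence(csd, 0, 1), LOW_BETA)
        assert coh > 0.9
        assert rec.metadata["realized_coherence"][0] == pytest.approx(
            1.0, abs=0.1)

    def test_empty_spec_gives_incoherent_sensors(self, toy_leadfield):
        rec = generate_subject_recording([], toy_leadfield, duration_s=180.0,
                                         fs=300.0, sensor_snr=1.0, seed=1)
        csd = compute_csd(rec.pick(["MEG000", "LFP"]))
        assert band_average(csd.freqs, coherence(csd, 0, 1), LOW_BETA) < 0.05

    def test_realized_coherence_within_tolerance(self, toy_leadfield):
        spec = SourceSpec(location=5, band=LOW_BETA, coherence_target=0.5,
                          coupling_lag=4)
        rec = generate_subject_recording([spec], toy_leadfield, seed=2)
        assert rec.metadata["realized_coherence"][0] == pytest.approx(
            0.5, abs=0.1)

    def test_source_drives_ref_granger_sign(self, toy_leadfield):
        # noiseless source at its best sensor vs the reference: the
        # planted direction must come out as the dominant one
        spec = SourceSpec(location=3, band=LOW_BETA, coherence_target=0.9,
                          direction="source_drives_ref", coupling_lag=6)
        rec = generate_subject_recording(
            [spec], toy_leadfield, duration_s=180.0, fs=300.0,
            sensor_snr=np.inf, seed=3,
        )
        best = int(np.argmax(toy_leadfield[3]))
        pair = rec.pick([f"MEG{best:03d}", "LFP"])
        csd = compute_csd(pair, window_s=2.0, freq_resolution=0.5)
        gr = spectral_gc(wilson_factorize(csd), csd)
        fwd = band_average(csd.freqs, gr.gc_xy, LOW_BETA)
        back = band_average(csd.freqs, gr.gc_yx, LOW_BETA)
        assert fwd > back

    def test_band_above_nyquist_rejected(self, toy_leadfield):
        spec = SourceSpec(location=0, band=FrequencyBand("hf", 40, 80),
                          coherence_target=0.5)
        with pytest.raises(ValueError, match="Nyquist"):
            generate_subject_recording([spec], toy_leadfield, duration_s=10.0,
                                       fs=100.0, seed=0)

    def test_determinism(self, toy_leadfield):
        spec = SourceSpec(location=1, band=LOW_BETA, coherence_target=0.6)
        a = generate_subject_recording([spec], toy_leadfield,
                                       duration_s=20.0, seed=9)
        b = generate_subject_recording([spec], toy_leadfield,
                                       duration_s=20.0, seed=9)
        assert np.array_equal(a.data, b.data)


class TestSourceSpecValidation:
    @pytest.mark.parametrize("kwargs,msg", [
        (dict(coherence_target=1.5), "coherence_target"),
        (dict(direction="sideways"), "direction"),
        (dict(direction="source_drives_ref", coupling_lag=0), "coupling_lag"),
    ])
    def test_invalid_specs_rejected(self, kwargs, msg):
        base = dict(location=0, band=LOW_BETA, coherence_target=0.5)
        base.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            SourceSpec(**base)


class TestStreamlineCohort:
    def _space(self):
        return make_symmetric_space((12, 12, 12), 2.0)

    def test_single_voxel_exact_density(self):
        from sfcoupling.tracts import density_image
        space = self._space()
        target = space.copy_with(np.zeros(space.shape))
        vox = (8, 6, 6)
        target.data[vox] = 5.0
        center = space.voxel_to_world(np.array(vox, dtype=float))
        cohort = CohortSpec(n_subjects=3, n_hemispheres_per_subject=1, seed=0)
        out = generate_streamline_cohort(cohort, center, 0.9, target,
                                         noise_sd=0.0)
        for sset in out.streamline_sets:
            img = density_image(sset, space)
            assert img.data[vox] == 5
            other = np.asarray(img.data).copy()
            other[vox] = 0
            assert other.sum() == 0

    def test_doubling_target_doubles_mean_density(self):
        from sfcoupling.tracts import density_image
        space = self._space()
        vox = (8, 6, 6)
        center = space.voxel_to_world(np.array(vox, dtype=float))

        def mean_density(value, seed):
            target = space.copy_with(np.zeros(space.shape))
            target.data[vox] = value
            cohort = CohortSpec(n_subjects=10,
                                n_hemispheres_per_subject=2, seed=seed)
            out = generate_streamline_cohort(cohort, center, 0.9, target,
                                             noise_sd=2.0)
            return np.mean([density_image(s, space).data[vox]
                            for s in out.streamline_sets])

        m1, m2 = mean_density(5.0, 1), mean_density(10.0, 1)
        assert m2 == pytest.approx(2 * m1, rel=0.15)

    def test_every_streamline_touches_seed_sphere(self):
        space = self._space()
        target = space.copy_with(np.zeros(space.shape))
        target.data[9, 8, 5] = 4.0
        target.data[3, 3, 8] = 2.0
        center = np.array([1.0, -1.0, 1.0])
        cohort = CohortSpec(n_subjects=3, seed=2)
        out = generate_streamline_cohort(cohort, center, 3.0, target)
        for sset in out.streamline_sets:
            assert len(sset) > 0
            for line in sset:
                d = np.linalg.norm(line - center[None, :], axis=1)
                assert d.min() <= 3.0

    def test_all_zero_target_warns_and_is_empty(self):
        space = self._space()
        target = space.copy_with(np.zeros(space.shape))
        cohort = CohortSpec(n_subjects=3, seed=3)
        with pytest.warns(UserWarning, match="all-zero"):
            out = generate_streamline_cohort(cohort, np.zeros(3), 3.0, target)
        assert all(len(s) == 0 for s in out.streamline_sets)

    def test_determinism(self):
        space = self._space()
        target = space.copy_with(np.zeros(space.shape))
        target.data[8, 6, 6] = 3.0
        center = space.voxel_to_world(np.array([8.0, 6.0, 6.0]))
        cohort = CohortSpec(n_subjects=3, seed=5)
        a = generate_streamline_cohort(cohort, center, 2.0, target)
        b = generate_streamline_cohort(cohort, center, 2.0, target)
        assert len(a.streamline_sets[0]) == len(b.streamline_sets[0])
        for la, lb in zip(a.streamline_sets[0], b.streamline_sets[0]):
            assert np.array_equal(la, lb)

    def test_sfc_voxel_outside_volume_rejected(self):
        space = self._space()
        target = space.copy_with(np.zeros(space.shape))
        target.data[5, 5, 5] = 1.0
        cohort = CohortSpec(n_subjects=3, sfc_voxels=((40, 0, 0),), seed=0)
        with pytest.raises(ValueError, match="outside"):
            generate_streamline_cohort(cohort, np.zeros(3), 2.0, target)


def test_cohort_spec_minimum_subjects():
    with pytest.raises(ValueError, match="3 subjects"):
        CohortSpec(n_subjects=2)
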