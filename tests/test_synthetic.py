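import numpy as np
import pytest

from smoothsweep.connectivity import pearson_matrix, upper_triangle
from smoothsweep.core import BrainVolume4D
from smoothsweep.parcellation import roi_time_series
from smoothsweep.smoothing import estimate_smoothness
from smoothsweep.synthetic import (
    CohortSpec,
    generate_cohort,
    generate_roi_series,
    generate_subject_volume,
    make_block_parcellation,
    make_group_covariances,
)


class TestGroupCovariances:
    def test_null_contrast_gives_identical_groups(self):
        spec = CohortSpec(delta=0.0)
        control, patient, _ = make_group_covariances(spec)
        assert np.array_equal(control, patient)

    def test_three_roi_single_link_case(self):
        # requested matrix has eigenvalues {1.5, 1.0, 0.5}: already PSD
        spec = CohortSpec(n_rois=3, r0=0.0, planted_links=((0, 1),), delta=0.5,
                          background="none")
        control, patient, gt = make_group_covariances(spec)
        assert np.array_equal(control, np.eye(3))
        expected = np.eye(3)
        expected[0, 1] = expected[1, 0] = 0.5
        assert np.array_equal(patient, expected)
        assert gt.achieved_delta[(0, 1)] == pytest.approx(0.5)

    def test_achieved_contrast_close_to_requested_after_repair(self):
        spec = CohortSpec(n_rois=10, r0=0.2, delta=0.3,
                          planted_links=((0, 1), (1, 2), (2, 3), (3, 4), (4, 5)))
        _, patient, gt = make_group_covariances(spec)
        assert np.linalg.eigvalsh(patient).min() >= -1e-10
        for v in gt.achieved_delta.values():
            assert abs(v - 0.3) < 0.02

    def test_unreachable_contrast_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            CohortSpec(r0=0.7, delta=0.4)

    def test_disconnected_planted_links_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            CohortSpec(planted_links=((0, 1), (3, 4)))


class TestRoiSeries:
    def test_identity_cov_uncorrelated(self):
        t = 4096
        x = generate_roi_series(np.eye(6), t, 2.0, (0.01, 0.08), 0)
        emp = np.corrcoef(x)
        iu = np.triu_indices(6, 1)
        assert abs(emp[iu].mean()) < 3 / np.sqrt(t)

    def test_strong_pair_recovered_within_fisher_interval(self):
        cov = np.eye(2)
        cov[0, 1] = cov[1, 0] = 0.8
        x = generate_roi_series(cov, 4096, 2.0, (0.01, 0.08), 1)
        assert 0.74 <= np.corrcoef(x)[0, 1] <= 0.86

    def test_rows_standardized(self):
        x = generate_roi_series(np.eye(4), 256, 2.0, (0.01, 0.08), 2)
        assert np.allclose(x.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(x.std(axis=1), 1, atol=1e-12)

    def test_out_of_band_power_suppressed(self):
        t, tr = 1024, 2.0
        x = generate_roi_series(np.eye(3), t, tr, (0.01, 0.08), 3)
        f = np.fft.rfftfreq(t, tr)
        p = (np.abs(np.fft.rfft(x, axis=1)) ** 2).mean(axis=0)
        in_band = p[(f >= 0.01) & (f <= 0.08)].mean()
        out_band = p[f > 0.1]
        assert 10 * np.log10(out_band.max() / in_band) < -20

    def test_full_band_correlation_recovery(self):
        # entrywise recovery of a full cohort covariance at large T
        spec = CohortSpec(seed=3)
        _, patient, _ = make_group_covariances(spec)
        x = generate_roi_series(patient, 4096, 2.0, (0.0, 0.25), 0)
        assert np.abs(np.corrcoef(x) - patient).max() < 0.05

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            generate_roi_series(np.eye(3), 128, 2.0, (0.01, 0.3), 0)


class TestSubjectVolume:
    def test_noise_free_voxels_carry_roi_series(self):
        spec = CohortSpec(n_rois=4, roi_voxels=8, T=16, voxel_noise_sd=0.0,
                          planted_links=((0, 1),))
        parc = make_block_parcellation(spec)
        _, patient, _ = make_group_covariances(spec)
        series = generate_roi_series(patient, spec.T, spec.tr, spec.band, 0)
        vol = generate_subject_volume(parc, series, spec, 0)
        for roi in range(1, 5):
            member_series = vol.data[parc.labels == roi]
            assert np.abs(member_series - series[roi - 1]).max() == 0.0
        recovered = roi_time_series(vol, parc)
        assert np.abs(recovered - series).max() < 1e-12

    def test_intrinsic_smoothness_recovered(self):
        spec = CohortSpec(n_rois=2, roi_voxels=1, T=3, voxel_noise_sd=1.0,
                          intrinsic_fwhm=6.0, planted_links=((0, 1),))
        # pure-noise volume on a larger grid for a stable estimate
        from smoothsweep.core import VolumeGrid
        from smoothsweep.parcellation import Parcellation

        dims = (30, 30, 30)
        labels = np.zeros(dims, int)
        labels[:15] = 1
        labels[15:] = 2
        parc = Parcellation(VolumeGrid(dims, (2.0, 2.0, 2.0)), labels)
        series = np.zeros((2, 3))
        series[:, 0] = 1e-9  # avoid all-constant degenerate input
        vol = generate_subject_volume(parc, series, spec, 5)
        est = estimate_smoothness(vol)
        assert abs(est - 6.0) / 6.0 < 0.2

    def test_roi_mean_noise_variance_scales_with_voxel_count(self):
        spec = CohortSpec(n_rois=4, roi_voxels=27, T=512, voxel_noise_sd=0.5,
                          intrinsic_fwhm=0.0, planted_links=((0, 1),), seed=9)
        parc = make_block_parcellation(spec)
        series = np.zeros((4, spec.T))
        series[:, 0] = 1e-9
        vol = generate_subject_volume(parc, series, spec, 9)
        roi_means = roi_time_series(vol, parc)
        expected_var = spec.voxel_noise_sd**2 / spec.roi_voxels
        measured = roi_means.var(axis=1).mean()
        assert expected_var / 1.3 < measured < expected_var * 1.3


class TestGenerateCohort:
    def test_same_seed_is_bitwise_identical(self):
        spec = CohortSpec(n_per_group=3, n_rois=6, T=64,
                          planted_links=((0, 1), (1, 2)), roi_voxels=8)
        a = generate_cohort(spec, mode="volume")
        b = generate_cohort(spec, mode="volume")
        assert [s.id for s in a.subjects] == [s.id for s in b.subjects]
        assert [s.mean_fd for s in a.subjects] == [s.mean_fd for s in b.subjects]
        for va, vb in zip(a.volumes, b.volumes):
            assert np.array_equal(va.data, vb.data)

    def test_different_seed_changes_data(self):
        spec = CohortSpec(n_per_group=2, n_rois=6, T=64, planted_links=((0, 1),))
        a = generate_cohort(spec, mode="roi")
        b = generate_cohort(
            CohortSpec(n_per_group=2, n_rois=6, T=64, planted_links=((0, 1),), seed=1),
            mode="roi",
        )
        assert not np.array_equal(a.roi_series[0], b.roi_series[0])

    def test_round_robin_site_assignment(self):
        spec = CohortSpec(n_per_group=5, n_sites=2, n_rois=6, T=64,
                          planted_links=((0, 1),))
        cohort = generate_cohort(spec, mode="roi")
        for group in ("patient", "control"):
            sites = [s.site for s in cohort.subjects if s.group == group]
            assert sorted([sites.count("site0"), sites.count("site1")]) == [2, 3]

    def test_mean_fd_within_truncation_cap(self):
        cohort = generate_cohort(
            CohortSpec(n_per_group=20, n_rois=6, T=64, planted_links=((0, 1),)),
            mode="roi",
        )
        fds = np.array([s.mean_fd for s in cohort.subjects])
        assert np.all(fds >= 0) and np.all(fds < 0.5)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            CohortSpec(n_per_group=1)

    def test_planted_correlation_visible_in_patient_matrices(self):
        spec = CohortSpec(n_per_group=4, n_rois=8, T=2048, delta=0.5, r0=0.0,
                          planted_links=((0, 1), (1, 2)), site_effect_sd=0.0,
                          fd_effect_slope=0.0)
        cohort = generate_cohort(spec, mode="roi")
        pat = [np.corrcoef(s)[0, 1] for sub, s in zip(cohort.subjects, cohort.roi_series)
               if sub.group == "patient"]
        ctl = [np.corrcoef(s)[0, 1] for sub, s in zip(cohort.subjects, cohort.roi_series)
               if sub.group == "control"]
        assert np.mean(pat) - np.mean(ctl) > 0.3
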