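"""Ground-truth recoverability of every synthetic input the pipeline uses."""

import math

import numpy as np
import pytest
from scipy.stats import norm

import sarcoreg as sr
from sarcoreg.imaging_io import FormatError


def clipped_normal_mean_sd(mu, sigma):
    """Closed-form mean/SD of max(N(mu, sigma), 0) — the generator's law."""
    if sigma == 0:
        return max(mu, 0.0), 0.0
    a = mu / sigma
    mean = mu * norm.cdf(a) + sigma * norm.pdf(a)
    second = (mu**2 + sigma**2) * norm.cdf(a) + mu * sigma * norm.pdf(a)
    return mean, math.sqrt(max(second - mean**2, 0.0))


class TestInvivoPhantom:
    def test_roi_volume_matches_requested_tumor_volume(self, invivo_phantom):
        volume, roi, _ = invivo_phantom
        requested = 4.0 / 3.0 * math.pi * 22.0 * 16.0 * 18.0
        got = float((roi.data > 0).sum() * np.prod(volume.spacing))
        assert got == pytest.approx(requested, rel=0.10)

    def test_byte_identical_under_seed(self):
        v1, r1, l1 = sr.make_invivo_phantom(seed=11)
        v2, r2, l2 = sr.make_invivo_phantom(seed=11)
        assert v1.data.tobytes() == v2.data.tobytes()
        assert r1.data.tobytes() == r2.data.tobytes()
        np.testing.assert_array_equal(l1.points, l2.points)

    def test_landmark_count_and_field_of_view(self, invivo_phantom):
        volume, roi, landmarks = invivo_phantom
        assert 30 <= len(landmarks) <= 40
        idx = volume.index_of_world(landmarks.points)
        assert np.all(idx >= 0) and np.all(idx < np.asarray(volume.shape))
        with pytest.raises(FormatError, match="30..40|n_landmarks"):
            sr.make_invivo_phantom(n_landmarks=20)

    def test_oversized_tumor_rejected(self):
        with pytest.raises(FormatError, match="larger than grid"):
            sr.make_invivo_phantom(tumor_radii_mm=(60.0, 60.0, 60.0))


class TestExvivoPhantom:
    def test_identity_transform_is_identity(self, invivo_phantom):
        volume, _, landmarks = invivo_phantom
        ex, ex_lm = sr.make_exvivo_phantom(
            volume, landmarks, sr.RigidTransform.identity(), shrink_factor=1.0
        )
        np.testing.assert_allclose(ex.data, volume.data, atol=1e-9)
        np.testing.assert_allclose(ex_lm.points, landmarks.points, atol=1e-9)

    def test_known_oblique_rotation_recovered_from_landmarks(self, invivo_phantom):
        volume, _, landmarks = invivo_phantom
        axis = np.array([0.2, 0.5, 0.84])
        axis /= np.linalg.norm(axis)
        truth = sr.RigidTransform(
            sr.rotation_matrix_from_axis_angle(axis, math.radians(25.0)),
            (4.0, -3.0, 6.0),
        )
        _, ex_lm = sr.make_exvivo_phantom(volume, landmarks, truth)
        report = sr.estimate_rigid(sr.pair_landmarks(ex_lm, landmarks))
        # recovered transform maps ex vivo back onto in vivo: inverse of truth
        residual = report.transform.rotation @ truth.rotation
        angle_err = math.acos(np.clip((np.trace(residual) - 1) / 2, -1, 1))
        assert angle_err < 1e-6
        assert report.rms_residual < 1e-6

    def test_shrink_scales_pairwise_distances(self, invivo_phantom):
        volume, _, landmarks = invivo_phantom
        _, ex_lm = sr.make_exvivo_phantom(
            volume, landmarks, sr.RigidTransform.identity(), shrink_factor=0.95
        )
        d0 = np.linalg.norm(landmarks.points[0] - landmarks.points[1])
        d1 = np.linalg.norm(ex_lm.points[0] - ex_lm.points[1])
        assert d1 / d0 == pytest.approx(0.95, abs=1e-6)

    def test_shrink_out_of_range_rejected(self, invivo_phantom):
        volume, _, landmarks = invivo_phantom
        with pytest.raises(FormatError, match="shrink"):
            sr.make_exvivo_phantom(
                volume, landmarks, sr.RigidTransform.identity(), shrink_factor=0.5
            )


class TestSectionPhantom:
    def test_zero_deformation_zero_noise_is_the_slice_itself(self, mri_slice):
        data, px = mri_slice
        phantom = sr.make_section_phantom(
            data, px, deformation_amplitude_mm=0.0, landmark_noise_sigma=0.0, seed=2
        )
        np.testing.assert_allclose(phantom.section.data, data, atol=1e-9)
        result = sr.run_tre_protocol(phantom.pairs, n_iter=10, seed=0)
        assert np.max(result.distances) < 1e-9

    def test_affine_deformation_recovered_exactly_by_protocol(self, mri_slice):
        data, px = mri_slice
        phantom = sr.make_section_phantom(
            data, px, deformation_amplitude_mm=3.0, landmark_noise_sigma=0.0,
            deformation="affine", seed=4,
        )
        result = sr.run_tre_protocol(phantom.pairs, n_iter=20, seed=1)
        assert np.median(result.distances) < 1e-6

    def test_truth_warp_maps_mri_landmarks_to_histology(self, mri_slice):
        data, px = mri_slice
        phantom = sr.make_section_phantom(
            data, px, deformation_amplitude_mm=2.0, landmark_noise_sigma=0.0, seed=6
        )
        mapped = phantom.truth_warp(phantom.pairs.target.points)
        np.testing.assert_allclose(mapped, phantom.pairs.source.points, atol=1e-9)

    def test_deterministic_under_seed(self, mri_slice):
        data, px = mri_slice
        p1 = sr.make_section_phantom(data, px, seed=9)
        p2 = sr.make_section_phantom(data, px, seed=9)
        assert p1.section.data.tobytes() == p2.section.data.tobytes()
        np.testing.assert_array_equal(p1.pairs.source.points, p2.pairs.source.points)


class TestMapStack:
    def test_zero_sd_returns_exact_habitat_means(self):
        roi = sr.make_block_roi((8, 8, 4))
        params = {
            name: tuple((m, 0.0) for m, _ in per_region)
            for name, per_region in sr.TABLE_HABITAT_PARAMS.items()
        }
        stack, truth, n_clipped = sr.make_map_stack(roi, habitat_params=params, seed=0)
        assert n_clipped == 0
        table = sr.region_stats(stack, truth).table
        for _, row in table.iterrows():
            expected = params[row["channel"]][int(row["region"]) - 1][0]
            assert row["mean"] == pytest.approx(expected, abs=1e-12)
            assert row["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_sample_means_within_three_se_of_generator_law(self):
        """~500 voxels per habitat: per-region sample means agree with the
        clipped-normal law of the generator within 3 standard errors."""
        roi = sr.make_block_roi((16, 16, 8))  # 2048 voxels
        stack, truth, _ = sr.make_map_stack(roi, seed=5)
        table = sr.region_stats(stack, truth).table
        for _, row in table.iterrows():
            mu, sd = sr.TABLE_HABITAT_PARAMS[row["channel"]][int(row["region"]) - 1]
            exp_mean, exp_sd = clipped_normal_mean_sd(mu, sd)
            se = exp_sd / math.sqrt(row["n_voxels"])
            assert abs(row["mean"] - exp_mean) <= 3.0 * se, (
                row["channel"], row["region"]
            )

    def test_habitats_are_contiguous_and_cover_roi(self):
        roi = sr.make_block_roi((12, 12, 6))
        stack, truth, _ = sr.make_map_stack(roi, seed=1)
        labels = truth.data
        assert set(np.unique(labels[roi.data > 0])) == {1, 2, 3, 4}
        assert np.all(labels[roi.data == 0] == 0)

    def test_negative_sd_rejected(self):
        roi = sr.make_block_roi((6, 6, 3))
        params = {
            name: tuple((m, -1.0) for m, _ in per_region)
            for name, per_region in sr.TABLE_HABITAT_PARAMS.items()
        }
        with pytest.raises(FormatError, match="negative sd"):
            sr.make_map_stack(roi, habitat_params=params)

    def test_byte_identical_under_seed(self):
        roi = sr.make_block_roi((8, 8, 4))
        s1, t1, _ = sr.make_map_stack(roi, seed=3)
        s2, t2, _ = sr.make_map_stack(roi, seed=3)
        assert t1.data.tobytes() == t2.data.tobytes()
        assert s1.channels["ADC"].data.tobytes() == s2.channels["ADC"].data.tobytes()
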