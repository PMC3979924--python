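"""Synthetic nerve generator: rendering primitives, optical effects,
whole-scene ground truth, and walking-track print synthesis."""

import logging

import numpy as np
import pytest
from scipy import ndimage

import axonquant as aq
from axonquant.simulate import LABEL_FRAGMENT, LABEL_LONG


ISO = dict(shape=(21, 21, 61), spacing=(1.0, 1.0, 1.0))  # 1 um isotropic grid


def _axial_path(z=10.0, y=10.0, x0=0.0, x1=60.0):
    return np.array([[z, y, x0], [z, y, x1]])


class TestAxonTube:
    def test_cross_section_area_matches_circle(self):
        """A radius-3 um tube on a 1 um grid labels ~pi*3^2 voxels per slice."""
        _, labels = aq.render_axon_tube(ISO["shape"], ISO["spacing"],
                                        _axial_path(), radius_um=3.0)
        per_slice = labels.sum(axis=(0, 1))[10:50]  # away from the tube ends
        assert np.all(per_slice >= np.pi * 9 * 0.8)
        assert np.all(per_slice <= np.pi * 9 * 1.2)

    def test_zero_length_path_rejected(self):
        path = np.array([[10, 10, 5], [10, 10, 5]])
        with pytest.raises(ValueError, match="zero length"):
            aq.render_axon_tube(ISO["shape"], ISO["spacing"], path, 3.0)

    def test_path_outside_field_names_vertex(self):
        path = np.array([[10, 10, 0], [10, 10, 200]])
        with pytest.raises(ValueError, match="vertex 1"):
            aq.render_axon_tube(ISO["shape"], ISO["spacing"], path, 3.0)

    def test_subvoxel_radius_advises_finer_spacing(self):
        with pytest.raises(ValueError, match="finer voxel spacing"):
            aq.render_axon_tube(ISO["shape"], ISO["spacing"], _axial_path(), 0.5)

    def test_parallel_tubes_have_disjoint_labels(self):
        _, la = aq.render_axon_tube(ISO["shape"], ISO["spacing"],
                                    _axial_path(y=5.0), 2.0)
        _, lb = aq.render_axon_tube(ISO["shape"], ISO["spacing"],
                                    _axial_path(y=15.0), 2.0)
        assert not np.any((la > 0) & (lb > 0))

    def test_intensity_peaks_on_axis(self):
        intensity, _ = aq.render_axon_tube(ISO["shape"], ISO["spacing"],
                                           _axial_path(), 3.0, peak_intensity=100.0)
        assert intensity[10, 10, 30] == pytest.approx(100.0, rel=1e-3)
        assert intensity[10, 13, 30] < intensity[10, 10, 30]


class TestFragmentChain:
    def test_single_fragment_is_one_component(self):
        _, labels = aq.render_fragment_chain(ISO["shape"], ISO["spacing"],
                                             _axial_path(), [10.0], [], 2.5)
        n = ndimage.label(labels == LABEL_FRAGMENT)[1]
        assert n == 1

    def test_component_count_follows_placement_rule(self):
        """10 um fragments with 5 um gaps on a 100 um track: floor(100/15)+1."""
        shape, spacing = (21, 21, 101), (1.0, 1.0, 1.0)
        path = np.array([[10, 10, 0], [10, 10, 100]])
        k = 7
        _, labels = aq.render_fragment_chain(shape, spacing, path,
                                             [10.0] * k, [5.0] * (k - 1), 2.5)
        n = ndimage.label(labels == LABEL_FRAGMENT)[1]
        assert n == int(100 // 15) + 1 == k

    def test_empty_fragment_list_labels_nothing(self):
        _, labels = aq.render_fragment_chain(ISO["shape"], ISO["spacing"],
                                             _axial_path(), [], [], 2.5)
        assert labels.sum() == 0

    def test_overlong_chain_truncated_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="axonquant"):
            _, labels = aq.render_fragment_chain(
                ISO["shape"], ISO["spacing"], _axial_path(x1=30.0),
                [20.0, 20.0], [5.0], 2.5,
            )
        assert any("truncated" in r.message for r in caplog.records)
        assert ndimage.label(labels == LABEL_FRAGMENT)[1] == 1


class TestDepthAttenuation:
    def _uniform(self, value=100.0):
        return aq.ImageVolume(np.full((11, 8, 8), value, np.float32),
                              spacing=(10.0, 1.0, 1.0))

    def test_slice_mean_ratio_is_exp_minus_one_at_depth_L(self):
        out = aq.apply_depth_attenuation(self._uniform(), length_constant_um=50.0)
        ratio = out.data[5].mean() / out.data[0].mean()  # depth 50 um = L
        assert ratio == pytest.approx(np.exp(-1), rel=1e-6)

    def test_infinite_length_constant_is_identity(self):
        vol = self._uniform()
        out = aq.apply_depth_attenuation(vol, float("inf"))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_non_positive_length_constant_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            aq.apply_depth_attenuation(self._uniform(), -5.0)

    def test_slice_means_monotone_non_increasing(self):
        out = aq.apply_depth_attenuation(self._uniform(), 80.0)
        means = out.data.mean(axis=(1, 2))
        assert np.all(np.diff(means) <= 1e-9)

    def test_planted_constant_recovered_by_log_linear_fit(self):
        out = aq.apply_depth_attenuation(self._uniform(), 75.0)
        prof = aq.depth_intensity_profile(out, {}, axis="z")
        assert aq.fit_attenuation_length(prof) == pytest.approx(75.0, rel=0.10)


class TestRadialStaining:
    def _vol(self):
        return aq.ImageVolume(np.full((5, 64, 32), 100.0, np.float32),
                              spacing=(2.0, 1.0, 1.0))

    def test_disabled_is_identity(self):
        vol = self._vol()
        out = aq.apply_radial_staining_profile(vol, decay_constant_um=None)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_centre_dimmer_than_surface(self):
        out = aq.apply_radial_staining_profile(self._vol(), nerve_axis=2,
                                               decay_constant_um=10.0,
                                               nerve_radius_um=30.0)
        centre = out.data[2, 32, 16]
        edge = out.data[2, 3, 16]
        assert centre < edge

    def test_factor_matches_closed_form_at_two_radii(self):
        c, R = 12.0, 30.0
        out = aq.apply_radial_staining_profile(self._vol(), nerve_axis=2,
                                               decay_constant_um=c, nerve_radius_um=R)
        # centre row of the section: radial position = |y - 31.5| um, z offset ~ dz*(2-2)=0
        for y in (12, 22):
            rho = abs((y - 31.5) * 1.0)  # um from the nerve axis (z term zero on plane 2)
            rho = np.hypot(rho, 0.0)
            expected = 100.0 * np.exp(-(R - rho) / c)
            assert out.data[2, y, 16] == pytest.approx(expected, rel=1e-6)


class TestNoise:
    def _vol(self):
        return aq.ImageVolume(np.full((4, 16, 16), 100.0, np.float32))

    def test_zero_noise_is_identity(self):
        vol = self._vol()
        out = aq.apply_noise(vol, gain=0.0, read_noise_sd=0.0, seed=3)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_mean_preserved_within_three_standard_errors(self):
        vol = self._vol()
        out = aq.apply_noise(vol, gain=2.0, read_noise_sd=4.0, seed=3)
        n = out.data.size
        se = np.sqrt(2.0 * 100.0 + 16.0) / np.sqrt(n)  # var = gain*v + sd^2
        assert abs(out.data.mean() - 100.0) < 3 * se

    def test_fixed_seed_reproducible(self):
        a = aq.apply_noise(self._vol(), 1.0, 5.0, seed=11)
        b = aq.apply_noise(self._vol(), 1.0, 5.0, seed=11)
        np.testing.assert_array_equal(a.data, b.data)

    def test_negative_variance_parameters_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            aq.apply_noise(self._vol(), gain=-1.0)


class TestGenerateNerveVolume:
    def test_baseline_planted_fraction_is_exactly_one(self, small_spec):
        _, gt = aq.generate_nerve_volume(small_spec)
        assert gt.planted_long_fraction == 1.0

    def test_deterministic_for_fixed_seed(self, small_spec):
        va, ga = aq.generate_nerve_volume(small_spec)
        vb, gb = aq.generate_nerve_volume(small_spec)
        np.testing.assert_array_equal(va.data, vb.data)
        np.testing.assert_array_equal(ga.labels, gb.labels)

    def test_planted_fraction_hits_target_within_002(self):
        spec = aq.SceneSpec(stage="d6", long_fraction=0.45, seed=9)
        _, gt = aq.generate_nerve_volume(spec)
        assert 0.43 <= gt.planted_long_fraction <= 0.47

    def test_ground_truth_fraction_is_conserved(self):
        """The stored planted fraction is exactly recomputable from labels."""
        spec = aq.SceneSpec(stage="d3", long_fraction=0.7, seed=4)
        _, gt = aq.generate_nerve_volume(spec)
        n_long = (gt.labels == LABEL_LONG).sum()
        n_frag = (gt.labels == LABEL_FRAGMENT).sum()
        assert gt.planted_long_fraction == n_long / (n_long + n_frag)

    def test_more_fragmentation_never_raises_planted_fraction(self):
        planted = []
        for target in (1.0, 0.7, 0.3):
            spec = aq.SceneSpec(stage="d6", long_fraction=target, seed=2)
            _, gt = aq.generate_nerve_volume(spec)
            planted.append(gt.planted_long_fraction)
        assert planted[0] >= planted[1] >= planted[2]

    def test_regenerating_axons_thinner_than_baseline(self):
        spec12 = aq.scene_for_stage("d12", seed=0)
        spec0 = aq.scene_for_stage("baseline", seed=0)
        assert spec12.intact_radius_um() < spec0.intact_radius_um()

    def test_unreachable_target_reports_achievable_range(self):
        spec = aq.SceneSpec(stage="d6", long_fraction=0.05, seed=0,
                            field_size_um=(24.0, 60.0, 120.0), n_tracks=3)
        with pytest.raises(ValueError, match="achievable range"):
            aq.generate_nerve_volume(spec)

    def test_metadata_records_seed_and_fraction(self, small_spec):
        vol, gt = aq.generate_nerve_volume(small_spec)
        assert vol.metadata["seed"] == small_spec.seed
        assert vol.metadata["planted_long_fraction"] == gt.planted_long_fraction


class TestSceneSpecValidation:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="long_fraction"):
            aq.SceneSpec(long_fraction=1.2)

    def test_non_positive_voxels_rejected(self):
        with pytest.raises(ValueError, match="voxel"):
            aq.SceneSpec(voxel_size_um=(2.0, 0.39, 0.0))

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            aq.scene_for_stage("d15")


class TestTrackMeasurements:
    def test_full_recovery_without_noise_matches_normal_side(self):
        m = aq.generate_track_measurements(1.0, seed=0, noise_sd_mm=0.0)
        assert np.allclose(m.epl_mm, m.npl_mm)
        assert np.allclose(m.ets_mm, m.nts_mm)
        assert np.allclose(m.eit_mm, m.nit_mm)

    def test_zero_recovery_preset_scores_minus_100(self):
        m = aq.generate_track_measurements(0.0, seed=0, noise_sd_mm=0.0)
        result = aq.compute_sfi(m)
        assert result.mean_sfi == pytest.approx(-100.0, abs=1e-9)

    def test_fixed_seed_reproducible(self):
        a = aq.generate_track_measurements(0.5, seed=8, noise_sd_mm=0.5)
        b = aq.generate_track_measurements(0.5, seed=8, noise_sd_mm=0.5)
        np.testing.assert_array_equal(a.epl_mm, b.epl_mm)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="recovery fraction"):
            aq.generate_track_measurements(1.5)
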