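"""Microbubble tracking, velocity estimation, map rendering and FRC."""

import numpy as np
import pandas as pd
import pytest

from renovasc.srus import (
    DetectionSequence,
    Track,
    estimate_resolution_frc,
    estimate_track_velocities,
    frc_curve,
    link_detections,
    max_detectable_velocity,
    mean_detections_per_frame,
    render_srus_image,
    sample_vessel_velocities,
    srus_density,
)


def line_sequence(speed_mm_s, n_frames, frame_rate=54.0, z=0.0):
    frames = np.arange(n_frames)
    df = pd.DataFrame({"frame": frames, "x_mm": speed_mm_s / frame_rate * frames,
                       "z_mm": float(z)})
    return DetectionSequence(df, frame_rate)


class TestLinking:
    def test_collinear_detections_form_one_track(self):
        tracks = link_detections(line_sequence(0.1 * 54, 5))
        assert len(tracks) == 1
        assert len(tracks[0]) == 5

    def test_two_frame_trajectory_is_discarded(self):
        assert link_detections(line_sequence(2.0, 2)) == []

    def test_supragate_speed_yields_no_tracks(self):
        # 0.5 mm/frame = 27 mm/s at 54 Hz, beyond the gate
        assert link_detections(line_sequence(27.0, 10)) == []

    def test_two_simultaneous_straight_tracks(self):
        a = line_sequence(3.0, 6, z=0.0).detections
        b = line_sequence(4.0, 6, z=5.0).detections
        seq = DetectionSequence(pd.concat([a, b], ignore_index=True), 54.0)
        tracks = link_detections(seq)
        assert len(tracks) == 2
        assert sorted(len(t) for t in tracks) == [6, 6]

    def test_frame_gap_splits_the_track(self):
        df = line_sequence(2.0, 8).detections
        df = df[df.frame != 4]
        tracks = link_detections(DetectionSequence(df, 54.0))
        assert sorted(len(t) for t in tracks) == [3, 4]

    def test_empty_sequence(self):
        seq = DetectionSequence(pd.DataFrame({"frame": [], "x_mm": [], "z_mm": []}), 54.0)
        assert link_detections(seq) == []


class TestVelocityCap:
    def test_default_gate_realizes_15_mm_s(self):
        assert max_detectable_velocity(0.278, 54.0) == pytest.approx(15.0, abs=0.02)

    def test_identity_at_1_hz(self):
        assert max_detectable_velocity(0.3, 1.0) == pytest.approx(0.3)

    def test_cap_linear_in_frame_rate(self):
        assert max_detectable_velocity(0.28, 108.0) == 2 * max_detectable_velocity(0.28, 54.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            max_detectable_velocity(0.0, 54.0)

    def test_censoring_curve_noiseless(self):
        """Recovery is total well below the cap and zero above it."""
        cap = max_detectable_velocity()
        for speed in np.arange(1.0, 0.8 * cap + 1e-9, 1.0):
            assert len(link_detections(line_sequence(speed, 12))) == 1, speed
        for speed in np.arange(np.ceil(cap) + 0.5, 30.0, 1.0):
            assert link_detections(line_sequence(speed, 12)) == [], speed

    def test_speed_not_overestimated_near_cap_with_noise(self):
        """Gating truncates fast noisy steps, so speeds near the cap are
        underestimated on average rather than inflated."""
        rng = np.random.default_rng(0)
        cap = max_detectable_velocity()
        biases = []
        for speed in np.linspace(0.8 * cap, cap, 5):
            errs = []
            for _ in range(40):
                df = line_sequence(speed, 10).detections.copy()
                df[["x_mm", "z_mm"]] += rng.normal(0, 0.02, (len(df), 2))
                for t in link_detections(DetectionSequence(df, 54.0)):
                    errs.append(t.mean_speed_mm_s - speed)
            if errs:
                biases.append(np.mean(errs))
        assert biases and np.mean(biases) <= 0


class TestVelocities:
    def test_constant_velocity_track(self):
        t = Track(np.arange(10), np.stack([10.0 / 54 * np.arange(10),
                                           np.zeros(10)], axis=1), 54.0)
        steps, mean = estimate_track_velocities(t)
        assert mean == pytest.approx(10.0)
        assert np.allclose(steps, 10.0)

    def test_stationary_track(self):
        t = Track(np.arange(5), np.zeros((5, 2)), 54.0)
        _, mean = estimate_track_velocities(t)
        assert mean == 0.0

    def test_circular_track_chord_correction_below_0_1_percent(self):
        # unit circle traversed at 1 rad/s sampled at 54 Hz: chord speed
        # 2 r sin(w dt / 2) / dt, within 0.1% of 1 mm/s
        fr = 54.0
        t_s = np.arange(200) / fr
        pos = np.stack([np.cos(t_s), np.sin(t_s)], axis=1)
        t = Track(np.arange(200), pos, fr)
        _, mean = estimate_track_velocities(t)
        expected = 2 * np.sin(0.5 / fr) * fr
        assert mean == pytest.approx(expected, rel=1e-9)
        assert abs(mean - 1.0) / 1.0 < 1e-3

    def test_single_point_track_rejected(self):
        t = Track(np.array([0]), np.zeros((1, 2)), 54.0)
        with pytest.raises(ValueError):
            estimate_track_velocities(t)

    def test_vessel_sampling_rule(self):
        def mk(speed, label):
            tr = Track(np.arange(3), np.stack([speed / 54 * np.arange(3),
                                               np.zeros(3)], axis=1), 54.0)
            tr.vessel_label = label
            return tr

        tracks = [mk(5, "arcuate_vein"), mk(6, "arcuate_vein"), mk(7, "arcuate_vein"),
                  mk(9, "segmental_vein"), mk(11, "segmental_vein")]
        out = sample_vessel_velocities(tracks, k=3)
        assert out["arcuate_vein"] == pytest.approx(6.0)
        assert out["segmental_vein"] is None          # only 2 vessels -> excluded
        assert "segmental_artery" not in out          # absent class not reported


class TestDetectionRate:
    def test_printed_formula(self):
        assert mean_detections_per_frame(32400, 600.0, 54.0) == pytest.approx(1.0)

    def test_zero_detections(self):
        assert mean_detections_per_frame(0, 600.0, 54.0) == 0.0

    def test_inverse_proportionality_in_duration(self):
        r1 = mean_detections_per_frame(1000, 300.0, 54.0)
        r2 = mean_detections_per_frame(1000, 600.0, 54.0)
        assert r1 == pytest.approx(2 * r2)

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            mean_detections_per_frame(10, 0.0, 54.0)


def track_hitting_pixel_n_times(n, x_mm, frame0=0):
    """A >=3-frame track whose detections hit the pixel at (x_mm, 0) n times,
    padded with far-away filler detections to reach length 3."""
    xs = [x_mm] * n
    while len(xs) < 3:
        xs.append(x_mm + 0.1 * (len(xs) - n + 1))
    frames = np.arange(frame0, frame0 + len(xs))
    return Track(frames, np.stack([xs, np.zeros(len(xs))], axis=1), 54.0)


class TestRendering:
    def test_count_threshold_excludes_single_hits(self):
        # pixels hit 1, 2 and 3 times; only >1 survives
        tracks = [
            track_hitting_pixel_n_times(1, 1.0),
            track_hitting_pixel_n_times(2, 2.0),
            track_hitting_pixel_n_times(3, 3.0),
        ]
        img = render_srus_image(tracks)
        pix = img.pixel_um / 1000.0

        def count_and_kept(x):
            i = int(np.floor((x - img.origin_mm[0]) / pix))
            j = int(np.floor((0.0 - img.origin_mm[1]) / pix))
            return img.counts[i, j], bool(img.vascular[i, j])

        c1, k1 = count_and_kept(1.0)
        c2, k2 = count_and_kept(2.0)
        c3, k3 = count_and_kept(3.0)
        assert (c1, c2, c3) == (1, 2, 3)
        assert not k1 and k2 and k3

    def test_dilated_band_width_two_pixels(self):
        # straight horizontal kept track: 42.25 um diameter at 22.6 um pixels
        # -> ceil = 2 pixel wide band
        n = 40
        pos = np.stack([np.full(n, 1.0), 0.005 * np.arange(n)], axis=1)
        tracks = [Track(np.arange(n), pos, 54.0), Track(np.arange(n), pos, 54.0)]
        img = render_srus_image(tracks)
        cols = np.where(img.vascular.any(axis=1))[0]
        assert len(cols) == 2 and np.all(np.diff(cols) == 1)

    def test_empty_track_list_warns(self):
        with pytest.warns(UserWarning, match="no tracks"):
            img = render_srus_image([])
        assert not img.vascular.any()


class TestFRC:
    def test_frc_of_image_with_itself_is_one(self, rng):
        img = rng.poisson(3.0, (96, 96)).astype(float)
        _, frc, _ = frc_curve(img, img)
        assert np.allclose(frc, 1.0)

    def test_independent_noise_decorrelates(self, rng):
        a = rng.poisson(2.0, (128, 128)).astype(float)
        b = rng.poisson(2.0, (128, 128)).astype(float)
        _, frc, _ = frc_curve(a, b)
        assert np.mean(np.abs(frc[10:])) < 0.1

    def test_resolution_monotone_in_localization_blur(self):
        rng = np.random.default_rng(5)
        # points along fixed line structures, jittered with rising sigma
        base = []
        for z0 in np.linspace(0.5, 4.5, 9):
            x = np.linspace(0.2, 4.8, 400)
            base.append(np.stack([x, np.full_like(x, z0)], axis=1))
        base = np.vstack(base)
        resolutions = []
        for sigma in (0.005, 0.02, 0.08):
            pts = base + rng.normal(0, sigma, base.shape)
            df = pd.DataFrame({"frame": np.zeros(len(pts), int),
                               "x_mm": pts[:, 0], "z_mm": pts[:, 1]})
            res = estimate_resolution_frc(DetectionSequence(df, 54.0), shape=(256, 256))
            resolutions.append(res)
        assert resolutions[0] < resolutions[1] < resolutions[2]

    def test_too_few_detections_rejected(self):
        df = pd.DataFrame({"frame": [0, 1], "x_mm": [0.0, 1.0], "z_mm": [0.0, 1.0]})
        with pytest.raises(ValueError, match="detections"):
            estimate_resolution_frc(DetectionSequence(df, 54.0))


class TestDensity:
    @staticmethod
    def _image(vascular):
        from renovasc.srus import SRUSImage

        return SRUSImage(vascular.astype(int), vascular.astype(bool))

    def test_fully_vascular_roi(self):
        img = self._image(np.ones((10, 12)))
        assert srus_density(img, np.ones((10, 12), bool)) == 1.0

    def test_counting(self):
        vasc = np.zeros((12, 10), bool)
        vasc[:3, :] = True                      # 30 vascular pixels
        roi = np.ones((12, 10), bool)           # 120 ROI pixels
        assert srus_density(self._image(vasc), roi) == 0.25

    def test_disjoint_roi_is_zero(self):
        vasc = np.zeros((8, 8), bool)
        vasc[:2] = True
        roi = np.zeros((8, 8), bool)
        roi[6:] = True
        assert srus_density(self._image(vasc), roi) == 0.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            srus_density(self._image(np.ones((4, 4))), np.zeros((4, 4), bool))


class TestDensityRecovery:
    def test_tube_phantom_density_matches_voxel_oracle(self):
        """Saturating noiseless MB coverage of a tube reproduces the
        rasterized ground-truth density to within 1.5 pixel-widths."""
        from renovasc.grid import VolumeGrid
        from renovasc.synthgen import Branch, VesselTree, rasterize_tree

        pixel = 22.6 / 1000.0
        radius_mm = 0.3
        length = 6.0
        zc = 1.01          # off voxel boundaries so the rasterized edge is stable
        # shared analysis window in world coordinates
        xw = (0.5, 5.5)
        zw = (0.1, 1.9)

        # oracle: rasterize the tube in 3D, count voxels on the central plane
        vox = 0.02
        grid = VolumeGrid(
            np.zeros((int(7.0 / vox) + 1, 21, int(2.0 / vox) + 1)),
            np.full(3, 1000 * vox), np.array([-0.5, -0.2, 0.0]),
        )
        tube = Branch(np.array([[0.0, 0.0, zc], [length, 0.0, zc]]),
                      1000 * radius_mm, "segmental_vein", 1.0)
        vasc3d = rasterize_tree(VesselTree([tube]), grid)
        jc = int(round(0.2 / vox))
        xs3 = -0.5 + vox * np.arange(grid.shape[0])
        zs3 = vox * np.arange(grid.shape[2])
        win3 = np.ix_((xs3 >= xw[0]) & (xs3 <= xw[1]), (zs3 >= zw[0]) & (zs3 <= zw[1]))
        truth = vasc3d[:, jc, :][win3].mean()

        # saturating coverage: parallel MB paths across the lumen, two passes
        tracks = []
        n_lines = int(np.ceil(2 * radius_mm / pixel)) + 1
        xs = np.arange(0.0, length + 1e-9, 0.009)      # 0.5 mm/s at 54 Hz
        for z in np.linspace(zc - radius_mm, zc + radius_mm, n_lines):
            pos = np.stack([xs, np.full_like(xs, z)], axis=1)
            tracks.append(Track(np.arange(len(xs)), pos, 54.0))
            tracks.append(Track(np.arange(len(xs)), pos, 54.0))
        img = render_srus_image(
            tracks, origin_mm=np.array([-0.5, 0.0]),
            shape=(int(np.ceil(7.0 / pixel)), int(np.ceil(2.0 / pixel))),
        )
        xs2 = -0.5 + pixel * (np.arange(img.vascular.shape[0]) + 0.5)
        zs2 = pixel * (np.arange(img.vascular.shape[1]) + 0.5)
        roi2d = np.zeros(img.vascular.shape, bool)
        roi2d[np.ix_((xs2 >= xw[0]) & (xs2 <= xw[1]), (zs2 >= zw[0]) & (zs2 <= zw[1]))] = True
        measured = srus_density(img, roi2d)
        # 1.5 pixel-widths of band-width error over the ROI depth
        tol = 1.5 * pixel / (zw[1] - zw[0])
        assert measured == pytest.approx(truth, abs=tol)
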