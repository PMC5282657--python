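"""Stereo geometry: rectification, disparity, repair, triangulation."""

import numpy as np
import pytest

from stereoleaf import stereo, synth
from stereoleaf.stereo import (CameraRig, DisparityMap, StereoFrame, Validity,
                               spatial_resolution)


def _checkerboard(shape=(240, 320), square=20):
    rows, cols = np.indices(shape)
    board = (((rows // square) + (cols // square)) % 2 * 255).astype(np.uint8)
    return board


def _rotation_homography(angle_deg, center):
    t = np.radians(angle_deg)
    cx, cy = center
    c, s = np.cos(t), np.sin(t)
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    to = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    back = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    return back @ rot @ to


class TestCameraRig:
    def test_validation(self):
        with pytest.raises(ValueError):
            CameraRig(-1, 0.1, (160, 120), (320, 240))
        with pytest.raises(ValueError):
            CameraRig(400, 0.0, (160, 120), (320, 240))

    def test_json_round_trip(self, tmp_path, test_rig):
        path = tmp_path / "rig.json"
        test_rig.to_json(path)
        loaded = CameraRig.from_json(path)
        assert loaded.focal_px == test_rig.focal_px
        assert loaded.baseline_m == test_rig.baseline_m
        assert np.allclose(loaded.rectifying_transform[0],
                           test_rig.rectifying_transform[0])

    def test_spatial_resolution_arithmetic(self):
        assert round(spatial_resolution(449.9, 2056), 4) == 0.2188


class TestRectifyPair:
    def test_identity_transforms_leave_images_unchanged(self, test_rig):
        img = _checkerboard()
        frame = StereoFrame(img, img.copy(), test_rig, rectified=False)
        out = stereo.rectify_pair(frame)
        assert out.rectified
        assert np.array_equal(out.left_image, img)
        assert np.array_equal(out.right_image, img)

    def test_refuses_already_rectified(self, test_rig):
        img = _checkerboard()
        frame = StereoFrame(img, img, test_rig, rectified=True)
        with pytest.raises(ValueError, match="already rectified"):
            stereo.rectify_pair(frame)

    def test_derotation_restores_row_alignment(self):
        """A 2-degree roll of the right camera is undone by its homography."""
        from skimage.feature import corner_harris, corner_peaks, corner_subpix
        from skimage.transform import ProjectiveTransform, warp

        left = _checkerboard()
        center = (160, 120)
        H_roll = _rotation_homography(2.0, center)
        rolled = warp(left.astype(float), ProjectiveTransform(H_roll).inverse,
                      order=1, cval=0)
        rig = CameraRig(400, 0.08, center, (320, 240),
                        rectifying_transform=(np.eye(3), np.linalg.inv(H_roll)))
        frame = StereoFrame(left, rolled.astype(np.uint8), rig, rectified=False)

        def corner_rows(img):
            img = np.asarray(img, dtype=float)
            c = corner_peaks(corner_harris(img), min_distance=10,
                             threshold_rel=0.2)
            sub = corner_subpix(img, c, window_size=9)
            ok = np.isfinite(sub).all(axis=1)
            return sub[ok]

        before = corner_rows(rolled)
        ref = corner_rows(left)
        out = stereo.rectify_pair(frame)
        after = corner_rows(out.right_image)
        # match corners to reference by nearest neighbour and compare rows
        def max_row_gap(a, b):
            gaps = []
            for p in a:
                q = b[np.argmin(np.hypot(*(b - p).T))]
                gaps.append(abs(p[0] - q[0]))
            return max(gaps)
        assert max_row_gap(ref[4:-4], before) > 2.0
        assert max_row_gap(ref[4:-4], after) < 0.5

    def test_singular_transform_rejected(self, test_rig):
        img = _checkerboard()
        rig = CameraRig(400, 0.08, (160, 120), (320, 240),
                        rectifying_transform=(np.eye(3), np.zeros((3, 3))))
        frame = StereoFrame(img, img, rig, rectified=False)
        with pytest.raises(ValueError, match="invertible"):
            stereo.rectify_pair(frame)


class TestComputeDisparity:
    def test_fronto_parallel_plane_median_disparity(self, test_rig):
        z0 = 1.0
        spec = synth.SurfaceSpec(kind="plane", z0=z0, extent=0.5, texture_seed=3)
        frame, truth = synth.render_stereo(spec, test_rig)
        dmap = stereo.compute_disparity(frame, truth["mask"], d_range=(0, 60))
        valid = dmap.valid_mask()
        assert valid.sum() > 0.25 * truth["mask"].sum()
        expected = test_rig.focal_px * test_rig.baseline_m / z0
        assert abs(np.median(dmap.values[valid]) - expected) < 0.5

    def test_textureless_pair_is_mismatch(self, test_rig):
        gray = np.full((240, 320), 127, dtype=np.uint8)
        frame = StereoFrame(gray, gray.copy(), test_rig, rectified=True)
        fg = np.zeros((240, 320), dtype=bool)
        fg[40:200, 40:280] = True
        dmap = stereo.compute_disparity(frame, fg, d_range=(0, 40))
        flagged = (dmap.validity == Validity.MISMATCH)[fg].mean()
        assert flagged >= 0.9

    def test_empty_foreground_all_background(self, test_rig):
        img = _checkerboard()
        frame = StereoFrame(img, img, test_rig, rectified=True)
        dmap = stereo.compute_disparity(frame, np.zeros((240, 320), bool))
        assert (dmap.validity == Validity.BACKGROUND).all()
        assert not dmap.valid_mask().any()

    def test_unrectified_frame_rejected(self, test_rig):
        img = _checkerboard()
        frame = StereoFrame(img, img, test_rig, rectified=False)
        with pytest.raises(ValueError, match="rectified"):
            stereo.compute_disparity(frame, np.ones((240, 320), bool))


def _plane_disparity_fixture(shape=(120, 160), d0=20.0, slope=0.05):
    rows, cols = np.indices(shape)
    values = d0 + slope * cols
    validity = np.full(shape, int(Validity.VALID), dtype=np.uint8)
    return values, validity


class TestRepairDisparity:
    def test_hole_refilled_from_plane(self):
        values, validity = _plane_disparity_fixture()
        labels = np.ones(values.shape, dtype=int)
        truth = values.copy()
        validity[50:70, 60:80] = Validity.MISMATCH
        values[50:70, 60:80] = 0.0
        out = stereo.repair_disparity(DisparityMap(values, validity), labels)
        assert out.valid_mask().all()
        assert np.abs(out.values[50:70, 60:80] - truth[50:70, 60:80]).max() < 0.5

    def test_fully_valid_map_unchanged(self):
        values, validity = _plane_disparity_fixture()
        labels = np.ones(values.shape, dtype=int)
        out = stereo.repair_disparity(DisparityMap(values, validity), labels)
        assert np.array_equal(out.values, values)
        assert np.array_equal(out.validity, validity)

    def test_repair_respects_leaf_boundaries(self):
        """A hole on leaf A interpolates from A's plane, never from B's."""
        shape = (100, 160)
        labels = np.zeros(shape, dtype=int)
        labels[:, :80] = 1   # leaf A: disparity 30
        labels[:, 80:] = 2   # leaf B: disparity 10
        values = np.where(labels == 1, 30.0, 10.0)
        validity = np.where(labels > 0, int(Validity.VALID),
                            int(Validity.BACKGROUND)).astype(np.uint8)
        validity[40:60, 70:80] = Validity.MISMATCH  # hole on A, adjacent to B
        values[40:60, 70:80] = 0.0
        out = stereo.repair_disparity(DisparityMap(values, validity), labels)
        hole = out.values[40:60, 70:80]
        err_a = np.abs(hole - 30.0).max()
        err_b = np.abs(hole - 10.0).min()
        assert err_a < 1e-6
        assert err_b > 10  # nowhere near leaf B's plane
        # previously valid pixels untouched
        assert (out.values[labels == 2] == 10.0).all()

    def test_leaf_without_valid_pixels_warns(self):
        values = np.zeros((50, 50))
        validity = np.full((50, 50), int(Validity.MISMATCH), dtype=np.uint8)
        labels = np.ones((50, 50), dtype=int)
        with pytest.warns(UserWarning, match="unreconstructable"):
            out = stereo.repair_disparity(DisparityMap(values, validity), labels)
        assert not out.valid_mask().any()


class TestTriangulate:
    def test_closed_form_depth(self, test_rig):
        rig = CameraRig(1000.0, 0.1, (160, 120), (320, 240))
        values = np.zeros((240, 320))
        validity = np.zeros((240, 320), dtype=np.uint8)
        labels = np.zeros((240, 320), dtype=int)
        values[100, 200] = 50.0
        validity[100, 200] = Validity.VALID
        labels[100, 200] = 1
        cloud = stereo.triangulate(DisparityMap(values, validity), rig, labels)
        assert cloud.points[0, 2] == pytest.approx(2.0)

    def test_doubling_disparity_halves_depth(self, test_rig):
        values, validity = _plane_disparity_fixture(shape=(240, 320))
        labels = np.ones((240, 320), dtype=int)
        c1 = stereo.triangulate(DisparityMap(values, validity), test_rig, labels)
        c2 = stereo.triangulate(DisparityMap(2 * values, validity), test_rig, labels)
        assert np.allclose(c2.points[:, 2], c1.points[:, 2] / 2)

    def test_projection_round_trip(self, test_rig):
        """Project grid pixels to 3-D and re-project: exact to 1e-6 m."""
        rng = np.random.default_rng(8)
        w, h = test_rig.image_size
        f = test_rig.focal_px
        cx, cy = test_rig.principal_point
        values = np.zeros((h, w))
        validity = np.zeros((h, w), dtype=np.uint8)
        labels = np.zeros((h, w), dtype=int)
        pix = [(int(r), int(c)) for r, c in
               zip(rng.integers(0, h, 50), rng.integers(0, w, 50))]
        z_true = {}
        for r, c in pix:
            z = rng.uniform(0.4, 2.5)
            values[r, c] = f * test_rig.baseline_m / z
            validity[r, c] = Validity.VALID
            labels[r, c] = 1
            z_true[(r, c)] = z
        cloud = stereo.triangulate(DisparityMap(values, validity), test_rig, labels)
        for (x, y, z), (r, c) in zip(cloud.points, cloud.source_pixel):
            assert abs(z - z_true[(r, c)]) < 1e-6
            # re-project through the pinhole model
            assert abs(f * x / z + cx - c) < 1e-6
            assert abs(f * y / z + cy - r) < 1e-6

    def test_zero_disparity_skipped_with_warning(self, test_rig):
        values = np.zeros((240, 320))
        validity = np.zeros((240, 320), dtype=np.uint8)
        labels = np.zeros((240, 320), dtype=int)
        validity[10, 10] = Validity.VALID
        labels[10, 10] = 1
        with pytest.warns(UserWarning, match="non-positive disparity"):
            cloud = stereo.triangulate(DisparityMap(values, validity),
                                       test_rig, labels)
        assert len(cloud) == 0


def test_depth_ordering_of_two_planes(test_rig):
    """The plane with larger disparity lies strictly closer to the camera."""
    labels = np.ones((240, 320), dtype=int)
    validity = np.full((240, 320), int(Validity.VALID), dtype=np.uint8)
    near = stereo.triangulate(
        DisparityMap(np.full((240, 320), 40.0), validity), test_rig, labels)
    far = stereo.triangulate(
        DisparityMap(np.full((240, 320), 20.0), validity), test_rig, labels)
    assert (near.points[:, 2] < far.points[:, 2]).all()
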