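"""Canonical ROI frame, 161-point correspondence, piecewise-affine warp."""
import numpy as np
import pytest
from skimage.transform import AffineTransform, warp as sk_warp

import petalign as pa
from petalign.errors import ConfigError, InputError
from petalign.frame import FrameConfig, correspondence_residuals

R, H = 128, 64


def _frame_shaped_annotation():
    """An annotation whose anatomy coincides with the frame geometry."""
    th = np.linspace(np.pi, 0, 181)
    arc = np.column_stack([R + R * np.cos(th), R - R * np.sin(th)])
    contour = np.vstack(
        [
            arc,
            [[2 * R, R + H]],
            [[0, R + H]],
        ]
    )
    y_side = R - R * np.sqrt(1 - 0.25)
    return pa.AnatomicalAnnotation(
        specimen_id="frame",
        frame_of_reference="fresh",
        lobe_contour=contour,
        midvein=np.array([[R, 0], [R, R + H]], float),
        sidevein_left=np.array([[R / 2, y_side], [R / 2, R + H]], float),
        sidevein_right=np.array([[3 * R / 2, y_side], [3 * R / 2, R + H]], float),
        tube_boundary_left=np.array([[0, R], [0, R + H]], float),
        tube_boundary_right=np.array([[2 * R, R], [2 * R, R + H]], float),
        rim_endpoints=np.array([[0, R], [2 * R, R]], float),
    )


class TestBuildFrame:
    def test_default_frame_layout(self, frame):
        assert len(frame.destination_points) == 161
        assert frame.shape == (R + H, 2 * R)
        apex = frame.points_of("contour_arc")[30]
        assert np.allclose(apex, [R, 0])
        assert frame.group_counts == {
            "contour_arc": 61, "midvein": 26, "sidevein_left": 22,
            "sidevein_right": 22, "tube_boundary_left": 15,
            "tube_boundary_right": 15,
        }

    def test_counts_must_sum_to_161(self):
        with pytest.raises(ConfigError, match="161"):
            pa.build_frame(FrameConfig(group_counts=(60, 26, 22, 22, 15, 15)))

    def test_left_right_mirror_symmetry(self, frame):
        # reflect-and-compare oracle: mirroring about x = R must swap the
        # left and right point sets exactly
        for left, right in [
            ("sidevein_left", "sidevein_right"),
            ("tube_boundary_left", "tube_boundary_right"),
        ]:
            l, r = frame.points_of(left), frame.points_of(right)
            mirrored = np.column_stack([2 * R - r[:, 0], r[:, 1]])
            assert np.allclose(l, mirrored)
        arc = frame.points_of("contour_arc")
        mirrored = np.column_stack([2 * R - arc[::-1, 0], arc[::-1, 1]])
        assert np.allclose(arc, mirrored, atol=1e-9)

    def test_minimum_size_enforced(self):
        with pytest.raises(ConfigError):
            pa.build_frame(FrameConfig(radius_px=8))

    def test_points_inside_frame(self, frame):
        pts = frame.destination_points
        assert (pts[:, 0] >= 0).all() and (pts[:, 0] <= 2 * R).all()
        assert (pts[:, 1] >= 0).all() and (pts[:, 1] <= R + H).all()


class TestResampleSources:
    def test_frame_shaped_annotation_is_fixed_point(self, frame):
        corr = pa.resample_sources(_frame_shaped_annotation(), frame)
        err = np.linalg.norm(
            corr.source_points - corr.destination_points, axis=1
        )
        assert err.max() <= 0.5

    def test_reversed_vein_gives_identical_sources(self, frame):
        ann = _frame_shaped_annotation()
        corr1 = pa.resample_sources(ann, frame)
        ann.midvein = ann.midvein[::-1].copy()
        ann.sidevein_left = ann.sidevein_left[::-1].copy()
        corr2 = pa.resample_sources(ann, frame)
        assert np.allclose(corr1.source_points, corr2.source_points)

    def test_requires_fresh_frame_of_reference(self, frame, distal_specimen):
        with pytest.raises(InputError, match="fresh"):
            pa.resample_sources(distal_specimen.truth_annotation_hist, frame)


class TestWarp:
    def test_identity_warp_reproduces_crop(self, frame):
        rng = np.random.default_rng(0)
        base = rng.integers(60, 200, (R + H + 2, 2 * R + 2, 3)).astype(np.uint8)
        # smooth the noise so bilinear resampling at integer coords is exact
        corr = pa.PointCorrespondence(
            source_points=frame.destination_points.copy(),
            destination_points=frame.destination_points,
            groups=frame.groups,
        )
        roi = pa.warp_to_roi(base, corr, frame)
        m = roi.validity_mask
        diff = np.abs(
            roi.pixels[m].astype(int) - base[: R + H, : 2 * R][m].astype(int)
        )
        assert diff.max() <= 1

    def test_global_affine_sources_match_direct_resampling(self, frame):
        # oracle: skimage's own affine warp of the same image
        A = AffineTransform(
            rotation=np.deg2rad(9), scale=1.25, translation=(40, 30)
        )
        dest = frame.destination_points
        src = A(dest)
        yy, xx = np.mgrid[0:500, 0:500]
        img = (
            120
            + 60 * np.sin(xx / 23.0)
            + 50 * np.cos(yy / 31.0)
        )
        img3 = np.clip(np.stack([img] * 3, axis=2), 0, 255).astype(np.uint8)
        corr = pa.PointCorrespondence(
            source_points=src, destination_points=dest, groups=frame.groups
        )
        roi = pa.warp_to_roi(img3, corr, frame, method="piecewise")
        oracle = sk_warp(
            img, A, output_shape=frame.shape, order=1, preserve_range=True
        )
        m = roi.validity_mask
        rms = np.sqrt(np.mean((roi.pixels[:, :, 0][m].astype(float) - oracle[m]) ** 2))
        assert rms <= 1.0

    def test_exact_interpolation_at_all_correspondences(self, frame):
        ann = _frame_shaped_annotation()
        corr = pa.resample_sources(ann, frame)
        res = correspondence_residuals(corr)
        assert res.max() <= 0.5

    def test_warp_is_deterministic(self, frame, distal_specimen):
        t = pa.estimate_transform(distal_specimen.control_points)
        ann = pa.map_annotation(distal_specimen.truth_annotation_hist, t)
        corr = pa.resample_sources(ann, frame)
        r1 = pa.warp_to_roi(distal_specimen.fresh_image, corr, frame)
        r2 = pa.warp_to_roi(distal_specimen.fresh_image, corr, frame)
        assert (r1.pixels == r2.pixels).all()
        assert (r1.validity_mask == r2.validity_mask).all()

    def test_source_outside_image_rejected(self, frame):
        corr = pa.PointCorrespondence(
            source_points=frame.destination_points + 500.0,
            destination_points=frame.destination_points,
            groups=frame.groups,
        )
        img = np.zeros((R + H, 2 * R, 3), np.uint8)
        with pytest.raises(InputError, match="outside"):
            pa.warp_to_roi(img, corr, frame)

    def test_validity_mask_covers_frame_interior(self, frame, distal_specimen):
        t = pa.estimate_transform(distal_specimen.control_points)
        ann = pa.map_annotation(distal_specimen.truth_annotation_hist, t)
        corr = pa.resample_sources(ann, frame)
        roi = pa.warp_to_roi(distal_specimen.fresh_image, corr, frame)
        interior = frame.frame_mask()
        assert (roi.validity_mask & interior).sum() >= 0.9 * interior.sum()
        # pixels outside the mask are zeroed
        assert roi.pixels[~roi.validity_mask].max() == 0
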