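"""FOV detection, moment-ellipse geometry, color constancy and resizing."""

import numpy as np
import pytest

from dermpipe import (
    ColorConstancyParams,
    CropHeuristicParams,
    EllipseParams,
    FovBox,
    ImageRecord,
    NoFieldOfViewError,
    PreprocessParams,
    SyntheticImageSpec,
    auto_crop,
    binarize_fov,
    ellipse_to_bbox,
    fit_fov_ellipse,
    gen_dermoscopy_image,
    needs_cropping,
    preprocess,
    resize_longer_side,
    shades_of_gray,
)

from conftest import random_disk_spec


def disk_mask(h, w, cx, cy, r):
    ys = np.arange(h)[:, None] + 0.5
    xs = np.arange(w)[None, :] + 0.5
    return (((xs - cx) ** 2 + (ys - cy) ** 2) <= r * r).astype(np.uint8)


class TestBinarize:
    def test_all_bright_and_all_dark(self):
        assert binarize_fov(np.full((5, 5, 3), 200, np.uint8), 20).all()
        assert not binarize_fov(np.zeros((5, 5, 3), np.uint8), 20).any()

    def test_disk_image_mask_matches_analytic_disk(self, rng):
        spec = random_disk_spec(rng)
        rec, _ = gen_dermoscopy_image(spec)
        mask = binarize_fov(rec.image, 20)
        cx, cy = spec.center
        truth = disk_mask(spec.height, spec.width, cx, cy, spec.fov_radius)
        inter = np.logical_and(mask, truth).sum()
        union = np.logical_or(mask, truth).sum()
        assert inter / union >= 0.99

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            binarize_fov(np.zeros((0, 0, 3), np.uint8))


class TestFitEllipse:
    def test_centered_disk_recovers_radius(self):
        for r in (40, 80, 120):
            e = fit_fov_ellipse(disk_mask(300, 300, 150, 150, r))
            assert abs(e.a - r) / r < 0.015
            assert abs(e.b - r) / r < 0.015
            assert abs(e.cx - 150) < 0.5 and abs(e.cy - 150) < 0.5

    def test_full_frame_rectangle(self):
        # uniform segment of length L has second central moment L^2/12,
        # so the equal-moments semi-axis is 2 L / sqrt(12) = L / sqrt(3)
        e = fit_fov_ellipse(np.ones((90, 120), np.uint8))
        assert abs(e.a - 120 / np.sqrt(3)) < 0.1
        assert abs(e.b - 90 / np.sqrt(3)) < 0.1

    def test_translation_equivariance(self):
        base = np.zeros((200, 260), np.uint8)
        base[40:120, 30:150] = 1
        e1 = fit_fov_ellipse(base)
        shifted = np.roll(np.roll(base, 37, axis=0), 52, axis=1)
        e2 = fit_fov_ellipse(shifted)
        assert np.isclose(e2.cx - e1.cx, 52) and np.isclose(e2.cy - e1.cy, 37)
        assert np.isclose(e1.a, e2.a) and np.isclose(e1.b, e2.b)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(NoFieldOfViewError):
            fit_fov_ellipse(np.zeros((10, 10), np.uint8))
        line = np.zeros((10, 10), np.uint8)
        line[5, 2:9] = 1
        with pytest.raises(NoFieldOfViewError):
            fit_fov_ellipse(line)


class TestEllipseToBbox:
    def test_circle(self):
        e = EllipseParams(cx=300, cy=225, a=200, b=200, theta=0.3)
        box = ellipse_to_bbox(e, (450, 600))
        assert (box.x0, box.y0, box.x1, box.y1) == (100, 25, 500, 425)

    def test_axis_aligned_ellipse(self):
        e = EllipseParams(cx=200, cy=200, a=100, b=50, theta=0.0)
        box = ellipse_to_bbox(e, (400, 400))
        assert (box.x0, box.y0, box.x1, box.y1) == (100, 150, 300, 250)

    def test_rotated_ellipse_box_contains_all_foreground(self, rng):
        for _ in range(20):
            cx, cy = rng.uniform(120, 180, size=2)
            a, b = sorted(rng.uniform(20, 80, size=2))[::-1]
            theta = rng.uniform(-np.pi / 2, np.pi / 2)
            ys = np.arange(300)[:, None] + 0.5
            xs = np.arange(300)[None, :] + 0.5
            c, s = np.cos(theta), np.sin(theta)
            u = (xs - cx) * c + (ys - cy) * s
            v = -(xs - cx) * s + (ys - cy) * c
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1
            box = ellipse_to_bbox(EllipseParams(cx, cy, a, b, theta), (300, 300))
            yy, xx = np.nonzero(mask)
            assert (xx >= box.x0).all() and (xx < box.x1).all()
            assert (yy >= box.y0).all() and (yy < box.y1).all()


class TestCropHeuristic:
    def test_uniform_image_never_needs_cropping(self):
        img = np.full((100, 100, 3), 150, np.uint8)
        assert not needs_cropping(img, FovBox(10, 10, 90, 90))
        # box covering the whole image: no outside region
        assert not needs_cropping(img, FovBox(0, 0, 100, 100))

    def test_disk_image_needs_cropping(self, disk_image):
        rec, box, _ = disk_image
        assert needs_cropping(rec.image, box)


class TestAutoCrop:
    def test_recovery_on_disk_images(self, rng):
        hits = 0
        n = 40
        for _ in range(n):
            rec, box = gen_dermoscopy_image(random_disk_spec(rng))
            _, rbox, cropped = auto_crop(rec.image)
            if cropped and max(abs(rbox.x0 - box.x0), abs(rbox.y0 - box.y0),
                               abs(rbox.x1 - box.x1), abs(rbox.y1 - box.y1)) <= 3:
                hits += 1
        assert hits >= 0.95 * n

    def test_full_frame_left_unchanged(self):
        rec, _ = gen_dermoscopy_image(SyntheticImageSpec(200, 150, fov_radius=0, seed=5))
        out, box, cropped = auto_crop(rec.image)
        assert not cropped and box is None
        assert np.array_equal(out, rec.image)

    def test_all_black_image_is_a_no_crop_with_warning(self, caplog):
        img = np.zeros((50, 50, 3), np.uint8)
        with caplog.at_level("WARNING"):
            out, box, cropped = auto_crop(img)
        assert not cropped and box is None
        assert np.array_equal(out, img)
        assert any("no field of view" in r.message for r in caplog.records)

    def test_second_crop_is_stable(self, disk_image):
        rec, _, _ = disk_image
        out1, box1, cropped1 = auto_crop(rec.image)
        assert cropped1
        out2, box2, cropped2 = auto_crop(out1)
        area1 = out1.shape[0] * out1.shape[1]
        area2 = out2.shape[0] * out2.shape[1]
        assert area2 >= 0.99 * area1


class TestShadesOfGray:
    def test_achromatic_uniform_image_is_fixed_point(self):
        img = np.full((40, 40, 3), 117, np.uint8)
        assert np.array_equal(shades_of_gray(img), img)

    def test_uniform_color_becomes_achromatic(self):
        img = np.zeros((30, 30, 3), np.float64)
        img[:] = (120.0, 60.0, 180.0)
        out = shades_of_gray(img)
        assert np.allclose(out[..., 0], out[..., 1])
        assert np.allclose(out[..., 1], out[..., 2])
        assert np.allclose(out[..., 0], 120.0)  # gain preserves mean illuminant

    def test_minkowski_means_equalized(self, rng):
        # float images far from the clipping range
        p = 6.0
        for _ in range(10):
            img = rng.uniform(50, 150, size=(60, 80, 3))
            img[..., 0] *= 1.2
            img[..., 2] *= 0.85
            out = shades_of_gray(img, ColorConstancyParams(p_minkowski=p))
            e = np.power(np.mean(np.power(out, p), axis=(0, 1)), 1 / p)
            assert np.ptp(e) / e.mean() < 1e-4

    def test_zero_channel_left_unchanged_with_warning(self):
        img = np.zeros((20, 20, 3), np.float64)
        img[..., 0] = 100.0
        with pytest.warns(UserWarning, match="identically zero"):
            out = shades_of_gray(img)
        assert np.allclose(out[..., 1], 0)
        assert np.allclose(out[..., 2], 0)


class TestResize:
    @pytest.mark.parametrize(
        "shape,expected",
        [((1024, 1024), (600, 600)), ((900, 1200), (450, 600)), ((300, 400), (300, 400))],
    )
    def test_longer_side_examples(self, shape, expected):
        img = np.random.default_rng(0).integers(0, 255, size=shape + (3,), dtype=np.uint8)
        assert resize_longer_side(img).shape[:2] == expected

    def test_idempotent(self, rng):
        img = rng.integers(0, 255, size=(800, 700, 3), dtype=np.uint8)
        once = resize_longer_side(img)
        assert np.array_equal(resize_longer_side(once), once)


class TestFullChain:
    def test_disk_image_cropped_and_resized(self, rng):
        spec = random_disk_spec(rng, width=1024, height=1024)
        rec, box = gen_dermoscopy_image(spec)
        out = preprocess(rec, PreprocessParams())
        assert out.cropped and out.preprocessed
        assert max(out.image.shape[:2]) == min(600, max(box.height, box.width))

    def test_full_frame_small_gray_image_unchanged(self):
        img = np.full((450, 600, 3), 120, np.uint8)
        rec = ImageRecord(image=img, image_id="flat")
        out = preprocess(rec)
        assert not out.cropped
        assert np.array_equal(out.image, img)

    def test_batch_cropped_count_matches_fov_bookkeeping(self, rng):
        n_fov, n_flat = 12, 8
        records = []
        for _ in range(n_fov):
            rec, _ = gen_dermoscopy_image(random_disk_spec(rng, width=240, height=180))
            records.append(rec)
        for _ in range(n_flat):
            rec, _ = gen_dermoscopy_image(
                SyntheticImageSpec(240, 180, fov_radius=0, seed=int(rng.integers(2**31))))
            records.append(rec)
        cropped = [preprocess(r).cropped for r in records]
        assert sum(cropped) == n_fov
        assert not any(cropped[n_fov:])
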