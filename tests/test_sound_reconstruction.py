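import numpy as np
import pytest

from qlfloss import (
    FluorescenceImage,
    PolygonROI,
    interpolate_polygon,
    interpolate_rectangle,
    rasterize,
    smoothed_border_values,
)
from qlfloss.errors import GeometryError

from conftest import random_star_polygon


def rectangle_oracle(px, rect):
    """Direct scalar transcription of the two-step interpolation equations."""
    x0, y0, x1, y1 = rect
    out = np.full(px.shape, np.nan)
    for y in range(y0 + 1, y1):
        for x in range(x0 + 1, x1):
            lg, lh = px[y, x0], px[y, x1]
            lmx = lg + (lh - lg) * (x - x0) / (x1 - x0)
            le_i = px[y0, x0] + (px[y0, x1] - px[y0, x0]) * (x - x0) / (x1 - x0)
            lf_i = px[y1, x0] + (px[y1, x1] - px[y1, x0]) * (x - x0) / (x1 - x0)
            dle = px[y0, x] - le_i
            dlf = px[y1, x] - lf_i
            lmy = dle + (dlf - dle) * (y - y0) / (y1 - y0)
            out[y, x] = lmx + lmy
    return out


def polygon_loss(image, roi):
    raster = rasterize(roi, image.height, image.width)
    return interpolate_polygon(image, raster, smoothed_border_values(image, raster))


def test_constant_field_reproduced_exactly(constant_image, quad_roi):
    loss = polygon_loss(constant_image, quad_roi)
    assert np.nanmax(np.abs(loss.delta)) == 0.0
    assert np.nanmax(np.abs(loss.percent)) == 0.0
    rect = interpolate_rectangle(constant_image, (2, 2, 15, 15))
    assert np.nanmax(np.abs(rect.delta)) == 0.0


def test_affine_field_exact_for_rectangle_and_polygon(affine_image, quad_roi):
    ys, xs = np.mgrid[0:20, 0:20]
    plane = 5.0 + 2.0 * xs + 3.0 * ys
    rect = interpolate_rectangle(affine_image, (3, 4, 14, 12))
    m = rect.valid_mask
    np.testing.assert_allclose(rect.sound[m], plane[m], rtol=1e-12)
    poly = polygon_loss(affine_image, quad_roi)
    np.testing.assert_allclose(poly.sound[poly.valid_mask], plane[poly.valid_mask], rtol=1e-12)


def test_gaussian_dip_recovers_plane_and_loss():
    ys, xs = np.mgrid[0:26, 0:26]
    plane = 50.0 + 1.5 * xs + 0.5 * ys
    dip = 30.0 * np.exp(-(((xs - 12) ** 2 + (ys - 12) ** 2) / (2 * 1.8**2)))
    img = FluorescenceImage(plane - dip)
    loss = interpolate_rectangle(img, (2, 2, 23, 23))
    m = loss.valid_mask
    # anchors are >= 10 px from the dip center, where the Gaussian is ~1e-6
    np.testing.assert_allclose(loss.sound[m], plane[m], atol=1e-3)
    assert loss.delta[12, 12] == pytest.approx(30.0, abs=1e-3)
    expected_pct = 100.0 * 30.0 / plane[12, 12]
    assert loss.percent[12, 12] == pytest.approx(expected_pct, abs=1e-3)


def test_production_matches_scalar_oracle_on_random_images():
    rng = np.random.default_rng(7)
    for _ in range(10):
        px = rng.uniform(1.0, 255.0, size=(16, 16))
        rect = (1, 2, 13, 14)
        got = interpolate_rectangle(FluorescenceImage(px), rect)
        want = rectangle_oracle(px, rect)
        m = got.valid_mask
        np.testing.assert_allclose(got.sound[m], want[m], rtol=1e-9)


def test_polygon_reduces_to_rectangle_on_constant_border_field():
    # constant everywhere except strictly inside the ROI: smoothing is a no-op
    # on the border ring, so the polygon form must equal the reference form
    px = np.full((20, 20), 100.0)
    rng = np.random.default_rng(3)
    px[7:12, 7:12] = rng.uniform(40.0, 100.0, size=(5, 5))
    img = FluorescenceImage(px)
    rect = interpolate_rectangle(img, (4, 4, 15, 15))
    roi = PolygonROI(np.array([[4, 4], [15, 4], [15, 15], [4, 15]], dtype=float))
    poly = polygon_loss(img, roi)
    np.testing.assert_array_equal(poly.valid_mask, rect.valid_mask)
    m = poly.valid_mask
    np.testing.assert_allclose(poly.percent[m], rect.percent[m], rtol=1e-12)


def test_anchor_locality_interior_edits_do_not_move_sound_map(quad_roi):
    rng = np.random.default_rng(11)
    px = rng.uniform(50.0, 200.0, size=(20, 20))
    img_a = FluorescenceImage(px)
    raster = rasterize(quad_roi, 20, 20)
    # perturb pixels strictly interior to the ROI, >1 px from the border so
    # the 3x3 smoothing windows of border pixels are untouched
    from scipy import ndimage

    deep = raster.interior_mask & ~ndimage.binary_dilation(raster.border_mask, iterations=2)
    assert deep.any()
    px_b = px.copy()
    px_b[deep] = rng.uniform(1.0, 30.0, size=int(deep.sum()))
    img_b = FluorescenceImage(px_b)
    loss_a = interpolate_polygon(img_a, raster, smoothed_border_values(img_a, raster))
    loss_b = interpolate_polygon(img_b, raster, smoothed_border_values(img_b, raster))
    m = loss_a.valid_mask
    np.testing.assert_allclose(loss_a.sound[m], loss_b.sound[m], rtol=1e-12)


def test_scale_equivariance(quad_roi):
    rng = np.random.default_rng(5)
    px = rng.uniform(10.0, 250.0, size=(20, 20))
    img = FluorescenceImage(px)
    scaled = FluorescenceImage(3.5 * px)
    a = polygon_loss(img, quad_roi)
    b = polygon_loss(scaled, quad_roi)
    m = a.valid_mask
    np.testing.assert_allclose(b.sound[m], 3.5 * a.sound[m], rtol=1e-12)
    np.testing.assert_allclose(b.delta[m], 3.5 * a.delta[m], rtol=1e-9)
    np.testing.assert_allclose(b.percent[m], a.percent[m], rtol=1e-9)


def test_affine_exactness_on_random_polygons():
    rng = np.random.default_rng(2024)
    ys, xs = np.mgrid[0:24, 0:24]
    for _ in range(20):
        a, bx, by = rng.uniform(20, 80), rng.uniform(-2, 2), rng.uniform(-2, 2)
        plane = a + bx * xs + by * ys
        plane -= plane.min() - 1.0  # keep intensities positive
        img = FluorescenceImage(plane)
        roi = random_star_polygon(rng, center=(11.5, 11.5), r_min=5.0, r_max=9.5)
        loss = polygon_loss(img, roi)
        scale = np.abs(plane).max()
        assert np.nanmax(np.abs(loss.delta)) <= 1e-9 * scale


def test_degenerate_rectangle_rejected(constant_image):
    with pytest.raises(GeometryError):
        interpolate_rectangle(constant_image, (2, 2, 3, 10))
    with pytest.raises(GeometryError):
        interpolate_rectangle(constant_image, (2, 2, 30, 10))


def test_nonpositive_sound_pixels_flagged_invalid():
    # force a negative reconstruction: bright border column, dark elsewhere
    px = np.full((9, 9), 50.0)
    px[0, :] = 200.0  # top edge much brighter -> residual interpolation can
    px[8, :] = 1.0    # push reconstructed values below zero near the bottom
    img = FluorescenceImage(px)
    loss = interpolate_rectangle(img, (1, 0, 7, 8))
    mask = ~np.isnan(loss.sound)
    if (loss.sound[mask] <= 0).any():
        bad = mask & (loss.sound <= 0)
        assert not loss.valid_mask[bad].any()
        assert np.isnan(loss.percent[bad]).all()
    # percent is always finite on valid pixels
    assert np.isfinite(loss.percent[loss.valid_mask]).all()


def test_loss_map_csv_export(tmp_path, affine_image, quad_roi):
    loss = polygon_loss(affine_image, quad_roi)
    df = loss.to_dataframe(observed=affine_image.pixels)
    assert set(df.columns) == {"x", "y", "sound", "delta", "percent", "observed"}
    assert len(df) == int(loss.valid_mask.sum())
    np.testing.assert_allclose(df["delta"], df["sound"] - df["observed"], rtol=1e-12)
    out = tmp_path / "loss.csv"
    loss.to_csv(out)
    assert out.exists() and out.stat().st_size > 0
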