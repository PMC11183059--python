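import numpy as np
import pytest
import tifffile
from shapely.geometry import Polygon

from dugongrisk.geo import (
    DomainError,
    Grid,
    GridTransform,
    PolygonSet,
    align_to_template,
    masked_area,
    minmax_normalize,
    rasterize,
    read_grid,
    read_polygons,
    write_grid,
    write_polygons,
)
from tests.conftest import make_grid


@pytest.mark.parametrize("fmt,suffix", [("ascii", ".asc"), ("geotiff", ".tif")])
def test_raster_round_trip_identity(tmp_path, fmt, suffix):
    rng = np.random.default_rng(0)
    values = rng.normal(size=(7, 9))
    mask = rng.random((7, 9)) > 0.2
    grid = make_grid(values, cell=2.0, mask=mask)
    path = tmp_path / f"grid{suffix}"
    write_grid(grid, path, format=fmt)
    back = read_grid(path, format=fmt)
    assert np.array_equal(back.mask, grid.mask)
    assert np.array_equal(back.values[back.mask], grid.values[grid.mask])
    t, u = grid.transform, back.transform
    assert (t.x0, t.y0, t.cell_w, t.cell_h) == (u.x0, u.y0, u.cell_w, u.cell_h)


def test_ascii_nodata_cell_masks(tmp_path):
    path = tmp_path / "grid.asc"
    path.write_text(
        "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\nNODATA_value -9999\n"
        "1 2\n-9999 4\n"
    )
    grid = read_grid(path)
    assert grid.mask.sum() == 3
    assert not grid.mask[1, 0]


def test_geotiff_from_independent_writer(tmp_path):
    """A GeoTIFF produced directly by tifffile (not our writer) reads back
    with zero value difference."""
    ramp = np.arange(100, dtype=np.float64).reshape(10, 10)
    path = tmp_path / "ramp.tif"
    tifffile.imwrite(
        str(path),
        ramp,
        extratags=[
            (33550, "d", 3, (1.0, 1.0, 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, 0.0, 10.0, 0.0)),
        ],
    )
    grid = read_grid(path)
    assert np.abs(grid.values - ramp).max() == 0.0
    assert grid.transform.x0 == 0.0 and grid.transform.y0 == 10.0


def test_align_identity_and_constant():
    grid = make_grid(np.random.default_rng(1).normal(size=(6, 6)))
    same = align_to_template(grid, grid, method="bilinear")
    assert np.allclose(same.values[same.mask], grid.values[grid.mask])
    const = make_grid(np.full((6, 6), 3.5))
    for method in ("bilinear", "nearest"):
        out = align_to_template(const, grid, method=method)
        assert np.allclose(out.values[out.mask], 3.5)


def test_align_bilinear_matches_closed_form_ramp():
    src = make_grid(np.array([[0.0, 0.0], [10.0, 10.0]]), cell=10.0)
    tmpl = make_grid(np.zeros((20, 20)), cell=1.0)
    out = align_to_template(src, tmpl, method="bilinear")
    # Row centers at y = 19.5 .. 0.5 map to source fractional rows; the
    # expected profile is linear interpolation between the two cell-center
    # values, clamped at the edges.
    ys = 20.0 - (np.arange(20) + 0.5)
    row_f = (20.0 - ys) / 10.0 - 0.5
    expected = np.interp(row_f, [0.0, 1.0], [0.0, 10.0])
    assert np.allclose(out.values.mean(axis=1), expected, atol=1e-12)


def test_align_nearest_preserves_value_set():
    src = make_grid(np.array([[1.0, 2.0], [3.0, 4.0]]), cell=5.0)
    tmpl = make_grid(np.zeros((10, 10)), cell=1.0)
    out = align_to_template(src, tmpl, method="nearest")
    assert set(np.unique(out.values[out.mask])) <= {1.0, 2.0, 3.0, 4.0}


def test_align_disjoint_extent_raises():
    src = make_grid(np.zeros((4, 4)))
    far = Grid(
        values=np.zeros((4, 4)),
        transform=GridTransform(x0=100.0, y0=104.0, cell_w=1.0, cell_h=1.0),
        mask=np.ones((4, 4), dtype=bool),
    )
    with pytest.raises(DomainError):
        align_to_template(src, far)


def test_align_idempotent_on_template():
    rng = np.random.default_rng(2)
    src = make_grid(rng.normal(size=(8, 8)), cell=2.0)
    tmpl = make_grid(np.zeros((16, 16)), cell=1.0)
    once = align_to_template(src, tmpl, method="bilinear")
    twice = align_to_template(once, tmpl, method="bilinear")
    assert np.allclose(once.values[twice.mask], twice.values[twice.mask])


def test_minmax_normalize_affine_and_degenerate():
    grid = make_grid(np.array([[2.0, 4.0, 6.0]]).T)
    out = minmax_normalize(grid)
    assert np.allclose(out.valid_values(), [0.0, 0.5, 1.0])
    with pytest.warns(UserWarning):
        flat = minmax_normalize(make_grid(np.full((2, 1), 5.0)))
    assert flat.degenerate and np.all(flat.values == 0.0)


def test_minmax_normalize_preserves_ranks():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(3)
    grid = make_grid(rng.normal(size=(50, 50)))
    out = minmax_normalize(grid)
    assert spearmanr(grid.values.ravel(), out.values.ravel()).statistic == pytest.approx(1.0)


def _point_in_ring(x, y, ring):
    # Independent ray-casting oracle.
    inside = False
    n = len(ring) - 1
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[i + 1]
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xin:
                inside = not inside
    return inside


def test_rasterize_full_empty_and_brute_force():
    tmpl = make_grid(np.zeros((4, 4)))
    full = PolygonSet([Polygon([(-1, -1), (5, -1), (5, 5), (-1, 5), (-1, -1)])])
    assert rasterize(full, tmpl).values.sum() == 16
    empty = PolygonSet([], labels=[])
    assert rasterize(empty, tmpl).values.sum() == 0

    ring = [(0.2, 0.7), (1.9, 0.3), (2.4, 2.6), (0.6, 3.1), (0.2, 0.7)]
    polys = PolygonSet([Polygon(ring)])
    out = rasterize(polys, tmpl)
    xs, ys = tmpl.cell_centers()
    expected = sum(
        _point_in_ring(x, y, ring) for x, y in zip(xs.ravel(), ys.ravel())
    )
    assert out.values.sum() == expected


def test_rasterize_crs_mismatch():
    tmpl = make_grid(np.zeros((2, 2)))
    polys = PolygonSet([Polygon([(0, 0), (1, 0), (1, 1), (0, 0)])], crs_tag="other")
    with pytest.raises(DomainError):
        rasterize(polys, tmpl)


def test_masked_area_counting_and_additivity():
    assert masked_area(make_grid(np.zeros((3, 3)))) == 0.0
    seven = np.zeros((3, 3))
    seven.ravel()[:7] = 1.0
    assert masked_area(make_grid(seven)) == 7.0

    rng = np.random.default_rng(4)
    vals = (rng.random((10, 10)) > 0.5).astype(float)
    grid = make_grid(vals, cell=2.0)
    loop = sum(1 for v in vals.ravel() if v == 1.0) * 4.0
    assert masked_area(grid) == loop

    a = np.zeros((6, 6))
    a[:3] = (rng.random((3, 6)) > 0.5)
    b = np.zeros((6, 6))
    b[3:] = (rng.random((3, 6)) > 0.5)
    assert masked_area(make_grid(a)) + masked_area(make_grid(b)) == masked_area(make_grid(a + b))


def test_masked_area_rejects_nonbinary():
    with pytest.raises(DomainError):
        masked_area(make_grid(np.array([[0.5]])))


def test_polygon_geojson_round_trip(tmp_path):
    polys = PolygonSet(
        [Polygon([(0, 0), (2, 0), (2, 2), (0, 2), (0, 0)])], labels=["MPA_1"]
    )
    path = tmp_path / "mpas.geojson"
    write_polygons(polys, path)
    back = read_polygons(path)
    assert back.labels == ["MPA_1"]
    assert back.polygons[0].equals(polys.polygons[0])
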