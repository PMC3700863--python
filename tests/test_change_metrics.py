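import numpy as np
import pytest

from rangeshift.change_metrics import (
    area_change_percent,
    centroid_displacement_km,
    overlap_map,
    overlap_percent,
    range_change,
    turnover_same_species,
    turnover_table,
    zonal_centroid,
    zonal_ellipse,
)
from rangeshift.grid import GridSpec
from rangeshift.postprocess import BinaryMap


@pytest.fixture(scope="module")
def grid():
    # 10 rows x 6 cols at 0.5 degrees, 36-41 N
    return GridSpec(30.0, 36.0, 0.5, 10, 6)


def bmap(grid, cells, species="sp", period="current", scenario=""):
    data = np.zeros(grid.shape)
    for r, c in cells:
        data[r, c] = 1.0
    return BinaryMap(grid, data, species, period, scenario)


# --- overlap ---------------------------------------------------------------

def test_overlap_map_cases(grid):
    a = bmap(grid, [(0, 0), (1, 1), (2, 2), (3, 3)])
    same = overlap_map(a, a)
    np.testing.assert_array_equal(same.data, a.data)
    disjoint = overlap_map(a, bmap(grid, [(5, 5)]))
    assert disjoint.presence_count == 0
    b = bmap(grid, [(0, 0), (1, 1), (2, 2), (4, 4)])
    assert overlap_map(a, b).presence_count == 3


def test_overlap_percent_cases(grid):
    a = bmap(grid, [(0, 0), (1, 1), (2, 2), (3, 3)])
    assert overlap_percent(a, a) == 100.0
    assert overlap_percent(a, bmap(grid, [(5, 5)])) == 0.0
    b = bmap(grid, [(0, 0), (1, 1), (2, 2), (4, 4)])
    assert overlap_percent(a, b) == 75.0


def test_overlap_percent_empty_current_nan(grid):
    empty = bmap(grid, [])
    with pytest.warns(UserWarning):
        assert np.isnan(overlap_percent(empty, bmap(grid, [(0, 0)])))


# --- area change -----------------------------------------------------------

def test_area_change_identity_and_doubling(grid):
    a = bmap(grid, [(2, 0), (2, 1)])
    assert area_change_percent(a, a) == 0.0
    doubled = bmap(grid, [(2, 0), (2, 1), (2, 3), (2, 4)])  # same latitude row
    assert area_change_percent(a, doubled) == pytest.approx(100.0)


def test_area_change_cosine_weights(grid):
    """Cells at different latitudes carry cos(lat) area weights."""
    current = bmap(grid, [(0, 0)])  # lat center 36.25
    future = bmap(grid, [(0, 0), (9, 0)])  # adds lat center 40.75
    w36, w40 = np.cos(np.deg2rad([36.25, 40.75]))
    expected = 100.0 * ((w36 + w40) - w36) / w36
    assert area_change_percent(current, future) == pytest.approx(expected, rel=1e-12)


# --- centroid --------------------------------------------------------------

def test_centroid_single_cell(grid):
    assert zonal_centroid(bmap(grid, [(0, 0)])) == pytest.approx((30.25, 36.25))


def test_centroid_symmetry_about_meridian(grid):
    lon, lat = zonal_centroid(bmap(grid, [(3, 1), (3, 4)]))
    assert lon == pytest.approx(0.5 * (30.75 + 32.25))
    assert lat == pytest.approx(37.75)


def test_centroid_three_cells_weighted_mean(grid):
    cells = [(0, 0), (4, 2), (9, 5)]
    lons = np.array([30.25, 31.25, 32.75])
    lats = np.array([36.25, 38.25, 40.75])
    w = np.cos(np.deg2rad(lats))
    expected = (np.average(lons, weights=w), np.average(lats, weights=w))
    assert zonal_centroid(bmap(grid, cells)) == pytest.approx(expected)


def test_centroid_empty_errors(grid):
    with pytest.raises(ValueError):
        zonal_centroid(bmap(grid, []))


# --- displacement ----------------------------------------------------------

def test_displacement_zero_and_symmetry():
    assert centroid_displacement_km((35.0, 39.0), (35.0, 39.0)) == 0.0
    d1 = centroid_displacement_km((35.0, 39.0), (36.2, 40.1))
    d2 = centroid_displacement_km((36.2, 40.1), (35.0, 39.0))
    assert d1 == pytest.approx(d2)


def test_displacement_one_degree_latitude():
    # 1 degree of arc on a 6371-km sphere: 6371 * pi / 180 = 111.1949 km
    d = centroid_displacement_km((35.0, 39.0), (35.0, 40.0))
    assert d == pytest.approx(111.19, abs=0.01)


# --- ellipse ---------------------------------------------------------------

def test_ellipse_cells_along_parallel(grid):
    vals, vecs = zonal_ellipse(bmap(grid, [(3, 0), (3, 2), (3, 5)]))
    assert vals[1] == pytest.approx(0.0, abs=1e-9)
    # leading axis east-west: eigenvector along x
    assert abs(vecs[0, 0]) == pytest.approx(1.0)


def test_ellipse_isotropic_square():
    # a degree-square block is only km-square where cos(lat) ~ 1, so probe
    # isotropy on a grid straddling the equator
    eq_grid = GridSpec(30.0, -0.5, 0.5, 2, 2)
    cells = [(r, c) for r in (0, 1) for c in (0, 1)]
    vals, _ = zonal_ellipse(bmap(eq_grid, cells))
    assert vals[0] == pytest.approx(vals[1], rel=1e-3)


def test_ellipse_against_closed_form(grid):
    cells = [(0, 0), (2, 1), (5, 3), (9, 5)]
    binary = bmap(grid, cells)
    vals, vecs = zonal_ellipse(binary)
    lon = grid.lon_centers()[[c for _, c in cells]]
    lat = grid.lat_centers()[[r for r, _ in cells]]
    lon_c, lat_c = zonal_centroid(binary)
    km = 6371 * np.pi / 180
    x = (lon - lon_c) * np.cos(np.deg2rad(lat_c)) * km
    y = (lat - lat_c) * km
    w = np.cos(np.deg2rad(lat))
    w = w / w.sum()
    mx, my = (w * x).sum(), (w * y).sum()
    cov = np.array(
        [
            [(w * (x - mx) ** 2).sum(), (w * (x - mx) * (y - my)).sum()],
            [(w * (x - mx) * (y - my)).sum(), (w * (y - my) ** 2).sum()],
        ]
    )
    ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(vals, ev, rtol=1e-9)
    for i in range(2):
        np.testing.assert_allclose(cov @ vecs[:, i], vals[i] * vecs[:, i], atol=1e-9)


def test_ellipse_single_cell_degenerate(grid):
    with pytest.warns(UserWarning):
        vals, _ = zonal_ellipse(bmap(grid, [(0, 0)]))
    np.testing.assert_array_equal(vals, 0.0)


# --- turnover --------------------------------------------------------------

def test_turnover_static_ranges(grid):
    a = bmap(grid, [(0, 0), (1, 1)])
    result = turnover_same_species([a] * 4)
    assert result["pairwise_percent"] == [100.0, 100.0, 100.0]
    assert result["all_timeline_percent"] == 100.0


def test_turnover_vanishing_range(grid):
    a = bmap(grid, [(0, 0), (1, 1)])
    gone = bmap(grid, [])
    result = turnover_same_species([a, a, a, gone])
    assert result["all_timeline_percent"] == 0.0


def test_turnover_nested_shrinking(grid):
    m4 = bmap(grid, [(0, 0), (1, 1), (2, 2), (3, 3)])
    m3 = bmap(grid, [(0, 0), (1, 1), (2, 2)])
    m2 = bmap(grid, [(0, 0), (1, 1)])
    result = turnover_same_species([m4, m3, m2])
    assert result["pairwise_percent"] == pytest.approx([75.0, 200 / 3])
    assert result["all_timeline_percent"] == 50.0


def test_turnover_persistence_bounded_by_pairwise_for_nested(grid):
    m4 = bmap(grid, [(0, 0), (1, 1), (2, 2), (3, 3)])
    m3 = bmap(grid, [(0, 0), (1, 1), (2, 2)])
    m2 = bmap(grid, [(0, 0), (1, 1)])
    result = turnover_same_species([m4, m3, m2])
    assert result["all_timeline_percent"] <= min(result["pairwise_percent"])


def test_turnover_table_excludes_empty_current(grid):
    timelines = {
        "ok": [bmap(grid, [(0, 0), (1, 1)], species="ok")] * 3,
        "void": [bmap(grid, [], species="void")] * 3,
    }
    with pytest.warns(UserWarning):
        table, summary = turnover_table(timelines)
    assert summary["n_species"] == 1
    assert summary["excluded"] == ["void"]
    assert summary["mean"]["all_timeline_percent"] == 100.0


def test_range_change_record(grid):
    cur = bmap(grid, [(2, 2), (2, 3)], period="current")
    fut = bmap(grid, [(2, 3), (3, 3)], period="2050", scenario="A2a")
    r = range_change(cur, fut)
    assert r.overlap_percent == 50.0
    assert r.displacement_km > 0
    assert r.scenario == "A2a"
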