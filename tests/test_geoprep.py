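"""Study-region geometry, thinning, covariate transforms."""

import itertools

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from urbancline.geoprep import (
    StudyRegion,
    buffer_city,
    build_model_frame,
    cardinal_extents,
    select_cities,
    thin_points,
)


def _square(side, center=(0.0, 0.0)):
    s = side / 2
    cx, cy = center
    return shapely.box(cx - s, cy - s, cx + s, cy + s)


# -- buffering ----------------------------------------------------------------


def test_square_buffer_is_quarter_half_side():
    region = buffer_city(_square(2_000.0))
    assert region.buffer_distance == pytest.approx(0.25 * 1_000.0)


def test_rectangle_buffer_uses_mean_cardinal_extent():
    # 40 km E-W x 10 km N-S: extents (5, 5, 20, 20) km -> buffer 3.125 km
    poly = shapely.box(-20_000, -5_000, 20_000, 5_000)
    region = buffer_city(poly)
    assert region.buffer_distance == pytest.approx(3_125.0)


def test_irregular_footprint_buffer_is_strict_superset():
    rng = np.random.default_rng(0)
    theta = np.linspace(0, 2 * np.pi, 30, endpoint=False)
    r = 5_000 * (1 + 0.3 * np.sin(3 * theta) + 0.1 * rng.standard_normal(30))
    poly = Polygon(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    region = buffer_city(poly)
    assert region.buffered.area > region.footprint.area
    assert region.buffered.contains(region.footprint)


def test_degenerate_polygon_rejected():
    with pytest.raises(ValueError):
        cardinal_extents(Polygon())


# -- thinning -----------------------------------------------------------------


def test_thinning_identity_when_all_far_apart():
    xy = np.array([[0, 0], [100, 0], [0, 100], [100, 100]], dtype=float)
    kept = thin_points(xy, min_dist=10.0, seed=0)
    np.testing.assert_array_equal(kept, np.arange(4))


def test_thinning_close_pair_keeps_exactly_one():
    xy = np.array([[0.0, 0.0], [5.0, 0.0]])
    kept = thin_points(xy, min_dist=10.0, seed=0)
    assert len(kept) == 1


def _brute_force_max_independent(xy, min_dist):
    """Exhaustive maximum independent set of the proximity graph."""
    n = len(xy)
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
    conflict = (d < min_dist) & ~np.eye(n, dtype=bool)
    masks = [sum(1 << j for j in range(n) if conflict[i, j]) for i in range(n)]
    best = 0
    for subset in range(1 << n):
        size = subset.bit_count()
        if size <= best:
            continue
        ok = True
        s = subset
        while s:
            i = (s & -s).bit_length() - 1
            if masks[i] & subset:
                ok = False
                break
            s &= s - 1
        if ok:
            best = size
    return best


def test_thinning_matches_maximum_independent_set_oracle():
    rng = np.random.default_rng(1)
    for trial in range(25):
        n = rng.integers(6, 13)
        xy = rng.uniform(0, 40, size=(n, 2))
        kept = thin_points(xy, min_dist=12.0, seed=trial, n_replicates=20)
        # validity: no two retained points conflict
        d = np.linalg.norm(xy[kept][:, None] - xy[kept][None, :], axis=-1)
        assert (d[~np.eye(len(kept), dtype=bool)] >= 12.0).all()
        assert len(kept) == _brute_force_max_independent(xy, 12.0)


def test_thinning_output_is_independent_set_at_scale():
    rng = np.random.default_rng(2)
    xy = rng.uniform(0, 300, size=(400, 2))
    kept = thin_points(xy, min_dist=15.0, seed=0)
    from scipy.spatial import cKDTree

    pairs = cKDTree(xy[kept]).query_pairs(r=15.0 * (1 - 1e-12))
    assert not pairs


# -- city selection -----------------------------------------------------------


def _region_at(center, side=10_000.0, city_id="c"):
    return buffer_city(_square(side, center), city_id=city_id)


def _obs_in(region, n, rng):
    xmin, ymin, xmax, ymax = region.footprint.bounds
    return pd.DataFrame(
        {
            "obs_id": [f"{region.city_id}_{k}" for k in range(n)],
            "x": rng.uniform(xmin, xmax, n),
            "y": rng.uniform(ymin, ymax, n),
        }
    )


def test_undersampled_region_dropped():
    rng = np.random.default_rng(3)
    a = _region_at((0, 0), city_id="a")
    b = _region_at((100_000, 0), city_id="b")
    obs = pd.concat([_obs_in(a, 99, rng), _obs_in(b, 150, rng)], ignore_index=True)
    winners, assigned = select_cities([a, b], obs, min_obs=100)
    assert [w.city_id for w in winners] == ["b"]
    assert (assigned.city_id == "b").all()


def test_disjoint_regions_both_retained():
    rng = np.random.default_rng(4)
    a = _region_at((0, 0), city_id="a")
    b = _region_at((100_000, 0), city_id="b")
    obs = pd.concat([_obs_in(a, 200, rng), _obs_in(b, 150, rng)], ignore_index=True)
    winners, assigned = select_cities([a, b], obs, min_obs=100)
    assert sorted(w.city_id for w in winners) == ["a", "b"]
    assert assigned.groupby("city_id").size().to_dict() == {"a": 200, "b": 150}


def test_overlapping_regions_keep_larger_sample():
    rng = np.random.default_rng(5)
    a = _region_at((0, 0), city_id="a")
    b = _region_at((8_000, 0), city_id="b")  # overlaps a
    obs = pd.concat([_obs_in(a, 500, rng), _obs_in(b, 200, rng)], ignore_index=True)
    winners, assigned = select_cities([a, b], obs, min_obs=100)
    assert [w.city_id for w in winners] == ["a"]


# -- model frame --------------------------------------------------------------


def _toy_region(city_id, forest=30.0, temp=-5.0, area=20_000.0):
    reg = _region_at((0, 0), city_id=city_id)
    reg.forest_pct = forest
    reg.winter_temp = temp
    reg.city_area_ha = area
    return reg


def _toy_obs(city_ids, colors=None):
    n = len(city_ids)
    df = pd.DataFrame(
        {
            "obs_id": [f"o{k}" for k in range(n)],
            "x": np.linspace(0, 100, n),
            "y": np.zeros(n),
            "city_id": city_ids,
        }
    )
    if colors is not None:
        df["color"] = colors
    return df


def test_within_city_minmax_rescaling():
    regions = [_toy_region("a"), _toy_region("b", forest=40.0, temp=0.0, area=50_000.0)]
    obs = _toy_obs(["a", "a", "a", "b", "b"], colors=["gray"] * 5)
    frame = build_model_frame(obs, regions, np.array([10.0, 20.0, 30.0, 5.0, 15.0]))
    np.testing.assert_allclose(
        frame.data.imperv_rescaled.to_numpy(), [0.0, 0.5, 1.0, 0.0, 1.0]
    )


def test_other_morph_counts_as_nonmelanic():
    regions = [_toy_region("a"), _toy_region("b", forest=40.0, temp=0.0, area=50_000.0)]
    obs = _toy_obs(
        ["a", "a", "b", "b"], colors=["melanic", "other", "gray", "melanic"]
    )
    frame = build_model_frame(obs, regions, np.array([1.0, 2.0, 3.0, 4.0]))
    np.testing.assert_array_equal(frame.data.melanic.to_numpy(), [1, 0, 0, 1])


def test_standardized_columns_have_mean_zero_sd_one():
    rng = np.random.default_rng(6)
    regions = [
        _toy_region("a"),
        _toy_region("b", forest=40.0, temp=0.0, area=50_000.0),
        _toy_region("c", forest=15.0, temp=5.0, area=8_000.0),
    ]
    obs = _toy_obs(list(np.repeat(["a", "b", "c"], 50)), colors=["gray"] * 150)
    frame = build_model_frame(obs, regions, rng.uniform(0, 80, 150))
    for col in ("x_imperv", "x_temp", "x_forest", "x_logsize"):
        vals = frame.data[col].to_numpy()
        assert abs(vals.mean()) < 1e-8
        assert abs(vals.std(ddof=0) - 1) < 1e-6


def test_constant_impervious_city_warns_and_zeroes():
    regions = [_toy_region("a"), _toy_region("b", forest=40.0, temp=0.0, area=50_000.0)]
    obs = _toy_obs(["a", "a", "b", "b"], colors=["gray"] * 4)
    with pytest.warns(UserWarning, match="constant impervious"):
        frame = build_model_frame(obs, regions, np.array([7.0, 7.0, 1.0, 9.0]))
    np.testing.assert_allclose(frame.data.imperv_rescaled.to_numpy()[:2], 0.0)


@settings(max_examples=50, deadline=None)
@given(
    scale=st.floats(min_value=0.1, max_value=50.0),
    shift=st.floats(min_value=-100.0, max_value=100.0),
)
def test_rescaling_invariant_to_affine_transforms(scale, shift):
    """Within-city min-max rescaling kills affine changes of the raw
    impervious scale, so the standardized predictor is unchanged."""
    regions = [_toy_region("a"), _toy_region("b", forest=40.0, temp=0.0, area=50_000.0)]
    obs = _toy_obs(["a", "a", "a", "b", "b"], colors=["gray"] * 5)
    raw = np.array([10.0, 25.0, 30.0, 5.0, 15.0])
    f1 = build_model_frame(obs, regions, raw)
    f2 = build_model_frame(obs, regions, raw * scale + shift)
    np.testing.assert_allclose(
        f1.data.x_imperv.to_numpy(), f2.data.x_imperv.to_numpy(), atol=1e-9
    )


def test_frame_building_is_deterministic():
    regions = [_toy_region("a"), _toy_region("b", forest=40.0, temp=0.0, area=50_000.0)]
    obs = _toy_obs(["a", "a", "b", "b"], colors=["gray", "melanic", "gray", "other"])
    imp = np.array([1.0, 4.0, 2.0, 8.0])
    f1 = build_model_frame(obs, regions, imp)
    f2 = build_model_frame(obs, regions, imp)
    pd.testing.assert_frame_equal(f1.data, f2.data)


def test_projection_roundtrip_and_scale():
    from urbancline.projection import aeqd_forward, aeqd_inverse

    lon0, lat0 = -76.5, 43.0
    lons = np.array([-76.5, -76.3, -76.8])
    lats = np.array([43.0, 43.2, 42.9])
    x, y = aeqd_forward(lons, lats, lon0, lat0)
    lon2, lat2 = aeqd_inverse(x, y, lon0, lat0)
    np.testing.assert_allclose(lon2, lons, atol=1e-9)
    np.testing.assert_allclose(lat2, lats, atol=1e-9)
    # one degree of latitude is ~111.2 km
    _, y1 = aeqd_forward(lon0, lat0 + 1.0, lon0, lat0)
    assert y1 == pytest.approx(111_195.0, rel=0.005)
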