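"""Study-region geometry, spatial thinning, covariate extraction, and
assembly of the model frame.

All metric work happens in planar meters.  Geographic (lon/lat) inputs
are first projected per city with a local azimuthal equidistant
projection centred on the city centroid (:mod:`urbancline.projection`);
planar inputs are used as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .raster import (
    Raster,
    extract_point_buffer,
    extract_points_buffer,
    extract_region_mean,
)

__all__ = [
    "StudyRegion",
    "ModelFrame",
    "StandardizationStats",
    "buffer_city",
    "cardinal_extents",
    "select_cities",
    "thin_points",
    "extract_point_buffer",
    "extract_points_buffer",
    "extract_region_covariates",
    "build_model_frame",
]

PREDICTORS = ("x_imperv", "x_temp", "x_forest", "x_logsize")


@dataclass
class StudyRegion:
    """A city footprint with its buffered study polygon and covariates."""

    city_id: str
    footprint: Polygon
    buffered: Polygon
    centroid: tuple[float, float]
    buffer_distance: float
    city_area_ha: float
    forest_pct: float | None = None
    winter_temp: float | None = None


@dataclass
class StandardizationStats:
    """Transform state needed to reproduce predictor scaling at
    prediction time."""

    means: dict[str, float]
    sds: dict[str, float]
    imperv_minmax: dict[str, tuple[float, float]]  # per city, raw percent
    standardize_rescaled: bool = True

    def standardize(self, name: str, value):
        return (np.asarray(value, dtype=float) - self.means[name]) / self.sds[name]


@dataclass
class ModelFrame:
    """Per-observation response and transformed predictors, plus the
    statistics needed to map raw covariates onto the fitted scale."""

    data: pd.DataFrame
    stats: StandardizationStats


def cardinal_extents(footprint: Polygon) -> tuple[float, float, float, float]:
    """(d_N, d_S, d_E, d_W): distance from the centroid to the
    footprint's maximum extent along each cardinal axis (bounding-box
    edges)."""
    if footprint.is_empty or footprint.area <= 0:
        raise ValueError("degenerate footprint polygon")
    cx, cy = footprint.centroid.x, footprint.centroid.y
    xmin, ymin, xmax, ymax = footprint.bounds
    return ymax - cy, cy - ymin, xmax - cx, cx - xmin


def buffer_city(footprint: Polygon, city_id: str = "") -> StudyRegion:
    """Dilate a city footprint by 25% of its mean cardinal-extent
    distance to form the buffered study region (city plus surrounding
    rural hinterland)."""
    dn, ds, de, dw = cardinal_extents(footprint)
    dist = 0.25 * (dn + ds + de + dw) / 4.0
    buffered = footprint.buffer(dist)
    c = footprint.centroid
    return StudyRegion(
        city_id=city_id,
        footprint=footprint,
        buffered=buffered,
        centroid=(c.x, c.y),
        buffer_distance=dist,
        city_area_ha=footprint.area / 1e4,
    )


# -- spatial thinning ---------------------------------------------------------


def _proximity_pairs(xy: np.ndarray, min_dist: float) -> np.ndarray:
    from scipy.spatial import cKDTree

    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=min_dist, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
    return pairs[d < min_dist]  # strictly closer than min_dist conflicts


def _greedy_thin(n: int, pairs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Remove the point with the most unresolved neighbours until no two
    retained points conflict; ties broken uniformly at random."""
    deg = np.bincount(pairs.ravel(), minlength=n)
    alive = np.ones(n, dtype=bool)
    # adjacency lists
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)
    while True:
        top = deg[alive].max() if alive.any() else 0
        if top == 0:
            break
        cand = np.flatnonzero(alive & (deg == top))
        victim = cand[rng.integers(len(cand))]
        alive[victim] = False
        for nb in adj[victim]:
            if alive[nb]:
                deg[nb] -= 1
        deg[victim] = 0
    return np.flatnonzero(alive)


def _mis_branch_bound(neigh: list[int], remaining: int) -> int:
    """Maximum independent set of a small graph, as a bitmask.

    Vertices with at most one remaining neighbour are always safely
    taken; otherwise branch on a maximum-degree vertex.
    """
    taken = 0
    while remaining:
        progress = False
        m = remaining
        while m:
            v = (m & -m).bit_length() - 1
            m &= m - 1
            if not (remaining >> v) & 1:
                continue
            nb = neigh[v] & remaining
            if nb == 0:
                taken |= 1 << v
                remaining &= ~(1 << v)
                progress = True
            elif nb & (nb - 1) == 0:  # exactly one neighbour: take v, drop it
                taken |= 1 << v
                remaining &= ~((1 << v) | nb)
                progress = True
        if not progress:
            break
    if not remaining:
        return taken
    # branch on the highest-degree remaining vertex
    best_v, best_d = -1, -1
    m = remaining
    while m:
        v = (m & -m).bit_length() - 1
        m &= m - 1
        d = (neigh[v] & remaining).bit_count()
        if d > best_d:
            best_v, best_d = v, d
    with_v = (1 << best_v) | _mis_branch_bound(
        neigh, remaining & ~((1 << best_v) | neigh[best_v])
    )
    without_v = _mis_branch_bound(neigh, remaining & ~(1 << best_v))
    chosen = with_v if with_v.bit_count() >= without_v.bit_count() else without_v
    return taken | chosen


_EXACT_COMPONENT_LIMIT = 28


def thin_points(
    xy: np.ndarray,
    min_dist: float,
    seed: int = 0,
    n_replicates: int = 10,
) -> np.ndarray:
    """Spatially thin points to a minimum inter-point distance.

    The conflict graph (edges between points closer than ``min_dist``)
    splits into connected components; small components are solved to a
    true maximum independent set exactly, while large components fall
    back to seeded greedy removal of the most-conflicted point over
    replicates, keeping the replicate that retains the most points.
    Returns retained indices (sorted).
    """
    xy = np.asarray(xy, dtype=float)
    if min_dist < 0:
        raise ValueError("min_dist must be nonnegative")
    n = len(xy)
    if n == 0 or min_dist == 0:
        return np.arange(n)
    pairs = _proximity_pairs(xy, min_dist)
    if len(pairs) == 0:
        return np.arange(n)

    from scipy import sparse
    from scipy.sparse.csgraph import connected_components

    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    comp_of_pair = labels[pairs[:, 0]]
    keep_mask = np.ones(n, dtype=bool)
    root = np.random.default_rng(seed)
    for c in np.unique(comp_of_pair):
        nodes = np.flatnonzero(labels == c)
        cpairs = pairs[comp_of_pair == c]
        local = {g: l for l, g in enumerate(nodes)}
        k = len(nodes)
        if k <= _EXACT_COMPONENT_LIMIT:
            neigh = [0] * k
            for a, b in cpairs:
                la, lb = local[a], local[b]
                neigh[la] |= 1 << lb
                neigh[lb] |= 1 << la
            best = _mis_branch_bound(neigh, (1 << k) - 1)
            for l, g in enumerate(nodes):
                if not (best >> l) & 1:
                    keep_mask[g] = False
        else:
            lp = np.array([[local[a], local[b]] for a, b in cpairs])
            best_kept = None
            for _ in range(n_replicates):
                kept = _greedy_thin(k, lp, np.random.default_rng(root.integers(2**31)))
                if best_kept is None or len(kept) > len(best_kept):
                    best_kept = kept
            dropped = np.setdiff1d(np.arange(k), best_kept)
            keep_mask[nodes[dropped]] = False
    return np.flatnonzero(keep_mask)


# -- city selection -----------------------------------------------------------


def _spread(xy: np.ndarray) -> float:
    """Convex-hull area of a point set (0 for degenerate sets)."""
    if len(xy) < 3:
        return 0.0
    hull = shapely.convex_hull(shapely.multipoints(xy))
    return float(getattr(hull, "area", 0.0))


def select_cities(
    regions: list[StudyRegion],
    obs: pd.DataFrame,
    min_obs: int = 100,
    spread_tol: float = 0.05,
) -> tuple[list[StudyRegion], pd.DataFrame]:
    """Retain regions with enough observations and resolve overlaps.

    Each observation is matched to every buffered region containing it;
    regions with fewer than ``min_obs`` contained observations are
    dropped.  When two retained regions overlap, the one with the
    larger sample size wins; if samples are within ``spread_tol``
    (relative), the larger convex-hull spread of its observations wins.
    Observations contained in more than one surviving region go to the
    region with the nearer centroid; unassigned observations are
    dropped.  Returns the retained regions and the observation table
    with a ``city_id`` column.
    """
    xy = obs[["x", "y"]].to_numpy(dtype=float)
    membership = {}
    counts = {}
    for reg in regions:
        xmin, ymin, xmax, ymax = reg.buffered.bounds
        cand = np.flatnonzero(
            (xy[:, 0] >= xmin) & (xy[:, 0] <= xmax) & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax)
        )
        if len(cand) == 0:
            membership[reg.city_id] = cand
            counts[reg.city_id] = 0
            continue
        inside = shapely.contains_xy(reg.buffered, xy[cand, 0], xy[cand, 1])
        membership[reg.city_id] = cand[inside]
        counts[reg.city_id] = int(inside.sum())

    kept = [r for r in regions if counts[r.city_id] >= min_obs]
    # overlap resolution, largest sample first
    kept.sort(key=lambda r: -counts[r.city_id])
    winners: list[StudyRegion] = []
    for reg in kept:
        clash = None
        for w in winners:
            if reg.buffered.intersects(w.buffered):
                clash = w
                break
        if clash is None:
            winners.append(reg)
            continue
        n_r, n_w = counts[reg.city_id], counts[clash.city_id]
        if abs(n_r - n_w) > spread_tol * max(n_r, n_w):
            keep_reg = n_r > n_w
        else:
            keep_reg = _spread(xy[membership[reg.city_id]]) > _spread(
                xy[membership[clash.city_id]]
            )
        if keep_reg:
            winners.remove(clash)
            winners.append(reg)
        # else: reg is dropped
    winners.sort(key=lambda r: r.city_id)

    assign = np.full(len(obs), -1, dtype=int)
    dist = np.full(len(obs), np.inf)
    for k, reg in enumerate(winners):
        idx = membership[reg.city_id]
        d = np.hypot(xy[idx, 0] - reg.centroid[0], xy[idx, 1] - reg.centroid[1])
        closer = d < dist[idx]
        assign[idx[closer]] = k
        dist[idx[closer]] = d[closer]
    out = obs.copy()
    out["city_id"] = [winners[a].city_id if a >= 0 else None for a in assign]
    out = out[out["city_id"].notna()].reset_index(drop=True)
    return winners, out


# -- covariates and the model frame -------------------------------------------


def extract_region_covariates(
    region: StudyRegion, forest_raster: Raster, temp_raster: Raster
) -> tuple[float, float]:
    """Area-weighted means of forest cover and winter temperature over
    the buffered study region."""
    forest = extract_region_mean(forest_raster, region.buffered)
    temp = extract_region_mean(temp_raster, region.buffered)
    return forest, temp


def _standardize(col: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(col.mean())
    sd = float(col.std(ddof=0))
    if sd == 0:
        raise ValueError("cannot standardize a constant predictor")
    return (col - mu) / sd, mu, sd


def build_model_frame(
    obs: pd.DataFrame,
    regions: list[StudyRegion],
    imperv: np.ndarray,
    melanic: np.ndarray | None = ...,
    standardize_rescaled: bool = True,
) -> ModelFrame:
    """Assemble the analysis frame.

    Impervious cover (raw percent within the buffer of each
    observation) is min-max rescaled to [0, 1] within each city, then —
    together with log city area, forest cover, and winter temperature —
    standardized to mean 0, SD 1 over the full frame.  The melanism
    response is 1 for the melanic morph and 0 for gray and rare other
    morphs.  Pass ``melanic=None`` to build a covariate-only frame
    (e.g. before simulating the response).
    """
    obs = obs.reset_index(drop=True)
    imperv = np.asarray(imperv, dtype=float)
    if len(imperv) != len(obs):
        raise ValueError("imperv length does not match observations")
    reg_by_id = {r.city_id: r for r in regions}
    missing = set(obs["city_id"].unique()) - set(reg_by_id)
    if missing:
        raise ValueError(f"observations reference unknown regions: {sorted(missing)}")

    rescaled = np.empty(len(obs))
    minmax: dict[str, tuple[float, float]] = {}
    for city_id, grp in obs.groupby("city_id", sort=True):
        vals = imperv[grp.index.to_numpy()]
        lo, hi = float(vals.min()), float(vals.max())
        minmax[city_id] = (lo, hi)
        if hi > lo:
            rescaled[grp.index] = (vals - lo) / (hi - lo)
        else:
            warnings.warn(
                f"city {city_id}: constant impervious cover; rescaled to 0 "
                "(no within-city cline information)",
                stacklevel=2,
            )
            rescaled[grp.index] = 0.0

    city_ids = obs["city_id"].to_numpy()
    forest = np.array([reg_by_id[c].forest_pct for c in city_ids], dtype=float)
    temp = np.array([reg_by_id[c].winter_temp for c in city_ids], dtype=float)
    logsize = np.array(
        [np.log(reg_by_id[c].city_area_ha) for c in city_ids], dtype=float
    )
    if np.isnan(forest).any() or np.isnan(temp).any():
        raise ValueError("regions missing forest/temperature covariates")

    raw = {
        "x_imperv": rescaled if standardize_rescaled else imperv,
        "x_temp": temp,
        "x_forest": forest,
        "x_logsize": logsize,
    }
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    cols: dict[str, np.ndarray] = {}
    for name, col in raw.items():
        cols[name], means[name], sds[name] = _standardize(np.asarray(col, dtype=float))

    data = pd.DataFrame(
        {
            "obs_id": obs["obs_id"] if "obs_id" in obs else np.arange(len(obs)),
            "city_id": city_ids,
            "x": obs["x"].to_numpy(dtype=float),
            "y": obs["y"].to_numpy(dtype=float),
            "imperv_raw": imperv,
            "imperv_rescaled": rescaled,
            **cols,
        }
    )
    if melanic is None:
        pass
    elif melanic is ...:
        if "color" not in obs.columns:
            raise ValueError("observations need a 'color' column (or pass melanic=)")
        data["melanic"] = (obs["color"] == "melanic").astype(int).to_numpy()
    else:
        data["melanic"] = np.asarray(melanic, dtype=int)

    stats = StandardizationStats(
        means=means,
        sds=sds,
        imperv_minmax=minmax,
        standardize_rescaled=standardize_rescaled,
    )
    return ModelFrame(data=data, stats=stats)
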