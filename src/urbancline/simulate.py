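"""Synthetic study generator.

Emulates a multi-city coat-color survey: irregular city footprints with
impervious cover decaying logistically from the urban core, city-level
forest cover and winter temperature, observation point patterns with an
urban observer-effort bias, melanism drawn from a logistic model with
city random intercepts (optionally plus a spatially autocorrelated
logit-scale noise field), and multi-participant vote records with a
configurable error rate.

Defaults mirror the observed study system: 43 cities, per-city counts
with a long right tail (median ~254, range 101–4731, total ~27k),
city areas 25,000–350,000 ha, winter temperatures spanning roughly
−11 to 9 °C, forest cover 10–50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .raster import Raster, extract_points_buffer

__all__ = [
    "SimConfig",
    "SpatialNoise",
    "CityLandscape",
    "SyntheticStudy",
    "simulate_landscape",
    "simulate_observations",
    "simulate_melanism",
    "simulate_votes",
    "simulate_frame",
    "simulate_study",
    "FIXED_TERMS",
]

#: Fixed-effect terms, in coefficient-vector order, on the standardized scale.
FIXED_TERMS = (
    "intercept",
    "x_imperv",
    "x_temp",
    "x_forest",
    "x_logsize",
    "x_imperv:x_temp",
    "x_imperv:x_forest",
    "x_imperv:x_logsize",
)

COLOR_LABELS = ("gray", "melanic", "other", "unclear")
COUNT_LABELS = ("zero", "one", "two_or_more")


@dataclass(frozen=True)
class SpatialNoise:
    """Spatially autocorrelated logit-scale noise (exponential covariance)."""

    range_m: float
    sd: float

    def __post_init__(self) -> None:
        if self.range_m <= 0:
            raise ValueError("spatial noise range must be positive")
        if self.sd < 0:
            raise ValueError("spatial noise sd must be nonnegative")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``beta`` is on the standardized-predictor scale in :data:`FIXED_TERMS`
    order; ``sigma_city`` is the SD of city random intercepts on the
    logit scale.
    """

    n_cities: int = 43
    city_area_range: tuple[float, float] = (25_000.0, 350_000.0)  # hectares
    n_obs_per_city_range: tuple[int, int] = (101, 4731)
    raster_cell_size: float = 150.0  # meters
    beta: np.ndarray = field(
        default_factory=lambda: np.array(
            [-2.3, 0.17, -2.14, 0.25, 0.58, -0.30, 0.15, 0.13]
        )
    )
    sigma_city: float = 1.5
    spatial_noise: SpatialNoise | None = None
    vote_error_rate: float = 0.02
    n_voters: int = 10
    seed: int = 0

    # landscape shape
    imp_baseline: float = 3.0
    imp_amplitude: float = 75.0
    imp_noise_frac: float = 0.06  # white-noise SD as a fraction of amplitude
    forest_range: tuple[float, float] = (10.0, 50.0)  # percent
    temp_range: tuple[float, float] = (-11.0, 9.0)  # deg C (coldest quarter)

    # observation pattern
    effort_k: float = 2.0  # density multiplier at 100% impervious
    obs_count_log_median: float = 254.0
    obs_count_log_sigma: float = 1.3
    target_total_obs: int | None = 26_924

    # vote-record realism
    missing_location_rate: float = 0.08
    out_of_range_rate: float = 0.06
    other_color_rate: float = 0.02
    zero_image_rate: float = 0.01
    two_plus_image_rate: float = 0.02

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(FIXED_TERMS),):
            raise ValueError(f"beta must have {len(FIXED_TERMS)} entries")
        for name in ("city_area_range", "n_obs_per_city_range", "forest_range", "temp_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min must be <= max")
        if self.raster_cell_size <= 0:
            raise ValueError("raster cell size must be positive")
        if self.sigma_city < 0:
            raise ValueError("sigma_city must be nonnegative")
        if not 0.0 <= self.vote_error_rate <= 1.0:
            raise ValueError("vote_error_rate must be in [0, 1]")
        if self.n_voters < 1:
            raise ValueError("n_voters must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "spatial_noise" in raw and raw["spatial_noise"] is not None:
            raw["spatial_noise"] = SpatialNoise(**raw["spatial_noise"])
        for key in ("city_area_range", "n_obs_per_city_range", "forest_range", "temp_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CityLandscape:
    city_id: str
    footprint: Polygon
    area_ha: float
    center: tuple[float, float]
    imperv: Raster
    forest_pct: float
    winter_temp: float

    def forest_raster(self) -> Raster:
        return Raster(
            np.full_like(self.imperv.values, self.forest_pct),
            self.imperv.x0,
            self.imperv.y0,
            self.imperv.cell_size,
        )

    def temp_raster(self) -> Raster:
        return Raster(
            np.full_like(self.imperv.values, self.winter_temp),
            self.imperv.x0,
            self.imperv.y0,
            self.imperv.cell_size,
        )


@dataclass
class SyntheticStudy:
    config: SimConfig
    landscapes: list[CityLandscape]
    observations: pd.DataFrame  # obs_id, x, y, city_id, true_color, melanic
    frame: "object"  # ModelFrame of the generative covariates
    true_u: np.ndarray  # city random intercepts actually drawn
    votes: pd.DataFrame | None = None
    images: pd.DataFrame | None = None


# -- landscape ----------------------------------------------------------------


def _radial_polygon(rng: np.random.Generator, center, area_m2: float, n_vertices: int = 72) -> Polygon:
    """Irregular star-shaped polygon scaled to the requested area exactly."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for m in range(2, 6):
        amp = rng.uniform(0.0, 0.25 / m)
        phase = rng.uniform(0.0, 2 * np.pi)
        r += amp * np.cos(m * theta + phase)
    r = np.clip(r, 0.3, None)
    poly = Polygon(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    scale = math.sqrt(area_m2 / poly.area)
    xy = np.asarray(poly.exterior.coords)[:-1] * scale
    xy[:, 0] += center[0]
    xy[:, 1] += center[1]
    return Polygon(xy)


def _landscape_extent(footprint: Polygon, margin: float) -> tuple[float, float, float, float]:
    xmin, ymin, xmax, ymax = footprint.bounds
    cx, cy = footprint.centroid.x, footprint.centroid.y
    # same cardinal-extent buffer rule as the geoprep stage, so the raster
    # always covers the buffered study region plus the extraction radius
    d = 0.25 * np.mean([ymax - cy, cy - ymin, xmax - cx, cx - xmin])
    pad = d + margin
    return xmin - pad, ymin - pad, xmax + pad, ymax + pad


def simulate_landscape(
    config: SimConfig,
    city_index: int,
    rng: np.random.Generator,
    center: tuple[float, float] = (0.0, 0.0),
    margin: float = 1_500.0,
) -> CityLandscape:
    """Generate one city: footprint polygon plus impervious/forest/temperature.

    Impervious cover declines logistically (in expectation) with
    distance from the city centroid, clipped to [0, 100]; forest cover
    and winter temperature are drawn once per city.
    """
    area_ha = math.exp(
        rng.uniform(*np.log(np.asarray(config.city_area_range, dtype=float)))
    )
    footprint = _radial_polygon(rng, center, area_ha * 1e4)
    xmin, ymin, xmax, ymax = _landscape_extent(footprint, margin)
    cs = config.raster_cell_size
    ncols = int(np.ceil((xmax - xmin) / cs))
    nrows = int(np.ceil((ymax - ymin) / cs))
    xc = xmin + cs * (np.arange(ncols) + 0.5)
    yc = ymin + cs * (np.arange(nrows) + 0.5)
    cx, cy = footprint.centroid.x, footprint.centroid.y
    dist = np.hypot(xc[None, :] - cx, yc[:, None] - cy)
    r_eff = math.sqrt(area_ha * 1e4 / math.pi)
    r_mid = 0.9 * r_eff
    steep = r_eff / 3.0
    imp = config.imp_baseline + config.imp_amplitude / (1.0 + np.exp((dist - r_mid) / steep))
    noise_sd = config.imp_noise_frac * config.imp_amplitude
    if noise_sd > 0:
        imp = imp + rng.normal(0.0, noise_sd, size=imp.shape)
    imp = np.clip(imp, 0.0, 100.0)
    return CityLandscape(
        city_id=f"city_{city_index:03d}",
        footprint=footprint,
        area_ha=area_ha,
        center=(cx, cy),
        imperv=Raster(imp, xmin, ymin, cs),
        forest_pct=float(rng.uniform(*config.forest_range)),
        winter_temp=float(rng.uniform(*config.temp_range)),
    )


def city_centers(config: SimConfig) -> list[tuple[float, float]]:
    """Lay cities on a planar grid spaced so landscapes never interact."""
    r_max = math.sqrt(config.city_area_range[1] * 1e4 / math.pi)
    spacing = 2 * (2.0 * r_max + 50_000.0)
    side = int(np.ceil(math.sqrt(config.n_cities)))
    return [
        (spacing * (k % side), spacing * (k // side))
        for k in range(config.n_cities)
    ]


# -- observations -------------------------------------------------------------


def _draw_counts(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-city observation counts: long-tailed lognormal within the
    configured range, rescaled (when a target is set) so the study
    total matches the survey's overall sample size."""
    lo, hi = config.n_obs_per_city_range
    raw = rng.lognormal(
        mean=math.log(config.obs_count_log_median),
        sigma=config.obs_count_log_sigma,
        size=config.n_cities,
    )

    def clipped(scale: float) -> np.ndarray:
        return np.clip(np.round(raw * scale), lo, hi).astype(int)

    target = config.target_total_obs
    if target is None or lo == hi:
        return clipped(1.0)
    s_lo, s_hi = 1e-3, 1e3
    for _ in range(80):
        mid = math.sqrt(s_lo * s_hi)
        if clipped(mid).sum() < target:
            s_lo = mid
        else:
            s_hi = mid
    return clipped(s_hi)


def simulate_observations(
    config: SimConfig,
    landscapes: list[CityLandscape],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample observation locations within each buffered city region.

    Point density scales with ``1 + effort_k * impervious/100``,
    mimicking the urban bias of community-science effort, but retains
    nonzero rural mass everywhere inside the region.
    """
    from .geoprep import buffer_city  # local import to avoid a cycle

    counts = _draw_counts(config, rng)
    rows = []
    for land, n in zip(landscapes, counts):
        region = buffer_city(land.footprint, city_id=land.city_id)
        poly = region.buffered
        xmin, ymin, xmax, ymax = poly.bounds
        got = 0
        xs = np.empty(n)
        ys = np.empty(n)
        while got < n:
            m = max(int((n - got) * 3), 64)
            px = rng.uniform(xmin, xmax, m)
            py = rng.uniform(ymin, ymax, m)
            inside = shapely.contains_xy(poly, px, py)
            px, py = px[inside], py[inside]
            if len(px) == 0:
                continue
            imp = land.imperv.value_at(px, py)
            imp = np.nan_to_num(imp, nan=0.0)
            accept = rng.random(len(px)) < (1.0 + config.effort_k * imp / 100.0) / (
                1.0 + config.effort_k
            )
            px, py = px[accept], py[accept]
            take = min(len(px), n - got)
            xs[got : got + take] = px[:take]
            ys[got : got + take] = py[:take]
            got += take
        rows.append(
            pd.DataFrame(
                {
                    "x": xs,
                    "y": ys,
                    "city_id": land.city_id,
                    "date": pd.to_datetime("2010-01-01")
                    + pd.to_timedelta(rng.integers(0, 4007, n), unit="D"),
                }
            )
        )
    obs = pd.concat(rows, ignore_index=True)
    obs.insert(0, "obs_id", [f"obs_{k:06d}" for k in range(len(obs))])
    return obs


# -- melanism -----------------------------------------------------------------


def _exp_cov_field(
    xy: np.ndarray, noise: SpatialNoise, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian field with exponential covariance, simulated on a coarse
    grid and bilinearly interpolated to the points."""
    from scipy.interpolate import RegularGridInterpolator

    step = noise.range_m / 2.0
    xmin, ymin = xy.min(axis=0) - step
    xmax, ymax = xy.max(axis=0) + step
    gx = np.arange(xmin, xmax + step, step)
    gy = np.arange(ymin, ymax + step, step)
    if len(gx) * len(gy) > 6000:
        raise ValueError(
            "spatial noise grid too large; increase range_m or shrink the landscape"
        )
    gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([gxx.ravel(), gyy.ravel()])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    cov = noise.sd**2 * np.exp(-d / noise.range_m)
    cov[np.diag_indices_from(cov)] += 1e-10 * noise.sd**2 + 1e-12
    z = np.linalg.cholesky(cov) @ rng.standard_normal(len(pts))
    interp = RegularGridInterpolator(
        (gx, gy), z.reshape(len(gx), len(gy)), method="linear"
    )
    return interp(xy)


def simulate_melanism(
    config: SimConfig,
    frame_df: pd.DataFrame,
    rng: np.random.Generator,
    return_truth: bool = False,
):
    """Draw Bernoulli melanism from the logistic model.

    ``frame_df`` must carry the standardized covariates exactly as the
    fitting stage builds them (columns ``x_imperv``, ``x_temp``,
    ``x_forest``, ``x_logsize``), plus ``city_id`` and coordinates.
    P(melanic) = inverse-logit(X beta + u_city + eps_spatial).
    """
    needed = ["x_imperv", "x_temp", "x_forest", "x_logsize"]
    missing = [c for c in needed if c not in frame_df.columns]
    if missing:
        raise ValueError(f"frame missing standardized columns: {missing}")
    X = np.column_stack(
        [
            np.ones(len(frame_df)),
            frame_df["x_imperv"],
            frame_df["x_temp"],
            frame_df["x_forest"],
            frame_df["x_logsize"],
            frame_df["x_imperv"] * frame_df["x_temp"],
            frame_df["x_imperv"] * frame_df["x_forest"],
            frame_df["x_imperv"] * frame_df["x_logsize"],
        ]
    )
    if X.shape[1] != len(config.beta):
        raise ValueError("design / beta dimension mismatch")
    cities, city_codes = np.unique(frame_df["city_id"].to_numpy(), return_inverse=True)
    u = rng.normal(0.0, config.sigma_city, size=len(cities))
    eta = X @ config.beta + u[city_codes]
    if config.spatial_noise is not None and config.spatial_noise.sd > 0:
        xy = frame_df[["x", "y"]].to_numpy()
        eps = np.zeros(len(frame_df))
        for c in range(len(cities)):
            mask = city_codes == c
            eps[mask] = _exp_cov_field(xy[mask], config.spatial_noise, rng)
        eta = eta + eps
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(len(p)) < p).astype(int)
    if return_truth:
        return y, u, p
    return y


# -- votes --------------------------------------------------------------------


def _noisy_votes(
    truth: str, labels: tuple[str, ...], n: int, err: float, rng: np.random.Generator
) -> list[str]:
    wrong = [l for l in labels if l != truth]
    out = []
    for _ in range(n):
        if rng.random() < err:
            out.append(wrong[rng.integers(len(wrong))])
        else:
            out.append(truth)
    return out


def simulate_votes(
    observations: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crowd votes for each observation image.

    Returns ``(votes, images)``: votes in long format (image_id,
    question, slot, label, voter_id) and an image table with location
    and native-range metadata.  A small fraction of images hold two
    squirrels (slot-indexed colors) and a further fraction are
    squirrel-free, exercising every consensus branch.
    """
    obs = observations.reset_index(drop=True)
    n = len(obs)
    err = config.vote_error_rate
    nv = config.n_voters

    # pair a small fraction of same-city neighbours into two-squirrel images
    image_of = np.arange(n)
    is_second = np.zeros(n, dtype=bool)
    order = obs.sort_values(["city_id"]).index.to_numpy()
    k = 0
    n_pairs = int(config.two_plus_image_rate * n / 2)
    paired = 0
    while paired < n_pairs and k + 1 < n:
        a, b = order[k], order[k + 1]
        if obs.loc[a, "city_id"] == obs.loc[b, "city_id"] and not is_second[a]:
            image_of[b] = a
            is_second[b] = True
            paired += 1
            k += 2
        else:
            k += 1

    vote_rows: list[tuple] = []
    image_rows: list[tuple] = []
    for a in np.flatnonzero(~is_second):
        members = np.flatnonzero(image_of == a)
        image_id = f"img_{a:06d}"
        truth_count = "one" if len(members) == 1 else "two_or_more"
        for v, lab in enumerate(_noisy_votes(truth_count, COUNT_LABELS, nv, err, rng)):
            vote_rows.append((image_id, "count", -1, lab, v))
        for slot, m in enumerate(members):
            truth_color = obs.loc[m, "true_color"]
            for v, lab in enumerate(
                _noisy_votes(truth_color, COLOR_LABELS, nv, err, rng)
            ):
                vote_rows.append((image_id, "color", slot, lab, v))
        missing = rng.random() < config.missing_location_rate
        out_of_range = rng.random() < config.out_of_range_rate
        image_rows.append(
            (
                image_id,
                np.nan if missing else obs.loc[a, "x"],
                np.nan if missing else obs.loc[a, "y"],
                not out_of_range,
                ",".join(obs.loc[m, "true_color"] for m in members),
            )
        )
    # squirrel-free images (tracks, signs)
    n_zero = int(config.zero_image_rate * n)
    for z in range(n_zero):
        image_id = f"img_zero_{z:05d}"
        for v, lab in enumerate(_noisy_votes("zero", COUNT_LABELS, nv, err, rng)):
            vote_rows.append((image_id, "count", -1, lab, v))
        image_rows.append((image_id, 0.0, 0.0, True, ""))

    votes = pd.DataFrame(
        vote_rows, columns=["image_id", "question", "slot", "label", "voter_id"]
    )
    images = pd.DataFrame(
        image_rows, columns=["image_id", "x", "y", "in_native_range", "true_colors"]
    )
    return votes, images


# -- end-to-end helpers -------------------------------------------------------


def simulate_frame(config: SimConfig, rng: np.random.Generator | None = None):
    """Landscapes -> observations -> covariates -> melanism, returning a
    fitted-format ModelFrame plus the landscapes and truth.

    This is the fast generative path used by the replicate studies: the
    impervious covariate is the 1-km disc mean around each observation
    extracted from the simulated raster, transformed exactly as the
    fitting stage transforms user data (within-city [0,1] rescale, then
    global standardization).
    """
    from .geoprep import build_model_frame, buffer_city

    if rng is None:
        rng = np.random.default_rng(config.seed)
    centers = city_centers(config)
    landscapes = [
        simulate_landscape(config, k, rng, center=centers[k])
        for k in range(config.n_cities)
    ]
    obs = simulate_observations(config, landscapes, rng)
    regions = []
    imperv = np.empty(len(obs))
    for land in landscapes:
        region = buffer_city(land.footprint, city_id=land.city_id)
        region.forest_pct = land.forest_pct
        region.winter_temp = land.winter_temp
        regions.append(region)
        mask = (obs["city_id"] == land.city_id).to_numpy()
        imperv[mask] = extract_points_buffer(
            land.imperv, obs.loc[mask, ["x", "y"]].to_numpy(), radius=1_000.0
        )
    frame = build_model_frame(obs, regions, imperv, melanic=None)
    y, u, p = simulate_melanism(config, frame.data, rng, return_truth=True)
    frame.data["melanic"] = y
    obs = obs.copy()
    obs["melanic"] = y
    other = (y == 0) & (rng.random(len(y)) < config.other_color_rate)
    obs["true_color"] = np.where(y == 1, "melanic", np.where(other, "other", "gray"))
    return frame, landscapes, obs, u


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Full synthetic study including crowd votes."""
    rng = np.random.default_rng(config.seed)
    frame, landscapes, obs, u = simulate_frame(config, rng)
    votes, images = simulate_votes(obs, config, rng)
    return SyntheticStudy(
        config=config,
        landscapes=landscapes,
        observations=obs,
        frame=frame,
        true_u=u,
        votes=votes,
        images=images,
    )
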