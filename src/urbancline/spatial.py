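"""Spatial residual diagnostics and the residual-autocovariate (RAC)
correction.

The RAC workflow: take response-scale residuals from the initial GLMM,
build symmetric inverse-distance ("B"-style, no row standardization)
neighbourhood weights within a radius — by default the greatest
nearest-neighbour distance of the data — compute each point's weighted
mean of neighbouring residuals, standardize it, and refit the model
with that autocovariate as an extra predictor.  Moran's I correlograms
over 1-km distance rings quantify residual spatial autocorrelation
before and after.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .glmm import GLMMFit, GLMMSpec, fit_glmm

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "RacResult",
    "max_nn_distance",
    "build_weights",
    "autocovariate",
    "morans_i",
    "rac_refit",
]


@dataclass
class SpatialWeights:
    """Symmetric inverse-distance weights within a fixed radius.

    ``pairs`` holds each unordered neighbour pair once; ``w = 1/d`` in
    per-meter units.  Coincident points get the distance floor
    ``eps`` (half the minimum nonzero pairwise distance).  Points with
    no neighbour inside the radius are flagged ``isolated``.
    """

    n: int
    radius: float
    pairs: np.ndarray  # (m, 2) int
    dist: np.ndarray  # (m,)
    w: np.ndarray  # (m,)
    isolated: np.ndarray  # (n,) bool
    style: str = "B"

    def matrix(self) -> sparse.csr_matrix:
        i = np.concatenate([self.pairs[:, 0], self.pairs[:, 1]])
        j = np.concatenate([self.pairs[:, 1], self.pairs[:, 0]])
        w = np.concatenate([self.w, self.w])
        return sparse.coo_matrix((w, (i, j)), shape=(self.n, self.n)).tocsr()

    def check(self) -> None:
        assert (self.pairs[:, 0] != self.pairs[:, 1]).all(), "self-neighbours present"
        assert (self.dist <= self.radius + 1e-9).all(), "neighbour beyond radius"
        assert (self.w > 0).all()


@dataclass
class MoranResult:
    """Distance-binned Moran's I correlogram."""

    table: pd.DataFrame  # bin_lo, bin_hi, I, n_pairs

    @property
    def first_bin_i(self) -> float:
        valid = self.table.dropna(subset=["I"])
        return float(valid["I"].iloc[0]) if len(valid) else np.nan

    @property
    def max_i(self) -> float:
        valid = self.table.dropna(subset=["I"])
        return float(valid["I"].max()) if len(valid) else np.nan


@dataclass
class RacResult:
    initial: GLMMFit
    refit: GLMMFit
    radius: float
    moran_before: MoranResult
    moran_after: MoranResult
    autocov: np.ndarray


def max_nn_distance(xy: np.ndarray) -> float:
    """Greatest nearest-neighbour distance over all points."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        raise ValueError("need at least 2 points")
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=2)
    return float(d[:, 1].max())


def build_weights(xy: np.ndarray, radius: float) -> SpatialWeights:
    """Inverse-distance weights for all point pairs within ``radius``."""
    xy = np.asarray(xy, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(xy)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs) == 0:
        pairs = pairs.reshape(0, 2)
        dist = np.empty(0)
        w = np.empty(0)
        isolated = np.ones(n, dtype=bool)
        return SpatialWeights(n, radius, pairs, dist, w, isolated)
    dist = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
    nz = dist[dist > 0]
    eps = 0.5 * nz.min() if len(nz) else radius
    d_eff = np.where(dist > 0, dist, eps)
    w = 1.0 / d_eff
    isolated = np.ones(n, dtype=bool)
    isolated[np.unique(pairs)] = False
    sw = SpatialWeights(n, radius, pairs, dist, w, isolated)
    sw.check()
    return sw


def autocovariate(values: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Weighted mean of neighbouring values: a_i = sum_j w_ij v_j /
    sum_j w_ij; isolated points get 0."""
    values = np.asarray(values, dtype=float)
    if len(values) != weights.n:
        raise ValueError("values length does not match weights")
    num = np.zeros(weights.n)
    den = np.zeros(weights.n)
    i, j, w = weights.pairs[:, 0], weights.pairs[:, 1], weights.w
    np.add.at(num, i, w * values[j])
    np.add.at(num, j, w * values[i])
    np.add.at(den, i, w)
    np.add.at(den, j, w)
    out = np.zeros(weights.n)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def morans_i(values: np.ndarray, xy: np.ndarray, bin_edges) -> MoranResult:
    """Moran's I per distance bin with binary within-bin weights.

    I_bin = (n / S0) * sum_{ij in bin} z_i z_j / sum_i z_i^2 with z the
    centred values and S0 the number of ordered pairs in the bin.
    """
    values = np.asarray(values, dtype=float)
    xy = np.asarray(xy, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 points")
    z = values - values.mean()
    s2 = float(z @ z)
    if s2 == 0:
        raise ValueError("Moran's I undefined for constant values")
    edges = np.asarray(bin_edges, dtype=float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=float(edges[-1]), output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        cross = z[pairs[:, 0]] * z[pairs[:, 1]]
    else:
        d = np.empty(0)
        cross = np.empty(0)
    n = len(values)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (d >= lo) & (d < hi)
        m = int(mask.sum())
        if m == 0:
            rows.append({"bin_lo": lo, "bin_hi": hi, "I": np.nan, "n_pairs": 0})
            continue
        s0 = 2.0 * m  # ordered pairs
        i_val = (n / s0) * (2.0 * float(cross[mask].sum())) / s2
        rows.append({"bin_lo": lo, "bin_hi": hi, "I": i_val, "n_pairs": m})
    return MoranResult(pd.DataFrame(rows))


def rac_refit(
    frame,
    fit: GLMMFit,
    radius: float | None = None,
    bin_width: float = 1_000.0,
    residual_type: str = "response",
) -> RacResult:
    """Refit the GLMM with a standardized residual spatial autocovariate.

    ``radius=None`` uses the greatest nearest-neighbour distance of the
    data.  Returns the refit together with before/after Moran's I
    correlograms over ``bin_width`` rings spanning [0, radius].
    """
    df = frame.data if hasattr(frame, "data") else frame
    xy = df[["x", "y"]].to_numpy(dtype=float)
    if radius is None:
        radius = max_nn_distance(xy)
    if residual_type == "response":
        resid = fit.resid_response
    elif residual_type == "pearson":
        p = fit.fitted_prob
        resid = fit.resid_response / np.sqrt(np.clip(p * (1 - p), 1e-12, None))
    else:
        raise ValueError("residual_type must be 'response' or 'pearson'")

    weights = build_weights(xy, radius)
    ac = autocovariate(resid, weights)
    sd = ac.std(ddof=0)
    degenerate = sd == 0
    ac_std = np.zeros_like(ac) if degenerate else (ac - ac.mean()) / sd

    edges = np.arange(0.0, max(radius, bin_width) + bin_width, bin_width)
    before = morans_i(resid, xy, edges)

    df2 = df.copy()
    df2["x_autocov"] = ac_std
    base_terms = tuple(t for t in fit.terms if t != "x_autocov")
    if degenerate:
        # no neighbours anywhere: the autocovariate carries no signal,
        # so the refit reduces to the base model
        warnings.warn(
            "autocovariate is constant (no neighbours within radius); "
            "refitting without it",
            stacklevel=2,
        )
        spec = GLMMSpec(terms=base_terms, autocovariate=False)
    else:
        spec = GLMMSpec(terms=base_terms, autocovariate=True)
    frame2 = frame
    if hasattr(frame, "data"):
        from .geoprep import ModelFrame

        frame2 = ModelFrame(data=df2, stats=frame.stats)
    else:
        frame2 = df2
    refit = fit_glmm(frame2, spec=spec)
    after = morans_i(refit.resid_response, xy, edges)
    return RacResult(
        initial=fit,
        refit=refit,
        radius=float(radius),
        moran_before=before,
        moran_after=after,
        autocov=ac_std,
    )
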