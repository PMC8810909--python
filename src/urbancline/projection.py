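"""Azimuthal equidistant projection on the sphere.

Geographic (lon/lat) inputs are projected per city onto a local planar
system centred on the city centroid before any metric buffering,
distance, or area computation.  The spherical form (authalic mean
radius) is accurate to well under 1% over the tens-of-kilometres scale
of a single city region, which is ample for buffer distances and
point thinning.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8

__all__ = ["aeqd_forward", "aeqd_inverse", "EARTH_RADIUS_M"]


def aeqd_forward(lon, lat, lon0: float, lat0: float):
    """Project lon/lat (degrees) to local x/y meters around (lon0, lat0)."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    lam0 = np.radians(lon0)
    phi0 = np.radians(lat0)
    dlam = lam - lam0
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    cosc = np.clip(cosc, -1.0, 1.0)
    c = np.arccos(cosc)
    # k = c / sin(c), with the removable singularity at c = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(dlam)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
    )
    return x, y


def aeqd_inverse(x, y, lon0: float, lat0: float):
    """Inverse of :func:`aeqd_forward`; returns lon/lat in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    phi0 = np.radians(lat0)
    lam0 = np.radians(lon0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_M
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc_over_rho = np.where(rho > 1e-9, np.sin(c) / np.where(rho > 1e-9, rho, 1.0), 1.0 / EARTH_RADIUS_M)
    phi = np.arcsin(np.cos(c) * np.sin(phi0) + y * sinc_over_rho * np.cos(phi0))
    lam = lam0 + np.arctan2(
        x * sinc_over_rho,
        np.cos(c) * np.cos(phi0) - y * sinc_over_rho * np.sin(phi0),
    )
    return np.degrees(lam), np.degrees(phi)
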