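"""Spherical mapping and Miller cylindrical projection.

The mould's dummy atoms are pushed radially onto the sphere centred at their
unweighted centre of mass, with radius equal to the largest centre-to-point
distance:

    c    = mean(v_i)
    v'_i = v_i - c
    w_i  = radius * v'_i / ||v'_i||

Each w_i is then expressed as latitude/longitude (radians) and projected to
the plane with the Miller cylindrical projection,

    x = longitude
    y = (5/4) * ln( tan(pi/4 + (2/5) * latitude) ),

which depicts the whole sphere, poles included, with distortion that is zero
at the equator and maximal (but finite) at the poles. Longitude uses the
two-argument arctangent so the two hemispheres are distinguished; the
structure's own z-axis is the polar axis, so maps are orientation-dependent
and comparable only between pre-superposed structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMouldError, MolcartoWarning

__all__ = [
    "SphereMapping",
    "GeoPoints",
    "centre_of_mass",
    "max_radius",
    "spherify",
    "to_geographic",
    "miller_project",
    "miller_y",
    "miller_latitude",
    "MILLER_Y_MAX",
]

#: Ordinate of the poles: (5/4) * ln(tan(9*pi/20)).
MILLER_Y_MAX = 1.25 * np.log(np.tan(9 * np.pi / 20))


@dataclass
class SphereMapping:
    """Mould points radially mapped onto the bounding sphere."""

    centre: np.ndarray
    radius: float
    points: np.ndarray  # (n, 3) vectors w_i, expressed relative to the centre
    residues: list[str]
    n_dropped: int = 0


@dataclass
class GeoPoints:
    """Latitude/longitude (radians) for each sphere point."""

    latitude: np.ndarray  # in [-pi/2, pi/2]
    longitude: np.ndarray  # in (-pi, pi]
    residues: list[str]


def centre_of_mass(points: np.ndarray) -> np.ndarray:
    """Unweighted mean position (every point counts equally)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.shape[0] == 0:
        raise ValueError("centre_of_mass of empty point set")
    return points.mean(axis=0)


def max_radius(points: np.ndarray, c: np.ndarray) -> float:
    """Largest Euclidean distance of any point from *c*."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.shape[0] == 0:
        raise ValueError("max_radius of empty point set")
    r = float(np.linalg.norm(points - np.asarray(c, dtype=float), axis=1).max())
    if r == 0.0:
        raise DegenerateMouldError("degenerate mould: all points coincide with the centre of mass")
    return r


def spherify(
    points: np.ndarray,
    c: np.ndarray,
    radius: float,
    residues: list[str] | None = None,
) -> SphereMapping:
    """Scale every centred point to length *radius*.

    Points exactly at the centre of mass have no direction and are dropped
    with a warning; the drop count is recorded on the result.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if residues is None:
        residues = [""] * points.shape[0]
    centred = points - np.asarray(c, dtype=float)
    norms = np.linalg.norm(centred, axis=1)
    keep = norms > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} point(s) coincide with the centre of mass; dropped",
            MolcartoWarning,
            stacklevel=2,
        )
    if not keep.any():
        raise DegenerateMouldError("all points coincide with the centre of mass")
    w = centred[keep] * (radius / norms[keep])[:, None]
    return SphereMapping(
        centre=np.asarray(c, dtype=float),
        radius=float(radius),
        points=w,
        residues=[r for r, k in zip(residues, keep) if k],
        n_dropped=n_dropped,
    )


def to_geographic(m: SphereMapping) -> GeoPoints:
    """Convert sphere points to latitude/longitude in radians.

    Latitude is arctan(z / hypot(x, y)), evaluated with the two-argument
    arctangent for stability at the poles. Longitude is the quadrant-aware
    arctangent of (y, x), covering the full (-pi, pi] range; points on the
    polar axis get longitude 0.
    """
    x, y, z = m.points[:, 0], m.points[:, 1], m.points[:, 2]
    lat = np.arctan2(z, np.hypot(x, y))
    lon = np.arctan2(y, x)
    lon = np.where(lon == -np.pi, np.pi, lon)  # range convention (-pi, pi]
    lon = np.where((x == 0) & (y == 0), 0.0, lon)
    return GeoPoints(latitude=lat, longitude=lon, residues=list(m.residues))


def miller_y(latitude: np.ndarray | float) -> np.ndarray | float:
    """Miller ordinate, finite at the poles (|y| <= (5/4) ln tan(9 pi/20))."""
    return 1.25 * np.log(np.tan(np.pi / 4 + 0.4 * np.asarray(latitude, dtype=float)))


def miller_latitude(y: np.ndarray | float) -> np.ndarray | float:
    """Closed-form inverse of :func:`miller_y`."""
    return 2.5 * (np.arctan(np.exp(np.asarray(y, dtype=float) / 1.25)) - np.pi / 4)


def miller_project(g: GeoPoints) -> tuple[np.ndarray, np.ndarray]:
    """Project geographic points to map coordinates ``(x, y)``.

    The abscissa is the longitude itself (radians); the ordinate is the
    Miller formula, strictly increasing and odd in latitude.
    """
    return g.longitude.copy(), np.asarray(miller_y(g.latitude))
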