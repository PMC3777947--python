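"""Geodetic (WGS84 lat/lon/alt) <-> local East-North-Up conversions.

Handheld-GPS grade surveys do not distinguish ellipsoidal from orthometric
height, so altitudes are treated as relative heights above the tangent-plane
origin.  A single local tangent plane anchored at a configured geodetic
origin maps every geodetic coordinate into a metric ENU frame in which all
residuals are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)


def geodetic_to_ecef(lat_deg, lon_deg, alt_m):
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    alt = np.asarray(alt_m, dtype=float)
    sin_lat, cos_lat = np.sin(lat), np.cos(lat)
    N = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sin_lat**2)
    x = (N + alt) * cos_lat * np.cos(lon)
    y = (N + alt) * cos_lat * np.sin(lon)
    z = (N * (1.0 - WGS84_E2) + alt) * sin_lat
    return np.stack([x, y, z], axis=-1)


def ecef_to_geodetic(xyz):
    """Iterative (Bowring-style) inverse; millimetre convergence in 5 steps."""
    xyz = np.asarray(xyz, dtype=float)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    lon = np.arctan2(y, x)
    p = np.hypot(x, y)
    lat = np.arctan2(z, p * (1.0 - WGS84_E2))
    for _ in range(6):
        sin_lat = np.sin(lat)
        N = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sin_lat**2)
        alt = p / np.cos(lat) - N
        lat = np.arctan2(z, p * (1.0 - WGS84_E2 * N / (N + alt)))
    sin_lat = np.sin(lat)
    N = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sin_lat**2)
    alt = p / np.cos(lat) - N
    return np.degrees(lat), np.degrees(lon), alt


@dataclass(frozen=True)
class GeodeticOrigin:
    """Anchor of the local ENU tangent plane."""

    lat_deg: float
    lon_deg: float
    alt_m: float = 0.0

    def _rotation(self) -> np.ndarray:
        lat = np.radians(self.lat_deg)
        lon = np.radians(self.lon_deg)
        sl, cl = np.sin(lat), np.cos(lat)
        so, co = np.sin(lon), np.cos(lon)
        # rows: east, north, up in ECEF
        return np.array(
            [
                [-so, co, 0.0],
                [-sl * co, -sl * so, cl],
                [cl * co, cl * so, sl],
            ]
        )

    def geodetic_to_enu(self, lat_deg, lon_deg, alt_m) -> np.ndarray:
        ecef = geodetic_to_ecef(lat_deg, lon_deg, alt_m)
        ecef0 = geodetic_to_ecef(self.lat_deg, self.lon_deg, self.alt_m)
        return (ecef - ecef0) @ self._rotation().T

    def enu_to_geodetic(self, enu) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        enu = np.asarray(enu, dtype=float)
        ecef0 = geodetic_to_ecef(self.lat_deg, self.lon_deg, self.alt_m)
        ecef = ecef0 + enu @ self._rotation()
        return ecef_to_geodetic(ecef)

    def to_dict(self) -> dict:
        return {"lat_deg": self.lat_deg, "lon_deg": self.lon_deg, "alt_m": self.alt_m}

    @classmethod
    def from_dict(cls, d: dict) -> "GeodeticOrigin":
        return cls(**d)


#: Default origin: intertidal rocky shore on the western edge of Jervis Bay,
#: New South Wales (the kind of site the synthetic scenes emulate).
DEFAULT_ORIGIN = GeodeticOrigin(lat_deg=-35.0857, lon_deg=150.6933, alt_m=0.0)
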