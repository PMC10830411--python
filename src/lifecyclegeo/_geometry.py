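"""Small geodesic helpers shared across the pipeline.

Coordinates are WGS84 decimal degrees throughout. The equal-area grid used
as the ecoregion alternative is built in a Lambert cylindrical equal-area
projection (x = R*lon, y = R*sin(lat)), which preserves cell area at every
latitude at the cost of shape distortion near the poles — acceptable for a
presence-counting grid.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


def haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances in km between points (lon, lat in degrees)."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def cylindrical_equal_area(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project (lon, lat) degrees to equal-area plane coordinates in km."""
    x = EARTH_RADIUS_KM * np.radians(np.asarray(lon, dtype=float))
    y = EARTH_RADIUS_KM * np.sin(np.radians(np.asarray(lat, dtype=float)))
    return x, y
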