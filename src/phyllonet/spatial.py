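"""Geographic distances and PCNM spatial eigenvectors.

PCNM (principal coordinates of neighbour matrices) builds multiscale
spatial predictors from a geographic distance matrix: distances beyond a
truncation threshold (the longest minimum-spanning-tree edge by default)
are replaced by four times the threshold, and the truncated matrix is
ordinated by PCoA; the positive-eigenvalue axes are the PCNM vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .distmat import DistanceMatrix, EigenvectorSet, pcoa

__all__ = ["GeoCoordinates", "haversine_matrix", "pcnm_vectors", "read_metadata_tsv"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class GeoCoordinates:
    """Decimal-degree coordinates (and elevation in metres) per object.

    Duplicate coordinates are allowed: plants sampled at the same site
    share the site's coordinates.
    """

    labels: list[str]
    latitude: np.ndarray
    longitude: np.ndarray
    elevation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        n = len(self.labels)
        if self.latitude.shape != (n,) or self.longitude.shape != (n,):
            raise ValueError("latitude/longitude must match labels")
        if np.any((self.latitude < -90) | (self.latitude > 90)):
            raise ValueError("latitude out of [-90, 90]")
        if np.any((self.longitude < -180) | (self.longitude > 180)):
            raise ValueError("longitude out of [-180, 180]")
        if self.elevation is not None:
            self.elevation = np.asarray(self.elevation, dtype=float)


def haversine_matrix(coords: GeoCoordinates) -> DistanceMatrix:
    """Great-circle distances in kilometres (Earth radius 6371.0 km)."""
    lat = np.radians(coords.latitude)
    lon = np.radians(coords.longitude)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against rounding
    return DistanceMatrix(coords.labels, d)


def pcnm_vectors(
    D_geo: DistanceMatrix, truncation: float | None = None
) -> EigenvectorSet:
    """PCNM spatial eigenvectors from a geographic distance matrix.

    The truncation threshold defaults to the longest edge of the
    minimum spanning tree of the distance matrix; entries above it are
    replaced by four times the threshold before PCoA. All
    positive-eigenvalue axes are retained and named PCNM1..k.
    """
    if D_geo.n < 3:
        raise ValueError("PCNM needs at least 3 locations")
    if np.any(np.isinf(D_geo.values)):
        raise ValueError("PCNM requires finite distances")
    if truncation is None:
        mst = minimum_spanning_tree(D_geo.values).toarray()
        truncation = float(mst.max())
    w = D_geo.values.copy()
    if truncation > 0:
        w[w > truncation] = 4.0 * truncation
    np.fill_diagonal(w, 0.0)
    return pcoa(DistanceMatrix(D_geo.labels, w)).renamed("PCNM")


def read_metadata_tsv(path) -> pd.DataFrame:
    """Sample metadata table.

    Expected columns: sample_id, population, region, latitude,
    longitude, elevation, MAT, MAP (climate columns optional).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "population", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return df.set_index("sample_id")
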