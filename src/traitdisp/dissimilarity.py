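"""Distance structures: Jaccard, Euclidean, great-circle and soil distances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_validation import BinaryTraitMatrix, ContinuousTraitMatrix, EnvironmentTable
from .ordination import zscore

__all__ = [
    "DistanceMatrix",
    "filter_shared_columns",
    "jaccard_dissimilarity",
    "euclidean_distance",
    "spatial_distance",
    "soil_distance",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0

#: metric tags whose off-diagonal entries may legitimately be negative
SIGNED_METRICS = frozenset({"log_km", "soil_residual"})


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix over named entities with a metric tag."""

    entity_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if self.metric not in SIGNED_METRICS and np.any(v < 0):
            raise ValueError(f"negative entries invalid for metric {self.metric!r}")
        if self.metric == "jaccard" and np.any(v > 1 + 1e-12):
            raise ValueError("Jaccard dissimilarity above 1")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.entity_ids)

    def sub(self, ids: list[str]) -> np.ndarray:
        """Square sub-matrix for a list of entity ids (repeats allowed)."""
        idx = [self.entity_ids.index(i) for i in ids]
        return self.values[np.ix_(idx, idx)]

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.entity_ids.index(a), self.entity_ids.index(b)])


def filter_shared_columns(sm: BinaryTraitMatrix, min_species: int = 2) -> BinaryTraitMatrix:
    """Keep only trait columns present in at least `min_species` species."""
    sums = sm.data.sum(axis=0)
    keep = list(sums.index[sums >= min_species])
    return BinaryTraitMatrix(sm.data[keep].copy())


def jaccard_dissimilarity(sm: BinaryTraitMatrix) -> DistanceMatrix:
    """1 - Jaccard index over binary trait profiles: 1 - |A&B| / |A|B|."""
    rowsums = sm.data.sum(axis=1)
    empty = list(rowsums.index[rowsums == 0])
    if empty:
        raise ValueError(f"Jaccard undefined for all-zero profile(s): {empty}")
    d = pdist(sm.data.to_numpy(dtype=bool), metric="jaccard")
    return DistanceMatrix(sm.species_ids, squareform(d), metric="jaccard")


def euclidean_distance(
    rut: ContinuousTraitMatrix, trait_subset: list[str] | None = None
) -> DistanceMatrix:
    """Euclidean distance over (a subset of) continuous trait columns.

    Values are used as given — standardize upstream; distances are over
    raw trait columns, not ordination scores.
    """
    if trait_subset is None:
        trait_subset = rut.trait_ids
    if not trait_subset:
        raise ValueError("empty trait subset")
    missing = sorted(set(trait_subset) - set(rut.trait_ids))
    if missing:
        raise ValueError(f"trait subset names unknown trait(s) {missing}")
    X = rut.data[list(trait_subset)].to_numpy(dtype=float)
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(rut.species_ids, d, metric="euclidean")


def haversine_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) on a spherical Earth."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return d


def spatial_distance(
    coordinates: pd.DataFrame, log_transform: bool = True
) -> DistanceMatrix:
    """Great-circle plot distances, natural-log transformed off-diagonal.

    `coordinates` has columns ``longitude`` and ``latitude`` in decimal
    degrees.  The diagonal stays at 0; the log applies to off-diagonal
    entries only and requires all plots to be >= 1 m apart.
    """
    d = haversine_km(
        coordinates["longitude"].to_numpy(), coordinates["latitude"].to_numpy()
    )
    ids = list(coordinates.index.astype(str))
    if not log_transform:
        return DistanceMatrix(ids, d, metric="km")
    off = ~np.eye(len(ids), dtype=bool)
    if np.any(d[off] < 1e-3):  # < 1 m
        raise ValueError("coincident plots: log spatial distance undefined")
    out = d.copy()
    out[off] = np.log(d[off])
    return DistanceMatrix(ids, out, metric="log_km")


def soil_distance(
    env: EnvironmentTable,
    variable_subset: list[str],
    residualize_on: DistanceMatrix | None = None,
) -> DistanceMatrix:
    """Euclidean distance over z-scored soil variables.

    The subset columns are re-z-scored within the subset so variables
    weigh equally.  With ``residualize_on`` (typically the log spatial
    distance), off-diagonal entries are replaced by residuals of the OLS
    fit of soil distance on the companion distance over the vectorized
    upper triangle — removing the spatial effect; residuals may be
    negative.
    """
    missing = sorted(set(variable_subset) - set(env.variable_ids))
    if missing:
        raise ValueError(f"soil variable(s) missing from environment table: {missing}")
    Z = zscore(env.data[list(variable_subset)])
    d = squareform(pdist(Z.to_numpy(dtype=float), metric="euclidean"))
    ids = list(env.plot_ids)
    if residualize_on is None:
        return DistanceMatrix(ids, d, metric="soil")
    if residualize_on.entity_ids != ids:
        raise ValueError("companion distance matrix plots do not match")
    iu = np.triu_indices(len(ids), k=1)
    y = d[iu]
    x = residualize_on.values[iu]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    out = np.zeros_like(d)
    out[iu] = resid
    out = out + out.T
    return DistanceMatrix(ids, out, metric="soil_residual")
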