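"""Divergence vectors and theta parallelism angles.

A divergence vector runs from a marine reference centroid to a freshwater
site centroid in PC morphospace; its Euclidean norm L measures the
magnitude of divergence.  For two freshwater sites sharing the same marine
reference, theta is the angle between their divergence vectors: angles well
below the 90 degree null indicate parallel trajectories.  All angles are
reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from mfdiv.morphospace import axis_divergence


class ZeroVectorError(ValueError):
    """Angle requested for a zero-length vector (direction undefined)."""


@dataclass(frozen=True)
class DivergenceVector:
    marine: str
    freshwater: str
    axes: tuple
    components: tuple  # freshwater centroid - marine centroid, per axis

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.components))


def divergence_vector(
    centroids: pd.DataFrame, marine: str, freshwater: str, axes=None
) -> DivergenceVector:
    """Vector from the marine reference centroid to the freshwater centroid."""
    if axes is None:
        axes = [c for c in centroids.columns if c != "n"]
    axes = list(axes)
    missing = set(axes) - set(centroids.columns)
    if missing:
        raise KeyError(f"axes not in centroids: {sorted(missing)}")
    for site in (marine, freshwater):
        if site not in centroids.index:
            raise KeyError(f"site {site!r} not in centroids")
    comp = (
        centroids.loc[freshwater, axes].to_numpy(dtype=float)
        - centroids.loc[marine, axes].to_numpy(dtype=float)
    )
    return DivergenceVector(
        marine=marine, freshwater=freshwater, axes=tuple(axes),
        components=tuple(comp.tolist()),
    )


def theta(v1: DivergenceVector, v2: DivergenceVector) -> float:
    """Angle in degrees between two divergence vectors sharing a reference.

    Computed with the numerically stable half-angle form
    2 * atan2(|u - v|, |u + v|) on the unit vectors, which returns exactly 0
    for collinear vectors (arccos of a rounded cosine would not).
    Zero-length vectors are an error: an undefined direction must not
    silently count as perfect parallelism.
    """
    if v1.marine != v2.marine:
        raise ValueError("vectors must share the same marine reference")
    if v1.axes != v2.axes:
        raise ValueError("vectors must be computed on identical axes")
    a = np.asarray(v1.components)
    b = np.asarray(v2.components)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ZeroVectorError("theta undefined for a zero-length vector")
    u, w = a / na, b / nb
    rad = 2.0 * np.arctan2(np.linalg.norm(u - w), np.linalg.norm(u + w))
    return float(np.degrees(rad))


def theta_set(
    centroids: pd.DataFrame, marine: str, freshwater_sites, axes=None
) -> pd.DataFrame:
    """Theta for every unordered freshwater pair under one marine reference.

    For f freshwater sites this yields C(f, 2) records.
    """
    freshwater_sites = list(freshwater_sites)
    if len(freshwater_sites) < 2:
        raise ValueError("theta_set needs >= 2 freshwater sites")
    vecs = {
        f: divergence_vector(centroids, marine, f, axes) for f in freshwater_sites
    }
    rows = [
        {
            "marine": marine,
            "freshwater_a": a,
            "freshwater_b": b,
            "theta_deg": theta(vecs[a], vecs[b]),
        }
        for a, b in combinations(freshwater_sites, 2)
    ]
    return pd.DataFrame(rows)


def all_theta_records(
    centroids: pd.DataFrame, marine_sites, freshwater_sites, axes=None
) -> pd.DataFrame:
    """theta_set over every marine reference, concatenated."""
    return pd.concat(
        [theta_set(centroids, m, freshwater_sites, axes) for m in marine_sites],
        ignore_index=True,
    )


def divergence_estimates(
    centroids: pd.DataFrame,
    marine_sites,
    freshwater_sites,
    metric: str = "pc_axis_diff",
    axis: str = "PC1",
    axes=None,
) -> pd.DataFrame:
    """Long table of divergence values for every marine x freshwater pair.

    ``metric`` is ``"pc_axis_diff"`` (absolute centroid difference on one
    axis) or ``"vector_length"`` (Euclidean norm over ``axes``).
    """
    if metric not in ("pc_axis_diff", "vector_length"):
        raise ValueError(f"unknown metric {metric!r}")
    rows = []
    for m in marine_sites:
        for f in freshwater_sites:
            if metric == "pc_axis_diff":
                value = axis_divergence(centroids, m, f, axis)
            else:
                value = divergence_vector(centroids, m, f, axes).length
            rows.append(
                {"freshwater": f, "marine": m, "metric": metric, "value": value}
            )
    return pd.DataFrame(rows)


def per_reference_summary(records: pd.DataFrame, value_col: str = "theta_deg") -> pd.DataFrame:
    """Mean/min/max of a value column per marine reference."""
    g = records.groupby("marine")[value_col]
    out = g.agg(["mean", "min", "max", "count"]).reset_index()
    return out.rename(columns={c: f"{value_col}_{c}" for c in ("mean", "min", "max", "count")})
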