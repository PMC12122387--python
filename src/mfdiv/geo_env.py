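"""Shortest-through-water geographic distance and climatic difference.

Fish disperse through water, so the relevant geographic separation between
two sites is the shortest path through the water mask of a rasterised map,
not the great-circle distance.  Paths are 8-connected by default with
diagonal steps costing sqrt(2) x cell size (4-connectivity overestimates
diagonal channels); site coordinates snap to the nearest water cell within
a small documented radius.

Environmental difference is computed from the 19 standard bioclimatic
variables: collinear variables (|Pearson r| above 0.80) are pruned greedily
in a priority order that prefers annual means and overall variation to
monthly/quarterly summaries, the retained set is run through a
correlation-matrix PCA at site level, and each marine-freshwater pair gets
the absolute difference of site scores on the requested axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from mfdiv.simulate import BIO_VARS

logger = logging.getLogger(__name__)

#: Greedy retention priority: annual trends and overall variation first.
DEFAULT_BIO_PRIORITY = (
    "BIO01", "BIO12", "BIO02", "BIO03", "BIO15", "BIO08",
) + tuple(v for v in BIO_VARS if v not in
          ("BIO01", "BIO12", "BIO02", "BIO03", "BIO15", "BIO08"))

SNAP_RADIUS_CELLS = 3


class DisconnectedError(RuntimeError):
    """No through-water path exists between the two sites."""


class SnapError(ValueError):
    """A coordinate has no water cell within the snap radius."""


@dataclass
class WaterRaster:
    """Boolean water mask over a regular grid with a fixed cell size in km."""

    water: np.ndarray  # 2-D bool, True = water
    resolution_km: float

    def __post_init__(self):
        self.water = np.asarray(self.water, dtype=bool)
        if self.water.ndim != 2:
            raise ValueError("water mask must be 2-D")
        if self.resolution_km <= 0:
            raise ValueError("resolution_km must be > 0")
        if not self.water.any():
            raise ValueError("raster has no water cells")

    @property
    def shape(self):
        return self.water.shape

    def to_ascii(self, path) -> None:
        """Plain-text grid: header line, then one row of 0/1 per line."""
        with open(path, "w") as fh:
            fh.write(f"rows {self.shape[0]} cols {self.shape[1]} "
                     f"resolution_km {self.resolution_km}\n")
            for row in self.water.astype(int):
                fh.write("".join(map(str, row)) + "\n")

    @classmethod
    def from_ascii(cls, path) -> "WaterRaster":
        with open(path) as fh:
            header = fh.readline().split()
            res = float(header[header.index("resolution_km") + 1])
            water = np.array(
                [[ch == "1" for ch in line.strip()] for line in fh if line.strip()]
            )
        return cls(water=water, resolution_km=res)


def snap_to_water(raster: WaterRaster, cell, radius: int = SNAP_RADIUS_CELLS):
    """Nearest water cell to ``cell`` within ``radius`` (Euclidean, cells)."""
    r, c = int(round(cell[0])), int(round(cell[1]))
    nrow, ncol = raster.shape
    best, best_d = None, np.inf
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and raster.water[rr, cc]:
                d = dr * dr + dc * dc
                if d < best_d:
                    best, best_d = (rr, cc), d
    if best is None:
        raise SnapError(f"no water cell within {radius} cells of {(r, c)}")
    if best != (r, c):
        logger.debug("snapped %s -> %s", (r, c), best)
    return best


def _water_graph(raster: WaterRaster, connectivity: int = 8):
    """Sparse weighted adjacency over water cells; node id = flat cell index."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    nrow, ncol = raster.shape
    w = raster.water
    steps = [(-1, 0, 1.0), (0, -1, 1.0)]
    if connectivity == 8:
        steps += [(-1, -1, np.sqrt(2)), (-1, 1, np.sqrt(2))]
    rows, cols, data = [], [], []
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    for dr, dc, cost in steps:
        r0, r1 = max(0, -dr), min(nrow, nrow - dr)
        c0, c1 = max(0, -dc), min(ncol, ncol - dc)
        a = idx[r0:r1, c0:c1]
        b = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = w[r0:r1, c0:c1] & w[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        rows.append(a[ok]); cols.append(b[ok])
        data.append(np.full(ok.sum(), cost * raster.resolution_km))
    rows = np.concatenate(rows); cols = np.concatenate(cols)
    data = np.concatenate(data)
    n = nrow * ncol
    return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def waterway_distance(
    raster: WaterRaster, a, b, connectivity: int = 8,
    snap_radius: int = SNAP_RADIUS_CELLS,
) -> float:
    """Shortest through-water distance in km between two (row, col) cells.

    Coordinates snap to the nearest water cell within ``snap_radius``.
    Raises :class:`DisconnectedError` when the two cells lie in different
    water components.
    """
    ca = snap_to_water(raster, a, snap_radius)
    cb = snap_to_water(raster, b, snap_radius)
    if ca == cb:
        return 0.0
    ncol = raster.shape[1]
    graph = _water_graph(raster, connectivity)
    src = ca[0] * ncol + ca[1]
    dst = cb[0] * ncol + cb[1]
    dist = dijkstra(graph, directed=False, indices=src)
    d = dist[dst]
    if not np.isfinite(d):
        raise DisconnectedError(f"no water path between {ca} and {cb}")
    return float(d)


def distance_matrix(
    raster: WaterRaster, site_cells: dict, connectivity: int = 8,
    snap_radius: int = SNAP_RADIUS_CELLS,
) -> pd.DataFrame:
    """Symmetric through-water distance matrix (km) over named sites."""
    sites = list(site_cells)
    snapped = {s: snap_to_water(raster, site_cells[s], snap_radius) for s in sites}
    ncol = raster.shape[1]
    graph = _water_graph(raster, connectivity)
    nodes = {s: rc[0] * ncol + rc[1] for s, rc in snapped.items()}
    srcs = sorted(set(nodes.values()))
    dist = dijkstra(graph, directed=False, indices=srcs)
    row_of = {node: i for i, node in enumerate(srcs)}
    out = pd.DataFrame(0.0, index=sites, columns=sites)
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            d = dist[row_of[nodes[a]], nodes[b]]
            if not np.isfinite(d):
                raise DisconnectedError(f"no water path between {a} and {b}")
            out.loc[a, b] = out.loc[b, a] = float(d)
    return out


# ---------------------------------------------------------------------------
# climate

def prune_climate_variables(
    climate: pd.DataFrame,
    threshold: float = 0.80,
    priority=DEFAULT_BIO_PRIORITY,
) -> list[str]:
    """Greedy collinearity pruning of the bioclim table.

    Walking the priority list, a variable is retained unless its |Pearson r|
    with an already-retained variable exceeds ``threshold``.  Constant
    variables (undefined correlation) are dropped with a warning.  The
    result is independent of site (row) order.
    """
    if len(climate) < 2:
        raise ValueError("pruning needs >= 2 sites")
    present = [v for v in priority if v in climate.columns]
    retained: list[str] = []
    for var in present:
        x = climate[var].to_numpy(dtype=float)
        if np.std(x) == 0:
            logger.warning("dropping constant climate variable %s", var)
            continue
        collinear = False
        for kept in retained:
            r = np.corrcoef(x, climate[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) > threshold:
                collinear = True
                break
        if not collinear:
            retained.append(var)
    return retained


def climate_pca(climate: pd.DataFrame, retained) -> "PcaResult":
    """Correlation-matrix PCA of the retained climate variables at site level."""
    from mfdiv.morphospace import run_pca

    return run_pca(
        climate, traits=list(retained), scale=True, orient_pc1_by_habitat=False
    )


def environment_difference(
    climate: pd.DataFrame,
    retained,
    axes=("PC1", "PC2"),
    pairs=None,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Absolute climate-PC score difference for site pairs.

    ``pairs`` is an iterable of (marine, freshwater) site names; when omitted
    it is every marine x freshwater combination from ``metadata``.  Returns a
    long table (marine, freshwater, one abs-difference column per axis).
    Pairs with a missing climate value are flagged missing, not dropped.
    """
    if pairs is None:
        if metadata is None:
            raise ValueError("provide pairs or metadata")
        marine = metadata.loc[metadata["habitat"] == "marine", "site"]
        fresh = metadata.loc[metadata["habitat"] == "freshwater", "site"]
        pairs = [(m, f) for m in marine for f in fresh]
    pca = climate_pca(climate.dropna(subset=list(retained)), retained)
    scores = pca.scores.copy()
    scores["site"] = climate.loc[scores.index, "site"].to_numpy()
    scores = scores.set_index("site")
    rows = []
    for m, f in pairs:
        row = {"marine": m, "freshwater": f}
        for ax in axes:
            if m in scores.index and f in scores.index:
                row[f"abs_diff_{ax}"] = float(abs(scores.loc[f, ax] - scores.loc[m, ax]))
            else:
                row[f"abs_diff_{ax}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
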