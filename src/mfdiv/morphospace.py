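"""Morphospace PCA, site centroids, and per-axis divergence scores.

The composite morphospace is a principal component analysis of the ten
(size-corrected) traits, fitted once on all specimens jointly so marine and
freshwater fish share one coordinate system.  Traits are z-scored by default
(they mix millimetres and counts).  Two determinism conventions are applied:
the largest-magnitude loading on each axis is made positive, and — when
habitat labels are available — PC1 is oriented so the freshwater mean score
exceeds the marine mean, making divergence directions comparable across
runs.

Divergence between a freshwater site and a marine reference on one axis is
the absolute difference of the two site centroids (per-specimen score means)
on that axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mfdiv.simulate import TRAITS

logger = logging.getLogger(__name__)

PANMICTIC = "panmictic"


@dataclass
class PcaResult:
    """Loadings, per-specimen scores, and percent variance per axis.

    ``scores`` rows align with the input table rows (same index); ``sites``
    and ``habitats`` are the corresponding labels, carried along so centroid
    computations need no re-join.
    """

    loadings: pd.DataFrame  # trait x axis
    scores: pd.DataFrame  # specimen x axis
    pct_variance: pd.Series  # per axis, sums to 100
    mean: pd.Series
    scale: pd.Series | None  # None when fitted on the covariance matrix
    sites: pd.Series | None = None
    habitats: pd.Series | None = None
    dropped_rows: int = 0

    @property
    def axes(self) -> list[str]:
        return list(self.loadings.columns)


def run_pca(
    table: pd.DataFrame,
    traits=None,
    scale: bool = True,
    orient_pc1_by_habitat: bool = True,
) -> PcaResult:
    """PCA of the trait columns (correlation matrix when ``scale`` is True).

    Rows with any missing trait value are dropped and logged.  Axes are
    ordered by decreasing explained variance and named PC1, PC2, ...  A
    constant trait column with scaling on is an error (its z-score is
    undefined).
    """
    if traits is None:
        traits = [t for t in TRAITS if t in table.columns]
        if not traits:
            raise ValueError("no recognised trait columns in table")
    X = table[list(traits)].astype(float)
    keep = X.notna().all(axis=1)
    if (~keep).any():
        logger.warning("run_pca: dropping %d rows with missing traits", (~keep).sum())
    X = X[keep]
    if len(X) < 2:
        raise ValueError("PCA needs >= 2 complete specimens")

    mean = X.mean()
    Xc = X - mean
    scale_ser = None
    if scale:
        sd = X.std(ddof=1)
        constant = sd[sd == 0].index.tolist()
        if constant:
            raise ValueError(f"constant trait column(s) with scale=True: {constant}")
        Xc = Xc / sd
        scale_ser = sd

    U, s, Vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
    var = s**2 / (len(X) - 1)
    pct = 100.0 * var / var.sum()
    axes = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(Vt.T, index=list(traits), columns=axes)
    scores = pd.DataFrame(U * s, index=X.index, columns=axes)

    # deterministic sign: largest-|loading| per axis is positive
    for ax in axes:
        col = loadings[ax]
        if col.iloc[np.argmax(np.abs(col.to_numpy()))] < 0:
            loadings[ax] = -col
            scores[ax] = -scores[ax]

    sites = table.loc[X.index, "site"] if "site" in table.columns else None
    habitats = table.loc[X.index, "habitat"] if "habitat" in table.columns else None
    if orient_pc1_by_habitat and habitats is not None and habitats.nunique() == 2:
        fw = scores.loc[habitats == "freshwater", "PC1"].mean()
        ma = scores.loc[habitats == "marine", "PC1"].mean()
        if fw < ma:
            loadings["PC1"] = -loadings["PC1"]
            scores["PC1"] = -scores["PC1"]

    return PcaResult(
        loadings=loadings,
        scores=scores,
        pct_variance=pd.Series(pct, index=axes, name="pct_variance"),
        mean=mean,
        scale=scale_ser,
        sites=sites,
        habitats=habitats,
        dropped_rows=int((~keep).sum()),
    )


def site_centroids(pca: PcaResult, axes=None, sites=None) -> pd.DataFrame:
    """Per-site mean scores on the requested axes (all axes by default).

    ``sites`` overrides the site labels carried by the PCA (used for the
    panmictic relabelling); it must align with the score rows.  The result
    has one row per site with the axis columns plus ``n``.
    """
    labels = sites if sites is not None else pca.sites
    if labels is None:
        raise ValueError("no site labels available")
    labels = labels.loc[pca.scores.index]
    axes = list(axes) if axes is not None else pca.axes
    unknown = set(axes) - set(pca.axes)
    if unknown:
        raise KeyError(f"unknown axes: {sorted(unknown)}")
    cent = pca.scores[axes].groupby(labels).mean()
    cent["n"] = pca.scores.groupby(labels).size()
    cent.index.name = "site"
    return cent


def axis_divergence(
    centroids: pd.DataFrame, marine: str, freshwater: str, axis: str = "PC1"
) -> float:
    """|centroid difference| between a freshwater site and a marine reference
    on one PC axis; symmetric in site order."""
    for site in (marine, freshwater):
        if site not in centroids.index:
            raise KeyError(f"site {site!r} not in centroids")
    if axis not in centroids.columns:
        raise KeyError(f"unknown axis {axis!r}")
    return float(abs(centroids.loc[freshwater, axis] - centroids.loc[marine, axis]))


def pool_panmictic(table: pd.DataFrame, label: str = PANMICTIC) -> pd.DataFrame:
    """Recode all marine specimens as one pooled 'panmictic' site.

    Freshwater rows are untouched; row count and order are preserved.
    """
    marine = table["habitat"] == "marine"
    if not marine.any():
        raise ValueError("no marine specimens to pool")
    out = table.copy()
    out.loc[marine, "site"] = label
    return out
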