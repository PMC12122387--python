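"""Allometric size correction and variance-homogeneity testing.

Linear traits covary with body size, so before any divergence analysis each
trait is adjusted to a common standard length: gamma_i = chi_i - beta *
(L_i - Lbar), where beta is the OLS slope of the raw trait on standard
length (fitted per population by default, since slopes differ among sites),
L_i the fish's standard length, and Lbar the grand mean standard length of
the dataset.  Two traits follow the conventional exemptions for this system:
gill raker number is never size corrected, and lateral plate number is only
corrected in freshwater fish (marine fish are fully plated, with essentially
no size-related plate variation).

Levene's test (Brown-Forsythe median-centred by default) compares trait
variances between the marine and freshwater samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mfdiv.simulate import TRAITS

logger = logging.getLogger(__name__)

COMMON = "common"

#: (trait, habitat) combinations exempt from size correction. ``None``
#: habitat means exempt everywhere.
DEFAULT_EXEMPTIONS = (
    ("gill_raker_number", None),
    ("lateral_plate_number", "marine"),
)


class MissingFitError(KeyError):
    """A (trait, group) pair needing correction has no allometry fit."""


@dataclass(frozen=True)
class AllometryFit:
    """OLS slope of a raw trait on standard length for one group of fish."""

    trait: str
    group: str  # site name, or "common" for a pooled fit
    beta: float
    mean_length_mm: float  # grand mean standard length of the whole dataset
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("an allometry fit needs n >= 3")
        if self.mean_length_mm <= 0:
            raise ValueError("mean_length_mm must be positive")


@dataclass(frozen=True)
class LeveneResult:
    statistic: float
    df_num: int
    df_den: int
    p: float
    group_variances: dict
    center: str


def fit_allometry(
    table: pd.DataFrame,
    trait: str,
    grouping: str = "per_population",
    length_col: str = "standard_length_mm",
) -> dict[str, AllometryFit]:
    """Fit the trait-on-length slope per site (or pooled).

    ``grouping`` is ``"per_population"`` (one slope per site; the default,
    because slopes genuinely differ among populations) or ``"common"`` (one
    pooled slope).  Groups with fewer than 3 usable fish are excluded and
    logged.  ``mean_length_mm`` in every fit is the grand mean standard
    length over all rows with a length, shared across groups.
    """
    if grouping not in ("per_population", "common"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table")
    lbar = float(table[length_col].mean())
    usable = table[[length_col, trait]].notna().all(axis=1)
    fits: dict[str, AllometryFit] = {}
    if grouping == "common":
        groups = {COMMON: table[usable]}
    else:
        groups = dict(tuple(table[usable].groupby("site", sort=True)))
    for name, sub in groups.items():
        if len(sub) < 3:
            logger.warning(
                "allometry: group %r has %d usable fish for %s; excluded",
                name, len(sub), trait,
            )
            continue
        x = sub[length_col].to_numpy(dtype=float)
        y = sub[trait].to_numpy(dtype=float)
        vx = np.var(x, ddof=0)
        beta = 0.0 if vx == 0 else float(np.cov(x, y, ddof=0)[0, 1] / vx)
        fits[name] = AllometryFit(
            trait=trait, group=name, beta=beta, mean_length_mm=lbar, n=len(sub)
        )
    return fits


def fit_all_allometries(
    table: pd.DataFrame, traits=TRAITS, grouping: str = "per_population"
) -> dict[str, dict[str, AllometryFit]]:
    """Per-trait dict of allometry fits; convenience over ``fit_allometry``."""
    return {t: fit_allometry(table, t, grouping=grouping) for t in traits}


def _is_exempt(trait: str, habitat: str, exemptions) -> bool:
    for t, hab in exemptions:
        if t == trait and (hab is None or hab == habitat):
            return True
    return False


def size_correct(
    table: pd.DataFrame,
    fits: dict[str, dict[str, AllometryFit]],
    exemptions=DEFAULT_EXEMPTIONS,
    length_col: str = "standard_length_mm",
) -> pd.DataFrame:
    """Apply gamma_i = chi_i - beta * (L_i - Lbar) trait by trait.

    ``fits`` maps trait -> group -> AllometryFit (from
    ``fit_all_allometries``).  Exempted (trait, habitat) combinations pass
    through unchanged.  A row whose (trait, site) has no fit — and is not
    exempt — raises :class:`MissingFitError`.  Missing trait values stay
    missing.  The output schema is identical to the input.
    """
    out = table.copy()
    for trait, group_fits in fits.items():
        if trait not in out.columns:
            continue
        corrected = out[trait].astype(float).copy()
        for (site, habitat), sub in out.groupby(["site", "habitat"], sort=False):
            if _is_exempt(trait, habitat, exemptions):
                continue
            fit = group_fits.get(site, group_fits.get(COMMON))
            if fit is None:
                raise MissingFitError(
                    f"no allometry fit for trait {trait!r} in group {site!r}"
                )
            idx = sub.index
            corrected.loc[idx] = sub[trait] - fit.beta * (
                sub[length_col] - fit.mean_length_mm
            )
        out[trait] = corrected
    return out


def allometry_audit(fits: dict[str, dict[str, AllometryFit]]) -> pd.DataFrame:
    """Flat audit table (trait, group, beta, mean_length_mm, n)."""
    rows = [
        {
            "trait": f.trait,
            "group": f.group,
            "beta": f.beta,
            "mean_length_mm": f.mean_length_mm,
            "n": f.n,
        }
        for per_trait in fits.values()
        for f in per_trait.values()
    ]
    return pd.DataFrame(rows)


def levene_test(values, groups, center: str = "median") -> LeveneResult:
    """Levene's homogeneity-of-variance test (one-way ANOVA on absolute
    deviations from the group centre; median centring — Brown-Forsythe — by
    default, matching the convention of the standard regression packages)."""
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("levene_test needs >= 2 groups")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    stat, p = stats.levene(*samples, center=center)
    n = len(values)
    k = len(labels)
    return LeveneResult(
        statistic=float(stat),
        df_num=k - 1,
        df_den=n - k,
        p=float(p),
        group_variances={str(g): float(np.var(s, ddof=1)) for g, s in zip(labels, samples)},
        center=center,
    )


def habitat_variance_table(
    table: pd.DataFrame, traits=TRAITS, center: str = "median"
) -> pd.DataFrame:
    """Per-trait marine vs freshwater Levene test, one row per trait."""
    rows = []
    for t in traits:
        usable = table[t].notna()
        res = levene_test(table.loc[usable, t], table.loc[usable, "habitat"], center)
        rows.append(
            {
                "trait": t,
                "freshwater_variance": res.group_variances.get("freshwater", np.nan),
                "marine_variance": res.group_variances.get("marine", np.nan),
                "F": res.statistic,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p": res.p,
                "center": center,
            }
        )
    return pd.DataFrame(rows)
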