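"""Mixed-effects tests of the marine-reference effect and distance-decay fits.

Two fitting routes are used.  The marine-reference effect on divergence is
tested on the complete pairwise table (every marine reference crossed with
every freshwater site, one value per cell), which is a balanced two-way
layout with marine reference as a fixed factor and freshwater site as a
random intercept; for that design the REML solution has a closed form, and
``reference_effect_test`` computes it directly: F = MS_reference /
MS_residual with (r - 1, (r - 1)(f - 1)) degrees of freedom, and the
random-intercept variance from the ANOVA estimator (MS_freshwater -
MS_residual) / r.  General models with continuous predictors (divergence
against waterway distance or climate difference, with freshwater site as a
random intercept) go through ``fit_lmm``, a thin wrapper over statsmodels
MixedLM (REML) that also reduces to OLS when no random intercept is
declared.

Denominator degrees of freedom for fixed-effect tests use the
between-within (containment) convention: n_obs - rank(fixed) - n_groups + 1
for mixed fits, n_obs - rank(fixed) for OLS.  Fixed-effect sums of squares
are reported on the residual-variance scale (SS = F x df_num x sigma^2), the
convention of the standard mixed-model ANOVA tables.  p-values are reported
but never drive control flow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class LmmFit:
    response: str
    fixed_terms: list
    coefficients: pd.DataFrame  # term, beta, se, t, p
    anova: pd.DataFrame  # term, ss, df_num, df_den, F, p
    random_intercept_variance: float | None
    random_intercept_se: float | None
    residual_variance: float
    n_obs: int
    n_groups: int | None
    method: str  # "reml", "ols", "balanced_anova"
    converged: bool = True


def _term_of(exog_name: str) -> str:
    # "C(marine)[T.m2]" -> "C(marine)"; "distance_km" -> itself
    return exog_name.split("[")[0]


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed,
    random_intercept: str | None = None,
) -> LmmFit:
    """Linear (mixed) model of ``response`` on the fixed terms.

    ``fixed`` is a list of formula terms (e.g. ``["distance_km"]`` or
    ``["C(marine)"]``).  With ``random_intercept`` set to a grouping column
    a random-intercept model is fitted by REML; with ``None`` the fit is
    ordinary least squares.  Non-convergence is flagged on the result, never
    silent.  A single-level grouping is an error.
    """
    import statsmodels.formula.api as smf

    fixed = list(fixed)
    formula = f"{response} ~ " + " + ".join(fixed)
    if random_intercept is not None:
        n_groups = data[random_intercept].nunique()
        if n_groups < 2:
            raise ValueError("random intercept grouping needs >= 2 levels")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data[random_intercept])
            res = None
            # boundary fits (group variance ~ 0) can break the default
            # optimiser; fall back to derivative-free methods
            for method in ("bfgs", "powell", "nm"):
                try:
                    res = model.fit(reml=True, method=method)
                    break
                except (np.linalg.LinAlgError, ValueError):
                    continue
            if res is None:
                raise RuntimeError("mixed-model fit failed with every optimiser")
        converged = bool(getattr(res, "converged", True))
        beta = res.fe_params
        se = res.bse_fe
        sigma2 = float(res.scale)
        var_re = float(res.cov_re.iloc[0, 0])
        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore")  # bse_re is NaN at the boundary
            bre = res.bse_re
        se_re = float(bre.iloc[0]) if hasattr(bre, "iloc") else float(bre[0])
        k = len(beta)
        df_den = len(data) - k - n_groups + 1
        cov_fe = np.asarray(res.cov_params())[:k, :k]
        method = "reml"
    else:
        model = smf.ols(formula, data)
        res = model.fit()
        converged = True
        beta = res.params
        se = res.bse
        sigma2 = float(res.mse_resid)
        var_re = None
        se_re = None
        n_groups = None
        df_den = int(res.df_resid)
        cov_fe = np.asarray(res.cov_params())
        method = "ols"

    tvals = beta / se
    coef = pd.DataFrame(
        {
            "term": beta.index,
            "beta": beta.to_numpy(),
            "se": se.to_numpy(),
            "t": tvals.to_numpy(),
            "p": 2 * stats.t.sf(np.abs(tvals.to_numpy()), df_den),
        }
    )

    # per-term Wald F on the fixed effects, grouped by formula term
    names = list(beta.index)
    anova_rows = []
    for term in fixed:
        idx = [i for i, nm in enumerate(names) if _term_of(nm) == term]
        if not idx:
            continue
        b = beta.to_numpy()[idx]
        V = cov_fe[np.ix_(idx, idx)]
        q = len(idx)
        F = float(b @ np.linalg.solve(V, b) / q)
        anova_rows.append(
            {
                "term": term,
                "ss": F * q * sigma2,
                "df_num": q,
                "df_den": df_den,
                "F": F,
                "p": float(stats.f.sf(F, q, df_den)),
            }
        )
    return LmmFit(
        response=response,
        fixed_terms=fixed,
        coefficients=coef,
        anova=pd.DataFrame(anova_rows),
        random_intercept_variance=var_re,
        random_intercept_se=se_re,
        residual_variance=sigma2,
        n_obs=len(data),
        n_groups=n_groups,
        method=method,
        converged=converged,
    )


def _complete_matrix(divergences: pd.DataFrame, value_col: str) -> pd.DataFrame:
    mat = divergences.pivot_table(
        index="freshwater", columns="marine", values=value_col, aggfunc="mean"
    )
    incomplete = mat.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "reference_effect_test: dropping freshwater sites with missing "
            "cells: %s", list(mat.index[incomplete]),
        )
        mat = mat[~incomplete]
    return mat


def reference_effect_test(
    divergences: pd.DataFrame, value_col: str = "value"
) -> LmmFit:
    """Does the estimated divergence depend on which marine reference is used?

    ``divergences`` is a long table with columns ``freshwater``, ``marine``
    and ``value_col`` (one divergence estimate per marine x freshwater
    pair).  Fits divergence ~ marine_reference (fixed) + (1 | freshwater)
    via the closed-form balanced two-way decomposition and reports the
    marine sum of squares, F with df_num = n_references - 1, and the
    freshwater random-intercept variance with its large-sample SE.
    """
    mat = _complete_matrix(divergences, value_col)
    r = mat.shape[1]  # marine references
    f = mat.shape[0]  # freshwater sites
    if r < 2:
        raise ValueError("need >= 2 marine references")
    if f < 2:
        raise ValueError("need >= 2 freshwater sites")
    y = mat.to_numpy(dtype=float)
    grand = y.mean()
    row_means = y.mean(axis=1)  # freshwater
    col_means = y.mean(axis=0)  # marine
    ss_marine = f * float(((col_means - grand) ** 2).sum())
    ss_fresh = r * float(((row_means - grand) ** 2).sum())
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ss_res = float((resid**2).sum())
    df_m, df_f, df_e = r - 1, f - 1, (r - 1) * (f - 1)
    ms_m, ms_f, ms_e = ss_marine / df_m, ss_fresh / df_f, ss_res / df_e
    if ms_m == 0:
        F = 0.0
    elif ms_e == 0:
        F = np.inf  # perfectly additive table: no residual variation
    else:
        F = ms_m / ms_e
    var_b = max((ms_f - ms_e) / r, 0.0)
    se_b = np.sqrt((2.0 / r**2) * (ms_f**2 / df_f + ms_e**2 / df_e))

    coef = pd.DataFrame(
        {
            "term": [f"marine[{m}]" for m in mat.columns],
            "beta": col_means - grand,
            "se": np.sqrt(ms_e * (1.0 / f) * (1 - 1.0 / r)),
            "t": np.nan,
            "p": np.nan,
        }
    )
    anova = pd.DataFrame(
        [
            {
                "term": "marine_reference",
                "ss": ss_marine,
                "df_num": df_m,
                "df_den": df_e,
                "F": F,
                "p": float(stats.f.sf(F, df_m, df_e)),
            },
            {
                "term": "residual",
                "ss": ss_res,
                "df_num": df_e,
                "df_den": np.nan,
                "F": np.nan,
                "p": np.nan,
            },
        ]
    )
    return LmmFit(
        response=value_col,
        fixed_terms=["marine_reference"],
        coefficients=coef,
        anova=anova,
        random_intercept_variance=var_b,
        random_intercept_se=float(se_b),
        residual_variance=ms_e,
        n_obs=r * f,
        n_groups=f,
        method="balanced_anova",
    )


def permute_within_freshwater(
    divergences: pd.DataFrame, rng: np.random.Generator, value_col: str = "value"
) -> pd.DataFrame:
    """Null-permuted copy: divergence values shuffled across marine references
    within each freshwater site (the exchangeable unit under no reference
    effect)."""
    out = divergences.copy()
    for _, idx in out.groupby("freshwater").groups.items():
        idx = list(idx)
        out.loc[idx, value_col] = (
            out.loc[idx, value_col].to_numpy()[rng.permutation(len(idx))]
        )
    return out


def percent_change_by_reference(
    divergences: pd.DataFrame, value_col: str = "value", normalize: str = "max"
) -> pd.Series:
    """Per freshwater site: how much the divergence estimate moves when the
    marine reference is substituted, as 100 x (max - min) / max (by default).

    ``normalize`` may also be ``"min"`` or ``"mean"``.  A site whose maximum
    is zero has no defined percent change and is reported missing.
    """
    if normalize not in ("max", "min", "mean"):
        raise ValueError(f"unknown normalize {normalize!r}")
    out = {}
    for site, sub in divergences.groupby("freshwater"):
        vals = sub[value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"freshwater site {site!r} has < 2 references")
        hi, lo = vals.max(), vals.min()
        denom = {"max": hi, "min": lo, "mean": vals.mean()}[normalize]
        if denom == 0:
            logger.warning("percent change undefined for %r (denominator 0)", site)
            out[site] = np.nan
        else:
            out[site] = 100.0 * (hi - lo) / denom
    return pd.Series(out, name="percent_change").rename_axis("freshwater")
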