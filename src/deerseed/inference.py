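"""Variance partitioning and seed-load regressions (study questions 1-4).

Q1/Q2 ask how much of the variance in LDD probability (per individual x
month cell) and in log seed load (per dung sample) is attributable to the
deer individual versus the sampling month; both are answered with ordinary
least-squares linear models, reported as separate one-way fits per factor
(matching the study's degrees of freedom) alongside a joint additive fit.
Q3 regresses log-transformed seed load on logit-transformed LDD probability
(both z-standardized); Q4 adds plant species and its interaction with LDD
probability and F-tests the interaction.

Fits go through statsmodels OLS; this module owns the transforms, the
variance bookkeeping and the result containers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

log = logging.getLogger("deerseed")


@dataclass
class AnovaResult:
    """One factor's share of variance from a least-squares fit."""

    factor: str
    r_squared: float
    f_statistic: float
    df_factor: int
    df_residual: int
    p_value: float
    n: int

    def __str__(self) -> str:
        return (f"{self.factor}: R^2 = {self.r_squared:.3f}, "
                f"F({self.df_factor}, {self.df_residual}) = "
                f"{self.f_statistic:.3f}, p = {self.p_value:.3g}")


@dataclass
class RegressionResult:
    """Simple OLS on transformed, standardized scales."""

    slope: float
    intercept: float
    f_statistic: float
    df_model: int
    df_residual: int
    p_value: float
    r_squared: float
    n: int


@dataclass
class InteractionResult:
    """F-test of a species x LDD-probability interaction."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    partial_r_squared: float
    n: int
    n_species: int


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def transform(values, kind: str, standardize: bool = True,
              n_events=None) -> np.ndarray:
    """Logit- or log-transform values, optionally z-standardizing.

    ``kind="logit"`` expects probabilities in [0, 1]; exact 0s and 1s are
    smoothed to (p*(n-1) + 0.5)/n using the per-cell event count ``n_events``
    before transforming, so finite-draw boundary cells stay finite.
    ``kind="log"`` expects non-negative values; if zeros are present, half
    the smallest positive value is added throughout before the log.
    """
    x = np.asarray(values, dtype=float)
    if kind == "logit":
        if ((x < 0) | (x > 1)).any():
            raise ValueError("logit inputs must lie in [0, 1]")
        boundary = (x == 0) | (x == 1)
        if boundary.any():
            if n_events is None:
                raise ValueError(
                    "logit of exact 0/1 needs n_events for smoothing")
            n = np.broadcast_to(np.asarray(n_events, dtype=float), x.shape)
            x = np.where(boundary, (x * (n - 1) + 0.5) / n, x)
        out = np.log(x / (1 - x))
    elif kind == "log":
        if (x < 0).any():
            raise ValueError("log inputs must be >= 0")
        if (x == 0).any():
            pos = x[x > 0]
            if pos.size == 0:
                raise ValueError("cannot log-transform an all-zero vector")
            x = x + pos.min() / 2
        out = np.log(x)
    else:
        raise ValueError(f"unknown transform kind {kind!r}")
    if standardize:
        sd = out.std(ddof=0)
        if sd == 0:
            raise ValueError("cannot standardize a zero-variance vector")
        out = (out - out.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

def one_way_partition(response, factor, name: str | None = None) -> AnovaResult:
    """One-way OLS variance partition of ``response`` by ``factor`` levels.

    R^2 is the factor sum of squares over the total; F and its p-value come
    from the usual one-way ANOVA decomposition. Levels with no observations
    simply do not appear; a factor with fewer than two levels, or a fit with
    no residual degrees of freedom, is an error.
    """
    df = pd.DataFrame({"y": np.asarray(response, dtype=float),
                       "g": pd.Categorical([str(v) for v in factor])})
    df = df.dropna()
    levels = df["g"].cat.remove_unused_categories().cat.categories
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 observed levels")
    if len(df) - len(levels) < 1:
        raise ValueError("no residual degrees of freedom")
    fit = smf.ols("y ~ C(g)", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    ss_factor = float(anova.loc["C(g)", "sum_sq"])
    ss_resid = float(anova.loc["Residual", "sum_sq"])
    ss_total = ss_factor + ss_resid
    return AnovaResult(
        factor=name or "factor",
        r_squared=ss_factor / ss_total if ss_total > 0 else 0.0,
        f_statistic=float(anova.loc["C(g)", "F"]),
        df_factor=int(anova.loc["C(g)", "df"]),
        df_residual=int(anova.loc["Residual", "df"]),
        p_value=float(anova.loc["C(g)", "PR(>F)"]),
        n=len(df),
    )


def joint_partition(response, factor_a, factor_b,
                    names: tuple[str, str] = ("a", "b")
                    ) -> tuple[list[AnovaResult], float]:
    """Two-factor additive OLS fit with sequential sums of squares.

    Returns per-factor results from BOTH fitting orders (order matters in
    unbalanced designs) plus the combined R^2 of the additive model. Aliased
    (confounded) factors are an error.
    """
    df = pd.DataFrame({
        "y": np.asarray(response, dtype=float),
        "a": pd.Categorical([str(v) for v in factor_a]),
        "b": pd.Categorical([str(v) for v in factor_b]),
    }).dropna()
    for col in ("a", "b"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col} needs at least 2 observed levels")
    fit = smf.ols("y ~ C(a) + C(b)", data=df).fit()
    if fit.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("factors are aliased (confounded design)")
    ss_total = float(((df["y"] - df["y"].mean()) ** 2).sum())
    combined_r2 = float(fit.rsquared)

    results: list[AnovaResult] = []
    name_of = {"a": names[0], "b": names[1]}
    for first, second in (("a", "b"), ("b", "a")):
        seq = sm.stats.anova_lm(
            smf.ols(f"y ~ C({first}) + C({second})", data=df).fit(), typ=1)
        for pos, fac in (("first", first), ("second", second)):
            row = seq.loc[f"C({fac})"]
            results.append(AnovaResult(
                factor=f"{name_of[fac]} (fitted {pos})",
                r_squared=float(row["sum_sq"]) / ss_total if ss_total else 0.0,
                f_statistic=float(row["F"]),
                df_factor=int(row["df"]),
                df_residual=int(seq.loc["Residual", "df"]),
                p_value=float(row["PR(>F)"]),
                n=len(df),
            ))
    return results, combined_r2


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def regress_load_on_ldd(loads, ldd, n_events=None) -> RegressionResult:
    """Regress log seed load on logit LDD probability (both standardized)."""
    loads = np.asarray(loads, dtype=float)
    ldd = np.asarray(ldd, dtype=float)
    if loads.size != ldd.size:
        raise ValueError("loads and ldd must align")
    if loads.size < 3:
        raise ValueError("need at least 3 observations")
    try:
        y = transform(loads, "log", standardize=True)
    except ValueError:
        # constant loads: the slope is identically 0, keep the raw scale
        y = transform(loads, "log", standardize=False)
    if np.ptp(np.asarray(ldd, dtype=float)) == 0:
        raise ValueError("zero-variance predictor")
    x = transform(ldd, "logit", standardize=True, n_events=n_events)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        f_statistic=float(fit.fvalue), df_model=int(fit.df_model),
        df_residual=int(fit.df_resid), p_value=float(fit.f_pvalue),
        r_squared=float(fit.rsquared), n=int(fit.nobs),
    )


def species_interaction_model(cells: pd.DataFrame,
                              min_cells_per_species: int = 2
                              ) -> InteractionResult:
    """Test whether the load-LDD relationship differs between plant species.

    ``cells`` must carry columns species, q (seed load), ldd (probability)
    and n_events. The full model (species + logit LDD + species:logit LDD)
    is compared to the reduced additive model by an F-test on the
    interaction; the interaction's partial R^2 is
    (SS_resid(reduced) - SS_resid(full)) / SS_resid(reduced).
    """
    df = cells.copy()
    counts = df.groupby("species")["q"].size()
    thin = counts[counts < min_cells_per_species].index
    if len(thin):
        log.warning("dropping %d species with < %d cells", len(thin),
                    min_cells_per_species)
        df = df[~df["species"].isin(thin)]
    if df["species"].nunique() < 2:
        raise ValueError("need at least 2 species with enough cells")
    df = df.assign(
        y=transform(df["q"].to_numpy(), "log", standardize=True),
        x=transform(df["ldd"].to_numpy(), "logit", standardize=True,
                    n_events=df["n_events"].to_numpy()),
    )
    full = smf.ols("y ~ C(species) * x", data=df).fit()
    reduced = smf.ols("y ~ C(species) + x", data=df).fit()
    ss_full = float(full.ssr)
    ss_red = float(reduced.ssr)
    df_num = int(reduced.df_resid - full.df_resid)
    df_den = int(full.df_resid)
    if ss_full == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ((ss_red - ss_full) / df_num) / (ss_full / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    return InteractionResult(
        f_statistic=float(f_stat), df_num=df_num, df_den=df_den, p_value=p,
        partial_r_squared=(ss_red - ss_full) / ss_red if ss_red else 0.0,
        n=len(df), n_species=int(df["species"].nunique()),
    )
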