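"""Island classification, diversity-geography regressions, and the ANCOVA.

Islands are split at fixed cutoffs into near/far (distance to mainland) and
small/large (terrestrial area) classes, diversity metrics are regressed on
the continuous geography, and a fixed-factor ANCOVA tests whether a weekly
diversity metric differs between island classes, across weeks, or in their
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import EstimationError, ParameterError
from .occurrence import IslandGeo

#: Classification cutoffs: near < 1.65 km <= far; small < 0.54 km^2 <= large.
DEFAULT_CUTOFFS = (1.65, 0.54)


@dataclass(frozen=True)
class IslandClass:
    island: str
    distance_class: str  # "near" | "far"
    size_class: str      # "small" | "large"


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    p_value: float
    adj_r2: float
    intercept: float
    n: int


@dataclass(frozen=True)
class AncovaTable:
    """Sequential (Type-I) ANCOVA table: class factor, week covariate, interaction."""

    terms: pd.DataFrame  # index: term name; columns: sum_sq, df, F, p
    residual_df: int
    residual_ss: float

    def __post_init__(self) -> None:
        total_df = self.terms["df"].sum() + self.residual_df
        n = total_df + 1  # total observations
        if n < 2:
            raise EstimationError("ANCOVA needs at least 2 observations")


def classify_island(
    geo: IslandGeo, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
) -> IslandClass:
    """Binary near/far and small/large classification with half-open intervals.

    The lower interval is [0, cutoff) and the upper [cutoff, inf), so an island
    sitting exactly on the area cutoff classes as large.
    """
    dist_cut, area_cut = cutoffs
    return IslandClass(
        island=geo.island,
        distance_class="near" if geo.isolation_km < dist_cut else "far",
        size_class="small" if geo.area_km2 < area_cut else "large",
    )


def regress_metric(values, predictor, transform: str = "none") -> RegressionResult:
    """OLS of a per-island metric on area or isolation, optionally log-log."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(y) != len(x):
        raise ParameterError("metric and predictor must have equal length")
    if len(y) < 3:
        raise ParameterError("regression requires at least 3 islands")
    if transform == "log-log":
        if (y <= 0).any() or (x <= 0).any():
            raise ParameterError("log-log transform requires strictly positive values")
        y, x = np.log(y), np.log(x)
    elif transform != "none":
        raise ParameterError(f"unknown transform {transform!r}")
    if np.allclose(x, x[0]):
        raise ParameterError("predictor has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        p_value=float(model.pvalues[1]),
        adj_r2=float(model.rsquared_adj),
        intercept=float(model.params[0]),
        n=len(y),
    )


def ancova(
    observations: pd.DataFrame,
    response: str = "value",
    class_col: str = "island_class",
    week_col: str = "week",
    week_as_factor: bool = False,
    ss_type: int = 1,
) -> AncovaTable:
    """Fixed-factor ANCOVA: response ~ class + week + class:week.

    Week enters as a continuous covariate by default (``week_as_factor=True``
    switches to categorical weeks). Sums of squares are sequential (Type I) by
    default, with main effects fitted before the interaction; ``ss_type`` 2 or
    3 are available.
    """
    df = observations[[response, class_col, week_col]].dropna().copy()
    if df[class_col].nunique() < 2:
        raise EstimationError(f"ANCOVA term {class_col!r} is aliased: fewer than 2 classes")
    if df[week_col].nunique() < 2:
        raise EstimationError(f"ANCOVA term {week_col!r} is aliased: fewer than 2 weeks")
    df = df.rename(columns={response: "_y", class_col: "_cls", week_col: "_wk"})
    wk = "C(_wk)" if week_as_factor else "_wk"
    formula = f"_y ~ C(_cls) + {wk} + C(_cls):{wk}"
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise EstimationError("ANCOVA design is rank-deficient: interaction term aliased")
    anova = sm.stats.anova_lm(fit, typ=ss_type)
    resid = anova.loc["Residual"]
    terms = anova.drop(index="Residual").rename(
        columns={"sum_sq": "sum_sq", "PR(>F)": "p"}
    )[["sum_sq", "df", "F", "p"]]
    # all-constant responses give 0/0 F ratios; report them as 0, p = 1
    if np.isclose(resid["sum_sq"], 0.0) :
        zero = np.isclose(terms["sum_sq"].values, 0.0)
        terms.loc[zero, "F"] = 0.0
        terms.loc[zero, "p"] = 1.0
    rename = {}
    for name in terms.index:
        clean = name.replace("C(_cls)", "class").replace("C(_wk)", "week").replace("_wk", "week")
        rename[name] = clean.replace(":", " x ")
    terms = terms.rename(index=rename)
    return AncovaTable(
        terms=terms,
        residual_df=int(resid["df"]),
        residual_ss=float(resid["sum_sq"]),
    )


def classify_all(
    geos, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """Classification table for a collection of islands."""
    rows = []
    for g in geos:
        c = classify_island(g, cutoffs)
        rows.append(
            {
                "island": g.island,
                "area_km2": g.area_km2,
                "isolation_km": g.isolation_km,
                "distance_class": c.distance_class,
                "size_class": c.size_class,
            }
        )
    return pd.DataFrame(rows).set_index("island")
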