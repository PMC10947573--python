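"""Environment and trait-covariation models.

Three model families back the environmental and covariation analyses:

* :func:`polyfit` - ordinary least squares on a polynomial basis in one
  predictor (degree 1 or 2), with the overall F test against the
  intercept-only model. Used for light~fire and diversity~fire curves.
* :func:`mixed_fit` - a random-intercept linear mixed model (REML) for
  soil variables measured repeatedly on the same plots across years, with
  a Wald F test on the fire terms using containment denominator degrees of
  freedom.
* :func:`sma_fit` - Type II line fitting (standardized major axis or major
  axis) for trait-trait covariation, where both variables carry error; the
  SMA slope magnitude is sd(y)/sd(x) signed by the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["polyfit", "mixed_fit", "sma_fit", "sma_by_group", "ModelFit", "SMAFit"]


@dataclass
class ModelFit:
    params: pd.Series
    bse: pd.Series
    f_statistic: float
    df_num: int
    df_den: float
    p_value: float
    r_squared: float
    variance_components: dict = field(default_factory=dict)
    converged: bool = True


def polyfit(x, y, degree: int = 1) -> ModelFit:
    """OLS of ``y`` on a degree-1 or degree-2 polynomial in ``x``."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= degree + 1:
        raise ValueError("need n > degree + 1 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: polynomial basis is rank deficient")
    cols = {"intercept": np.ones_like(x), "x": x}
    if degree == 2:
        cols["x2"] = x ** 2
    X = pd.DataFrame(cols)
    fit = sm.OLS(y, X).fit()
    return ModelFit(
        params=fit.params,
        bse=fit.bse,
        f_statistic=float(fit.fvalue),
        df_num=int(fit.df_model),
        df_den=float(fit.df_resid),
        p_value=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
    )


def mixed_fit(y, x, groups, degree: int = 1) -> ModelFit:
    """Random-intercept mixed model of ``y`` on a polynomial in ``x``.

    ``groups`` identifies the repeated-measure unit (plot). Fit by REML via
    statsmodels MixedLM. The F test on the ``x`` terms uses a Wald statistic
    with containment denominator df: for predictors constant within groups
    (the usual case for a treatment applied at the plot level) the
    denominator is n_groups - rank(X); for predictors varying within groups
    it is N - rank(X) - (n_groups - 1). With a single observation per group
    the residual and group variances are unidentifiable and the fit is
    flagged (``converged = False``).
    """
    df = pd.DataFrame({"y": np.asarray(y, float), "x": np.asarray(x, float),
                       "g": np.asarray(groups)})
    n_groups = df["g"].nunique()
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    formula = "y ~ x + I(x**2)" if degree == 2 else "y ~ x"
    n_fixed = degree + 1
    max_size = df.groupby("g").size().max()
    if max_size < 2:
        # one observation per group: sigma^2 and the group variance are
        # confounded; report the OLS fit and flag it
        ols = polyfit(df["x"], df["y"], degree=degree)
        ols.converged = False
        ols.variance_components = {"group": np.nan, "residual": np.nan}
        return ols
    model = smf.mixedlm(formula, df, groups=df["g"])
    try:
        fit = model.fit(reml=True, method=["bfgs", "powell", "nm"])
    except Exception as err:  # pragma: no cover
        raise RuntimeError(f"mixed model failed to converge: {err}") from err
    if not fit.converged:
        raise RuntimeError(
            "mixed model failed to converge; optimizer history: "
            f"{getattr(fit, 'hist', None)}"
        )
    params = fit.fe_params
    fixed_names = [n for n in params.index if n != "Intercept"]
    # Wald F on the fire terms
    K = np.zeros((len(fixed_names), len(params)))
    for i, name in enumerate(fixed_names):
        K[i, list(params.index).index(name)] = 1.0
    covb = fit.cov_params().loc[params.index, params.index].values
    Kb = K @ params.values
    F = float(Kb @ np.linalg.solve(K @ covb @ K.T, Kb) / len(fixed_names))
    # containment df
    within = df.groupby("g")["x"].nunique().max() > 1
    N = len(df)
    if within:
        df_den = N - n_fixed - (n_groups - 1)
    else:
        df_den = n_groups - n_fixed
    p = float(stats.f.sf(F, len(fixed_names), df_den))
    # fixed-effects r^2: squared correlation of fixed-part prediction with y
    yhat = np.asarray(model.exog @ params.values)
    r2 = float(np.corrcoef(yhat, df["y"])[0, 1] ** 2)
    return ModelFit(
        params=params,
        bse=fit.bse_fe,
        f_statistic=F,
        df_num=len(fixed_names),
        df_den=float(df_den),
        p_value=p,
        r_squared=r2,
        variance_components={
            "group": float(fit.cov_re.iloc[0, 0]),
            "residual": float(fit.scale),
        },
    )


@dataclass
class SMAFit:
    slope: float
    intercept: float
    r: float
    rho: float
    p_value: float
    method: str
    n: int


def sma_fit(x, y, method: str = "SMA") -> SMAFit:
    """Type II line fit between two variables measured with error.

    ``method`` is ``"SMA"`` (standardized major axis: |slope| = sd(y)/sd(x),
    signed by the correlation), ``"MA"`` (major axis: first eigenvector of
    the covariance matrix) or ``"OLS"``. The intercept passes through the
    means. Significance is the two-sided correlation test (t on Pearson r),
    the standard practice for Type II lines; Spearman rho is also reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: Type II fit undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    rho = float(stats.spearmanr(x, y).statistic)
    method = method.upper()
    if method == "SMA":
        slope = np.sign(r) * sy / sx if r != 0 else sy / sx
    elif method == "MA":
        cov = np.cov(x, y)
        w, v = np.linalg.eigh(cov)
        major = v[:, np.argmax(w)]
        slope = major[1] / major[0]
    elif method == "OLS":
        slope = r * sy / sx
    else:
        raise ValueError("method must be 'SMA', 'MA' or 'OLS'")
    intercept = float(np.mean(y) - slope * np.mean(x))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return SMAFit(slope=float(slope), intercept=intercept, r=r, rho=rho,
                  p_value=p, method=method, n=n)


def sma_by_group(data: pd.DataFrame, x: str, y: str, by, method: str = "SMA",
                 min_n: int = 5) -> pd.DataFrame:
    """Type II fits within groups, reporting only groups with n >= min_n.

    ``by`` is a column name or list of column names (e.g. fire treatment
    and/or functional group); smaller groups are statistically unstable and
    are skipped.
    """
    by = [by] if isinstance(by, str) else list(by)
    rows = []
    for keys, sub in data.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        sub = sub[[x, y]].dropna()
        if len(sub) < min_n or sub[x].nunique() < 2 or sub[y].nunique() < 2:
            continue
        fit = sma_fit(sub[x], sub[y], method=method)
        rows.append(
            (*keys, fit.n, fit.slope, fit.intercept, fit.r, fit.rho, fit.p_value)
        )
    return pd.DataFrame(
        rows, columns=[*by, "n", "slope", "intercept", "r", "rho", "p_value"]
    )
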