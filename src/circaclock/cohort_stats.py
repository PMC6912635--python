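"""Cohort-level statistics: mixed models for τ, GLM tests of rhythmicity,
latitudinal clines and the phase-vs-period regression.

The free-running period τ is analysed with a Gaussian random-intercept
mixed model,

    y_ij = x_ij' β + u_j + ε_ij,   u_j ~ N(0, σ²_u),  ε_ij ~ N(0, σ²),

where j indexes isofemale lines nested in sampling locations (each line is a
distinct group, so a single variance component encodes the nesting).  The
model is fit by maximum likelihood through the profile likelihood over the
variance ratio λ = σ²_u/σ²: for fixed λ the marginal covariance is
block-diagonal with V_j = I + λ11', whose inverse and determinant are closed
form, so β is a GLS solve and λ is a one-dimensional optimisation.  ML is the
default so likelihood-ratio tests on fixed effects are valid; REML is
available for variance reporting.

Rhythmicity (a binary outcome) is compared between groups with a
binomial-logit GLM and analysis-of-deviance χ² tests; the GLM itself is an
ordinary IRLS fit delegated to statsmodels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phase_markers import circular_mean_h

logger = logging.getLogger("circaclock")

__all__ = [
    "ModelFit",
    "build_design",
    "fit_random_intercept",
    "likelihood_ratio_test",
    "rhythmicity_glm",
    "phase_tau_regression",
    "summarize_cline",
    "ClineSummary",
]


@dataclass
class ModelFit:
    """A fitted random-intercept model (or its OLS degenerate case)."""

    beta: np.ndarray
    se: np.ndarray
    x_names: list[str]
    sigma2: float          # residual variance
    sigma2_u: float        # line random-intercept variance
    loglik: float
    n: int
    df: int                # free parameters: len(beta) + 2 variance components
    method: str            # "ML" or "REML"

    def summary_frame(self) -> pd.DataFrame:
        z = self.beta / self.se
        return pd.DataFrame({
            "coef": self.beta,
            "se": self.se,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        }, index=self.x_names)


def build_design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept from data-frame columns.

    Numeric columns enter as-is; object/category columns are dummy-expanded
    with the first level as reference.
    """
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for t in terms:
        s = df[t]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(t)
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{t}[{lev}]")
    return np.column_stack(cols), names


def _profile_pieces(y, X, group_idx, lam):
    """GLS pieces at variance ratio ``lam``: beta, rss, logdet, XtVinvX."""
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for idx in group_idx:
        Xg = X[idx]
        yg = y[idx]
        ng = len(idx)
        c = lam / (1.0 + ng * lam)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        xtvx += Xg.T @ Xg - c * np.outer(sx, sx)
        xtvy += Xg.T @ yg - c * sx * sy
        ytvy += yg @ yg - c * sy * sy
        logdet += np.log1p(ng * lam)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = float(ytvy - 2 * beta @ xtvy + beta @ xtvx @ beta)
    rss = max(rss, 1e-300)
    return beta, rss, logdet, xtvx


def _neg_profile_ll(y, X, group_idx, lam, reml):
    n, p = X.shape
    beta, rss, logdet, xtvx = _profile_pieces(y, X, group_idx, lam)
    if reml:
        nstar = n - p
        sigma2 = rss / nstar
        sign, ld_x = np.linalg.slogdet(xtvx)
        ll = -0.5 * (nstar * np.log(2 * np.pi * sigma2) + logdet + ld_x + nstar)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return -ll


def fit_random_intercept(y, X, groups, method: str = "ML",
                         x_names: list[str] | None = None) -> ModelFit:
    """Fit y = Xβ + u_group + ε by (RE)ML profile likelihood over σ²_u/σ².

    ``X`` must include the intercept column.  Deterministic given the data:
    the variance ratio is found by bounded scalar optimisation on a log grid
    and the λ = 0 boundary is always checked.  With a single group the model
    degenerates to OLS (warning logged).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("shape mismatch between y and X")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effects design")
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    reml = method == "REML"
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    group_idx = [np.flatnonzero(groups == g) for g in labels]
    if len(labels) < 2:
        logger.warning("only one group: random intercept not identifiable; "
                       "fitting ordinary least squares")
        lam_hat = 0.0
    else:
        obj = lambda theta: _neg_profile_ll(y, X, group_idx, np.exp(theta), reml)
        res = optimize.minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                                       options={"xatol": 1e-8})
        lam_hat = float(np.exp(res.x))
        # boundary: no between-group variance
        if _neg_profile_ll(y, X, group_idx, 0.0, reml) <= res.fun:
            lam_hat = 0.0

    beta, rss, logdet, xtvx = _profile_pieces(y, X, group_idx, lam_hat)
    sigma2 = rss / (n - p) if reml else rss / n
    ll = -_neg_profile_ll(y, X, group_idx, lam_hat, reml)
    cov = sigma2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov))
    return ModelFit(
        beta=beta,
        se=se,
        x_names=x_names or [f"x{i}" for i in range(p)],
        sigma2=float(sigma2),
        sigma2_u=float(lam_hat * sigma2),
        loglik=float(ll),
        n=n,
        df=p + 2,
        method=method,
    )


def likelihood_ratio_test(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """LRT = 2(llik_full − llik_reduced), p from χ² with df = parameter diff.

    Both fits must be ML on the same observations with the reduced model
    nested in the full one.
    """
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("likelihood-ratio tests require ML fits")
    if full.n != reduced.n:
        raise ValueError("models fit on different numbers of observations")
    df = full.df - reduced.df
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    lrt = 2.0 * (full.loglik - reduced.loglik)
    if lrt < -1e-6:
        raise ValueError("full model has lower likelihood: models are not nested "
                         "or the fit failed")
    lrt = max(lrt, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(lrt, df))
    return float(lrt), int(df), p


# ---------------------------------------------------------------------------
# Rhythmicity GLM
# ---------------------------------------------------------------------------


def rhythmicity_glm(table: pd.DataFrame,
                    factors: list[str] = ["sex", "mating", "population", "latitude"],
                    ) -> pd.DataFrame:
    """Analysis-of-deviance χ² tests of each factor on the rhythmic fraction.

    Fits a binomial-logit GLM of ``rhythmic`` on all requested factors and
    tests each by the deviance drop when it is removed (type-II style).
    Factors with a single observed level are skipped.  Complete separation is
    flagged with ``reliable = False``.
    """
    import statsmodels.api as sm

    factors = [f for f in factors if table[f].nunique() > 1]
    if not factors:
        raise ValueError("no factor with more than one level")
    yb = table["rhythmic"].astype(int).to_numpy()

    def deviance(terms):
        X, _ = build_design(table, terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(yb, X, family=sm.families.Binomial()).fit()
        mu = fit.fittedvalues
        separated = bool(np.any((mu < 1e-8) | (mu > 1 - 1e-8)))
        return fit.deviance, X.shape[1], separated

    dev_full, p_full, sep_full = deviance(factors)
    rows = []
    for f in factors:
        dev_red, p_red, _ = deviance([t for t in factors if t != f])
        chi2 = max(dev_red - dev_full, 0.0)
        df = p_full - p_red
        rows.append({
            "factor": f,
            "chi2": chi2,
            "df": df,
            "p": float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan,
            "reliable": not sep_full,
        })
    if sep_full:
        logger.warning("rhythmicity GLM shows complete separation; "
                       "tests flagged unreliable")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phase-vs-τ regression and latitudinal cline
# ---------------------------------------------------------------------------


def _nested_line_labels(table: pd.DataFrame) -> np.ndarray:
    """Line-within-location group labels (one variance component)."""
    return (table["population"].astype(str) + "/" + table["line"].astype(str)).to_numpy()


def phase_tau_regression(table: pd.DataFrame, method: str = "ML") -> ModelFit:
    """Regress τ on the peak activity phase with a line random intercept.

    The circular peak phase is unwrapped to a continuous covariate around the
    cohort circular mean (deviations in (−12, 12] h) before the linear fit,
    which is adequate when phases cluster within ~half a cycle.
    """
    sub = table.dropna(subset=["tau_hat_h", "peak_zt"])
    if len(sub) < 3:
        raise ValueError("need at least 3 rows with both tau and peak phase")
    cm = circular_mean_h(sub["peak_zt"].to_numpy())
    dev = ((sub["peak_zt"].to_numpy() - cm + 12.0) % 24.0) - 12.0
    if np.ptp(dev) == 0:
        raise ValueError("peak phase is constant: slope undefined")
    X = np.column_stack([np.ones(len(sub)), cm + dev])
    return fit_random_intercept(
        sub["tau_hat_h"].to_numpy(), X, _nested_line_labels(sub),
        method=method, x_names=["Intercept", "peak_zt_unwrapped"],
    )


@dataclass
class ClineSummary:
    """Per-population τ means ordered by latitude plus the cline slope."""

    per_population: pd.DataFrame  # population, latitude, n, mean_tau_h, se_tau_h
    slope_h_per_degN: float
    slope_se: float
    model: ModelFit


def summarize_cline(table: pd.DataFrame, subgroup: dict | None = None,
                    method: str = "ML") -> ClineSummary:
    """Population τ means ± SE ordered by latitude, and the latitude slope.

    ``subgroup`` filters rows first (e.g. ``{"sex": "F", "mating":
    "virgin"}``).  Only rhythmic individuals with a τ estimate enter.  The
    slope comes from the line-nested random-intercept model of τ on latitude.
    """
    sub = table
    if subgroup:
        for k, v in subgroup.items():
            sub = sub[sub[k] == v]
    sub = sub.dropna(subset=["tau_hat_h"])
    if len(sub) == 0:
        raise ValueError("empty subgroup")
    if sub["population"].nunique() < 2:
        raise ValueError("need at least 2 populations for a cline")
    per_pop = (
        sub.groupby(["population", "latitude"])["tau_hat_h"]
        .agg(n="count", mean_tau_h="mean",
             se_tau_h=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
        .sort_values("latitude")
        .reset_index(drop=True)
    )
    X = np.column_stack([np.ones(len(sub)), sub["latitude"].to_numpy(dtype=float)])
    fit = fit_random_intercept(
        sub["tau_hat_h"].to_numpy(), X, _nested_line_labels(sub),
        method=method, x_names=["Intercept", "latitude"],
    )
    return ClineSummary(
        per_population=per_pop,
        slope_h_per_degN=float(fit.beta[1]),
        slope_se=float(fit.se[1]),
        model=fit,
    )
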