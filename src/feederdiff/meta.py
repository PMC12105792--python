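"""Inverse-variance-weighted meta-regression of logit-pST on temperature.

Each feeder x diffusion-period contributes one pST estimate with a
profile-likelihood CI.  Assuming logit-pST is Gaussian, its standard error
is the logit-scale CI range divided by 3.92 (two 1.96 half-widths), and each
observation is weighted by 1/SE^2.  Feeder-periods where the asocial model
won carry pST = 0 with no CI; those receive the average SE across the
social-model estimates.  The model is a linear mixed model

    logit(pST) ~ temperature + DP  +  (1 | feeder)

with heteroscedastic residual variance sigma^2 / w_i.  Because standard
mixed-model routines do not accept per-observation residual variance
weights, the two-variance-component (RE)ML criterion is implemented
directly; with the feeder variance at zero the fit reduces exactly to
closed-form weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOGIT_EPS = 1e-5
CI_RANGE_TO_SE = 3.92
VAR_FLOOR = 1e-12
VAR_ZERO_REPORT = 1e-8


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def logit_and_se(pst: float, ci_lower: float, ci_upper: float):
    """Logit-transform a pST estimate and derive its logit-scale SE.

    Boundary values (0 or 1, for the estimate or either CI endpoint) are
    adjusted by 1e-5 before the transform; the SE is the logit CI range
    divided by 3.92.
    """
    if not (0.0 <= ci_lower <= ci_upper <= 1.0):
        raise ValueError("require 0 <= lower <= upper <= 1")
    if not (ci_lower <= pst <= ci_upper):
        raise ValueError("pst must lie within its CI")

    def adjust(p: float) -> float:
        if p == 0.0:
            return LOGIT_EPS
        if p == 1.0:
            return 1.0 - LOGIT_EPS
        return p

    lo, hi, p = adjust(ci_lower), adjust(ci_upper), adjust(pst)
    return _logit(p), (_logit(hi) - _logit(lo)) / CI_RANGE_TO_SE


def impute_fixed_zero_se(table: pd.DataFrame) -> pd.DataFrame:
    """Give fixed-zero pST rows the mean logit-SE of the social-fit rows.

    Asocial winners have pST fixed at 0 and hence no estimable SE; they
    receive the average ``logit_se`` across social-fit estimates, and all
    weights are (re)computed as 1/SE^2.
    """
    out = table.copy()
    social = out["source"] == "social_fit"
    if not social.any():
        raise ValueError("cannot impute: no social-fit estimates with an SE")
    mean_se = float(out.loc[social, "logit_se"].mean())
    out.loc[~social, "logit_se"] = out.loc[~social, "logit_se"].fillna(mean_se)
    fixed = out["source"] == "fixed_zero"
    out.loc[fixed, "logit_se"] = mean_se
    out["weight"] = 1.0 / out["logit_se"] ** 2
    return out


@dataclass
class MetaFit:
    """Fitted weighted mixed model for logit-pST."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2_resid: float
    sigma2_feeder: float
    n_obs: int
    method: str  # "REML" or "ML"
    df_method: str = "residual"
    loglik: float = np.nan

    def tidy(self) -> pd.DataFrame:
        rows = [
            (name, self.params[name], self.bse[name], self.tvalues[name],
             self.pvalues[name])
            for name in self.params.index
        ]
        df = pd.DataFrame(
            rows, columns=["predictor", "estimate", "se", "t", "p"]
        )
        var = pd.DataFrame(
            [("residual_variance", self.sigma2_resid, np.nan, np.nan, np.nan),
             ("feeder_variance", self.sigma2_feeder, np.nan, np.nan, np.nan)],
            columns=df.columns,
        )
        return pd.concat([df, var], ignore_index=True)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        rdiag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [
            names[i]
            for i in range(len(names))
            if rdiag[i] < 1e-10 * max(rdiag.max(), 1.0)
        ]
        raise ValueError(f"design matrix is singular; collinear columns: {bad}")


def _wls(X, y, w, reml: bool):
    W = np.diag(w)
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    r = y - X @ beta
    dof = len(y) - X.shape[1] if reml else len(y)
    sigma2 = float((r * w * r).sum() / dof)
    cov = sigma2 * np.linalg.inv(XtW @ X)
    return beta, cov, sigma2


def fit_weighted_lmm(
    data: pd.DataFrame,
    response: str = "logit_pst",
    fixed: tuple[str, ...] = ("temp", "dp"),
    group: str = "feeder_id",
    weight_col: str = "weight",
    method: str = "REML",
    fix_group_var: float | None = None,
) -> MetaFit:
    """Weighted linear mixed model with one random intercept.

    Marginal model: ``y ~ N(X b, sigma2_g Z Z' + sigma2 diag(1/w))``.
    Variance components are optimized on the log scale (floored at 1e-12)
    by REML (default) or ML; a feeder variance below 1e-8 is reported as 0.
    ``fix_group_var=0`` forces the closed-form WLS solution.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    names = ["intercept", *fixed]
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in fixed]
    )
    _check_full_rank(X, names)
    y = data[response].to_numpy(dtype=float)
    w = data[weight_col].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    codes = pd.Categorical(data[group]).codes
    Z = np.zeros((len(y), codes.max() + 1))
    Z[np.arange(len(y)), codes] = 1.0
    n, p = X.shape
    reml = method == "REML"

    log_floor = np.log(VAR_FLOOR)

    def neg_crit(log_theta):
        s2g, s2 = np.exp(np.clip(log_theta, log_floor, 50.0))
        V = s2g * (Z @ Z.T) + np.diag(s2 / w)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(V, r))
        crit = logdet + quad
        if reml:
            crit += float(np.linalg.slogdet(XtViX)[1])
        return 0.5 * crit

    if fix_group_var is not None and fix_group_var <= VAR_ZERO_REPORT:
        beta, cov, sigma2 = _wls(X, y, w, reml)
        s2g = 0.0
        ll = -neg_crit(np.log([VAR_FLOOR, sigma2]))
    else:
        beta0, _, s2_wls = _wls(X, y, w, reml)
        best = None
        for s2g0 in (VAR_FLOOR, 0.1 * s2_wls, s2_wls):
            res = optimize.minimize(
                neg_crit,
                np.log([max(s2g0, VAR_FLOOR), s2_wls]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        s2g, sigma2 = np.exp(np.clip(best.x, log_floor, 50.0))
        if s2g < VAR_ZERO_REPORT:
            s2g = 0.0
        V = s2g * (Z @ Z.T) + np.diag(sigma2 / w)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ np.linalg.solve(V, y))
        cov = np.linalg.inv(XtViX)
        ll = -float(best.fun)

    se = np.sqrt(np.diag(cov))
    t = beta / se
    df = n - p
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    idx = pd.Index(names)
    return MetaFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(t, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        sigma2_resid=float(sigma2),
        sigma2_feeder=float(s2g),
        n_obs=n,
        method=method,
        loglik=ll,
    )


def build_pst_table(estimates) -> pd.DataFrame:
    """Assemble PstEstimate objects into the meta-regression input table."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "feeder_id": e.feeder_id,
                "dp_index": e.dp_index,
                "pst": e.pst,
                "pst_lower": e.pst_lower,
                "pst_upper": e.pst_upper,
                "source": e.source,
            }
        )
    return pd.DataFrame(rows)


def run_meta_regression(
    pst_table: pd.DataFrame,
    temperature_table: pd.DataFrame,
    method: str = "REML",
    include_dp: bool = True,
):
    """Join temperatures, transform, impute, and fit the weighted LMM.

    ``pst_table`` needs columns feeder_id, dp_index, pst, pst_lower,
    pst_upper, source; ``temperature_table`` needs dp_index and
    daytime_avg_temp.  Returns ``(MetaFit, tidy report DataFrame)``.
    """
    df = pst_table.merge(
        temperature_table[["dp_index", "daytime_avg_temp"]],
        on="dp_index",
        how="left",
    )
    if df["daytime_avg_temp"].isna().any():
        missing = sorted(df.loc[df["daytime_avg_temp"].isna(), "dp_index"].unique())
        raise ValueError(f"missing temperature for DP(s) {missing}")
    logits, ses = [], []
    for row in df.itertuples(index=False):
        if row.source == "fixed_zero" or pd.isna(row.pst_lower):
            lp, _ = logit_and_se(row.pst, row.pst, row.pst)
            logits.append(lp)
            ses.append(np.nan)
        else:
            lp, se = logit_and_se(row.pst, row.pst_lower, row.pst_upper)
            logits.append(lp)
            ses.append(se)
    df["logit_pst"] = logits
    df["logit_se"] = ses
    df = impute_fixed_zero_se(df)
    df = df.rename(columns={"daytime_avg_temp": "temp", "dp_index": "dp"})
    fixed = ("temp", "dp") if include_dp else ("temp",)
    fit = fit_weighted_lmm(df, fixed=fixed, method=method)
    return fit, fit.tidy()
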