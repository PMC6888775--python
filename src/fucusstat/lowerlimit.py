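"""Log-linear model for the lower limit of the Fucus zone.

Ordinary least squares of ln(lower limit in metres) on salinity, log
exposure, Secchi depth and N-tot plus their two-way interactions, with the
same backward interaction pruning as the hurdle model, followed by residual
diagnostics (Shapiro-Wilk normality, Breusch-Pagan homoscedasticity).
Natural logs throughout. Predictions back-transform with exp; an optional
Duan smearing factor is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from fucusstat.errors import InputError
from fucusstat.hurdle import (
    RegressionFit,
    _check_full_rank,
    design_matrix,
    prune_interactions,
    two_way_interactions,
)

log = logging.getLogger(__name__)

LOWERLIMIT_MAINS = ("salinity", "log_exposure", "secchi", "ntot")


def fit_ols(X: np.ndarray, y: np.ndarray, terms: Sequence[str]) -> RegressionFit:
    """OLS with classical t statistics (QR least squares, not normal equations)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    terms = list(terms)
    _check_full_rank(X, terms)
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    df = n - k
    if df <= 0:
        raise InputError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df)
    rss = float(resid @ resid)
    ll = -0.5 * n * (np.log(2 * np.pi * max(rss, 1e-300) / n) + 1)
    return RegressionFit(
        family="gaussian",
        link="identity",
        terms=terms,
        estimates=beta,
        std_errors=se,
        stat_values=t,
        p_values=p,
        stat_name="t",
        log_likelihood=ll,
        n=n,
        converged=True,
        df_resid=df,
        residuals=resid,
        fitted=fitted,
        exog=X,
    )


def fit_lower_limit(
    dataset: pd.DataFrame,
    alpha: float = 0.05,
    mains: Sequence[str] = LOWERLIMIT_MAINS,
    prune: bool = True,
    min_rows: int = 20,
) -> tuple[RegressionFit, list[dict]]:
    """Fit ln(lower_limit_m) ~ mains + two-way interactions, pruning interactions.

    ``dataset`` must contain ``lower_limit_m`` (> 0) plus the covariates.
    Returns the final fit and the ledger of dropped interactions.
    """
    if "lower_limit_m" not in dataset.columns:
        raise InputError("dataset missing 'lower_limit_m'")
    limits = dataset["lower_limit_m"].to_numpy(dtype=float)
    if np.any(~np.isfinite(limits)) or np.any(limits <= 0):
        raise InputError("lower_limit_m must be finite and > 0 (log response)")
    if len(dataset) < min_rows:
        raise InputError(f"need >= {min_rows} rows, got {len(dataset)}")
    y = np.log(limits)
    mains = list(mains)
    terms = ["intercept", *mains, *two_way_interactions(mains)]
    if prune:
        fit, _, ledger = prune_interactions(fit_ols, dataset, y, terms, alpha=alpha)
    else:
        fit = fit_ols(design_matrix(dataset, terms), y, terms)
        ledger = []
    return fit, ledger


@dataclass
class DiagnosticsReport:
    shapiro_stat: float
    shapiro_p: float
    normality_ok: bool
    bp_stat: float
    bp_p: float
    homoscedastic_ok: bool
    alpha: float
    degenerate: bool = False

    def to_text(self) -> str:
        lines = [
            "Residual diagnostics",
            f"  Shapiro-Wilk W = {self.shapiro_stat:.4f}, p = {self.shapiro_p:.4g}"
            f" -> normality {'OK' if self.normality_ok else 'REJECTED'}"
            f" at alpha={self.alpha}",
            f"  Breusch-Pagan LM = {self.bp_stat:.4f}, p = {self.bp_p:.4g}"
            f" -> homoscedasticity {'OK' if self.homoscedastic_ok else 'REJECTED'}"
            f" at alpha={self.alpha}",
        ]
        if self.degenerate:
            lines.append("  WARNING: residuals degenerate (zero variance)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "shapiro_stat": self.shapiro_stat,
            "shapiro_p": self.shapiro_p,
            "normality_ok": self.normality_ok,
            "bp_stat": self.bp_stat,
            "bp_p": self.bp_p,
            "homoscedastic_ok": self.homoscedastic_ok,
            "alpha": self.alpha,
            "degenerate": self.degenerate,
        }


def diagnostics(fit: RegressionFit, alpha: float = 0.05) -> DiagnosticsReport:
    """Normality (Shapiro-Wilk) and homoscedasticity (Breusch-Pagan) checks.

    Reports pass/fail at ``alpha``; never refits automatically.
    """
    if fit.residuals is None or fit.exog is None:
        raise InputError("fit carries no residuals/design for diagnostics")
    resid = np.asarray(fit.residuals, dtype=float)
    if len(resid) < 3:
        raise InputError("diagnostics unavailable for n < 3")
    if np.allclose(resid, 0):
        log.warning("diagnostics: residuals are all zero (degenerate)")
        return DiagnosticsReport(
            shapiro_stat=np.nan, shapiro_p=np.nan, normality_ok=False,
            bp_stat=np.nan, bp_p=np.nan, homoscedastic_ok=False,
            alpha=alpha, degenerate=True,
        )
    sw_stat, sw_p = stats.shapiro(resid)
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, fit.exog)
    return DiagnosticsReport(
        shapiro_stat=float(sw_stat),
        shapiro_p=float(sw_p),
        normality_ok=bool(sw_p >= alpha),
        bp_stat=float(bp_stat),
        bp_p=float(bp_p),
        homoscedastic_ok=bool(bp_p >= alpha),
        alpha=alpha,
    )


def predict_lower_limit(
    fit: RegressionFit, covariates: pd.DataFrame, smearing: bool = False
) -> np.ndarray:
    """Predicted lower limit on the metre scale: exp(linear predictor).

    With ``smearing`` the prediction is multiplied by Duan's smearing factor
    mean(exp(residuals)) to correct retransformation bias.
    """
    lp = design_matrix(covariates, fit.terms) @ fit.estimates
    out = np.exp(lp)
    if smearing:
        if fit.residuals is None:
            raise InputError("smearing requires a fit with stored residuals")
        out = out * float(np.mean(np.exp(fit.residuals)))
    return out
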