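"""Two-part hurdle model for zero-inflated occurrence rates.

The binomial part models presence/absence of Fucus in a zone with a
logit-link GLM fitted by Newton-Raphson. The positive part models the
occurrence rate of the zones where Fucus is present with a truncated beta
regression in the mean-precision parameterisation: y ~ Beta(mu*phi,
(1-mu)*phi) with logit(mu) = X beta and a single precision phi, fitted by
quasi-Newton maximum likelihood on (beta, log phi) with an analytic
gradient. Standard errors come from the inverse of a finite-difference
observed-information matrix. Non-significant two-way interactions are pruned
backwards, one per step, refitting at each step; main effects are never
dropped. Merged predictions multiply P(presence) by the conditional beta
mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from fucusstat.errors import ConvergenceError, InputError

log = logging.getLogger(__name__)

MAIN_EFFECTS = ("salinity", "log_exposure", "secchi", "ntot", "ptot")
GRADIENT_TOL = 1e-8


@dataclass
class RegressionFit:
    """Coefficient table plus fit metadata for one regression part."""

    family: str                # binomial | beta | gaussian
    link: str                  # logit | identity
    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    stat_values: np.ndarray    # Wald z (binomial/beta) or t (gaussian)
    p_values: np.ndarray
    stat_name: str             # "z" | "t"
    log_likelihood: float
    n: int
    converged: bool
    phi: float | None = None
    df_resid: int | None = None
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None
    exog: np.ndarray | None = None
    loglik_trace: list[float] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def p_value(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "std_error": self.std_errors,
                self.stat_name: self.stat_values,
                "p_value": self.p_values,
            }
        )

    def to_dict(self) -> dict:
        out = {
            "family": self.family,
            "link": self.link,
            "terms": list(self.terms),
            "estimates": [float(v) for v in self.estimates],
            "std_errors": [float(v) for v in self.std_errors],
            f"{self.stat_name}_values": [float(v) for v in self.stat_values],
            "p_values": [float(v) for v in self.p_values],
            "log_likelihood": float(self.log_likelihood),
            "n": int(self.n),
            "converged": bool(self.converged),
        }
        if self.phi is not None:
            out["phi"] = float(self.phi)
        return out


@dataclass
class HurdleFit:
    positive_part: RegressionFit
    binomial_part: RegressionFit
    dropped_terms: list[dict]
    covariate_support: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "positive_part": self.positive_part.to_dict(),
            "binomial_part": self.binomial_part.to_dict(),
            "dropped_terms": self.dropped_terms,
        }


def two_way_interactions(mains: Sequence[str]) -> list[str]:
    return [f"{a}:{b}" for a, b in combinations(mains, 2)]


def _main_column(table: pd.DataFrame, name: str) -> np.ndarray:
    if name in table.columns:
        return table[name].to_numpy(dtype=float)
    if name == "log_exposure":
        if "exposure" not in table.columns:
            raise InputError("need 'log_exposure' or 'exposure' column")
        expo = table["exposure"].to_numpy(dtype=float)
        if np.any(expo <= 0):
            raise InputError("exposure must be > 0 to enter as natural log")
        return np.log(expo)
    raise InputError(f"covariate column '{name}' not found")


def design_matrix(
    table: pd.DataFrame, terms: Sequence[str]
) -> np.ndarray:
    """Build the model matrix for the given terms.

    ``intercept`` yields a column of ones, ``a:b`` the elementwise product of
    the two main-effect columns, and ``log_exposure`` the natural log of the
    ``exposure`` column when not already present.
    """
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(len(table)))
        elif ":" in term:
            a, b = term.split(":")
            cols.append(_main_column(table, a) * _main_column(table, b))
        else:
            cols.append(_main_column(table, term))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def _check_full_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise InputError(f"more terms ({X.shape[1]}) than observations ({X.shape[0]})")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns via QR pivoting on the diagonal of R
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        aliased = [terms[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise InputError(f"design matrix rank deficient; aliased terms: {aliased}")


def fit_binomial(
    X: np.ndarray, presence: np.ndarray, terms: Sequence[str]
) -> RegressionFit:
    """Logit-link binomial MLE by Newton-Raphson with step halving.

    Raises :class:`ConvergenceError` on a degenerate response or complete
    separation instead of returning silently wrong output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(presence, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InputError("presence response must be 0/1")
    if y.min() == y.max():
        raise ConvergenceError(
            "degenerate binomial response (all "
            f"{int(y[0])}s): presence/absence model cannot be fitted"
        )
    terms = list(terms)
    _check_full_rank(X, terms)
    # Newton on column-scaled covariates: conditioning, and |beta| becomes a
    # scale-free divergence diagnostic; transform back exactly at the end
    scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
    X = X / scale

    def loglik(b: np.ndarray) -> float:
        eta = np.clip(X @ b, -35, 35)
        return float(np.sum(y * eta - np.log1p(np.exp(eta))))

    beta = np.zeros(X.shape[1])
    ll = loglik(beta)
    trace = [ll]
    converged = False
    for _ in range(100):
        eta = np.clip(X @ beta, -35, 35)
        p = special.expit(eta)
        grad = X.T @ (y - p)
        w = p * (1 - p)
        H = X.T @ (w[:, None] * X)
        if np.linalg.norm(grad) < GRADIENT_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix (possible complete separation)"
            ) from exc
        # step halving keeps the likelihood ascending
        damp = 1.0
        for _half in range(30):
            cand = beta + damp * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            damp /= 2
        beta = cand
        ll = ll_new
        trace.append(ll)
    if not converged:
        raise ConvergenceError("binomial Newton-Raphson did not converge")
    eta = X @ beta
    p = special.expit(np.clip(eta, -35, 35))
    # a vanishing gradient with every observation perfectly predicted is the
    # degenerate boundary solution of complete separation, not an MLE
    if np.all(np.where(y == 1, p > 1 - 1e-8, p < 1e-8)):
        raise ConvergenceError(
            "complete separation: all observations perfectly predicted"
        )
    # a linear predictor saturating the numeric clip means some observations
    # are perfectly predicted at the boundary: quasi-complete separation
    if np.max(np.abs(eta)) >= 30:
        raise ConvergenceError(
            "quasi-complete separation: saturated linear predictor "
            f"(max |eta| = {np.max(np.abs(eta)):.1f})"
        )
    w = p * (1 - p)
    H = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(H)
    beta = beta / scale
    se = np.sqrt(np.diag(cov)) / scale
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return RegressionFit(
        family="binomial",
        link="logit",
        terms=terms,
        estimates=beta,
        std_errors=se,
        stat_values=z,
        p_values=pvals,
        stat_name="z",
        log_likelihood=ll,
        n=len(y),
        converged=True,
        fitted=p,
        residuals=y - p,
        exog=X * scale,
        loglik_trace=trace,
    )


def beta_loglik(
    params: np.ndarray, X: np.ndarray, y: np.ndarray
) -> float:
    """Beta-regression log-likelihood at params = (beta, log phi)."""
    beta, logphi = params[:-1], params[-1]
    phi = np.exp(logphi)
    mu = special.expit(np.clip(X @ beta, -35, 35))
    a, b = mu * phi, (1 - mu) * phi
    return float(
        np.sum(
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1) * np.log(y)
            + (b - 1) * np.log1p(-y)
        )
    )


def _beta_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, logphi = params[:-1], params[-1]
    phi = np.exp(logphi)
    eta = np.clip(X @ beta, -35, 35)
    mu = special.expit(eta)
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
    gbeta = X.T @ (phi * (ystar - mustar) * mu * (1 - mu))
    gphi = np.sum(
        special.digamma(phi)
        - mu * special.digamma(mu * phi)
        - (1 - mu) * special.digamma((1 - mu) * phi)
        + mu * np.log(y)
        + (1 - mu) * np.log1p(-y)
    )
    return np.append(gbeta, gphi * phi)  # chain rule for log phi


def _num_hessian(grad: Callable[[np.ndarray], np.ndarray], x: np.ndarray) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    for j in range(k):
        h = 1e-5 * max(1.0, abs(x[j]))
        e = np.zeros(k)
        e[j] = h
        H[:, j] = (grad(x + e) - grad(x - e)) / (2 * h)
    return (H + H.T) / 2


def fit_beta(
    X: np.ndarray, rates: np.ndarray, terms: Sequence[str]
) -> RegressionFit:
    """Mean-precision beta-regression MLE (logit mean link, constant phi).

    ``rates`` must lie strictly in (0,1); exact zeros or ones are the hurdle
    split's responsibility and raise an error here rather than being squeezed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(rates, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise InputError(
            "beta regression requires rates strictly in (0,1); move zeros to "
            "the hurdle's binomial part instead of squeezing them"
        )
    terms = list(terms)
    _check_full_rank(X, terms)
    # optimize on column-scaled covariates for conditioning; exact transform back
    scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
    Xs = X / scale
    # starting values: least squares on the logit response, moments for phi
    z = np.log(y) - np.log1p(-y)
    beta0, *_ = np.linalg.lstsq(Xs, z, rcond=None)
    mu0 = special.expit(np.clip(Xs @ beta0, -35, 35))
    resid_var = float(np.var(y - mu0))
    phi0 = max(float(np.mean(mu0 * (1 - mu0)) / max(resid_var, 1e-8)) - 1, 1.0)
    x0 = np.append(beta0, np.log(phi0))

    def nll(p: np.ndarray) -> float:
        return -beta_loglik(p, Xs, y)

    def ngrad(p: np.ndarray) -> np.ndarray:
        return -_beta_grad(p, Xs, y)

    trace = [beta_loglik(x0, Xs, y)]
    res = optimize.minimize(
        nll, x0, jac=ngrad, method="BFGS",
        callback=lambda xk: trace.append(beta_loglik(xk, Xs, y)),
        options={"gtol": GRADIENT_TOL, "maxiter": 1000},
    )
    # BFGS can stall on its line search at near-machine gradient norms;
    # accept when the gradient is small, otherwise flag non-convergence.
    gnorm = float(np.linalg.norm(ngrad(res.x)))
    if not res.success and gnorm > 1e-4:
        raise ConvergenceError(f"beta regression did not converge: {res.message}")
    params = res.x
    H = _num_hessian(ngrad, params)  # observed information of the neg. loglik
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular observed information in beta fit") from exc
    k = X.shape[1]
    beta = params[:k] / scale
    se = np.sqrt(np.abs(np.diag(cov)[:k])) / scale
    zvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    phi = float(np.exp(params[-1]))
    mu = special.expit(np.clip(X @ beta, -35, 35))
    return RegressionFit(
        family="beta",
        link="logit",
        terms=terms,
        estimates=beta,
        std_errors=se,
        stat_values=zvals,
        p_values=pvals,
        stat_name="z",
        log_likelihood=float(-res.fun),
        n=len(y),
        converged=True,
        phi=phi,
        fitted=mu,
        residuals=y - mu,
        exog=X,
        loglik_trace=trace,
    )


FitProcedure = Callable[[np.ndarray, np.ndarray, Sequence[str]], RegressionFit]


def prune_interactions(
    fit_procedure: FitProcedure,
    covariates: pd.DataFrame,
    response: np.ndarray,
    terms: Sequence[str],
    alpha: float = 0.05,
) -> tuple[RegressionFit, list[str], list[dict]]:
    """Backward-eliminate non-significant interaction terms, one per step.

    Only interaction terms (``a:b``) are candidates; main effects and the
    intercept are never dropped. At each step the interaction with the
    largest Wald p >= alpha is removed and the model refitted. Returns the
    final fit, the final term list and a ledger of removals.
    """
    current = list(terms)
    ledger: list[dict] = []
    step = 0
    while True:
        X = design_matrix(covariates, current)
        fit = fit_procedure(X, response, current)
        inter = [(t, fit.p_value(t)) for t in current if ":" in t]
        droppable = [(t, p) for t, p in inter if p >= alpha or not np.isfinite(p)]
        if not droppable:
            return fit, current, ledger
        victim, pval = max(
            droppable, key=lambda tp: tp[1] if np.isfinite(tp[1]) else np.inf
        )
        step += 1
        ledger.append({"step": step, "term": victim, "p_value": float(pval)})
        log.info("prune_interactions: step %d dropped %s (p=%.4f)", step, victim, pval)
        current.remove(victim)


def _degenerate_fit(terms: Sequence[str], n: int, family: str) -> RegressionFit:
    k = len(terms)
    nan = np.full(k, np.nan)
    return RegressionFit(
        family=family, link="logit", terms=list(terms), estimates=nan,
        std_errors=nan.copy(), stat_values=nan.copy(), p_values=nan.copy(),
        stat_name="z", log_likelihood=np.nan, n=n, converged=False,
    )


def fit_hurdle(
    zone_covariates: pd.DataFrame,
    rates: np.ndarray,
    mains: Sequence[str] = MAIN_EFFECTS,
    alpha: float = 0.05,
    min_positive: int = 10,
) -> HurdleFit:
    """Fit the full hurdle: pruned truncated-beta part, then binomial part.

    ``rates`` may be fractions in [0,1) or percent in [0,100) — values above
    1 are interpreted as percent and divided by 100 once at this boundary.
    The binomial part (response: rate > 0, all zones) uses all main effects
    plus only the interaction(s) that survived pruning in the positive part.
    """
    y = np.asarray(rates, dtype=float)
    if np.any(y > 1.0):
        y = y / 100.0
    if np.any((y < 0) | (y >= 1)):
        raise InputError("rates must lie in [0,1) (or [0,100) as percent)")
    mains = list(mains)
    pos_mask = y > 0
    n_pos = int(pos_mask.sum())
    if n_pos < min_positive:
        raise InputError(f"need >= {min_positive} positive zones, got {n_pos}")
    start_terms = ["intercept", *mains, *two_way_interactions(mains)]
    pos_fit, pos_terms, ledger = prune_interactions(
        fit_beta, zone_covariates[pos_mask].reset_index(drop=True),
        y[pos_mask], start_terms, alpha=alpha,
    )
    kept_interactions = [t for t in pos_terms if ":" in t]
    bin_terms = ["intercept", *mains, *kept_interactions]
    presence = pos_mask.astype(float)
    try:
        Xb = design_matrix(zone_covariates, bin_terms)
        bin_fit = fit_binomial(Xb, presence, bin_terms)
    except ConvergenceError as exc:
        log.warning("binomial part degenerate: %s", exc)
        bin_fit = _degenerate_fit(bin_terms, len(y), "binomial")
    support = {
        m: (
            float(_main_column(zone_covariates, m).min()),
            float(_main_column(zone_covariates, m).max()),
        )
        for m in mains
    }
    return HurdleFit(
        positive_part=pos_fit,
        binomial_part=bin_fit,
        dropped_terms=ledger,
        covariate_support=support,
    )


def predict_hurdle(fit: HurdleFit, covariates: pd.DataFrame) -> np.ndarray:
    """Merged prediction: P(presence) x E[rate | positive], in (0,1)."""
    if not fit.positive_part.converged or not fit.binomial_part.converged:
        raise ConvergenceError("cannot predict from a non-converged hurdle fit")
    for m, (lo, hi) in fit.covariate_support.items():
        vals = _main_column(covariates, m)
        if np.any(vals < lo) or np.any(vals > hi):
            warnings.warn(
                f"predict_hurdle: '{m}' outside the design support "
                f"[{lo:.4g}, {hi:.4g}]; extrapolating", stacklevel=2,
            )
    from scipy.special import expit

    p_presence = expit(
        np.clip(design_matrix(covariates, fit.binomial_part.terms)
                @ fit.binomial_part.estimates, -35, 35)
    )
    mu = expit(
        np.clip(design_matrix(covariates, fit.positive_part.terms)
                @ fit.positive_part.estimates, -35, 35)
    )
    return p_presence * mu
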