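"""Regression engines for rare-events vaccine-trial data.

Ordinary logistic maximum likelihood breaks down under separation — the
data configurations (for example, zero events in the vaccinated arm of a
high-efficacy trial) for which the MLE is infinite.  Two penalized
alternatives guarantee finite estimates:

* **Firth / Jeffreys penalty** — maximizes ``l(b) + 0.5*log det I(b)``,
  which for a single binary covariate reduces exactly to adding half an
  event to every cell of the 2x2 table;
* **Weakly informative Cauchy prior (WIP)** — the posterior-mode algorithm
  of Gelman et al.'s ``bayesglm``: independent Cauchy priors (scale 2.5 on
  slopes after rescaling each input by its range or twice its standard
  deviation, scale 10 on the intercept) fitted by iteratively reweighted
  least squares with an EM update of per-coefficient prior variances.

All engines return a :class:`GlmResults` with coefficients, covariance,
and convergence/divergence flags, so a broken MLE can still be carried
into a downstream meta-analysis exactly as standard software would carry
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from .data import RegressionData, TwoByTwo

__all__ = [
    "GlmResults",
    "PenalizedLogit",
    "fit_logistic_mle",
    "fit_firth",
    "fit_cauchy_wip",
    "fit_linear_gaussian",
    "wald_test",
    "fit_two_by_two",
]

#: divergence is declared when any coefficient magnitude passes this bound
#: (about 30 on the log-odds-ratio scale under +/-1 treatment coding)
COEF_BOUND = 15.0


@dataclass
class GlmResults:
    """Estimates, covariance and diagnostics of a (penalized) regression fit."""

    method: str
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    converged: bool
    diverged: bool
    n_iter: int
    nobs: int
    #: per-iteration objective values (for WIP: one list per outer EM cycle)
    objective_trace: list = field(default=None, repr=False)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self.cov_params.to_numpy()), 0, None)),
                         index=self.params.index)

    def wald_test(self, name: str, null_value: float = 0.0) -> tuple[float, float]:
        return wald_test(self, name, null_value)

    def wald_joint(self, names: list[str]) -> tuple[float, float]:
        """Joint Wald chi-square test that all named coefficients are zero.

        Returns ``(statistic, p)`` with ``len(names)`` degrees of freedom.
        """
        from scipy.stats import chi2

        b = self.params[names].to_numpy()
        V = self.cov_params.loc[names, names].to_numpy()
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as err:
            raise ValueError("singular covariance block in joint Wald test") from err
        if not np.isfinite(stat) or stat < 0:
            raise ValueError("joint Wald statistic is not computable")
        return stat, float(chi2.sf(stat, df=len(names)))

    def summary(self) -> str:
        se = self.bse
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / se
        p = 2 * norm.sf(np.abs(z))
        tab = pd.DataFrame({"coef": self.params, "std err": se, "z": z,
                            "P>|z|": p})
        head = (f"{self.method} fit  (n={self.nobs}, iterations={self.n_iter}, "
                f"converged={self.converged}, diverged={self.diverged})\n"
                f"log-likelihood / log-posterior: {self.llf:.4f}\n")
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}")


def _validate(data: RegressionData, binary: bool) -> tuple[np.ndarray, np.ndarray]:
    y = data.outcome
    X = data.exog
    if X.shape[1] < 1:
        raise ValueError("at least one predictor column is required")
    if binary and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (degenerate input)")
    return y, X


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # Bernoulli log-likelihood, numerically stable for large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _is_intercept(col: np.ndarray) -> bool:
    return bool(np.all(col == col[0]) and col[0] != 0)


class PenalizedLogit:
    """Binary-outcome regression model with selectable likelihood penalty.

    Parameters
    ----------
    data
        Outcome and named predictor columns (include the intercept column).
    penalty
        ``"none"`` (ordinary maximum likelihood), ``"firth"`` (Jeffreys
        invariant prior), or ``"cauchy"`` (weakly informative Cauchy prior).
    slope_scale, intercept_scale
        Cauchy prior scales; slopes are additionally rescaled by each
        predictor's range (binary inputs) or twice its standard deviation
        (continuous inputs), the ``bayesglm`` convention, unless
        ``standardize_priors=False``.
    coef_bound
        Coefficient magnitude beyond which the MLE iteration is declared
        divergent.
    var_bound
        Estimated-variance magnitude beyond which a converged MLE is
        declared quasi-separated (the likelihood is numerically flat in
        some direction, so no finite MLE exists).
    """

    def __init__(self, data: RegressionData, penalty: str = "none", *,
                 slope_scale: float = 2.5, intercept_scale: float = 10.0,
                 standardize_priors: bool = True,
                 coef_bound: float = COEF_BOUND,
                 var_bound: float = 1e3):
        if penalty not in ("none", "firth", "cauchy"):
            raise ValueError(f"unknown penalty {penalty!r}")
        self.data = data
        self.penalty = penalty
        self.coef_bound = float(coef_bound)
        self.var_bound = float(var_bound)
        self.y, self.X = _validate(data, binary=True)
        self.names = data.names
        if penalty == "cauchy":
            self.prior_scales = self._prior_scales(slope_scale, intercept_scale,
                                                   standardize_priors)

    # -- Cauchy prior scaling --------------------------------------------
    def _prior_scales(self, slope_scale: float, intercept_scale: float,
                      standardize: bool) -> np.ndarray:
        scales = np.empty(self.X.shape[1])
        for j in range(self.X.shape[1]):
            col = self.X[:, j]
            if _is_intercept(col):
                scales[j] = intercept_scale
                continue
            if not standardize:
                scales[j] = slope_scale
                continue
            uniq = np.unique(col)
            if uniq.size == 2:
                denom = uniq.max() - uniq.min()
            else:
                denom = 2.0 * col.std()
            scales[j] = slope_scale / max(denom, 1e-12)
        return scales

    # -- fitting ----------------------------------------------------------
    def fit(self, max_iter: int | None = None, tol: float = 1e-8) -> GlmResults:
        if max_iter is None:
            max_iter = 25 if self.penalty == "none" else 50
        if self.penalty == "none":
            return self._fit_mle(max_iter, tol)
        if self.penalty == "firth":
            return self._fit_firth(max_iter, tol)
        return self._fit_cauchy(max_iter, tol)

    def _info(self, p: np.ndarray) -> np.ndarray:
        W = p * (1.0 - p)
        return self.X.T @ (self.X * W[:, None])

    def _wrap(self, method, beta, cov, llf, converged, diverged, n_iter,
              trace) -> GlmResults:
        return GlmResults(
            method=method,
            params=pd.Series(beta, index=self.names),
            cov_params=pd.DataFrame(cov, index=self.names, columns=self.names),
            llf=llf, converged=converged, diverged=diverged,
            n_iter=n_iter, nobs=len(self.y),
            objective_trace=trace,
        )

    def _fit_mle(self, max_iter: int, tol: float) -> GlmResults:
        X, y = self.X, self.y
        beta = np.zeros(X.shape[1])
        diverged = converged = False
        trace, prev_step = [], np.inf
        it = 0
        for it in range(1, max_iter + 1):
            eta = X @ beta
            p = expit(eta)
            score = X.T @ (y - p)
            info = self._info(p)
            trace.append(_loglik(y, eta))
            if np.max(np.abs(score)) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(info + 1e-10 * np.eye(len(beta)), score)
            beta = beta + step
            step_norm = float(np.max(np.abs(step)))
            if np.max(np.abs(beta)) > self.coef_bound:
                diverged = True
                break
            prev_step = step_norm
        else:
            # iteration cap: divergent if the steps stopped shrinking
            diverged = prev_step >= tol and np.max(np.abs(beta)) > 1.0
        eta = X @ beta
        p = expit(eta)
        info = self._info(p)
        cov = _safe_inv(info)
        # quasi-separation: the score can vanish at a finite iterate although
        # no MLE exists; the giveaway is an exploding information inverse
        # (a numerically flat likelihood direction), as when an arm with
        # zero events drives a coefficient off to infinity
        if np.max(np.diag(cov)) > self.var_bound:
            diverged = True
        if diverged:
            converged = False
        return self._wrap("mle", beta, cov, _loglik(y, eta),
                          converged, diverged, it, trace)

    # Firth: penalized objective l(b) + 0.5 log det I(b); the score of the
    # penalty shifts each observation's residual by h_i * (1/2 - p_i).
    def _firth_objective(self, beta: np.ndarray) -> float:
        eta = self.X @ beta
        p = expit(eta)
        info = self._info(p)
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        return _loglik(self.y, eta) + 0.5 * logdet

    def _fit_firth(self, max_iter: int, tol: float) -> GlmResults:
        X, y = self.X, self.y
        beta = np.zeros(X.shape[1])
        converged = False
        trace = [self._firth_objective(beta)]
        it = 0
        for it in range(1, max_iter + 1):
            p = expit(X @ beta)
            W = p * (1.0 - p)
            info = self._info(p)
            info_inv = _safe_inv(info)
            # hat diagonal of the weighted design
            h = np.einsum("ij,jk,ik->i", X, info_inv, X) * W
            score = X.T @ (y - p + h * (0.5 - p))
            if np.max(np.abs(score)) < tol:
                converged = True
                break
            step = info_inv @ score
            # step-halving guarantees ascent of the penalized objective
            cur = trace[-1]
            for _ in range(30):
                cand = beta + step
                val = self._firth_objective(cand)
                if val >= cur - 1e-12:
                    break
                step = step / 2.0
            beta = cand
            trace.append(val)
        p = expit(X @ beta)
        cov = _safe_inv(self._info(p))
        return self._wrap("firth", beta, cov, self._firth_objective(beta),
                          converged, False, it, trace)

    # Cauchy WIP: bayesglm's augmented IRLS.  Prior variances sigma2_j are
    # EM-updated as (beta_j^2 + Var(beta_j) + df*scale_j^2)/(1+df) with
    # df=1 (Cauchy); the +Var term makes the fixed point match bayesglm.
    def _fit_cauchy(self, max_iter: int, tol: float, df: float = 1.0) -> GlmResults:
        X, y = self.X, self.y
        k = X.shape[1]
        scales = self.prior_scales
        beta = np.zeros(k)
        sigma2 = scales ** 2
        converged = False
        trace, H_inv = [], np.eye(k)
        it = 0
        for it in range(1, max_iter + 1):
            # inner ridge-IRLS to convergence at fixed prior variances;
            # each Newton step ascends the ridge-penalized log-likelihood
            inner_trace = []
            for _ in range(100):
                eta = X @ beta
                p = expit(eta)
                inner_trace.append(_loglik(y, eta) - 0.5 * np.sum(beta ** 2 / sigma2))
                score = X.T @ (y - p) - beta / sigma2
                H = self._info(p) + np.diag(1.0 / sigma2)
                step = np.linalg.solve(H, score)
                beta = beta + step
                if np.max(np.abs(step)) < tol:
                    break
            H_inv = _safe_inv(H)
            trace.append(inner_trace)
            sigma2_new = (beta ** 2 + np.diag(H_inv) + df * scales ** 2) / (1.0 + df)
            if np.max(np.abs(sigma2_new - sigma2)) < tol:
                sigma2 = sigma2_new
                converged = True
                break
            sigma2 = sigma2_new
        eta = X @ beta
        # log posterior under the effective Cauchy priors (diagnostic)
        logpost = _loglik(y, eta) - float(np.sum(np.log1p((beta / scales) ** 2)))
        return self._wrap("wip", beta, H_inv, logpost, converged, False, it, trace)


def _safe_inv(A: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A)


# ---------------------------------------------------------------------------
# spec-surface convenience functions
# ---------------------------------------------------------------------------

def fit_logistic_mle(data: RegressionData, max_iter: int = 25,
                     tol: float = 1e-8) -> GlmResults:
    """Ordinary logistic maximum likelihood (Newton/IRLS).

    Under separation the estimate does not exist; the fit is flagged
    ``diverged`` and the last iterate is returned so downstream analyses
    can reproduce the infinite-estimate pathology of standard software.
    """
    return PenalizedLogit(data, "none").fit(max_iter, tol)


def fit_firth(data: RegressionData, max_iter: int = 50,
              tol: float = 1e-8) -> GlmResults:
    """Firth (Jeffreys-prior) penalized logistic regression; always finite."""
    return PenalizedLogit(data, "firth").fit(max_iter, tol)


def fit_cauchy_wip(data: RegressionData, slope_scale: float = 2.5,
                   intercept_scale: float = 10.0, max_iter: int = 50,
                   tol: float = 1e-8, *,
                   standardize_priors: bool = True) -> GlmResults:
    """Logistic posterior mode under weakly informative Cauchy priors."""
    return PenalizedLogit(data, "cauchy", slope_scale=slope_scale,
                          intercept_scale=intercept_scale,
                          standardize_priors=standardize_priors).fit(max_iter, tol)


def fit_linear_gaussian(data: RegressionData) -> GlmResults:
    """Ordinary least squares with the unbiased residual-variance estimator."""
    y, X = _validate(data, binary=False)
    res = sm.OLS(y, X).fit()
    return GlmResults(
        method="gaussian",
        params=pd.Series(res.params, index=data.names),
        cov_params=pd.DataFrame(np.asarray(res.cov_params()),
                                index=data.names, columns=data.names),
        llf=float(res.llf), converged=True, diverged=False,
        n_iter=1, nobs=data.n,
    )


def wald_test(fit: GlmResults, coefficient: str,
              null_value: float = 0.0) -> tuple[float, float]:
    """Two-sided Wald z-test of one coefficient against ``null_value``.

    Raises ``ValueError`` when the standard error is zero or non-finite;
    the caller must treat such a test as failed, not as significant.
    """
    if coefficient not in fit.params.index:
        raise KeyError(f"no coefficient named {coefficient!r}")
    se = float(fit.bse[coefficient])
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"unusable standard error ({se}) for {coefficient!r}")
    z = (float(fit.params[coefficient]) - null_value) / se
    return z, float(2 * norm.sf(abs(z)))


_METHODS = {
    "logistic": fit_logistic_mle,
    "mle": fit_logistic_mle,
    "firth": fit_firth,
    "wip": fit_cauchy_wip,
}


def fit_two_by_two(table: TwoByTwo, method: str = "firth",
                   coding: str = "pm1") -> GlmResults:
    """Fit a treatment-only logistic model to a 2x2 event-count table.

    Expands the table to subject rows with the chosen treatment coding and
    dispatches to the matching fitter; identical to fitting the expanded
    data directly.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; use one of {sorted(_METHODS)}")
    return _METHODS[method](table.expand(coding))
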