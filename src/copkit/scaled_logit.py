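"""The scaled logistic ("Dunning") protection-curve model.

The model relates a continuous immunological surrogate ``S`` to the
probability of disease through a logistic curve scaled by an exposure
probability ``pi``::

    P(T = 1 | S) = pi * expit(mu + gamma * S)

``pi`` is interpretable as the probability of being exposed to the
pathogen: an unexposed subject cannot become a case no matter how low the
antibody titre.  The curve is monotone, skewed and bounded by ``pi``,
which makes it both a realistic generator of high-efficacy trial data and
a flexible full-mediation model (optionally with a residual treatment
term ``beta_z * Z``).

The likelihood is maximized by quasi-Newton search on the unconstrained
parameterization ``eta = logit(pi)`` with multiple starting values, since
the likelihood can be multimodal as ``pi`` approaches 1.  Standard errors
are computed by nonparametric case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import RegressionData, TrialData
from .glm import PenalizedLogit

__all__ = [
    "ScaledLogitParams",
    "ScaledLogitResults",
    "ScaledLogit",
    "scaled_logit_prob",
    "fit_scaled_logit",
    "bootstrap_se",
]

_PI_STARTS = (0.05, 0.2, 0.5, 0.8, 0.99)


@dataclass(frozen=True)
class ScaledLogitParams:
    """Parameters of the scaled logistic curve."""

    pi: float
    intercept: float
    surrogate_coef: float
    treatment_coef: float | None = None

    def __post_init__(self) -> None:
        vals = [self.pi, self.intercept, self.surrogate_coef]
        if self.treatment_coef is not None:
            vals.append(self.treatment_coef)
        if not all(np.isfinite(vals)):
            raise ValueError("parameters must be finite")
        if not (0.0 < self.pi <= 1.0):
            raise ValueError("pi must lie in (0, 1]")

    @property
    def names(self) -> list[str]:
        base = ["pi", "intercept", "surrogate"]
        return base + (["treatment"] if self.treatment_coef is not None else [])

    def as_series(self) -> pd.Series:
        vals = [self.pi, self.intercept, self.surrogate_coef]
        if self.treatment_coef is not None:
            vals.append(self.treatment_coef)
        return pd.Series(vals, index=self.names)


def scaled_logit_prob(params: ScaledLogitParams, s, z=None) -> np.ndarray | float:
    """Disease probability ``pi * expit(mu + gamma*s [+ beta_z*z])``."""
    eta = params.intercept + params.surrogate_coef * np.asarray(s, dtype=float)
    if params.treatment_coef is not None:
        if z is None:
            raise ValueError("model includes a treatment term; z is required")
        eta = eta + params.treatment_coef * np.asarray(z, dtype=float)
    return params.pi * expit(eta)


@dataclass
class ScaledLogitResults:
    """Fitted scaled-logit model with optional bootstrap uncertainty."""

    params: ScaledLogitParams
    llf: float
    converged: bool
    n_starts: int
    bse: pd.Series | None = None
    boot_reps: int = 0
    boot_failures: int = 0
    boot_ci: pd.DataFrame | None = None

    def predict(self, s, z=None):
        return scaled_logit_prob(self.params, s, z)

    def wald_test(self, name: str, null_value: float = 0.0) -> tuple[float, float]:
        """Two-sided Wald test using bootstrap standard errors."""
        from scipy.stats import norm

        if self.bse is None:
            raise ValueError("no standard errors; refit with bootstrap reps > 0")
        se = float(self.bse[name])
        if not np.isfinite(se) or se <= 0:
            raise ValueError(f"unusable bootstrap standard error for {name!r}")
        zstat = (float(self.params.as_series()[name]) - null_value) / se
        return zstat, float(2 * norm.sf(abs(zstat)))

    def summary(self) -> str:
        tab = pd.DataFrame({"estimate": self.params.as_series()})
        if self.bse is not None:
            tab["boot se"] = self.bse
        head = (f"scaled-logit fit (log-likelihood {self.llf:.4f}, "
                f"converged={self.converged}, bootstrap B={self.boot_reps}, "
                f"failed replicates={self.boot_failures})\n")
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}")


class ScaledLogit:
    """Scaled-logit model of a binary endpoint on a continuous surrogate.

    Parameters
    ----------
    endpoint, surrogate
        Binary outcome and continuous surrogate, one value per subject.
    treatment
        Optional 0/1 treatment indicator; when given, a residual treatment
        effect ``beta_z`` is estimated alongside the protection curve.
    """

    def __init__(self, endpoint, surrogate, treatment=None):
        self.t = np.asarray(endpoint, dtype=float)
        self.s = np.asarray(surrogate, dtype=float)
        self.z = None if treatment is None else np.asarray(treatment, dtype=float)
        if not np.isin(self.t, (0.0, 1.0)).all():
            raise ValueError("endpoint must be binary 0/1")
        if self.t.min() == self.t.max():
            raise ValueError("degenerate endpoint: all outcomes identical")
        if len(self.s) != len(self.t) or (self.z is not None and
                                          len(self.z) != len(self.t)):
            raise ValueError("input vectors must have equal length")

    @classmethod
    def from_trial(cls, data: TrialData, include_treatment: bool = False) -> "ScaledLogit":
        return cls(data.t, data.s, data.z if include_treatment else None)

    # -- likelihood -------------------------------------------------------
    @property
    def k_params(self) -> int:
        return 3 + (self.z is not None)

    def _nll_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        eta_pi, rest = theta[0], theta[1:]
        pi = expit(eta_pi)
        lin = rest[0] + rest[1] * self.s
        if self.z is not None:
            lin = lin + rest[2] * self.z
        p = expit(lin)
        P = np.clip(pi * p, 1e-300, 1.0 - 1e-12)
        t = self.t
        nll = -float(np.sum(t * np.log(P) + (1 - t) * np.log1p(-P)))
        # dNLL/dP, then chain rule through (eta_pi, mu, gamma[, beta_z])
        dP = -(t / P - (1 - t) / (1 - P))
        d_eta_pi = float(np.sum(dP * P * (1 - pi)))
        base = dP * P * (1 - p)
        grads = [d_eta_pi, float(np.sum(base)), float(np.sum(base * self.s))]
        if self.z is not None:
            grads.append(float(np.sum(base * self.z)))
        return nll, np.asarray(grads)

    def loglike(self, params: ScaledLogitParams) -> float:
        theta = np.r_[logit(min(params.pi, 1 - 1e-12)),
                      params.intercept, params.surrogate_coef]
        if self.z is not None:
            theta = np.r_[theta, params.treatment_coef]
        return -self._nll_grad(theta)[0]

    # -- fitting ----------------------------------------------------------
    def _warm_start(self) -> np.ndarray:
        cols = {"intercept": np.ones_like(self.s), "s": self.s}
        if self.z is not None:
            cols["z"] = self.z
        fit = PenalizedLogit(RegressionData(self.t, pd.DataFrame(cols)),
                             "firth").fit()
        return fit.params.to_numpy()

    def fit(self, max_iter: int = 500, tol: float = 1e-9,
            starts: tuple[float, ...] = _PI_STARTS,
            start_params: ScaledLogitParams | None = None) -> ScaledLogitResults:
        if start_params is not None:
            theta0s = [np.r_[logit(min(start_params.pi, 1 - 1e-9)),
                             start_params.as_series().to_numpy()[1:]]]
        else:
            warm = self._warm_start()
            theta0s = [np.r_[logit(pi0), warm] for pi0 in starts]
        best = None
        n_ok = 0
        for theta0 in theta0s:
            res = minimize(self._nll_grad, theta0, jac=True, method="L-BFGS-B",
                           options={"maxiter": max_iter, "ftol": tol,
                                    "gtol": 1e-9})
            n_ok += bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        th = best.x
        params = ScaledLogitParams(
            pi=float(expit(th[0])), intercept=float(th[1]),
            surrogate_coef=float(th[2]),
            treatment_coef=float(th[3]) if self.z is not None else None)
        return ScaledLogitResults(params=params, llf=-float(best.fun),
                                  converged=n_ok > 0, n_starts=len(theta0s))

    def fit_bootstrap(self, B: int = 500, seed=None,
                      max_fail_frac: float = 0.2) -> ScaledLogitResults:
        """Point fit plus case-resampling bootstrap standard errors.

        Resampling is stratified by treatment arm when a treatment column
        is present.  Replicate fits that fail to converge are dropped and
        counted; more than ``max_fail_frac`` failures is an error.
        """
        point = self.fit()
        if B == 0:
            return point
        if B < 50:
            raise ValueError("use at least 50 bootstrap replicates")
        rng = np.random.default_rng(seed)
        n = len(self.t)
        strata = ([np.arange(n)] if self.z is None
                  else [np.flatnonzero(self.z == v) for v in (0.0, 1.0)])
        draws, failures = [], 0
        for _ in range(B):
            idx = np.concatenate([rng.choice(ix, size=len(ix), replace=True)
                                  for ix in strata])
            try:
                rep = ScaledLogit(self.t[idx], self.s[idx],
                                  None if self.z is None else self.z[idx])
                fit = rep.fit(start_params=point.params)
                if not fit.converged:
                    raise RuntimeError("replicate did not converge")
                draws.append(fit.params.as_series())
            except (ValueError, RuntimeError, np.linalg.LinAlgError):
                failures += 1
        if failures > max_fail_frac * B:
            raise RuntimeError(f"{failures}/{B} bootstrap replicates failed")
        boot = pd.DataFrame(draws)
        ci = boot.quantile([0.025, 0.975]).T
        ci.columns = ["2.5%", "97.5%"]
        return replace(point, bse=boot.std(ddof=1), boot_reps=B,
                       boot_failures=failures, boot_ci=ci)


# ---------------------------------------------------------------------------
# spec-surface convenience functions
# ---------------------------------------------------------------------------

def fit_scaled_logit(data: RegressionData | TrialData,
                     include_treatment: bool = False, max_iter: int = 500,
                     tol: float = 1e-9) -> ScaledLogitResults:
    """Maximum-likelihood fit of the scaled-logit curve to trial data."""
    if isinstance(data, TrialData):
        model = ScaledLogit.from_trial(data, include_treatment)
    else:
        cols = {c.lower(): c for c in data.names}
        if "s" not in cols:
            raise ValueError("a surrogate column named 's' is required")
        z = data.predictors[cols["z"]] if include_treatment else None
        model = ScaledLogit(data.outcome, data.predictors[cols["s"]], z)
    return model.fit(max_iter=max_iter, tol=tol)


def bootstrap_se(data: TrialData, include_treatment: bool = False,
                 B: int = 500, seed=None) -> ScaledLogitResults:
    """Scaled-logit fit with nonparametric bootstrap standard errors."""
    return ScaledLogit.from_trial(data, include_treatment).fit_bootstrap(B, seed)
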