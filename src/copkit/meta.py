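"""Two-stage meta-analytic trial-level surrogacy on randomized subgroups.

A single trial is split into randomized subgroups (centers, regions).
Stage one estimates, per subgroup *i*, the treatment effect on the
surrogate (``alpha_i``, Gaussian regression of S on Z) and on the
clinical endpoint (``beta_i``, a logistic-family regression of T on Z).
Stage two regresses the endpoint effects on the surrogate effects by
weighted least squares with inverse-variance weights
``w_i = 1 / Var(beta_i)``; the R-squared of that regression measures
trial-level surrogacy.

With high vaccine efficacy many subgroups have zero events in the
vaccinated arm, so ordinary-ML ``beta_i`` are infinite and trial-level
R-squared collapses.  Selecting a penalized stage-one fitter (``firth``
or ``wip``) keeps every subgroup estimate finite and restores the
meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import MultiSubgroupData, RegressionData
from .glm import (fit_cauchy_wip, fit_firth, fit_linear_gaussian,
                  fit_logistic_mle)

__all__ = [
    "StageOneEstimates",
    "SurrogacyResults",
    "TwoStageSurrogacy",
    "stage_one",
    "stage_two",
    "weighted_r2",
    "two_stage",
]

_ENDPOINT_FITTERS = {
    "logistic": fit_logistic_mle,
    "firth": fit_firth,
    "wip": fit_cauchy_wip,
    "gaussian": fit_linear_gaussian,
}


@dataclass
class StageOneEstimates:
    """Per-subgroup treatment effects on surrogate and endpoint."""

    table: pd.DataFrame  # one row per usable subgroup
    excluded: list[tuple[object, str]]
    outcome_method: str
    coding: str

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SurrogacyResults:
    """Trial-level surrogacy regression: slope, intercept and weighted R2."""

    lambda0: float
    lambda_: float
    r_squared: float
    #: plain OLS R2 of beta_i on alpha_i, in which diverged stage-one
    #: estimates are NOT self-downweighted by their huge variances; this
    #: is the quantity that standard unpenalized software visibly wrecks
    #: when subgroups separate, so it is reported alongside the weighted R2
    r_squared_unweighted: float
    n_subgroups_used: int
    excluded_subgroups: list[tuple[object, str]]
    weights: pd.Series
    stage_one: StageOneEstimates = field(repr=False)
    wls: object = field(default=None, repr=False)

    def summary(self) -> str:
        n_div = int(self.stage_one.table["diverged"].sum())
        return (
            "Two-stage trial-level surrogacy\n"
            f"  endpoint fitter: {self.stage_one.outcome_method} "
            f"(coding {self.stage_one.coding})\n"
            f"  subgroups used: {self.n_subgroups_used} "
            f"(excluded: {len(self.excluded_subgroups)}, "
            f"diverged stage-one fits: {n_div})\n"
            f"  beta_i = {self.lambda0:.4f} + {self.lambda_:.4f} * alpha_i\n"
            f"  weighted R2 (trial-level surrogacy): {self.r_squared:.4f}\n"
            f"  unweighted R2 (diagnostic): {self.r_squared_unweighted:.4f}"
        )

    def plot(self, ax=None):
        """Scatter of endpoint vs surrogate effects, sized by weight."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.stage_one.table
        w = self.weights / self.weights.max()
        ax.scatter(tab["alpha_hat"], tab["beta_hat"], s=20 + 180 * w,
                   alpha=0.6, edgecolor="k")
        xs = np.linspace(tab["alpha_hat"].min(), tab["alpha_hat"].max(), 50)
        ax.plot(xs, self.lambda0 + self.lambda_ * xs, "r-")
        ax.set_xlabel("treatment effect on surrogate (alpha_i)")
        ax.set_ylabel("treatment effect on endpoint (beta_i)")
        ax.set_title(f"trial-level surrogacy R2 = {self.r_squared:.2f}")
        return ax


def stage_one(data: MultiSubgroupData, outcome_method: str = "firth",
              coding: str = "pm1") -> StageOneEstimates:
    """Per-subgroup treatment-effect estimates.

    ``alpha_i`` comes from a Gaussian fit of S on Z and ``beta_i`` from the
    selected endpoint fitter applied to T on Z; divergence flags from
    separated ordinary-ML fits are carried through rather than hidden.
    """
    if outcome_method not in _ENDPOINT_FITTERS:
        raise ValueError(f"unknown outcome_method {outcome_method!r}")
    if outcome_method != "gaussian" and not data.t_is_binary:
        raise ValueError("non-binary endpoint requires outcome_method='gaussian'")
    rows, excluded = [], []
    for sid, grp in data.iter_subgroups():
        z01 = grp["z"].to_numpy(dtype=float)
        if z01.min() == z01.max():
            excluded.append((sid, "single-arm subgroup"))
            continue
        z = z01 if coding == "01" else 2.0 * z01 - 1.0
        X = pd.DataFrame({"intercept": np.ones_like(z), "z": z})
        fa = fit_linear_gaussian(RegressionData(grp["s"].to_numpy(), X))
        fb = _ENDPOINT_FITTERS[outcome_method](
            RegressionData(grp["t"].to_numpy(dtype=float), X))
        t, zz = grp["t"].to_numpy(), z01
        rows.append({
            "subgroup": sid,
            "alpha_hat": fa.params["z"], "var_alpha": fa.cov_params.loc["z", "z"],
            "beta_hat": fb.params["z"], "var_beta": fb.cov_params.loc["z", "z"],
            "diverged": bool(getattr(fb, "diverged", False)),
            "events_control": int(np.sum(t[zz == 0])) if data.t_is_binary else -1,
            "events_vaccinated": int(np.sum(t[zz == 1])) if data.t_is_binary else -1,
        })
    return StageOneEstimates(pd.DataFrame(rows), excluded, outcome_method, coding)


def weighted_r2(x, y, w) -> float:
    """R-squared of the weighted regression of ``y`` on ``(1, x)``.

    Defined as ``1 - sum(w*(y-yhat)^2) / sum(w*(y-ybar_w)^2)`` with
    ``ybar_w`` the weighted mean of ``y``.
    """
    x, y, w = (np.asarray(v, dtype=float) for v in (x, y, w))
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal length")
    if len(x) < 3:
        raise ValueError("at least 3 points are required")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    ybar = np.sum(w * y) / np.sum(w)
    tss = float(np.sum(w * (y - ybar) ** 2))
    if tss <= 0:
        raise ValueError("zero weighted variance of y")
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    rss = float(np.sum(w * res.resid ** 2))
    return 1.0 - rss / tss


def stage_two(est: StageOneEstimates,
              weight_policy: str = "naive") -> SurrogacyResults:
    """Weighted regression of endpoint effects on surrogate effects.

    ``weight_policy="naive"`` keeps diverged ordinary-ML fits with their
    huge estimated variances (which self-downweight), reproducing the
    broken-logistic benchmark; ``"exclude_diverged"`` drops them.
    """
    if weight_policy not in ("naive", "exclude_diverged"):
        raise ValueError(f"unknown weight_policy {weight_policy!r}")
    tab = est.table.copy()
    excluded = list(est.excluded)
    usable = np.isfinite(tab["alpha_hat"]) & np.isfinite(tab["beta_hat"]) \
        & np.isfinite(tab["var_beta"]) & (tab["var_beta"] > 0)
    for sid in tab.loc[~usable, "subgroup"]:
        excluded.append((sid, "non-finite stage-one estimate or variance"))
    if weight_policy == "exclude_diverged":
        for sid in tab.loc[usable & tab["diverged"], "subgroup"]:
            excluded.append((sid, "diverged ordinary-ML fit"))
        usable &= ~tab["diverged"]
    tab = tab[usable]
    if len(tab) < 3:
        raise ValueError(f"only {len(tab)} usable subgroups; need at least 3")
    w = 1.0 / tab["var_beta"].to_numpy()
    x = tab["alpha_hat"].to_numpy()
    y = tab["beta_hat"].to_numpy()
    wls = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    r2 = weighted_r2(x, y, w)
    r2u = float(sm.OLS(y, sm.add_constant(x)).fit().rsquared)
    return SurrogacyResults(
        lambda0=float(wls.params[0]), lambda_=float(wls.params[1]),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        r_squared_unweighted=r2u,
        n_subgroups_used=len(tab), excluded_subgroups=excluded,
        weights=pd.Series(w, index=tab["subgroup"].to_numpy()),
        stage_one=StageOneEstimates(tab, est.excluded, est.outcome_method,
                                    est.coding),
        wls=wls)


class TwoStageSurrogacy:
    """Trial-level surrogacy model on randomized subgroups.

    ``TwoStageSurrogacy(data, outcome_method="firth").fit()`` runs both
    stages and returns a :class:`SurrogacyResults`.
    """

    def __init__(self, data: MultiSubgroupData | pd.DataFrame,
                 outcome_method: str = "firth", coding: str = "pm1",
                 weight_policy: str = "naive"):
        if isinstance(data, pd.DataFrame):
            data = MultiSubgroupData.from_dataframe(data)
        self.data = data
        self.outcome_method = outcome_method
        self.coding = coding
        self.weight_policy = weight_policy

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "TwoStageSurrogacy":
        return cls(MultiSubgroupData.from_dataframe(df), **kw)

    def fit(self) -> SurrogacyResults:
        est = stage_one(self.data, self.outcome_method, self.coding)
        return stage_two(est, self.weight_policy)


def two_stage(data: MultiSubgroupData, outcome_method: str = "firth",
              coding: str = "pm1",
              weight_policy: str = "naive") -> SurrogacyResults:
    """One-call composition of :func:`stage_one` and :func:`stage_two`."""
    return TwoStageSurrogacy(data, outcome_method, coding, weight_policy).fit()
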