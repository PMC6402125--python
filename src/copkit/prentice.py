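"""The Prentice criteria for statistical surrogacy in a vaccine trial.

A surrogate endpoint ``S`` (for example an antibody titre) is a valid
statistical substitute for the clinical endpoint ``T`` when

1. treatment affects the clinical endpoint:      ``logit P(T=1) = mu_T + beta*Z``
2. treatment affects the surrogate:              ``S = mu_S + alpha*Z + eps``
3. the surrogate predicts the clinical endpoint: ``logit P(T=1) = mu + gamma*S``
4. the surrogate captures the *full* treatment effect (mediation):
   in ``logit P(T=1) = mu_T' + beta_S*Z + gamma_Z*S`` the surrogate term is
   significant and the residual treatment term is not.

When vaccine efficacy is very high, the linear criterion-4 model suffers
lack of fit: the misfit of the linear surrogate effect is absorbed by the
treatment term, inflating its type-I error and destroying the power to
meet criterion 4.  This module therefore offers three criterion-4
variants: ``linear``, ``quadratic`` (an extra ``S^2`` term), and
``scaled_logit`` (the Dunning curve with a residual treatment effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RegressionData, TrialData
from .glm import (GlmResults, fit_linear_gaussian, fit_logistic_mle, wald_test)
from .scaled_logit import ScaledLogit, ScaledLogitResults

__all__ = ["PrenticeCriteria", "PrenticeResults", "fit_model4", "assess_prentice"]

VARIANTS = ("linear", "quadratic", "scaled_logit")


def _design(cols: dict[str, np.ndarray]) -> pd.DataFrame:
    n = len(next(iter(cols.values())))
    out = {"intercept": np.ones(n)}
    out.update(cols)
    return pd.DataFrame(out)


def fit_model4(data: TrialData, variant: str = "linear", *,
               coding: str = "01", bootstrap_reps: int = 500,
               seed=None) -> GlmResults | ScaledLogitResults:
    """Fit the criterion-4 (full mediation) model in the chosen variant.

    ``linear`` and ``quadratic`` are ordinary logistic fits of ``T`` on
    ``(Z, S)`` and ``(Z, S, S^2)``; ``scaled_logit`` is a Dunning fit with
    a residual treatment term and bootstrap standard errors.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; use one of {VARIANTS}")
    z = data.z if coding == "01" else 2.0 * data.z - 1.0
    if variant == "scaled_logit":
        model = ScaledLogit(data.t, data.s, z)
        return model.fit_bootstrap(B=bootstrap_reps, seed=seed)
    cols = {"z": z, "s": data.s}
    if variant == "quadratic":
        cols["s2"] = data.s ** 2
    return fit_logistic_mle(RegressionData(data.t, _design(cols)))


@dataclass
class PrenticeResults:
    """Per-criterion fits, p-values, and met/not-met decisions."""

    variant: str
    alpha_level: float
    fit_c1: GlmResults
    fit_c2: GlmResults
    fit_c3: GlmResults
    fit_c4: GlmResults | ScaledLogitResults
    p_beta: float      # criterion 1: treatment effect on T
    p_alpha: float     # criterion 2: treatment effect on S
    p_gamma: float     # criterion 3: surrogate effect on T
    p_S: float         # criterion 4: surrogate term(s)
    p_Z: float         # criterion 4: residual treatment term
    p_S_linear: float  # 1-df surrogate test (diagnostic for the quadratic variant)
    criteria_met: tuple[bool, bool, bool, bool]
    c4_assessable: bool
    diagnostics: list[str]

    @property
    def all_met(self) -> bool:
        return all(self.criteria_met)

    def summary(self) -> str:
        rows = [
            ("1: vaccine protects (T ~ Z)", self.p_beta, self.criteria_met[0]),
            ("2: vaccine moves surrogate (S ~ Z)", self.p_alpha, self.criteria_met[1]),
            ("3: surrogate predicts disease (T ~ S)", self.p_gamma, self.criteria_met[2]),
            (f"4: full mediation [{self.variant}] (surrogate)", self.p_S, None),
            ("4: full mediation (residual treatment)", self.p_Z, self.criteria_met[3]),
        ]
        lines = [f"Prentice criteria assessment (alpha={self.alpha_level}, "
                 f"model-4 variant: {self.variant})"]
        for label, p, met in rows:
            flag = "" if met is None else ("  MET" if met else "  NOT MET")
            ptxt = "n/a" if not np.isfinite(p) else f"{p:.4g}"
            lines.append(f"  criterion {label}: p = {ptxt}{flag}")
        if not self.c4_assessable:
            lines.append("  criterion 4 NOT ASSESSABLE: " + "; ".join(self.diagnostics))
        lines.append(f"  all criteria met: {self.all_met}")
        return "\n".join(lines)


class PrenticeCriteria:
    """Prentice-criteria assessment model for one randomized trial.

    Parameters
    ----------
    data
        Subject-level trial records ``(z, s, t)``.
    variant
        Criterion-4 model: ``"linear"``, ``"quadratic"`` or
        ``"scaled_logit"``.
    coding
        Treatment coding used in the criterion models (``"01"`` default,
        matching the usual parameterization; ``"pm1"`` available).
    """

    def __init__(self, data: TrialData, variant: str = "linear",
                 coding: str = "01"):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; use one of {VARIANTS}")
        if coding not in ("01", "pm1"):
            raise ValueError("coding must be '01' or 'pm1'")
        self.data = data
        self.variant = variant
        self.coding = coding

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variant: str = "linear",
                       **cols) -> "PrenticeCriteria":
        return cls(TrialData.from_dataframe(df, **cols), variant)

    def fit(self, alpha_level: float = 0.05, bootstrap_reps: int = 500,
            seed=None) -> PrenticeResults:
        d = self.data
        z = d.z if self.coding == "01" else 2.0 * d.z - 1.0
        diagnostics: list[str] = []

        fit_c1 = fit_logistic_mle(RegressionData(d.t, _design({"z": z})))
        fit_c2 = fit_linear_gaussian(RegressionData(d.s, _design({"z": z})))
        fit_c3 = fit_logistic_mle(RegressionData(d.t, _design({"s": d.s})))
        fit_c4 = fit_model4(d, self.variant, coding=self.coding,
                            bootstrap_reps=bootstrap_reps, seed=seed)

        p_beta = self._p(fit_c1, "z", diagnostics, "criterion 1")
        p_alpha = self._p(fit_c2, "z", diagnostics, "criterion 2")
        p_gamma = self._p(fit_c3, "s", diagnostics, "criterion 3")
        p_S, p_Z, p_S_linear, assessable = self._criterion4(fit_c4, diagnostics)

        met = (
            np.isfinite(p_beta) and p_beta < alpha_level,
            np.isfinite(p_alpha) and p_alpha < alpha_level,
            np.isfinite(p_gamma) and p_gamma < alpha_level,
            bool(assessable and p_S < alpha_level and p_Z >= alpha_level),
        )
        return PrenticeResults(
            variant=self.variant, alpha_level=alpha_level,
            fit_c1=fit_c1, fit_c2=fit_c2, fit_c3=fit_c3, fit_c4=fit_c4,
            p_beta=p_beta, p_alpha=p_alpha, p_gamma=p_gamma,
            p_S=p_S, p_Z=p_Z, p_S_linear=p_S_linear,
            criteria_met=met, c4_assessable=assessable,
            diagnostics=diagnostics)

    @staticmethod
    def _p(fit: GlmResults, name: str, diagnostics: list[str],
           label: str) -> float:
        if getattr(fit, "diverged", False):
            diagnostics.append(f"{label}: fit diverged (separation)")
            return np.nan
        try:
            return wald_test(fit, name)[1]
        except ValueError as err:
            diagnostics.append(f"{label}: {err}")
            return np.nan

    def _criterion4(self, fit, diagnostics):
        """Surrogate and residual-treatment p-values for model 4.

        For the quadratic variant the surrogate test is the joint 2-df
        Wald test of both surrogate terms (the coherent reading when S
        enters the model twice); the 1-df test of the linear term is also
        returned as a diagnostic.
        """
        p_S = p_Z = p_S_lin = np.nan
        if isinstance(fit, ScaledLogitResults):
            try:
                p_S = fit.wald_test("surrogate")[1]
                p_Z = fit.wald_test("treatment")[1]
                p_S_lin = p_S
            except ValueError as err:
                diagnostics.append(f"criterion 4 (scaled logit): {err}")
                return p_S, p_Z, p_S_lin, False
            return p_S, p_Z, p_S_lin, True
        if fit.diverged:
            diagnostics.append("criterion 4: model-4 fit diverged (separation); "
                               "treatment test is meaningless")
            return p_S, p_Z, p_S_lin, False
        try:
            p_Z = wald_test(fit, "z")[1]
            p_S_lin = wald_test(fit, "s")[1]
            if self.variant == "quadratic":
                p_S = fit.wald_joint(["s", "s2"])[1]
            else:
                p_S = p_S_lin
        except ValueError as err:
            diagnostics.append(f"criterion 4: {err}")
            return p_S, p_Z, p_S_lin, False
        return p_S, p_Z, p_S_lin, True


def assess_prentice(data: TrialData, variant: str = "linear",
                    alpha_level: float = 0.05, *, coding: str = "01",
                    bootstrap_reps: int = 500, seed=None) -> PrenticeResults:
    """Fit all four Prentice criterion models and apply the decision rule."""
    return PrenticeCriteria(data, variant, coding).fit(
        alpha_level, bootstrap_reps=bootstrap_reps, seed=seed)
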