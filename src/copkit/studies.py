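"""Monte-Carlo study runners quantifying the operating characteristics
of the criterion-4 variants and of the penalized meta-analytic estimators.

Each runner draws its replicates from explicit counter-based substreams
(``default_rng([seed, cell, replicate])``), so any cell can be reproduced
independently of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import RegressionData, TwoByTwo
from .glm import fit_linear_gaussian, fit_logistic_mle, fit_two_by_two, wald_test
from .meta import StageOneEstimates, stage_two
from .prentice import fit_model4
from .scaled_logit import ScaledLogitResults
from .simulate import (MetaSimConfig, PrenticeSimConfig, empirical_ve,
                       gen_meta_trial, gen_prentice_trial)

__all__ = [
    "StudySummary",
    "run_prentice_power_study",
    "run_event_grid",
    "run_surrogacy_sim_study",
    "DEFAULT_MU1_VALUES",
    "DEFAULT_EVENT_PATTERNS",
]

DEFAULT_MU1_VALUES = (4.5, 4.0, 3.75, 3.33)

#: event patterns (e_c, e_v) of the per-table comparison grid
DEFAULT_EVENT_PATTERNS = tuple((ec, 0) for ec in range(11)) + \
    ((1, 1), (3, 1), (9, 2), (2, 3))


@dataclass
class StudySummary:
    """A simulation-study summary table plus its reproducibility metadata."""

    table: pd.DataFrame
    replications: int
    seed: int
    alpha: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def max_failure_rate(self) -> float:
        if "n_failed" not in self.table.columns or self.replications == 0:
            return 0.0
        return float(self.table["n_failed"].max() / self.replications)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _binom_se(p: float, n: int) -> float:
    return float(np.sqrt(max(p * (1 - p), 0.0) / n))


def run_prentice_power_study(reps: int = 1000,
                             mu1_values=DEFAULT_MU1_VALUES,
                             variants=("linear", "quadratic"),
                             alpha: float = 0.05, seed: int = 0,
                             base_config: PrenticeSimConfig = PrenticeSimConfig(),
                             bootstrap_reps: int = 200) -> StudySummary:
    """Power/type-I study of the criterion-4 decision under full mediation.

    For each surrogate-shift setting ``mu1`` and each model-4 variant,
    simulates ``reps`` trials from the scaled-logit generator and
    tabulates the mean empirical VE, the rejection rate of the surrogate
    test ``P(p_S < alpha)``, the rejection rate of the residual treatment
    test ``P(p_Z < alpha)`` (a type-I error under full mediation), and
    the probability of meeting criterion 4.
    """
    if reps < 1:
        raise ValueError("reps must be positive")
    rows = []
    for ci, mu1 in enumerate(mu1_values):
        cfg = replace(base_config, mu1=float(mu1), seed=None)
        recs = {v: [] for v in variants}
        ves = []
        for r in range(reps):
            rng_seed = [seed, ci, r]
            data = gen_prentice_trial(cfg, seed=rng_seed)
            try:
                ves.append(empirical_ve(data.z, data.t))
            except ValueError:
                ves.append(np.nan)
            for vi, variant in enumerate(variants):
                p_S = p_Z = np.nan
                try:
                    fit = fit_model4(data, variant,
                                     bootstrap_reps=bootstrap_reps,
                                     seed=[seed, ci, r, vi])
                    if isinstance(fit, ScaledLogitResults):
                        p_S = fit.wald_test("surrogate")[1]
                        p_Z = fit.wald_test("treatment")[1]
                    elif not fit.diverged:
                        p_Z = wald_test(fit, "z")[1]
                        if variant == "quadratic":
                            p_S = fit.wald_joint(["s", "s2"])[1]
                        else:
                            p_S = wald_test(fit, "s")[1]
                except (ValueError, RuntimeError, np.linalg.LinAlgError):
                    pass
                recs[variant].append((p_S, p_Z))
        for variant in variants:
            ps = np.array(recs[variant])
            # rates are computed among assessable fits; replicates whose
            # model-4 fit diverged or failed are counted separately
            ok = np.isfinite(ps).all(axis=1)
            n_ok = int(ok.sum())
            rej_S = ps[ok, 0] < alpha
            rej_Z = ps[ok, 1] < alpha
            met4 = rej_S & ~rej_Z
            p_Z_rate = float(rej_Z.mean()) if n_ok else np.nan
            power = float(met4.mean()) if n_ok else np.nan
            rows.append({
                "mu1": mu1, "variant": variant,
                "ve_hat_mean": float(np.nanmean(ves)),
                "p_S_rate": float(rej_S.mean()) if n_ok else np.nan,
                "p_Z_rate": p_Z_rate,
                "criterion4_power": power,
                "p_Z_rate_se": _binom_se(p_Z_rate, n_ok) if n_ok else np.nan,
                "criterion4_power_se": _binom_se(power, n_ok) if n_ok else np.nan,
                "n_assessed": n_ok,
                "n_failed": reps - n_ok,
            })
    return StudySummary(pd.DataFrame(rows), reps, seed, alpha,
                        metadata={"generator": cfg.to_dict(),
                                  "mu1_values": list(mu1_values),
                                  "variants": list(variants),
                                  "bootstrap_reps": bootstrap_reps})


def run_event_grid(n_per_arm: int = 10,
                   patterns=DEFAULT_EVENT_PATTERNS,
                   coding: str = "pm1") -> pd.DataFrame:
    """Fit logistic, Firth and WIP models to a grid of 2x2 event patterns.

    One row per ``(e_c, e_v)`` pattern with the treatment coefficient and
    its estimated variance under each method.
    """
    rows = []
    for e_c, e_v in patterns:
        table = TwoByTwo(n_per_arm, n_per_arm, e_c, e_v)
        rec = {"e_c": e_c, "e_v": e_v}
        for method in ("logistic", "firth", "wip"):
            fit = fit_two_by_two(table, method, coding)
            rec[f"coef_{method}"] = float(fit.params["treatment"])
            rec[f"var_{method}"] = float(
                fit.cov_params.loc["treatment", "treatment"])
            if method == "logistic":
                rec["diverged_logistic"] = bool(fit.diverged)
        rows.append(rec)
    return pd.DataFrame(rows)


def _stage_one_multi(data, methods, coding: str = "pm1"):
    """Stage-one estimates for several endpoint fitters in one pass
    (the surrogate regressions are shared across methods)."""
    from .glm import fit_cauchy_wip, fit_firth

    fitters = {"logistic": fit_logistic_mle, "firth": fit_firth,
               "wip": fit_cauchy_wip}
    rows = {m: [] for m in methods}
    excluded = []
    for sid, grp in data.iter_subgroups():
        z01 = grp["z"].to_numpy(dtype=float)
        if z01.min() == z01.max():
            excluded.append((sid, "single-arm subgroup"))
            continue
        z = z01 if coding == "01" else 2.0 * z01 - 1.0
        X = pd.DataFrame({"intercept": np.ones_like(z), "z": z})
        fa = fit_linear_gaussian(RegressionData(grp["s"].to_numpy(), X))
        t = grp["t"].to_numpy(dtype=float)
        reg = RegressionData(t, X)
        base = {"subgroup": sid, "alpha_hat": fa.params["z"],
                "var_alpha": fa.cov_params.loc["z", "z"],
                "events_control": int(t[z01 == 0].sum()),
                "events_vaccinated": int(t[z01 == 1].sum())}
        for m in methods:
            fb = fitters[m](reg)
            rows[m].append({**base, "beta_hat": fb.params["z"],
                            "var_beta": fb.cov_params.loc["z", "z"],
                            "diverged": bool(fb.diverged)})
    return {m: StageOneEstimates(pd.DataFrame(rows[m]), excluded, m, coding)
            for m in methods}


def run_surrogacy_sim_study(reps: int = 300, betas=(-1.0, -2.0, -4.0),
                            methods=("logistic", "firth", "wip"),
                            seed: int = 0,
                            base_config: MetaSimConfig = MetaSimConfig(),
                            coding: str = "pm1") -> StudySummary:
    """Sampling distribution of trial-level R2 under each stage-one fitter.

    For each fixed endpoint treatment effect ``beta``, simulates ``reps``
    multi-subgroup trials, runs the two-stage surrogacy analysis with each
    endpoint fitter on the *same* replicates, and summarizes the estimated
    R2 (mean, median, SD, 2.5%/97.5% quantiles, MSE against the true
    random-slope R2) together with the mean number of subgroups with zero
    vaccinated-arm events.
    """
    if reps < 1:
        raise ValueError("reps must be positive")
    rows = []
    true_r2 = base_config.true_r2
    for ci, beta in enumerate(betas):
        cfg = replace(base_config, beta=float(beta), seed=None)
        r2s = {m: [] for m in methods}
        fails = {m: 0 for m in methods}
        zero_events = []
        for r in range(reps):
            data = gen_meta_trial(cfg, seed=[seed, ci, r])
            ests = _stage_one_multi(data, methods, coding)
            any_tab = ests[methods[0]].table
            zero_events.append(int((any_tab["events_vaccinated"] == 0).sum()))
            for m in methods:
                try:
                    r2s[m].append(stage_two(ests[m]).r_squared)
                except ValueError:
                    fails[m] += 1
        for m in methods:
            v = np.asarray(r2s[m])
            rows.append({
                "beta": beta, "method": m, "true_r2": true_r2,
                "r2_mean": float(v.mean()), "r2_median": float(np.median(v)),
                "r2_sd": float(v.std(ddof=1)),
                "r2_q025": float(np.quantile(v, 0.025)),
                "r2_q975": float(np.quantile(v, 0.975)),
                "r2_mse": float(np.mean((v - true_r2) ** 2)),
                "zero_vacc_event_subgroups_mean": float(np.mean(zero_events)),
                "n_failed": fails[m],
            })
    return StudySummary(pd.DataFrame(rows), reps, seed,
                        metadata={"generator": cfg.to_dict(),
                                  "betas": list(betas),
                                  "methods": list(methods),
                                  "coding": coding})
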