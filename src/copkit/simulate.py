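"""Synthetic trial generators for the simulation studies.

Two generators define the study conditions:

* :func:`gen_prentice_trial` — a single high-efficacy trial under *full
  mediation*: treatment shifts the surrogate distribution, and disease
  risk depends on treatment only through the surrogate via the scaled
  logistic curve ``P(T=1|S) = pi * expit(mu + gamma*S)``.  Defaults:
  n=5000 subjects, 1:1 randomization, pi=0.1, mu=8.3, gamma=log(0.05),
  S ~ Normal(3, 0.2) in controls; shifting the vaccinated surrogate mean
  mu1 over {4.5, 4, 3.75, 3.33} sweeps vaccine efficacy over roughly
  {0.96, 0.87, 0.76, 0.41}.

* :func:`gen_meta_trial` — a trial split into randomized subgroups with
  correlated random treatment effects on surrogate and binary endpoint
  (no random intercepts): 25 subgroups of 40 subjects; the squared
  random-slope correlation (0.9 by default) is the true trial-level
  surrogacy R2.

A continuous-endpoint variant, :func:`gen_continuous_surrogacy_trial`,
emulates the classical multi-center dataset layout (50 subgroups of 20,
both endpoints Gaussian, high trial-level association) so that the
information-loss and penalization orderings can be demonstrated after
dichotomizing the endpoint.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data import MultiSubgroupData, TrialData

__all__ = [
    "PrenticeSimConfig",
    "MetaSimConfig",
    "ContinuousSurrogacyConfig",
    "gen_prentice_trial",
    "gen_meta_trial",
    "gen_continuous_surrogacy_trial",
    "dichotomize_outcome",
    "empirical_ve",
]


@dataclass(frozen=True)
class PrenticeSimConfig:
    """Full-mediation scaled-logit generator settings (one trial)."""

    n: int = 5000
    pi: float = 0.1
    mu: float = 8.3
    gamma: float = float(np.log(0.05))   # log(1 - 0.95)
    mu0: float = 3.0
    mu1: float = 4.5
    var_s: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n % 2:
            raise ValueError("n must be even for 1:1 randomization")
        if not (0 < self.pi <= 1):
            raise ValueError("pi must lie in (0, 1]")
        if self.var_s <= 0:
            raise ValueError("var_s must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MetaSimConfig:
    """Reduced bivariate random-treatment-effects generator settings."""

    n_subgroups: int = 25
    n_per_subgroup: int = 40
    mu_s: float = 4.609
    mu_t: float = -2.2401
    alpha: float = 5.458
    beta: float = -4.0
    var_a: float = 10.0
    var_b: float = 4.0
    rho: float = float(np.sqrt(0.9))
    sigma_s: float = 1.0
    #: generator treatment coding; with "pm1" the random endpoint slope
    #: b_i moves both arms, so separated subgroups (zero vaccinated
    #: events) still leave a penalized-estimable trace in the control arm
    coding: str = "pm1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.var_a < 0 or self.var_b < 0:
            raise ValueError("random-slope variances must be nonnegative")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must not exceed 1")
        if self.n_per_subgroup % 2:
            raise ValueError("n_per_subgroup must be even for 1:1 randomization")
        if self.coding not in ("01", "pm1"):
            raise ValueError("coding must be '01' or 'pm1'")

    @property
    def true_r2(self) -> float:
        return self.rho ** 2

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ContinuousSurrogacyConfig:
    """Continuous-endpoint multi-subgroup emulation (synthetic stand-in
    for the classical public multi-center surrogacy dataset: 50 subgroups,
    20 subjects each, 1:1, continuous S and T, trial-level R2 = rho^2).

    Defaults are chosen so that dichotomizing the endpoint at
    ``T < -2.87`` yields a vaccine efficacy of about 0.95 on the binary
    scale (control event rate ~0.25, vaccinated ~0.0125).  As in
    :class:`MetaSimConfig`, treatment enters with +/-1 coding so the
    random slopes move both arms.
    """

    n_subgroups: int = 50
    n_per_subgroup: int = 20
    mu_s: float = 3.0
    mu_t: float = -1.085
    alpha: float = 0.75
    beta: float = 0.959
    var_a: float = 1.0
    var_b: float = 0.5
    rho: float = float(np.sqrt(0.9))
    sigma_s: float = 1.0
    sigma_t: float = 1.0
    coding: str = "pm1"
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config_seed, seed):
    if seed is None:
        seed = config_seed
    return np.random.default_rng(seed)


def gen_prentice_trial(config: PrenticeSimConfig = PrenticeSimConfig(),
                       seed=None) -> TrialData:
    """Simulate one full-mediation trial from the scaled-logit curve.

    Treatment is assigned 1:1; ``S | Z=z ~ Normal(mu_z, var_s)``;
    ``T ~ Bernoulli(pi * expit(mu + gamma*S))`` — the treatment affects
    the endpoint only through the surrogate.
    """
    from scipy.special import expit

    rng = _rng(config.seed, seed)
    half = config.n // 2
    z = np.r_[np.zeros(half), np.ones(half)]
    mu_arm = np.where(z == 1, config.mu1, config.mu0)
    s = rng.normal(mu_arm, np.sqrt(config.var_s))
    p = config.pi * expit(config.mu + config.gamma * s)
    t = rng.binomial(1, p)
    return TrialData(z, s, t)


def _bivariate_slopes(rng, cfg, n):
    sd_a, sd_b = np.sqrt(cfg.var_a), np.sqrt(cfg.var_b)
    cov = np.array([[cfg.var_a, cfg.rho * sd_a * sd_b],
                    [cfg.rho * sd_a * sd_b, cfg.var_b]])
    ab = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return ab[:, 0], ab[:, 1]


def gen_meta_trial(config: MetaSimConfig = MetaSimConfig(),
                   seed=None) -> MultiSubgroupData:
    """Simulate a multi-subgroup trial with a binary endpoint.

    Per subgroup, correlated random treatment slopes ``(a_i, b_i)`` are
    drawn; then ``S = mu_s + (alpha + a_i) Z + eps`` and
    ``T ~ Bernoulli(expit(mu_t + (beta + b_i) Z))`` under the generator's
    treatment coding.
    """
    from scipy.special import expit

    rng = _rng(config.seed, seed)
    a, b = _bivariate_slopes(rng, config, config.n_subgroups)
    half = config.n_per_subgroup // 2
    frames = []
    for i in range(config.n_subgroups):
        z01 = np.r_[np.zeros(half), np.ones(half)]
        zg = z01 if config.coding == "01" else 2.0 * z01 - 1.0
        s = config.mu_s + (config.alpha + a[i]) * zg + \
            rng.normal(0.0, config.sigma_s, config.n_per_subgroup)
        t = rng.binomial(1, expit(config.mu_t + (config.beta + b[i]) * zg))
        frames.append(pd.DataFrame({"subgroup": i + 1, "z": z01.astype(int),
                                    "s": s, "t": t}))
    return MultiSubgroupData(pd.concat(frames, ignore_index=True))


def gen_continuous_surrogacy_trial(
        config: ContinuousSurrogacyConfig = ContinuousSurrogacyConfig(),
        seed=None) -> MultiSubgroupData:
    """Simulate a multi-subgroup trial with *continuous* S and T."""
    rng = _rng(config.seed, seed)
    a, b = _bivariate_slopes(rng, config, config.n_subgroups)
    half = config.n_per_subgroup // 2
    frames = []
    for i in range(config.n_subgroups):
        z01 = np.r_[np.zeros(half), np.ones(half)]
        zg = z01 if config.coding == "01" else 2.0 * z01 - 1.0
        s = config.mu_s + (config.alpha + a[i]) * zg + \
            rng.normal(0.0, config.sigma_s, config.n_per_subgroup)
        t = config.mu_t + (config.beta + b[i]) * zg + \
            rng.normal(0.0, config.sigma_t, config.n_per_subgroup)
        frames.append(pd.DataFrame({"subgroup": i + 1, "z": z01.astype(int),
                                    "s": s, "t": t}))
    return MultiSubgroupData(pd.concat(frames, ignore_index=True))


def dichotomize_outcome(t, threshold: float = -2.87) -> np.ndarray:
    """Binary event indicator: 1 where ``t`` is strictly below ``threshold``."""
    return (np.asarray(t, dtype=float) < threshold).astype(int)


def empirical_ve(z, t) -> float:
    """Empirical vaccine efficacy ``1 - attack_rate(Z=1)/attack_rate(Z=0)``.

    Raises ``ValueError`` when the control arm has no events (the ratio is
    undefined) or either arm is empty.
    """
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    n1, n0 = np.sum(z == 1), np.sum(z == 0)
    if n0 == 0 or n1 == 0:
        raise ValueError("both arms must be non-empty")
    r0 = np.sum(t[z == 0]) / n0
    r1 = np.sum(t[z == 1]) / n1
    if r0 == 0:
        raise ValueError("zero control events: empirical VE is undefined")
    return float(1.0 - r1 / r0)
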