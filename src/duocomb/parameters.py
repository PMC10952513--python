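"""Parameter containers and prior specifications for the two outcome models.

Toxicity is modelled marginally as

    pi_T(x, y) = F(alpha0 + alpha1*x + alpha2*y + alpha3*x*y)

on standardized doses (x, y) in [0,1]^2, reparameterized through the DLT
probabilities at three corners of the unit square: rho00 at (0,0), rho10 at
(1,0) and rho01 at (0,1).  Efficacy is modelled per stage S as

    pi_E^S(x, y) = F(beta0_S + exp(beta1_S)*x + exp(beta2_S)*y + beta3_S*x*y)

with the exponential guaranteeing monotonicity in each agent.  The pair
Psi_S = (beta1_S, beta2_S) is the only block shared across stages through
the exchangeable/nonexchangeable (EXNEX) hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .links import logistic_cdf, logistic_quantile


class InvalidParameterError(ValueError):
    """Raised when model parameters violate their structural constraints."""


@dataclass(frozen=True)
class ToxParams:
    """Dose-toxicity surface parameters in the clinician-facing scale.

    Parameters
    ----------
    rho00, rho01, rho10 : float
        DLT probabilities at the standardized corners (0,0), (0,1), (1,0).
        Monotonicity of toxicity in each agent requires
        ``0 < rho00 <= min(rho01, rho10) < 1``.
    alpha3 : float
        Nonnegative drug-drug interaction on the logit scale.
    """

    rho00: float
    rho01: float
    rho10: float
    alpha3: float

    def __post_init__(self):
        if not (0.0 < self.rho00 < 1.0 and 0.0 < self.rho01 < 1.0 and 0.0 < self.rho10 < 1.0):
            raise InvalidParameterError("corner DLT probabilities must lie in (0, 1)")
        if self.rho00 > min(self.rho01, self.rho10):
            raise InvalidParameterError(
                "rho00 must not exceed min(rho01, rho10); toxicity is monotone in each agent"
            )
        if self.alpha3 < 0:
            raise InvalidParameterError("alpha3 (interaction) must be nonnegative")

    @property
    def alpha0(self) -> float:
        return float(logistic_quantile(self.rho00))

    @property
    def alpha1(self) -> float:
        return float(logistic_quantile(self.rho10) - logistic_quantile(self.rho00))

    @property
    def alpha2(self) -> float:
        return float(logistic_quantile(self.rho01) - logistic_quantile(self.rho00))

    def prob_dlt(self, x, y):
        """Marginal DLT probability pi_T at standardized dose(s) (x, y)."""
        u = self.alpha0 + self.alpha1 * np.asarray(x) + self.alpha2 * np.asarray(y) \
            + self.alpha3 * np.asarray(x) * np.asarray(y)
        return logistic_cdf(u)

    def to_dict(self) -> dict:
        return {"rho00": self.rho00, "rho01": self.rho01,
                "rho10": self.rho10, "alpha3": self.alpha3}

    @classmethod
    def from_dict(cls, d: dict) -> "ToxParams":
        return cls(rho00=float(d["rho00"]), rho01=float(d["rho01"]),
                   rho10=float(d["rho10"]), alpha3=float(d["alpha3"]))


@dataclass(frozen=True)
class ToxPriorSpec:
    """Informative priors for the toxicity model.

    Defaults reproduce the single-MTD anchoring used for the motivating
    cisplatin/cabazitaxel combination: independent Beta priors for the
    single-agent corner probabilities, a Beta prior for the ratio
    ``rho00 / min(rho01, rho10)`` (conditional on the corners), and a Gamma
    prior for the interaction.
    """

    rho01_beta: tuple = (1.4, 5.6)
    rho10_beta: tuple = (1.4, 5.6)
    ratio_beta: tuple = (0.8, 7.2)
    alpha3_shape: float = 0.8
    alpha3_rate: float = 0.0384

    def __post_init__(self):
        for pair in (self.rho01_beta, self.rho10_beta, self.ratio_beta):
            if pair[0] <= 0 or pair[1] <= 0:
                raise InvalidParameterError("Beta shape parameters must be positive")
        if self.alpha3_shape <= 0 or self.alpha3_rate <= 0:
            raise InvalidParameterError("Gamma shape and rate must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> dict:
        """Draw ``n`` joint prior samples; returns arrays keyed by parameter."""
        rho01 = rng.beta(*self.rho01_beta, n)
        rho10 = rng.beta(*self.rho10_beta, n)
        ratio = rng.beta(*self.ratio_beta, n)
        rho00 = ratio * np.minimum(rho01, rho10)
        alpha3 = rng.gamma(self.alpha3_shape, 1.0 / self.alpha3_rate, n)
        return {"rho00": rho00, "rho01": rho01, "rho10": rho10, "alpha3": alpha3}


@dataclass(frozen=True)
class EffStageParams:
    """Stage-specific dose-efficacy parameters.

    ``beta1`` and ``beta2`` are on the log scale (the main effects entering
    the linear predictor are ``exp(beta1)`` and ``exp(beta2)``); together
    they form the stage's Psi block.  ``beta3 >= 0`` is the synergy term.
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self):
        if self.beta3 < 0:
            raise InvalidParameterError("beta3 (efficacy interaction) must be nonnegative")

    @property
    def psi(self) -> tuple:
        return (self.beta1, self.beta2)

    def prob_eff(self, x, y):
        """Probability of response pi_E at standardized dose(s) (x, y)."""
        u = self.beta0 + np.exp(self.beta1) * np.asarray(x) \
            + np.exp(self.beta2) * np.asarray(y) \
            + self.beta3 * np.asarray(x) * np.asarray(y)
        return logistic_cdf(u)

    def to_dict(self) -> dict:
        return {"beta0": self.beta0, "beta1": self.beta1,
                "beta2": self.beta2, "beta3": self.beta3}

    @classmethod
    def from_dict(cls, d: dict) -> "EffStageParams":
        return cls(beta0=float(d["beta0"]), beta1=float(d["beta1"]),
                   beta2=float(d["beta2"]), beta3=float(d["beta3"]))


@dataclass(frozen=True)
class EffPriorSpec:
    """Priors and hyperpriors for the robust hierarchical efficacy model.

    The stage-wise main-effect pairs Psi_S follow a bivariate-normal
    hierarchy: Psi_1 ~ BVN(mu, Phi) always, while Psi_2 is exchangeable with
    stage 1 (same BVN(mu, Phi)) with prior probability ``omega`` and
    otherwise draws from the weakly informative BVN(m0, R0) with
    ``m0 = (0, 0)`` and ``R0 = [[100, 100*zeta], [100*zeta, 100]]``.

    Parameters
    ----------
    beta0_normal : (mean, sd)
        Prior for both stage intercepts.
    beta3_gamma : (shape, rate)
        Prior for both stage interactions.
    mu_normal : (mean, sd)
        Prior for each component of the exchangeable mean mu.
    tau_halfnormal_scale : float
        Scale of the half-normal priors on the heterogeneity SDs tau1, tau2.
    xi_uniform, zeta_uniform : (lo, hi)
        Uniform priors for the correlations in Phi and R0.
    omega : float
        Prior probability that Psi_2 is exchangeable with Psi_1.
    nonexch_sd : float
        Marginal SD (default 10) of the nonexchangeable prior on Psi_2.
    """

    beta0_normal: tuple = (-1.8, 3.16)
    beta3_gamma: tuple = (0.1, 0.1)
    mu_normal: tuple = (0.0, 3.16)
    tau_halfnormal_scale: float = 0.5
    xi_uniform: tuple = (0.0, 0.5)
    zeta_uniform: tuple = (0.0, 0.5)
    omega: float = 0.0
    nonexch_sd: float = 10.0

    def __post_init__(self):
        if not (0.0 <= self.omega <= 1.0):
            raise InvalidParameterError("omega must lie in [0, 1]")
        if self.beta0_normal[1] <= 0 or self.mu_normal[1] <= 0:
            raise InvalidParameterError("normal prior SDs must be positive")
        if self.tau_halfnormal_scale <= 0 or self.nonexch_sd <= 0:
            raise InvalidParameterError("scale parameters must be positive")
        if min(self.beta3_gamma) <= 0:
            raise InvalidParameterError("Gamma shape and rate must be positive")

    def with_omega(self, omega: float) -> "EffPriorSpec":
        from dataclasses import replace
        return replace(self, omega=omega)
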