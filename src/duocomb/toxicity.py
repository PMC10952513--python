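"""Bayesian dose-toxicity model and the stage-I safety machinery.

The marginal DLT model is a logistic regression on the standardized dose
plane with a nonnegative interaction, reparameterized through corner DLT
probabilities (see :mod:`duocomb.parameters`).  Inference follows the usual
statsmodels idiom: build a :class:`ToxicityModel` from patient records, call
:meth:`~ToxicityModel.fit`, and interrogate the returned
:class:`ToxicityResults` for posterior summaries, EWOC conditional-MTD
percentiles, the estimated MTD curve and the stage-I stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, gammaln, logit

from . import records as rec
from .doses import DoseCombination, MTDCurve, mtd_x_solution, mtd_y_solution
from .links import bernoulli_loglik
from .parameters import InvalidParameterError, ToxParams, ToxPriorSpec
from .sampling import SamplerDiagnostics, run_ensemble

PARAM_NAMES = ["rho00", "rho01", "rho10", "alpha3"]


def prob_dlt(dose: DoseCombination, params: ToxParams) -> float:
    """Marginal probability of DLT at a standardized dose combination."""
    return float(params.prob_dlt(dose.x, dose.y))


def tox_log_posterior(params: ToxParams, data: pd.DataFrame, prior: ToxPriorSpec) -> float:
    """Unnormalized log posterior density on the constrained scale.

    The density is taken with respect to (ratio, rho01, rho10, alpha3) where
    ``ratio = rho00 / min(rho01, rho10)`` — the parameterization in which the
    prior factorizes.  Structurally invalid parameters return ``-inf``.
    """
    try:
        params = ToxParams(params.rho00, params.rho01, params.rho10, params.alpha3)
    except InvalidParameterError:
        return -np.inf
    ratio = params.rho00 / min(params.rho01, params.rho10)
    if not (0.0 < ratio < 1.0):
        return -np.inf
    a, b = prior.ratio_beta
    lp = (a - 1) * np.log(ratio) + (b - 1) * np.log1p(-ratio) - betaln(a, b)
    for p, (sa, sb) in ((params.rho01, prior.rho01_beta), (params.rho10, prior.rho10_beta)):
        lp += (sa - 1) * np.log(p) + (sb - 1) * np.log1p(-p) - betaln(sa, sb)
    sh, rt = prior.alpha3_shape, prior.alpha3_rate
    if params.alpha3 <= 0:
        return -np.inf
    lp += sh * np.log(rt) - gammaln(sh) + (sh - 1) * np.log(params.alpha3) - rt * params.alpha3
    if len(data):
        z = data["dlt"].to_numpy(dtype=float)
        pi = params.prob_dlt(data["x_std"].to_numpy(), data["y_std"].to_numpy())
        u = np.log(pi) - np.log1p(-pi)
        lp += float(np.sum(bernoulli_loglik(z, u)))
    return float(lp)


def _unconstrained_to_params(theta: np.ndarray) -> dict:
    """Map (logit ratio, logit rho01, logit rho10, log alpha3) to arrays."""
    th = np.atleast_2d(theta)
    ratio = expit(th[:, 0])
    rho01 = expit(th[:, 1])
    rho10 = expit(th[:, 2])
    alpha3 = np.exp(th[:, 3])
    rho00 = ratio * np.minimum(rho01, rho10)
    return {"ratio": ratio, "rho00": rho00, "rho01": rho01, "rho10": rho10, "alpha3": alpha3}


class ToxicityModel:
    """Dose-toxicity model bound to stage-I patient records.

    Parameters
    ----------
    data : DataFrame
        Patient records with at least columns ``x_std``, ``y_std``, ``dlt``.
        May be empty, in which case the posterior is the prior.
    prior : ToxPriorSpec, optional
        Defaults to the informative single-MTD-anchored priors.
    """

    def __init__(self, data: pd.DataFrame = None, prior: ToxPriorSpec = None):
        self.data = rec.validate_frame(data) if data is not None and len(data) else rec.empty_frame()
        self.prior = prior if prior is not None else ToxPriorSpec()
        self._x = self.data["x_std"].to_numpy(dtype=float) if len(self.data) else np.empty(0)
        self._y = self.data["y_std"].to_numpy(dtype=float) if len(self.data) else np.empty(0)
        self._z = self.data["dlt"].to_numpy(dtype=float) if len(self.data) else np.empty(0)

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        """Vectorized unnormalized log posterior on the unconstrained scale.

        ``theta`` has columns (logit ratio, logit rho01, logit rho10,
        log alpha3); log-Jacobians of the transforms are included.
        """
        th = np.atleast_2d(theta)
        v_r, v_01, v_10, la3 = th[:, 0], th[:, 1], th[:, 2], th[:, 3]
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            ratio, rho01, rho10 = expit(v_r), expit(v_01), expit(v_10)
            alpha3 = np.exp(np.clip(la3, -600.0, 600.0))
            pr = self.prior
            # Beta log densities with the logit Jacobian folded in: shapes (a, b)
            # contribute a*log p + b*log(1-p) up to constants.
            lp = (pr.ratio_beta[0] * np.log(ratio) + pr.ratio_beta[1] * np.log1p(-ratio)
                  + pr.rho01_beta[0] * np.log(rho01) + pr.rho01_beta[1] * np.log1p(-rho01)
                  + pr.rho10_beta[0] * np.log(rho10) + pr.rho10_beta[1] * np.log1p(-rho10)
                  + pr.alpha3_shape * la3 - pr.alpha3_rate * alpha3)
            if self._z.size:
                rho00 = ratio * np.minimum(rho01, rho10)
                a0 = logit(rho00)
                a1 = logit(rho10) - a0
                a2 = logit(rho01) - a0
                u = (a0[:, None] + a1[:, None] * self._x + a2[:, None] * self._y
                     + alpha3[:, None] * (self._x * self._y))
                lp = lp + bernoulli_loglik(self._z, u).sum(axis=1)
        lp = np.where(np.isfinite(lp), lp, -np.inf)
        return lp if np.ndim(theta) == 2 else float(lp[0])

    def fit(self, n_walkers: int = 24, n_steps: int = 1500, discard: int = 750,
            seed: int = 0, compute_diagnostics: bool = True,
            ess_floor: float = 400.0) -> "ToxicityResults":
        """Sample the posterior and return a results object."""
        rng = np.random.default_rng(seed)
        init = self.prior.sample(n_walkers, rng)
        ratio0 = init["rho00"] / np.minimum(init["rho01"], init["rho10"])
        p0 = np.column_stack([
            logit(np.clip(ratio0, 1e-6, 1 - 1e-6)),
            logit(np.clip(init["rho01"], 1e-6, 1 - 1e-6)),
            logit(np.clip(init["rho10"], 1e-6, 1 - 1e-6)),
            np.log(np.clip(init["alpha3"], 1e-8, None)),
        ])
        sampler_seed = int(rng.integers(2 ** 31))
        draws_u, diag = run_ensemble(self.log_posterior, p0, n_steps, discard,
                                     seed=sampler_seed,
                                     compute_diagnostics=compute_diagnostics,
                                     ess_floor=ess_floor)
        cons = _unconstrained_to_params(draws_u)
        draws = pd.DataFrame({k: cons[k] for k in PARAM_NAMES})
        return ToxicityResults(model=self, draws=draws, diagnostics=diag)


def empirical_percentile(values: np.ndarray, alpha: float) -> float:
    """Sort-based (inverted-CDF) empirical percentile of a 1-D sample."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    v = np.sort(np.asarray(values, dtype=float))
    idx = max(int(np.ceil(alpha * v.size)) - 1, 0)
    return float(v[idx])


@dataclass
class ToxicityResults:
    """Posterior draws of the toxicity parameters with EWOC utilities."""

    model: ToxicityModel
    draws: pd.DataFrame
    diagnostics: SamplerDiagnostics

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def posterior_median(self) -> ToxParams:
        """Coordinatewise posterior medians of (rho00, rho10, rho01, alpha3)."""
        med = self.draws.median()
        rho00 = float(med["rho00"])
        rho01 = float(med["rho01"])
        rho10 = float(med["rho10"])
        # medians of the corners can in principle cross the monotonicity
        # constraint satisfied drawwise; nudge rho00 down if so
        rho00 = min(rho00, min(rho01, rho10))
        return ToxParams(rho00=rho00, rho01=rho01, rho10=rho10, alpha3=float(med["alpha3"]))

    def mtd_curve(self, theta_T: float) -> MTDCurve:
        """MTD curve built from the coordinatewise posterior medians."""
        return MTDCurve(tox_params=self.posterior_median(), theta_T=theta_T)

    def prob_dlt_draws(self, dose: DoseCombination) -> np.ndarray:
        d = self.draws
        a0 = logit(d["rho00"].to_numpy())
        a1 = logit(d["rho10"].to_numpy()) - a0
        a2 = logit(d["rho01"].to_numpy()) - a0
        u = a0 + a1 * dose.x + a2 * dose.y + d["alpha3"].to_numpy() * dose.x * dose.y
        return expit(u)

    def conditional_mtd_draws(self, fixed_dose: float, fixed_agent: str,
                              theta_T: float) -> np.ndarray:
        """Per-draw conditional MTD of the free agent (raw, untruncated)."""
        d = self.draws
        out = np.empty(len(d))
        A = logit(theta_T) - logit(d["rho00"].to_numpy())
        B = logit(d["rho10"].to_numpy()) - logit(d["rho00"].to_numpy())
        C = logit(d["rho01"].to_numpy()) - logit(d["rho00"].to_numpy())
        a3 = d["alpha3"].to_numpy()
        if fixed_agent.upper() == "Y":
            # solve for x given y
            out = (A - C * fixed_dose) / (B + a3 * fixed_dose)
        elif fixed_agent.upper() == "X":
            out = (A - B * fixed_dose) / (C + a3 * fixed_dose)
        else:
            raise ValueError("fixed_agent must be 'X' or 'Y'")
        return out

    def conditional_mtd_percentile(self, fixed_dose: float, fixed_agent: str,
                                   alpha: float, theta_T: float,
                                   truncate: bool = True) -> float:
        """EWOC dose: alpha-th percentile of the conditional MTD posterior.

        The next patient's dose of the free agent is the ``alpha``-th
        empirical percentile of the per-draw conditional MTD, truncated to
        the standardized range [0, 1] so the overdosing probability stays
        bounded by ``alpha``.
        """
        vals = self.conditional_mtd_draws(fixed_dose, fixed_agent, theta_T)
        q = empirical_percentile(vals, alpha)
        return float(np.clip(q, 0.0, 1.0)) if truncate else q

    def safety_stop(self, theta_T: float, delta_theta1: float = 0.5,
                    excess_tox_margin: float = 0.1) -> bool:
        """Stage-I stopping rule: the lowest combination is already too toxic.

        True iff the posterior probability that ``rho00`` (the DLT rate at
        the minimum dose combination) exceeds ``theta_T + margin`` is above
        ``delta_theta1``.
        """
        frac = float(np.mean(self.draws["rho00"].to_numpy() > theta_T + excess_tox_margin))
        return frac > delta_theta1

    def summary(self) -> pd.DataFrame:
        qs = self.draws.quantile([0.025, 0.5, 0.975]).T
        qs.columns = ["2.5%", "median", "97.5%"]
        qs.insert(0, "mean", self.draws.mean())
        qs.insert(1, "sd", self.draws.std())
        return qs
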