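"""Robust hierarchical dose-efficacy model with cross-stage borrowing.

Efficacy in each stage follows a monotone logistic surface (see
:mod:`duocomb.parameters`).  The two stages are linked only through their
main-effect pairs ``Psi_S = (beta1_S, beta2_S)``, combined with a
meta-analytic-combined (MAC) approach: ``Psi_1 ~ BVN(mu, Phi)`` always,
while ``Psi_2`` is either exchangeable with stage 1 — drawn from the same
``BVN(mu, Phi)`` with prior probability ``omega`` — or nonexchangeable,
drawn from a weakly informative ``BVN(m0, R0)``.  The binary
exchangeability indicator is marginalized out of the joint density
(log-sum-exp of the two branch densities), and the posterior
exchangeability weight is recovered from per-draw branch responsibilities.

This mixture is what makes borrowing robust: when the stage-wise efficacy
profiles agree, the exchangeable branch dominates and stage-1 responses
sharpen the stage-2 estimates; when they conflict, the nonexchangeable
branch absorbs Psi_2 and stage-1 data are discounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import records as rec
from .doses import DoseCombination, MTDCurve
from .links import bernoulli_loglik
from .parameters import EffPriorSpec, EffStageParams
from .sampling import SamplerDiagnostics, run_ensemble

PARAM_NAMES = ["beta0_1", "beta1_1", "beta2_1", "beta3_1",
               "beta0_2", "beta1_2", "beta2_2", "beta3_2",
               "mu1", "mu2", "tau1", "tau2", "xi", "zeta"]

_TAU_FLOOR = 1e-6


def prob_eff(dose: DoseCombination, params: EffStageParams) -> float:
    """Probability of response at a standardized dose combination."""
    return float(params.prob_eff(dose.x, dose.y))


def _bvn_logpdf(d1, d2, s1, s2, corr):
    """Bivariate normal log density of deviations (d1, d2); vectorized."""
    om = 1.0 - corr ** 2
    q = (d1 / s1) ** 2 - 2.0 * corr * (d1 / s1) * (d2 / s2) + (d2 / s2) ** 2
    return -np.log(2 * np.pi) - np.log(s1) - np.log(s2) - 0.5 * np.log(om) - 0.5 * q / om


def eff_log_joint(all_params: dict, data_s1: pd.DataFrame, data_s2: pd.DataFrame,
                  prior: EffPriorSpec, exch_indicator: int) -> float:
    """Log joint density on the constrained scale with a fixed indicator.

    ``all_params`` maps the names in :data:`PARAM_NAMES` to scalars.  Used
    mainly as a reference density for low-dimensional quadrature checks;
    the sampler works on an unconstrained reparameterization.
    """
    if exch_indicator not in (0, 1):
        raise ValueError("exch_indicator must be 0 or 1")
    p = all_params
    if p["beta3_1"] < 0 or p["beta3_2"] < 0 or p["tau1"] <= 0 or p["tau2"] <= 0:
        return -np.inf
    lo_x, hi_x = prior.xi_uniform
    lo_z, hi_z = prior.zeta_uniform
    if not (lo_x <= p["xi"] <= hi_x and lo_z <= p["zeta"] <= hi_z):
        return -np.inf
    m0, s0 = prior.beta0_normal
    sh, rt = prior.beta3_gamma
    mm, sm = prior.mu_normal
    z = prior.tau_halfnormal_scale
    lp = 0.0
    for b0 in (p["beta0_1"], p["beta0_2"]):
        lp += -0.5 * ((b0 - m0) / s0) ** 2 - np.log(s0) - 0.5 * np.log(2 * np.pi)
    for b3 in (p["beta3_1"], p["beta3_2"]):
        lp += (sh - 1) * np.log(b3) - rt * b3 if b3 > 0 else -np.inf
    for mu in (p["mu1"], p["mu2"]):
        lp += -0.5 * ((mu - mm) / sm) ** 2
    for tau in (p["tau1"], p["tau2"]):
        lp += -0.5 * (tau / z) ** 2
    # Psi_1 always exchangeable
    lp += _bvn_logpdf(p["beta1_1"] - p["mu1"], p["beta2_1"] - p["mu2"],
                      max(p["tau1"], _TAU_FLOOR), max(p["tau2"], _TAU_FLOOR), p["xi"])
    if exch_indicator == 1:
        lp += _bvn_logpdf(p["beta1_2"] - p["mu1"], p["beta2_2"] - p["mu2"],
                          max(p["tau1"], _TAU_FLOOR), max(p["tau2"], _TAU_FLOOR), p["xi"])
    else:
        s = prior.nonexch_sd
        lp += _bvn_logpdf(p["beta1_2"], p["beta2_2"], s, s, p["zeta"])
    for df, (b0k, b1k, b2k, b3k) in ((data_s1, ("beta0_1", "beta1_1", "beta2_1", "beta3_1")),
                                     (data_s2, ("beta0_2", "beta1_2", "beta2_2", "beta3_2"))):
        obs = rec.with_efficacy_observed(df) if len(df) else df
        if len(obs):
            x = obs["x_std"].to_numpy(dtype=float)
            y = obs["y_std"].to_numpy(dtype=float)
            e = obs["eff"].to_numpy(dtype=float)
            u = p[b0k] + np.exp(p[b1k]) * x + np.exp(p[b2k]) * y + p[b3k] * x * y
            lp += float(np.sum(bernoulli_loglik(e, u)))
    return float(lp)


class EfficacyMAC:
    """MAC/EXNEX efficacy model bound to both stages' patient records.

    Parameters
    ----------
    data_s1, data_s2 : DataFrame
        Patient records for stage 1 and stage 2.  Rows with unobserved
        efficacy (NaN ``eff``) are excluded from the likelihood.
    prior : EffPriorSpec
        Priors, hyperpriors and the prior exchangeability weight ``omega``.
    """

    def __init__(self, data_s1: pd.DataFrame = None, data_s2: pd.DataFrame = None,
                 prior: EffPriorSpec = None):
        self.prior = prior if prior is not None else EffPriorSpec()
        self._xy = {}
        for key, df in (("s1", data_s1), ("s2", data_s2)):
            if df is None or not len(df):
                self._xy[key] = (np.empty(0), np.empty(0), np.empty(0))
                continue
            obs = rec.with_efficacy_observed(rec.validate_frame(df))
            self._xy[key] = (obs["x_std"].to_numpy(dtype=float),
                             obs["y_std"].to_numpy(dtype=float),
                             obs["eff"].to_numpy(dtype=float))
        self.n_obs = {k: len(v[2]) for k, v in self._xy.items()}

    # -- unconstrained parameterization ------------------------------------
    # theta columns: b0_1, psi1 (2), log b3_1, b0_2, psi2 (2), log b3_2,
    #                mu1, mu2, log tau1, log tau2, v_xi, v_zeta

    def _branch_logdens(self, psi1_a, psi1_b, psi2_a, psi2_b, mu1, mu2, tau1, tau2, xi, zeta):
        """Per-walker log densities of Psi blocks under both Psi_2 branches."""
        lp_psi1 = _bvn_logpdf(psi1_a - mu1, psi1_b - mu2, tau1, tau2, xi)
        l_ex = _bvn_logpdf(psi2_a - mu1, psi2_b - mu2, tau1, tau2, xi)
        s = self.prior.nonexch_sd
        l_nex = _bvn_logpdf(psi2_a, psi2_b, s, s, zeta)
        return lp_psi1, l_ex, l_nex

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(theta)
        pr = self.prior
        b0_1, psi1_a, psi1_b, lb3_1 = th[:, 0], th[:, 1], th[:, 2], th[:, 3]
        b0_2, psi2_a, psi2_b, lb3_2 = th[:, 4], th[:, 5], th[:, 6], th[:, 7]
        mu1, mu2 = th[:, 8], th[:, 9]
        lt1, lt2 = th[:, 10], th[:, 11]
        v_xi, v_zeta = th[:, 12], th[:, 13]
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            # exponentials clipped: beyond these bounds the density is
            # indistinguishable from zero and proposals are rejected anyway
            b3_1 = np.exp(np.clip(lb3_1, -600.0, 600.0))
            b3_2 = np.exp(np.clip(lb3_2, -600.0, 600.0))
            tau1 = np.exp(np.clip(lt1, -600.0, 600.0)) + _TAU_FLOOR
            tau2 = np.exp(np.clip(lt2, -600.0, 600.0)) + _TAU_FLOOR
            lo_x, hi_x = pr.xi_uniform
            lo_z, hi_z = pr.zeta_uniform
            e_xi, e_zeta = expit(v_xi), expit(v_zeta)
            xi = lo_x + (hi_x - lo_x) * e_xi
            zeta = lo_z + (hi_z - lo_z) * e_zeta

            m0, s0 = pr.beta0_normal
            sh, rt = pr.beta3_gamma
            mm, sm = pr.mu_normal
            z = pr.tau_halfnormal_scale
            lp = (-0.5 * (((b0_1 - m0) / s0) ** 2 + ((b0_2 - m0) / s0) ** 2)
                  + sh * lb3_1 - rt * b3_1 + sh * lb3_2 - rt * b3_2  # Gamma + log-Jacobian
                  - 0.5 * (((mu1 - mm) / sm) ** 2 + ((mu2 - mm) / sm) ** 2)
                  - 0.5 * ((tau1 / z) ** 2 + (tau2 / z) ** 2) + lt1 + lt2  # half-normal + log-Jac
                  + np.log(e_xi * (1 - e_xi)) + np.log(e_zeta * (1 - e_zeta)))  # uniform Jacobians

            lp_psi1, l_ex, l_nex = self._branch_logdens(psi1_a, psi1_b, psi2_a, psi2_b,
                                                        mu1, mu2, tau1, tau2, xi, zeta)
            lp = lp + lp_psi1
            if pr.omega >= 1.0:
                lp = lp + l_ex
            elif pr.omega <= 0.0:
                lp = lp + l_nex
            else:
                lp = lp + np.logaddexp(np.log(pr.omega) + l_ex, np.log1p(-pr.omega) + l_nex)

            for key, (b0, pa, pb, b3) in (("s1", (b0_1, psi1_a, psi1_b, b3_1)),
                                          ("s2", (b0_2, psi2_a, psi2_b, b3_2))):
                x, y, e = self._xy[key]
                if x.size:
                    u = (b0[:, None] + np.exp(np.clip(pa, -600.0, 600.0))[:, None] * x
                         + np.exp(np.clip(pb, -600.0, 600.0))[:, None] * y
                         + b3[:, None] * (x * y))
                    lp = lp + bernoulli_loglik(e, u).sum(axis=1)
        lp = np.where(np.isfinite(lp), lp, -np.inf)
        return lp if np.ndim(theta) == 2 else float(lp[0])

    def _prior_walkers(self, n_walkers: int, rng: np.random.Generator) -> np.ndarray:
        """Walkers dispersed roughly like the prior (tails truncated)."""
        pr = self.prior
        sh, rt = pr.beta3_gamma

        def log_b3():
            return np.log(np.clip(rng.gamma(sh, 1.0 / rt, n_walkers), 1e-10, 1e4))

        cols = [
            rng.normal(*pr.beta0_normal, n_walkers),   # b0_1
            rng.normal(0.0, 2.0, n_walkers),           # psi1
            rng.normal(0.0, 2.0, n_walkers),
            log_b3(),
            rng.normal(*pr.beta0_normal, n_walkers),   # b0_2
            rng.normal(0.0, 2.0, n_walkers),           # psi2
            rng.normal(0.0, 2.0, n_walkers),
            log_b3(),
            rng.normal(*pr.mu_normal, n_walkers),      # mu
            rng.normal(*pr.mu_normal, n_walkers),
            np.log(np.abs(rng.normal(0, pr.tau_halfnormal_scale, n_walkers)) + 1e-3),
            np.log(np.abs(rng.normal(0, pr.tau_halfnormal_scale, n_walkers)) + 1e-3),
            rng.normal(0.0, 1.0, n_walkers),           # v_xi
            rng.normal(0.0, 1.0, n_walkers),           # v_zeta
        ]
        return np.column_stack(cols)

    def _map_estimate(self) -> np.ndarray:
        """Posterior mode on the unconstrained scale (L-BFGS, for walker init).

        The gradient is a central finite difference evaluated in a single
        vectorized log-density call, so the optimization costs a few dozen
        batched evaluations.
        """
        from scipy.optimize import minimize

        dim = 14
        eye = np.eye(dim)
        eps = 1e-5

        def neg(th):
            v = float(np.asarray(self.log_posterior(th[None, :]))[0])
            return -v if np.isfinite(v) else 1e12

        def neg_grad(th):
            pts = np.vstack([th + eps * eye, th - eps * eye])
            vals = np.asarray(self.log_posterior(pts))
            g = -(vals[:dim] - vals[dim:]) / (2 * eps)
            return np.where(np.isfinite(g), g, 0.0)

        x0 = np.array([self.prior.beta0_normal[0], 0.0, 0.0, np.log(0.5)] * 2
                      + [0.0, 0.0, np.log(0.3), np.log(0.3), 0.0, 0.0])
        opt = minimize(neg, x0, jac=neg_grad, method="L-BFGS-B",
                       bounds=[(-40, 40)] * dim, options={"maxiter": 150})
        return opt.x if np.all(np.isfinite(opt.x)) else x0

    def _initial_walkers(self, n_walkers: int, rng: np.random.Generator) -> np.ndarray:
        """Two-thirds of walkers jittered around the posterior mode, the rest
        dispersed like the prior (keeps both EXNEX branches represented)."""
        n_map = max(n_walkers * 2 // 3, 1)
        p_map = self._map_estimate() + rng.normal(0.0, 0.3, (n_map, 14))
        p_prior = self._prior_walkers(n_walkers - n_map, rng)
        return np.vstack([p_map, p_prior]) if n_walkers > n_map else p_map

    def fit(self, n_walkers: int = 32, n_steps: int = 2000, discard: int = 1000,
            seed: int = 0, compute_diagnostics: bool = True,
            ess_floor: float = 400.0) -> "EfficacyResults":
        rng = np.random.default_rng(seed)
        p0 = self._initial_walkers(n_walkers, rng)
        sampler_seed = int(rng.integers(2 ** 31))
        draws_u, diag = run_ensemble(self.log_posterior, p0, n_steps, discard,
                                     seed=sampler_seed,
                                     compute_diagnostics=compute_diagnostics,
                                     ess_floor=ess_floor, moves="de")
        pr = self.prior
        lo_x, hi_x = pr.xi_uniform
        lo_z, hi_z = pr.zeta_uniform
        draws = pd.DataFrame({
            "beta0_1": draws_u[:, 0], "beta1_1": draws_u[:, 1], "beta2_1": draws_u[:, 2],
            "beta3_1": np.exp(draws_u[:, 3]),
            "beta0_2": draws_u[:, 4], "beta1_2": draws_u[:, 5], "beta2_2": draws_u[:, 6],
            "beta3_2": np.exp(draws_u[:, 7]),
            "mu1": draws_u[:, 8], "mu2": draws_u[:, 9],
            "tau1": np.exp(draws_u[:, 10]) + _TAU_FLOOR,
            "tau2": np.exp(draws_u[:, 11]) + _TAU_FLOOR,
            "xi": lo_x + (hi_x - lo_x) * expit(draws_u[:, 12]),
            "zeta": lo_z + (hi_z - lo_z) * expit(draws_u[:, 13]),
        })
        # per-draw responsibility of the exchangeable branch
        if pr.omega >= 1.0:
            w = np.ones(len(draws))
        elif pr.omega <= 0.0:
            w = np.zeros(len(draws))
        else:
            _, l_ex, l_nex = self._branch_logdens(
                draws["beta1_1"].to_numpy(), draws["beta2_1"].to_numpy(),
                draws["beta1_2"].to_numpy(), draws["beta2_2"].to_numpy(),
                draws["mu1"].to_numpy(), draws["mu2"].to_numpy(),
                draws["tau1"].to_numpy(), draws["tau2"].to_numpy(),
                draws["xi"].to_numpy(), draws["zeta"].to_numpy())
            w = expit(np.log(pr.omega) - np.log1p(-pr.omega) + l_ex - l_nex)
        draws["exch_prob"] = w
        return EfficacyResults(model=self, draws=draws, diagnostics=diag)


@dataclass
class EfficacyResults:
    """Joint posterior draws of the two-stage efficacy hierarchy."""

    model: EfficacyMAC
    draws: pd.DataFrame
    diagnostics: SamplerDiagnostics

    @property
    def exchangeability_weight(self) -> float:
        """Posterior probability that Psi_2 is exchangeable with Psi_1."""
        return float(self.draws["exch_prob"].mean())

    def stage2_params_draws(self) -> np.ndarray:
        d = self.draws
        return np.column_stack([d["beta0_2"], d["beta1_2"], d["beta2_2"], d["beta3_2"]])

    def prob_eff_draws(self, dose: DoseCombination) -> np.ndarray:
        """Posterior draws of the stage-2 response probability at a dose."""
        d = self.draws
        u = (d["beta0_2"].to_numpy() + np.exp(d["beta1_2"].to_numpy()) * dose.x
             + np.exp(d["beta2_2"].to_numpy()) * dose.y
             + d["beta3_2"].to_numpy() * dose.x * dose.y)
        return expit(u)

    def prob_eff_exceeds(self, dose: DoseCombination, p0: float) -> float:
        """Posterior probability that the stage-2 response rate exceeds p0."""
        return float(np.mean(self.prob_eff_draws(dose) > p0))

    def exceedance_profile(self, points, p0: float) -> np.ndarray:
        """Exceedance probabilities at a list of dose combinations."""
        xs = np.array([p.x for p in points])
        ys = np.array([p.y for p in points])
        d = self.draws
        u = (d["beta0_2"].to_numpy()[:, None]
             + np.exp(d["beta1_2"].to_numpy())[:, None] * xs
             + np.exp(d["beta2_2"].to_numpy())[:, None] * ys
             + d["beta3_2"].to_numpy()[:, None] * (xs * ys))
        return (expit(u) > p0).mean(axis=0)

    def plugin_params(self) -> EffStageParams:
        """Stage-2 plug-in parameters: coordinatewise posterior medians."""
        med = self.draws[["beta0_2", "beta1_2", "beta2_2", "beta3_2"]].median()
        return EffStageParams(beta0=float(med["beta0_2"]), beta1=float(med["beta1_2"]),
                              beta2=float(med["beta2_2"]), beta3=float(max(med["beta3_2"], 0.0)))

    def plugin_eff_curve(self, curve: MTDCurve):
        """Plug-in stage-2 efficacy along the MTD curve, as a function of x."""
        if curve.is_empty:
            raise ValueError("cannot evaluate efficacy along an empty MTD curve")
        params = self.plugin_params()

        def pi_hat(x):
            y = np.clip(curve.y_at(x), 0.0, 1.0)
            return params.prob_eff(x, y)

        return pi_hat

    def summary(self) -> pd.DataFrame:
        cols = [c for c in PARAM_NAMES if c in self.draws]
        qs = self.draws[cols].quantile([0.025, 0.5, 0.975]).T
        qs.columns = ["2.5%", "median", "97.5%"]
        qs.insert(0, "mean", self.draws[cols].mean())
        qs.insert(1, "sd", self.draws[cols].std())
        return qs
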