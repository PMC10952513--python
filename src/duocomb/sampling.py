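"""Thin wrapper around the affine-invariant ensemble sampler.

Both posteriors in this package are low-dimensional (4 parameters for
toxicity, 14 for the joint efficacy hierarchy) with cheap, fully vectorized
log-densities, which is exactly the regime where an ensemble of stretch-move
walkers mixes quickly without gradient information.  All randomness is
controlled by an integer seed so that trial simulations are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import emcee


@dataclass
class SamplerDiagnostics:
    acceptance_rate: float
    n_draws: int
    ess_min: float = np.nan
    rhat_max: float = np.nan
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "acceptance_rate": self.acceptance_rate,
            "n_draws": self.n_draws,
            "ess_min": None if np.isnan(self.ess_min) else self.ess_min,
            "rhat_max": None if np.isnan(self.rhat_max) else self.rhat_max,
            "converged": bool(self.converged),
        }


def _split_rhat(chain: np.ndarray) -> float:
    """Largest split-Rhat across dimensions; chain is (steps, walkers, dim)."""
    n = chain.shape[0] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([chain[:n], chain[n:2 * n]], axis=1)  # (n, 2*walkers, dim)
    m = halves.shape[1]
    means = halves.mean(axis=0)
    varis = halves.var(axis=0, ddof=1)
    W = varis.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return float(np.nanmax(rhat))


def _ess_min(chain: np.ndarray) -> float:
    """Crude effective sample size: per-walker autocorrelation-time estimate."""
    steps, walkers, dim = chain.shape
    flat = chain.reshape(steps * walkers, dim)
    total = steps * walkers
    # batch-means ESS per dimension
    nb = max(4, int(np.sqrt(steps)))
    bs = steps // nb
    if bs < 2:
        return np.nan
    ess = []
    for d in range(dim):
        x = chain[: nb * bs, :, d]
        batches = x.reshape(nb, bs, walkers).mean(axis=1)
        var_b = batches.var(axis=0, ddof=1).mean()
        var_x = x.var()
        if var_b <= 0 or var_x <= 0:
            ess.append(total)
            continue
        tau = bs * var_b / var_x
        ess.append(total / max(tau, 1.0))
    return float(min(ess))


def _build_moves(moves: str):
    if moves == "stretch":
        return None  # emcee default
    if moves == "de":
        # differential-evolution moves handle the multi-scale hierarchical
        # posteriors better than pure stretch moves
        return [(emcee.moves.DEMove(), 0.7), (emcee.moves.DESnookerMove(), 0.3)]
    raise ValueError(f"unknown move set {moves!r}")


def run_ensemble(log_prob, p0: np.ndarray, n_steps: int, discard: int, seed: int,
                 compute_diagnostics: bool = True, ess_floor: float = 400.0,
                 rhat_ceiling: float = 1.05, moves: str = "stretch"):
    """Run the stretch-move ensemble and return flattened posterior draws.

    Parameters
    ----------
    log_prob : callable
        Vectorized log density taking an (n_walkers, dim) array.
    p0 : ndarray (n_walkers, dim)
        Initial walker positions.
    n_steps, discard : int
        Total steps and warm-up steps to drop.
    seed : int
        Seed for the sampler's internal random state.

    Returns
    -------
    draws : ndarray (n_draws, dim)
    diagnostics : SamplerDiagnostics
    """
    n_walkers, dim = p0.shape
    sampler = emcee.EnsembleSampler(n_walkers, dim, log_prob, vectorize=True,
                                    moves=_build_moves(moves))
    state = emcee.State(p0, random_state=np.random.RandomState(int(seed) % (2 ** 31)).get_state())
    sampler.run_mcmc(state, n_steps, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=discard)  # (steps, walkers, dim)
    draws = chain.reshape(-1, dim)
    acc = float(np.mean(sampler.acceptance_fraction))
    diag = SamplerDiagnostics(acceptance_rate=acc, n_draws=draws.shape[0])
    if compute_diagnostics:
        diag.rhat_max = _split_rhat(chain)
        diag.ess_min = _ess_min(chain)
        diag.converged = bool(
            (np.isnan(diag.rhat_max) or diag.rhat_max <= rhat_ceiling)
            and (np.isnan(diag.ess_min) or diag.ess_min >= ess_floor)
        )
    return draws, diag
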