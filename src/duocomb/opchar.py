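"""Operating characteristics over replicated simulated trials.

``simulate_trials`` runs ``J`` independent trials of the design against a
scenario truth, with per-trial seeds derived from the master seed by index
so results are invariant to execution order and to changes of ``J``.
``OperatingCharacteristics.compute`` aggregates the standard metrics:
rejection rate (Bayesian power under H1, type-I error under H0), the
proportion of correct recommendations, futility/safety stopping rates,
stage-II allocation quality, DLT summaries and sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .doses import DoseCombination
from .scenarios import ScenarioTruth
from .trial import DesignConfig, TrialDesign, TrialResult


def derive_trial_seed(master_seed: int, trial_index: int) -> int:
    """Stable per-trial seed; independent of J and of execution order."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(trial_index),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_trials(config: DesignConfig, truth: ScenarioTruth, J: int,
                    seed: int, progress: bool = False) -> list:
    """Run ``J`` replicate trials; individual failures are recorded, not fatal."""
    design = TrialDesign(config)
    results = []
    for j in range(J):
        trial_seed = derive_trial_seed(seed, j)
        try:
            results.append(design.run(truth, seed=trial_seed))
        except Exception as err:  # pragma: no cover - defensive
            results.append(err)
        if progress and (j + 1) % 10 == 0:
            print(f"  completed {j + 1}/{J} trials")
    return results


def _completed(results):
    return [r for r in results if isinstance(r, TrialResult)]


def estimate_power(results, config: DesignConfig) -> float:
    """Fraction of trials rejecting H0; early-stopped trials count as
    non-rejections (the final test never fires in them)."""
    res = _completed(results)
    return float(np.mean([r.decision == "reject_h0" for r in res])) if res else np.nan


def estimate_power_completers(results, config: DesignConfig) -> float:
    """Rejection rate among trials that reached the final test."""
    res = [r for r in _completed(results) if r.decision in ("reject_h0", "accept_h0")]
    return float(np.mean([r.decision == "reject_h0" for r in res])) if res else np.nan


def correct_recommendation_rate(results, truth: ScenarioTruth,
                                config: DesignConfig) -> Optional[float]:
    """Among rejecting trials, fraction whose recommended combination has
    true stage-II response probability above p0.  None when no trial made a
    recommendation."""
    recs = [r.optimal_dose for r in _completed(results)
            if r.decision == "reject_h0" and r.optimal_dose is not None]
    if not recs:
        return None
    good = [truth.true_prob_eff(d, stage=2) > config.p0 for d in recs]
    return float(np.mean(good))


def allocation_above_p0(results, truth: ScenarioTruth, config: DesignConfig) -> float:
    """Fraction of stage-II patients (pooled over trials) treated at doses
    with true stage-II response probability above p0."""
    total, good = 0, 0
    for r in _completed(results):
        s2 = r.records[r.records["stage"] == 2]
        for _, row in s2.iterrows():
            total += 1
            d = DoseCombination(float(row["x_std"]), float(row["y_std"]))
            if truth.true_prob_eff(d, stage=2) > config.p0:
                good += 1
    return good / total if total else np.nan


def stopping_and_safety_summaries(results, config: DesignConfig) -> dict:
    res = _completed(results)
    if not res:
        return {}
    n = len(res)
    dlt_rates, dlt_rates_s2, above = [], [], []
    for r in res:
        if r.n_enrolled:
            dlt_rates.append(r.n_dlt / r.n_enrolled)
            above.append(dlt_rates[-1] > config.theta_T + config.excess_tox_margin)
        s2 = r.records[r.records["stage"] == 2]
        if len(s2):
            dlt_rates_s2.append(float(s2["dlt"].mean()))
    return {
        "futility_stop_rate": float(np.mean([r.decision == "stopped_futility" for r in res])),
        "safety_stop_rate": float(np.mean([r.decision in ("stopped_safety_s1", "stopped_safety_s2")
                                           for r in res])),
        "no_tolerable_set_rate": float(np.mean([r.decision == "no_tolerable_set" for r in res])),
        "mean_dlt_rate": float(np.mean(dlt_rates)) if dlt_rates else np.nan,
        "mean_dlt_rate_stage2": float(np.mean(dlt_rates_s2)) if dlt_rates_s2 else np.nan,
        "frac_trials_dlt_above_margin": float(np.mean(above)) if above else np.nan,
        "mean_sample_size": float(np.mean([r.n_enrolled for r in res])),
        "n_failed": len(results) - n,
    }


@dataclass
class OperatingCharacteristics:
    """Aggregated metrics of a batch of simulated trials."""

    reject_rate: float
    reject_rate_completers: float
    correct_recommendation_rate: Optional[float]
    allocation_above_p0_rate: float
    futility_stop_rate: float
    safety_stop_rate: float
    no_tolerable_set_rate: float
    mean_dlt_rate: float
    mean_dlt_rate_stage2: float
    frac_trials_dlt_above_margin: float
    mean_sample_size: float
    mean_exchangeability_weight: Optional[float]
    recommended_doses: list
    J: int
    seed: int
    scenario_label: str = ""
    n_failed: int = 0

    @classmethod
    def compute(cls, results, truth: ScenarioTruth, config: DesignConfig,
                seed: int) -> "OperatingCharacteristics":
        res = _completed(results)
        summ = stopping_and_safety_summaries(results, config)
        weights = [r.exchangeability_weight for r in res
                   if r.exchangeability_weight is not None]
        recs = [list(r.optimal_dose.as_tuple()) for r in res
                if r.optimal_dose is not None]
        return cls(
            reject_rate=estimate_power(results, config),
            reject_rate_completers=estimate_power_completers(results, config),
            correct_recommendation_rate=correct_recommendation_rate(results, truth, config),
            allocation_above_p0_rate=allocation_above_p0(results, truth, config),
            futility_stop_rate=summ.get("futility_stop_rate", np.nan),
            safety_stop_rate=summ.get("safety_stop_rate", np.nan),
            no_tolerable_set_rate=summ.get("no_tolerable_set_rate", np.nan),
            mean_dlt_rate=summ.get("mean_dlt_rate", np.nan),
            mean_dlt_rate_stage2=summ.get("mean_dlt_rate_stage2", np.nan),
            frac_trials_dlt_above_margin=summ.get("frac_trials_dlt_above_margin", np.nan),
            mean_sample_size=summ.get("mean_sample_size", np.nan),
            mean_exchangeability_weight=float(np.mean(weights)) if weights else None,
            recommended_doses=recs,
            J=len(results),
            seed=seed,
            scenario_label=truth.label,
            n_failed=summ.get("n_failed", 0),
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        def clean(v):
            if isinstance(v, float) and np.isnan(v):
                return None
            return v

        return {k: clean(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "OperatingCharacteristics":
        d = dict(d)
        for k, v in d.items():
            if v is None and k not in ("correct_recommendation_rate",
                                       "mean_exchangeability_weight"):
                d[k] = np.nan
        return cls(**d)


def per_trial_frame(results) -> pd.DataFrame:
    """Tidy one-row-per-trial summary for CSV export."""
    rows = []
    for j, r in enumerate(results):
        if not isinstance(r, TrialResult):
            rows.append({"trial": j, "decision": "error"})
            continue
        opt = r.optimal_dose
        rows.append({
            "trial": j,
            "decision": r.decision,
            "opt_x": opt.x if opt else np.nan,
            "opt_y": opt.y if opt else np.nan,
            "max_exceedance": r.max_exceedance,
            "n_enrolled": r.n_enrolled,
            "dlt_count": r.n_dlt,
            "exchangeability_weight": r.exchangeability_weight,
        })
    return pd.DataFrame(rows)
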