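"""End-to-end conduct of the two-stage phase I-II combination trial.

Stage I escalates cohorts of two patients under escalation with overdose
control (EWOC): after every cohort the toxicity posterior is refit and the
next patients receive the alpha-th percentile of the posterior conditional
MTD of one agent given the other agent's previous dose, with the
conditioning pattern alternating by cohort parity.  The feasibility bound
alpha grows from 0.25 by 0.05 per cohort up to 0.5.

Stage II works on the MTD curve estimated from the stage-I posterior
medians: a run-in of ``n2`` patients at equally spaced curve points, then
response-adaptive cohorts drawn by rejection sampling from the normalized
plug-in efficacy density along the curve, refitting the robust MAC
efficacy model after every cohort.  The trial can stop early for stage-I
safety (minimum combination too toxic), stage-II safety (pooled DLT rate
excessive under a Jeffreys Beta posterior), or futility; otherwise the
final test rejects the null of no efficacious tolerable combination when
the maximum posterior exceedance probability along the curve passes
``delta_u``, recommending the argmax as the optimal combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import records as rec
from .doses import DoseCombination, MTDCurve, NoTolerableDoseError
from .efficacy import EfficacyMAC, EfficacyResults
from .parameters import EffPriorSpec, ToxPriorSpec
from .records import PatientRecord
from .toxicity import ToxicityModel, ToxicityResults

DECISIONS = ("reject_h0", "accept_h0", "stopped_futility",
             "stopped_safety_s1", "stopped_safety_s2", "no_tolerable_set")

logger = logging.getLogger("duocomb.trial")


@dataclass
class SamplerSettings:
    """MCMC effort knobs; defaults suit a single-trial analysis.

    ``for_simulation`` returns a lighter preset used inside large
    operating-characteristics runs.
    """

    tox_walkers: int = 24
    tox_steps: int = 1500
    tox_discard: int = 750
    eff_walkers: int = 32
    eff_steps: int = 2000
    eff_discard: int = 1000
    ess_floor: float = 400.0
    compute_diagnostics: bool = True

    @classmethod
    def for_simulation(cls) -> "SamplerSettings":
        return cls(tox_walkers=20, tox_steps=400, tox_discard=200,
                   eff_walkers=28, eff_steps=700, eff_discard=350,
                   ess_floor=0.0, compute_diagnostics=False)


@dataclass
class DesignConfig:
    """All design constants of the two-stage trial."""

    theta_T: float = 0.33
    p0: float = 0.15
    delta_u: float = 0.4
    delta_0: float = 0.1
    delta_theta1: float = 0.5
    delta_theta2: float = 0.9
    excess_tox_margin: float = 0.1
    C1: int = 15
    m1: int = 2
    n2: int = 10
    C2: int = 4
    m2: int = 5
    ewoc_alpha_start: float = 0.25
    ewoc_alpha_max: float = 0.5
    ewoc_alpha_step: float = 0.05
    start_dose: tuple = (0.33, 0.5)
    grid_size: int = 101
    curve_spacing: str = "arc_length"
    stage2_safety_pooled: bool = True
    omega: float = 0.0
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def __post_init__(self):
        if isinstance(self.sampler, dict):
            self.sampler = SamplerSettings(**self.sampler)
        if isinstance(self.start_dose, list):
            self.start_dose = tuple(self.start_dose)
        if not (0 < self.delta_0 < self.delta_u < 1):
            raise ValueError("need 0 < delta_0 < delta_u < 1")
        for name in ("theta_T", "p0", "delta_theta1", "delta_theta2"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("C1", "m1", "n2", "C2", "m2", "grid_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not (0 <= self.omega <= 1):
            raise ValueError("omega must lie in [0, 1]")

    @property
    def N1(self) -> int:
        return self.C1 * self.m1

    @property
    def N2(self) -> int:
        return self.n2 + self.C2 * self.m2

    def ewoc_alpha(self, cohort: int) -> float:
        """Feasibility bound for stage-I cohort ``cohort`` (1-based).

        Cohort 1 is the fixed start dose; from cohort 2 on the bound starts
        at ``ewoc_alpha_start`` and grows by ``ewoc_alpha_step`` per cohort,
        capped at ``ewoc_alpha_max``.
        """
        if cohort <= 1:
            return self.ewoc_alpha_start
        a = self.ewoc_alpha_start + self.ewoc_alpha_step * (cohort - 2)
        return min(a, self.ewoc_alpha_max)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_dose"] = list(self.start_dose)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        if "sampler" in d and isinstance(d["sampler"], dict):
            d["sampler"] = SamplerSettings(**d["sampler"])
        return cls(**d)


@dataclass
class TrialResult:
    decision: str
    records: pd.DataFrame
    curve: Optional[MTDCurve] = None
    optimal_dose: Optional[DoseCombination] = None
    max_exceedance: Optional[float] = None
    exchangeability_weight: Optional[float] = None
    cohort_log: list = field(default_factory=list)
    truncation_events: int = 0

    def __post_init__(self):
        if self.decision not in DECISIONS:
            raise ValueError(f"unknown decision {self.decision!r}")

    @property
    def n_enrolled(self) -> int:
        return len(self.records)

    @property
    def n_dlt(self) -> int:
        return int(self.records["dlt"].sum()) if len(self.records) else 0

    def to_dict(self) -> dict:
        return {
            "decision": self.decision,
            "n_enrolled": self.n_enrolled,
            "n_dlt": self.n_dlt,
            "curve": self.curve.to_dict() if self.curve is not None else None,
            "optimal_dose": list(self.optimal_dose.as_tuple()) if self.optimal_dose else None,
            "max_exceedance": self.max_exceedance,
            "exchangeability_weight": self.exchangeability_weight,
            "truncation_events": self.truncation_events,
            "cohort_log": self.cohort_log,
            "records": self.records.where(pd.notna(self.records), None).to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialResult":
        df = pd.DataFrame(d["records"], columns=rec.COLUMNS)
        return cls(
            decision=d["decision"],
            records=df,
            curve=MTDCurve.from_dict(d["curve"]) if d.get("curve") else None,
            optimal_dose=DoseCombination(*d["optimal_dose"]) if d.get("optimal_dose") else None,
            max_exceedance=d.get("max_exceedance"),
            exchangeability_weight=d.get("exchangeability_weight"),
            cohort_log=d.get("cohort_log", []),
            truncation_events=d.get("truncation_events", 0),
        )


# --------------------------------------------------------------------------
# stage-II allocation machinery


class StandardizedDensity:
    """Normalized plug-in efficacy density along the MTD curve.

    Wraps a strictly positive function of x on the curve's x-domain and
    normalizes it by numeric quadrature so it integrates to one.
    """

    def __init__(self, eff_curve: Callable, domain: tuple, n_grid: int = 1001):
        self.domain = domain
        lo, hi = domain
        if not hi > lo:
            raise ValueError("density needs a non-degenerate domain")
        self._xs = np.linspace(lo, hi, n_grid)
        vals = np.asarray(eff_curve(self._xs), dtype=float)
        if np.any(vals <= 0):
            raise ValueError("efficacy curve must be strictly positive on the domain")
        self._norm = float(np.trapezoid(vals, self._xs))
        self._vals = vals / self._norm
        self._fn = eff_curve
        cdf = np.concatenate([[0.0], np.cumsum(
            (self._vals[1:] + self._vals[:-1]) / 2 * np.diff(self._xs))])
        self._cdf = cdf / cdf[-1]

    def pdf(self, x):
        return np.asarray(self._fn(x), dtype=float) / self._norm

    def cdf(self, x):
        return np.interp(x, self._xs, self._cdf)

    @property
    def max_pdf(self) -> float:
        return float(self._vals.max())

    def integral(self) -> float:
        return float(np.trapezoid(self._vals, self._xs))


def sample_doses_rejection(density: StandardizedDensity, curve: MTDCurve, m: int,
                           rng: np.random.Generator, max_tries: int = 100000):
    """Sample ``m`` dose combinations on the curve from the standardized density.

    Uniform proposals over the x-domain are accepted with probability
    ``pdf(x) / max pdf``; accepted x values are mapped onto the curve.
    """
    lo, hi = density.domain
    cap = density.max_pdf
    accepted = []
    tries = 0
    while len(accepted) < m:
        batch = max(2 * (m - len(accepted)), 16)
        tries += batch
        if tries > max_tries:
            raise RuntimeError(
                "rejection sampler acceptance rate below 1e-3; the proposal "
                "density looks inconsistent with the target")
        xs = rng.uniform(lo, hi, batch)
        u = rng.uniform(0.0, 1.0, batch)
        keep = xs[u * cap <= density.pdf(xs)]
        accepted.extend(keep.tolist())
    xs = np.array(accepted[:m])
    ys = np.clip(curve.y_at(xs), 0.0, 1.0)
    return [DoseCombination(float(x), float(y)) for x, y in zip(xs, ys)]


def stage2_safety_stop(all_records: pd.DataFrame, config: DesignConfig) -> bool:
    """Stage-II stopping rule on the pooled DLT rate.

    With ``k`` DLTs among ``n`` patients, the DLT rate carries a Jeffreys
    Beta(0.5, 0.5) prior, and the trial stops when the posterior probability
    that the rate exceeds ``theta_T + margin`` is above ``delta_theta2``.
    By default patients from both stages are pooled; set
    ``stage2_safety_pooled=False`` to restrict to stage-II patients.
    """
    df = all_records
    if not config.stage2_safety_pooled:
        df = df[df["stage"] == 2]
    n = len(df)
    if n == 0:
        return False
    k = int(df["dlt"].sum())
    surv = stats.beta.sf(config.theta_T + config.excess_tox_margin, 0.5 + k, 0.5 + n - k)
    return bool(surv > config.delta_theta2)


def futility_stop(eff_post: EfficacyResults, curve: MTDCurve, config: DesignConfig) -> bool:
    """True when no point of the curve shows a promising exceedance probability."""
    points = curve.equally_spaced_points(config.grid_size, spacing=config.curve_spacing)
    exc = eff_post.exceedance_profile(points, config.p0)
    return bool(np.max(exc) < config.delta_0)


def final_test(eff_post: EfficacyResults, curve: MTDCurve, config: DesignConfig):
    """Terminal decision: reject H0 iff the max exceedance passes delta_u.

    Returns ``(reject, optimal_dose, max_exceedance)``.  The argmax over the
    grid is the recommended combination; ties break toward the lowest x.
    """
    points = curve.equally_spaced_points(config.grid_size, spacing=config.curve_spacing)
    exc = eff_post.exceedance_profile(points, config.p0)
    i = int(np.argmax(exc))  # first occurrence = lowest x
    return bool(exc[i] > config.delta_u), points[i], float(exc[i])


# --------------------------------------------------------------------------
# the trial engine


class TrialDesign:
    """Runs the two-stage design against an outcome source.

    ``outcome_source`` is any callable ``(dose, stage, rng) -> (z, e)``
    producing the binary DLT and efficacy outcome for a patient treated at a
    standardized dose combination — in simulations a
    :class:`~duocomb.scenarios.ScenarioTruth`, in a real trial a lookup of
    observed data.
    """

    def __init__(self, config: DesignConfig = None,
                 tox_prior: ToxPriorSpec = None, eff_prior: EffPriorSpec = None):
        self.config = config if config is not None else DesignConfig()
        self.tox_prior = tox_prior if tox_prior is not None else ToxPriorSpec()
        base_eff = eff_prior if eff_prior is not None else EffPriorSpec()
        self.eff_prior = base_eff.with_omega(self.config.omega)

    # -- stage I -----------------------------------------------------------

    def run_stage1(self, outcome_source, rng: np.random.Generator):
        """EWOC escalation; returns (records list, ToxicityResults or None, log).

        The toxicity posterior is refit after every cohort; the safety rule
        is checked after every fit.  A safety stop is signalled by a None
        posterior together with a log entry, not by an exception.
        """
        cfg = self.config
        records: list[PatientRecord] = []
        log = []
        truncations = 0
        post: Optional[ToxicityResults] = None
        x_prev = {}
        y_prev = {}

        def observe(pid, dose, cohort):
            z, e = outcome_source(dose, 1, rng)
            records.append(PatientRecord(patient_id=pid, stage=1, x_std=dose.x,
                                         y_std=dose.y, dlt=int(z), eff=int(e),
                                         cohort=cohort))
            x_prev[pid] = dose.x
            y_prev[pid] = dose.y

        def refit(cohort):
            nonlocal post
            df = rec.to_frame(records)
            # stage-1 efficacy outcomes are collected but unobservable until
            # stage II; the toxicity fit uses DLT data only
            model = ToxicityModel(df, prior=self.tox_prior)
            s = cfg.sampler
            post = model.fit(n_walkers=s.tox_walkers, n_steps=s.tox_steps,
                             discard=s.tox_discard,
                             seed=int(rng.integers(2 ** 31)),
                             compute_diagnostics=s.compute_diagnostics,
                             ess_floor=s.ess_floor)
            return post

        def ewoc(fixed_dose, fixed_agent, alpha):
            nonlocal truncations
            raw = post.conditional_mtd_percentile(fixed_dose, fixed_agent, alpha,
                                                  cfg.theta_T, truncate=False)
            clipped = float(np.clip(raw, 0.0, 1.0))
            if clipped != raw:
                truncations += 1
            return clipped

        start = DoseCombination(*cfg.start_dose)
        pid = 1
        for c1 in range(1, cfg.C1 + 1):
            alpha = cfg.ewoc_alpha(c1)
            if c1 == 1:
                doses = [start, start]
            elif c1 == 2:
                x3 = ewoc(y_prev[1], "Y", alpha)
                doses = [DoseCombination(x3, y_prev[1])]
                y4 = ewoc(x_prev[2], "X", alpha)
                doses.append(DoseCombination(x_prev[2], y4))
            elif c1 % 2 == 0:
                # even cohort: first patient gets a new x at the previous y,
                # second gets a new y at the previous x
                y_keep = y_prev[2 * c1 - 3]
                x_new = ewoc(y_keep, "Y", alpha)
                doses = [DoseCombination(x_new, y_keep)]
                x_keep = x_prev[2 * c1 - 2]
                y_new = ewoc(x_keep, "X", alpha)
                doses.append(DoseCombination(x_keep, y_new))
            else:
                # odd cohort: pattern flips
                x_keep = x_prev[2 * c1 - 3]
                y_new = ewoc(x_keep, "X", alpha)
                doses = [DoseCombination(x_keep, y_new)]
                y_keep = y_prev[2 * c1 - 2]
                x_new = ewoc(y_keep, "Y", alpha)
                doses.append(DoseCombination(x_new, y_keep))
            for dose in doses:
                observe(pid, dose, c1)
                pid += 1
            refit(c1)
            stop = post.safety_stop(cfg.theta_T, cfg.delta_theta1, cfg.excess_tox_margin)
            log.append({"stage": 1, "cohort": c1, "alpha": alpha,
                        "doses": [list(d.as_tuple()) for d in doses],
                        "safety_stop": bool(stop)})
            logger.info("stage I cohort %d: alpha=%.2f doses=%s safety_stop=%s",
                        c1, alpha, [d.as_tuple() for d in doses], stop)
            if stop:
                return records, None, log, truncations
        return records, post, log, truncations

    # -- stage II ----------------------------------------------------------

    def estimate_mtd_curve(self, tox_post: ToxicityResults) -> MTDCurve:
        return tox_post.mtd_curve(self.config.theta_T)

    def _fit_efficacy(self, df_s1, df_s2, rng) -> EfficacyResults:
        s = self.config.sampler
        model = EfficacyMAC(df_s1, df_s2, prior=self.eff_prior)
        return model.fit(n_walkers=s.eff_walkers, n_steps=s.eff_steps,
                         discard=s.eff_discard, seed=int(rng.integers(2 ** 31)),
                         compute_diagnostics=s.compute_diagnostics,
                         ess_floor=s.ess_floor)

    def run_stage2(self, curve: MTDCurve, stage1_records: list, outcome_source,
                   rng: np.random.Generator, log=None, truncations: int = 0) -> TrialResult:
        cfg = self.config
        log = log if log is not None else []
        records = list(stage1_records)
        pid = len(records) + 1

        if curve.is_empty:
            return TrialResult(decision="no_tolerable_set", records=rec.to_frame(records),
                               curve=curve, cohort_log=log, truncation_events=truncations)

        def enroll(doses, cohort):
            nonlocal pid
            for dose in doses:
                z, e = outcome_source(dose, 2, rng)
                records.append(PatientRecord(patient_id=pid, stage=2, x_std=dose.x,
                                             y_std=dose.y, dlt=int(z), eff=int(e),
                                             cohort=cohort))
                pid += 1

        def frames():
            df = rec.to_frame(records)
            return df[df["stage"] == 1], df[df["stage"] == 2], df

        # run-in: n2 patients equally spaced along the curve
        run_in = curve.equally_spaced_points(cfg.n2, spacing=cfg.curve_spacing)
        enroll(run_in, cohort=0)
        df1, df2, df = frames()
        eff_post = self._fit_efficacy(df1, df2, rng)
        log.append({"stage": 2, "cohort": 0, "n": cfg.n2,
                    "exch_weight": eff_post.exchangeability_weight})
        logger.info("stage II run-in: %d patients, exchangeability weight %.3f",
                    cfg.n2, eff_post.exchangeability_weight)

        def finish(decision, post):
            reject, opt, mx = final_test(post, curve, cfg)
            if decision is None:
                decision = "reject_h0" if reject else "accept_h0"
                chosen = opt if reject else None
            else:
                chosen = None
            return TrialResult(decision=decision, records=rec.to_frame(records),
                               curve=curve, optimal_dose=chosen, max_exceedance=mx,
                               exchangeability_weight=post.exchangeability_weight,
                               cohort_log=log, truncation_events=truncations)

        if stage2_safety_stop(df, cfg):
            return finish("stopped_safety_s2", eff_post)
        if futility_stop(eff_post, curve, cfg):
            return finish("stopped_futility", eff_post)

        for c2 in range(1, cfg.C2 + 1):
            density = StandardizedDensity(eff_post.plugin_eff_curve(curve), curve.x_domain)
            doses = sample_doses_rejection(density, curve, cfg.m2, rng)
            enroll(doses, cohort=c2)
            df1, df2, df = frames()
            eff_post = self._fit_efficacy(df1, df2, rng)
            log.append({"stage": 2, "cohort": c2,
                        "doses": [list(d.as_tuple()) for d in doses],
                        "exch_weight": eff_post.exchangeability_weight})
            logger.info("stage II cohort %d: doses=%s exchangeability weight %.3f",
                        c2, [d.as_tuple() for d in doses],
                        eff_post.exchangeability_weight)
            if stage2_safety_stop(df, cfg):
                return finish("stopped_safety_s2", eff_post)
            if futility_stop(eff_post, curve, cfg):
                return finish("stopped_futility", eff_post)
        return finish(None, eff_post)

    # -- full trial ---------------------------------------------------------

    def run(self, outcome_source, seed: int) -> TrialResult:
        """Run a complete trial with all randomness derived from ``seed``."""
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        s1_records, tox_post, log, truncations = self.run_stage1(outcome_source, rng)
        if tox_post is None:
            return TrialResult(decision="stopped_safety_s1",
                               records=rec.to_frame(s1_records), cohort_log=log,
                               truncation_events=truncations)
        curve = self.estimate_mtd_curve(tox_post)
        return self.run_stage2(curve, s1_records, outcome_source, rng,
                               log=log, truncations=truncations)
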