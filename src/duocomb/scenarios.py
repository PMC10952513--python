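"""Synthetic ground truth for simulation studies.

A scenario fixes a true dose-toxicity surface (shared by both stages), a
true stage-II dose-efficacy surface and a true stage-I surface whose
agreement with stage II is one of

* ``CA`` — complete agreement: identical parameters;
* ``PA`` — partial agreement: the most efficacious combination on the MTD
  curve is the same but the response probabilities differ;
* ``CD`` — complete disagreement: the peak sits at the opposite end of the
  curve.

Efficacy profiles are calibrated on the composition ``x -> pi_E(x, y(x))``
along the true MTD curve: although the efficacy surface is monotone in each
agent, the curve trades one agent against the other, so the composed
profile can peak anywhere on the curve.  Under the alternative hypothesis
the stage-II peak equals ``p0 + effect_size`` (default 0.15 + 0.25 = 0.40);
under the null it equals ``p0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
import yaml
from scipy.optimize import brentq

from .doses import DoseCombination, MTDCurve
from .links import logistic_quantile
from .parameters import EffStageParams, ToxParams


class CalibrationError(RuntimeError):
    pass


def _composite_logits(curve: MTDCurve, beta1, beta2, beta3, n_grid=1001):
    lo, hi = curve.x_domain
    xs = np.linspace(lo, hi, n_grid)
    ys = np.clip(curve.y_at(xs), 0.0, 1.0)
    g = np.exp(beta1) * xs + np.exp(beta2) * ys + beta3 * xs * ys
    return xs, ys, g


def _argmax_frac(curve: MTDCurve, beta1, beta2, beta3, n_grid=1001) -> float:
    xs, _, g = _composite_logits(curve, beta1, beta2, beta3, n_grid)
    i = int(np.argmax(g))
    return (xs[i] - xs[0]) / (xs[-1] - xs[0])


def calibrate_eff_profile(curve: MTDCurve, peak_x: float, peak_prob: float,
                          beta2: float = 1.0, beta3: float = 8.0,
                          endpoint_contrast: float = 1.5,
                          n_grid: int = 1001) -> EffStageParams:
    """Solve for efficacy parameters whose curve-composite peaks as requested.

    ``peak_x`` is the x-coordinate (on the curve's domain) of the most
    efficacious combination and ``peak_prob`` its response probability.
    ``beta2`` and ``beta3`` act as shape controls; ``beta1`` is the free
    knob.  For a peak at either end of the domain, ``beta1`` is solved so
    that the favoured end beats the opposite end by ``endpoint_contrast``
    on the logit scale (the difference of end logits is strictly monotone
    in ``beta1``, so this is a clean root-find); for an interior peak the
    argmax location is driven to the target by bisection.  ``beta0`` then
    scales the whole profile so the maximum hits ``peak_prob``.

    Interior peaks exist only because the curve trades one agent against
    the other; for shape controls under which the composite is convex the
    argmax jumps between the two ends and an interior request raises
    :class:`CalibrationError`.
    """
    if curve.is_empty:
        raise CalibrationError("cannot calibrate an efficacy profile on an empty MTD curve")
    lo, hi = curve.x_domain
    if not lo <= peak_x <= hi:
        raise CalibrationError(f"peak_x={peak_x} outside the curve domain {curve.x_domain}")
    if not 0.0 < peak_prob < 1.0:
        raise CalibrationError("peak_prob must lie in (0, 1)")
    target_frac = (peak_x - lo) / (hi - lo)
    grid_step = 1.0 / (n_grid - 1)
    b1_lo, b1_hi = -12.0, 8.0

    if target_frac <= grid_step or target_frac >= 1.0 - grid_step:
        # endpoint peak: pin the logit gap between the two curve ends
        sign = 1.0 if target_frac >= 0.5 else -1.0

        def end_gap(b1):
            _, _, g = _composite_logits(curve, b1, beta2, beta3, n_grid)
            return sign * (g[-1] - g[0]) - endpoint_contrast

        if end_gap(b1_lo) * end_gap(b1_hi) > 0:
            raise CalibrationError(
                "cannot separate the curve endpoints by the requested contrast "
                "for these shape controls; adjust beta2/beta3 or endpoint_contrast")
        beta1 = brentq(end_gap, b1_lo, b1_hi, xtol=1e-10)
    else:
        f_lo = _argmax_frac(curve, b1_lo, beta2, beta3, n_grid) - target_frac
        f_hi = _argmax_frac(curve, b1_hi, beta2, beta3, n_grid) - target_frac
        if f_lo > 0 or f_hi < 0:
            raise CalibrationError(
                "the requested peak location cannot be reached for these shape "
                "controls; interior peaks only arise from the x -> (x, y(x)) "
                "composition — adjust beta2/beta3 or the peak location")
        beta1 = brentq(lambda b1: _argmax_frac(curve, b1, beta2, beta3, n_grid) - target_frac,
                       b1_lo, b1_hi, xtol=1e-10)

    achieved = _argmax_frac(curve, beta1, beta2, beta3, n_grid)
    if abs(achieved - target_frac) > 2 * grid_step:
        raise CalibrationError(
            f"peak location {target_frac:.3f} (domain fraction) is not attainable "
            f"with beta2={beta2}, beta3={beta3}: the composite profile's maximum "
            f"lands at {achieved:.3f}; the argmax jumps between the curve ends "
            "for these shape controls")
    _, _, g = _composite_logits(curve, beta1, beta2, beta3, n_grid)
    g_max = float(np.max(g))
    beta0 = float(logistic_quantile(peak_prob) - g_max)
    return EffStageParams(beta0=beta0, beta1=beta1, beta2=beta2, beta3=beta3)


def profile_on_curve(params: EffStageParams, curve: MTDCurve, n_grid: int = 1001):
    """(xs, pi_E(x, y(x))) of an efficacy surface along the MTD curve."""
    lo, hi = curve.x_domain
    xs = np.linspace(lo, hi, n_grid)
    ys = np.clip(curve.y_at(xs), 0.0, 1.0)
    return xs, params.prob_eff(xs, ys)


def make_agreement_variant(eff_s2: EffStageParams, curve: MTDCurve, level: str,
                           pa_peak_prob: Optional[float] = None,
                           cd_peak_prob: Optional[float] = None,
                           n_grid: int = 1001) -> EffStageParams:
    """Derive the stage-I efficacy truth from the stage-II profile.

    ``CA`` copies the parameters.  ``PA`` keeps the argmax (intercept shift
    only, which leaves the location of the composite maximum unchanged) but
    moves the peak response to ``pa_peak_prob`` (default: stage-II peak
    minus 0.15, floored at 0.05 above zero).  ``CD`` recalibrates the peak
    at the opposite end of the curve domain.
    """
    level = level.upper()
    xs, prof = profile_on_curve(eff_s2, curve, n_grid)
    i2 = int(np.argmax(prof))
    peak2 = float(prof[i2])
    if level == "CA":
        return replace(eff_s2)
    if level == "PA":
        target = pa_peak_prob if pa_peak_prob is not None else max(peak2 - 0.15, 0.05)
        _, _, g = _composite_logits(curve, eff_s2.beta1, eff_s2.beta2, eff_s2.beta3, n_grid)
        beta0 = float(logistic_quantile(target) - np.max(g))
        return replace(eff_s2, beta0=beta0)
    if level == "CD":
        lo, hi = curve.x_domain
        opposite = lo if (xs[i2] - lo) > (hi - xs[i2]) else hi
        target = cd_peak_prob if cd_peak_prob is not None else peak2
        return calibrate_eff_profile(curve, opposite, target,
                                     beta2=eff_s2.beta2, beta3=eff_s2.beta3, n_grid=n_grid)
    raise ValueError(f"unknown agreement level {level!r}; expected CA, PA or CD")


@dataclass(frozen=True)
class ScenarioTruth:
    """True generative parameters for one simulated trial configuration."""

    tox: ToxParams
    eff_s1: EffStageParams
    eff_s2: EffStageParams
    hypothesis: str = "H1"
    label: str = "custom"
    provenance: str = "calibrated"

    def __post_init__(self):
        if self.hypothesis not in ("H0", "H1"):
            raise ValueError("hypothesis must be 'H0' or 'H1'")

    def mtd_curve(self, theta_T: float) -> MTDCurve:
        return MTDCurve(tox_params=self.tox, theta_T=theta_T)

    def true_prob_eff(self, dose: DoseCombination, stage: int) -> float:
        params = self.eff_s1 if stage == 1 else self.eff_s2
        return float(params.prob_eff(dose.x, dose.y))

    def generate_outcomes(self, dose: DoseCombination, stage: int,
                          rng: np.random.Generator):
        """Independent Bernoulli DLT and efficacy outcomes at a dose."""
        pz = float(self.tox.prob_dlt(dose.x, dose.y))
        pe = self.true_prob_eff(dose, stage)
        z = int(rng.random() < pz)
        e = int(rng.random() < pe)
        return z, e

    # makes a ScenarioTruth directly usable as a trial outcome_source
    __call__ = generate_outcomes

    def to_dict(self) -> dict:
        return {
            "tox": self.tox.to_dict(),
            "eff_s1": self.eff_s1.to_dict(),
            "eff_s2": self.eff_s2.to_dict(),
            "hypothesis": self.hypothesis,
            "label": self.label,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioTruth":
        return cls(tox=ToxParams.from_dict(d["tox"]),
                   eff_s1=EffStageParams.from_dict(d["eff_s1"]),
                   eff_s2=EffStageParams.from_dict(d["eff_s2"]),
                   hypothesis=d.get("hypothesis", "H1"),
                   label=d.get("label", "custom"),
                   provenance=d.get("provenance", "file"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _default_config() -> dict:
    with resources.files("duocomb.data").joinpath("scenarios.yaml").open() as fh:
        return yaml.safe_load(fh)


def build_scenario(tox_profile: int = 1, eff_profile: int = 1, hypothesis: str = "H1",
                   agreement: str = "CA", theta_T: float = 0.33, p0: float = 0.15,
                   effect_size: float = 0.25, config: dict = None) -> ScenarioTruth:
    """Assemble a calibrated scenario from the packaged configuration data.

    The two dose-toxicity parameter sets both put the true MTD curve through
    the standardized anchor (0.33, 0.5); the two stage-II efficacy profiles
    place the most efficacious combination at opposite parts of the curve.
    Under H1 the stage-II peak response is ``p0 + effect_size``; under H0 it
    is ``p0``.
    """
    cfg = config if config is not None else _default_config()
    tox = ToxParams.from_dict(cfg["toxicity_profiles"][tox_profile - 1])
    curve = MTDCurve(tox_params=tox, theta_T=theta_T)
    prof = cfg["efficacy_profiles"][f"tox{tox_profile}"][eff_profile - 1]
    lo, hi = curve.x_domain
    peak_x = lo + float(prof["peak_frac"]) * (hi - lo)
    peak_prob = p0 + effect_size if hypothesis == "H1" else p0
    eff_s2 = calibrate_eff_profile(curve, peak_x, peak_prob,
                                   beta2=float(prof["beta2"]), beta3=float(prof["beta3"]),
                                   endpoint_contrast=float(prof.get("endpoint_contrast", 1.5)))
    eff_s1 = make_agreement_variant(eff_s2, curve, agreement)
    label = f"tox{tox_profile}-eff{eff_profile}-{hypothesis}-{agreement.upper()}"
    return ScenarioTruth(tox=tox, eff_s1=eff_s1, eff_s2=eff_s2,
                         hypothesis=hypothesis, label=label)
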