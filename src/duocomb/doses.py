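"""Dose standardization and geometry of the maximum-tolerated-dose curve.

For a fixed toxicity parameter vector the MTD set at target DLT probability
``theta_T`` is the curve

    M = {(x, y) : y = (A - alpha1*x) / (alpha2 + alpha3*x)}

with ``A = F^{-1}(theta_T) - F^{-1}(rho00)``, restricted to the standardized
unit square.  Because ``alpha1, alpha2 > 0`` and ``alpha3 >= 0`` the curve is
strictly decreasing in x wherever it is defined, so its intersection with
the unit square is a single closed x-interval with closed-form endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .links import logistic_quantile
from .parameters import InvalidParameterError, ToxParams


class DoseOutOfRangeError(ValueError):
    pass


class NoTolerableDoseError(RuntimeError):
    """The estimated MTD curve does not intersect the unit dose square."""


@dataclass(frozen=True)
class DoseCombination:
    """A standardized dose pair (x, y) in the unit square."""

    x: float
    y: float

    def __post_init__(self):
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise DoseOutOfRangeError(f"standardized doses must lie in [0,1], got {(self.x, self.y)}")

    def as_tuple(self) -> tuple:
        return (self.x, self.y)


@dataclass(frozen=True)
class DoseScale:
    """Raw dose bounds for the two agents (any consistent unit, e.g. mg/m2)."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise InvalidParameterError("dose bounds require xmin < xmax and ymin < ymax")

    def standardize(self, raw_x: float, raw_y: float) -> DoseCombination:
        return DoseCombination(standardize(raw_x, self.xmin, self.xmax),
                               standardize(raw_y, self.ymin, self.ymax))

    def destandardize(self, dose: DoseCombination) -> tuple:
        return (destandardize(dose.x, self.xmin, self.xmax),
                destandardize(dose.y, self.ymin, self.ymax))


def standardize(raw_dose: float, lo: float, hi: float) -> float:
    """Map a raw dose in [lo, hi] linearly onto [0, 1]."""
    if not lo < hi:
        raise InvalidParameterError(f"invalid dose bounds: lo={lo} must be < hi={hi}")
    if raw_dose < lo:
        raise DoseOutOfRangeError(f"dose {raw_dose} is below the lower bound {lo}")
    if raw_dose > hi:
        raise DoseOutOfRangeError(f"dose {raw_dose} is above the upper bound {hi}")
    return (raw_dose - lo) / (hi - lo)


def destandardize(std_dose: float, lo: float, hi: float) -> float:
    """Inverse of :func:`standardize`."""
    if not lo < hi:
        raise InvalidParameterError(f"invalid dose bounds: lo={lo} must be < hi={hi}")
    return lo + std_dose * (hi - lo)


def _curve_coeffs(params: ToxParams, theta_T: float) -> tuple:
    """Return (A, B, C) with y(x) = (A - B x) / (C + alpha3 x)."""
    A = float(logistic_quantile(theta_T) - logistic_quantile(params.rho00))
    B = params.alpha1
    C = params.alpha2
    if C <= 0 or B <= 0:
        raise InvalidParameterError("toxicity must be strictly increasing in each agent")
    return A, B, C


def mtd_y_given_x(x, params: ToxParams, theta_T: float):
    """Dose y of agent Y putting (x, y) on the MTD curve; NaN if outside [0,1].

    Vectorized over ``x``.  The raw algebraic solution (possibly outside the
    unit interval) is available via :func:`mtd_y_solution`.
    """
    y = mtd_y_solution(x, params, theta_T)
    return np.where((y >= 0.0) & (y <= 1.0), y, np.nan)


def mtd_y_solution(x, params: ToxParams, theta_T: float):
    """Algebraic solution y(x) of pi_T(x, y) = theta_T, not truncated."""
    A, B, C = _curve_coeffs(params, theta_T)
    x = np.asarray(x, dtype=float)
    return (A - B * x) / (C + params.alpha3 * x)


def mtd_x_given_y(y, params: ToxParams, theta_T: float):
    """Dose x of agent X putting (x, y) on the MTD curve; NaN if outside [0,1]."""
    x = mtd_x_solution(y, params, theta_T)
    return np.where((x >= 0.0) & (x <= 1.0), x, np.nan)


def mtd_x_solution(y, params: ToxParams, theta_T: float):
    """Algebraic solution x(y) of pi_T(x, y) = theta_T, not truncated."""
    A, B, C = _curve_coeffs(params, theta_T)
    y = np.asarray(y, dtype=float)
    return (A - C * y) / (B + params.alpha3 * y)


def curve_domain(params: ToxParams, theta_T: float):
    """Closed x-interval on which the MTD curve stays inside the unit square.

    Returns ``(x_lo, x_hi)`` or ``None`` when the curve misses the square
    (for instance when even the lowest combination is too toxic,
    rho00 > theta_T).
    """
    A, B, C = _curve_coeffs(params, theta_T)
    if A <= 0:  # rho00 >= theta_T: (0,0) already at or above target risk
        return None
    # y(x) is strictly decreasing, so the domain is bounded by y(x)=1 (left)
    # and y(x)=0 (right).
    x_at_y1 = (A - C) / (B + params.alpha3)
    x_at_y0 = A / B
    lo = max(0.0, x_at_y1)
    hi = min(1.0, x_at_y0)
    if lo > hi:
        return None
    return (lo, hi)


@dataclass(frozen=True)
class MTDCurve:
    """The MTD set at target DLT probability ``theta_T`` for fixed parameters."""

    tox_params: ToxParams
    theta_T: float

    @property
    def x_domain(self):
        return curve_domain(self.tox_params, self.theta_T)

    @property
    def is_empty(self) -> bool:
        return self.x_domain is None

    def y_at(self, x):
        return mtd_y_solution(x, self.tox_params, self.theta_T)

    def x_at(self, y):
        return mtd_x_solution(y, self.tox_params, self.theta_T)

    def points(self, x):
        """Stack of (x, y(x)) pairs for x inside the domain."""
        x = np.asarray(x, dtype=float)
        return np.column_stack([x, self.y_at(x)])

    def _require_domain(self):
        dom = self.x_domain
        if dom is None:
            raise NoTolerableDoseError(
                "the MTD curve does not intersect the unit dose square; "
                "no tolerable dose combinations exist at this target")
        return dom

    def _dydx(self, x):
        A, B, C = _curve_coeffs(self.tox_params, self.theta_T)
        a3 = self.tox_params.alpha3
        return -(B * C + a3 * A) / (C + a3 * np.asarray(x, dtype=float)) ** 2

    def arc_length_grid(self, n_grid: int = 2049):
        """Cumulative arc length along the curve on a fine x grid."""
        lo, hi = self._require_domain()
        xs = np.linspace(lo, hi, n_grid)
        speed = np.sqrt(1.0 + self._dydx(xs) ** 2)
        s = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2.0 * np.diff(xs))])
        return xs, s

    def total_arc_length(self) -> float:
        _, s = self.arc_length_grid()
        return float(s[-1])

    def equally_spaced_points(self, n: int, spacing: str = "arc_length"):
        """``n`` dose combinations equally spaced along the curve.

        Spacing is by arc length by default (the curve is treated as the
        one-dimensional set of tolerable combinations); ``spacing="x"``
        gives equal x-coordinate spacing instead.  Both include the two
        domain endpoints.
        """
        if n < 2:
            raise ValueError("need at least 2 points to span the curve")
        lo, hi = self._require_domain()
        if spacing == "x":
            xq = np.linspace(lo, hi, n)
        elif spacing == "arc_length":
            xs, s = self.arc_length_grid()
            targets = np.linspace(0.0, s[-1], n)
            xq = np.interp(targets, s, xs)
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        yq = np.clip(self.y_at(xq), 0.0, 1.0)
        return [DoseCombination(float(x), float(y)) for x, y in zip(xq, yq)]

    def to_dict(self) -> dict:
        dom = self.x_domain
        return {
            "theta_T": self.theta_T,
            "rho00": self.tox_params.rho00,
            "rho01": self.tox_params.rho01,
            "rho10": self.tox_params.rho10,
            "alpha3": self.tox_params.alpha3,
            "x_domain": list(dom) if dom is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MTDCurve":
        return cls(tox_params=ToxParams(rho00=d["rho00"], rho01=d["rho01"],
                                        rho10=d["rho10"], alpha3=d["alpha3"]),
                   theta_T=float(d["theta_T"]))
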