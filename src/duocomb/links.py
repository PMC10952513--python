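"""Numerically stable logistic link functions.

The dose-toxicity and dose-efficacy models are both logistic regressions on
the standardized dose plane, so the logistic CDF ``F`` and its inverse are
used throughout the package.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit as _logit


def logistic_cdf(u):
    """Logistic CDF ``F(u) = 1 / (1 + exp(-u))``, stable for large ``|u|``."""
    return expit(u)


def logistic_quantile(p):
    """Inverse logistic CDF ``F^{-1}(p) = log(p / (1 - p))`` for p in (0, 1)."""
    return _logit(p)


def bernoulli_loglik(y, u):
    """Sum of Bernoulli log-likelihood terms with logit ``u``.

    ``y`` is a 0/1 array of outcomes; ``u`` may be broadcast against it.
    Uses ``y*u - log(1 + e^u)`` which is stable in both tails.
    """
    y = np.asarray(y, dtype=float)
    return y * u - np.logaddexp(0.0, u)
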