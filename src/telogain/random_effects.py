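"""Random-effects extension: between-individual variation in attrition rate.

The fixed-effect model assumes every individual loses telomere length at
the same rate. Real cohorts vary: let individual i's true rate be
``rate_i ~ Normal(mu_rate, sigma_between)``, so the true change over T
years is ``rate_i * T`` and the measured change adds independent
``Normal(0, sigma_d)`` noise. The measured change is then normal with mean
``-mu_rate * T`` and variance ``sigma_between^2 * T^2 + sigma_d^2``, giving

    P(gain) = Phi(-mu_rate * T / sqrt(sigma_between^2 T^2 + sigma_d^2)).

With ``sigma_between = 0`` this reduces exactly to the fixed-effect model;
any ``sigma_between > 0`` inflates the predicted gainer percentage (for
``mu_rate > 0``), because part of the population now truly loses little or
even gains. As T grows the measurement term washes out and the probability
tends to ``Phi(-mu_rate / sigma_between)`` — the fraction of true
biological gainers in the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["MixedModelParams", "mixed_gainer_probability", "estimate_sigma_between"]


@dataclass(frozen=True)
class MixedModelParams:
    """Parameters of the mixed (random-rate) misclassification model.

    mu_rate : mean attrition rate (TL units/yr, positive = shortening)
    sigma_between : SD of the per-individual true rate (TL units/yr)
    followup_years : follow-up duration T
    sigma_d : SD of the measured baseline-to-follow-up difference (TL units)
    """

    mu_rate: float
    sigma_between: float
    followup_years: float
    sigma_d: float

    def __post_init__(self) -> None:
        if self.sigma_between < 0:
            raise ValueError("sigma_between must be >= 0")
        if self.sigma_d < 0:
            raise ValueError("sigma_d must be >= 0")
        if not self.followup_years > 0:
            raise ValueError("followup_years must be > 0")
        if self.sigma_between == 0 and self.sigma_d == 0:
            raise ValueError("degenerate model: sigma_between and sigma_d both zero")


def mixed_gainer_probability(params: MixedModelParams) -> float:
    """Probability of an apparent gain when true rates vary between individuals.

    Returns ``Phi(-mu_rate*T / sqrt(sigma_between^2 T^2 + sigma_d^2))``.
    Equals the fixed-effect ``gainer_probability(mu_rate*T, sigma_d)`` when
    ``sigma_between = 0`` and is strictly larger for any
    ``sigma_between > 0`` with ``mu_rate > 0``. Note that with
    ``sigma_between > 0`` a positive measured change may reflect a genuine
    biological gainer, not only measurement error.
    """
    t = params.followup_years
    total_sd = float(np.hypot(params.sigma_between * t, params.sigma_d))
    return float(norm.sf(params.mu_rate * t / total_sd))


def estimate_sigma_between(
    observed_changes,
    sigma_d: float,
    followup_years: float,
) -> float:
    """Method-of-moments estimate of the between-individual rate SD.

    The variance of measured changes decomposes as
    ``sigma_between^2 * T^2 + sigma_d^2``, so
    ``sigma_between = sqrt(max(0, var(changes) - sigma_d^2)) / T`` using the
    unbiased (n-1) sample variance, clamped at zero when measurement error
    alone explains the observed spread.
    """
    if not followup_years > 0:
        raise ValueError("followup_years must be > 0")
    if sigma_d < 0:
        raise ValueError("sigma_d must be >= 0")
    changes = np.asarray(observed_changes, dtype=float)
    if changes.size < 2:
        raise ValueError("need at least 2 observed changes")
    excess = np.var(changes, ddof=1) - sigma_d**2
    return float(np.sqrt(max(0.0, excess)) / followup_years)
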