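"""Exponential progression model.

Tumour progression times are modelled as exponential with rate
``hazard = ln(2) / median_ttp`` (months^-1), so the distribution is pinned
down by the clinician-facing median time to progression (TTP).  Early
progressive disease (EPD) -- progression already present at the first
post-baseline tumour measurement at ``t_first`` months -- then has
probability

    P(EPD) = 1 - exp(-hazard * t_first) = 1 - 2**(-t_first / median_ttp),

which is how a stated median TTP is interpolated back to an expected EPD
rate for the stage-I futility rule.  All times are in months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

LN2 = math.log(2.0)

__all__ = [
    "LN2",
    "ProgressionModel",
    "median_to_hazard",
    "hazard_to_median",
    "epd_probability",
    "sample_ttp",
]


def median_to_hazard(median_ttp: float) -> float:
    """Exponential hazard rate (per month) for a given median TTP (months)."""
    if not median_ttp > 0:
        raise InvalidParameterError(
            f"median_ttp must be positive, got {median_ttp!r}"
        )
    return LN2 / median_ttp


def hazard_to_median(hazard: float) -> float:
    """Median TTP (months) for a given exponential hazard rate (per month)."""
    if not hazard > 0:
        raise InvalidParameterError(f"hazard must be positive, got {hazard!r}")
    return LN2 / hazard


def epd_probability(median_ttp: float, t_first: float) -> float:
    """Probability of early progressive disease at the first measurement.

    Parameters
    ----------
    median_ttp
        True median time to progression, months (> 0).
    t_first
        Time of the first post-baseline tumour measurement, months (> 0).

    Returns
    -------
    float
        ``1 - 2**(-t_first / median_ttp)``, strictly inside (0, 1).
    """
    if not median_ttp > 0:
        raise InvalidParameterError(
            f"median_ttp must be positive, got {median_ttp!r}"
        )
    if not t_first > 0:
        raise InvalidParameterError(f"t_first must be positive, got {t_first!r}")
    return -math.expm1(-LN2 * t_first / median_ttp)


def sample_ttp(hazard: float, rng: np.random.Generator, size=None):
    """Draw exponential progression times (months) with the given rate.

    The empirical median over many draws converges to ``ln(2)/hazard``.
    """
    if not hazard > 0:
        raise InvalidParameterError(f"hazard must be positive, got {hazard!r}")
    return rng.exponential(scale=1.0 / hazard, size=size)


@dataclass(frozen=True)
class ProgressionModel:
    """Exponential progression law for one true median TTP.

    ``hazard`` is derived, never supplied: the median determines the rate
    exactly and the two round-trip through :func:`median_to_hazard` /
    :func:`hazard_to_median`.
    """

    median_ttp: float
    t_first: float
    hazard: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hazard", median_to_hazard(self.median_ttp))
        if not self.t_first > 0:
            raise InvalidParameterError(
                f"t_first must be positive, got {self.t_first!r}"
            )

    @property
    def epd_probability(self) -> float:
        return epd_probability(self.median_ttp, self.t_first)

    def sample(self, rng: np.random.Generator, size=None):
        return sample_ttp(self.hazard, rng, size=size)
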