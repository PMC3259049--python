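"""Monte-Carlo operating characteristics of a fixed stopping rule.

The null hypothesis states the drug is uninteresting on both axes
(``r <= r_nul`` and ``median ttp <= ttp_nul``); the alternative states it
is interesting on either (``r >= r_alt`` or ``ttp >= ttp_alt``).  Alpha is
estimated at the boundary null scenario (RR = r_nul, median = ttp_nul).
Power is estimated under a 50/50 mixture of alternatives: half the
replicates set RR = r_alt with the median drawn uniformly between the
configured floor and ttp_alt, the other half set median = ttp_alt with RR
drawn uniformly below r_alt -- the drug is assumed equally likely to act
through response or through progression delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .exceptions import InvalidConfigurationError, InvalidParameterError
from .progression import epd_probability
from .simulate import StoppingRules, TrialBank, TrialConfig, simulate_bank

__all__ = [
    "DesignHypotheses",
    "OperatingCharacteristics",
    "RejectionEstimate",
    "rejection_probability",
    "alt_mixture_power",
    "operating_characteristics",
    "mixture_parameters",
]


@dataclass(frozen=True)
class DesignHypotheses:
    """Clinician-facing design hypotheses.

    ``r_nul``/``ttp_nul`` are the response rate and median TTP (months) of
    disinterest, ``r_alt``/``ttp_alt`` those of interest.  The matching EPD
    probabilities are derived from the exponential progression law at the
    first-measurement time and are what the stage-I rule thresholds.
    """

    r_nul: float
    r_alt: float
    ttp_nul: float
    ttp_alt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_nul < self.r_alt <= 1.0:
            raise InvalidConfigurationError(
                f"need 0 <= r_nul < r_alt <= 1, got r_nul={self.r_nul!r}, r_alt={self.r_alt!r}"
            )
        if not 0.0 < self.ttp_nul < self.ttp_alt:
            raise InvalidConfigurationError(
                f"need 0 < ttp_nul < ttp_alt, got ttp_nul={self.ttp_nul!r}, "
                f"ttp_alt={self.ttp_alt!r}"
            )

    def epd_nul(self, t_first: float) -> float:
        """EPD probability implied by the uninteresting median TTP."""
        return epd_probability(self.ttp_nul, t_first)

    def epd_alt(self, t_first: float) -> float:
        """EPD probability implied by the interesting median TTP."""
        return epd_probability(self.ttp_alt, t_first)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Simulated operating characteristics of one rule set.

    ``en_*`` follow the exact identity ``n1 + (1 - pes) * n2`` computed from
    the simulated stage-I stop fractions; pre-scan replacements are excluded
    there and reported separately via ``mean_enrolled_*``.
    """

    power: float
    alpha: float
    pes_nul: float
    pes_alt: float
    en_nul: float
    en_alt: float
    mc_se_power: float
    mc_se_alpha: float
    mc_se_pes_nul: float = math.nan
    mean_enrolled_nul: float = math.nan
    mean_enrolled_alt: float = math.nan
    n_sim: int = 0

    def __post_init__(self) -> None:
        for name in ("power", "alpha", "pes_nul", "pes_alt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v!r}")


class RejectionEstimate(NamedTuple):
    """Rejection and stage-I stop fractions with their MC standard errors."""

    reject: float
    stop: float
    se_reject: float
    se_stop: float


def _binom_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n)


def rejection_probability(
    rules: StoppingRules,
    true_rr: float,
    true_median: float,
    config: TrialConfig,
    rng: np.random.Generator,
    bank: Optional[TrialBank] = None,
) -> RejectionEstimate:
    """Fractions of ``config.n_sim`` trials rejecting the null / stopping early.

    A pre-simulated :class:`TrialBank` for the same scenario may be passed to
    avoid re-simulation (the thresholds are pure functions of its summaries).
    """
    if bank is None:
        bank = simulate_bank(true_rr, true_median, config, rng, n_sim=config.n_sim)
    n = bank.n_sim
    reject = float(bank.reject_mask(rules).mean())
    stop = float(bank.stop_mask(rules).mean())
    return RejectionEstimate(reject, stop, _binom_se(reject, n), _binom_se(stop, n))


def mixture_parameters(
    hyps: DesignHypotheses,
    config: TrialConfig,
    rng: np.random.Generator,
    n_sim: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (rr, median) draws for the 50/50 alternative mixture.

    The first half fixes RR = r_alt and draws the median uniformly on
    (min_median_ttp, ttp_alt); the second half fixes median = ttp_alt and
    draws RR uniformly on (0, r_alt).
    """
    if rng is None:
        rng = np.random.default_rng()
    if config.min_median_ttp >= hyps.ttp_alt:
        raise InvalidConfigurationError(
            f"min_median_ttp ({config.min_median_ttp}) must be below "
            f"ttp_alt ({hyps.ttp_alt})"
        )
    n = config.n_sim if n_sim is None else n_sim
    n_rr_half = n - n // 2
    n_ttp_half = n // 2
    rr = np.concatenate(
        [np.full(n_rr_half, hyps.r_alt), rng.uniform(0.0, hyps.r_alt, n_ttp_half)]
    )
    med = np.concatenate(
        [
            rng.uniform(config.min_median_ttp, hyps.ttp_alt, n_rr_half),
            np.full(n_ttp_half, hyps.ttp_alt),
        ]
    )
    return rr, med


def mixture_bank(
    hyps: DesignHypotheses,
    config: TrialConfig,
    rng: np.random.Generator,
    n_sim: Optional[int] = None,
) -> TrialBank:
    """Simulate a bank of trials under the 50/50 alternative mixture."""
    rr, med = mixture_parameters(hyps, config, rng, n_sim=n_sim)
    return simulate_bank(rr, med, config, rng)


def alt_mixture_power(
    rules: StoppingRules,
    hyps: DesignHypotheses,
    config: TrialConfig,
    rng: np.random.Generator,
    bank: Optional[TrialBank] = None,
) -> float:
    """Overall rejection fraction (power) under the alternative mixture."""
    if bank is None:
        bank = mixture_bank(hyps, config, rng)
    return float(bank.reject_mask(rules).mean())


def _mean_enrolled(bank: TrialBank, rules: StoppingRules) -> float:
    stop = bank.stop_mask(rules)
    enrolled = bank.n1 + bank.repl_stage1 + np.where(
        stop, 0, bank.n2 + bank.repl_stage2
    )
    return float(enrolled.mean())


def operating_characteristics(
    rules: StoppingRules,
    hyps: DesignHypotheses,
    config: TrialConfig,
    rng: np.random.Generator,
    null_bank: Optional[TrialBank] = None,
    alt_bank: Optional[TrialBank] = None,
) -> OperatingCharacteristics:
    """Full operating characteristics of one rule set.

    Alpha and the null stop probability come from the boundary null scenario
    (RR = r_nul, median = ttp_nul); power and the alternative stop
    probability from the 50/50 mixture.  Expected sample sizes use the exact
    identity ``EN = n1 + (1 - PES) * n2``.
    """
    if null_bank is None:
        null_bank = simulate_bank(
            hyps.r_nul, hyps.ttp_nul, config, rng, n_sim=config.n_sim
        )
    if alt_bank is None:
        alt_bank = mixture_bank(hyps, config, rng)

    alpha = float(null_bank.reject_mask(rules).mean())
    pes_nul = float(null_bank.stop_mask(rules).mean())
    power = float(alt_bank.reject_mask(rules).mean())
    pes_alt = float(alt_bank.stop_mask(rules).mean())
    n1, n2 = null_bank.n1, null_bank.n2
    return OperatingCharacteristics(
        power=power,
        alpha=alpha,
        pes_nul=pes_nul,
        pes_alt=pes_alt,
        en_nul=n1 + (1.0 - pes_nul) * n2,
        en_alt=n1 + (1.0 - pes_alt) * n2,
        mc_se_power=_binom_se(power, alt_bank.n_sim),
        mc_se_alpha=_binom_se(alpha, null_bank.n_sim),
        mc_se_pes_nul=_binom_se(pes_nul, null_bank.n_sim),
        mean_enrolled_nul=_mean_enrolled(null_bank, rules),
        mean_enrolled_alt=_mean_enrolled(alt_bank, rules),
        n_sim=null_bank.n_sim,
    )
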