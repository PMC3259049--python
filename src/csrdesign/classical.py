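"""Exact-binomial Simon optimal and Fleming two-stage designs.

These single-endpoint (response-rate only) designs are the classical
comparators for the combination stopping rule: they stop early far more
often under the null because they only need to differentiate one endpoint.
All error rates here are exact binomial sums, not simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import DesignInfeasibleError, InvalidParameterError

__all__ = [
    "ClassicalDesign",
    "binom_cdf",
    "simon_optimal",
    "fleming_two_stage",
]


@dataclass(frozen=True)
class ClassicalDesign:
    """A two-stage exact-binomial design on the response endpoint.

    Stage I enrolls ``n1`` patients and stops for futility if responses are
    <= ``r1_futility``; otherwise accrual continues to ``n_total`` and the
    null is rejected iff total responses >= ``r_reject``.  ``r1_reject`` is
    the optional stage-I rejection bound of group-sequential (Fleming)
    designs; Simon designs have none.
    """

    name: str
    n1: int
    r1_futility: int
    n_total: int
    r_reject: int
    alpha: float
    power: float
    pes_null: float
    en_null: float
    p0: float
    p1: float
    r1_reject: Optional[int] = None


def binom_cdf(k: int, n: int, p: float) -> float:
    """Exact cumulative binomial probability P(X <= k), X ~ Bin(n, p)."""
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise InvalidParameterError("k and n must be integers")
    if not 0 <= k <= n:
        raise InvalidParameterError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"p must lie in [0, 1], got {p!r}")
    return float(stats.binom.cdf(k, n, p))


def _check_p0_p1(p0: float, p1: float) -> None:
    if not 0.0 <= p0 < p1 <= 1.0:
        raise InvalidParameterError(f"need 0 <= p0 < p1 <= 1, got p0={p0!r}, p1={p1!r}")


def _two_stage_reject_prob(n1: int, n2: int, r1: int, r_reject: int, p: float) -> float:
    """P(X1 > r1 and X1 + X2 >= r_reject) by exact binomial sums."""
    x1 = np.arange(r1 + 1, n1 + 1)
    pmf1 = stats.binom.pmf(x1, n1, p)
    need = r_reject - x1  # responses still needed in stage II
    tail2 = np.where(need <= 0, 1.0, stats.binom.sf(need - 1, n2, p))
    return float(np.sum(pmf1 * tail2))


def simon_optimal(
    p0: float,
    p1: float,
    alpha_max: float = 0.05,
    beta_max: float = 0.20,
    n_max: int = 100,
) -> ClassicalDesign:
    """Simon (1989) optimal two-stage design by exhaustive exact search.

    Minimizes the expected sample size under the null, EN0 = n1 +
    (1 - P(X1 <= r1 | p0)) * n2, over all (n1, r1, n, r) with exact
    alpha <= alpha_max and power >= 1 - beta_max.  Ties in EN0 are broken
    by smaller total size, then smaller n1.
    """
    _check_p0_p1(p0, p1)
    best = None
    best_key = None
    for n in range(2, n_max + 1):
        for n1 in range(1, n):
            if best_key is not None and n1 >= best_key[0]:
                break  # EN0 >= n1 can no longer beat the incumbent
            n2 = n - n1
            pet0 = stats.binom.cdf(np.arange(0, n1), n1, p0)  # P(stop) per r1
            for r1 in range(0, n1):
                en0 = n1 + (1.0 - pet0[r1]) * n2
                if best_key is not None and en0 >= best_key[0]:
                    continue
                # smallest r_reject with alpha <= alpha_max (alpha decreasing in r)
                lo, hi = r1 + 1, n + 1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if _two_stage_reject_prob(n1, n2, r1, mid, p0) <= alpha_max:
                        hi = mid
                    else:
                        lo = mid + 1
                r_reject = lo
                if r_reject > n:
                    continue
                power = _two_stage_reject_prob(n1, n2, r1, r_reject, p1)
                if power < 1.0 - beta_max:
                    continue
                key = (en0, n, n1)
                if best_key is None or key < best_key:
                    best_key = key
                    best = ClassicalDesign(
                        name="simon-optimal",
                        n1=n1,
                        r1_futility=r1,
                        n_total=n,
                        r_reject=r_reject,
                        alpha=_two_stage_reject_prob(n1, n2, r1, r_reject, p0),
                        power=power,
                        pes_null=float(pet0[r1]),
                        en_null=float(en0),
                        p0=p0,
                        p1=p1,
                    )
    if best is None:
        raise DesignInfeasibleError(
            f"no Simon design with n <= {n_max} meets alpha <= {alpha_max}, "
            f"power >= {1 - beta_max}"
        )
    return best


def fleming_two_stage(
    p0: float,
    p1: float,
    n1: int,
    n2: int,
    alpha_nominal: float = 0.05,
    beta_nominal: float = 0.20,
) -> ClassicalDesign:
    """Fleming (1982) two-stage group-sequential single-arm design.

    Boundaries come from the single-stage normal-approximation critical
    value partitioned by stage, using two-sided critical values
    ``z_{1-alpha/2}`` and ``z_{1-beta/2}``: with cumulative size ``m`` at a
    stage and ``N = n1 + n2``,

        reject bound  r_m = floor(m*p0 + z_{1-a/2} * sqrt(N*p0*(1-p0))) + 1
        accept bound  a_m = floor(m*p1 - z_{1-b/2} * sqrt(N*p1*(1-p1)))

    (final acceptance bound forced to r_N - 1).  The reported alpha, power
    and early-stopping probability are exact binomial, not approximations.
    Early stopping (PES) counts futility acceptance only.
    """
    _check_p0_p1(p0, p1)
    if n1 < 1 or n2 < 0:
        raise InvalidParameterError(f"need n1 >= 1 and n2 >= 0, got n1={n1}, n2={n2}")
    if not (0.0 < alpha_nominal < 1.0 and 0.0 < beta_nominal < 1.0):
        raise InvalidParameterError("alpha_nominal and beta_nominal must lie in (0, 1)")
    n_total = n1 + n2
    z_a = stats.norm.ppf(1.0 - alpha_nominal / 2.0)
    z_b = stats.norm.ppf(1.0 - beta_nominal / 2.0)
    sd0 = np.sqrt(n_total * p0 * (1.0 - p0))
    sd1 = np.sqrt(n_total * p1 * (1.0 - p1))

    r_final = int(np.floor(n_total * p0 + z_a * sd0)) + 1
    if r_final > n_total:
        raise InvalidParameterError(
            "Fleming boundary construction failed: rejection bound exceeds n"
        )
    if n2 == 0:
        # single-stage exact binomial test
        alpha = float(stats.binom.sf(r_final - 1, n_total, p0))
        power = float(stats.binom.sf(r_final - 1, n_total, p1))
        return ClassicalDesign(
            name="fleming",
            n1=n1,
            r1_futility=r_final - 1,
            n_total=n_total,
            r_reject=r_final,
            alpha=alpha,
            power=power,
            pes_null=0.0,
            en_null=float(n_total),
            p0=p0,
            p1=p1,
            r1_reject=None,
        )

    r1_reject = int(np.floor(n1 * p0 + z_a * sd0)) + 1
    a1 = int(np.floor(n1 * p1 - z_b * sd1))
    a1 = min(a1, r1_reject - 1)
    r1_reject = min(r1_reject, n1 + 1)  # n1+1 means no stage-I rejection

    def _reject_prob(p: float) -> float:
        pmf1 = stats.binom.pmf(np.arange(0, n1 + 1), n1, p)
        prob = float(pmf1[r1_reject:].sum()) if r1_reject <= n1 else 0.0
        x1 = np.arange(max(a1 + 1, 0), min(r1_reject - 1, n1) + 1)
        if x1.size:
            need = r_final - x1
            tail2 = np.where(need <= 0, 1.0, stats.binom.sf(need - 1, n2, p))
            prob += float(np.sum(pmf1[x1] * tail2))
        return prob

    pes = binom_cdf(a1, n1, p0) if a1 >= 0 else 0.0
    return ClassicalDesign(
        name="fleming",
        n1=n1,
        r1_futility=a1,
        n_total=n_total,
        r_reject=r_final,
        alpha=_reject_prob(p0),
        power=_reject_prob(p1),
        pes_null=float(pes),
        en_null=n1 + (1.0 - float(pes)) * n2,
        p0=p0,
        p1=p1,
        r1_reject=r1_reject if r1_reject <= n1 else None,
    )
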