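"""Grid search for the combination stopping rule (CSR) thresholds.

The search runs in the order the rule is used in reverse: stage-II first,
stage-I second.

Stage II splits the alpha budget equally between the two endpoints.  The
responder bound is the smallest count whose exact binomial tail under the
null response rate is at most half of ``alpha_max`` -- a deterministic,
noise-free anchor (it is lowered, one patient at a time, only if the power
floor is unreachable with it).  The median-TTP bound is then calibrated by
simulation: the largest value on the 0.25-month grid keeping the mixture
power at or above the floor, i.e. the most stringent TTP threshold the
power requirement allows.  The overall alpha of the pair is estimated at
the boundary null scenario; if it exceeds ``alpha_max`` the design is
reported anyway with a warning (small trials with close hypotheses
genuinely cannot hold alpha) and no stage-I stopping is added, since error
rates must be maintained for the whole study before the trial is allowed
to stop early.

Stage I (alpha-feasible designs only) enumerates (responder, EPD) stop
pairs and keeps the one maximizing the probability of early stopping
under the null, subject to the overall mixture power staying within
Monte-Carlo resolution of the floor (power >= power_min - 2 SE).  Stage-I
stopping can only lower both power and alpha; when it costs so much power
that no stop pair survives, one stage-II relaxation round (one grid step
looser on either axis) is tried before falling back to the never-stop
sentinel.

All estimates across the whole grid are thresholded from a single
simulated bank per scenario, so the search is internally consistent and
orders of magnitude cheaper than re-simulating per candidate.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .evaluate import (
    DesignHypotheses,
    OperatingCharacteristics,
    mixture_bank,
    operating_characteristics,
)
from .exceptions import DesignInfeasibleError, DesignWarning
from .simulate import (
    GRID_EPS,
    StoppingRules,
    TrialBank,
    TrialConfig,
    simulate_bank,
    stream_rng,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Stage2Result",
    "Stage1Result",
    "DesignResult",
    "ttp_threshold_grid",
    "search_stage2",
    "search_stage1",
    "design_csr",
]

# Fixed stream offsets for the per-component RNGs derived from one seed.
STREAM_SEARCH_NULL = 1
STREAM_SEARCH_ALT = 2
STREAM_FINAL_NULL = 3
STREAM_FINAL_ALT = 4

#: Months searched above ttp_alt for the stage-II median threshold.
TTP_GRID_BUFFER = 2.0


class Stage2Result(NamedTuple):
    r2_reject: int
    ttp2_reject: float
    alpha: float
    power: float
    feasible: bool  # alpha_max met (False -> warning path, no stage-I rules)


class Stage1Result(NamedTuple):
    rules: StoppingRules
    pes_nul: float
    power: float
    alpha: float


class DesignResult(NamedTuple):
    rules: StoppingRules
    oc: OperatingCharacteristics
    info: dict


def ttp_threshold_grid(hyps: DesignHypotheses, config: TrialConfig) -> np.ndarray:
    """Candidate median-TTP thresholds: [ttp_nul, ttp_alt + 2] in 0.25 steps."""
    step = config.ttp_grid_step
    start = math.ceil(hyps.ttp_nul / step - GRID_EPS) * step
    stop = hyps.ttp_alt + TTP_GRID_BUFFER
    n_steps = int(math.floor((stop - start) / step + GRID_EPS))
    return np.round(start + step * np.arange(n_steps + 1), 6)


def binomial_response_bound(n: int, p0: float, tail_max: float) -> int:
    """Smallest r with exact binomial tail P(X >= r | n, p0) <= tail_max."""
    tails = stats.binom.sf(np.arange(0, n + 1) - 1, n, p0)  # P(X >= r), r=0..n
    ok = np.nonzero(tails <= tail_max)[0]
    return int(ok[0]) if ok.size else n + 1


def _reject_rate_row(bank: TrialBank, r2: int, grid: np.ndarray) -> np.ndarray:
    """P(r_total >= r2 or km >= t) for each grid t, one bank."""
    resp = bank.r_total >= r2
    km_ge = bank.km_median[None, :] >= grid[:, None] - GRID_EPS
    return (resp[None, :] | km_ge).mean(axis=1)


def search_stage2(
    hyps: DesignHypotheses,
    config: TrialConfig,
    rng: Optional[np.random.Generator] = None,
    null_bank: Optional[TrialBank] = None,
    alt_bank: Optional[TrialBank] = None,
) -> Stage2Result:
    """Select the stage-II thresholds (r2_reject, ttp2_reject).

    Alpha here excludes stage-I stopping (those rules are chosen later and
    can only decrease alpha).  Raises :class:`DesignInfeasibleError` when no
    threshold pair reaches the power floor at all; merely failing the alpha
    limit returns the selected pair with a :class:`DesignWarning`.
    """
    if null_bank is None:
        null_bank = simulate_bank(hyps.r_nul, hyps.ttp_nul, config, rng, config.n_sim)
    if alt_bank is None:
        alt_bank = mixture_bank(hyps, config, rng)

    grid = ttp_threshold_grid(hyps, config)
    r2 = binomial_response_bound(config.n_total, hyps.r_nul, config.alpha_max / 2.0)
    r2 = min(r2, config.n_total)
    logger.info(
        "stage-II: binomial response bound r2=%d (tail %.4f), TTP grid %.2f..%.2f",
        r2,
        float(stats.binom.sf(r2 - 1, config.n_total, hyps.r_nul)),
        grid[0],
        grid[-1],
    )
    while True:
        power_row = _reject_rate_row(alt_bank, r2, grid)
        ok = np.nonzero(power_row >= config.power_min)[0]
        if ok.size:
            break
        if r2 == 1:
            raise DesignInfeasibleError(
                "no stage-II threshold pair reaches the requested power "
                f"({config.power_min}) at n1={config.n1}, n2={config.n2}"
            )
        r2 -= 1  # response bound alone cannot carry the power; loosen it
        logger.info("stage-II: power unreachable, lowering response bound to %d", r2)

    j = int(ok[-1])  # most stringent TTP bound that retains the power floor
    ttp2 = float(grid[j])
    alpha = float(
        (
            (null_bank.r_total >= r2)
            | (null_bank.km_median >= ttp2 - GRID_EPS)
        ).mean()
    )
    feasible = alpha <= config.alpha_max
    if not feasible:
        warnings.warn(
            f"alpha limit {config.alpha_max} unattainable at this sample size; "
            f"best design has alpha ~ {alpha:.3f}",
            DesignWarning,
            stacklevel=2,
        )
    result = Stage2Result(
        r2_reject=r2,
        ttp2_reject=ttp2,
        alpha=alpha,
        power=float(power_row[j]),
        feasible=feasible,
    )
    if result.ttp2_reject > hyps.ttp_alt + GRID_EPS:
        warnings.warn(
            f"selected ttp2_reject={result.ttp2_reject} exceeds ttp_alt={hyps.ttp_alt}",
            DesignWarning,
            stacklevel=2,
        )
    logger.info(
        "stage-II selected r2>=%d, ttp>=%.2f (alpha %.4f, power %.4f, feasible=%s)",
        result.r2_reject,
        result.ttp2_reject,
        result.alpha,
        result.power,
        result.feasible,
    )
    return result


def search_stage1(
    stage2: tuple,
    hyps: DesignHypotheses,
    config: TrialConfig,
    rng: Optional[np.random.Generator] = None,
    null_bank: Optional[TrialBank] = None,
    alt_bank: Optional[TrialBank] = None,
) -> Stage1Result:
    """Select the stage-I stop thresholds (r1_stop, epd_stop).

    Maximizes the null early-stopping probability subject to the overall
    mixture power staying >= power_min - 2 MC standard errors (a hard
    cutoff at the floor would make the selection flip on simulation noise
    for rules whose true power sits at the boundary); overall alpha is
    re-estimated and reported (stage-I stopping can only reduce it).  Ties
    in PES prefer a smaller EPD threshold, then a larger responder
    threshold, keeping the stop decision driven by the progression signal.
    The never-stop sentinel (r1_stop=-1, epd_stop=n1+1) is always
    admissible.
    """
    r2_reject, ttp2_reject = int(stage2[0]), float(stage2[1])
    if null_bank is None:
        null_bank = simulate_bank(hyps.r_nul, hyps.ttp_nul, config, rng, config.n_sim)
    if alt_bank is None:
        alt_bank = mixture_bank(hyps, config, rng)

    n1 = config.n1
    rej2_null = (null_bank.r_total >= r2_reject) | (
        null_bank.km_median >= ttp2_reject - GRID_EPS
    )
    rej2_alt = (alt_bank.r_total >= r2_reject) | (
        alt_bank.km_median >= ttp2_reject - GRID_EPS
    )
    pm = config.power_min
    power_floor = pm - 2.0 * math.sqrt(pm * (1.0 - pm) / alt_bank.n_sim)

    best_key = None
    best = None  # (r1_stop, epd_stop, pes, power)
    for r1s in range(0, r2_reject):
        for es in range(0, n1 + 1):
            if r1s + es > n1 + 1:
                continue  # stage-I stop state unreachable
            stop_alt = (alt_bank.r1 <= r1s) & (alt_bank.epd1 >= es)
            power = float((~stop_alt & rej2_alt).mean())
            if power < power_floor:
                continue
            stop_null = (null_bank.r1 <= r1s) & (null_bank.epd1 >= es)
            pes = float(stop_null.mean())
            key = (pes, -es, r1s)
            if best_key is None or key > best_key:
                best_key = key
                best = (r1s, es, pes, power)

    if best is None or best[2] == 0.0:
        rules = StoppingRules(
            r1_stop=-1,
            epd_stop=n1 + 1,
            r2_reject=r2_reject,
            ttp2_reject=ttp2_reject,
        )
        pes = 0.0
        power = float(rej2_alt.mean())
    else:
        r1s, es, pes, power = best
        rules = StoppingRules(
            r1_stop=r1s, epd_stop=es, r2_reject=r2_reject, ttp2_reject=ttp2_reject
        )
    alpha = float((~null_bank.stop_mask(rules) & rej2_null).mean())
    logger.info(
        "stage-I selected r1<=%d, epd>=%d (PES_nul %.4f, power %.4f, alpha %.4f)",
        rules.r1_stop,
        rules.epd_stop,
        pes,
        power,
        alpha,
    )
    return Stage1Result(rules=rules, pes_nul=pes, power=power, alpha=alpha)


def design_csr(hyps: DesignHypotheses, config: TrialConfig) -> DesignResult:
    """Full CSR design: stage-II search, stage-I search, final evaluation.

    Deterministic given ``config.seed``: the search banks and the fresh
    banks used for the final operating characteristics come from fixed
    per-component RNG streams derived from that one seed.  When the alpha
    limit cannot be met, the minimum-alpha stage-II rule is returned with
    the never-stop sentinel at stage I (a design already exceeding its
    error limit is not degraded further by early stopping).
    """
    rng_null = stream_rng(config.seed, STREAM_SEARCH_NULL)
    rng_alt = stream_rng(config.seed, STREAM_SEARCH_ALT)
    null_bank = simulate_bank(hyps.r_nul, hyps.ttp_nul, config, rng_null, config.n_sim)
    # the power constraint is the one selection quantity whose Monte-Carlo
    # error can flip the chosen thresholds (candidate rules sit right at the
    # floor by construction), so the search-phase mixture bank is doubled
    alt_bank = mixture_bank(hyps, config, rng_alt, n_sim=2 * config.n_sim)
    logger.info(
        "derived EPD probabilities: epd_nul=%.4f, epd_alt=%.4f (t_first=%.2f)",
        hyps.epd_nul(config.t_first),
        hyps.epd_alt(config.t_first),
        config.t_first,
    )

    stage2 = search_stage2(hyps, config, null_bank=null_bank, alt_bank=alt_bank)
    if stage2.feasible:
        stage1 = search_stage1(
            stage2, hyps, config, null_bank=null_bank, alt_bank=alt_bank
        )
    else:
        stage1 = Stage1Result(
            rules=StoppingRules(
                r1_stop=-1,
                epd_stop=config.n1 + 1,
                r2_reject=stage2.r2_reject,
                ttp2_reject=stage2.ttp2_reject,
            ),
            pes_nul=0.0,
            power=stage2.power,
            alpha=stage2.alpha,
        )

    relaxed = False
    if stage2.feasible and stage1.pes_nul == 0.0:
        # adding any stage-I stop dropped power below the floor: allow one
        # grid step of stage-II loosening (more rejection headroom, higher
        # alpha) and retry, keeping the variant that stops most often
        grid = ttp_threshold_grid(hyps, config)
        candidates = []
        if stage2.r2_reject > 1:
            candidates.append((stage2.r2_reject - 1, stage2.ttp2_reject))
        looser_t = round(stage2.ttp2_reject - config.ttp_grid_step, 6)
        if looser_t >= grid[0] - GRID_EPS:
            candidates.append((stage2.r2_reject, looser_t))
        retries = [
            search_stage1(cand, hyps, config, null_bank=null_bank, alt_bank=alt_bank)
            for cand in candidates
        ]
        retries = [r for r in retries if r.pes_nul > 0.0]
        if retries:
            stage1 = max(retries, key=lambda r: (r.pes_nul, -r.alpha))
            relaxed = True
            logger.info(
                "stage-II relaxed one grid step to (r2>=%d, ttp>=%.2f)",
                stage1.rules.r2_reject,
                stage1.rules.ttp2_reject,
            )

    oc = operating_characteristics(
        stage1.rules,
        hyps,
        config,
        rng=None,
        null_bank=simulate_bank(
            hyps.r_nul,
            hyps.ttp_nul,
            config,
            stream_rng(config.seed, STREAM_FINAL_NULL),
            config.n_sim,
        ),
        alt_bank=mixture_bank(hyps, config, stream_rng(config.seed, STREAM_FINAL_ALT)),
    )
    info = {
        "stage2_alpha": stage2.alpha,
        "stage2_power": stage2.power,
        "alpha_feasible": stage2.feasible,
        "relaxed": relaxed,
        "epd_nul": hyps.epd_nul(config.t_first),
        "epd_alt": hyps.epd_alt(config.t_first),
    }
    return DesignResult(rules=stage1.rules, oc=oc, info=info)
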