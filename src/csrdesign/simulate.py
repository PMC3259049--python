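"""Patient-level simulation of a single-arm two-stage trial.

Each simulated patient carries an independent Bernoulli tumour response and
a latent exponential time to progression (TTP).  A patient may be censored
for the TTP endpoint: with probability ``censor_prob`` a censoring time is
drawn uniformly on ``(0, ttp)``, so the censoring event always precedes
progression.  Patients censored before the first tumour measurement at
``t_first`` never contribute an assessment and are replaced by a fresh
draw (their accrual is still counted); patients censored afterwards are
kept as right-censored observations.  Early progressive disease (EPD)
means progression observed at or before ``t_first`` in a non-responder --
response and EPD are mutually exclusive at the first assessment.

Two execution paths are provided: a readable per-patient path
(:func:`simulate_patient`, :func:`simulate_trial`) and a vectorized bank
(:func:`simulate_bank`) that simulates all replicate trials at once and is
the engine behind the threshold search.  The two are statistically
identical; tests assert their agreement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateConfigurationError,
    InvalidConfigurationError,
    InvalidParameterError,
)
from .progression import LN2

#: Sentinel for a Kaplan-Meier median beyond the observed follow-up.
NOT_REACHED = math.inf

#: Safety cap on the pre-scan replacement loop.
MAX_REPLACEMENTS = 10_000

#: Numerical slack for comparisons against the 0.25-month threshold grid.
GRID_EPS = 1e-9

__all__ = [
    "NOT_REACHED",
    "TrialConfig",
    "PatientOutcome",
    "TrialResult",
    "StoppingRules",
    "TrialBank",
    "simulate_patient",
    "simulate_trial",
    "simulate_bank",
    "km_median",
    "stream_rng",
]


def stream_rng(seed: Optional[int], stream: int = 0) -> np.random.Generator:
    """Derive an independent generator from one top-level seed.

    Streams are children of ``SeedSequence([seed, stream])``, so adding a new
    consumer (a new ``stream`` number) never perturbs existing streams.
    """
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialConfig:
    """Operational parameters of the simulated trial.

    Parameters
    ----------
    n1, n2
        Stage-I and stage-II sample sizes (n1 >= 1, n2 >= 0).
    t_first
        Months from treatment start to the first tumour measurement.
    censor_prob
        Per-patient probability of being censored for the TTP endpoint.
    min_median_ttp
        Smallest median TTP (months) considered possible for any drug; also
        the lower bound of the alternative-mixture median draw.
    alpha_max, power_min
        Error limits for the design search.
    n_sim
        Monte-Carlo replicates per operating-characteristic estimate.
    ttp_grid_step
        Granularity of the median-TTP threshold grid (months).
    seed
        Top-level RNG seed; ``None`` means non-reproducible entropy.
    """

    n1: int
    n2: int
    t_first: float = 1.5
    censor_prob: float = 0.05
    min_median_ttp: float = 1.0
    alpha_max: float = 0.05
    power_min: float = 0.80
    n_sim: int = 100_000
    ttp_grid_step: float = 0.25
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if int(self.n1) != self.n1 or self.n1 < 1:
            raise InvalidParameterError(f"n1 must be an integer >= 1, got {self.n1!r}")
        if int(self.n2) != self.n2 or self.n2 < 0:
            raise InvalidParameterError(f"n2 must be an integer >= 0, got {self.n2!r}")
        object.__setattr__(self, "n1", int(self.n1))
        object.__setattr__(self, "n2", int(self.n2))
        if not self.t_first > 0:
            raise InvalidParameterError(f"t_first must be positive, got {self.t_first!r}")
        if not 0.0 <= self.censor_prob < 1.0:
            raise InvalidParameterError(
                f"censor_prob must lie in [0, 1), got {self.censor_prob!r}"
            )
        if not self.min_median_ttp > 0:
            raise InvalidParameterError(
                f"min_median_ttp must be positive, got {self.min_median_ttp!r}"
            )
        if not 0.0 < self.alpha_max < 1.0:
            raise InvalidParameterError(f"alpha_max must lie in (0, 1), got {self.alpha_max!r}")
        if not 0.0 < self.power_min < 1.0:
            raise InvalidParameterError(f"power_min must lie in (0, 1), got {self.power_min!r}")
        if self.n_sim < 1:
            raise InvalidParameterError(f"n_sim must be >= 1, got {self.n_sim!r}")
        if self.n_sim < 1000:
            warnings.warn(
                f"n_sim={self.n_sim} is very small; Monte-Carlo error will dominate",
                stacklevel=2,
            )
        if not self.ttp_grid_step > 0:
            raise InvalidParameterError(
                f"ttp_grid_step must be positive, got {self.ttp_grid_step!r}"
            )

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2

    def with_(self, **kwargs) -> "TrialConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StoppingRules:
    """The four thresholds defining the combination stopping rule.

    Stage I accepts the null (stops the trial) iff ``r1 <= r1_stop`` and
    ``epd1 >= epd_stop``.  Stage II rejects the null iff the cumulative
    responder count reaches ``r2_reject`` or the Kaplan-Meier median TTP
    reaches ``ttp2_reject`` months (a median never reached counts as
    exceeding any threshold).

    ``r1_stop = -1`` and/or ``epd_stop = n1 + 1`` make the stage-I stop
    unreachable (the "never stop" sentinel of small designs).
    """

    r1_stop: int
    epd_stop: int
    r2_reject: int
    ttp2_reject: float

    def __post_init__(self) -> None:
        if self.r1_stop < -1:
            raise InvalidParameterError(f"r1_stop must be >= -1, got {self.r1_stop!r}")
        if self.epd_stop < 0:
            raise InvalidParameterError(f"epd_stop must be >= 0, got {self.epd_stop!r}")
        if self.r2_reject < 1:
            raise InvalidParameterError(f"r2_reject must be >= 1, got {self.r2_reject!r}")
        if self.r1_stop >= self.r2_reject:
            raise InvalidParameterError(
                f"r1_stop ({self.r1_stop}) must be smaller than r2_reject ({self.r2_reject})"
            )
        if not self.ttp2_reject > 0:
            raise InvalidParameterError(
                f"ttp2_reject must be positive, got {self.ttp2_reject!r}"
            )

    def is_no_stop(self, n1: int) -> bool:
        """True if the stage-I stop state is unreachable for a stage of n1."""
        return self.r1_stop < 0 or self.epd_stop > n1


@dataclass(frozen=True)
class PatientOutcome:
    """One retained (non-replaced) patient."""

    response: bool
    ttp: float
    censor_time: Optional[float]
    observed_time: float
    event: bool
    epd: bool
    n_draws: int = 1  # accrual including replaced pre-scan dropouts


@dataclass(frozen=True)
class TrialResult:
    """Counts and decisions from one simulated trial."""

    r1: int
    epd1: int
    stopped_stage1: bool
    r_total: int
    km_median: float  # NOT_REACHED if the survivor curve never falls to 0.5,
    # nan if the trial stopped at stage I and no KM estimate was formed
    reject_null: bool
    n_enrolled: int


# ---------------------------------------------------------------------------
# Kaplan-Meier median
# ---------------------------------------------------------------------------


def km_median(
    observed_times: Sequence[float],
    events: Sequence[int],
    tie: str = "at_or_below",
) -> float:
    """Median of the Kaplan-Meier product-limit survivor estimate.

    With ``tie="at_or_below"`` (the conventional definition, also used by
    lifelines) the median is the smallest observed event time ``t`` with
    ``S(t) <= 0.5``; with ``tie="below"`` it is the smallest event time
    with ``S(t) < 0.5``, so a curve sitting exactly at one half does not
    yet count as having reached its median.  The two differ by one order
    statistic whenever the curve hits 0.5 exactly -- for an even number of
    uncensored subjects that is the typical case, not an edge case, and
    the trial decision engine uses the ``"below"`` reading (see
    :func:`simulate_trial`).  Returns :data:`NOT_REACHED` if the estimate
    never crosses (including the all-censored case).  Tied times follow
    the usual convention that events precede censorings.
    """
    t = np.asarray(observed_times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.ndim != 1 or t.shape != e.shape or t.size == 0:
        raise InvalidParameterError("times and events must be equal-length nonempty 1-d sequences")
    if np.any(t < 0):
        raise InvalidParameterError("observed times must be nonnegative")
    if tie not in ("at_or_below", "below"):
        raise InvalidParameterError(f"tie must be 'at_or_below' or 'below', got {tie!r}")
    return float(
        _km_median_matrix(t[None, :], e[None, :] > 0, below_half=(tie == "below"))[0]
    )


def _km_median_matrix(
    obs: np.ndarray, events: np.ndarray, below_half: bool = False
) -> np.ndarray:
    """Row-wise KM median for a (n_trials, n_patients) matrix.

    Subjects are sorted by time with events before censorings at ties; the
    product-limit factor ``1 - d/n`` is applied per subject with the at-risk
    count decremented one at a time, which reproduces the grouped estimator
    exactly for tied event times.
    """
    cens = ~events
    order = np.lexsort((cens, obs), axis=1)
    obs_s = np.take_along_axis(obs, order, axis=1)
    ev_s = np.take_along_axis(events, order, axis=1)
    n = obs.shape[1]
    at_risk = np.arange(n, 0, -1, dtype=float)
    surv = np.cumprod(1.0 - ev_s / at_risk, axis=1)
    if below_half:
        crossed = ev_s & (surv < 0.5 - GRID_EPS)
    else:
        crossed = ev_s & (surv <= 0.5 + GRID_EPS)
    any_cross = crossed.any(axis=1)
    first = crossed.argmax(axis=1)
    med = obs_s[np.arange(obs.shape[0]), first]
    return np.where(any_cross, med, NOT_REACHED)


# ---------------------------------------------------------------------------
# scalar (per-patient) path
# ---------------------------------------------------------------------------


def simulate_patient(
    true_rr: float,
    true_median_ttp: float,
    config: TrialConfig,
    rng: np.random.Generator,
) -> PatientOutcome:
    """Draw one retained patient, replacing pre-scan censored dropouts.

    Response ~ Bernoulli(true_rr) independent of ttp ~ Exp(ln2/median).
    With probability ``censor_prob`` the patient is censored at a time
    uniform on (0, ttp); if that happens before ``t_first`` the patient is
    replaced (the draw repeats) and the accrual counter grows.
    """
    if not 0.0 <= true_rr <= 1.0:
        raise InvalidParameterError(f"true_rr must lie in [0, 1], got {true_rr!r}")
    if not true_median_ttp > 0:
        raise InvalidParameterError(
            f"true_median_ttp must be positive, got {true_median_ttp!r}"
        )
    scale = true_median_ttp / LN2
    for draw in range(1, MAX_REPLACEMENTS + 1):
        response = rng.random() < true_rr
        ttp = rng.exponential(scale)
        censored = rng.random() < config.censor_prob
        censor_time = rng.random() * ttp if censored else None
        if censored and censor_time < config.t_first:
            continue  # off study before first measurement: replace
        observed_time = censor_time if censored else ttp
        event = not censored
        epd = event and ttp <= config.t_first and not response
        return PatientOutcome(
            response=response,
            ttp=ttp,
            censor_time=censor_time,
            observed_time=observed_time,
            event=event,
            epd=epd,
            n_draws=draw,
        )
    raise DegenerateConfigurationError(
        f"replacement loop exceeded {MAX_REPLACEMENTS} iterations; "
        "censoring configuration leaves almost no patient assessable"
    )


def simulate_trial(
    true_rr: float,
    true_median_ttp: float,
    rules: StoppingRules,
    config: TrialConfig,
    rng: np.random.Generator,
) -> TrialResult:
    """Run one two-stage trial under the given stopping rules.

    Stage I enrolls ``n1`` patients and accepts the null (stops) iff
    ``r1 <= rules.r1_stop`` and ``epd1 >= rules.epd_stop``.  Otherwise
    ``n2`` more patients are enrolled and the null is rejected iff the
    total responder count reaches ``r2_reject`` or the KM median TTP over
    all retained patients reaches ``ttp2_reject``.  Stage-I rejection of
    the null is not permitted.
    """
    stage1 = [
        simulate_patient(true_rr, true_median_ttp, config, rng)
        for _ in range(config.n1)
    ]
    r1 = sum(p.response for p in stage1)
    epd1 = sum(p.epd for p in stage1)
    n_enrolled = sum(p.n_draws for p in stage1)
    stopped = r1 <= rules.r1_stop and epd1 >= rules.epd_stop
    if stopped:
        return TrialResult(
            r1=r1,
            epd1=epd1,
            stopped_stage1=True,
            r_total=r1,
            km_median=math.nan,
            reject_null=False,
            n_enrolled=n_enrolled,
        )
    stage2 = [
        simulate_patient(true_rr, true_median_ttp, config, rng)
        for _ in range(config.n2)
    ]
    patients = stage1 + stage2
    r_total = sum(p.response for p in patients)
    n_enrolled += sum(p.n_draws for p in stage2)
    med = km_median(
        [p.observed_time for p in patients],
        [int(p.event) for p in patients],
        tie="below",
    )
    reject = r_total >= rules.r2_reject or med >= rules.ttp2_reject - GRID_EPS
    return TrialResult(
        r1=r1,
        epd1=epd1,
        stopped_stage1=False,
        r_total=r_total,
        km_median=med,
        reject_null=reject,
        n_enrolled=n_enrolled,
    )


# ---------------------------------------------------------------------------
# vectorized trial bank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialBank:
    """Per-trial summaries of many simulated trials, before any rule.

    The bank stores, for every replicate, the stage-I responder and EPD
    counts, the full-study responder count, and the KM median over all
    n1+n2 retained patients.  Any stopping rule is then a pure function of
    these summaries, so one bank can be thresholded many times -- the
    search re-uses a single bank across the whole threshold grid.
    """

    n1: int
    n2: int
    r1: np.ndarray
    epd1: np.ndarray
    r_total: np.ndarray
    km_median: np.ndarray
    repl_stage1: np.ndarray
    repl_stage2: np.ndarray

    @property
    def n_sim(self) -> int:
        return self.r1.shape[0]

    def stop_mask(self, rules: StoppingRules) -> np.ndarray:
        return (self.r1 <= rules.r1_stop) & (self.epd1 >= rules.epd_stop)

    def reject_mask(self, rules: StoppingRules) -> np.ndarray:
        stage2 = (self.r_total >= rules.r2_reject) | (
            self.km_median >= rules.ttp2_reject - GRID_EPS
        )
        return ~self.stop_mask(rules) & stage2

    def to_frame(self, rules: Optional[StoppingRules] = None) -> pd.DataFrame:
        """Per-trial debug dump; decisions included when rules are given."""
        df = pd.DataFrame(
            {
                "trial_id": np.arange(self.n_sim),
                "r1": self.r1,
                "epd1": self.epd1,
                "r_total": self.r_total,
                "km_median": self.km_median,
            }
        )
        if rules is not None:
            df["stopped"] = self.stop_mask(rules)
            df["reject"] = self.reject_mask(rules)
        return df


def simulate_bank(
    true_rr,
    true_median_ttp,
    config: TrialConfig,
    rng: np.random.Generator,
    n_sim: Optional[int] = None,
) -> TrialBank:
    """Simulate ``n_sim`` trials at once and return their summaries.

    ``true_rr`` and ``true_median_ttp`` may be scalars or per-trial arrays
    of length ``n_sim`` (the alternative mixture passes arrays).
    """
    if rng is None:
        rng = np.random.default_rng()
    rr = np.asarray(true_rr, dtype=float)
    med = np.asarray(true_median_ttp, dtype=float)
    if n_sim is None:
        n_sim = rr.shape[0] if rr.ndim else (med.shape[0] if med.ndim else config.n_sim)
    if rr.ndim == 0:
        rr = np.full(n_sim, float(rr))
    if med.ndim == 0:
        med = np.full(n_sim, float(med))
    if rr.shape != (n_sim,) or med.shape != (n_sim,):
        raise InvalidConfigurationError(
            "true_rr and true_median_ttp must be scalars or length-n_sim arrays"
        )
    if np.any((rr < 0) | (rr > 1)):
        raise InvalidParameterError("true_rr values must lie in [0, 1]")
    if np.any(med <= 0):
        raise InvalidParameterError("true_median_ttp values must be positive")

    n_tot = config.n_total
    shape = (n_sim, n_tot)
    scale = (med / LN2)[:, None]
    rr_full = rr[:, None]

    resp = rng.random(shape) < rr_full
    ttp = rng.exponential(1.0, shape) * scale
    if config.censor_prob > 0:
        cens = rng.random(shape) < config.censor_prob
        ctime = rng.random(shape) * ttp
    else:
        cens = np.zeros(shape, dtype=bool)
        ctime = np.zeros(shape)
    repl = np.zeros(shape, dtype=np.int64)
    needs = cens & (ctime < config.t_first)
    iters = 0
    while needs.any():
        iters += 1
        if iters > MAX_REPLACEMENTS:
            raise DegenerateConfigurationError(
                f"replacement loop exceeded {MAX_REPLACEMENTS} iterations; "
                "censoring configuration leaves almost no patient assessable"
            )
        rows, cols = np.nonzero(needs)
        repl[rows, cols] += 1
        k = rows.size
        new_resp = rng.random(k) < rr[rows]
        new_ttp = rng.exponential(1.0, k) * (med[rows] / LN2)
        new_cens = rng.random(k) < config.censor_prob
        new_ctime = rng.random(k) * new_ttp
        resp[rows, cols] = new_resp
        ttp[rows, cols] = new_ttp
        cens[rows, cols] = new_cens
        ctime[rows, cols] = new_ctime
        needs = np.zeros(shape, dtype=bool)
        needs[rows, cols] = new_cens & (new_ctime < config.t_first)

    events = ~cens
    obs = np.where(cens, ctime, ttp)
    epd = events & (ttp <= config.t_first) & ~resp

    n1 = config.n1
    return TrialBank(
        n1=n1,
        n2=config.n2,
        r1=resp[:, :n1].sum(axis=1),
        epd1=epd[:, :n1].sum(axis=1),
        r_total=resp.sum(axis=1),
        km_median=_km_median_matrix(obs, events, below_half=True),
        repl_stage1=repl[:, :n1].sum(axis=1),
        repl_stage2=repl[:, n1:].sum(axis=1),
    )
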