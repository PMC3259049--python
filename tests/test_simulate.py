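import math

import numpy as np
import pytest
from scipy import stats

import csrdesign.simulate as sim
from csrdesign import (
    DegenerateConfigurationError,
    InvalidParameterError,
    NOT_REACHED,
    StoppingRules,
    TrialConfig,
    epd_probability,
    km_median,
    simulate_bank,
    simulate_patient,
    simulate_trial,
    stream_rng,
)


# ---------------------------------------------------------------------------
# Kaplan-Meier median
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "times,events,expected",
    [
        ((1, 2, 3, 4, 5), (1, 1, 1, 1, 1), 3.0),  # S(3)=0.4 first <= 0.5
        ((1, 2, 3, 4), (1, 1, 1, 1), 2.0),  # S(2)=0.5 exactly
        ((1, 2, 3), (1, 0, 0), NOT_REACHED),  # S stuck at 2/3
        ((5, 1, 4, 2, 3), (1, 1, 1, 1, 1), 3.0),  # order-independent
        ((2.5, 2.5, 2.5), (0, 0, 0), NOT_REACHED),  # all censored
    ],
)
def test_km_median_hand_examples(times, events, expected):
    assert km_median(times, events) == expected


def test_km_median_below_half_convention():
    # at exactly S=0.5 the curve has not yet fallen below one half
    assert km_median((1, 2, 3, 4), (1, 1, 1, 1), tie="below") == 3.0
    assert km_median((1, 2, 3, 4, 5), (1, 1, 1, 1, 1), tie="below") == 3.0
    # a curve ending at exactly 0.5 never crosses under the strict reading
    assert km_median((1, 2), (1, 0), tie="at_or_below") == 1.0
    assert km_median((1, 2), (1, 0), tie="below") == NOT_REACHED


def test_km_median_tied_event_and_censor_times():
    # events precede censorings at ties: the patient censored at t=1 is still
    # at risk for the event at t=1, so S(1) = 3/4 and S(2) = 3/4 * 1/2 = 3/8
    assert km_median((1, 1, 2, 3), (1, 0, 1, 1)) == 2.0


def test_km_median_input_validation():
    with pytest.raises(InvalidParameterError):
        km_median([], [])
    with pytest.raises(InvalidParameterError):
        km_median([1, 2], [1])
    with pytest.raises(InvalidParameterError):
        km_median([-1, 2], [1, 1])
    with pytest.raises(InvalidParameterError):
        km_median([1, 2], [1, 1], tie="nearest")


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_km_median_matches_lifelines(seed):
    """Cross-check against the independent product-limit implementation."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(seed)
    n = 40
    t = rng.exponential(4.0, n).round(2)  # rounding forces ties
    c = rng.random(n) < 0.3
    obs = np.where(c, t * rng.random(n), t).round(2)
    ev = (~c).astype(int)
    kmf = lifelines.KaplanMeierFitter().fit(obs, ev)
    expected = kmf.median_survival_time_
    ours = km_median(obs, ev)
    if math.isinf(expected):
        assert ours == NOT_REACHED
    else:
        assert ours == pytest.approx(expected, abs=1e-9)


def test_mean_km_median_consistent_for_exponential(rng):
    """Mean KM median over many uncensored samples converges to the truth.

    At n = 200 the order-statistic bias of the product-limit median is
    below 0.01 months; at small n it is visibly negative (~ -0.07 at
    n = 30), which is inherent to the estimator, not an implementation
    artifact.
    """
    n_rep, n = 5_000, 200
    draws = rng.exponential(3.0 / math.log(2.0), (n_rep, n))
    meds = sim._km_median_matrix(draws, np.ones_like(draws, dtype=bool))
    assert np.isfinite(meds).all()
    assert meds.mean() == pytest.approx(3.0, abs=0.05)


# ---------------------------------------------------------------------------
# patient level
# ---------------------------------------------------------------------------


def test_responders_are_never_epd(rng):
    cfg = TrialConfig(n1=5, n2=5, censor_prob=0.0)
    for _ in range(200):
        p = simulate_patient(1.0, 0.1, cfg, rng)  # progression almost surely early
        assert p.response and not p.epd


def test_no_censoring_means_no_replacement(rng):
    cfg = TrialConfig(n1=10, n2=10, censor_prob=0.0)
    rules = StoppingRules(-1, cfg.n1 + 1, 1, 0.25)
    for _ in range(50):
        res = simulate_trial(0.2, 3.0, rules, cfg, rng)
        assert res.n_enrolled == cfg.n_total


def test_retained_censored_patients_are_past_first_scan(rng):
    cfg = TrialConfig(n1=5, n2=0, censor_prob=0.6, t_first=1.5)
    outcomes = [simulate_patient(0.1, 3.0, cfg, rng) for _ in range(500)]
    for p in outcomes:
        if not p.event:
            assert p.censor_time >= cfg.t_first
            assert p.observed_time == p.censor_time
        else:
            assert p.observed_time == p.ttp
        if p.epd:
            assert p.event and p.ttp <= cfg.t_first and not p.response
    assert any(p.n_draws > 1 for p in outcomes)  # replacements did occur


def test_epd_fraction_matches_progression_model(rng):
    """Without censoring the EPD rate among non-responders is the closed form."""
    cfg = TrialConfig(n1=30, n2=0, censor_prob=0.0, n_sim=3000)
    bank = simulate_bank(0.0, 3.0, cfg, rng, n_sim=3000)
    frac = bank.epd1.sum() / (3000 * 30)
    p = epd_probability(3.0, cfg.t_first)
    se = math.sqrt(p * (1 - p) / (3000 * 30))
    assert abs(frac - p) < 3 * se


def test_patient_parameter_validation(rng):
    cfg = TrialConfig(n1=5, n2=5)
    with pytest.raises(InvalidParameterError):
        simulate_patient(1.5, 3.0, cfg, rng)
    with pytest.raises(InvalidParameterError):
        simulate_patient(0.5, 0.0, cfg, rng)


def test_replacement_loop_safety_cap(rng, monkeypatch):
    monkeypatch.setattr(sim, "MAX_REPLACEMENTS", 5)
    cfg = TrialConfig(n1=5, n2=0, censor_prob=0.99, t_first=1e9)
    with pytest.raises(DegenerateConfigurationError):
        simulate_patient(0.0, 3.0, cfg, rng)
    with pytest.raises(DegenerateConfigurationError):
        simulate_bank(0.0, 3.0, cfg, rng, n_sim=200)


# ---------------------------------------------------------------------------
# trial level
# ---------------------------------------------------------------------------


def test_sentinel_rules_never_stop(rng):
    cfg = TrialConfig(n1=15, n2=15, n_sim=2000)
    bank = simulate_bank(0.05, 3.0, cfg, rng, n_sim=2000)
    never_r = StoppingRules(-1, 5, 5, 5.25)
    never_e = StoppingRules(0, cfg.n1 + 1, 5, 5.25)
    assert not bank.stop_mask(never_r).any()
    assert not bank.stop_mask(never_e).any()


def test_stage1_counts_within_bounds(rng):
    cfg = TrialConfig(n1=15, n2=15, censor_prob=0.05)
    rules = StoppingRules(0, 5, 5, 5.25)
    for _ in range(100):
        res = simulate_trial(0.2, 3.0, rules, cfg, rng)
        assert 0 <= res.r1 <= cfg.n1
        assert res.r1 + res.epd1 <= cfg.n1
        if res.stopped_stage1:
            assert res.r_total == res.r1
            assert not res.reject_null
            assert math.isnan(res.km_median)


def test_stage1_distribution_is_binomial(rng):
    """censor 0, n2 = 0: responder counts are exactly Binomial(n1, p)."""
    n1, p, n_sim = 15, 0.3, 100_000
    cfg = TrialConfig(n1=n1, n2=0, censor_prob=0.0, n_sim=n_sim)
    bank = simulate_bank(p, 3.0, cfg, rng, n_sim=n_sim)
    counts = np.bincount(bank.r1, minlength=n1 + 1)
    expected = stats.binom.pmf(np.arange(n1 + 1), n1, p) * n_sim
    # pool the sparse upper tail to keep expected cell counts > 5
    keep = expected > 5
    obs = np.append(counts[keep], counts[~keep].sum())
    exp = np.append(expected[keep], expected[~keep].sum())
    gof = stats.chisquare(obs, exp)
    assert gof.pvalue > 1e-4


def exact_stop_probability(n1, r1_stop, epd_stop, rr, median, t_first):
    """Exhaustive trinomial oracle for P(stage-I stop), censoring off.

    Each patient is responder / EPD / neither with probabilities
    (rr, (1-rr)*p_epd, rest); stop iff responders <= r1_stop and
    EPD count >= epd_stop.
    """
    p_epd = (1.0 - rr) * epd_probability(median, t_first)
    probs = [rr, p_epd, 1.0 - rr - p_epd]
    total = 0.0
    for r in range(0, min(r1_stop, n1) + 1):
        if r1_stop < 0:
            break
        for e in range(epd_stop, n1 - r + 1):
            total += stats.multinomial.pmf([r, e, n1 - r - e], n1, probs)
    return total


@pytest.mark.parametrize(
    "rr,median,r1_stop,epd_stop",
    [(0.05, 3.0, 0, 5), (0.2, 3.0, 1, 4), (0.05, 6.0, 0, 3), (0.1, 4.0, 2, 2)],
)
def test_stop_probability_matches_trinomial_oracle(rng, rr, median, r1_stop, epd_stop):
    n_sim = 50_000
    cfg = TrialConfig(n1=15, n2=0, censor_prob=0.0, n_sim=n_sim)
    bank = simulate_bank(rr, median, cfg, rng, n_sim=n_sim)
    rules = StoppingRules(r1_stop, epd_stop, cfg.n_total, 1e6)
    sim_stop = bank.stop_mask(rules).mean()
    exact = exact_stop_probability(15, r1_stop, epd_stop, rr, median, cfg.t_first)
    se = math.sqrt(exact * (1 - exact) / n_sim)
    assert abs(sim_stop - exact) < 3 * se + 1e-12


def test_scalar_and_vectorized_paths_agree(rng):
    """The per-patient and bank simulators estimate the same probabilities."""
    cfg = TrialConfig(n1=15, n2=15, censor_prob=0.05)
    rules = StoppingRules(0, 5, 5, 5.25)
    n_rep = 4000
    scalar = [simulate_trial(0.05, 3.0, rules, cfg, rng) for _ in range(n_rep)]
    bank = simulate_bank(0.05, 3.0, cfg, rng, n_sim=20_000)
    stop_s = np.mean([t.stopped_stage1 for t in scalar])
    stop_v = bank.stop_mask(rules).mean()
    se = math.sqrt(0.2 * 0.8 * (1 / n_rep + 1 / 20_000))
    assert abs(stop_s - stop_v) < 4 * se
    rej_s = np.mean([t.reject_null for t in scalar])
    rej_v = bank.reject_mask(rules).mean()
    se = math.sqrt(0.05 * 0.95 * (1 / n_rep + 1 / 20_000))
    assert abs(rej_s - rej_v) < 4 * se


def test_bank_is_deterministic_given_seed():
    cfg = TrialConfig(n1=10, n2=10, n_sim=2000)
    a = simulate_bank(0.1, 4.0, cfg, stream_rng(3, 1), n_sim=2000)
    b = simulate_bank(0.1, 4.0, cfg, stream_rng(3, 1), n_sim=2000)
    np.testing.assert_array_equal(a.r1, b.r1)
    np.testing.assert_array_equal(a.km_median, b.km_median)
    rules = StoppingRules(0, 4, 3, 4.0)
    r1 = simulate_trial(0.1, 4.0, rules, cfg, stream_rng(3, 2))
    r2 = simulate_trial(0.1, 4.0, rules, cfg, stream_rng(3, 2))
    assert r1 == r2


def test_bank_debug_frame(rng):
    cfg = TrialConfig(n1=5, n2=5, n_sim=1000)
    bank = simulate_bank(0.2, 3.0, cfg, rng, n_sim=1000)
    df = bank.to_frame(StoppingRules(0, 3, 3, 4.0))
    assert list(df.columns) == [
        "trial_id", "r1", "epd1", "r_total", "km_median", "stopped", "reject",
    ]
    assert len(df) == 1000
    assert (df.r1 + df.epd1 <= cfg.n1).all()


def test_config_validation():
    with pytest.raises(InvalidParameterError):
        TrialConfig(n1=0, n2=5)
    with pytest.raises(InvalidParameterError):
        TrialConfig(n1=5, n2=-1)
    with pytest.raises(InvalidParameterError):
        TrialConfig(n1=5, n2=5, censor_prob=1.0)
    with pytest.raises(InvalidParameterError):
        TrialConfig(n1=5, n2=5, t_first=0.0)
    with pytest.warns(UserWarning, match="n_sim"):
        TrialConfig(n1=5, n2=5, n_sim=10)


def test_rule_validation():
    with pytest.raises(InvalidParameterError):
        StoppingRules(5, 3, 5, 4.0)  # r1_stop must stay below r2_reject
    with pytest.raises(InvalidParameterError):
        StoppingRules(-2, 3, 5, 4.0)
    with pytest.raises(InvalidParameterError):
        StoppingRules(0, 3, 0, 4.0)
    assert StoppingRules(-1, 16, 5, 5.25).is_no_stop(15)
    assert not StoppingRules(0, 5, 5, 5.25).is_no_stop(15)
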