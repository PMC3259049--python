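# Methods

## The design problem

A single-arm two-stage phase II oncology trial usually screens a drug on
its objective response rate (RR) alone. Drugs that stabilize disease
without shrinking tumours fail such screens even when they meaningfully
delay progression. The combination stopping rule (CSR) implemented here
treats the drug as interesting if **either** endpoint clears its bar:

- **Null** (drug uninteresting): RR ≤ r_nul **and** median time to
  progression (TTP) ≤ ttp_nul.
- **Alternative** (drug interesting): RR ≥ r_alt **or** median TTP ≥
  ttp_alt.

The final decision after `n1 + n2` patients rejects the null iff the
cumulative responder count reaches `r2_reject` or the Kaplan-Meier (KM)
median TTP reaches `ttp2_reject` months. Waiting for median TTP on the
stage-I cohort would stall accrual, so the interim futility test instead
uses early progressive disease (EPD) — progression already present at the
first post-baseline scan — as the instant surrogate for a short TTP: the
trial stops (accepting the null) after `n1` patients iff the stage-I
responder count is ≤ `r1_stop` **and** the EPD count is ≥ `epd_stop`.
Early *rejection* of the null is never allowed.

## Progression model

TTP is exponential with hazard `ln 2 / median`, so a stated clinical
median pins the whole distribution, and

    P(EPD) = 1 − 2^(−t_first / median),

where `t_first` is the time of the first scan. This is how the
clinician-facing `ttp_nul`/`ttp_alt` are interpolated back to the EPD
probabilities the stage-I rule thresholds. Response is Bernoulli,
independent of the same patient's latent TTP; the two are mutually
exclusive *labels* at the first assessment (a responder is never counted
as EPD), but a responder's latent progression time still enters the KM
estimate unchanged. No association between an individual's response and
their TTP is modelled; single-arm designs only.

## Censoring and replacement

Each patient is censored for the TTP endpoint with probability
`censor_prob` (default 0.05). The censoring time is drawn uniformly on
(0, ttp), the simplest mechanism that guarantees censoring precedes
progression at the stated per-patient rate; published sensitivity to this
rate is low (doubling it changes results little), so the mechanism's fine
structure is not critical. Patients censored before `t_first` never
contribute an assessment and are replaced by fresh draws; their accrual is
tracked separately and excluded from the expected-sample-size identity
`EN = n1 + (1 − PES)·n2`.

## Kaplan-Meier median and its tie convention

The product-limit estimate is computed over all retained `n1 + n2`
patients, events preceding censorings at tied times. Two readings of "the
median" exist and they are *not* an edge case here: with an even number of
lightly censored patients the survivor curve hits 0.5 exactly in most
replicates, and

- `at_or_below` (the textbook/lifelines definition): smallest event time
  with S(t) ≤ 0.5;
- `below`: smallest event time with S(t) < 0.5, one order statistic later.

The public `km_median()` defaults to `at_or_below`. The trial decision
engine uses `below`: calibrating against the published operating
characteristics of six printed rule sets showed the original simulations
behave as if the curve must fall strictly under one half (e.g. the 15+15
design's power/alpha reproduce as 0.807/0.032 vs the printed 0.815/0.035
under `below`, but 0.775/0.025 under `at_or_below`; designs with odd total
n are insensitive, which is why only even-n rows discriminate). A KM median
that never crosses ("not reached") counts as exceeding any threshold — a
median beyond follow-up is evidence of long TTP, never of futility.

## Operating characteristics

- **Alpha** is the rejection fraction at the boundary null scenario
  (RR = r_nul, median = ttp_nul).
- **Power** is the rejection fraction under a 50/50 mixture of
  alternatives: half the replicates set RR = r_alt and draw the median
  uniformly on (`min_median_ttp`, ttp_alt); half set median = ttp_alt and
  draw RR uniformly on (0, r_alt). The drug is assumed equally likely to
  act through response or through progression delay, and the mixture
  deliberately contains marginal drugs, so power near the floor — not near
  one — is the expected outcome even for generous hypotheses. Uniform is
  the minimal-assumption law for the "below the interesting value" draws;
  `min_median_ttp` (default 1 month) is the smallest median any drug is
  assumed capable of.
- **PES** (probability of early stopping) and **EN** follow from the
  stage-I stop fraction; Monte-Carlo standard errors accompany every
  stochastic estimate.

## Threshold search

The search runs stage II first, stage I second, and thresholds a single
simulated bank of per-trial summaries across the whole grid (thresholds
are pure functions of those summaries), which makes the search orders of
magnitude cheaper than re-simulating per candidate and internally
consistent.

**Stage II.** The alpha budget is split equally between the endpoints.
The responder bound is the smallest count whose exact binomial tail under
r_nul is ≤ alpha_max/2 — deterministic and free of simulation noise; it is
lowered one patient at a time only if the power floor is unreachable with
it. The TTP bound is then the largest value on the 0.25-month grid
(spanning ttp_nul to ttp_alt + 2) that keeps the mixture power at or above
`power_min`: the most stringent TTP bar the power requirement allows,
which keeps the realized alpha well below its limit rather than hugging
it. If the resulting pair still exceeds alpha_max the design is returned
with a warning — small trials with close hypotheses genuinely cannot hold
alpha — and no stage-I stopping is added, since the study's error rates
must be maintained before it may stop early.

**Stage I.** Among all reachable (r1_stop, epd_stop) pairs, the one
maximizing PES under the null subject to the overall mixture power staying
≥ power_min − 2·SE_MC. The explicit Monte-Carlo slack matters: candidate
rules sit at the power boundary by construction, and a hard cutoff would
let estimation noise flip the selection. For the same reason the
search-phase mixture bank is twice `n_sim` (the admissibility constraint
is the one quantity whose error can change the answer; the final reported
operating characteristics come from fresh banks of `n_sim` per scenario).
Ties in PES prefer a smaller EPD threshold, then a larger responder
threshold, keeping the stop decision driven by the progression signal. If
no active pair survives, one relaxation round loosens stage II by a single
grid step on either axis (trading alpha for stoppability) before falling
back to the never-stop sentinel `(-1, n1+1)`.

## Classical comparators

`simon_optimal` is the exhaustive exact-binomial search minimizing the
expected null sample size subject to the alpha/power constraints (ties:
smaller total, then smaller first stage; default search cap n = 100).
`fleming_two_stage` builds the two-stage group-sequential boundaries from
the single-stage normal-approximation critical value partitioned by stage,
using two-sided critical values z₁₋α/₂ and z₁₋β/₂ — with one-sided values
the published 15+15 futility bound (stop only on zero responses) is not
reproduced, with two-sided it is exact. All reported error rates are exact
binomial sums regardless of how the boundaries were constructed; its PES
counts futility stops only.

## Defaults and units

All times are months. `t_first` defaults to 1.5 months (~6 weeks, a
standard restaging interval); this value also reproduces the published
stage-I stop probability analytically (P(Bin(15, 0.05) = 0) · P(EPD ≥ 5)
≈ 0.21) and remains user-configurable. `censor_prob` 0.05,
`min_median_ttp` 1.0 month, `alpha_max` 0.05, `power_min` 0.80, `n_sim`
100,000 (estimates at this size carry SE ≈ 0.0013 on a probability near
0.8; the full design search is typically run at 20,000 replicates, which
keeps a complete search under ten seconds on one core). The TTP threshold
grid step is 0.25 months; responder thresholds move in single patients.
One top-level seed drives everything; per-component generator streams are
derived from `SeedSequence([seed, stream])` with fixed stream numbers, so
adding a consumer never perturbs existing streams.

## What the simulator does and does not emulate

The generator reproduces the study conditions the design targets:
Bernoulli response, exponential progression, uniform-within-lifetime
censoring with pre-scan replacement, and scan-time EPD classification.
It does not model accrual calendars or suspension between stages,
administrative end of follow-up, non-exponential (e.g. Gompertz) growth,
response-TTP association within a patient, progression-free survival
(death as an event), or randomized comparisons. Passing tests therefore
demonstrate correctness of the design arithmetic under the stated model,
not robustness of the CSR to violations of exponentiality or informative
censoring in real trials.

## Known limitations

- The stage-I selection objective of the original program is not fully
  recoverable from its published tables; for designs whose alpha exceeds
  the limit by a wide margin the original sometimes prints small
  non-sentinel stage-I rules where this implementation returns the
  sentinel.
- The KM tie convention was inferred from published operating
  characteristics (see above); both conventions are exposed.
- Expected sample sizes exclude pre-scan replacements by definition of the
  EN identity; the separate `mean_enrolled_*` fields include them.
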