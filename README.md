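# csrdesign

Stopping-rule designs for single-arm, two-stage phase II oncology trials
whose drug may act by shrinking tumours **or** by stabilizing them.

## The problem

Phase II screens traditionally judge a drug by its response rate (RR)
alone, so a cytostatic agent with a 2% response rate but a long time to
progression (TTP) fails the screen. `csrdesign` implements a combination
stopping rule (CSR) whose hypotheses live on both endpoints:

- H₀ (uninteresting): r ≤ r_nul **and** median TTP ≤ ttp_nul
- H₁ (interesting):  r ≥ r_alt **or** median TTP ≥ ttp_alt

After `n1 + n2` patients, H₀ is rejected iff the responder count reaches
`r2_reject` or the Kaplan-Meier median TTP reaches `ttp2_reject` months.
Because waiting for the median TTP of the stage-I cohort would stall
accrual, the interim futility test instead uses **early progressive
disease** (EPD) — progression already present at the first scan, time
`t_first`. Under the exponential progression model, a stated median TTP
implies

    P(EPD) = 1 − 2^(−t_first / median),

so the clinician only ever specifies response rates and median TTPs; the
engine interpolates the EPD thresholds. The trial stops for futility after
`n1` patients iff responders ≤ `r1_stop` **and** EPD ≥ `epd_stop`.

Thresholds are calibrated by Monte-Carlo simulation (100,000 trials by
default): alpha at the boundary null (RR = r_nul, median = ttp_nul), power
under a 50/50 mixture of alternatives (half RR = r_alt with median drawn
below ttp_alt, half median = ttp_alt with RR drawn below r_alt). Exact
Simon optimal and Fleming two-stage designs are included as single-endpoint
comparators. See `docs/methods.md` for the model, its assumptions, and the
numerical conventions.

## Worked example

Design a 15 + 15 trial distinguishing RR 5% vs 20% and median TTP 3 vs 6
months:

```python
from csrdesign import DesignHypotheses, TrialConfig, design_csr

hyps = DesignHypotheses(r_nul=0.05, r_alt=0.20, ttp_nul=3.0, ttp_alt=6.0)
config = TrialConfig(n1=15, n2=15, n_sim=20_000, seed=0)
rules, oc, info = design_csr(hyps, config)
print(f"stage I : stop if responders <= {rules.r1_stop} and EPD >= {rules.epd_stop}")
print(f"stage II: reject H0 if responders >= {rules.r2_reject} "
      f"or KM median TTP >= {rules.ttp2_reject} months")
print(f"power {oc.power:.3f}  alpha {oc.alpha:.3f}  "
      f"PES_nul {oc.pes_nul:.3f}  EN_nul {oc.en_nul:.1f}")
```

prints

```
stage I : stop if responders <= 0 and EPD >= 5
stage II: reject H0 if responders >= 5 or KM median TTP >= 5.25 months
power 0.806  alpha 0.031  PES_nul 0.201  EN_nul 27.0
```

Read it as: at the end of stage I, zero responders together with five or
more early progressions stop the trial and accept H₀ (this happens for
20% of truly uninteresting drugs, so such trials enrol 27 patients on
average instead of 30). Otherwise the second stage accrues, and the drug
is declared active on five responders or an estimated median TTP of at
least 5.25 months. The design holds alpha at 0.031 with power 0.806
against the mixed alternative.

The same engine evaluates fixed rules (`evaluate`), and the exact
comparators are one call away — the Simon optimal design for the same
response hypotheses stops 60% of null trials after only 10 patients
(`simon_optimal(0.05, 0.20)` → n1 = 10, stop on 0 responses, n = 29,
PES 0.599, EN₀ 17.6), illustrating the price the CSR pays for watching
two endpoints at once.

### Command line

```sh
csrdesign design --r-nul 0.05 --r-alt 0.2 --ttp-nul 3 --ttp-alt 6 \
    --n1 15 --n2 15 --seed 1 --json-out design.json
csrdesign evaluate --config design.yaml --r1-stop 0 --epd-stop 5 \
    --r2-reject 5 --ttp2-reject 5.25
csrdesign classic simon --p0 0.05 --p1 0.2
csrdesign table --config batch.yaml --csv-out table.csv
```

Flags override config-file values; every run is fully reproducible from
its seed. Exit code 2 flags an invalid configuration, 3 an infeasible
design.

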