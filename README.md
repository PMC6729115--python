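# attriphase

Detection of dropout-attrition phases in item-by-item survey completion
data.

Web-based questionnaires lose participants mid-survey: someone starts, answers
a run of questions, and silently stops. Attrition of this kind is commonly
described in three phases — an initial *curiosity plateau* where retention
stays high, a *dropout phase* where exits spike, and a *stable use phase*
where the remaining, committed respondents finish. Locating the dropout phase
tells a survey methodologist which questions are shedding respondents (and
hence where the missing-data mechanism is likely tied to content), but doing
it by eye from a dropout plot is subjective. `attriphase` implements three
ways of doing it empirically, plus the simulation harness needed to measure
how well each one works.

## The methods

All three operate on monotone dropout records over a fixed grid of questions
1..K: participant i either completes the survey or exits at question
q_i, having answered questions 1..q_i − 1. The discrete hazard at question q
is h(q) = Pr(exit at q | reached q), estimated by d_q / n_q (dropouts at q
over participants at risk at q).

1. **User-specified thresholds** — the analyst states what dropout proportion
   is practically meaningful. The dropout phase starts at the first question
   whose dropout proportion strictly exceeds the start threshold and ends at
   the last question exceeding the end threshold (defaults: 3%/3% on the
   conditional, i.e. discrete-hazard, proportion).
2. **GLMM** — a logistic generalized linear mixed model of the cumulative
   indicator Y_iq = 1{participant i has dropped out by question q}, with one
   fixed effect per question (cell means, no intercept) and a normal
   participant random intercept: logit Pr(Y_iq = 1 | b_i) = β_q + b_i,
   b_i ~ N(0, σ²). Fitted by marginal maximum likelihood with Gauss–Hermite
   quadrature.
3. **DTSA** — discrete-time survival analysis of the exit time on
   person-period data, with a step-function baseline hazard (one dummy per
   question): logit h(q) = γ_q. The fit is the saturated closed form
   γ̂_q = logit(d_q / n_q).

For the two model-based methods, successive-difference contrasts test each
adjacent pair of coefficients (question q+1 vs q) with two-sided Wald z
tests; the K−1 p-values get a Benjamini–Hochberg false-discovery-rate
adjustment evaluated at the 5% level. The first and last significant pairs
mark the start and end of the dropout phase. No boundary found ⇒ one stable
phase; boundaries at the extreme ends of the scan ⇒ the dropout phase spans
the whole survey (also one phase); one interior boundary ⇒ two phases; two ⇒
three.

The evaluation module scores each method over replicate simulated surveys:
**type I error** = share of replicates detecting ≥ 2 phases when the
simulated hazard is constant, **sensitivity** = share detecting exactly the
true phase count when 2 or 3 phases exist.

## Worked example

```python
import numpy as np
import attriphase as ap

# three-phase attrition: stable hazard 0.01, severe dropout hazard 0.04 on
# questions 8-13, stable again from question 14
pattern = ap.make_pattern("three_phase", "severe", "middle", K=20)
dataset = ap.simulate_dataset(pattern, 200, np.random.default_rng(42))

summary = ap.summarize(dataset)           # per-question discrete hazards
det = ap.detect_threshold(dataset, ap.ThresholdConfig(0.03, 0.03))
print(det.start_question, det.end_question, det.n_phases)
```

Running the three detectors on that dataset prints:

```
true transitions: (8, 14)
completers: 138 of 200
threshold: start=9 end=13 phases=3 (ok)
     glmm: start=None end=None phases=1 (ok)
     dtsa: start=None end=None phases=1 (ok)
```

The 3% threshold scan brackets the simulated dropout phase (questions 8–13;
the first question's exceedance is a matter of sampling noise at n = 200),
while neither hypothesis-testing method finds any adjacent difference
significant after FDR adjustment on a single dataset of this size — the
sensitivity gap the simulation study quantifies.

The same is available from the shell:

```sh
attriphase simulate sim.yaml --out data/        # replicate dropout CSVs
attriphase detect data/replicate_00000.csv --method threshold --n-questions 20
attriphase study study.yaml --out study/        # full pattern x method grid
attriphase plot study/                          # boundary-choice histograms
```

Every command writes a `manifest.json` capturing the full configuration and
master seed, so runs are reproducible from the manifest alone.

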