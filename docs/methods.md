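# Methods

## Data model

A survey is an ordered battery of K ≥ 2 questions. Dropout is monotone: a
participant answers questions 1..q−1 and exits at question q (q = 1 means
they exited before answering anything), or completes all K. Skipping and
re-entry are not representable, and the package deliberately refuses
nonmonotone wide-format rows unless asked to coerce them to the first gap.
Three equivalent views are provided: dropout records (id, exit question),
the cumulative long format (K rows per participant, indicator "dropped out
by question q"), and the person-period format (one row per question reached,
event indicator in the final row). Exit questions are recoverable from
either long format, and round-trip tests enforce that.

The discrete hazard at question q is h(q) = d_q / n_q, the share of
participants at risk at q who exit there. The per-question "dropout
proportion" that the threshold method scans is this conditional quantity by
default. A marginal variant (d_q / N) is available, but conditional is the
default for two reasons: it is the quantity the survival model estimates,
and under a constant hazard the marginal proportion decays geometrically
with q, which would make late-survey exceedances of any fixed threshold
nearly impossible regardless of how severe the attrition is — contradicting
the intended reading of "constant severe attrition throughout".

## Detectors

**Threshold scan.** Start = first question with proportion strictly greater
than the start threshold; end = last question strictly exceeding the end
threshold. "Strictly" is deliberate: a proportion exactly at the threshold
does not trigger. Start and end thresholds may differ; if the resulting
boundaries are incoherent (possible only with unequal thresholds) the
detection is flagged degenerate rather than patched. Questions with nobody
left at risk terminate the scan range.

**GLMM.** Random-intercept logistic regression of the cumulative dropout
indicator with cell-means question effects (no global intercept), so the
successive-difference contrast β_{q+1} − β_q is directly the adjacent
difference of cumulative dropout on the logit scale. The marginal likelihood
integrates the random intercept by Gauss–Hermite quadrature (25 nodes;
participants collapse onto at most K+1 distinct exit patterns, so each
likelihood evaluation is O(K² · nodes) regardless of sample size) and is
maximised by L-BFGS-B with an analytic gradient, two deterministic restarts
from perturbed starts, and a projected-gradient convergence criterion. The
reported coefficient covariance is the inverse observed information of the
question effects at the optimum with the variance component held at its
estimate, the convention of standard mixed-model software whose contrast
tests this mirrors.

One property of this model is worth stating plainly: for perfectly monotone
trajectories the marginal likelihood increases in the random-intercept SD σ
without bound — as σ → ∞ with β/σ fixed the model tends to a latent
threshold model whose exit-pattern probabilities can match the saturated
multinomial fit, the supremum of any likelihood on these data. The MLE
therefore sits at infinity. The fit caps σ at 10 on the logit scale (an odds
ratio of e¹⁰ between typical participants, far beyond any practically
distinguishable heterogeneity), reports boundary estimates as converged, and
records σ̂ in the detection metadata. Contrast z statistics vary mildly with
the cap; there is no principled interior optimum to prefer, and the cap is
the documented, fixed choice. With σ fixed at 0 the model reduces exactly to
independent per-cell logistic regression, whose cell-means MLE is the
empirical logit — the oracle used by the test suite.

Questions whose cumulative dropout count is 0 or N are separated; their
coefficients are flagged non-estimable and pinned at ±30 (their likelihood
contribution is then negligible), and contrasts touching them are excluded.

**DTSA.** Bernoulli regression of the person-period event indicator with a
step-function baseline hazard — one dummy per question, no intercept, logit
link. The question dummies saturate the model, so the MLE is closed-form:
γ̂_q = logit(d_q / n_q) with Var(γ̂_q) = 1/(n_q h_q (1 − h_q)) and diagonal
covariance; the test suite verifies agreement with an iterative GLM fit to
10⁻⁶. Completers are censored after question K (K event-free rows).
Questions with 0 or all of their at-risk participants exiting are
non-estimable. A complementary log-log link is a deliberate non-feature: the
logit link is what makes the closed form exact and matches the GLMM.
Hazards are unweighted; no survey weights are applied.

**Inference.** Successive-difference contrasts (K−1 rows, each −1/+1 on an
adjacent pair), two-sided Wald z tests, Benjamini–Hochberg step-up
adjustment at α = 0.05 (delegated to statsmodels; a brute-force step-up
implementation is the test oracle). z rather than t reference distribution —
the saturated DTSA has no residual variance to estimate, and the GLMM's
effective degrees of freedom are ill-defined; a t option was considered and
rejected as false precision. Non-estimable comparisons are treated as not
significant and excluded from the BH family size m, keeping the procedure
defined on degenerate replicates instead of aborting them.

**Phase counting.** No boundaries ⇒ 1 phase. Start at the earliest
reportable position *and* end at the latest ⇒ the dropout phase spans the
survey ⇒ 1 phase. Exactly one interior boundary ⇒ 2 phases; both interior ⇒
3. The earliest reportable start is question 1 for the threshold scan but
question 2 for the contrast methods (the first adjacent pair is (1,2) and
boundaries use the pair's later index); the latest is K for all methods.

## The simulator and its calibration

Each simulated participant walks questions 1..K and exits at question q with
probability hazards[q], independently of everyone else; survivors of all K
complete. Replicate r of a batch draws from a child stream spawned from
`SeedSequence(master_seed)`, so batches are reproducible and replicate
streams are order-independent.

The preset patterns use three regime hazards: **stable 0.01**, **mild
dropout 0.03**, **severe dropout 0.04** per question. The default study
design is 200 participants × 20 questions per replicate. Transition presets
for K = 20: two-phase at question 5/10/15 (start/middle/end; stable-then-
dropout, or the reverse), three-phase at (8,14) middle, (4,10) one-start,
(11,17) one-end, (4,17) ends; other K scale proportionally. The stable and
severe rates were calibrated once, analytically, against the original
study's reported threshold-method operating characteristics under constant
attrition (type I error ≈ 0.19 at the 3% threshold under mild-constant, ≈
0.53 at 3% and ≈ 94% at 5% under severe-constant), since the study describes
its rates only verbally; with 0.01/0.04 all four of those numbers are
reproduced within Monte-Carlo error, which pins the calibration about as
tightly as the published values allow. The mild rate 0.03 sits between
them. All rates are config-overridable and every study cell echoes the
hazards it used.

What the generator emulates: monotone, content-independent dropout with
piecewise-constant hazards and independent participants. What it does not:
covariate-driven or informative missingness (MAR/MNAR mechanisms), question
skipping, hazard drift within a phase, or dependence between respondents.
Passing tests therefore demonstrate the methods' operating characteristics
under clean phase structure, not their behaviour when dropout is driven by
question content.

## Evaluation

Type I error: share of usable replicates detecting ≥ 2 phases under a
constant pattern. Sensitivity: share detecting exactly the true count (2 or
3). Replicates with failed or degenerate fits are excluded from the
denominator and reported; a `failed_as_negative` mode counts them as
non-detections instead, for sensitivity analyses. Boundary histograms count
the chosen start/end questions (with a "none" bin) over usable replicates.

Problem sizes: the package reruns threshold cells at 10,000 replicates and
the model-based cells at 500 (GLMM) and 1,000 (DTSA) replicates in
`scripts/acceptance.py` — binomial SE at worst ≈ 0.011 for the smallest cell
— and smaller counts in the test suite, chosen so the whole suite stays
fast enough to run habitually.

## Known limitations and discrepancies

* **DTSA type I error under constant attrition.** The original study
  reports 0.74–0.96 and notes its DTSA flagged the first two questions as
  significantly different even at hazard 0.001. Under a constant hazard
  every adjacent-hazard null is true, and a correctly specified saturated
  model with Wald/BH testing controls the familywise error; moreover, at
  n = 200 the per-question event counts are small enough that the
  logit-difference z statistic is conservative (measured null SD ≈ 0.93,
  essentially no mass beyond |z| = 3). This implementation accordingly
  yields type I error ≈ 0.00–0.05 in those cells and cannot reproduce the
  published inflation, which must stem from an implementation artifact the
  original report does not describe in reproducible detail. The diagnostic
  scenario (hazard 0.001) is kept in the test suite and runs clean.
* The GLMM's σ cap (above) means its contrast tests depend on a documented
  convention, not a well-identified variance estimate; this is a property
  of applying the model to deterministic monotone trajectories, not of the
  optimizer.
* Wald tests on empirical logits are first-order; no small-sample or
  continuity corrections are applied anywhere, matching the plain contrast
  machinery the methods are defined with.
* The threshold method's boundaries are sample statistics with no
  uncertainty attached; its "sensitivity" is entirely threshold-relative.
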