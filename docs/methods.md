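# Methods

This note documents the models, the synthetic data-generating process,
the numerical choices, and what the package's tests do and do not
establish.

## Outcome and discretization

The outcome is care location (routine ward vs ICU) per 6-hour period,
anchored at admission; the final window may be partial and is retained
(configurable). A window containing a care-location change anywhere in
its interior is labeled `transition` and excluded from training and
evaluation — the strictest reading of "exclude transitioning periods",
since the boundary rule is otherwise underdetermined. Horizon *j* of
origin window *k* targets window *k + 1 + j*, i.e. offsets >6j to 6(j+1)
hours beyond the origin window's end (half-open windows `[start, end)`).
An outcome is undefined (and the row dropped for that horizon) when the
target window falls after discharge or is itself a transition window.

Predictions are gated on new data: a row enters training/evaluation only
if at least one raw event (lab, vital, coma score, medication start or
end) occurred in its window. "New data element" is taken in the broadest
event-based sense.

## Features and imputation

Per window: min/max/mean for each of 30 labs, 6 vitals and the coma
score; exposure fraction-of-time and administration count for each of
143 medication classes; patient age. Lookback is per-slot (the current
block shifted by 1–4 windows) rather than pooled over 24 h — the richer
of the two readings, chosen because per-slot summaries preserve trend
information. The resulting vector has 1,986 entries.

Missing labs/vitals/coma values are imputed by last observation carried
forward within the encounter (past-only; a leakage test perturbs future
events and asserts earlier features unchanged), then by age-band normal
defaults (three bands: <12 months, 12–144, >144; heart and respiratory
rate defaults scaled by band). The defaults are placeholders standing in
for a published imputation table that is not reproduced here; the
strategy is isolated in `episodes.impute` and replaceable. Medication
features default to zero exposure, which is an observed value, not
missingness. Lookback slots reaching before admission are flagged
missing and filled with the defaults (zeros for medications).

Patients are split 75/13/12 (train/validation/test) by largest-remainder
rounding on shuffled patient ids; all periods of a patient share a
partition.

## Synthetic cohort generator

The generator's purpose is a population with known ground truth whose
*structure* matches the studied pediatric sample: 19.2% direct ICU
admissions, 3.0% routine→ICU transfers (of all admissions), 78.1% of ICU
admissions later stepped down, ~20.8% of 6-hour periods in ICU, hospital
LOS median ≈ 2.5 d (IQR ≈ 1.3–4.9), log-normal age with median 68
months. Where two published LOS figures conflict (2.4 vs 2.7 d median),
the defaults follow the higher, results-section figure; per-pathway
segment medians were then fixed once from the population table so that
period-level ICU occupancy lands at 20.8% (the printed cohort LOS values
cannot be matched simultaneously with the occupancy — ICU stays in the
real data are heavier-tailed than any log-normal fit to the printed
quartiles).

Latent severity is an hourly AR(1): s(t+1) = s(t) + κ(m(t) − s(t)) + σε,
κ = 0.12 h⁻¹, σ = 0.12, with location setpoints −1 (ward) and +1 (ICU)
and transfer thresholds +0.5 / −0.5 (hysteresis). Admission type and
transfer *propensity* are seeded draws at the configured rates — this is
what makes the realized fractions converge exactly — while transfer
*timing* is the first threshold crossing of the forward-simulated path:
a patient destined to deteriorate has a setpoint ramp toward
threshold + 0.8 (capped at a physiologic ceiling of 2.5) whose duration
is drawn from the pathway LOS distribution; the crossing, not the draw,
sets the transfer time. With zero volatility and unreachable thresholds
no transfers occur. 6% of ward admissions are "neuro-presentation"
patients with elevated initial severity that resolves on the ward —
these make the coma-score admission practice consequential.

A ward patient destined to transfer deteriorates along a ~2.2-day median
setpoint ramp; the severity-linked medication term is signed, so therapy
escalates as severity rises and is withdrawn as it falls (visible
de-escalation before ICU step-down). Neuro-presentation severity decays
to the ward setpoint within ~18 h (rapid resolution after ED treatment),
so persistently elevated ward severity remains a genuine transfer
signal.

Observables are reference-midpoint + coefficient × severity + noise,
clipped to configured physiologic ranges. Sampling frequency follows
care intensity: vitals ~hourly in ICU vs ~4-hourly on the ward, lab
panels ~6-hourly vs ~daily, matching the sparse-ward-data rationale for
6-hour windows. Medication classes are synthetic ids 1–143 with
per-location start probabilities per 6 h; a severity-linked subset (the
site's "escalation" drugs) gains 0.5 × s start probability per unit
severity (signed, clipped to [0, 1]). Race and sex are drawn at the
published proportions and never used as model features.

**Practice shifts.** A `SiteShift` may change only medication usage
(rates and which classes are severity-linked) and the coma-score bar for
direct ICU admission; physiology is untouchable by construction. The
default shift makes the reference site's ICU-marker classes (1–15)
ordinary ward drugs at the local site, makes classes 31–45 the local
ICU/escalation set, and raises the coma threshold by 2.5 points. The
medication swap is what degrades the transferred model's ranking: the
care-intensity fingerprint (sampling frequencies) is site-invariant and
dominates short-horizon prediction, so a shift that only removed
information would barely move AUROC; making reference evidence *misfire*
on local wards produces the robust directional gap. A
coma-threshold shift alone cannot produce an AUROC gap at all, because
AUROC is invariant to monotone relabeling of an unchanged severity
ranking.

What the generator does **not** emulate: within-patient analyte
correlation beyond the shared severity factor, circadian structure,
measurement batching artifacts, diagnosis coding, real medication
vocabularies, repeated ICU readmissions (at most one round trip per
stay). Passing tests therefore show the pipeline's statistical machinery
is correct and the transportability phenomenon is reproducible under a
known mechanism — not that the specific AUROC levels would hold on real
EHR data (the synthetic task is easier; discrimination here is ~0.95+
versus ~0.91–0.94 reported on real data).

## Classifiers and the growth protocol

Each horizon's classifier is a fully connected net (ReLU hidden layers,
logistic output) written in numpy: Glorot-uniform init, RMSprop
(ρ = 0.9) on the binary cross entropy, learning rate 2e-4, minibatches
of 10,000 rows at full scale — desk-scale runs shrink the minibatch to
`min(10000, n/10)` and the documented experiments use 1–2 hidden layers
of 16–32 nodes. Inputs are standardized with training-set statistics.

Training grows the architecture: starting from one hidden layer, node
counts increase along a geometric schedule (default 8→16→32→64→128)
while MCC, sensitivity, specificity, precision and NPV are monitored at
cutpoints 0.15/0.5/0.9 on train and validation. A candidate whose
train-minus-validation MCC gap (cutpoint 0.5) exceeds the drift
tolerance is overfit; the protocol then escalates L2 + dropout (ladder:
1e-4/0.10, then 1e-3/0.25) and retrains. When node growth stops
improving validation MCC the depth grows, up to five hidden layers;
training stops when regularization no longer rescues overfitting. The
best non-overfit candidate by validation MCC is kept; per-epoch
checkpoint selection also maximizes validation MCC. If no candidate ever
meets the drift tolerance, training warns and returns the
best-validation-MCC candidate instead of failing — an ambitious
tolerance should degrade gracefully, not abort. Degenerate confusion
matrices define MCC = 0.

The full-scale drift tolerance is 0.02 absolute MCC. At desk scale the
experiments use 0.10: with a few hundred validation *patients* (rows
within a patient are correlated), the train–validation MCC gap is
dominated by patient-level sampling noise, and a 0.02 rule rejects every
candidate for reasons unrelated to overfitting. Classification is
strict: ICU iff score > cutpoint (a score equal to the cutpoint is
routine).

## Calibration and audit

Raw validation scores are mapped to risk by logistic regression on a
cubic B-spline basis (5 interior knots at equally spaced quantiles of
the validation scores; boundary clamping makes the map total on [0, 1];
the fit is effectively unpenalized, C = 1e6). Monotonicity is not
enforced. The map is fitted on validation data only and applied
unchanged to test data.

The audit sorts records by calibrated risk and cuts equal-count
intervals of exactly 200 (the last absorbs the remainder, so every
interval has ≥200) — equal-count rather than equal-width, consistent
with reported interval counts implying near-equal occupancy. Per
interval: expected = mean risk, observed = outcome rate, an exact
binomial test of the observed count against the expected proportion
(the source names no specific two-proportion test), and Cohen's h. No
multiplicity correction, matching the raw per-interval significance
reporting. The summary regresses expected on observed
(slope/intercept/R²) and reports the percentage of intervals with
h < 0.2 and with p < 0.05.

## Evaluation suite

AUROC is computed by midranks (exactly the pairwise concordance with
ties at ½) with a DeLong structural-components variance for the 95% CI.
AUPRC is trapezoidal integration of the precision–recall curve over all
distinct thresholds; its CI is a normal interval on the logit scale with
SE ≈ √(A(1−A)/n_pos) — a pragmatic choice where only "a logit method" is
specified. Operating points carry Wilson CIs per rate; identities
(accuracy, F1, NNE) hold to 1e-12 and are property-tested.
Fixed-sensitivity (0.85/0.90/0.95/0.99) and fixed-specificity thresholds
scan all distinct score values, ties resolved toward the larger
(respectively smaller) threshold; reported rates may overshoot the
target due to score ties.

Transfer-cohort accuracy evaluates only patients who actually changed
location: for horizon j the patient must have spent ≥6(j+1) hours in the
origin location immediately before the transition window (so the
horizon-j origin window lies inside the residence) and that origin
window must pass the new-data gate; the prediction is correct iff the
horizon model at the *global* test-set threshold (fixed sensitivity 0.95
for ward→ICU, fixed specificity 0.95 for ICU→ward) predicts the
post-transfer location. Thresholds are not refit per cohort. Eligible
counts are non-increasing in horizon by construction.

## Local importance

Each explanation perturbs the record (Gaussian jitter scaled by
per-feature training SDs; Bernoulli flips are available for strictly
binary features, though the default feature matrix has none — exposure
fractions are continuous), queries the model, weights perturbations by
exp(−d²/w²) on standardized distance (w = 0.75√d), and fits a weighted
ridge surrogate (λ = 1, solved in the dual when perturbations < features;
1,000 perturbations by default). Ranks break ties by feature index.
Profiles count top-30 membership over the cases with calibrated risk in
0.245–0.255; two profiles are compared per covariate with Wilson CIs and
Cohen's h, flagging a practical difference iff the CIs are disjoint and
h > 0.2. Kernel width, sampling count and sparsity are declared
defaults, not inferred from any reference implementation.

## Problem sizes and budgets

Chosen once as the package's documented desk-scale conditions: the
two-site test fixture uses 2,500 admissions per site (≈45,000 periods
each) with the (16,)-node protocol; the zero-shift exchangeability check
uses 1,200 per site; population-structure checks use 20,000 admissions;
calibration-audit recovery uses n = 100,000 simulated records; oracle
equivalence uses 1,000 random instances of n ≤ 200. The acceptance
script runs 3,000 admissions per site and importance with 300
perturbations over ≤120 in-band cases per model. Generator defaults
(rates, severity parameters, panels) are never varied per run.

## Known limitations

A consequence of the generator's clean location structure deserves
emphasis: current care location is close to deterministic in the
observables (sampling cadence, medication mix, severity level), so the
per-horizon classifiers reach AUROC ≈ 0.96–0.99 and their score
distributions are strongly bimodal. Pre-transfer ward windows — severity
only mildly elevated 12–30 h before the crossing — sit in the thin
left tail of the positive-score distribution, and the fixed-sensitivity
thresholds set by the mass of easy positives usually miss them. The
transfer-cohort percent-correct is therefore far below what richer
clinical data can support; the analysis machinery itself (eligibility
rules, global thresholds, per-horizon denominators) is what the tests
certify, via exact toy trajectories.

- The synthetic task is easier than real EHR prediction (see generator
  non-goals), so absolute metric levels are optimistic; directional and
  identity results are the meaningful outputs.
- The spline calibration map is not constrained monotone; with few
  validation points in a score region it can locally invert ranks.
- The AUPRC CI uses an SE approximation, not an exact method.
- Imputation defaults are population midpoints, not the published
  imputation table.
- The numpy training loop is single-threaded BLAS-bound; full-scale
  (10,000-row minibatch, five hidden layers) runs are documented but not
  exercised by the test suite.
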