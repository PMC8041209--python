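# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `equicare`.

## Data model

The unit of analysis is the patient × six-month period. Each row carries
fasting plasma glucose (FPG, mg/dl), LDL cholesterol (mg/dl), age, gender, a
13-level insurance group, a diagnosis code, the two encounter counts, and a
ZIP identifier that joins six community covariates from a census-style
table: population, annual income, and the high-school, college, white and
African American percentages. Percentages enter all models as proportions in
[0, 1]; population, income, age, glucose and cholesterol enter through
natural logarithms where the design says so — coefficients of the printed
magnitudes are only interpretable on those scales.

Cohort rules: only code E11 (type 2 diabetes) is analysed; codes E08, E09,
E10 (secondary, drug-induced, type 1), O24 and E13 are excluded. A patient
must be observed in strictly more than 80% of the panel's period span
("more than" is taken literally: 5 of 6 periods qualifies at the 0.80
threshold, 4 of 6 does not). Gaps in a patient's period sequence break
transition chains; nothing is imputed. FPG states: N below 100 mg/dl, P
from 100 to 125 inclusive on both ends, D strictly above 125.

## Encounter model (zero-inflated Poisson)

The count mixture has a single scalar structural-zero probability π
(an intercept-only inflation component): the data motivate one inflation
level per model, not an inflation regression. The rate design has 26 terms:
intercept; lagged log cholesterol, lagged log glucose, log age, male;
clinical-cluster dummies 2–4 (cluster 1 reference); insurance dummies 2–13
(group 1 reference); and the six community terms. Reference levels follow
the convention that cluster 1 is the mildest stratum, insurance group 1 the
largest, and gender is coded as a male indicator.

Estimation maximises the exact mixture likelihood by BFGS with the analytic
gradient, parameterising π through its logit so the optimisation is
unconstrained. Covariates are standardized internally (the estimates and the
covariance are mapped back through the affine transform), which makes the
quasi-Newton iteration insensitive to the wildly different covariate scales
(log income ≈ 10.9 versus white share ≈ 0.44). The warm start is a plain
Poisson GLM plus an excess-zero moment estimate of π. Convergence is
declared when the infinity norm of the gradient of the *mean*
log-likelihood falls below 1e−6 (the mean scale keeps the criterion
comparable across sample sizes); 500 iterations maximum. Standard errors
come from the inverse observed information (finite-difference Hessian of
the analytic objective at the optimum); π's standard error uses the delta
method through the logit. Wald 95% intervals throughout. The linear
predictor is clipped at ±30 as an overflow guard.

Degenerate inputs raise: all-zero counts (rate unidentified), no zero
counts (π unidentified), rank-deficient designs. A zero-truncated Poisson
fit on the positive counts — the count half of a hurdle reading of the same
process — is the robustness variant; its likelihood divides out
1 − e^{−λ}.

Per-cluster refits drop the cluster dummies and any dummy without variation
in the stratum; a stratum with fewer than twice as many observations as
coefficients raises (the pipeline records such strata as skipped instead of
aborting a whole run over a secondary robustness fit).

The quartile contrast averages the model-implied mean count (1 − π)λ over
the rows of patients in the upper and lower quartiles of a sociodemographic
variable. Quartiles are patient-weighted — cut points are taken over the
per-patient values, not over ZIP codes, so populous ZIP codes count in
proportion to their patients — and boundary ties fall to the lower stratum.

## Transition model (pooled multinomial logit)

All nine transition types are pooled into one multinomial over
patient-period pairs with D→D as reference; the model is *not*
origin-conditional. The origin-conditional 3×3 matrix is provided as a
derived view, renormalising the pooled probabilities within each origin
state. The design has 21 terms per non-reference category: intercept,
physical and telephonic encounter counts (untransformed), log age, the
white, African American, high-school and college shares, log income, and
the twelve encounter × covariate products. There are deliberately no
gender, insurance, cluster or cholesterol terms in this model.

Estimation is full Newton–Raphson with the analytic gradient and Hessian on
internally standardized covariates, with a log-sum-exp softmax, a small
Levenberg damping term, a step-norm cap of 2 (full Newton steps from a cold
start can overshoot in weakly identified corners of the interaction
design), and backtracking line search. Convergence: gradient of the mean
log-likelihood below 1e−6 in infinity norm. A standardized coefficient
exceeding 30 flags (quasi-)complete separation; the flag is reported
alongside the fit rather than voiding it, because at small samples the
gradient can converge while one poorly populated category drifts to an
extreme log-odds. Standard errors are the inverse observed information.
Every one of the nine categories must be observed at least once, otherwise
the fit raises.

## Marginal effects and the combined contrast

For the softmax with reference category, the derivative of category
probability p_j with respect to covariate x_k is p_j (d_j − Σ_{j'} p_{j'}
d_{j'}), where d_j is the derivative of the j-th linear predictor (zero for
the reference). d_j runs through the interaction products: an encounter's
derivative includes its six interaction terms evaluated at the observation's
sociodemographics, and a sociodemographic's derivative includes its two
encounter interactions. Derivatives therefore sum to zero across the nine
categories by construction, and in the two-category collapse the expression
reduces to the familiar β·p(1−p).

The AME is the sample average of the pointwise derivatives. Covariates that
enter in logs are reported per natural unit via the chain rule
∂/∂x = (1/x)·∂/∂log x when requested through the `age` / `income` aliases;
the default reports effects on the design scale. Uncertainty comes from a
seeded patient-level bootstrap of the average with the fitted coefficients
held fixed (resampling patients, not refitting — the quantity of interest
is the averaging variability; refitting 500 times would conflate it with
estimation noise and is documented as out of scope). Probability changes
are reported as absolute percentage points. Quartile-stratified AMEs use the
same patient-weighted quartile rule as the encounter contrast.

The combined contrast chains the two models: step 1 computes the
model-implied expected-encounter gap between the lower and upper quartiles
of a sociodemographic variable (reported as lower minus upper, typically
negative); step 2 shifts every transition observation's encounter count by
that gap, re-expands the interaction products, and averages the per-type
probability changes, which sum to zero across the nine types. An
origin-conditional view of the same shift is emitted as a derived quantity,
since per-encounter effects on pooled nine-way probabilities and on
conditional rows answer slightly different questions.

## Stratification

K-means runs on standardized features (income and shares differ by five
orders of magnitude) from 25 random initialisations; each run's partition is
canonicalised by sorting clusters on their first-feature centroid, and the
most frequent canonical partition wins, with ties broken by lowest
within-SS. Cluster labels then follow the field conventions: socioeconomic
cluster 1 has the higher income, racial cluster 1 the higher white share,
clinical cluster 1 the lowest glucose (mildest). Clinical clustering uses
per-patient mean (glucose, cholesterol) by default, with a switch for
clustering patient-periods directly. Quality is summarised by between-SS /
total-SS about the grand mean (defined as 0 for a single cluster or zero
total SS), and stability by the mean pairwise label agreement across
starts.

## Synthetic-data generator

The generator emulates the study conditions the models were built for: 95
ZIP codes with income ≈ $55.8k ± 12.7k, population mean 6 742 with SD 9 618
(drawn lognormal to carry the skew while matching both moments; a clamped
normal would pile a quarter of the mass at the floor), high-school share
0.910 ± 0.056, college 0.226 ± 0.137, white 0.438 ± 0.030, African American
0.063 ± 0.041 (normal draws clamped to [0, 1], with black share capped at
1 − white). Patients are assigned to ZIP codes proportionally to
population; age ~ N(64.0, 11.1²) floored at 21; gender 50.3% male; 13
insurance groups with geometrically decaying shares (decay 0.62, matching a
patients-per-group coefficient of variation near 1.4); diagnosis codes at
the shares the cohort filters report (E11 50.4%, E08 23.3%, E09 13.1%, the
rest small); and 29.6% of patients receive a truncated contiguous
observation window (late joiners or dropouts) short enough for the
completeness filter to remove them.

Dynamics: the initial state is categorical over (N, P, D) with default
(0.25, 0.25, 0.50) — a diabetic cohort skews to D; no empirical initial
distribution being available, this is configurable. Continuous glucose is
uniform inside the destination state's band — [70, 100) for N, [100, 125]
for P, (125, 300] for D — the simplest sampler consistent with the
diagnostic bands. Cholesterol is lognormal around a severity-class mean
(145/145/213/191 mg/dl, log-SD 0.15), independent of the glucose
trajectory given the class, because no dependence structure between the two
biomarkers is specified anywhere; this is a stated non-feature. Encounters
in period t are drawn from the two ZIP mixtures at rates evaluated at the
period t−1 clinical measures (period 0 uses its own values; model fitting
only uses rows with a true lag). The next state is drawn from the
truth-implied origin-conditional probabilities — the pooled softmax
renormalised over the three types sharing the current origin.

Ground-truth defaults: the encounter-model coefficients take the magnitudes
seen in US clinic panels of this kind (education and income gradients of
order 4 and 0.4 on the proportion and log scales, a negative African
American-share gradient, log age near 2, π = 0.15 physical / 0.20
telephonic), with the two intercepts calibrated once, against the
generator itself, so the mixture means land near the cohort means of 3.97
and 3.01 encounters per six months. Transition-model truth uses modest
coefficients sized so that per-encounter average marginal effects land at a
few percentage points, with effective encounter slopes positive for the
favourable transitions (D→P, P→N, N→N) at the mean covariate profile; the
eight intercepts are solved once so that the conditional matrix at mean
covariates is diagonal-heavy (N row 0.60/0.30/0.10, P row 0.25/0.50/0.25, D
row 0.05/0.15/0.80). Copying published real-data interaction estimates
verbatim into the generator saturates the softmax at realistic encounter
counts, so the generative truth is deliberately *not* a transcription of
any published coefficient table.

A separate `recovery_ground_truth` exists for designed parameter-recovery
experiments: uniform insurance mix, complete panels, one diagnosis code,
and insurance effects of |τ| ≈ 0.5–0.65. Under the skewed cohort mix the
rarest insurance groups have standard errors up to 0.27 at n ≈ 12 000, so
no realistic coefficient there can be measured to within 10% of itself;
recovery is a statement about the estimator and is run on a design with
adequate information in every direction. The cohort-emulation defaults are
unchanged by this.

Randomness: one master seed per generated panel; independent substreams
(statics, clinical draws, encounters, transitions, missingness) via
`SeedSequence.spawn`, so the panel is bit-reproducible.

What passing tests on this generator do **not** show: real EMR panels have
informative missingness, measurement error in FPG, within-patient
correlation beyond the state dynamics, appointment-scheduling feedback
(sicker patients get booked more), and A1C-based diagnosis — none of which
are emulated. Parameter recovery here demonstrates that the estimators are
correct for the stated models, not that the models are correct for any
clinic's data.

## Problem sizes and verification

The recovery studies run 20 seeded replicates each: 2000 patients × 6
periods (≈ 10 000 lagged rows) for the encounter model and 10 000
transition observations for the multinomial — sizes chosen to mirror the
motivating cohort's scale while keeping a full verification run at a few
tens of seconds on one CPU. Analytic marginal effects are checked against
central finite differences (step 1e−6) on random parameter draws; the ZIP
likelihood at π = 0 is checked term-for-term against the Poisson
likelihood; both likelihoods are cross-checked against independent
implementations (statsmodels' zero-inflated Poisson and multinomial logit)
in the test suite. The pipeline writes only plain-text artifacts with
checksums in a manifest, and repeated runs under one seed are byte-identical
(run timings are logged but excluded from the manifest for exactly this
reason).

## Known limitations

- Patient-periods are pooled as independent in both models; no period fixed
  effects or within-patient correlation structure is estimated. This
  mirrors the modelling frame the package implements and is a real
  limitation for inference on strongly autocorrelated panels.
- The combined contrast is associational end to end; no causal claim is
  made or supported.
- The multinomial interaction design (168 free coefficients) needs on the
  order of a thousand transition observations; below that, quasi-separation
  is common and is flagged.
- Bootstrap AME uncertainty conditions on the fitted coefficients.
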