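# equicare

Modelling inequality in healthcare encounters and its consequences for
glucose control, on ZIP-code-linked diabetes panels.

Patients with type 2 diabetes interact with their care system through
physical and telephonic encounters. Encounter use is unequal across
communities, and encounters in turn shape whether a patient's fasting
plasma glucose (FPG) improves or worsens over time. `equicare` implements
the two-model analysis that quantifies both links on a six-month
patient-period panel, for biostatisticians and health-services researchers
who want to run it on their own EMR extracts — or study its statistical
behaviour on fully synthetic data with known ground truth, which this
package generates.

## The models

**Encounter model** — a zero-inflated Poisson (ZIP) regression of the
six-month encounter count *y* on lagged clinical, demographic, insurance and
community covariates:

```
P(y = 0) = π + (1 − π) e^{−λ},   P(y = k) = (1 − π) e^{−λ} λ^k / k!
log λ = β₀ + β₁ log Chol_{t−1} + β₂ log Gluc_{t−1} + β₃ log Age + β₄ Male
        + Σ αⱼ Cluster_j + Σ τ_k Insurance_k
        + γ₁ log Pop + γ₂ White% + γ₃ AfrAm% + γ₄ log Income
        + γ₅ HighSchool% + γ₆ College%
```

with a scalar structural-zero probability π. A zero-truncated Poisson fit on
the positive counts is the robustness variant.

**Transition model** — FPG is discretised into N (<100 mg/dl), P
(100–125 mg/dl) and D (>125 mg/dl). Consecutive periods define nine
transition types i→j, pooled into a multinomial logit with reference D→D:

```
log( P_{i→j} / P_{D→D} ) = α₀ + α₁ Phy + α₂ Tel + α₃ log Age + ... 
        + Phy × (sociodemographics) + Tel × (sociodemographics)
```

**Effects** — average marginal effects ∂p_j/∂x_k = p_j (d_j − Σ p_{j'} d_{j'})
averaged over the sample (with patient-level bootstrap SEs), quartile-
stratified AMEs, and a combined contrast that prices a sociodemographic
quartile gap in expected encounters through the encounter model and pushes
that encounter difference through the transition probabilities.

Patients and ZIP codes are stratified beforehand by multi-start K-means
(socioeconomic, racial, clinical), taking the most frequent partition over
25 random starts.

## Worked example

```python
import equicare as ec

zips = ec.generate_zip_table(95, seed=0)
truth = ec.recovery_ground_truth(seed=0)
panel = ec.generate_panel(2000, 6, zips, truth)
lagged, transitions, report = ec.prepare_panel(panel, zips)
lagged = lagged.assign(clinical_cluster=lagged["severity_class"])

zip_fit = ec.ZeroInflatedPoissonModel.from_panel(lagged, "phys_encounters").fit()
print(f"structural-zero probability pi = {zip_fit.pi:.3f} (truth 0.15)")
print(f"log-income coefficient = {zip_fit.params['log_income']:.3f} "
      f"+- {zip_fit.bse['log_income']:.3f} (truth 0.43)")

tfit = ec.GlucoseTransitionModel.from_transitions(transitions).fit()
ame = ec.average_marginal_effect(tfit, transitions, "phys_encounters",
                                 bootstrap_reps=200, seed=0)
combo = ec.combined_contrast(zip_fit, tfit, lagged, transitions,
                             "pct_highschool")
print(f"encounter gap (lower - upper high-school quartile): "
      f"{combo['encounter_delta']:.2f}")
print(f"P->D probability shift: "
      f"{100 * combo['transition_deltas']['P->D']:.2f} percentage points")
```

prints

```
structural-zero probability pi = 0.151 (truth 0.15)
log-income coefficient = 0.419 +- 0.020 (truth 0.43)
encounter gap (lower - upper high-school quartile): -1.74
P->D probability shift: 1.25 percentage points
```

The fitted inflation probability and the income gradient recover the
generating values within one to two standard errors. The combined contrast
says: moving from the upper to the lower quartile of ZIP-level high-school
graduation costs about 1.7 expected physical encounters per six months,
which raises the average probability of the unfavourable P→D transition by
about 1.3 percentage points under this synthetic truth.

A full pipeline run (simulate → prepare → cluster → fit → effects, with CSV
and JSON artifacts and a checksummed manifest) is available from the shell:

```bash
equicare run-all --seed 1 --out-dir runs/demo
```

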