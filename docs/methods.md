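# Methods

This note documents the model structure, the parameter defaults and their
provenance, the synthetic-registry generator and its limits, the numerical
choices that affect results, and the known limitations. Everything described
here is configurable through `evtcea.ParameterFileSet`; nothing is hard-coded
beyond the documented defaults.

## 1. Model structure

### 1.1 Health states and time zero

The simulation starts at **Day 90 after the index stroke**, with each patient
in one of the seven modified Rankin Scale (mRS) states 0–5 (alive, increasing
disability) or 6 (dead). The 90-day mRS distribution is a property of the
treatment strategy being simulated — it is where the entire treatment effect
of thrombectomy enters the model. Patients entering in mRS 6 are carried as a
death at t = 0: they accrue the index acute cost (the strategy was still
paid for) and nothing else.

### 1.2 Discrete-event simulation

From Day 90, each surviving patient faces four competing clocks in continuous
time:

| event | time-to-event model | consequence |
|---|---|---|
| recurrent ischaemic stroke | exponential (Gompertz optional) | fatal with probability `p_fatal_recurrent_stroke`; otherwise new mRS = max(current, drawn severity) |
| myocardial infarction (MI) | exponential | fatal with probability `p_fatal_mi`; otherwise survivor enters a post-MI cost state |
| cardiovascular (CVD) death | age/sex-indexed mortality table | death |
| non-CVD death | age/sex-indexed mortality table | death |

The earliest clock fires. Survivors of non-fatal events re-enter the loop
with all clocks resampled (memoryless renewal) and age advanced by the elapsed
time; simulation stops at death or the horizon (default 25 years). Recurrent
stroke severity is drawn from a configurable mRS distribution and can only
worsen the current state (a disability ratchet). Simultaneous clock
realisations are measure-zero; ties resolve deterministically in the order
non-CVD death, CVD death, recurrent stroke, MI (deaths win).

Two implementations share the same sampling formulas: `simulate_patient`
produces a full per-patient event trace for audit, and `simulate_cohort` runs
an arm as array operations. A test asserts that their means agree within
Monte-Carlo error.

### 1.3 Cohorts at simulation scale

Simulated cohorts are generated at the simulation size (default 50,000 per
strategy) **directly from each arm's marginal distributions**, not
bootstrap-resampled from the registry-sized arms. The registry at published
arm sizes (tens of patients per stratum) exists for the classification and
matching stages; resampling it to 50,000 would freeze its small-sample noise
into every arm contrast. Both constructions have identical marginals.

## 2. Time-to-event inputs

### 2.1 Composite MI/vascular-death calibration

Long-term cardiovascular risk enters as a combined MI/vascular-death process
with a 5-year cumulative incidence of **17.4%**. A constant hazard is
calibrated as `rate = −ln(1 − 0.174)/5 = 0.038232 per year`, which
round-trips exactly: `1 − exp(−rate·5) = 0.174`. The composite is split
**MI : vascular death = 0.45 : 0.55** (configurable `mi_fraction`): the MI
share becomes the exponential MI hazard; the vascular-death share anchors the
CVD column of the mortality table at the cohort reference age (§2.2). The
split itself is an assumed default — the composite total is the calibrated
quantity.

### 2.2 Background mortality table

The packaged table (`data/mortality.csv`) gives annual non-CVD and CVD death
hazards per sex for ages 18–100, piecewise constant over one-year bands, with
last-value extrapolation beyond the table. It is generated by
`make_default_mortality` with Gompertz-shaped age growth:

- reference age 69 (the cohort mean);
- CVD hazard at reference = 0.55 × 0.038232 ≈ 0.0210/year (the vascular-death
  share of the calibrated composite), growing at 7%/year of age;
- non-CVD hazard at reference = 0.031/year, growing at 9%/year of age;
- sex multipliers 1.15 (male) / 0.88 (female); hazards capped at 0.7/year.

The non-CVD anchor is the one **calibrated** default: it was chosen so the
medical-arm 5-year survival lands inside the band spanned by external
long-term stroke outcome anchors (51.8%, "over 50%", 49.4%), which is the
model's stated validation procedure. Under packaged defaults the medical arm
reproduces 52.5% 5-year survival and 1.96 discounted 5-year QALYs (anchors
2.07–2.21).

Death-time sampling inverts the piecewise-constant cumulative hazard: with
E ~ Exp(1), the death age solves H(age) = H(age₀) + E. A flat table therefore
reduces exactly to an exponential, which is tested.

### 2.3 Gompertz alternative

For scenario analysis the recurrent-stroke process can be Gompertz with
hazard `b·exp(a·t)`; sampling uses the closed-form inverse
`T = ln(1 − (a/b)·ln U)/a`. Negative shape gives a defective distribution
(total event probability `1 − exp(b/a)` < 1); draws beyond that mass return
+∞ (the event never happens). As `a → 0` the sampler reduces to the
exponential, verified by a Kolmogorov–Smirnov test.

## 3. Economics

All costs are **2018 Australian dollars** (a fixed 2018 conversion of
1 AUD = 0.75 USD is provided for reporting). Discounting is **continuous** at
3%/year: in a continuous-time simulation the natural present value of a
constant flow v over [t₁, t₂] is `v·(e^(−rt₁) − e^(−rt₂))/r`, and of a lump
at t is `v·e^(−rt)`. (Annual-compounding conventions differ from this by
< 0.05% at r = 0.03 and are not used.)

Accrual rules:

- **index acute cost**: lump at t = 0 per treatment arm (EVT arms include the
  procedure); the only cost accrued by Day-90 deaths;
- **annual management cost by mRS state** (plus a post-MI annual surcharge
  after any non-fatal MI): continuous flow while alive;
- **event lumps**: recurrent-stroke acute cost indexed by the post-event mRS
  (entry 6 = fatal recurrence), MI hospitalisation cost; discounted at the
  event time;
- **QALYs**: life-years weighted by mRS utility (state 6 = 0; values down to
  −0.2 permitted, must be non-increasing in mRS). A temporary utility
  decrement (default 0.10 for 1 year) applies after each non-fatal CVD event.
  Decrements **do not stack**: a new event restarts the window rather than
  adding a second decrement. The accountant enforces QALY ≤ LY ≤
  undiscounted LY on every trace.

## 4. Synthetic registry generator

Per arm, covariates are drawn independently from distributions fitted to
published baseline marginals:

- **age**: normal truncated to [18, 100] (a degenerate SD yields the mean);
- **sex, occlusion site, treatment, 90-day mRS**: categorical draws from the
  published proportions (probability vectors are renormalised exactly before
  sampling; a 1e-3 tolerance admits 4-decimal rounded published tables);
- **NIHSS**: negative binomial fitted to the published median/IQR by direct
  grid search over mean and dispersion (discrete quantiles make the objective
  piecewise constant, so gradient methods are unreliable), clipped to 0–42;
- **core and perfusion-lesion volumes**: log-normals fitted to median/IQR —
  the median pins μ = ln(median) and the IQR pins σ = ln(q75/q25)/(2·z₀.₇₅).
  A two-parameter log-normal pins the median and the quartile *ratio*; when
  the published median is not the geometric mid-point of the quartiles the
  individual quartiles shift slightly while their ratio is preserved;
- **perfusion clipped at core**: the generator enforces perfusion lesion ≥
  core so penumbra = perfusion − core ≥ 0, matching how the quantities are
  defined; the joint core/perfusion dependence is otherwise not identified by
  marginal tables;
- **onset-to-imaging**: normal truncated to (270, 1440] minutes — strictly
  beyond the 4.5-hour window, within 24 hours.

**Limitations**: covariates are mutually independent within an arm (no
age–NIHSS–volume correlation), and the 90-day mRS is drawn from the arm
marginal independently of covariates. The generator reproduces a baseline
*table*, not a joint distribution; classification rates and matching
behaviour that depend on covariate correlations will differ from the real
cohort.

### 4.1 Eligibility criteria

- **DEFUSE 3**: core < 70 ml AND perfusion/core ratio ≥ 1.8 AND mismatch
  volume (penumbra) ≥ 15 ml. A zero perfusion lesion cannot show target
  mismatch and classifies negative (with a warning); a zero core gives an
  infinite ratio. Shrinking the core at fixed perfusion lesion never removes
  eligibility (tested as a property).
- **DAWN** (clinical-core mismatch): NIHSS ≥ 10 and one of — age ≥ 80,
  NIHSS ≥ 10, core < 21 ml; age < 80, NIHSS ≥ 10, core < 31 ml; age < 80,
  NIHSS ≥ 20, core < 51 ml. Core caps are strict.
- **large core**: core > 70 ml (strict), mutually exclusive with DEFUSE 3
  positivity.

All thresholds live in `data/criteria.yaml`.

## 5. Propensity matching

Treatment assignment is modelled by maximum-likelihood logistic regression on
age, sex, NIHSS and core volume (statsmodels `Logit`; categorical covariates
binary-encoded). Perfect separation raises a diagnostic error naming the
separating covariate. Matching is greedy 1:1 nearest-neighbour on the score:
treated patients in descending score order, each taking the closest control,
optionally within a caliper, without replacement by default. Equidistant
controls are broken by a seeded shuffle, making results reproducible. Balance
is reported as standardized mean differences (SMD = mean difference / pooled
SD) before and after matching. Matching is a cohort-construction diagnostic
stage; the simulation arms are defined by criteria status and treatment, not
by the matched subsets.

## 6. Cost-effectiveness analysis

- **Incremental**: ΔC, ΔE, ICER = ΔC/ΔE (undefined at ΔE = 0), NMB =
  WTP·ΔE − ΔC at the AUD 50,000/QALY base-case threshold. Classification:
  `dominant` (cheaper, more effective), `dominated` (costlier, less
  effective), else `cost_effective` iff NMB > 0. A configurable **mortality
  override** reclassifies a nominally cost-effective strategy as
  `mortality_dominated` when it produces more deaths per patient than its
  comparator.
- **CEAC**: P(cost-effective) over a WTP grid as the fraction of PSA draws
  with positive NMB. At w = 0 this is P(ΔC < 0); as w → ∞ it tends to
  P(ΔE > 0).
- **One-way DSA**: each parameter set to its low/high bound (ranges must
  bracket the base value, enforced), pipeline re-evaluated, entries sorted by
  spread (tornado). Packaged ranges cover the discount rate (0–5%), horizon
  (5–40 years), case fatalities, event hazards, utilities and cost scales.
- **PSA**: uncorrelated parameter draws per the packaged manifest — gamma for
  costs, beta for utilities and probabilities, log-normal for hazard rates
  and the mortality scale — each parameterised by its base value and a
  coefficient of variation (mean-preserving). Drawn mRS utilities are
  re-sorted non-increasing so every draw respects the disability ordering.
  Each draw simulates both arms with a **shared patient-level seed** (common
  random numbers), so the incremental difference is not swamped by sampling
  noise; a test verifies the variance reduction against independent streams.

## 7. Numerical choices

- **Counter-based random streams**: all stages draw from Philox generators
  keyed by `SeedSequence(seed, spawn_key=(stage, round))`. In the vectorised
  engine each patient consumes a contiguous block of six uniforms per round,
  so (a) identical (seed, n) gives bit-identical results, (b) enlarging the
  cohort never perturbs existing patients' streams, and (c) two arms run with
  the same seed are aligned patient-by-patient (the common-random-numbers
  property the PSA exploits).
- **Event-time inversion everywhere** (no rejection sampling), so a fixed
  uniform stream maps to a fixed event stream.
- **Continuous discounting in closed form** per accrual interval; verified
  against numerical quadrature to 1e-9 and additive over interval splits.
- **Probability-vector tolerance**: published frequency tables rounded to
  four decimals can sum to 0.9999; cohort validation accepts |sum − 1| ≤
  1e-3 and renormalises exactly before sampling.
- **Problem sizes**: the packaged base case uses 50,000 patients per
  strategy; PSA defaults to 1,000 draws × 2,000 patients/arm, which bounds
  the per-draw Monte-Carlo noise well below the parameter-uncertainty signal
  for these comparisons. Runtime is a few seconds for the base case and
  about half a minute for the full PSA on one CPU.

## 8. Parameter defaults

Every value below ships in `evtcea/data/*.csv|yaml`; rows marked
`assumed=true` are literature-class defaults standing in for inputs that are
not publicly documented, and `load_parameters` warns about them on load.
All are overridable via `ParameterFileSet`.

| parameter | default | units | status |
|---|---|---|---|
| composite MI/vascular-death 5-y risk | 0.174 | probability | published; calibrated to 0.038232/y |
| MI fraction of composite | 0.45 | share | assumed |
| recurrent stroke hazard | 0.04 | /year | assumed |
| case fatality (stroke, MI) | 0.25, 0.25 | probability | assumed |
| mortality table | §2.2 | /year | assumed, anchored to validation band |
| utilities mRS 0–5 | 0.95, 0.93, 0.83, 0.62, 0.42, 0.11 | utility | assumed |
| event decrement | 0.10 for 1 year | utility | assumed (non-stacking) |
| index acute cost EVT / EVT+tPA / tPA / none | 33,000 / 35,500 / 16,000 / 12,500 | AUD 2018 | assumed |
| acute recurrent stroke cost by mRS 0–6 | 11,000 … 26,000; 10,000 fatal | AUD 2018 | assumed |
| MI hospitalisation | 8,000 | AUD 2018 | assumed |
| annual management mRS 0–5 | 950 … 6,400 | AUD 2018 | assumed |
| post-MI annual cost | 1,200 | AUD 2018 | assumed |
| discount rate | 0.03 | /year | published |
| horizon | 25 | years | published |
| WTP threshold | 50,000 | AUD/QALY | published |
| recurrent severity mRS 0–5 | 0.10, 0.15, 0.15, 0.20, 0.25, 0.15 | probability | assumed |
| PSA CVs | 0.15 costs, 0.10 utilities/probabilities, 0.15 hazards | CV | assumed |

## 9. Limitations

- **Absolute levels are assumption-dependent.** With the packaged defaults
  the 25-year mortality is heavier, and absolute QALY/cost totals lower, than
  the original analysis reported from its non-public parameter tables. The
  incremental structure — roughly +1 QALY for criteria-positive EVT at an
  ICER well under threshold, criteria-negative EVT dominated with ≈100%/≈0%
  PSA separation — is the reproducible surface, and is what the acceptance
  suite asserts.
- PSA draws are uncorrelated across parameters; no correlation structure or
  expert-elicited joint distributions are modelled.
- Treatment affects outcomes only through the 90-day mRS distribution, the
  index cost, and state-dependent downstream costs; no strategy-specific
  long-term hazard modifiers are modelled.
- The generator's independence assumptions (§4) limit how faithfully
  criteria-positivity rates and propensity overlap mimic the real cohort.
- A single fixed exchange rate is provided for reporting; no price-year
  re-indexing is implemented.
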