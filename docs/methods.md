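# Methods

## Model structure

The model is an individual-level (first-order Monte-Carlo) state-transition
model with ten mutually exclusive health states, an annual cycle, and a
20-year horizon. Three states — normal weight, overweight, obesity — are
*weight-governed*: membership is recomputed every cycle from the
individual's BMI (weight/height², thresholds 25 and 30, both inclusive on
the heavier side). The remaining states — diabetes, acute stroke,
post-stroke, acute MI, post-MI, ESRD, death — are *disease-governed*:
individuals keep their weight dynamics but BMI no longer changes their
state, because the transition structure has no disease-to-weight-category
edges. Acute stroke and acute MI are one-cycle tunnel states: an individual
who spends a full cycle in the acute state without transitioning elsewhere
is promoted to the chronic post-state, which carries lower annual costs.
A stroke→MI (or MI→stroke) transition restarts the other event's tunnel.
Death is absorbing.

Within a cycle the order of operations is fixed: weight update, BMI
reclassification, one sampled transition from the current state's
annual-probability row (residual mass = remain), tunnel promotion, event
recording. The weight step must precede reclassification for the tax
mechanism to act at all; transitions then act on the updated state. Only
one transition can occur per individual per cycle, the standard convention
when inputs are marginal annual probabilities.

The intervention acts purely through weight: the tax arm subtracts a fixed
0.56 kg/y (its provenance chain — grams of added sugar → 4 kcal/g →
3,500 kcal per pound of body weight — is implemented as
`sugar_to_calories`/`calories_to_weight_rate` for documentation; note the
chain's own arithmetic gives 0.58 kg/y, and the headline −0.56 kg/y input
value is used as authoritative). The effect applies every cycle for the
whole horizon. Direct, non-weight-mediated effects of SSB intake on
diabetes or cardiovascular risk are deliberately out of scope.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| cohort size | 20,000 | persons | rescale factor 1,462.36 maps to 29,247,121 CA adults |
| horizon | 20 | years | annual cycles |
| discount rate | 0.03 | per year | costs and QALYs alike; year 0 undiscounted |
| natural weight gain | U(0.45, 0.91) | kg/y | independent per person per cycle |
| tax weight effect | −0.56 (95% CI −1.93, 0.77) | kg/y | normal PSA draw |
| annual tax revenue | 862,722,888 | USD/y | ±25% interval; gamma draw |
| administration cost | 8,627,229 (1% of revenue) | USD/y | ±25%; gamma draw |
| WTP threshold | 100,000 | USD/QALY | CEAC evaluated on a 0–200k grid |
| weight floor | 30 | kg | guards extreme PSA weight-effect draws |

Transition probabilities, per-state costs (2022 USD), and EQ-5D utilities
ship in `src/sodasim/data/default_parameters.yaml` (30 transition entries,
9 cost entries, 8 utility entries; acute and chronic stroke — likewise MI —
share one utility input and hence one PSA draw).

## Uncertainty encoding and PSA

Every interval, whether a reported 95% CI or a ±25% convention interval, is
converted to a standard deviation as (high − low)/3.92; the ±25% intervals
are thereby treated as if they were 95% intervals, since no alternative
rule is available and the PSA samples all inputs. Families are
moment-matched to (mean, sd) only — skewness of asymmetric printed
intervals is not matched, as two moments determine each mandated family:

* gamma (costs): shape = m²/s², scale = s²/m;
* beta (probabilities, utilities): ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν,
  with s clipped just below the feasibility bound √(m(1−m)) when necessary —
  a utility of exactly 1 therefore collapses to a point mass, as does the
  degenerate overweight→death interval (0.0087, 0.0087);
* log-normal (ratio measures): σ² = ln(1 + (s/m)²), μ = ln m − σ²/2;
* normal: reserved for the tax weight effect, whose interval spans zero and
  so admits none of the positive-support families.

Each fitted distribution reproduces the input mean analytically to 1e-9.
Draws are independent across parameters (no correlation structure is
specified by the inputs). A drawn transition row whose probabilities sum
above 1 is renormalised proportionally so the stay probability is never
negative. The natural-gain range is an interval, not a distribution
parameter, and stays fixed in the PSA.

The PSA regenerates the baseline cohort from the same seed each iteration:
parameter uncertainty only is propagated, not population sampling
uncertainty. The desk-scale default is 200 iterations × 2,000 individuals;
the full profile (1,000 × 20,000) sits behind `--full-scale`. Both arms use
common random numbers (identical per-individual, per-cycle draws), and
draws are made for dead individuals too so the streams never desynchronise;
with a zero weight effect the two arms are bitwise identical.

## Synthetic population

The generator emulates the joint adult weight/height distribution with a
log-normal weight marginal, a normal height marginal (mean 1.68 m, SD
0.10 m — height moments are a free nuisance dimension), and a Gaussian
copula. Calibration is two-stage: the weight marginal is matched in closed
form to the target mean (77.67 kg) and SD (19.96 kg), then the weight–height
correlation is found by Brent root search so the implied obesity prevalence
(BMI ≥ 30) hits 28.2%. The search objective uses a fixed 400,000-draw
antithetic standard-normal sample, making it smooth in the correlation and
keeping the calibration's own Monte-Carlo error near 0.1 percentage points;
the fitted correlation lands near 0.63. Heights are clipped to [1.2, 2.2] m
(a > 4σ event). Everyone starts alive and disease-free, classified by
baseline BMI; age and sex are not simulated because the transition inputs
are population-averaged.

What this does *not* emulate: survey weighting, demographic structure,
baseline disease prevalence, secular trends in obesity, or entry of new
18-year-olds over the horizon. Tests passing against this generator show
the model machinery is correct under these idealised conditions, not that
the cohort matches any real population beyond the three calibrated moments.

## Economics

Costs and utilities accrue for the state occupied at the end of each
cycle's updates, discounted by (1+r)^(−t) with t the 0-based cycle index;
no half-cycle correction is applied, and the cycle in which death occurs
accrues nothing (death carries zero cost and utility). The tunnel states
make first-year stroke/MI carry the acute cost and subsequent years the
chronic cost. Revenue and administration costs are annuities at the same
3% rate. Government-perspective net incremental cost is the health-care
increment plus administration minus revenue (an identity enforced by test).
The per-person annual health-care saving is (status-quo − tax total
cost) / population / horizon. Model totals are rescaled by 1,462.36; when a
run uses a cohort size other than 20,000 the factor scales inversely so
population totals are invariant.

The ICER is ΔC/ΔE with explicit qualitative labels: "dominant" (cheaper,
more effective), "dominated", "undefined" (ΔE = 0, value NaN). CEAC values
are the fraction of iterations with positive net monetary benefit
λ·ΔQALY − ΔC.

## Event counting

Weight-category case counts are *ever-in-category* counts (baseline members
plus first-ever entries over the horizon); disease counts are incident
first events; the death row is cumulative deaths. Recurrences of the same
event type (e.g. a second stroke after post-stroke) are not modelled
because no post-state→same-event probability is parameterised; only the
cross transitions (post-MI→stroke, post-stroke→MI, stroke→MI, MI→stroke)
exist.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.Generator`; batch runs derive
  sub-seeds below 2³¹ from one master seed, and identical seeds give
  byte-identical CSV outputs.
* Transition sampling uses a cumulative-probability search per origin
  state; a uniform draw landing exactly on a boundary (measure zero)
  resolves to the next destination.
* Calibration failure modes raise dedicated errors with diagnostics
  (unbracketed prevalence target, degenerate target prevalence).
* A zero-year horizon yields an empty trace and zero accruals; a
  probability row summing above 1 at simulation time is an internal error
  (renormalisation is guaranteed upstream).

## Limitations

* The incident-event scale is driven entirely by the input transition
  probabilities applied to all weight states with cumulative natural weight
  gain; under these inputs the 20-year incident counts (e.g. ~4.7 million
  diabetes cases status quo) and health-care totals sit well above some
  published point estimates for comparable scenarios, while calibration
  moments, QALY totals, and the CEAC probability reproduce closely. The
  package reports its own computed totals throughout and does not force
  agreement with any external table.
* Cost-effectiveness conclusions inherit the single-study weight-effect
  estimate and its wide interval; the CEAC is essentially the probability
  that the tax reduces weight at all.
* No societal perspective (indirect costs are excluded by design), no
  external-survey validation, and no inflation machinery (all inputs are
  already 2022 USD).
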