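# Methods

## Model structure and assumptions

The model chains a diagnostic decision tree into a three-state Markov
cohort model. The decision tree is evaluated analytically (cohort
expectations, not sampled patients), except for an optional individual-level
microsimulation of the classification stage used to attach Monte-Carlo
error bars. The Markov model propagates state-occupancy fractions in
one-year cycles until the whole cohort is absorbed in the dead state (or
the life table's terminal age, where the annual death probability is 1).

Key structural assumptions:

- **Minor vs major adaptation.** Both adaptation types carry the same
  protective effect (relative risk `rr_adaptation` on the embolic portion of
  stroke risk); only major adaptations cost money. Major adaptations occur
  only in true positives — a major adaptation begun on a false positive
  would immediately reveal the absent disease and be aborted — so false
  positives receive only minor, cost- and risk-neutral adaptations.
- **Mortality stratification.** Every patient with ascending-aorta
  atherosclerosis is assumed to carry the extra-cardiac arteriopathy risk
  factor, so the with/without strata differ by a fixed odds ratio
  (default exp(0.6559) ≈ 1.93, the published logistic-EuroSCORE
  coefficient) while mixing back to the subgroup-average early mortality.
  The split is solved by bracketed root-finding (Brent, xtol 1e-14,
  max 200 iterations); both invariants are verified to 1e-10.
- **Early outcomes are exclusive.** Early deaths and strokes are mutually
  exclusive terminal decision-tree outcomes; fatal strokes are counted
  within early mortality, and "other early death" absorbs the remainder
  (floored at zero with a result flag if the stroke linkage ever implies
  more fatal strokes than deaths).
- **Utilities are age-invariant.** Ageing is assumed to affect quality of
  life equally with and without a prior stroke, so utilities are constant
  multipliers (1 without complications, 0.439 post-stroke).

## The stroke-risk linkage (a pluggable policy)

The published point estimates do not uniquely determine how baseline stroke
risk attaches to patient strata, so the linkage is a pluggable policy
function. The default, `proportional_stroke_policy`, sets each stratum's
total stroke risk proportional to its early mortality,
`T_i = m_i · p_death_is_stroke / (1 − p_stroke_nonfatal)`, and applies the
embolic fraction (0.71) uniformly; adaptation multiplies the embolic part by
`rr_adaptation` in detected patients only. The alternative,
`concentrated_embolic_policy`, keeps the cohort-average total but assigns
the whole embolic burden to the atherosclerosis stratum (emboli originate
from the atherosclerotic aorta), which roughly doubles the between-strategy
stroke contrast. The default is the more conservative choice; both are
exercised by tests, and results that depend on the linkage magnitude
(absolute stroke risks, CEAC heights) should be read as
structurally-but-not-numerically comparable to any particular published
table.

A consequence worth noting: at a *fixed* cohort-average mortality the
default linkage pins the unadapted stroke total, so raising prevalence
alone (without raising average mortality) cannot raise total stroke risk.
The monotonicity one expects — more atherosclerosis, more strokes — holds
when the per-stratum mortalities are held fixed and only the mix varies,
which is how the property is tested and how the subgroup inputs behave
(higher-prevalence subgroups carry higher average mortality).

## Parameters

All parameters live in a YAML config (`teecea/data/default_config.yaml`);
the bundled defaults are the study conditions. Uncertain parameters carry
sampling distributions: beta for probabilities (moment-consistent with the
printed point values to <0.005), log-normal for the adaptation relative
risk (log-scale mean −0.864, sd 0.392; the printed three-decimal parameters
pin the implied 95% CI only to ~±0.001), uniform for the excess-mortality
risks and death-related costs, triangular (0.186, 0.439, 0.653) for the
post-stroke utility — the printed 0.439 is read as the mode, so the
distribution's mean (≈0.426) deviates slightly — and gamma for the device
cost, moment-matched to mean €212 with 95% mass on ≈[184, 243]
(sd = (243−184)/3.92).

Cost placeholders: the acute non-fatal stroke cost (€9,000) and the annual
post-stroke care cost (€7,500/yr) are **synthetic placeholders** at the
order of magnitude of published Dutch stroke-care costs; the original
itemized cost breakdown is not publicly available. They were fixed once,
before any end-to-end results were inspected, and should be replaced with
local reimbursement data for a real appraisal. Surgery costs €15,628
without and €23,886 with a major adaptation; weighting by the 2.7%
major-adaptation rate gives ≈€15,851 per detected patient.

Discount rates follow Dutch guidance (4.0% costs, 1.5% effects). The
EuroSCORE logistic calculator is an auxiliary path for users with raw risk
factors; the subgroup-average early mortalities in the config are treated
as already calibrated (the 71% reduction applied), and `calibrate()` is
provided for users starting from raw logistic predictions.

## Markov engine numerical choices

- Rewards (life-years, QALYs, state costs) are credited at the end of each
  cycle to that cycle's survivors; there is **no half-cycle correction**.
  Under constant hazard q and zero discounting this reproduces the
  geometric series Σ(1−q)^t = (1−q)/q exactly (verified to 1e-8).
- Excess post-surgical mortality **replaces** (does not add to) background
  life-table mortality during its window; the age band is fixed at the age
  of surgery (a 60-year-old keeps the under-61 band for both years of its
  window). Windows: years 1–2 (under 61), years 1–5 (61–70 and over 70).
- Both living states share the same mortality; there is no recurrent
  stroke and no recovery from the post-stroke state.
- Iteration stops when living occupancy falls below 1e-12, truncating
  discounted totals by at most ~1e-11 of a life-year.
- One-time costs (device, surgery, early-event costs) are incurred at
  cycle 0 undiscounted; deaths during Markov cycles carry no event cost.

## Probabilistic sensitivity analysis

Each of the `n_sims` simulations draws every uncertain parameter once
(common random parameters drive both strategies, since the shared
quantities are strategy-independent) and evaluates both strategies
deterministically. Draws producing infeasible probabilities are rejected
and resampled with a logged count (none occur at the default
distributions). Parameter fields are sampled in declaration order from a
single `numpy` Generator, so a seed fully determines the run.

The CEAC uses the net-monetary-benefit criterion
P(λ·ΔE − ΔC ≥ 0). The "probability that the new strategy is cost-saving
*and* health-gaining", P(ΔC<0 ∧ ΔE>0), is reported separately
(`p_cost_saving_health_gain`): it differs from the CEAC at λ=0 by draws
with ΔC<0, ΔE≤0, and the package exposes both rather than conflating
them. Confidence ellipses use the bivariate-normal approximation (sample
mean and covariance scaled by the χ²₂ quantile); a collapsed covariance is
flagged as degenerate.

## Synthetic life tables

`lifetable_synth` generates life tables from a Gompertz–Makeham hazard
μ(age) = A + a·e^{b·age}, q = 1 − e^{−μ}, per sex, ages 0–110 with q = 1
at 110. The bundled specs (male A=5e-4, a=1.97e-5, b=0.098; female
A=3e-4, a=1.32e-5, b=0.098) give remaining life expectancies of about
27/19/12 years for men and 31/22/15 for women at ages 55/65/75 — the shape
of a modern high-income population, with female mortality below male at
every age. They are **not** official statistics: the generator emulates the
age structure and sex gap of a national life table but not its exact
levels, cohort effects, or young-age mortality hump. Tests passing on the
synthetic table therefore establish structural behaviour (orderings,
monotonicities, conservation), not numeric agreement with analyses run on
official tables — which users can supply as CSV (`sex,age,qx`).

## Problem sizes

The test suite runs cohort models to full absorption (≈55 cycles),
10,000-patient classification microsimulations, and PSAs of up to 5,000
draws for one subgroup (run twice to verify bit-reproducibility); CLI tests
use 3–40 draws. These sizes match the analysis design (10,000-patient
cohorts, 5,000 PSA simulations) where it matters and are scaled down where
only determinism or shape is under test.

## Known limitations

- The stroke-risk linkage is a reconstruction; absolute stroke levels and
  downstream ICER magnitudes depend on it.
- Stroke-care costs are placeholders (see above); incremental-cost levels
  shift with them, though the age trend (costs falling, effects rising
  with age) is robust.
- No recurrent strokes, no surgery-technique-specific embolic risk, no
  post-stroke excess mortality beyond the shared background and early
  excess risks, no half-cycle correction, euros only.
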