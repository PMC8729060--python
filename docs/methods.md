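# Methods

## Scope and intent

`endosim` simulates the post-diagnosis consequences of extending adjuvant
endocrine therapy from 5 to 10 years in ER+, stage 1–3 breast cancer. It
starts *at diagnosis*: screening, incidence, and tumor natural history
before diagnosis are out of scope, as are second contralateral cancers,
molecular-subtype modelling, genomic risk scores, and costs. Chemotherapy
and HER2-targeted therapy are carried as flags but are inert — their
mortality effect is absorbed into the calibrated baseline and their
quality-of-life effect into the stage utility.

## Cohort and competing mortality

Each woman has a continuous age at diagnosis drawn from a truncated normal
(mean 61, SD 13, clipped to the configured age range within [25, 79]) — a
synthetic, SEER-like default, fully configurable — and a stage from the
default mix (0.45, 0.25, 0.18, 0.12) over stages (1, 2a, 2b, 3), likewise a
synthetic default. Nodal status is a pure function of stage (1/2a negative,
2b/3 positive). Birth years span 1935–2009 and are inert by default (a
cohort-shift hook on the life table exists but defaults to flat).

Other-cause mortality uses a Gompertz–Makeham hazard
μ(a) = α + β·e^{γa} with defaults α = 5×10⁻⁴, β = 3×10⁻⁵, γ = 0.095 per
year, chosen so remaining life expectancy is ≈39 y at age 40 and ≈14 y at
age 70 — a deliberate, synthetic approximation to U.S. female cohort
mortality. Death ages are inverse-sampled from the conditional survival
S(a | a > age at diagnosis) on a 0.05-year grid (capped at 120 y). A
2-column CSV life table (age, annual hazard) can be substituted.
Because the cohort life tables behind the reference results are not
public, absolute LY/QALY *levels* are approximate by construction; the
calibrated between-arm *differences* are the reproducible quantities, and
passing tests should be read accordingly.

## Baseline breast-cancer mortality and calibration

A woman's breast-cancer risk absent extended therapy is a lifetime
cumulative hazard Λ_total spread over (0, 25] years post-diagnosis by a
truncated-Weibull CDF F (shape k, scale λ; F(25) = 1, so no BC death after
year 25). Node-positive disease multiplies Λ_total by 2.5 — a synthetic
choice (no node-specific mortality is published) that reproduces the
*qualitative* node-positive > node-negative benefit ordering; it is a
config parameter, and nodal results should be treated as directional.

Two calibrations, per age-band stratum:

1. **Time shape.** With k fixed at 1, the scale λ is solved (deterministic
   bisection on the closed-form no-competing-risk expression) so the share
   of the 10-vs-5 cumulative-mortality difference accrued by year 15
   matches the reference ratios: 2.13/2.63 ≈ 0.81 (ages 25–49) and
   0.10/0.16 = 0.625 (ages 50–79). The bisection bracket respects the
   feasibility bound F(5) < HR₁₀/HR₅ (beyond it the 10-year arm's tail
   multiplier would be negative); unattainable targets raise an error
   listing the achievable interval.
2. **Lifetime level.** λ_base (the node-negative Λ_total) is solved by
   bisection on a fixed-draw (common-random-number) simulation of the
   5-year arm with competing mortality on, so the crude lifetime P(BC
   death) matches 11.91% (ages 25–49) or 10.20% (ages 50–79). The
   initializer is the closed-form no-competing solution
   Λ = −ln(1−p)/HR₅; the bracket widens twice before failing. One
   refinement pass re-fits the shape at the calibrated level (the share
   depends on it only weakly). Calibration always uses 100% completion;
   completion scenarios sit on top of the calibrated baseline.

Default calibration size is 4×10⁵ women (10⁶ in the acceptance script);
the achieved level must sit within 3 Monte-Carlo SEs of the target.

## Treatment effects

The strategy-level hazard ratios act as piecewise multipliers on the
baseline cumulative hazard: both arms use HR₅ (completion-adjusted) on
(0, 5] — therapy is identical there, so between-arm mortality differences
are exactly zero before year 5 — and the 5-year arm keeps HR₅ on (5, 25]
(the benefit of completed therapy persists), while the 10-year arm uses
m_tail = (HR₁₀ − HR₅·F(5)) / (1 − F(5)) so its lifetime effect equals
HR₁₀. Death times come from one shared latent exponential E per woman via
the inverse of the piecewise-scaled cumulative hazard; this coupling makes
extension monotone at the individual level (never an earlier death).

**Completion.** Efficacy scales linearly on the hazard-reduction scale:
HR₅ᵉᶠᶠ = 1 − c₁(1 − HR₅), HR₁₀ᵉᶠᶠ = HR₅ᵉᶠᶠ − c₂(HR₅ − HR₁₀), which
reduces to 1 − c(1 − HR) when c₁ = c₂ = c. Adverse-event probabilities
scale the same way (p₅ᵉᶠᶠ = c₁p₅; p₁₀ᵉᶠᶠ = c₁p₅ + c₂(p₁₀ − p₅), clamped
at 0). The linear form is a modelling choice; only the direction is
established.

## Adverse events

Grade 3–4 events are sampled independently per type with the arm's
cumulative column probability; the "Total" rows are treated as derived
sums, never as P(any). Grade 1–2 symptoms are pooled: one Bernoulli per
woman, and an affected woman receives exactly two instances (utilities
0.9 and 0.85 for 1 year each) at the window start and window midpoint.

**Cross-arm coupling.** The 10-year column is cumulative over years 0–10,
so one shared uniform per (woman, event type) is thresholded against both
columns: a draw below p₅ is an event of years 0–5 occurring in *both* arms
at the *same* onset in (0, 5]; a draw in (p₅, p₁₀] occurs only in the
10-year arm with onset in (5, 10]. (Where p₁₀ < p₅ — e.g. new cardiac
condition on tamoxifen — the draw in (p₁₀, p₅] occurs only in the 5-year
arm.) A naive per-arm uniform rescaling of onsets was rejected: it made
concordant lifetime events start later in the 10-year arm, manufacturing
spurious discounting benefits and breaking the first-5-years-identical
structure. Marginal onsets remain uniform within each 5-year span.

Duration semantics: fixed spans (fracture 1 y at 0.8; pulmonary embolus
0.75 y at 0.65); treatment duration (osteoporosis at 0.9 from onset to the
end of the arm's window — the "while-on-therapy" reading of an ambiguous
input); lifetime (new cardiac condition at 0.8); first year then lifetime
(stroke 0.7 → 0.85; endometrial cancer 0.85 → 0.9). Overlapping
decrements multiply. No adverse-event-attributable deaths are modelled:
fatal (grade 5) toxicity is acknowledged in the source inputs but carries
no published excess-mortality rate — a known limitation that biases the
simulated harms of extension slightly toward zero.

## Outcomes and aggregation

Utility at time t is age-band utility (0.913…0.724 by decade) × stage
utility (0.9/0.85/0.85/0.8) × active toxicity multipliers — multiplicative
combination, the standard QALY convention. The stage utility applies for
the whole post-diagnosis lifetime (no cure-state recovery), a documented
simplification. QALYs are exact integrals of this piecewise-constant
function: every discontinuity (decade birthdays, event onsets/ends, death)
is a breakpoint. Discounting is continuous, e^{−rt} from diagnosis at
r = 0.03/year by default; an annual-step variant ((1+r)^{−⌊t⌋}, also
integrated exactly) sits behind `discounting: annual`. The 15-year horizon
clips integration and BC-death attribution at t = 15.

Aggregation accumulates means, Monte-Carlo SEs, and paired 10-vs-5
differences (CRN makes paired SEs far smaller than unpaired) per stratum
(ages 25–49, 50–79, 50–59, 60–69, 70–79, all) × nodal status. Published-
layout tables round to 2 decimals; machine-readable companions keep full
precision.

## Randomness and reproducibility

Every stochastic quantity reads a named *purpose* stream (age, stage,
other-cause survival, latent BC exponential, one occurrence + one onset
stream per event type) from counter-based Philox generators keyed by
(master seed, purpose, fixed-size block). A woman's draws depend only on
her index and the purpose, so results are invariant to chunking, growing
the cohort never perturbs existing women, and both arms read identical
streams. Runs are bit-reproducible for a given (config, seed, n), and all
sensitivity scenarios share the base seed so the base-case point of every
sweep is bit-identical to the unperturbed run.

## Sensitivity analysis

One-way sweeps cover each adverse event's utility and duration ranges and
proportional rescaling of the grade 3–4 probability totals (components move
proportionally when a total is swept). Two-way best/worst cases set all
utilities high + durations short (best) or utilities low + durations long
(worst); by construction worst ≤ base ≤ best. Completion scenarios take
(c₁, c₂) schedules. The tornado table orders scenarios by |increment −
base| descending, ties alphabetical. Probabilistic sensitivity analysis is
a non-goal.

## Problem sizes and numerical choices

Default sweep granularity is 3 points (low/base/high). The test suite uses
4×10⁵-woman calibration and runs of 2×10⁴–2×10⁶ women chosen so paired
Monte-Carlo SEs are an order of magnitude below the tolerances being
asserted; the acceptance script uses 10⁶ paired women for the ages 25–49
quantities and 5×10⁶ for ages 50–79 (where the QALY difference is ~0.04
and the paired SE at that size is ~10⁻⁴). Bisections use `brentq` with
tolerances far below Monte-Carlo noise. Degenerate inputs are defined:
empty cohorts return empty results, zero discount rates reproduce
undiscounted outcomes exactly, u→0⁺ death draws collapse to the
conditioning age, and validation reports rather than raises.

## Known limitations

* Absolute LY/QALY levels track the synthetic life table, not any specific
  national cohort; only differences are calibrated.
* The node-positive multiplier (2.5) is synthetic; nodal-status results
  are directional, not quantitative.
* The simulated discounted QALY loss for ages 50–79 (≈0.04 at the
  defaults) is smaller in magnitude than the reference −0.06, consistent
  with the absent grade-5 mortality, the synthetic life table, and the
  stage-anchored utility assumptions; it remains within the stated
  reproduction band.
* No regimen switching at menopause, no sequential tamoxifen→AI regimens,
  no event-driven treatment discontinuation (completion is exogenous).
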