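# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `mortlag`. It covers what the code computes and why
the defaults are what they are; it states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

All surfaces live on the canonical abridged age grid 0, 1–4, 5–9, …,
80–84, 85+ (19 groups; closed-open intervals, one open terminal group).
HMD-style 5×1 tables are collapsed onto it by summing deaths and
exposures for ages 85 and above into the terminal group — the simplest
aggregation consistent with occurrence/exposure rates. WHO-style
cause-of-death rows must each fall inside a single canonical group;
spanning intervals are rejected rather than split, because any split
would need an age distribution we do not have. Lung-cancer cause codes
per ICD revision: 162+163 (ICD-7), 162 (ICD-8 and ICD-9), C33+C34
(ICD-10). Lung deaths exceeding all-cause deaths in a cell are treated as
data corruption (hard error), not clipped.

The WHO "Mortality Database" has many dialects; the package reads one
documented flat schema (`country_iso3, year, sex, icd_revision,
cause_code, age_group_start, age_group_width, deaths`) and expects other
dialects to be pre-converted. This keeps parsing strict and testable.

## Rate smoothing

Lung-cancer death rates are smoothed per country and sex with a
tensor-product P-spline: cubic B-spline bases over age-group midpoint and
calendar year (defaults: 10 basis functions in each dimension,
configurable via `k_age`/`k_year`), second-order difference penalties in
both directions, Poisson likelihood with log link and offset
log(exposure), fitted by penalized IRLS. The smoothing parameter is
chosen on a log-spaced grid by a GCV-style criterion n·Dev/(n − edf)².
The fit is deterministic. Because B-spline columns sum to one and the
difference penalty leaves constants unpenalized, the converged fit
reproduces each country-sex's total observed deaths exactly
(mean-matching), and smoothing an already-smoothed surface is idempotent
to numerical tolerance.

Practical choices:

- Cells with zero exposure are excluded from fitting (the offset is
  undefined) but still predicted.
- Age groups with zero observed counts in every year (structurally zero
  lung mortality, e.g. childhood) are returned as exact zeros instead of
  being fitted on the log scale, avoiding separation.
- Year knots span the observed years; years outside that span are filled
  by constant extension of the boundary fit, interior gaps by the smooth
  itself. Smoothing is per country-sex, not pooled with country terms —
  pooling would shrink small countries toward the roster mean, which is
  exactly the cross-country signal of interest.

Reference death-rate series of the record holders are smoothed with the
same machinery in one dimension: a quasi-binomial P-spline on the logit
scale over year. Death rates enter as proportions of a fixed ceiling of
1 — they are all far below it, so the link is used only for boundedness.

## Smoking attribution

The indirect method treats lung-cancer mortality in excess of a
never-smoker schedule λ\*(sex, age) as the footprint of cumulative
smoking damage:

- A_lung = max(0, (m_L − λ\*)/m_L); clamped at zero because negative
  attributable deaths are not meaningful (observed rates can fall below
  λ\* in small populations).
- A_other = 1 − exp(−β·max(0, m_L − λ\*)), with β per sex, age group and
  calendar-period band. Years after the last band reuse the last band;
  years before the first use the first.
- β is extended to age groups beyond the table by a least-squares line in
  the age-group midpoint within each sex×period stratum.
- A_total = (A_lung·D_L + A_other·(D − D_L))/D, forced to zero for age
  groups entirely below 45, where the method is not applied.

Smoothed lung rates are used both in the SAF formulas and in the
lung/other death split (D_L = smoothed rate × exposure, capped at D); a
single rate source keeps the two uses consistent.

The packaged λ\* and β tables are **constructed stand-ins** with
plausible magnitudes (never-smoker lung-cancer mortality rising from
~1.5 to ~30 per 100 000 between ages 45 and 85+; β of order 10²
(deaths/person-year)⁻¹, declining with age, with a ±10% period gradient
across three bands). They are labelled `*_synthetic.csv` and are shared
by the data generator, so all planted-truth checks are exact with
respect to them. For substantive analyses, pass study-specific tables
via `never_smoker_path`/`beta_path`.

## Lifetables

Standard abridged period lifetable: q = n·m/(1 + (n − a)·m) for closed
intervals, terminal q = 1 with exponential closure L = l/m (remaining
expectancy 1/m at 85+). Separation factors: a₀ = 0.07 + 1.7·m₀ for the
infant group, a = 1.5 for ages 1–4, a = n/2 elsewhere — the textbook
defaults for abridged tables. Radix 100 000. Against a continuous-time
Gompertz–Makeham oracle (fine-grid survival integration), abridged e₀
from the model's occurrence/exposure group rates agrees within 0.5 years
over realistic parameter ranges (verified in the test suite).

## Record trends and lag estimation

The record trend takes the best value per year across the roster
(highest e₀ / lowest death rate); ties break to the first country in
alphabetical ISO3 order. Before inversion the trend is replaced by its
monotone envelope (running best). The underlying idea needs a
monotone reference to define a unique equivalent year; empirical record
series are nearly monotone already, and the envelope makes the guarantee
exact. Plateaus invert to their latest year — the most favorable
(smallest-lag) reading. The inverse is linear interpolation between the
annual envelope points; it agrees with a brute-force 0.01-year grid scan
to within 0.02 years (tested). Censoring: values at/above the current
best are reported in the open bin "≤0"; values below the earliest
envelope value in "span≤" (e.g. "69≤" for a 1950–2019 reference). A
country at the envelope therefore has lag ≤ 0, and lag is antitone in
the country's value.

Lag tables report observed and smoking-eliminated lags against the
smoking-eliminated record trend; their difference is the smoking
contribution to the country's delay. The MEAN pseudo-country applies the
lifetable-then-lag chain to the unweighted arithmetic mean of
age-specific death rates across countries (no population weights — the
comparison treats countries, not people, as units). Output lags are
rounded to 0.1 years; internal computation keeps full precision.
Age-specific lags invert each age group's smoothed record-holder
death-rate series in the decreasing direction; below age 45 the observed
and eliminated variants coincide by construction (SAF = 0 there).

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes:

- Smoke-free hazard m₀(x,t) = c + a·e^{bx}·e^{−ρ(t−1950)} per country and
  sex (Makeham level c ≈ 1.5–2·10⁻⁴/yr, Gompertz a ≈ 4–5·10⁻⁵/yr,
  b ≈ 0.095/yr of age, improvement ρ ≈ 0.010–0.012/yr), giving e₀ in the
  high-70s to mid-80s by 2019 with steady improvement; females carry a
  0.82 hazard multiplier.
- Epidemic overlay on lung-cancer rates: amplitude·profile(x)·Gaussian
  wave in period (SD 18 years). The age profile is zero below 45, ramps
  linearly to 60 and is flat above — matching the method's zero-below-45
  assumption and producing mid/old-age lag signatures. Male peak years
  default to 1975–1985 (leaders earlier and weaker, laggards later and
  stronger, as in the historical epidemic), female peaks 20 years later
  at 0.6 amplitude. Peak excess lung-cancer rates of 1.2–3.5·10⁻³/yr
  correspond to heavy-epidemic lung-cancer mortality.
- Other-cause smoking mortality is constructed through the same
  exponential link the attribution inverts, with the packaged β, so the
  per-cell attributable fraction is known in closed form and the
  smoking-eliminated surface equals m₀ exactly.
- Exposure defaults to 5·10⁵ person-years per age group; counts are
  either exact expectations ("expected") or seeded Poisson draws.

The default roster is four countries: a leader, an exact 12-year-shifted
clone of the leader (the planted-lag fixture), a heavy-smoking country
and a middling one — small enough to keep the full test suite under a
minute while exercising every pipeline branch.

Shifted clones are built by shifting the hazard parameters themselves
(improvement rebased by e^{ρk}, epidemic peak moved k years), so the
smoke-free surface and the lung-cancer rates shift exactly, including
"pre-1950" behaviour. Observed rates shift exactly only within a β
period band: β is calendar-anchored, so across band boundaries the
other-cause excess of the clone differs from the shifted donor by the
band step (~1–2% of the rate at the affected years). The planted-lag
recovery therefore targets smoking-eliminated life expectancy, which is
exact.

What the generator does **not** emulate: cohort (rather than period)
structure of smoking histories, infant/accident humps in the age
profile, migration, heterogeneous exposures across ages, coding-practice
breaks in cause-of-death series, and cross-country correlation of
epidemics. Passing tests therefore demonstrate the correctness of the
estimation chain under the model's assumptions, not robustness to every
artefact of real vital-statistics data.

## Numerical details and edge cases

- Penalized IRLS converges on relative deviance change < 10⁻¹¹ with a
  10⁻⁹ ridge for conditioning; non-convergence raises an error naming
  the country and sex.
- The GCV grid is λ ∈ 10⁻⁴…10⁶ (11 points); on noise-free data the
  criterion selects the smallest useful λ and the fit is basis-limited.
- `lung_saf` returns 0 when m_L = 0; `total_saf` returns 0 when a cell
  has no deaths; a terminal (85+) rate of zero is an error because the
  open interval cannot be closed.
- Analysis years outside the data span, roster mismatches between lag
  tables, missing record-holder lifetables and incomplete age schedules
  all raise errors carrying the offending cell identity.
- Reruns with the same config and seed are byte-identical across all CSV
  outputs; the JSON-lines run log records package versions, the seed and
  per-stage summaries.

## Problem sizes

Default verification runs use the four-country roster over 1950–2019
(19 age groups × 70 years × 2 sexes × 4 countries ≈ 10 600 cells per
surface), with exposure 10⁶ per age group for the Poisson-mode
attributable-fraction check. These sizes make every planted-truth
comparison sharp (Monte-Carlo noise well below the tolerances) while a
full pipeline run completes in a few seconds.

## Limitations

- The attributable-fraction coefficients shipped with the package are
  illustrative; conclusions about real countries require the published
  coefficient tables and real HMD/WHO inputs.
- The indirect method ignores smoking effects below age 45 and assumes
  the never-smoker schedule is time-invariant.
- The open 85+ group hides detail exactly where record-holding
  populations differ most.
- The lag measure inherits the usual caveat of reference-trend choice:
  it is defined relative to the roster's own record, not an external
  standard.
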