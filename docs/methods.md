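# Methods

## The decision problem

Two ESA strategies for anemia of stage-5 chronic kidney disease on
hemodialysis are compared from the healthcare-payer perspective:
darbepoetin-alfa once monthly (reference) and epoetin-beta thrice weekly
(intervention). Therapeutic success is serum hemoglobin (Hb) inside the
target band **[10.5, 12] g/dL**, closed at both ends: out-of-target is
defined as Hb > 12 or Hb < 10.5, so both boundary values count as success.

## Decision tree

The base-case model is a one-year decision tree. Each strategy is a chance
node: with probability CSR (the arm's clinical success rate) the patient
reaches the target band (effectiveness 1), otherwise not (effectiveness 0).
Cost accrues identically on both branches — the arm's annual per-patient
cost — reflecting the assumption that surveillance, hospitalization and
dialysis visits do not differ by outcome within an arm. Branch QALYs over
the one-year horizon use utility weights `success = 0.70`,
`failure = 0.55`; these are model inputs, chosen to bracket the range of
published EQ-5D utilities in hemodialysis populations (roughly 0.55–0.70,
lower with uncontrolled anemia), and are configurable per arm.

Roll-back computes probability-weighted expected payoffs per strategy;
expected values are exact (no sampling). From the rolled-back payoffs:

- ACER = cost / effectiveness per strategy;
- Δcost, Δeffect (intervention minus reference), ICER = Δcost/Δeffect;
- ICUR = Δcost/ΔQALY;
- dominance: Δcost < 0 and Δeffect > 0 flags the intervention *dominant*
  (no ratio is reported, per standard CEA practice); the reverse flags it
  *dominated*; Δeffect = 0 with Δcost ≠ 0 yields an `undefined` flag rather
  than an exception.

An explicit nested tree block (chance probabilities and terminal payoffs,
optionally produced by Markov runs) is also accepted in the configuration
for non-standard layouts.

## Markov cohort model

States are defined by Hb bands, half-open `[low, high)`:

| state | band (g/dL) | meaning |
|---|---|---|
| `alive_anemia` | [9, 10) | alive on hemodialysis, anemia/stroke complications |
| `alive_other` | [10, 12) | alive, other complications (e.g. catheter infection) |
| `dying_other` | [12, 13) | dying, other complications |
| `dying_anemia` | [13, ∞) | dying, anemia/stroke complications |
| `death` | — | absorbing |

Hb below 9 g/dL (the severe-anemia comparator band) maps to `alive_anemia`;
severe anemia is clinically closest to the anemia-complication state. This
mapping is configurable.

Death is an explicit fifth state. The two dying states transition to death
with a per-cycle probability `p_death_dying` (default 1); the source
clinical description distinguishes "dying" conditions without giving exit
probabilities, so the default treats them as one-cycle transit states.

Cycles are 28 days; the cycle-to-year conversion uses 365.25 days/year. The
lifetime horizon runs from the cohort start age (55) to a maximum age
(default 100): `ceil((max_age − start_age) · 365.25 / 28) = 588` cycles,
with early stopping once death occupancy exceeds `1 − 1e-6`. Costs and
QALYs accrue on the occupancy at the start of each cycle and are discounted
at an annual rate that defaults to **0%** (a 3% rate is available in
configuration); life-years are undiscounted. No half-cycle correction is
applied by default (a flag-free design choice: the four-week cycle makes
the correction small relative to the input uncertainty); state membership
changes at cycle boundaries.

Transition probabilities are not observable from arm summaries alone, so
they are configuration inputs with two helpers:

1. `transition_matrix_from_hb(mean, sd)` — with i.i.d. monthly Hb
   ~ N(mean, sd), the next band is independent of the current one, so every
   alive row equals the band-mass vector of the normal law (mass below
   9 g/dL folded into `alive_anemia`), and the dying rows route to death.
2. `estimate_transitions_from_cohort(records)` — row-normalized counts of
   consecutive-month band moves in patient-level data; source bands never
   observed keep a self-loop row.

Per-state cycle costs default to the arm's annual cost scaled by the cycle
length; per-state utilities default to `(0.55, 0.70, 0.50, 0.45, 0)` in the
table's order — alive-in-range highest, dying states below the alive ones,
death zero. All are configurable.

## Sensitivity analysis

**One-way**: the model is re-evaluated twice with one parameter pinned at
its low/high value, everything else at base case; the tornado bar width is
the absolute outcome swing. **Multi-way**: all `2^k` Cartesian corners for
up to `k = 4` parameters (beyond that the corner count is uninformative and
the request is refused in favor of PSA).

**PSA**: each of `n_samples` draws samples every uncertain parameter and
re-evaluates the full decision model.

- Costs: log-normal, moment-matched on the natural scale —
  `σ² = ln(1 + cv²)`, `μ = ln(mean) − σ²/2` — so the sample mean and CV
  reproduce the specified ones. Default cost CV is **0.10**, consistent
  with an observed ±10% spread of the incremental cost; configurable.
- Clinical probabilities: normal, truncated to [0, 1] **by rejection**
  (resampling), never by clipping, to avoid point masses at the bounds. In
  the bundled base case the success-probability SDs are the binomial
  standard errors of the observed counts (0.0345 and 0.0403).
- A beta family (moment-matched from mean and sd) and a `fixed` family are
  also available.

One pseudo-random stream is derived from the user seed; parameters are
drawn in **sorted parameter-path order**, so results are invariant to the
ordering of the configuration's distribution block and bitwise reproducible
for a fixed seed. CE-plane quadrant fractions use a sign partition in which
boundary points (Δcost = 0 or Δeffect = 0) fall into the adjacent lower
quadrant, guaranteeing the four fractions always sum to 1; the point
`(0, 0)` is separately labeled `origin` by the scalar `ce_quadrant`
operation, which follows the five-label contract exactly.

## Synthetic cohort generator

The generator reproduces the *summary structure* of the two study arms, not
ESA pharmacology. Defaults per arm:

| parameter | darbepoetin-alfa | epoetin-beta |
|---|---|---|
| n | 194 | 97 |
| monthly Hb (g/dL) | N(10.68, 0.98) | N(11.63, 0.32) |
| CV event rate / year | 0.0979 | 0.0309 |
| annual cost (USD) | 12,319.41 | 919.47 (log-normal, CV 0.10) |
| age (years) | N(56.3, 11.2) | N(55.2, 7.8), truncated at 18 |
| male fraction | 0.51 | 0.5155 |
| fistula fraction | 0.938 | 0.907 |

Monthly Hb values are i.i.d. by default — the source summaries give only
means ± SD, not within-patient correlation — with an optional AR(1)
coefficient (stationary parameterization, marginal variance preserved) for
sensitivity work. Draws are truncated below at 4 g/dL by resampling from
the marginal law, a tail event for realistic profiles.

Consequences for interpretation: per-*measurement* in-target fractions
converge to the normal band masses (≈ 0.48 and ≈ 0.88 for the two arms),
but a per-*patient* criterion such as "final three months all in target"
compounds under independence (≈ p³), which is *lower* than the patient-level
CSRs observed in real data, where Hb is strongly autocorrelated within
patients. Passing tests on the synthetic cohort therefore demonstrate
statistical calibration of the generator and correctness of the estimators,
not that the i.i.d. process matches real Hb trajectories. Patient-level
success aggregation is configurable (`final3` default, `all`,
`per_measurement`); the per-measurement mode is the one whose expectation
is analytically known and used in calibration tests.

## Cohort statistics

- CSR and event rates are plain proportions; percentage rendering rounds
  **half-up** at the displayed precision (so 78/97 renders 80.4% and
  124/194 renders 63.92%).
- Both the absolute difference of out-of-target percentages (the quantity
  the source reports as a "relative risk reduction", 16.48 points) and the
  conventional ratio-based RRR are exposed, under the distinct names
  `risk_difference_pct` and `relative_risk_reduction`; neither is silently
  renamed into the other.
- Mann–Whitney U uses mid-ranks for ties. For `n_a·n_b ≤ 20` the two-sided
  p-value is exact: full enumeration of all `C(n, n_a)` rank splits with
  `p = P(|U − μ| ≥ |U_obs − μ|)`; identical samples give p = 1 by symmetry.
  Larger samples use the tie-corrected normal approximation. The
  significance threshold is 0.05.

## Costs and currency

Cost items are carried in USD at full precision; Saudi Riyal amounts
convert at a configurable 3.77 SAR/USD. Rounding to cents (half-up) happens
only at rendering. The observed average annual costs ($12,319.41 /
$919.47) and the itemized cost-profile components are carried as
*independent* configurable inputs: the itemized sums do not reduce to the
averages, and the package does not attempt to reconcile them. The headline
annual saving is the plain difference 12,319.41 − 919.47 = **11,399.94**
(a printed value of 11,399.95 reflects last-cent rounding upstream).

## Numerical conventions and degenerate inputs

- Row-stochasticity, occupancy conservation and chance-node probability
  sums are enforced at `1e-9`; violations raise before any cycle runs and
  name the offending row.
- Zero-denominator rates/ratios raise a dedicated undefined-rate error,
  except the incremental comparison, where Δeffect = 0 returns an
  `undefined` flag (a comparison of identical strategies is a legitimate
  query, not a usage error).
- Empty cohorts generate empty collections and header-only CSVs; malformed
  CSV rows raise an error naming the 1-based data row.
- Configuration validation collects *all* schema violations before raising.
- Reports serialize with sorted keys; two runs with the same configuration
  and seed are byte-identical apart from the timestamp field.

## Problem sizes

The test suite and the acceptance script use 50,000 PSA samples (matching
the study's Monte Carlo size), 5,000 patients per arm for parameter
recovery, 100 random matrices/trees for the engine-vs-oracle checks, and
10,000–200,000 draws for distribution-calibration checks; the full suite
runs in a few seconds on one core.

## Known limitations

- Transition probabilities, state utilities and the arm-to-matrix mapping
  are inputs, not estimates; the Hb-band-mass construction assumes i.i.d.
  monthly Hb.
- The dying-state semantics (one-cycle transit by default) are a structural
  choice, not an observed quantity.
- No dose-titration or iron-kinetics modeling; no microsimulation (cohort
  occupancy only); no multi-strategy (> 2) efficiency frontiers; net
  monetary benefit is limited to a single willingness-to-pay threshold via
  the exposed ratios.
- Several summary statistics printed in the motivating study (its average
  cost-effectiveness ratios, incremental-cost figure and cost-utility
  table) cannot be derived from its other printed inputs; the package
  computes all such quantities from explicit inputs instead of reproducing
  those figures.
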