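# Methods

## Model structure

The model is a discrete-time Markov cohort simulation with five mutually
exclusive states: T2DM controlled on a second-line regimen, uncontrolled
T2DM (second-line oral drug withdrawn, insulin started), complicated T2DM,
death from T2DM, and death from other causes. Cycles are one year; the
cohort enters at age 40 with unit mass in the controlled state and is
followed for 40 cycles (ages 40–80). The topology is forward-progressing:
no remission or re-entry transitions, no tunnel states, and no
individual-level simulation.

### Competing risks

Transition rows are composed in a fixed order: the age-specific background
(other-cause) death probability `q_b(age)` is applied first from every
transient state, and the cause-specific disease transitions then partition
the surviving fraction `1 − q_b`. From the controlled state the survivors
split between failure (→ uncontrolled, probability `p_failure`) and direct
progression to the complicated state (`p_complication_controlled`); the
model raises a named error if those two sum above 1 rather than
renormalising. Diabetes mortality is zero in the controlled and
uncontrolled states and applies only from the complicated state
(`q_t2dm(age)` among other-cause survivors). This composition guarantees
row-stochastic matrices by construction.

### Rewards, half-cycle correction and discounting

Each transient state carries an annual cost and an annual disutility;
entering the complicated state additionally triggers a one-off event cost
(US$228) and utility decrement (0.13), so complications are counted both as
a state and as an event. By default the per-event rewards are charged to
the entrant flow only; a `recurrent_complication_events` switch charges
them instead to everyone occupying the complicated state each cycle, for
users who read the "recurrent complications" convention that way.

With half-cycle correction on (the default), rewards for cycle `t` accrue
to the trapezoidal average of start- and end-of-cycle occupancy,
approximating mid-cycle transitions; the correction applies identically to
costs and disutilities, while event rewards follow the (instantaneous)
flow and are not averaged. Cycle-`t` rewards are discounted by
`(1 + r)^(−t)` with `r = 0.03/yr` for both costs and effects; the
trapezoidal membership already mixes cycle ends, so a single exponent per
cycle keeps the convention simple and stable over the 40-year horizon.

### DALYs

DALYs are computed as discounted disutility-weighted person-years over the
horizon: living states contribute their disutility (0.220 uncomplicated —
both controlled and uncontrolled are clinically uncomplicated — and 0.274
complicated, i.e. 1 minus utilities 0.78 and 0.726), and dead states
contribute weight 1 per person-year, which is the horizon-truncated
years-of-life-lost component. There is no age weighting and no separate
life-expectancy table for YLL beyond the model horizon; fewer DALYs are
better, and "DALYs averted" is always a difference against a comparator.

## Cost-effectiveness analysis

Strategies are ranked by expected cost. Strong dominance means another
strategy costs no more and produces no more DALYs (strictly better on at
least one axis); extended dominance removes frontier candidates whose
incremental ICER is at least that of the next, more effective candidate,
until ICERs increase strictly along the frontier. Exact cost/DALY ties are
kept as co-optimal, ordered by name. Frontier rows report incrementals
against the previous frontier member; dominated rows report them against
the previous row in cost order, matching conventional CEA table layout. An
ICER with zero incremental effect is reported as undefined (NaN), never as
infinity. Ratios are rounded to the nearest dollar only for display.

Willingness-to-pay thresholds ship as named constants from the 2019
Ethiopian GDP per capita of US$953: the study threshold 0.5 × GDP
(US$476.5) and the WHO-CHOICE 1× / 3× GDP bands (953 / 2859).

## Probabilistic sensitivity analysis

Each iteration independently draws every uncertain parameter, rebuilds the
strategies, and re-runs the deterministic cohort model. Costs are gamma
distributed with `shape = (mean/sd)²`, `rate = mean/sd²`; probabilities and
disutilities are beta distributed with `ν = mean(1−mean)/sd² − 1`,
`α = mean·ν`, `β = (1−mean)·ν`. Rows whose published spread is absent or
rounds to zero (the saxagliptin progression probability and the
uncomplicated disutility) are degenerate at their mean, and the event
decrement (0.13) is fixed. The published min/max columns serve only as
one-way ranges and never truncate draws, since the distributional families
are assigned untruncated. No correlation structure is imposed (none is
reported). A draw combination that violates the structural constraint
`p_complication_controlled + p_failure ≤ 1` is rejected and redrawn from
the same stream, preserving the marginal families; the rejection count is
reported. Identical seeds give bit-identical samples.

Acceptability curves (CEAC) report, at each willingness-to-pay, the
fraction of iterations in which each strategy attains maximal net monetary
benefit (ties resolved toward the cheaper strategy, so columns sum to 1);
the acceptability frontier (CEAF) reports the strategy with the highest
*expected* net monetary benefit, which can differ from the probability
winner. The reference run in the source analysis is 100,000 iterations;
the package's tests and examples use 200–3,000 iterations, which leaves
the estimators unchanged and only widens Monte Carlo error to a level the
4-standard-error checks still absorb.

## One-way sensitivity analysis

Sweeps move one parameter across its range (default: the published min/max
— ±20% for costs, the printed probability ranges — and ±20% around the
packaged default for the synthetic failure probabilities) while everything
else stays at base case; the reported ICER is always between the fixed
base-case frontier pair (glibenclamide vs saxagliptin arms in the
reference study), so bars are comparable across parameters. The tornado
table sorts parameters by the absolute ICER range. Threshold analysis
locates willingness-to-pay crossings by scanning a 25-point grid (default)
for sign changes and refining each bracket with Brent root finding; an
empty result means the ICER never crosses the threshold on the range.

## Synthetic study inputs and calibration

Two inputs the source tables do not print are synthesised and fully
overridable through the config file:

- **Mortality schedules.** Annual probabilities follow a Gompertz form
  `q(age) = 1 − exp(−a·e^{b(age−40)})`, clamped to [0, 1], separately for
  background mortality and for diabetes death from the complicated state.
  The form gives the monotone age increase expected of adult mortality with
  two interpretable parameters (level at 40, log-slope per year).
- **Failure probabilities.** Annual controlled → uncontrolled probabilities
  per arm, ordered saxagliptin < glibenclamide < metformin-only to reflect
  the stronger glycemic control of the newer agent.

`calibrate_defaults` grid-searches these five quantities, keeps the points
whose deterministic base case reproduces the study's qualitative pattern
(metformin-only strongly dominated; saxagliptin arm fewest DALYs;
glibenclamide arm cheapest; saxagliptin frontier ICER between 1× and 3×
GDP per capita), and among those selects the point whose per-arm
(cost, DALY) pairs are closest in squared relative error to the published
expected values. The selected defaults are frozen in the package
(`PACKAGED_DEFAULTS`, failure probabilities 0.20 / 0.06 / 0.04 and Gompertz
pairs (0.015, 0.07) background, (0.08, 0.05) diabetes excess) and the
search log ships as `data/calibration_log.txt`. Under these defaults the
base-case saxagliptin ICER is ≈ US$1383 per DALY averted — in the required
qualitative band, though the published point estimates themselves are not
exactly recoverable without the unprinted inputs, which is why they are
treated as calibration anchors rather than targets. Because the mortality
and failure inputs are synthetic, agreement with the published per-arm
costs and DALYs demonstrates the machinery and the qualitative economics,
not a validated Ethiopian life table.

## Numerical choices and edge cases

- Occupancy conservation is enforced to 1e−10 in tests; transition rows to
  1e−12 at construction.
- `sd = 0` makes any distribution family degenerate at its mean rather than
  an error, mirroring table rows with no printed spread.
- Mortality schedules must cover every model age on a contiguous 1-year
  grid; lookups outside the range raise.
- The complicated state's annual treatment cost equals the insulin-regimen
  cost (treatment continues after a complication); its excess burden enters
  through the event rewards and the higher state disutility.
- Degenerate models (a single strategy, zero transition probabilities, one
  cycle) are valid and exercised in tests.

## Limitations

The synthetic mortality and failure inputs are calibrated, not estimated
from Ethiopian data; no household/societal costs, currency conversion or
inflation adjustment; no EVPI/EVPPI, correlated draws, tunnel states or
discrete-event extension; QALY outputs are out of scope (the outcome is
DALYs).
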