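# Methods

## The microworld in brief

One participant plays `T` yearly trials. At the start of each year the
player holds an annual income budget; they buy any subset of three
insurance schemes (health, life, property — fixed premiums per scheme per
trial), invest any affordable amount in mitigation, and bank the rest. The
environment then samples whether a climate disaster occurs, its type, and
its damages, deducts losses, and advances the year. Total wealth is
uninvested cash plus property wealth; maximizing it is the player's goal.

The disaster probability is endogenous:
`p = 1 − m · (cumulative mitigation / cumulative income)^k`, clamped to
[0, 1] defensively (with valid parameters it already lies in [1−m, 1]).
`k = 1` is the low-probability ("linear") condition and `k = 3` the
high-probability ("cubic") one; since `s³ < s` on (0, 1), the cubic curve
dominates pointwise at every interior investment share.

Insured losses are attenuated to `r = min((100/T)·purchases, cap)` percent
of the same base the uninsured loss would use. Note the deliberate
asymmetry, kept exactly as the model defines it: more purchases give a
*larger* insured loss percentage (capped), and the caps for injury (10%)
and fatality (20%) sit *below* the uninsured percentages (12.5%, 25%), so
with default parameters holding insurance is weakly beneficial in every
state — the insured loss never exceeds the uninsured one.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `total_trials` | 36 | game years `T` |
| `mitigation_return` | 0.85 | `m`; residual probability at full mitigation is 1−m |
| `probability_exponent` | 1 | `k`; 1 linear, 3 cubic |
| `initial_annual_income` | 8,760 EC | yearly budget |
| `initial_property_wealth` | 5,000,000 EC | see "open readings" below |
| `disaster_type_probs` | 0.33/0.33/0.34 | cyclone/drought/flood |
| `damage_probs` | 0.30/0.09/0.50 | injury/fatality/property |
| `base_loss_fractions` | 0.125/0.25/0.50 | uninsured loss of income/income/property |
| `insured_loss_caps_percent` | 10/20/50 | caps on `r` |
| `premiums` | 365 EC each | per scheme per trial; configurable, echoed in logs |
| `coverage_window` | `current` | which trial a purchase covers |

Premiums have no canonical value; 365 EC (~4% of the initial income, one EC
per day of the game year) keeps all three schemes affordable for most of a
typical game while making insurance a real budget trade-off. Because the
choice is consequential, every premium is echoed into the game-log header
so downstream analyses are premium-explicit.

## Conventions that make seeded runs reproducible

* Every stochastic step consumes a fixed number of `rng.random()` draws:
  one for occurrence (`occur iff p ≥ u`); if a disaster occurs, one for its
  type (cumulative thresholds in the order cyclone, drought, flood), then
  one per applicable damage mode in the order injury, fatality, property
  (`damage iff u ≤ p_mode`; property is skipped entirely for droughts).
  The `p ≥ u` / `u ≤ p` asymmetry between occurrence and damages is kept
  exactly as the model states it.
* Policy randomness and environmental randomness come from sub-streams
  spawned from one seed, so an agent's choices never perturb the
  environment's sample path. The random benchmark policy consumes exactly
  four draws per trial (three scheme coin-flips — a successful flip whose
  premium is unaffordable is skipped, not deferred — then one mitigation
  draw on U(0, post-premium income)).
* Monte-Carlo experiments derive each repetition's seed from
  `(base_seed, crc32(condition label), rep index)`, so conditions are
  comparable, reps independent, and results independent of execution order.
* Currency is held in float64 with no intermediate rounding; two-decimal
  rounding happens only at display. Wealth conservation (income − spend −
  losses = change in wealth) therefore holds to machine precision, i.e. to
  about 1e−9 EC relative at the game's multi-million-EC wealth scale —
  an absolute sub-nanocurrency bound is not representable in double
  precision at that magnitude.

## Within-trial order of operations

Pay premiums and increment purchase counts → invest in mitigation → bank
the remainder → compute `p` from the updated cumulative sums → sample
occurrence/type/damages → deduct losses → advance the year, granting the
(possibly reduced) income into the cumulative-income denominator. The
original tool documents its screens rather than its exact sequencing; this
invest-then-feedback order matches the tool's flow and is frozen here as
the package's contract.

Injury and fatality losses are both taken as percentages of the *same*
pre-loss income level, are deducted from uninvested cash in the trial they
occur, and permanently reduce the income granted in later years (they
compound across trials). The cumulative-income denominator accumulates
each year's possibly-reduced budget at grant time, not the nominal initial
income.

## Open readings, resolved

* **Property wealth "50,000,00 EC"** — ambiguous digit grouping; read as
  5,000,000 EC (the grouping style of the study's locale), configurable.
* **Coverage window** — "applicable for the subsequent trial" can mean the
  trial of purchase or the one after. Default `current` keeps purchase and
  consequence in one decision cycle; `next` implements the other reading.
  Both are tested.
* **Caps vs. base losses** — the injury/fatality caps (10/20%) lie below
  the uninsured base losses (12.5/25%); the caps are applied as stated.
* **Insurance coin flips** — the random benchmark flips one coin *per
  scheme* (three independent 50% decisions), matching the three schemes
  being independent options.
* **Per-scheme insurance ratios** — averaged over all trials (bought = 1,
  not bought = 0), not over bought trials only.

## Metrics

"Money available at that instance" — the denominator of all three monetary
ratios within a trial — is the year's income budget before any spending.
Consequently `total_investment_ratio = mitigation_ratio +
total_insurance_ratio` exactly (to float round-off), which the suite checks
at 1e−12. Aggregation is games-weighted: each game's mean over trials,
then the mean over games per condition; per-trial condition means are also
produced for trajectory plots. A mixed-design ANOVA convenience wrapper
(`metrics.investment_anova`, between-factor condition × within-factor
trial) delegates entirely to pingouin and is offered for exploratory
reports on simulated cohorts; no human-subject statistics are reproduced
here, since that data is not part of the package.

## What the simulations do and do not show

The benchmark experiment (random policy, 1000 repetitions per curve)
characterizes the *model*: it demonstrates the cubic condition's higher
average disaster probability under identical investment behavior, checks
sampling calibration, and exercises the accounting invariants. It emulates
no human behavior — real participants learn, react to feedback, and shift
from adaptation toward mitigation over the game, none of which a random or
constant agent does. Passing tests therefore validate the simulator's
mechanics and reproducibility, not any behavioral prediction.

Problem sizes used by the default suite — 1000-rep experiments, 1000
replayed games for conservation checks, 100,000-draw calibration — were
chosen so the binomial/bootstrap intervals involved are a few thousandths
wide, tight enough to detect a miscalibrated probability while keeping the
whole suite in the seconds range.

## Known limitations

* Single player only: no group play, government actors, or naturally
  occurring (non-anthropogenic) disaster sources.
* No learning agents; the built-in policies are benchmarks and fixtures,
  and behavioral models would plug in through the same policy interface.
* The insurance premium level is a modeling choice, not an estimated
  quantity; analyses sensitive to it should sweep it explicitly.
* Losses can drive uninvested cash transiently negative in extreme
  parameterizations (income losses are charged against cash); with the
  default parameters this does not occur in practice.
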