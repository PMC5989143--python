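# Methods

## The decision problem

`sepcea` models the economic consequences of adopting the vitamin C /
thiamine / hydrocortisone ("HAT") sepsis bundle early — before definitive
multi-centre trial evidence arrives — versus continuing standard care.
The question is framed as an opportunity-cost calculation: if the bundle
works as reported, what do a health system and its patients lose by
waiting roughly 2.5 years for confirmatory trials?

The model is a two-armed decision tree. In each arm a septic patient
passes through three chance nodes:

1. **ARF** — acute renal failure, yes/no;
2. **vital status** — survive or die;
3. **chronic RRT** — renal replacement therapy (dialysis or transplant),
   reached only by ARF survivors.

That gives five terminal paths per arm. Payoffs accrue over a fixed
5-year horizon, undiscounted:

* cost = hospital episode + bundle drugs (bundle arm only) + ARF episode
  (ARF paths) + 5 × annual RRT cost (RRT path);
* QALYs = 0 for decedents; area under a piecewise-linear utility curve
  for survivors.

Expected cost and QALYs per arm are the probability-weighted sums over
the terminal paths (rollback). The bundle-versus-standard comparison is
reported as incremental cost and QALYs with dominance classification on
the cost-effectiveness plane, an ICER in the trade-off quadrants, and
net monetary benefit NMB = λ·ΔQALY − ΔCost at a default willingness to
pay λ = $50,000/QALY.

## Parameters

| parameter | units | default (dispersion) | source/role |
|---|---|---|---|
| p_mort, standard | – | 0.404 (SE 0.071) | observational control cohort |
| p_arf, standard | – | 0.234 (SE 0.062) | observational control cohort |
| p_mort, bundle | – | 0.085 (SE 0.041) | observational treated cohort |
| p_arf, bundle | – | 0.097 (SE 0.043) | observational treated cohort |
| p_mort, standard, scenario 1 | – | 0.255 (SE 0.064) | literature calibration, see below |
| p_arf, standard, scenario 1 | – | 0.170 (SE 0.055) | Lopes et al. 2009 |
| c_hosp | USD/stay | 32,421 (SD 15,051) | Arefian et al. 2017 |
| c_bundle | USD/course | 528 (SD 26.50) | drug-cost estimate |
| c_arf | USD/episode | 11,016 (SE 279.59) | Silver et al. 2017 |
| c_rrt_annual | USD/year | 76,936 (SD 15,387) | USRDS 2017 |
| u_nonarf at 1 / 2.5 / 5 y | – | 0.666 / 0.701 / 0.677 (SD 0.280 / 0.281 / 0.301) | Cuthbertson et al. 2010 |
| u_arf | – | 0.40 (SD 0.37) | constant post-ARF utility |
| u_death | – | 0 (fixed) | structural |
| horizon | years | 5 (fixed) | long-term ARF outcomes |

All printed transition-probability SEs are binomial standard errors at a
cohort size of 47 per arm. The bundle-cost dispersion is quoted both as
"5%" and as $26.50; the explicit dollar figure is used. Dispersions are
used directly as sampling SDs whatever their label (SD or SE); the label
is preserved in the parameter table for transparency.

**Scenario construction.** *Baseline* contrasts the observed control and
treated cohorts. *Scenario 1* (bundle less effective) replaces the
standard-care probabilities with literature values; its overall
mortality is derived from the ARF-associated mortality m = 21.2% and
ARF rate a = 17.0% as m/(1−a) = 25.5%. That division form is an
inference — it is the unique simple combination reproducing the reported
25.5% — and is exposed as `derive_overall_mortality`. *Scenario 2*
(bundle ineffective) applies the scenario-1 standard-care probability
set to both arms, so the increment is exactly the drug cost.

**RRT-branch calibration.** The probability that an ARF survivor needs
chronic RRT is not reported anywhere. The package solves for it per arm
so that the deterministic rollback reproduces the reference per-arm
expected 5-year costs ($41,982 standard baseline, $35,867 bundle,
$38,068 standard scenario 1), giving 0.1302, 0.0542 and 0.0775. The
closed-form solve is cross-checked against a root-find on the full tree
in the test suite. Because these points are calibration outputs rather
than cohort observations, no empirical SE exists for them; they are
assigned a relative SE of 0.30 × point, the rounded median relative SE
of the six reported transition probabilities — i.e. the typical
parameter uncertainty elsewhere in the model. Calibrated values are
stored in the parameter table, logged at WARNING level on every run, and
overridable through the `calibration` argument of `load_scenario`.

**Conditional structure.** Only marginal mortality and ARF probabilities
are available, so death is modelled independently of ARF status within
an arm (p(die|ARF) = p(die|no ARF) = p_mort). This is a genuine
modelling assumption: in reality ARF raises mortality, so the model may
shift some deaths between branches, but the arm-level expected values it
is calibrated to are unaffected.

**QALY conventions.** The survivor utility curve is anchored at
u(0) := u(1 y) (no earlier measurement exists), linearly interpolated
between knots, and held constant past the last knot; integration is
trapezoidal. The non-ARF track therefore accrues
1·0.666 + 1.5·(0.666+0.701)/2 + 2.5·(0.701+0.677)/2 = 3.41375 QALYs over
5 years, the constant ARF track 2.0, and decedents 0 (no partial-year
survival — there is no time-of-death model).

## Probabilistic sensitivity analysis

Each PSA draw samples every parameter independently from a
moment-matched distribution: beta for probabilities and utilities
(mean/variance inversion; infeasible moments, variance ≥ m(1−m), raise
an error), gamma for costs (shape = (m/s)², scale = s²/m). A truncated
normal family is available for sensitivity work; it matches moments
*before* truncation and reports the realized post-truncation mean/SD so
the shift is explicit. Families respect their supports by construction,
so no clamping is ever needed.

Within a draw, parameters that are identical in both arms — all costs
and utilities, and in scenario 2 the transition probabilities — receive
the same realized value in both arms (common random numbers). This makes
the scenario-2 incremental cost equal the drawn bundle cost exactly and
its incremental QALYs identically zero in every draw, the structural
identity the deterministic analysis also shows.

Summaries use the default 1000 draws, means, and 2.5th/97.5th empirical
percentiles under the linear-interpolation (closest-ranks) rule
(`numpy.percentile`, method `"linear"`; the 2.5th percentile of the
integers 1..100 is 3.475 under this rule). Dominance probability is the
fraction of draws with ΔCost < 0 and ΔQALY > 0; the CEAC reports
P(NMB > 0) over a willingness-to-pay grid.

**Worst-case carry.** Because scenario 2's own QALY increments are
identically zero under common random numbers, an optional, clearly
labelled reporting mode substitutes scenario 1's ΔQALY draws when
summarizing scenario 2, to illustrate the worst plausible health
outcome; with it the probability of a net health loss is about 2–2.5%.
The mode is off by default.

## Population and hospital scaling

National totals multiply per-patient increments by the expected case
count: incidence 300/100,000/year × population 325,000,000 × 2.5-year
adoption window = 2,437,500 cases. The population constant is not itself
a reported input; it is the unique round figure consistent with the
reference national totals, and is overridable. Display rounding follows
the field's convention (billions of USD and millions of QALYs to one
decimal); raw values are always retained in machine output. The hospital
worked example multiplies 230 patients/year by the $528 bundle cost
($121,440/year) and reports the break-even patient count
⌈outlay / per-patient saving⌉ (47 at the conservative $2,590 saving).

## Synthetic cohorts

The microsimulation draws each synthetic patient's path from the arm's
branch probabilities and assigns the deterministic terminal-path cost
and QALY. Utility and cost dispersions express *parameter* uncertainty,
which lives in the PSA, not patient heterogeneity; keeping payoffs
deterministic given the path makes the cohort mean an unbiased estimate
of the rollback expectation, so the simulator is an independent oracle
for the tree engine (verified at n = 200,000 per arm and scenario,
within 3 standard errors). What the generator does *not* emulate:
correlation between ARF and death beyond the conditional-independence
convention, within-path cost variance, time-to-event structure, or
patient covariates — so agreement with it validates the tree arithmetic,
not the model's fidelity to real sepsis cohorts.

## Numerical and reporting choices

* Dominance classification uses a 1e-9 tie tolerance; boundary cases
  with no health change are classified as dominated when costlier and as
  a trade-off with a limiting (infinite) ICER when cheaper, since strict
  dominance requires a health gain.
* Calibration root-finding uses Brent's method with xtol 1e-12; branch
  probabilities must sum to 1 within 1e-12.
* Parameter tables are CSV with `repr`-formatted floats so read(write(x))
  is exact, field for field.
* All machine outputs are deterministic given the configuration
  (sorted-key JSON, no timestamps); identical configurations give
  byte-identical files.
* Problem sizes in the shipped tests and acceptance script: 1000 PSA
  draws (the analysis default), 200,000-patient microsimulation cohorts,
  10⁶ draws for empirical moment checks, 1000 random parameter sets for
  the rollback-vs-enumeration property.

## Known limitations and quantities that do not reproduce

The reference analysis this model is calibrated against contains
internal inconsistencies, and several of its reported figures cannot —
and should not — be matched exactly:

* **Per-arm costs across scenarios.** The scenario-1 standard-care cost
  ($38,068) and scenario-2 standard-care cost ($37,022) are reported
  under identical stated probabilities, and the bundle arm is reported
  at $35,867 (baseline) but $35,478 (scenario 1) with unchanged
  parameters. These are most plausibly Monte-Carlo means from different
  1000-draw runs. The engine keeps one consistent parameterization
  (bundle arm calibrated once, to $35,867) and reports both
  deterministic and PSA-mean outputs; its deterministic scenario-1
  saving is therefore $2,201 rather than the reported $2,590.
* **Uncertainty interval endpoints.** The reported 95% uncertainty
  interval endpoints (e.g. baseline national savings −$7.3bn to $33.9bn)
  depend on an unknown RNG, seed and distribution table; this model's
  intervals bracket the same order of magnitude but are not expected to
  match endpoint-for-endpoint. The reported scenario-2 interval
  (−$0.9bn to −$0.7bn) excludes its own point estimate (−$1.3bn) and is
  treated as an artifact, not a target.
* **Dominance probabilities.** The reported 93.6% (baseline) and 87.8%
  (scenario 1) dominance frequencies depend on the same unknown
  distribution choices, chiefly the variance of the unreported
  RRT branch. Under this package's committed dispersion rule the
  corresponding 1000-draw estimates are ≈ 97% and ≈ 80%; the scenario-1
  shortfall also reflects the $2,201-vs-$2,590 saving inconsistency
  above. The acceptance suite asserts the reported values at 3 binomial
  SEs and records these two checks as failing rather than widening the
  tolerance or tuning the dispersion toward them.
* **Aggregate net monetary benefit.** At $50,000/QALY the per-patient
  NMB implied by the reference per-patient deltas is 50,000·1.46 + 6,115
  = $79,115, i.e. about $193bn over 2,437,500 cases; the reported $108bn
  headline is not derivable from any combination of the reported figures
  and is not matched. Similarly the "worst possible" ≈ $5,700 per QALY
  figure is approximately $7.3bn/1.3m ≈ $5,615 and is treated as
  approximate. The package reports its own computed NMB.

Implementation and de-implementation costs (training, labour), QALY
gains from reduced post-sepsis syndrome, demographic stratification,
time-varying incidence and discounting are all outside the model's
scope.
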