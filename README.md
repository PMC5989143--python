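# sepcea

Decision-analytic cost-effectiveness model of **early adoption of the
vitamin C / thiamine / hydrocortisone ("HAT") sepsis bundle** versus
standard care.

When a cheap, plausibly life-saving treatment is supported only by
uncertain evidence, decision-makers face a trade-off: adopt early and
risk paying for an ineffective drug, or wait years for definitive trials
and risk forgoing large savings in dollars and lives. `sepcea` quantifies
that trade-off for a US health system: it is intended for health
economists, intensive-care researchers and hospital decision-makers who
want the model's arithmetic to be transparent, reproducible and
re-runnable under their own assumptions.

## The model

A two-armed decision tree. In each arm (standard care, bundle) a septic
patient passes through chance nodes for acute renal failure (ARF),
vital status, and — among ARF survivors — chronic renal replacement
therapy (RRT), giving five terminal paths per arm. Over a fixed 5-year
horizon, undiscounted:

```
cost  = c_hosp + c_bundle·1[bundle arm] + c_arf·1[ARF] + 5·c_rrt·1[RRT]
QALYs = 0 for decedents; ∫₀⁵ u(t) dt for survivors (piecewise-linear u)
```

Expected values per arm come from probability-weighted rollback; the
comparison is reported as ΔC, ΔE (bundle − standard) with dominance
classification, ICER = ΔC/ΔE in the trade-off quadrants, and net
monetary benefit NMB = λ·ΔE − ΔC at λ = $50,000/QALY. Parameter
uncertainty is propagated by a probabilistic sensitivity analysis
(1000 draws; beta distributions for probabilities and utilities, gamma
for costs, moment-matched to the published means and dispersions, with
common random numbers for parameters shared between arms). Three
scenarios are built in: the bundle as observed (`baseline`), less
effective per literature-based standard-care rates (`scenario1`), and
ineffective (`scenario2`). Per-patient results scale to national totals
(300 cases/100,000/year × 325M population × 2.5-year evidence window)
and down to a single hospital's budget. See `docs/methods.md` for the
full specification, calibration of the unreported RRT-branch
probabilities, and known limitations.

## Worked example

```
$ sepcea run --scenario baseline --n-draws 1000 --seed 1 --outdir out/
WARNING calibrated (not literature-reported) parameter: baseline standard p_rrt_given_arf_survivor = 0.130166 (SE 0.039050)
WARNING calibrated (not literature-reported) parameter: baseline bundle p_rrt_given_arf_survivor = 0.054169 (SE 0.016251)
baseline: delta cost $-6,115, delta QALY 1.161 (dominant)
PSA (n=1000, seed=1): P(dominant) = 97.6%, P(health loss) = 0.0%
national (2,437,500 cases): saving $14.9bn, QALYs 2.8m
```

Reading this: per patient, the bundle is expected to *save* $6,115 and
add 1.16 QALYs over five years, so it dominates standard care (cheaper
and more effective); across 1000 parameter draws that conclusion holds
97.6% of the time, and a net health loss essentially never occurs.
Scaled to the ~2.4 million US severe-sepsis cases expected over a
2.5-year evidence-gathering window, the opportunity cost of waiting is
about $14.9bn and 2.8m QALYs. The warnings flag the two calibrated
(not literature-reported) RRT-branch probabilities used in the run.

`out/` contains the machine-readable report: `deterministic.json`,
`psa_draws.csv`, `psa_summary.json`, `ceac.csv`, `national.json`,
`hospital.json` (230 patients/year → $121,440 outlay and the break-even
patient count), `tree.txt` (an audit outline of the tree) and
`manifest.json` (every parameter value, calibrated default, seed and
version). Identical configurations produce byte-identical outputs.

The same machinery is available as a library:

```python
from sepcea import DecisionTree, load_scenario, roll_back, incremental

tree = DecisionTree()
out = roll_back(tree, load_scenario("baseline"))
print(incremental(out["standard"], out["bundle"]))
# IncrementalResult(delta_cost=-6114.99..., delta_qaly=1.1607...,
#                   classification='dominant', icer=None)
```

Other subcommands: `sepcea psa` (draws + summary only), `sepcea scale`
(national-impact table), `sepcea simulate` (patient-level synthetic
cohorts), `sepcea fixtures` (the three-scenario parameter table CSV).

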