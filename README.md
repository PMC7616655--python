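# practical-sizer

Simulation-based sample-size determination for **PRACTical trials**
(personalized randomized controlled trials) with a binary outcome,
including two-stage **PRACTical-SMART** designs with re-randomization to
second-line treatment.

## The problem

In settings with no single standard of care — the motivating example is
neonatal sepsis treated with eight combination antibiotic regimens — each
patient can only be randomized among the treatments that are clinically
acceptable for them.  The set of acceptable treatments is the patient's
*pattern* `S_k`, and the trial's goal is a **treatment ranking** that lets
a clinician pick a good option from any future patient's pattern, not a
hypothesis test.  Power-based sample-size formulas therefore do not apply.

This package sizes such trials by **value of information**: for each
candidate sample size `n` it simulates many trials from an assumed truth,
analyzes each one the way the real trial would be analyzed, and measures
how good the resulting treatment choices would be for a future population.

## The model and the measures

Simulated trials are analyzed with a pattern-adjusted logistic model that
borrows strength across patterns like a network meta-analysis:

    logit(P_jk) = α_k + θ_j                     (single-stage)
    logit(P_jklm) = α_k + θ_j + ψ_l             (SMART, weighted fit)

where `α_k` are pattern intercepts, `θ_j` treatment effects (log odds
ratios vs a reference), and `ψ_l` second-line effects with "no second-line
treatment" as reference.  In the SMART design, patients who never reach the
second randomization are *cloned* — one record per regimen in their
second-line menu `S_2m`, each weighted `1/|S_2m|` — so the weighted fit
estimates marginal effects over the whole population.

From each fitted trial the estimated best option per pattern,
`ĵ_k = argmin_j P̂_jk` (or the best first/second-line strategy
`(ĵ, l̂)`), is scored against the truth with three measures, each weighted
by the observed pattern prevalences `λ̂_k`:

* **Percent of perfect information** — mortality prevented by using the
  trial-informed choices instead of random choices, as a percentage of what
  perfect knowledge of the rankings would prevent:
  `100 · Σ_k λ̂_k (mean_j P_jk − P_ĵk) / Σ_k λ̂_k (mean_j P_jk − min_j P_jk)`
  (both expectations averaged over simulated trials before taking the ratio).
* **Near-best probability** — chance the chosen option's true risk is within
  `κ` (default 2 percentage points) of the best eligible option's.
* **Improvement over random choice** — chance the chosen option's true risk
  is no worse than the average over the patient's eligible options.

The NeoSep1 neonatal-sepsis trial scenarios ship as presets: 20% baseline
28-day mortality, per-regimen odds ratios from 1.0 down to 0.45, three
patterns reflecting local antibiotic resistance, sensitivity variants
(effects scaled ±25%, reversed effects, an all-regimen fourth pattern,
sparse patterns, unequal pattern frequencies), and SMART presets with
switching probabilities 0.10–0.75 and 5% early mortality.

## Worked example

```python
import practical_sizer as ps

smart = ps.preset_scenario("smart_base_q25")      # 25% switching
data = ps.simulate_smart_trial(smart, n=3000, seed=1)
fit = ps.fit_two_stage_weighted_logistic(data)
best = ps.estimated_best(ps.predict_risks(fit, smart))
summary = ps.run_cell(smart, n=3000, replicates=100, master_seed=7)
```

Running `python examples/smart_design.py` (which does the above) prints:

```
simulated 3000 infants -> 8051 analysis records (switchers keep 1 record, non-switchers are cloned with weights 1/|menu|)

estimated best strategy per pattern (true mortality in brackets):
  pattern 1: Fos+Amik -> Flom+Amik   [est 17.2%, true 15.0%]
  pattern 2: Meropenem -> no second line   [est 14.1%, true 10.1%]
  pattern 3: Meropenem -> no second line   [est 15.5%, true 10.1%]

Monte Carlo over 100 trials of n=3000:
  percent of perfect-information reduction: 54.2
  near-best (within 2pp) probability:       0.77
  improvement over random strategy:         0.88
```

Read this as: a 3000-infant SMART trial would, on average, realize about
half of the mortality reduction that perfect knowledge of the strategy
rankings would allow, and would pick a strategy within 2 percentage points
of the best one for 77% of future patients.  Comparing such summaries
across an `n` grid (see `examples/single_stage_curves.py` and the
`practical-sizer run` CLI) is the sample-size calculation.

Other examples: `examples/scenario_tables.py` (the preset truth tables),
`examples/custom_scenario.py` (your own network via the JSON schema).

## Command line

```bash
practical-sizer run --design practical --scenario base_case --scenario sparse \
    --n-grid 100,500,2000,10000 --replicates 1000 --seed 20240709 \
    --out results.csv --figure-data F1
```

writes a long-format CSV (scenario, design, n, measure, kappa, estimate,
mc_se, replicates), a JSON run manifest, and optionally per-figure
plot-ready tables (F1–F3 single-stage, F5–F7 SMART).

## Limitations

The two-stage model is not fully identified under the NeoSep1 structure
(the no-second-line level coincides with the meropenem first-line effect);
fitted probabilities and rankings are identified, and aliased levels are
reported in `FitResult.aliased`.  How non-switchers' outcomes relate to
second-line effects is a genuine modelling choice, switchable via
`simulate_smart_trial(..., clone_outcomes=...)`; see `docs/methods.md` for
the full discussion and known discrepancies at high switching rates.
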