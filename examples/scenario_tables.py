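"""Print the NeoSep1 scenario presets: patterns, odds ratios, true risks.

The scenario is the 'truth' of the simulation study: eight antibiotic
regimens, three personalized randomization patterns reflecting local
antibiotic resistance, a 20% baseline 28-day mortality and per-regimen odds
ratios.  The printed risks are what the trial is trying to rank.
"""

import practical_sizer as ps

base = ps.preset_scenario("base_case")
larger = ps.scale_scenario_effects(base, 1.25)
smaller = ps.scale_scenario_effects(base, 0.75)
reversed_ = ps.reverse_scenario_effects(base)

print("First-line regimens (true 28-day mortality, % by scenario)")
print(f"{'regimen':14s} {'OR':>5s} {'base':>6s} {'larger':>7s} {'smaller':>8s} {'reversed':>9s}  patterns")
for arm in base.treatments:
    j = arm.id
    pats = ",".join(str(p.id) for p in base.patterns if j in p.members)
    print(
        f"{arm.label:14s} {base.odds_ratios[j]:5.2f} {100 * base.risk(j):6.1f}"
        f" {100 * larger.risk(j):7.1f} {100 * smaller.risk(j):8.1f}"
        f" {100 * reversed_.risk(j):9.1f}  {pats}"
    )

smart = ps.preset_scenario("smart_base_q25")
tab = ps.build_strategy_risk_table(smart)
print("\nFirst/second-line strategy mortality (%), Pattern 2")
for (k, j, l), risk in sorted(tab.entries.items()):
    if k != 2:
        continue
    first = dict((t.id, t.label) for t in base.treatments)[j]
    second = "(no second line)" if l is None else dict(
        (t.id, t.label) for t in smart.second_line_treatments)[l]
    print(f"  {first:14s} -> {second:16s} {100 * risk:5.1f}")
print("\nEach strategy risk is expit(logit(0.20) + log OR1_j + log OR2_l);")
print("the trial's goal is to rank these options within each pattern.")
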