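"""Data-generating scenarios for PRACTical trial sample-size simulations.

A PRACTical (personalized randomized controlled) trial compares a network of
treatments in which each patient is randomized only among the treatments that
are clinically acceptable for them.  The set of acceptable treatments is the
patient's *pattern* ``S_k``; all patients sharing a pattern form a *subgroup*
with expected prevalence ``lambda_k``.  A data-generating scenario fixes the
treatments, the patterns and their frequencies, and the true adverse-outcome
probability ``P_jk`` for every treatment ``j`` eligible in subgroup ``k``.

Risks are generated on the logit scale from a baseline risk (the risk under
the reference treatment) and per-treatment odds ratios:

    P_j = expit(logit(baseline) + log(OR_j))

so the odds ratios, not the (rounded) printed risks, are the authoritative
parameters.

The module ships presets for the NeoSep1 neonatal-sepsis trial: eight
combination antibiotic regimens, three personalized randomization patterns
reflecting geographical levels of antibiotic resistance, and the sensitivity
variants (scaled effects, reversed effects, an all-regimen fourth pattern,
sparse patterns, unequal pattern frequencies).  SMART presets add the
second-line randomization structure: second-line lists determined by the
first-line regimen, second-line odds ratios, a switching probability ``q``
and early mortality before the second randomization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import expit, logit

__all__ = [
    "TreatmentArm",
    "RandomizationPattern",
    "SingleStageScenario",
    "SmartScenario",
    "StrategyRiskTable",
    "odds_ratio_to_probability",
    "scale_scenario_effects",
    "reverse_scenario_effects",
    "build_strategy_risk_table",
    "preset_scenario",
    "PRESET_NAMES",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "save_scenario",
]

_FREQ_TOL = 1e-9


class ScenarioError(ValueError):
    """Raised for invalid scenario definitions or unknown preset names."""


def odds_ratio_to_probability(baseline_risk: float, odds_ratio: float) -> float:
    """Risk implied by an odds ratio relative to a baseline risk.

    Computes ``expit(logit(baseline_risk) + log(odds_ratio))``, i.e. applies
    the odds ratio on the logit scale.

    Parameters
    ----------
    baseline_risk
        Probability of the adverse outcome under the reference treatment,
        strictly between 0 and 1.
    odds_ratio
        Odds ratio (treatment vs reference), strictly positive.
    """
    if not 0.0 < baseline_risk < 1.0:
        raise ScenarioError(f"baseline_risk must be in (0, 1), got {baseline_risk}")
    if not odds_ratio > 0.0:
        raise ScenarioError(f"odds_ratio must be > 0, got {odds_ratio}")
    return float(expit(logit(baseline_risk) + math.log(odds_ratio)))


@dataclass(frozen=True)
class TreatmentArm:
    """A treatment regimen: short stable code plus human-readable label."""

    id: str
    label: str


@dataclass(frozen=True)
class RandomizationPattern:
    """A personalized randomization list ``S_k`` with expected prevalence."""

    id: int
    members: tuple[str, ...]
    frequency: float

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ScenarioError(f"pattern {self.id}: members must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise ScenarioError(f"pattern {self.id}: duplicate members")
        if not 0.0 <= self.frequency <= 1.0:
            raise ScenarioError(f"pattern {self.id}: frequency outside [0, 1]")


@dataclass(frozen=True)
class SingleStageScenario:
    """Truth for a single-randomization PRACTical trial.

    ``risk_matrix`` maps ``(treatment_id, pattern_id) -> P_jk`` for every
    eligible pair.  In the NeoSep1 scenarios the generative model carries no
    pattern main effect, so ``P_jk`` depends on ``j`` only, but the matrix is
    the contract consumed downstream.
    """

    name: str
    treatments: tuple[TreatmentArm, ...]
    patterns: tuple[RandomizationPattern, ...]
    baseline_risk: float
    odds_ratios: Mapping[str, float]

    def __post_init__(self) -> None:
        ids = [t.id for t in self.treatments]
        if len(set(ids)) != len(ids):
            raise ScenarioError("treatment ids must be unique")
        known = set(ids)
        for pat in self.patterns:
            missing = set(pat.members) - known
            if missing:
                raise ScenarioError(f"pattern {pat.id} references unknown treatments {missing}")
        total = sum(p.frequency for p in self.patterns)
        if abs(total - 1.0) > _FREQ_TOL:
            raise ScenarioError(f"pattern frequencies sum to {total!r}, not 1")
        if set(self.odds_ratios) != known:
            raise ScenarioError("odds_ratios must cover exactly the declared treatments")
        for j, orr in self.odds_ratios.items():
            if not orr > 0:
                raise ScenarioError(f"odds ratio for {j} must be > 0")
        if not 0.0 < self.baseline_risk < 1.0:
            raise ScenarioError("baseline_risk must be in (0, 1)")
        if not self._connected():
            raise ScenarioError(
                "treatment-pattern graph is disconnected; model (pattern + treatment) "
                "effects would not be identifiable"
            )

    def _connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(("t", t.id) for t in self.treatments if self.is_used(t.id))
        for pat in self.patterns:
            g.add_node(("p", pat.id))
            for j in pat.members:
                g.add_edge(("p", pat.id), ("t", j))
        return nx.is_connected(g) if g.number_of_nodes() else False

    def is_used(self, treatment_id: str) -> bool:
        return any(treatment_id in p.members for p in self.patterns)

    @property
    def treatment_ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.treatments)

    @property
    def pattern_frequencies(self) -> np.ndarray:
        return np.array([p.frequency for p in self.patterns])

    def risk(self, treatment_id: str) -> float:
        """True risk ``P_j`` under a treatment (pattern-free in NeoSep1)."""
        return odds_ratio_to_probability(self.baseline_risk, self.odds_ratios[treatment_id])

    @property
    def risks(self) -> dict[str, float]:
        return {j: self.risk(j) for j in self.treatment_ids}

    @property
    def risk_matrix(self) -> dict[tuple[str, int], float]:
        """``(j, k) -> P_jk`` for every eligible treatment-pattern pair."""
        return {(j, p.id): self.risk(j) for p in self.patterns for j in p.members}

    @property
    def reference(self) -> str:
        return self.treatments[0].id


@dataclass(frozen=True)
class SmartScenario:
    """Truth for a two-stage PRACTical-SMART trial.

    ``second_line_pattern_map`` maps ``(first-line pattern id, first-line
    treatment id)`` to the ordered second-line list ``S_2m`` (possibly empty:
    meropenem has no second randomization).  ``switch_prob`` is the
    probability ``q_jk`` that a patient needs second-line treatment, either a
    scalar or a per-``(j, k)`` mapping; ``early_mortality_prob`` is the
    probability of death before the second randomization (an adverse outcome,
    never re-randomized).
    """

    name: str
    first_stage: SingleStageScenario
    second_line_treatments: tuple[TreatmentArm, ...]
    second_line_pattern_map: Mapping[tuple[int, str], tuple[str, ...]]
    second_line_odds_ratios: Mapping[str, float]
    switch_prob: float | Mapping[tuple[str, int], float]
    early_mortality_prob: float

    def __post_init__(self) -> None:
        ids = [t.id for t in self.second_line_treatments]
        if len(set(ids)) != len(ids):
            raise ScenarioError("second-line treatment ids must be unique")
        known = set(ids)
        for (k, j), lst in self.second_line_pattern_map.items():
            if j in lst:
                raise ScenarioError(
                    f"second-line list for pattern {k}, first-line {j} repeats the regimen already received"
                )
            if set(lst) - known:
                raise ScenarioError(f"unknown second-line treatments in list for ({k}, {j})")
        for pat in self.first_stage.patterns:
            for j in pat.members:
                if (pat.id, j) not in self.second_line_pattern_map:
                    raise ScenarioError(f"no second-line list declared for pattern {pat.id}, treatment {j}")
        for l_id, orr in self.second_line_odds_ratios.items():
            if l_id not in known:
                raise ScenarioError(f"odds ratio for unknown second-line treatment {l_id}")
            if not orr > 0:
                raise ScenarioError(f"second-line odds ratio for {l_id} must be > 0")
        if not 0.0 <= self.early_mortality_prob <= 1.0:
            raise ScenarioError("early_mortality_prob must be in [0, 1]")
        for q in ([self.switch_prob] if np.isscalar(self.switch_prob) else self.switch_prob.values()):
            if not 0.0 <= q <= 1.0:
                raise ScenarioError("switch probabilities must be in [0, 1]")

    def second_line_list(self, pattern_id: int, first_line: str) -> tuple[str, ...]:
        return tuple(self.second_line_pattern_map[(pattern_id, first_line)])

    def q(self, first_line: str, pattern_id: int) -> float:
        if np.isscalar(self.switch_prob):
            return float(self.switch_prob)
        return float(self.switch_prob[(first_line, pattern_id)])

    @property
    def second_line_ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.second_line_treatments)


@dataclass(frozen=True)
class StrategyRiskTable:
    """True risks ``P_jklm`` for every reachable first/second-line strategy.

    Keys are ``(pattern_id, first_line_id, second_line_id_or_None)``; ``None``
    marks the no-second-randomization strategy (empty second-line list), whose
    risk is the first-line-only risk.  Unreachable combinations are absent.
    """

    entries: Mapping[tuple[int, str, str | None], float]

    def strategies(self, pattern_id: int) -> list[tuple[str, str | None]]:
        """Eligible (first-line, second-line) strategies for one pattern."""
        return [(j, l) for (k, j, l) in self.entries if k == pattern_id]

    def __getitem__(self, key: tuple[int, str, str | None]) -> float:
        return self.entries[key]


def build_strategy_risk_table(smart: SmartScenario) -> StrategyRiskTable:
    """Tabulate ``P_jklm = expit(logit(baseline) + log(OR1_j) + log(OR2_l))``.

    For strategies with no second randomization the second-line term is
    omitted, so the strategy risk equals the first-line-only risk.
    """
    base = smart.first_stage
    eta0 = logit(base.baseline_risk)
    entries: dict[tuple[int, str, str | None], float] = {}
    for pat in base.patterns:
        for j in pat.members:
            eta_j = eta0 + math.log(base.odds_ratios[j])
            second = smart.second_line_list(pat.id, j)
            if not second:
                entries[(pat.id, j, None)] = float(expit(eta_j))
            for l_id in second:
                entries[(pat.id, j, l_id)] = float(
                    expit(eta_j + math.log(smart.second_line_odds_ratios[l_id]))
                )
    return StrategyRiskTable(entries)


def scale_scenario_effects(scenario: SingleStageScenario, factor: float) -> SingleStageScenario:
    """Scale every log odds ratio by ``factor`` (baseline risk unchanged).

    ``factor=1.25`` gives the larger-treatment-effects sensitivity scenario,
    ``factor=0.75`` the smaller-effects one.
    """
    if not factor > 0:
        raise ScenarioError(f"factor must be > 0, got {factor}")
    new_ors = {j: math.exp(factor * math.log(orr)) for j, orr in scenario.odds_ratios.items()}
    suffix = "" if factor == 1.0 else f"_x{factor:g}"
    return replace(scenario, name=scenario.name + suffix, odds_ratios=new_ors)


def reverse_scenario_effects(scenario: SingleStageScenario) -> SingleStageScenario:
    """Reassign the multiset of true risks to treatments in reversed rank order.

    The previously worst treatment receives the best risk and vice versa;
    ties in risk are broken by canonical (declaration) order.  Baseline risk
    and odds ratios are recomputed so the reference treatment's odds ratio
    stays exactly 1.
    """
    ids = list(scenario.treatment_ids)
    risks = np.array([scenario.risk(j) for j in ids])
    # stable sort: descending risk, canonical order breaking ties
    order = np.argsort(-risks, kind="stable")
    new_risks = dict(zip([ids[i] for i in order], np.sort(risks)))
    base = new_risks[scenario.reference]
    odds = {j: float(np.exp(logit(r) - logit(base))) for j, r in new_risks.items()}
    return replace(
        scenario,
        name=scenario.name + "_reversed",
        baseline_risk=float(base),
        odds_ratios=odds,
    )


# --------------------------------------------------------------------------
# NeoSep1 presets
#
# Treatment codes follow the first-line table's row order: this is the only
# lettering under which Pattern 3 = {E, F, H} = {Fos+Flom, Pip-Taz, Mero} and
# the amikacin-containing regimens are exactly {C, D, G}.

_REGIMENS: tuple[tuple[str, str], ...] = (
    ("A", "Amp/Pen+Gent"),
    ("B", "Cefotaxime"),
    ("C", "Fos+Amik"),
    ("D", "Flom+Amik"),
    ("E", "Fos+Flom"),
    ("F", "Pip-Taz"),
    ("G", "Pip-Taz+Amik"),
    ("H", "Meropenem"),
)

_BASELINE_RISK = 0.20

_FIRST_LINE_OR: dict[str, float] = {
    "A": 1.0, "B": 0.99, "C": 0.84, "D": 0.84,
    "E": 0.81, "F": 0.76, "G": 0.70, "H": 0.45,
}

_SECOND_LINE_OR: dict[str, float] = {
    "B": 0.98, "C": 0.86, "D": 0.84, "E": 0.83,
    "F": 0.81, "G": 0.70, "H": 0.61,
}

_PATTERNS_MAIN: tuple[tuple[str, ...], ...] = (
    ("A", "B", "C", "D", "E"),       # WHO-recommended regimens still in use
    ("C", "D", "E", "F", "G", "H"),  # moderate resistance
    ("E", "F", "H"),                 # high resistance
)

_PATTERNS_SPARSE: tuple[tuple[str, ...], ...] = (
    ("A", "B", "E"),
    ("C", "D", "E", "G"),
    ("E", "F", "H"),
)

# Second-line lists by first-line regimen (self-exclusion already applied);
# meropenem first-line has no second randomization.
_SECOND_LINE_LISTS: dict[str, tuple[str, ...]] = {
    "A": ("B", "C", "D", "E", "F", "G"),
    "B": ("C", "D", "E", "F", "G", "H"),
    "C": ("D", "F", "G", "H"),
    "D": ("C", "F", "G", "H"),
    "E": ("F", "G", "H"),
    "F": ("C", "D", "E", "H"),
    "G": ("C", "D", "E", "H"),
    "H": (),
}

# Amikacin-containing regimens, unsuitable as second-line under Pattern 3.
_AMIKACIN = frozenset({"C", "D", "G"})
_HIGH_RESISTANCE_PATTERN = 3

_EARLY_MORTALITY = 0.05

PRESET_NAMES: tuple[str, ...] = (
    "base_case",
    "larger_effects",
    "smaller_effects",
    "reversed_effects",
    "pattern4",
    "sparse",
    "unequal_frequencies",
    "smart_base_q25",
    "smart_unequal",
    "smart_q10",
    "smart_q50",
    "smart_q75",
)


def _single_stage(name: str, pattern_sets: Sequence[tuple[str, ...]],
                  frequencies: Sequence[float]) -> SingleStageScenario:
    return SingleStageScenario(
        name=name,
        treatments=tuple(TreatmentArm(i, lab) for i, lab in _REGIMENS),
        patterns=tuple(
            RandomizationPattern(k + 1, members, freq)
            for k, (members, freq) in enumerate(zip(pattern_sets, frequencies))
        ),
        baseline_risk=_BASELINE_RISK,
        odds_ratios=dict(_FIRST_LINE_OR),
    )


def _smart(name: str, first: SingleStageScenario, q: float) -> SmartScenario:
    second_map: dict[tuple[int, str], tuple[str, ...]] = {}
    for pat in first.patterns:
        for j in pat.members:
            lst = _SECOND_LINE_LISTS[j]
            if pat.id == _HIGH_RESISTANCE_PATTERN:
                lst = tuple(l for l in lst if l not in _AMIKACIN)
            second_map[(pat.id, j)] = lst
    return SmartScenario(
        name=name,
        first_stage=first,
        second_line_treatments=tuple(
            TreatmentArm(i, lab) for i, lab in _REGIMENS if i in _SECOND_LINE_OR
        ),
        second_line_pattern_map=second_map,
        second_line_odds_ratios=dict(_SECOND_LINE_OR),
        switch_prob=q,
        early_mortality_prob=_EARLY_MORTALITY,
    )


def preset_scenario(name: str) -> SingleStageScenario | SmartScenario:
    """Return a fully populated NeoSep1 scenario preset by name.

    Single-stage presets: ``base_case``, ``larger_effects``,
    ``smaller_effects``, ``reversed_effects``, ``pattern4``, ``sparse``,
    ``unequal_frequencies``.  SMART presets: ``smart_base_q25``,
    ``smart_unequal``, ``smart_q10``, ``smart_q50``, ``smart_q75``.
    """
    equal3 = (1 / 3, 1 / 3, 1 / 3)
    if name == "base_case":
        return _single_stage(name, _PATTERNS_MAIN, equal3)
    if name == "larger_effects":
        return replace(scale_scenario_effects(preset_scenario("base_case"), 1.25), name=name)
    if name == "smaller_effects":
        return replace(scale_scenario_effects(preset_scenario("base_case"), 0.75), name=name)
    if name == "reversed_effects":
        return replace(reverse_scenario_effects(preset_scenario("base_case")), name=name)
    if name == "pattern4":
        # fourth pattern with all 8 regimens; equal split over the 4 patterns
        sets = _PATTERNS_MAIN + (tuple(i for i, _ in _REGIMENS),)
        return _single_stage(name, sets, (0.25,) * 4)
    if name == "sparse":
        return _single_stage(name, _PATTERNS_SPARSE, equal3)
    if name == "unequal_frequencies":
        return _single_stage(name, _PATTERNS_MAIN, (0.50, 0.40, 0.10))
    if name == "smart_base_q25":
        return _smart(name, preset_scenario("base_case"), 0.25)
    if name == "smart_unequal":
        return _smart(name, preset_scenario("unequal_frequencies"), 0.25)
    if name == "smart_q10":
        return _smart(name, preset_scenario("base_case"), 0.10)
    if name == "smart_q50":
        return _smart(name, preset_scenario("base_case"), 0.50)
    if name == "smart_q75":
        return _smart(name, preset_scenario("base_case"), 0.75)
    raise ScenarioError(f"unknown preset {name!r}; known presets: {', '.join(PRESET_NAMES)}")


# --------------------------------------------------------------------------
# JSON serialization
#
# Schema:
# {
#   "name": str,
#   "treatments": [{"id": str, "label": str}, ...],
#   "patterns": [{"id": int, "members": [str, ...], "frequency": float}, ...],
#   "baseline_risk": float,
#   "odds_ratios": {id: float, ...},
#   "smart": {                               # optional; present => SmartScenario
#     "second_line_treatments": [{"id", "label"}, ...],
#     "second_line_map": [{"pattern": int, "first_line": str,
#                          "second_line": [str, ...]}, ...],
#     "second_line_odds_ratios": {id: float, ...},
#     "switch_prob": float | [{"first_line": str, "pattern": int, "q": float}, ...],
#     "early_mortality_prob": float
#   }
# }


def scenario_to_dict(scenario: SingleStageScenario | SmartScenario) -> dict:
    """Serialize a scenario to the documented JSON-compatible dict schema."""
    if isinstance(scenario, SmartScenario):
        first = scenario.first_stage
        d = scenario_to_dict(first)
        d["name"] = scenario.name
        q = scenario.switch_prob
        d["smart"] = {
            "second_line_treatments": [
                {"id": t.id, "label": t.label} for t in scenario.second_line_treatments
            ],
            "second_line_map": [
                {"pattern": k, "first_line": j, "second_line": list(lst)}
                for (k, j), lst in sorted(scenario.second_line_pattern_map.items())
            ],
            "second_line_odds_ratios": dict(scenario.second_line_odds_ratios),
            "switch_prob": q if np.isscalar(q) else [
                {"first_line": j, "pattern": k, "q": v} for (j, k), v in sorted(q.items())
            ],
            "early_mortality_prob": scenario.early_mortality_prob,
        }
        return d
    return {
        "name": scenario.name,
        "treatments": [{"id": t.id, "label": t.label} for t in scenario.treatments],
        "patterns": [
            {"id": p.id, "members": list(p.members), "frequency": p.frequency}
            for p in scenario.patterns
        ],
        "baseline_risk": scenario.baseline_risk,
        "odds_ratios": dict(scenario.odds_ratios),
    }


def scenario_from_dict(d: Mapping) -> SingleStageScenario | SmartScenario:
    """Inverse of :func:`scenario_to_dict` (validates on construction)."""
    first = SingleStageScenario(
        name=d["name"],
        treatments=tuple(TreatmentArm(t["id"], t.get("label", t["id"])) for t in d["treatments"]),
        patterns=tuple(
            RandomizationPattern(p["id"], tuple(p["members"]), p["frequency"])
            for p in d["patterns"]
        ),
        baseline_risk=d["baseline_risk"],
        odds_ratios=dict(d["odds_ratios"]),
    )
    if "smart" not in d:
        return first
    s = d["smart"]
    q = s["switch_prob"]
    if not np.isscalar(q):
        q = {(e["first_line"], e["pattern"]): e["q"] for e in q}
    return SmartScenario(
        name=d["name"],
        first_stage=first,
        second_line_treatments=tuple(
            TreatmentArm(t["id"], t.get("label", t["id"])) for t in s["second_line_treatments"]
        ),
        second_line_pattern_map={
            (e["pattern"], e["first_line"]): tuple(e["second_line"]) for e in s["second_line_map"]
        },
        second_line_odds_ratios=dict(s["second_line_odds_ratios"]),
        switch_prob=q,
        early_mortality_prob=s["early_mortality_prob"],
    )


def load_scenario(path) -> SingleStageScenario | SmartScenario:
    with open(path) as fh:
        return scenario_from_dict(json.load(fh))


def save_scenario(scenario: SingleStageScenario | SmartScenario, path) -> None:
    with open(path, "w") as fh:
        json.dump(scenario_to_dict(scenario), fh, indent=2)
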