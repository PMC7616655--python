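"""Performance measures for ranking-based sample-size determination.

After each simulated trial is analyzed, the estimated best option (treatment
or first/second-line strategy) is identified per pattern and scored against
the truth with three measures, each weighted by the observed pattern
prevalences ``lambda_hat_k``:

* **Reduction in adverse outcomes** — the drop in expected adverse-outcome
  probability from using the estimated best option instead of a random
  eligible option, expressed as a percentage of the drop achievable with
  perfect information (true rankings known).  Following the
  expected-value-of-perfect-information normalization, replicate numerators
  and denominators are averaged separately and the percentage is the ratio
  of the means.
* **Near-best probability** — the chance the chosen option's true risk is
  within ``kappa`` (absolute, e.g. 0.02 = 2 percentage points) of the best
  eligible option's risk.
* **Improvement over random choice** — the chance the chosen option's true
  risk is no worse (<=) than the mean over eligible options.

The same code scores single-stage trials (options = treatments eligible in
the pattern) and SMART trials (options = eligible first/second-line
strategies per first-line pattern, including the no-second-line strategy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateMeasures",
    "PerformanceSummary",
    "estimated_best",
    "replicate_measures",
    "summarize",
    "strategy_truth",
    "single_stage_truth",
]

DEFAULT_KAPPAS: tuple[float, ...] = (0.02, 0.01)


@dataclass(frozen=True)
class ReplicateMeasures:
    """Measures from one simulated trial (one replicate)."""

    numerator: float          # lambda-weighted risk reduction achieved
    denominator: float        # lambda-weighted risk reduction under perfect info
    near_best: Mapping[float, float]   # kappa -> lambda-weighted indicator mean
    improvement: float        # lambda-weighted indicator mean
    choices: Mapping[Hashable, Hashable] = field(default_factory=dict)
    penalized: bool = False
    converged: bool = True


@dataclass(frozen=True)
class PerformanceSummary:
    """Monte Carlo means of the three measures over replicates.

    ``percent_reduction`` is 100 x mean(numerator) / mean(denominator);
    its MC standard error comes from the delta method for a ratio of means.
    ``percent_reduction`` is ``nan`` when the mean denominator is 0.
    """

    scenario: str
    design: str
    n: int
    replicates: int
    percent_reduction: float
    percent_reduction_se: float
    near_best: Mapping[float, float]
    near_best_se: Mapping[float, float]
    improvement: float
    improvement_se: float
    n_penalized: int = 0
    n_nonconverged: int = 0

    def to_rows(self) -> list[dict]:
        """Long-format rows (one per measure) for CSV export."""
        rows = [
            {
                "scenario": self.scenario, "design": self.design, "n": self.n,
                "measure": "percent_reduction", "kappa": np.nan,
                "estimate": self.percent_reduction, "mc_se": self.percent_reduction_se,
                "replicates": self.replicates,
            },
            {
                "scenario": self.scenario, "design": self.design, "n": self.n,
                "measure": "improvement_over_random", "kappa": np.nan,
                "estimate": self.improvement, "mc_se": self.improvement_se,
                "replicates": self.replicates,
            },
        ]
        for kappa, est in self.near_best.items():
            rows.append(
                {
                    "scenario": self.scenario, "design": self.design, "n": self.n,
                    "measure": "near_best", "kappa": kappa,
                    "estimate": est, "mc_se": self.near_best_se[kappa],
                    "replicates": self.replicates,
                }
            )
        return rows


def single_stage_truth(scenario) -> dict[int, dict[Hashable, float]]:
    """True risks grouped per pattern: ``{k: {j: P_jk}}``."""
    truth: dict[int, dict[Hashable, float]] = {}
    for pat in scenario.patterns:
        truth[pat.id] = {j: scenario.risk_matrix[(j, pat.id)] for j in pat.members}
    return truth


def strategy_truth(risk_table) -> dict[int, dict[Hashable, float]]:
    """True strategy risks grouped per first-line pattern.

    ``{k: {(j, l_or_None): P_jklm}}`` — the second-line subgroup collapses
    onto the first-line pattern because the second-line list is a function
    of (pattern, first-line treatment).
    """
    truth: dict[int, dict[Hashable, float]] = {}
    for (k, j, l), risk in risk_table.entries.items():
        truth.setdefault(k, {})[(j, l)] = risk
    return truth


def estimated_best(
    phat: Mapping, patterns: Sequence[int] | None = None
) -> dict[int, Hashable]:
    """Option with the lowest estimated risk per pattern, ties to canonical order.

    Accepts either single-stage predictions keyed ``(j, k)`` or strategy
    predictions keyed ``(k, j, l)`` (the output formats of
    :func:`practical_sizer.estimation.predict_risks`).
    """
    grouped: dict[int, list[tuple[Hashable, float]]] = {}
    for key, value in phat.items():
        if len(key) == 2:       # (treatment, pattern)
            j, k = key
            grouped.setdefault(k, []).append((j, value))
        else:                   # (pattern, first-line, second-line)
            k, j, l = key
            grouped.setdefault(k, []).append(((j, l), value))
    best: dict[int, Hashable] = {}
    for k, options in grouped.items():
        if patterns is not None and k not in patterns:
            continue
        # insertion order is canonical; strict < keeps the earliest minimum
        choice, cmin = options[0]
        for opt, v in options[1:]:
            if v < cmin:
                choice, cmin = opt, v
        best[k] = choice
    return best


def replicate_measures(
    truth: Mapping[int, Mapping[Hashable, float]],
    choice: Mapping[int, Hashable],
    lambda_hat: Mapping[int, float],
    kappas: Sequence[float] = DEFAULT_KAPPAS,
    penalized: bool = False,
    converged: bool = True,
) -> ReplicateMeasures:
    """Score one replicate's per-pattern choices against the true risks.

    ``truth`` maps pattern -> {option: true risk} over eligible options;
    ``choice`` maps pattern -> chosen option; ``lambda_hat`` holds observed
    pattern prevalences.  Indicator comparisons use ``<=``, so ties at the
    threshold count in favour of the chosen option.
    """
    num = den = imp = 0.0
    nb = {kappa: 0.0 for kappa in kappas}
    for k, options in truth.items():
        lam = lambda_hat.get(k, 0.0)
        risks = np.fromiter(options.values(), dtype=float, count=len(options))
        mean_r = float(risks.mean())
        min_r = float(risks.min())
        chosen_r = options[choice[k]]
        num += lam * (mean_r - chosen_r)
        den += lam * (mean_r - min_r)
        imp += lam * (chosen_r <= mean_r)
        for kappa in kappas:
            nb[kappa] += lam * (chosen_r <= min_r + kappa)
    return ReplicateMeasures(
        numerator=num,
        denominator=den,
        near_best=nb,
        improvement=imp,
        choices=dict(choice),
        penalized=penalized,
        converged=converged,
    )


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    m = float(x.mean())
    if len(x) < 2:
        return m, float("nan")
    return m, float(x.std(ddof=1) / np.sqrt(len(x)))


def summarize(
    replicates: Sequence[ReplicateMeasures],
    scenario: str = "",
    design: str = "practical",
    n: int = 0,
) -> PerformanceSummary:
    """Aggregate replicate measures into Monte Carlo means with MC SEs."""
    if not replicates:
        raise ValueError("at least one replicate required")
    r = len(replicates)
    nums = np.array([m.numerator for m in replicates])
    dens = np.array([m.denominator for m in replicates])
    mean_num, mean_den = nums.mean(), dens.mean()
    if mean_den == 0.0:
        pct, pct_se = float("nan"), float("nan")
    else:
        pct = float(100.0 * mean_num / mean_den)
        if r >= 2:
            # delta method for the ratio of means
            cov = np.cov(nums, dens, ddof=1) / r
            grad = np.array([1.0 / mean_den, -mean_num / mean_den**2])
            pct_se = float(100.0 * np.sqrt(max(grad @ cov @ grad, 0.0)))
        else:
            pct_se = float("nan")
    kappas = list(replicates[0].near_best)
    nb, nb_se = {}, {}
    for kappa in kappas:
        est, se = _mean_se(np.array([m.near_best[kappa] for m in replicates]))
        nb[kappa], nb_se[kappa] = est, se
    imp, imp_se = _mean_se(np.array([m.improvement for m in replicates]))
    return PerformanceSummary(
        scenario=scenario,
        design=design,
        n=n,
        replicates=r,
        percent_reduction=pct,
        percent_reduction_se=pct_se,
        near_best=nb,
        near_best_se=nb_se,
        improvement=imp,
        improvement_se=imp_se,
        n_penalized=sum(m.penalized for m in replicates),
        n_nonconverged=sum(not m.converged for m in replicates),
    )


def summaries_to_frame(summaries: Sequence[PerformanceSummary]) -> pd.DataFrame:
    rows: list[dict] = []
    for s in summaries:
        rows.extend(s.to_rows())
    return pd.DataFrame(rows)
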