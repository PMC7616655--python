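"""Simulate single-stage PRACTical trial data sets.

Each simulated individual is assigned a randomization pattern by a
multinomial draw over the scenario's pattern frequencies, a treatment drawn
uniformly at random from the pattern's members, and a Bernoulli adverse
outcome at the scenario's true risk ``P_jk``.  Pattern membership is sampled
rather than fixed by quota, so the observed pattern prevalences
``lambda_hat_k`` are genuinely random, as the performance measures assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario_model import SingleStageScenario

__all__ = ["TrialData", "simulate_single_stage_trial"]


@dataclass(frozen=True)
class TrialData:
    """One simulated single-stage trial.

    Individuals are stored as parallel arrays of integer codes; ``patterns``
    and ``treatments`` give the code-to-id vocabularies (canonical order).
    """

    treatments: tuple[str, ...]
    patterns: tuple[int, ...]
    pattern_idx: np.ndarray   # index into `patterns`, one per individual
    treatment_idx: np.ndarray  # index into `treatments`
    outcome: np.ndarray       # 0/1
    seed: object = None

    @property
    def n(self) -> int:
        return self.pattern_idx.shape[0]

    @property
    def lambda_hat(self) -> dict[int, float]:
        """Observed pattern prevalences (sum to 1)."""
        counts = np.bincount(self.pattern_idx, minlength=len(self.patterns))
        return {k: c / self.n for k, c in zip(self.patterns, counts)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "pattern": np.asarray(self.patterns)[self.pattern_idx],
                "treatment": np.asarray(self.treatments)[self.treatment_idx],
                "outcome": self.outcome.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_single_stage_trial(
    scenario: SingleStageScenario, n: int, seed
) -> TrialData:
    """Generate one PRACTical trial of ``n`` individuals under a scenario.

    Reproducible: identical ``(scenario, n, seed)`` yield identical data.
    ``seed`` may be anything accepted by :func:`numpy.random.default_rng`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    treatments = scenario.treatment_ids
    t_index = {j: i for i, j in enumerate(treatments)}
    lam = scenario.pattern_frequencies
    risks = np.array([scenario.risk(j) for j in treatments])

    pattern_idx = rng.choice(len(scenario.patterns), size=n, p=lam)
    treatment_idx = np.empty(n, dtype=np.int64)
    for ki, pat in enumerate(scenario.patterns):
        mask = pattern_idx == ki
        members = np.array([t_index[j] for j in pat.members])
        treatment_idx[mask] = members[rng.integers(0, len(members), size=int(mask.sum()))]
    outcome = (rng.random(n) < risks[treatment_idx]).astype(np.int8)

    return TrialData(
        treatments=treatments,
        patterns=tuple(p.id for p in scenario.patterns),
        pattern_idx=pattern_idx,
        treatment_idx=treatment_idx,
        outcome=outcome,
        seed=seed,
    )
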