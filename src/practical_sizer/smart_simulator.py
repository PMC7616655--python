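"""Simulate two-stage PRACTical-SMART trial data with cloning and weights.

Event flow per individual (the order matters for the realized switch
fraction): first-line pattern and treatment are drawn as in the single-stage
design; with probability ``early_mortality_prob`` the individual dies before
the second randomization (adverse outcome, never switched); surviving
individuals need second-line treatment with probability ``q_jk``, in which
case a second-line regimen is drawn uniformly from their second-line list
``S_2m`` and the outcome follows the strategy risk ``P_jklm``.

Individuals without a second randomization (non-switching survivors and
early deaths) are expanded into one cloned record per member of ``S_2m``,
each carrying inverse-probability weight ``1/|S_2m|``, so that every
individual contributes total weight 1 to the weighted analysis whether or
not they switched.  Individuals whose ``S_2m`` is empty (meropenem
first-line) enter as a single weight-1 record.

By default all clones of an individual share one copied outcome drawn with
no second-line effect (their outcome cannot depend on a regimen never
received); ``clone_outcomes="independent"`` instead draws a potential
outcome per clone from ``P_jklm``, as a sensitivity option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .scenario_model import SmartScenario, build_strategy_risk_table

__all__ = ["SmartTrialData", "simulate_smart_trial"]


@dataclass(frozen=True)
class SmartTrialData:
    """Record-level (post-cloning) data from one simulated SMART trial.

    Arrays are parallel over records; ``individual`` maps records back to the
    ``n`` simulated individuals.  ``second_idx`` indexes into
    ``second_line_treatments`` (-1 = no second-line treatment on this
    record); ``second_group`` is an opaque id for the second-line subgroup
    ``m`` (-1 where ``S_2m`` is empty).
    """

    treatments: tuple[str, ...]
    second_line_treatments: tuple[str, ...]
    patterns: tuple[int, ...]
    individual: np.ndarray
    pattern_idx: np.ndarray
    treatment_idx: np.ndarray
    early_death: np.ndarray
    switched: np.ndarray
    second_group: np.ndarray
    second_idx: np.ndarray
    clone: np.ndarray
    weight: np.ndarray
    outcome: np.ndarray
    n: int
    seed: object = None

    @property
    def lambda_hat(self) -> dict[int, float]:
        """Observed first-line pattern prevalences, weight-aggregated.

        Each individual carries total weight 1, so this equals the
        individual-level prevalence and sums to 1.
        """
        totals = np.bincount(self.pattern_idx, weights=self.weight,
                             minlength=len(self.patterns))
        return {k: t / self.n for k, t in zip(self.patterns, totals)}

    def to_frame(self) -> pd.DataFrame:
        second = np.asarray(self.second_line_treatments + ("none",))
        return pd.DataFrame(
            {
                "id": self.individual,
                "pattern": np.asarray(self.patterns)[self.pattern_idx],
                "first_tx": np.asarray(self.treatments)[self.treatment_idx],
                "early_death": self.early_death.astype(int),
                "switched": self.switched.astype(int),
                "second_group": self.second_group,
                "second_tx": second[self.second_idx],
                "clone": self.clone.astype(int),
                "weight": self.weight,
                "outcome": self.outcome.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_smart_trial(
    smart: SmartScenario, n: int, seed, clone_outcomes: str = "copied"
) -> SmartTrialData:
    """Generate one PRACTical-SMART trial of ``n`` individuals.

    Parameters
    ----------
    clone_outcomes
        ``"copied"`` (default): all clones of a non-switching survivor share
        one outcome drawn with no second-line effect.  ``"independent"``:
        each clone draws its own potential outcome from ``P_jklm``.
        Early deaths have outcome 1 on every record in either mode.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if clone_outcomes not in ("copied", "independent"):
        raise ValueError("clone_outcomes must be 'copied' or 'independent'")
    rng = np.random.default_rng(seed)
    base = smart.first_stage
    treatments = base.treatment_ids
    t_index = {j: i for i, j in enumerate(treatments)}
    second_ids = smart.second_line_ids
    s_index = {l: i for i, l in enumerate(second_ids)}
    patterns = base.patterns
    risk_table = build_strategy_risk_table(smart)

    # enumerate second-line subgroups m: one per (pattern, first-line) pair
    group_key: dict[tuple[int, int], int] = {}
    group_members: list[np.ndarray] = []   # second-line treatment indices
    group_risks: list[np.ndarray] = []     # strategy risks P_jklm, aligned
    group_q: list[float] = []
    group_first_risk: list[float] = []
    eta0 = logit(base.baseline_risk)
    for ki, pat in enumerate(patterns):
        for j in pat.members:
            lst = smart.second_line_list(pat.id, j)
            g = len(group_members)
            group_key[(ki, t_index[j])] = g
            group_members.append(np.array([s_index[l] for l in lst], dtype=np.int64))
            group_risks.append(np.array([risk_table[(pat.id, j, l)] for l in lst]))
            group_q.append(smart.q(j, pat.id))
            group_first_risk.append(float(expit(eta0 + np.log(base.odds_ratios[j]))))

    # ---- individual-level draws -------------------------------------------
    lam = base.pattern_frequencies
    pattern_idx = rng.choice(len(patterns), size=n, p=lam)
    treatment_idx = np.empty(n, dtype=np.int64)
    for ki, pat in enumerate(patterns):
        mask = pattern_idx == ki
        members = np.array([t_index[j] for j in pat.members])
        treatment_idx[mask] = members[rng.integers(0, len(members), size=int(mask.sum()))]

    g_ind = np.array([group_key[(k, j)] for k, j in zip(pattern_idx, treatment_idx)])
    len_g = np.array([len(m) for m in group_members])[g_ind]
    q_ind = np.array(group_q)[g_ind]
    first_risk_ind = np.array(group_first_risk)[g_ind]

    early = rng.random(n) < smart.early_mortality_prob
    switched = (~early) & (rng.random(n) < q_ind) & (len_g > 0)
    sel_u = rng.random(n)        # second-line selection (used by switchers)
    out_u = rng.random(n)        # individual-level outcome draw

    sel_pos = np.minimum((sel_u * np.maximum(len_g, 1)).astype(np.int64),
                         np.maximum(len_g - 1, 0))
    # switcher's chosen second-line treatment and its strategy risk
    chosen_second = np.full(n, -1, dtype=np.int64)
    chosen_risk = np.zeros(n)
    for g, members in enumerate(group_members):
        mask = switched & (g_ind == g)
        if mask.any():
            chosen_second[mask] = members[sel_pos[mask]]
            chosen_risk[mask] = group_risks[g][sel_pos[mask]]

    outcome_ind = np.where(
        early, 1, np.where(switched, out_u < chosen_risk, out_u < first_risk_ind)
    ).astype(np.int8)

    # ---- clone expansion ---------------------------------------------------
    counts = np.where(switched | (len_g == 0), 1, len_g)
    offsets = np.cumsum(counts) - counts
    n_rec = int(counts.sum())
    rep = np.repeat(np.arange(n), counts)

    weight = 1.0 / counts[rep]
    clone = counts[rep] > 1
    second_idx = np.full(n_rec, -1, dtype=np.int64)
    pos_in_block = np.arange(n_rec) - offsets[rep]
    cloned_ind = clone  # record-level flag
    for g, members in enumerate(group_members):
        mask = cloned_ind & (g_ind[rep] == g)
        if mask.any():
            second_idx[mask] = members[pos_in_block[mask]]
    sw_rec = switched[rep]
    second_idx[sw_rec] = chosen_second[rep][sw_rec]

    outcome = outcome_ind[rep].copy()
    if clone_outcomes == "independent":
        # fresh potential-outcome draw per clone of a non-switching survivor
        u2 = rng.random(n_rec)
        redraw = cloned_ind & ~early[rep]
        if redraw.any():
            max_len = max(len(m) for m in group_members) or 1
            pad = np.zeros((len(group_members), max_len))
            for g, r in enumerate(group_risks):
                pad[g, : len(r)] = r
            outcome[redraw] = (
                u2[redraw] < pad[g_ind[rep][redraw], pos_in_block[redraw]]
            ).astype(np.int8)

    second_group = np.where(len_g[rep] > 0, g_ind[rep], -1)

    return SmartTrialData(
        treatments=treatments,
        second_line_treatments=second_ids,
        patterns=tuple(p.id for p in patterns),
        individual=rep,
        pattern_idx=pattern_idx[rep],
        treatment_idx=treatment_idx[rep],
        early_death=early[rep],
        switched=sw_rec,
        second_group=second_group,
        second_idx=second_idx,
        clone=clone,
        weight=weight,
        outcome=outcome,
        n=n,
        seed=seed,
    )
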