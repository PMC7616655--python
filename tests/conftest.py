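import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import practical_sizer as ps

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def base_case():
    return ps.preset_scenario("base_case")


@pytest.fixture(scope="session")
def smart_q25():
    return ps.preset_scenario("smart_base_q25")


@pytest.fixture(scope="session")
def base_truth(base_case):
    return ps.single_stage_truth(base_case)


def make_trial_data(counts, treatments=("A", "B"), patterns=(1,)):
    """Build a TrialData from per-(pattern, arm) (events, total) counts.

    ``counts`` maps (pattern_id, treatment_id) -> (n_events, n_total).
    """
    p_idx, t_idx, y = [], [], []
    p_pos = {k: i for i, k in enumerate(patterns)}
    t_pos = {j: i for i, j in enumerate(treatments)}
    for (k, j), (ev, tot) in counts.items():
        p_idx += [p_pos[k]] * tot
        t_idx += [t_pos[j]] * tot
        y += [1] * ev + [0] * (tot - ev)
    return ps.TrialData(
        treatments=tuple(treatments),
        patterns=tuple(patterns),
        pattern_idx=np.array(p_idx),
        treatment_idx=np.array(t_idx),
        outcome=np.array(y, dtype=np.int8),
    )
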