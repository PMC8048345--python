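import numpy as np
import pytest

from trajsurv.survival import SurvivalTable


def make_surv(times, events, ids=None):
    times = np.asarray(times, dtype=float)
    if ids is None:
        ids = [f"P{i:03d}" for i in range(len(times))]
    return SurvivalTable(np.asarray(ids, dtype=object), times,
                         np.asarray(events, dtype=int))


def random_surv(rng, n, censor_frac=0.3, scale=5.0):
    """Exponential event times with uniform random censoring."""
    t_event = rng.exponential(scale, size=n)
    censored = rng.uniform(size=n) < censor_frac
    t_cens = rng.uniform(0, 1.5 * scale, size=n)
    time = np.where(censored, np.minimum(t_event, t_cens), t_event)
    event = np.where(censored & (t_cens < t_event), 0, 1)
    return make_surv(time, event)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared across read-only tests."""
    from trajsurv.synthetic import CohortConfig, simulate_cohort
    cfg = CohortConfig(n_patients=60, n_genes=40, n_active_genes=5,
                       n_clusters=2, seed=42)
    return cfg, *simulate_cohort(cfg)
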