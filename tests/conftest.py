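import numpy as np
import pytest

from hccea import TrialArmSpec, km_curve, simulate_arm


@pytest.fixture(scope="session")
def loglogistic_arm():
    """A simulated log-logistic arm (n=200, 30-month follow-up) with its KM
    curve and a 5-interval risk table, reused across reconstruction tests."""
    spec = TrialArmSpec("arm", "loglogistic", {"scale": 8.0, "shape": 1.5},
                        n_patients=200, max_followup=30.0, seed=7)
    ipd = simulate_arm(spec)
    km = km_curve(ipd)
    risk = km.risk_table(np.arange(0.0, 30.0, 6.0))
    return spec, ipd, km, risk


def interval_event_counts(ipd, starts):
    """Events per half-open risk interval [start_i, start_{i+1})."""
    edges = np.concatenate([np.asarray(starts, dtype=float), [np.inf]])
    return [int(((ipd.times >= edges[i]) & (ipd.times < edges[i + 1])
                 & (ipd.events == 1)).sum())
            for i in range(len(edges) - 1)]
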