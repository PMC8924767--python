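import numpy as np
import pytest

import hevsim as hs
from hevsim.metrics import TriggerMetrics


def quiet(**kw):
    """Noise-free noise config."""
    base = {"pressure_sigma": 0.0, "flow_sigma": 0.0, "o2_sensor_sigma": 0.0, "seed": 0}
    base.update(kw)
    return base


def averaged_trigger_metrics(scenario) -> tuple[TriggerMetrics, int]:
    """Run a spontaneous-breathing scenario and average the trigger battery
    over all efforts whose metric horizon fits inside the trace."""
    res = hs.run_scenario(scenario)
    p = res.timeseries.column("p_airway")
    tms = [
        hs.trigger_metrics(p, scenario.dt, onset, scenario.settings.peep,
                           scenario.settings.delta_p)
        for onset in res.effort_onsets
        if onset + 1.3 <= scenario.duration
    ]
    assert tms, "no efforts fitted inside the trace"

    def avg(name):
        vals = [getattr(t, name) for t in tms if getattr(t, name) is not None]
        return float(np.mean(vals)) if vals else None

    n_patient = sum(1 for b in res.breaths if b.trigger_type == "patient")
    return (
        TriggerMetrics(avg("tpm"), avg("tdt"), avg("pd"), avg("ptp"),
                       avg("ptp300"), avg("ptp500")),
        n_patient,
    )


@pytest.fixture(scope="session")
def nominal_run():
    """A 30 s noise-free nominal PC-A/C run shared across tests."""
    sc = hs.preset("mhra_nominal", noise=quiet(), duration=30.0)
    return sc, hs.run_scenario(sc)
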