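import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design():
    """Three isolates, two conditions, low noise: fast end-to-end fixture."""
    from biofilmassay.plate_model import AssayCondition
    from biofilmassay.synthetic import ExperimentDesign

    isolates = ["ISO.A", "ISO.B", "ISO.C"]
    classes = {"ISO.A": "SP", "ISO.B": "WP", "ISO.C": "NP"}
    rows = []
    for factor, level in (("baseline", None), ("nacl", 8.0)):
        for tp in (24.0, 48.0):
            for iso in isolates:
                rows.append({"isolate_id": iso, "factor": factor, "level": level,
                             "timepoint_h": tp, "producer_class": classes[iso]})
    truth = pd.DataFrame(rows)
    return ExperimentDesign(
        truth=truth,
        conditions=(AssayCondition("baseline"), AssayCondition("nacl", 8.0)),
        noise_cv=0.05, seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    from biofilmassay.synthetic import simulate_experiment

    return simulate_experiment(small_design)
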