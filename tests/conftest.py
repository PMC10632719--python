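import numpy as np
import pandas as pd
import pytest

from admixclock import clock_engine, synthetic_data as sd


@pytest.fixture(scope="session")
def preset_cohort():
    spec, _ = sd.paper_preset()
    return sd.gen_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def preset_bundle():
    """Cohort, clocks, low-noise betas and estimator table under the design preset."""
    spec, plan = sd.paper_preset()
    cohort = sd.gen_cohort(spec, seed=11)
    clocks = [sd.gen_clock(name=name, seed=100 + k, **kw)
              for k, (name, kw) in enumerate(plan.items())]
    betas = sd.gen_betas(cohort, clocks, spec, noise_sd=0.01, seed=12)
    est = clock_engine.compute_all(betas, clocks, cohort)
    groups = pd.Series(cohort["population"].to_numpy(), index=cohort["sample_id"])
    return {"spec": spec, "cohort": cohort, "clocks": clocks, "betas": betas,
            "est": est, "groups": groups}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
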