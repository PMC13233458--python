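import numpy as np
import pytest

from repeatomix import pipeline


@pytest.fixture(scope="session")
def e2e():
    """One full synthetic comparative run (six species, ~18k read pairs),
    shared by the recovery and acceptance tests."""
    result = pipeline.run_pipeline(pipeline.RunConfig(seed=1))
    evaluation = pipeline.evaluate_run(result)
    return result, evaluation


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
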