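import pytest

import bariflow as bf


@pytest.fixture(scope="session")
def ref_cfg() -> bf.ModelConfig:
    """The calibrated Australian configuration (closed-form rebuild)."""
    return bf.reference_config()


@pytest.fixture(scope="session")
def model_run(ref_cfg) -> bf.ModelRun:
    """Full sweep over all scenarios at the standard uptakes plus 100%."""
    return bf.run_model(ref_cfg, uptakes=[0.2, 0.35, 0.75, 1.0])
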