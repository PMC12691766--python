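import numpy as np
import pytest

from cpexposure.data import ConcentrationRecord, ConsumptionRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)


@pytest.fixture
def censored_sccp_record():
    return ConcentrationRecord(
        sample_id="s1", oil_type="peanut", analyte="SCCP", value=None, censored=True, lod=32.0
    )


@pytest.fixture
def uniform_intake_records():
    """One-oil survey with intakes 1..100 g/d (one row per individual)."""
    return [
        ConsumptionRecord(
            individual_id=f"i{k}", oil_type="peanut", intake=float(k),
            body_weight=60.0, sex="F", age=40.0,
        )
        for k in range(1, 101)
    ]
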