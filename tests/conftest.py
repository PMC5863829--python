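import pandas as pd
import pytest

from placmed.params import AssayParams, GenerativeParams
from placmed.simulate import generate_cohort, generate_epityper_plates


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """400 subjects under default (calibrated) generative parameters."""
    return generate_cohort(GenerativeParams(n_subjects=400, seed=11))


@pytest.fixture(scope="session")
def small_plates(small_cohort):
    assay = AssayParams()
    return generate_epityper_plates(
        small_cohort, assay, cpg_ids=list(GenerativeParams().cpg_ids), seed=12
    )


@pytest.fixture(scope="session")
def clean_assay() -> AssayParams:
    """Noise-free assay: readouts equal latent values, nothing injected."""
    return AssayParams(
        missing_rate=0.0, measurement_noise_sd=0.0, censor_inject_rate=0.0
    )
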