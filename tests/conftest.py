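import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def wells_csv(tmp_path):
    """A small hand-written well table covering the parsing cases."""
    path = tmp_path / "wells.csv"
    path.write_text(
        "sample_id,primer_id,ct,tm_peaks,replicate\n"
        "E07,acheN,28.4,81.2,1\n"
        "E07,acheN,28.6,81.0,2\n"
        "E07,acheS,20.0,81.1,1\n"
        "E07,acheS,20.4,81.3,2\n"
        "E07,AluYb8,Undetermined,,1\n"
        "E07,AluYb8,36.2,79.9,2\n"
        "E08,acheS,21.0,81.2;73.0,1\n"
    )
    return path
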