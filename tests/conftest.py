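import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_gly_pdb(tmp_path):
    """Hand-written 3-atom glycine PDB."""
    text = (
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  GLY A   1       1.500   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   GLY A   1       2.400   1.100   0.000  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "gly.pdb"
    path.write_text(text)
    return path
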