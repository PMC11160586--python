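import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240524)


@pytest.fixture
def tiny_fasta(tmp_path):
    """A small two-record FASTA file with mixed case and one N."""
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">seq1 first\nACGTACGTACGTACGTACGTACGTACGT\n"
        ">seq2 second\nttggccaacgNtgacgtacgtacgtacg\n"
    )
    return path
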