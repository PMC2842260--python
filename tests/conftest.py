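import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="aln.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture(scope="session")
def planted_groups():
    """Two synthetic 10+10 groups with a 60-column donor tract planted in
    group-1 sequence g1_s0 (alignment columns 301-360, 1-based)."""
    from consenconv import simulate_two_groups

    g1, g2 = simulate_two_groups(
        n1=10,
        n2=10,
        length=1200,
        between_divergence=0.3,
        within_noise=0.005,
        tract=(300, 360),
        converted_index=0,
        seed=11,
    )
    return g1, g2


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
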