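import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_truth():
    """Small but complete simulated truth set shared across tests."""
    from popccdg.simulate import (
        SimConfig,
        simulate_cohort,
        simulate_founders,
        simulate_reference,
    )

    cfg = SimConfig(
        ref_length=60_000,
        n_founders=6,
        n_snp=60,
        n_small_indel=12,
        n_sv_indel=6,
        sv_size_range=(50, 200),
        n_samples=8,
        recomb_rate=2e-5,
        depth=30.0,
        seed=11,
    )
    ref = simulate_reference(cfg)
    founders = simulate_founders(ref, cfg)
    truth = simulate_cohort(founders, cfg)
    return truth


@pytest.fixture(scope="session")
def tiny_reference(tmp_path_factory, tiny_truth):
    """FASTA path for the tiny truth reference."""
    from popccdg.simulate import write_fasta

    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    write_fasta(str(path), tiny_truth.chrom, tiny_truth.reference)
    return str(path)
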