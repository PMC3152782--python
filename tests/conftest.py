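import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from denovotx import Read, SimulationConfig, simulate_dataset


def random_reads(rng, n, length=34, alphabet="ACGT"):
    bases = np.frombuffer(alphabet.encode(), dtype="S1")
    return [
        Read(id=f"r{i}", sequence=bases[rng.integers(0, len(bases), length)].tobytes().decode())
        for i in range(n)
    ]


def reads_from_transcript(transcript, depth, read_length, rng, stranded=True):
    """Uniform error-free tiling reads covering every position."""
    n = max(1, int(round(depth * len(transcript) / read_length)))
    starts = list(rng.integers(0, len(transcript) - read_length + 1, size=n))
    # guarantee end coverage so assemblies are full length
    starts += [0, len(transcript) - read_length]
    return [
        Read(id=f"t{i}", sequence=transcript[s : s + read_length], stranded=stranded)
        for i, s in enumerate(starts)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """A small error-free, duplicate-free stranded dataset with truth."""
    cfg = SimulationConfig(
        n_genes=6,
        gene_length_range=(250, 500),
        expression_log10_range=(1.7, 1.7),
        antisense_overlap_frac=0.0,
        error_rate=0.0,
        pcr_duplicate_rate=0.0,
        stranded_frac=1.0,
        seed=7,
    )
    genome, genes, truth, reads = simulate_dataset(cfg)
    return cfg, genome, genes, truth, reads
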