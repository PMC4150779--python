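import pytest

from silencescan.evaluate import run_synthetic_analysis
from silencescan.simulate import TruthConfig


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale generator conditions for fast end-to-end tests."""
    return TruthConfig(
        n_genes=200,
        genome_length=8_000_000,
        depth=100_000,
        noise_peaks_per_replicate=100,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_analysis(small_cfg):
    """One full in-memory pipeline run on the small configuration."""
    return run_synthetic_analysis(
        small_cfg, with_reads=True, with_peaks=True, with_motifs=True
    )
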