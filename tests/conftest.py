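import pytest

from ferrocre.seqio import WindowSpec, extract_windows
from ferrocre.synthgen import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene dataset at default study conditions (shared, read-only)."""
    return generate_dataset(SynthConfig(n_genes=300, seed=42))


@pytest.fixture(scope="session")
def small_windows(small_dataset):
    return extract_windows(
        small_dataset.genome, small_dataset.genes, WindowSpec(-500, 150)
    )
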