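import numpy as np
import pytest

import snptag as st


@pytest.fixture
def example() -> st.GenotypeMatrix:
    return st.worked_example()


@pytest.fixture
def cfg() -> st.SimilarityConfig:
    return st.SimilarityConfig()


@pytest.fixture
def order1() -> st.SimilarityConfig:
    return st.SimilarityConfig(spline_order=1)


@pytest.fixture(scope="session")
def five_block_data() -> tuple[st.GenotypeMatrix, st.SyntheticTruth]:
    """Five planted blocks (sizes 8-30) in 1,000 SNPs over 100 samples."""
    from snptag.simulate import random_blocks

    blocks = random_blocks(num_snps=1000, num_blocks=5, seed=41, size_range=(8, 30))
    return st.simulate(
        st.SimulationSpec(num_snps=1000, num_samples=100, blocks=blocks, seed=42)
    )


@pytest.fixture(scope="session")
def five_block_report(five_block_data) -> st.ScanReport:
    g, _ = five_block_data
    return st.scan_all(g, st.AttractorConfig())


def tiny_matrix(values, positions=None, **kwargs) -> st.GenotypeMatrix:
    values = np.asarray(values, dtype=np.float64)
    n = values.shape[0]
    if positions is None:
        positions = (np.arange(n) + 1) * 100
    return st.GenotypeMatrix(
        values=values,
        ids=np.array([f"v{i}" for i in range(n)], dtype=object),
        positions=np.asarray(positions),
        **kwargs,
    )
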