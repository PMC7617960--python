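import numpy as np
import pytest

from hrvmc import (
    FULL_BAND,
    SpectrumMatrix,
    SynthMatrixParams,
    synth_spectrum_matrix,
)


@pytest.fixture(scope="session")
def analysis_matrix() -> SpectrumMatrix:
    """Default 60-row, 3-prototype matrix restricted to the 0.04-0.4 Hz band."""
    matrix, _ = synth_spectrum_matrix(SynthMatrixParams(seed=42))
    return matrix.restrict(FULL_BAND)


@pytest.fixture(scope="session")
def cluster_matrix() -> tuple[SpectrumMatrix, np.ndarray]:
    """Cluster-pure rows (one-hot mixing plus jitter) with ground-truth weights."""
    matrix, weights = synth_spectrum_matrix(
        SynthMatrixParams(seed=7, mixing="cluster", mixing_noise_sd=0.05)
    )
    return matrix.restrict(FULL_BAND), weights
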