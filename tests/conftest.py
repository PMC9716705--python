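import numpy as np
import pytest

from selgen.core import MultiTraitCovariance, RelationshipMatrix


# Printed between-trait covariance estimates for the four-environment wheat
# analysis (the asymmetric residual cell is symmetrized downstream).
G0_WHEAT = np.array(
    [
        [0.831, -0.319, -0.247, -0.350],
        [-0.319, 0.750, -0.195, -0.213],
        [-0.247, -0.195, 0.757, -0.176],
        [-0.350, -0.213, -0.176, 0.752],
    ]
)
R0_WHEAT_RAW = np.array(
    [
        [0.830, -0.225, -0.289, -0.202],
        [-0.225, 0.872, -0.330, -0.317],
        [-0.289, -0.3330, 0.918, -0.352],
        [-0.202, -0.317, -0.352, 0.895],
    ]
)

# Printed single-trait wheat variance components (pedigree and genomic fits).
SIGMA2_A_WHEAT = 0.2859
SIGMA2_E_WHEAT = 0.5761
H2_WHEAT = 0.3316
SIGMA2_G_WHEAT = 0.5315


@pytest.fixture
def wheat_cov0() -> MultiTraitCovariance:
    return MultiTraitCovariance(G0_WHEAT, (R0_WHEAT_RAW + R0_WHEAT_RAW.T) / 2)


@pytest.fixture
def small_genomic_K() -> RelationshipMatrix:
    """A well-conditioned 5-individual genomic relationship matrix."""
    rng = np.random.default_rng(42)
    M = rng.standard_normal((5, 5))
    return RelationshipMatrix(list("abcde"), M @ M.T / 5 + 0.5 * np.eye(5),
                              "genomic")
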