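import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chromoclutch.structures import ChromatinConfig, NucleosomeFrame


def random_config(rng: np.random.Generator, n: int = 12, n_chains: int = 1,
                  scale: float = 8.0) -> ChromatinConfig:
    """Random chromatin configuration with proper orthonormal frames."""
    chains = []
    for c in range(n_chains):
        frames = []
        for i in range(n):
            R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            frames.append(NucleosomeFrame(
                chain_id=c,
                index=i,
                center=rng.normal(0, scale, 3) + np.array([40.0 * c, 0, 4.0 * i]),
                axis_a=R[0], axis_b=R[1], normal=R[2],
                wrap=float(rng.uniform(0.5, 1.0)),
            ))
        chains.append(frames)
    return ChromatinConfig(chains)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
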