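import numpy as np
import pytest

from bipathnet.data_io import RunConfig
from bipathnet.similarity import SimilarityMatrix, build_network
from bipathnet.synthetic_data import SyntheticConfig, generate


@pytest.fixture
def toy_network():
    """The 5-drug x 4-disease worked example: r1 similar to r4 and r5,
    d4 similar to d1 and d3, associations (r1,d2), (r1,d3), (r3,d4),
    (r5,d4). From r1 to d4 exactly two 2-edge paths exist:
    r1-r5-d4 and r1-d3-d4."""
    R = np.eye(5)
    R[0, 3] = R[3, 0] = 0.8   # r1 ~ r4
    R[0, 4] = R[4, 0] = 0.6   # r1 ~ r5
    D = np.eye(4)
    D[3, 0] = D[0, 3] = 0.7   # d4 ~ d1
    D[3, 2] = D[2, 3] = 0.5   # d4 ~ d3
    A = np.zeros((5, 4))
    for i, j in [(0, 1), (0, 2), (2, 3), (4, 3)]:
        A[i, j] = 1.0
    drugs = [f"r{i}" for i in range(1, 6)]
    diseases = [f"d{j}" for j in range(1, 5)]
    return build_network(SimilarityMatrix(drugs, R),
                         SimilarityMatrix(diseases, D), A)


@pytest.fixture(scope="session")
def small_world():
    """Default 50x40 planted-block world plus its heterogeneous network."""
    from bipathnet.similarity import cosine_similarity
    cfg = SyntheticConfig(seed=7)
    fp, D, assoc, block_map = generate(cfg)
    net = build_network(cosine_similarity(fp), D, assoc.matrix)
    return {"config": cfg, "fingerprints": fp, "disease_sim": D,
            "associations": assoc, "block_map": block_map, "net": net}


@pytest.fixture
def tiny_config():
    """A configuration small enough for exact float64 gradient work."""
    return RunConfig(conv1_kernel=(3, 3), conv1_channels=2, pool1_width=2,
                     conv2_kernel=(2, 3), conv2_channels=2, pool2_width=1,
                     lstm_hidden_size=2, epochs=2, batch_size=8,
                     dtype="float64", seed=3)
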