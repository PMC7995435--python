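import numpy as np
import pytest

from crso.matrix import BinaryEventMatrix, PenaltyMatrix


@pytest.fixture
def toy_dp():
    """5 events x 6 samples with hand-laid penalties (events A..E)."""
    labels = ["A-M", "B-M", "C-M", "D-M", "E-M"]
    samples = [f"s{j}" for j in range(6)]
    d = np.array(
        [
            [1, 1, 1, 0, 1, 0],
            [1, 1, 0, 1, 1, 0],
            [0, 1, 1, 1, 0, 0],
            [1, 0, 1, 1, 0, 0],
            [0, 0, 0, 0, 1, 1],
        ],
        dtype=bool,
    )
    p = np.array(
        [
            [2.0, 1.0, 3.0, 0.0, 2.0, 0.0],
            [1.0, 2.0, 0.0, 1.0, 4.0, 0.0],
            [0.0, 3.0, 1.0, 2.0, 0.0, 0.0],
            [1.0, 0.0, 2.0, 3.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 1.0, 5.0],
        ]
    )
    return (
        BinaryEventMatrix(labels, samples, d),
        PenaltyMatrix(labels, samples, p),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
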