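import numpy as np
import pytest

from gbacorr import AbundanceMatrix, CorrelationMatrix


@pytest.fixture
def toy_matrix() -> AbundanceMatrix:
    """3 proteins × 4 samples with two masked cells."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 0.0, 2.0, 1.0],
            [0.5, 1.5, 0.0, 2.5],
        ]
    )
    mask = np.zeros_like(values, dtype=bool)
    mask[1, 1] = True
    mask[2, 2] = True
    return AbundanceMatrix(["P1", "P2", "P3"], ["S1", "S2", "S3", "S4"], values, mask)


def correlation_from_pairs(
    protein_ids: list[str], pair_rhos: dict[tuple[str, str], float]
) -> CorrelationMatrix:
    """Build a CorrelationMatrix from explicit pair values (unspecified pairs 0)."""
    n = len(protein_ids)
    rho = np.zeros((n, n))
    np.fill_diagonal(rho, 1.0)
    idx = {p: i for i, p in enumerate(protein_ids)}
    for (a, b), v in pair_rhos.items():
        rho[idx[a], idx[b]] = v
        rho[idx[b], idx[a]] = v
    return CorrelationMatrix(protein_ids, rho, np.ones((n, n), dtype=bool))
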