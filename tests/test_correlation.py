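"""Zero imputation and the Spearman matrix against a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from gbacorr import (
    AbundanceMatrix,
    ValidationError,
    impute_missing_as_zero,
    spearman_matrix,
    spearman_pair,
)
from gbacorr.correlation import (
    read_correlation_matrix,
    write_correlation_long,
    write_correlation_matrix,
)


def oracle_pair(x, y):
    """Independent rank-then-Pearson oracle (closed-form Pearson on average ranks)."""
    rx, ry = rankdata(x), rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return None
    return float(np.corrcoef(rx, ry)[0, 1])


def random_masked_matrix(rng, n_proteins, n_samples):
    """Random intensities with ties (rounded) and random masked cells."""
    values = np.round(rng.gamma(2.0, 50.0, size=(n_proteins, n_samples)), 0)
    mask = rng.random(values.shape) < 0.15
    values[mask] = 0.0
    ids = [f"P{i}" for i in range(n_proteins)]
    samples = [f"S{j}" for j in range(n_samples)]
    return AbundanceMatrix(ids, samples, values, mask)


class TestImputation:
    def test_no_mask_is_identity(self, toy_matrix):
        clean = AbundanceMatrix(
            toy_matrix.protein_ids,
            toy_matrix.sample_ids,
            toy_matrix.values,
            np.zeros_like(toy_matrix.missing_mask),
        )
        assert impute_missing_as_zero(clean).equals(clean)

    def test_masked_cell_becomes_zero(self):
        values = np.array([[1.0, 7.0], [2.0, 3.0]])
        mask = np.array([[False, True], [False, False]])
        # stored value of a masked cell is irrelevant pre-imputation
        m = AbundanceMatrix(["P1", "P2"], ["S1", "S2"], values, mask)
        out = impute_missing_as_zero(m)
        assert out.values[0, 1] == 0.0
        assert out.missing_mask[0, 1]  # provenance retained

    def test_fully_masked_row_is_all_zero(self):
        values = np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
        mask = np.array([[False] * 3, [True] * 3])
        out = impute_missing_as_zero(
            AbundanceMatrix(["A", "B"], ["S1", "S2", "S3"], values, mask)
        )
        assert np.all(out.values[1] == 0.0)


class TestSpearmanPair:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 2, 4], [1, 3, 2, 4], 0.9486832980505138),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman_pair(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        assert spearman_pair([5, 5, 5], [1, 2, 3]) is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            spearman_pair([1, 2], [1, 2, 3])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(size=12), 1)  # rounding forces ties
        y = np.round(rng.normal(size=12), 1)
        ours, ref = spearman_pair(x, y), oracle_pair(x, y)
        if ref is None:
            assert ours is None
        else:
            assert ours == pytest.approx(ref, abs=1e-12)


class TestSpearmanMatrix:
    def test_agrees_with_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        m = random_masked_matrix(rng, 10, 20)
        c = spearman_matrix(m)
        imputed = impute_missing_as_zero(m)
        for i in range(m.n_proteins):
            for j in range(m.n_proteins):
                ref = oracle_pair(imputed.values[i], imputed.values[j])
                if ref is None:
                    assert not c.defined_mask[i, j]
                    assert c.rho[i, j] == 0.0
                else:
                    assert c.rho[i, j] == pytest.approx(ref, abs=1e-12)

    def test_symmetric_unit_diagonal_in_range(self):
        rng = np.random.default_rng(7)
        m = random_masked_matrix(rng, 15, 25)
        c = spearman_matrix(m)
        assert np.array_equal(c.rho, c.rho.T)
        defined_rows = c.defined_mask.diagonal()
        assert np.all(c.rho.diagonal()[defined_rows] == 1.0)
        assert np.all(np.abs(c.rho) <= 1 + 1e-12)

    def test_fully_missing_protein_row_stored_as_zero(self):
        values = np.array([[1.0, 2.0, 3.0], [4.0, 1.0, 2.0], [0.0, 0.0, 0.0]])
        mask = np.zeros_like(values, dtype=bool)
        mask[2] = True
        c = spearman_matrix(AbundanceMatrix(["A", "B", "C"], ["S1", "S2", "S3"], values, mask))
        assert np.all(c.rho[2] == 0.0)
        assert np.all(c.rho[:, 2] == 0.0)
        assert not c.defined_mask[2].any()

    def test_fewer_than_two_samples_errors(self):
        m = AbundanceMatrix(["A"], ["S1"], np.array([[1.0]]), np.array([[False]]))
        with pytest.raises(ValidationError, match="samples"):
            spearman_matrix(m)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.gamma(2.0, 10.0, size=(6, 30))
        mask = np.zeros_like(values, dtype=bool)
        m1 = AbundanceMatrix([f"P{i}" for i in range(6)], [f"S{j}" for j in range(30)], values, mask)
        transformed = values.copy()
        transformed[0] = np.exp(values[0] / 10.0)  # strictly increasing
        m2 = AbundanceMatrix(m1.protein_ids, m1.sample_ids, transformed, mask)
        assert np.allclose(spearman_matrix(m1).rho, spearman_matrix(m2).rho, atol=1e-12)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(11)
        m = random_masked_matrix(rng, 8, 20)
        perm = rng.permutation(m.n_samples)
        permuted = AbundanceMatrix(
            m.protein_ids,
            [m.sample_ids[j] for j in perm],
            m.values[:, perm],
            m.missing_mask[:, perm],
        )
        assert np.allclose(spearman_matrix(m).rho, spearman_matrix(permuted).rho, atol=0)


class TestPersistence:
    def test_square_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        m = random_masked_matrix(rng, 6, 15)
        c = spearman_matrix(m)
        path = tmp_path / "corr.tsv"
        write_correlation_matrix(c, path)
        back = read_correlation_matrix(path)
        assert back.protein_ids == c.protein_ids
        assert np.allclose(back.rho, c.rho, atol=1e-10)

    def test_long_format_lists_every_unordered_pair(self, tmp_path):
        rng = np.random.default_rng(6)
        m = random_masked_matrix(rng, 5, 12)
        c = spearman_matrix(m)
        path = tmp_path / "long.tsv"
        write_correlation_long(c, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "protein_a\tprotein_b\trho\tdefined"
        assert len(lines) - 1 == 5 * 4 // 2
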