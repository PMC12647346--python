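"""Synthetic-cohort generator: determinism, copula calibration, truth consistency."""

import numpy as np
import pytest

from gbacorr import (
    CohortSpec,
    MissingnessModel,
    generate_cohort,
    generate_depletion,
    generate_sparsity_panel,
    spearman_matrix,
    spearman_to_pearson_weight,
)


SMALL = CohortSpec(
    n_modules=3, module_sizes=4, module_rho=0.6, n_background=20,
    n_samples=100, n_decoy_terms=5, n_lethal_pairs=15, seed=7,
)


class TestCopulaCalibration:
    def test_weight_formula(self):
        # bivariate-normal relation: rho_S = (6/pi) asin(rho_P / 2)
        for rho_s in (0.0, 0.3, 0.6, 0.9):
            w = spearman_to_pearson_weight(rho_s)
            back = (6.0 / np.pi) * np.arcsin(w / 2.0)
            assert back == pytest.approx(rho_s, abs=1e-12)

    def test_rho_out_of_range(self):
        with pytest.raises(ValueError):
            spearman_to_pearson_weight(1.0)

    def test_realized_within_module_spearman_near_target(self):
        spec = CohortSpec(
            n_modules=1, module_sizes=10, module_rho=0.6, n_background=0,
            n_samples=1000, missingness=MissingnessModel(kind="none"),
            n_decoy_terms=0, n_lethal_pairs=0, seed=0,
        )
        matrix, _, _, truth = generate_cohort(spec)
        c = spearman_matrix(matrix)
        iu = np.triu_indices(10, k=1)
        assert c.rho[iu].mean() == pytest.approx(0.6, abs=0.05)

    def test_large_sample_convergence(self):
        spec = CohortSpec(
            n_modules=1, module_sizes=8, module_rho=0.7, n_background=0,
            n_samples=2000, missingness=MissingnessModel(kind="none"),
            n_decoy_terms=0, n_lethal_pairs=0, seed=1,
        )
        matrix, _, _, _ = generate_cohort(spec)
        c = spearman_matrix(matrix)
        iu = np.triu_indices(8, k=1)
        assert c.rho[iu].mean() == pytest.approx(0.7, abs=0.03)

    def test_null_cohort_uncorrelated(self):
        spec = CohortSpec(
            n_modules=0, module_sizes=[], module_rho=[], n_background=200,
            n_samples=500, missingness=MissingnessModel(kind="none"),
            n_decoy_terms=0, n_lethal_pairs=0, seed=2,
        )
        matrix, _, _, _ = generate_cohort(spec)
        c = spearman_matrix(matrix)
        iu = np.triu_indices(200, k=1)
        assert np.abs(c.rho[iu]).mean() <= 0.05


class TestDeterminismAndTruth:
    def test_same_spec_same_seed_identical(self):
        m1, t1, p1, _ = generate_cohort(SMALL)
        m2, t2, p2, _ = generate_cohort(SMALL)
        assert np.array_equal(m1.values, m2.values)
        assert np.array_equal(m1.missing_mask, m2.missing_mask)
        assert t1.terms == t2.terms
        assert p1.pairs == p2.pairs

    def test_different_seed_differs(self):
        m1, _, _, _ = generate_cohort(SMALL)
        m2, _, _, _ = generate_cohort(
            CohortSpec(**{**SMALL.__dict__, "seed": 8})
        )
        assert not np.array_equal(m1.values, m2.values)

    def test_truth_consistent_with_emitted_files(self, tmp_path):
        from gbacorr import (
            read_abundance_table,
            read_pair_list,
            read_term_map,
            write_abundance_table,
            write_pair_list,
            write_term_map,
        )

        matrix, terms, pairs, truth = generate_cohort(SMALL)
        write_abundance_table(matrix, tmp_path / "m.tsv")
        write_term_map(terms, tmp_path / "t.tsv")
        write_pair_list(pairs, tmp_path / "p.csv")
        m2 = read_abundance_table(tmp_path / "m.tsv")
        assert np.array_equal(m2.missing_mask, truth.missing_mask)
        t2 = read_term_map(tmp_path / "t.tsv")
        for mod_id, members in truth.modules.items():
            assert t2.terms[f"TERM_{mod_id}"] == set(members)
        p2 = read_pair_list(tmp_path / "p.csv")
        assert p2.pairs == pairs.pairs

    def test_module_membership_partitions_proteins(self):
        matrix, _, _, truth = generate_cohort(SMALL)
        in_modules = [p for p, m in truth.module_of.items() if m is not None]
        assert len(in_modules) == 3 * 4
        assert len(truth.module_of) == matrix.n_proteins

    def test_within_module_pair_fraction_respected(self):
        spec = CohortSpec(n_lethal_pairs=200, within_module_pair_fraction=0.8, seed=3)
        _, _, pairs, truth = generate_cohort(spec)
        frac = np.mean([truth.within_module_pair[p] for p in pairs.pairs])
        assert frac == pytest.approx(0.8, abs=0.1)

    def test_infeasible_spec_errors(self):
        with pytest.raises(ValueError):
            CohortSpec(n_modules=2, module_sizes=[1, 3])


class TestGenerateDepletion:
    def test_null_fold_gives_zero_expected_log2fc(self):
        e, members = generate_depletion(50, 10, 1.0, noise_sd=0.1, seed=0)
        log_a = np.log2(e.values[e.conditions[0]]).mean()
        log_b = np.log2(e.values[e.conditions[1]]).mean()
        assert log_a - log_b == pytest.approx(0.0, abs=0.1)

    def test_noiseless_members_exact(self):
        e, members = generate_depletion(20, 6, 1.74, noise_sd=0.0, seed=1)
        idx = [e.protein_ids.index(p) for p in members]
        lfc = (np.log2(e.values[e.conditions[0]]) - np.log2(e.values[e.conditions[1]]))
        assert np.allclose(lfc[idx], np.log2(1.74))
        non = [i for i in range(20) if i not in idx]
        assert np.allclose(lfc[non], 0.0)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            generate_depletion(5, 6, 1.5)
        with pytest.raises(ValueError):
            generate_depletion(5, 2, 1.5, n_reps=1)


class TestGenerateSparsityPanel:
    def test_degenerate_probabilities(self):
        m0 = generate_sparsity_panel(50, [0.0], seed=0)
        assert m0.missing_mask.all()
        m1 = generate_sparsity_panel(50, [1.0], seed=0)
        assert not m1.missing_mask.any()

    def test_detected_count_binomial(self):
        p, n = 69 / 1172, 1172
        m = generate_sparsity_panel(n, [p], seed=4)
        detected = int((~m.missing_mask[0]).sum())
        sd = np.sqrt(n * p * (1 - p))
        assert abs(detected - n * p) <= 3 * sd

    def test_probability_out_of_range(self):
        with pytest.raises(ValueError):
            generate_sparsity_panel(10, [1.5])


class TestMissingnessModels:
    def test_detection_model_targets_low_abundance(self):
        spec = CohortSpec(
            n_modules=0, module_sizes=[], module_rho=[], n_background=100,
            n_samples=200,
            missingness=MissingnessModel(kind="detection", floor=6.0, steepness=1.0),
            n_decoy_terms=0, n_lethal_pairs=0, seed=5,
        )
        matrix, _, _, _ = generate_cohort(spec)
        missing_rate = matrix.missing_mask.mean(axis=1)
        # proteins whose location is below the floor should drop out more
        observed_mean = np.array(
            [
                row[~mask].mean() if (~mask).any() else 0.0
                for row, mask in zip(matrix.values, matrix.missing_mask)
            ]
        )
        order = np.argsort(observed_mean)
        low, high = missing_rate[order[:30]].mean(), missing_rate[order[-30:]].mean()
        assert low > high

    def test_uniform_rate_realized(self):
        spec = CohortSpec(
            n_modules=0, module_sizes=[], module_rho=[], n_background=100,
            n_samples=300, missingness=MissingnessModel(kind="uniform", rate=0.1),
            n_decoy_terms=0, n_lethal_pairs=0, seed=6,
        )
        matrix, _, _, _ = generate_cohort(spec)
        assert matrix.missing_mask.mean() == pytest.approx(0.1, abs=0.01)
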