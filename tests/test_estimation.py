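"""Least-squares fitting, BIC scoring, subset search, published panels."""

import json
import math

import numpy as np
import pytest

from mutload import (
    EstimationModel,
    MutationMatrix,
    SearchConfig,
    bic_score,
    fit_least_squares,
    generate_from_model,
    model_space_size,
    predict_load,
    published_model,
    search_best_model,
)
from mutload.estimation import SingularDesignError


def matrix_from(counts, genes=None, patients=None):
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    patients = patients or [f"P{j}" for j in range(counts.shape[1])]
    return MutationMatrix(genes=genes, patients=patients, counts=counts)


class TestFitLeastSquares:
    def test_exact_recovery_without_noise(self, rng):
        counts = rng.integers(0, 4, size=(2, 30))
        loads = 2.0 * counts[0] + 3.0 * counts[1] + 7.0
        model, diag = fit_least_squares(counts, loads, gene_symbols=["A", "B"])
        assert model.weights == pytest.approx((2.0, 3.0), abs=1e-9)
        assert model.intercept == pytest.approx(7.0, abs=1e-9)
        assert diag.rss == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_is_mean(self, rng):
        loads = rng.normal(100, 20, 25)
        model, _ = fit_least_squares(np.empty((0, 25)), loads, gene_symbols=[])
        assert model.intercept == pytest.approx(loads.mean())

    def test_rss_matches_normal_equations_oracle(self, rng):
        counts = rng.integers(0, 5, size=(4, 50))
        loads = rng.normal(80, 25, 50)
        _, diag = fit_least_squares(counts, loads)
        # brute-force normal equations
        X = np.column_stack([np.ones(50), counts.T])
        beta = np.linalg.solve(X.T @ X, X.T @ loads)
        rss = float(((loads - X @ beta) ** 2).sum())
        assert diag.rss == pytest.approx(rss, rel=1e-10)
        assert diag.bic == pytest.approx(bic_score(rss, 50, 5), rel=1e-12)

    def test_duplicated_gene_rows_raise_singular_error(self, rng):
        row = rng.integers(0, 4, size=20)
        counts = np.vstack([row, row])
        loads = rng.normal(50, 10, 20)
        with pytest.raises(SingularDesignError, match="DUPL|GENE"):
            fit_least_squares(counts, loads, gene_symbols=["GENEX", "DUPLX"])

    def test_underdetermined_raises(self, rng):
        counts = rng.integers(0, 3, size=(5, 6))
        with pytest.raises(ValueError, match="patients"):
            fit_least_squares(counts, rng.normal(0, 1, 6))


class TestBicScore:
    def test_direct_formula_value(self):
        assert bic_score(100.0, 100, 2) == pytest.approx(
            100 * math.log(1.0) + 2 * math.log(100)
        )
        assert bic_score(100.0, 100, 2) == pytest.approx(9.2103403719761836)

    def test_monotone_in_rss_and_penalty(self):
        assert bic_score(50.0, 100, 2) < bic_score(100.0, 100, 2)
        assert bic_score(100.0, 100, 3) > bic_score(100.0, 100, 2)

    def test_perfect_fit_sentinel(self):
        with pytest.warns(UserWarning, match="perfect fit"):
            assert bic_score(0.0, 100, 2) == float("-inf")


class TestModelSpaceSize:
    def test_sixty_two_candidates(self):
        assert model_space_size(62) == 2**62 - 1 == 4611686018427387903

    def test_small_values(self):
        assert model_space_size(0) == 0
        assert model_space_size(3) == 7


def planted_signal_matrix(rng, n_patients=120, n_noise=9, effect=40.0):
    """One strong signal gene among pure-noise candidates."""
    signal = rng.integers(0, 4, size=n_patients)
    noise = rng.integers(0, 3, size=(n_noise, n_patients))
    loads = (effect * signal + 20.0 + rng.normal(0, 2.0, n_patients)).round().astype(int)
    loads = np.maximum(loads, 0)
    counts = np.vstack([signal, noise])
    genes = ["SIGNAL"] + [f"NOISE{i}" for i in range(n_noise)]
    # embed loads so that column sums equal loads: add a filler row
    filler = loads - counts.sum(axis=0)
    filler = np.maximum(filler, 0)
    matrix = MutationMatrix(
        genes=genes + ["FILLER"],
        patients=[f"P{j:03d}" for j in range(n_patients)],
        counts=np.vstack([counts, filler]),
    )
    return matrix, genes


class TestSearchBestModel:
    def test_forward_finds_only_the_planted_gene(self, rng):
        matrix, genes = planted_signal_matrix(rng)
        model, _ = search_best_model(matrix, genes, SearchConfig(strategy="forward"))
        assert model.gene_symbols == ("SIGNAL",)

    def test_empty_candidates_give_intercept_only(self, rng):
        matrix, _ = planted_signal_matrix(rng)
        model, _ = search_best_model(matrix, [])
        assert model.n_genes == 0
        assert model.intercept == pytest.approx(matrix.loads().mean())

    def test_forward_matches_exhaustive_on_planted_signal(self, rng):
        matrix, genes = planted_signal_matrix(rng, n_noise=7)
        fwd_model, fwd = search_best_model(matrix, genes, SearchConfig("forward"))
        exh_model, exh = search_best_model(matrix, genes, SearchConfig("exhaustive"))
        assert fwd.bic == pytest.approx(exh.bic, rel=1e-12)
        assert fwd_model.gene_symbols == exh_model.gene_symbols

    def test_exhaustive_never_worse_than_forward(self, rng):
        for seed in range(3):
            local = np.random.default_rng(seed)
            counts = local.integers(0, 4, size=(6, 40))
            matrix = matrix_from(counts)
            _, fwd = search_best_model(matrix, matrix.genes, SearchConfig("forward"))
            _, exh = search_best_model(matrix, matrix.genes, SearchConfig("exhaustive"))
            assert exh.bic <= fwd.bic + 1e-9

    def test_exhaustive_refused_above_limit(self, rng):
        matrix = matrix_from(rng.integers(0, 3, size=(25, 60)))
        with pytest.raises(ValueError, match="exhaustive"):
            search_best_model(matrix, matrix.genes, SearchConfig("exhaustive", exhaustive_limit=20))


class TestPredictLoad:
    def test_published_luad_arithmetic(self):
        model = published_model("luad24")
        zero = matrix_from(
            np.zeros((24, 1), dtype=int), genes=list(model.gene_symbols), patients=["Z"]
        )
        assert predict_load(model, zero)[0] == pytest.approx(47.24)
        one_pxdnl = zero.to_frame().copy()
        one_pxdnl.loc["PXDNL", "Z"] = 1
        est = predict_load(model, MutationMatrix.from_frame(one_pxdnl))[0]
        assert est == pytest.approx(47.24 + 68.72)

    def test_published_melanoma_intercept(self):
        model = published_model("melanoma22")
        zero = matrix_from(
            np.zeros((22, 1), dtype=int), genes=list(model.gene_symbols), patients=["Z"]
        )
        assert predict_load(model, zero)[0] == pytest.approx(18.17)

    def test_absent_model_genes_count_zero_with_warning(self, caplog):
        model = published_model("luad24")
        matrix = matrix_from(np.array([[2]]), genes=["UNRELATED"], patients=["P"])
        with caplog.at_level("WARNING"):
            est = predict_load(model, matrix)
        assert est[0] == pytest.approx(47.24)
        assert "absent" in caplog.text

    def test_affine_in_counts(self, rng):
        model = EstimationModel(("A", "B"), (2.5, -1.0), 10.0)
        base = rng.integers(0, 5, size=(2, 8))
        delta = rng.integers(0, 5, size=(2, 8))
        m1 = matrix_from(base, genes=["A", "B"])
        m2 = matrix_from(base + delta, genes=["A", "B"])
        diff = predict_load(model, m2) - predict_load(model, m1)
        expected = np.asarray(model.weights) @ delta
        assert diff == pytest.approx(expected)

    def test_clamp_flag(self):
        model = EstimationModel(("A",), (-5.0,), 1.0)
        matrix = matrix_from(np.array([[3]]), genes=["A"])
        assert predict_load(model, matrix)[0] == pytest.approx(-14.0)
        assert predict_load(model, matrix, clamp=True)[0] == 0.0


class TestPublishedModels:
    def test_gene_counts(self):
        assert published_model("luad24").n_genes == 24
        assert published_model("melanoma22").n_genes == 22

    def test_unknown_name_lists_available(self):
        with pytest.raises(KeyError, match="luad24"):
            published_model("colorectal")

    def test_serialization_round_trip(self, tmp_path):
        model = published_model("melanoma22")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = EstimationModel.from_json(path)
        assert back == model


class TestParameterRecovery:
    def test_noise_free_model_cohort_recovers_weights(self):
        truth = EstimationModel(("A", "B", "C"), (5.0, 3.0, 2.0), 11.0, name="truth")
        from mutload import CohortConfig, build_mutation_matrix, filter_nonsynonymous

        cohort = generate_from_model(truth, 0.0, CohortConfig(n_patients=100, seed=3))
        matrix = build_mutation_matrix(filter_nonsynonymous(cohort.maf_records))
        counts = matrix.gene_counts(truth.gene_symbols)
        loads = cohort.clinical.set_index("patient_id").loc[
            matrix.patients, "true_load"
        ].to_numpy()
        model, diag = fit_least_squares(counts, loads, gene_symbols=truth.gene_symbols)
        assert model.weights == pytest.approx(truth.weights, abs=1e-8)
        assert model.intercept == pytest.approx(truth.intercept, abs=1e-8)

    @pytest.mark.parametrize("n_patients", [100, 1000])
    def test_noisy_recovery_within_three_standard_errors(self, n_patients):
        truth = EstimationModel(("A", "B"), (40.0, 25.0), 50.0, name="truth")
        from mutload import CohortConfig, build_mutation_matrix, filter_nonsynonymous

        cohort = generate_from_model(
            truth, 10.0, CohortConfig(n_patients=n_patients, seed=17)
        )
        matrix = build_mutation_matrix(filter_nonsynonymous(cohort.maf_records))
        counts = matrix.gene_counts(truth.gene_symbols)
        loads = cohort.clinical.set_index("patient_id").loc[
            matrix.patients, "true_load"
        ].to_numpy()
        model, diag = fit_least_squares(counts, loads, gene_symbols=truth.gene_symbols)
        # standard errors from the fit itself
        n_fit = counts.shape[1]
        X = np.column_stack([np.ones(n_fit), counts.T])
        sigma2 = diag.rss / (n_fit - diag.k_params)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        params = np.array([model.intercept, *model.weights])
        true_params = np.array([truth.intercept, *truth.weights])
        assert np.all(np.abs(params - true_params) <= 3 * se)
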