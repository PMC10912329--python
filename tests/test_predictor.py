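import numpy as np
import pytest

import adtpred as ap
from adtpred.evaluate import _pearson_rows
from adtpred.predictor import LowDimMatrix, zscore_rows
from adtpred.preprocess import CLRMatrix, NormalizedGEX


def normal_equations_oracle(Z, Y):
    """Independent OLS oracle: explicit (X'X)^-1 X'Y with intercept column."""
    X = np.hstack([Z, np.ones((Z.shape[0], 1))])
    coef = np.linalg.inv(X.T @ X) @ X.T @ Y
    return coef[:-1], coef[-1]


class TestFitTSVD:
    def test_rank_one_matrix_reconstructed_exactly(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.normal(size=8), rng.normal(size=5))
        loadings, low_dim = ap.fit_tsvd(X, k=1)
        assert np.allclose(low_dim.values @ loadings.T, X, atol=1e-10)

    def test_loadings_are_orthonormal(self):
        rng = np.random.default_rng(1)
        loadings, _ = ap.fit_tsvd(rng.normal(size=(20, 10)), k=5)
        assert np.allclose(loadings.T @ loadings, np.eye(5), atol=1e-8)

    def test_matches_full_svd_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 10))
        loadings, low_dim = ap.fit_tsvd(X, k=5)
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        # singular values of the fit = column norms of the projection
        assert np.allclose(np.linalg.norm(low_dim.values, axis=0), s[:5], atol=1e-8)
        # loadings span the oracle's top-5 right singular subspace
        proj = vt[:5].T @ vt[:5]
        assert np.allclose(proj @ loadings, loadings, atol=1e-8)

    def test_k_above_bound_is_error_naming_bound(self):
        with pytest.raises(ap.FitError, match="min\\(cells-1, genes\\)=4"):
            ap.fit_tsvd(np.ones((5, 10)), k=5)

    def test_no_mean_centering(self):
        # a constant matrix has a nonzero top singular vector; PCA would be all zero
        X = np.full((6, 4), 3.0)
        loadings, low_dim = ap.fit_tsvd(X, k=1)
        assert np.abs(low_dim.values).max() > 1


class TestZscoreCells:
    def test_hand_computed_row(self):
        out = zscore_rows(np.array([[1.0, 2.0, 3.0]]))
        assert out[0] == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_rows_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        out = zscore_rows(rng.normal(2, 5, (50, 12)))
        assert np.allclose(out.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(out.std(axis=1), 1, atol=1e-10)

    def test_sample_ddof_variant(self):
        out = zscore_rows(np.array([[1.0, 2.0, 3.0]]), ddof="sample")
        assert out[0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zeros(self):
        out = zscore_rows(np.array([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]]))
        assert (out[0] == 0).all()
        assert out[1, 2] > 0

    def test_single_component_is_error(self):
        with pytest.raises(ap.FitError):
            zscore_rows(np.ones((3, 1)))


class TestFitLinear:
    def make(self, n=40, k=5, p=3, seed=0):
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(n, k))
        barcodes = [f"c{i}" for i in range(n)]
        return rng, Z, barcodes

    def test_noiseless_recovery(self):
        rng, Z, barcodes = self.make()
        W0 = rng.normal(size=(5, 3))
        b0 = rng.normal(size=3)
        Y = CLRMatrix(Z @ W0 + b0, ["p1", "p2", "p3"], barcodes)
        W, b = ap.fit_linear(LowDimMatrix(Z, barcodes), Y)
        assert np.allclose(W, W0, atol=1e-8)
        assert np.allclose(b, b0, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng, Z, barcodes = self.make(seed=4)
        Y = CLRMatrix(rng.normal(size=(40, 3)), ["p1", "p2", "p3"], barcodes)
        W, b = ap.fit_linear(LowDimMatrix(Z, barcodes), Y)
        W_o, b_o = normal_equations_oracle(Z, Y.values)
        assert np.allclose(W, W_o, atol=1e-8)
        assert np.allclose(b, b_o, atol=1e-8)

    def test_constant_protein_gets_zero_weights(self):
        rng, Z, barcodes = self.make(seed=5)
        Y = CLRMatrix(np.full((40, 1), 7.0), ["p"], barcodes)
        W, b = ap.fit_linear(LowDimMatrix(Z, barcodes), Y)
        assert np.allclose(W, 0, atol=1e-8)
        assert b == pytest.approx([7.0])

    def test_barcode_mismatch_is_error(self):
        _, Z, barcodes = self.make()
        Y = CLRMatrix(np.zeros((40, 1)), ["p"], list(reversed(barcodes)))
        with pytest.raises(ap.AlignmentError):
            ap.fit_linear(LowDimMatrix(Z, barcodes), Y)

    def test_fewer_cells_than_components_is_error(self):
        rng = np.random.default_rng(6)
        Z = LowDimMatrix(rng.normal(size=(4, 5)), [f"c{i}" for i in range(4)])
        Y = CLRMatrix(np.zeros((4, 1)), ["p"], Z.barcodes)
        with pytest.raises(ap.FitError, match="underdetermined"):
            ap.fit_linear(Z, Y)


@pytest.fixture(scope="module")
def small_paired():
    """Small well-specified paired dataset (no extra zeroing, no latent noise)."""
    cfg = ap.SyntheticConfig(
        n_cells=400, n_genes=200, n_proteins=8, n_factors=5,
        sparsity_target=0.0, adt_noise_sd=0.0,
        dispersion=1000.0, adt_depth_mean=5000.0, seed=11,
    )
    return ap.generate(cfg)


class TestFitPipeline:
    def test_refit_is_bit_identical(self, small_paired):
        cfg = ap.PipelineConfig(n_components=5, random_seed=1)
        a = ap.fit_pipeline(small_paired.gex, small_paired.adt, cfg)
        b = ap.fit_pipeline(small_paired.gex, small_paired.adt, cfg)
        assert a.loadings.tobytes() == b.loadings.tobytes()
        assert a.weights.tobytes() == b.weights.tobytes()
        assert a.intercepts.tobytes() == b.intercepts.tobytes()

    def test_training_fit_is_tight_in_well_specified_regime(self, small_paired):
        cfg = ap.PipelineConfig(n_components=5, random_seed=1)
        pipe = ap.fit_pipeline(small_paired.gex, small_paired.adt, cfg)
        pred = ap.predict_adt(pipe, small_paired.gex)
        truth = ap.clr_transform(small_paired.adt)
        r = _pearson_rows(pred.values.T, truth.values.T)
        assert np.median(r) >= 0.95

    def test_heldout_generalization_low_noise(self, small_paired):
        train, test = ap.train_test_split(small_paired, 0.5, seed=2)
        cfg = ap.PipelineConfig(n_components=5, random_seed=1)
        pipe = ap.fit_pipeline(train.gex, train.adt, cfg)
        pred = ap.predict_adt(pipe, test.gex)
        truth = ap.clr_transform(test.adt)
        assert np.median(_pearson_rows(pred.values.T, truth.values.T)) >= 0.9

    def test_oversized_k_clamped_and_recorded(self, small_paired):
        pipe = ap.fit_pipeline(small_paired.gex, small_paired.adt)  # default 300
        assert pipe.n_components == 200  # min(cells-1, genes)
        assert pipe.normalization_config["clamped_from"] == 300

    def test_oversized_k_errors_when_clamping_disabled(self, small_paired):
        cfg = ap.PipelineConfig(n_components=300, clamp_components=False)
        with pytest.raises(ap.FitError, match="clamping is disabled"):
            ap.fit_pipeline(small_paired.gex, small_paired.adt, cfg)

    def test_no_shared_barcodes_is_error(self, small_paired):
        adt = small_paired.adt
        renamed = ap.CountMatrix(
            adt.values, adt.feature_names,
            [f"other{i}" for i in range(adt.n_cells)], "ADT",
        )
        with pytest.raises(ap.AlignmentError):
            ap.fit_pipeline(small_paired.gex, renamed)


class TestAlignGenes:
    def make_pipeline(self):
        rng = np.random.default_rng(7)
        return ap.TrainedPipeline(
            gene_names=[f"g{i}" for i in range(10)],
            loadings=rng.normal(size=(10, 3)),
            weights=rng.normal(size=(3, 2)),
            intercepts=np.zeros(2),
            protein_names=["p1", "p2"],
            n_components=3,
            normalization_config={"min_gene_overlap_fraction": 0.3},
        )

    def test_identical_genes_any_order_is_permutation(self):
        p = self.make_pipeline()
        shuffled = list(reversed(p.gene_names))
        plan = ap.align_genes(p, shuffled)
        assert plan.overlap_fraction == 1.0
        assert not plan.missing_genes
        assert [shuffled[j] for j in plan.trained_to_input] == p.gene_names

    def test_disjoint_gene_lists_error(self):
        p = self.make_pipeline()
        with pytest.raises(ap.AlignmentError, match="0.0%"):
            ap.align_genes(p, ["x1", "x2"])

    def test_half_overlap_reports_missing(self):
        p = self.make_pipeline()
        plan = ap.align_genes(p, p.gene_names[:5] + ["x1", "x2"])
        assert plan.overlap_fraction == pytest.approx(0.5)
        assert plan.missing_genes == p.gene_names[5:]
        assert plan.dropped_input_genes == ["x1", "x2"]


class TestPredictADT:
    def test_in_sample_prediction_matches_fitted_values(self, small_paired):
        cfg = ap.PipelineConfig(n_components=5, random_seed=1)
        pipe = ap.fit_pipeline(small_paired.gex, small_paired.adt, cfg)
        norm = ap.normalize_gex(small_paired.gex)
        z = zscore_rows(norm.values @ pipe.loadings)
        fitted = z @ pipe.weights + pipe.intercepts
        pred = ap.predict_adt(pipe, small_paired.gex)
        assert np.allclose(pred.values, fitted, atol=1e-8)

    def test_gene_permutation_invariance(self, small_paired):
        cfg = ap.PipelineConfig(n_components=5, random_seed=1)
        pipe = ap.fit_pipeline(small_paired.gex, small_paired.adt, cfg)
        rng = np.random.default_rng(8)
        perm = rng.permutation(small_paired.gex.n_features)
        pred = ap.predict_adt(pipe, small_paired.gex)
        pred_perm = ap.predict_adt(pipe, small_paired.gex.subset_features(perm))
        assert np.allclose(pred.values, pred_perm.values, atol=1e-10)

    def test_cell_row_permutation_equivariance(self, small_paired):
        cfg = ap.PipelineConfig(n_components=5, random_seed=1)
        pipe = ap.fit_pipeline(small_paired.gex, small_paired.adt, cfg)
        rng = np.random.default_rng(9)
        perm = rng.permutation(small_paired.gex.n_cells)
        pred = ap.predict_adt(pipe, small_paired.gex)
        pred_perm = ap.predict_adt(pipe, small_paired.gex.subset_cells(perm))
        assert np.allclose(pred.values[perm], pred_perm.values, atol=1e-10)

    def test_prediction_of_a_cell_depends_only_on_its_own_row(self, small_paired):
        cfg = ap.PipelineConfig(n_components=5, random_seed=1)
        pipe = ap.fit_pipeline(small_paired.gex, small_paired.adt, cfg)
        norm = ap.normalize_gex(small_paired.gex)
        single = NormalizedGEX(
            norm.values[:1], norm.gene_names, norm.barcodes[:1], norm.size_factors[:1]
        )
        pred_all = ap.predict_adt(pipe, norm)
        pred_one = ap.predict_adt(pipe, single)
        assert np.allclose(pred_all.values[0], pred_one.values[0], atol=1e-12)

    def test_already_normalized_input_accepted_explicitly(self, small_paired):
        cfg = ap.PipelineConfig(n_components=5, random_seed=1)
        pipe = ap.fit_pipeline(small_paired.gex, small_paired.adt, cfg)
        norm = ap.normalize_gex(small_paired.gex)
        assert np.allclose(
            ap.predict_adt(pipe, norm).values,
            ap.predict_adt(pipe, small_paired.gex).values,
        )
        with pytest.raises(TypeError):
            ap.predict_adt(pipe, norm.values)

    def test_noise_monotonicity_of_recovery(self):
        """Held-out accuracy improves as latent ADT noise shrinks to zero."""
        medians = []
        for noise in (2.0, 0.5, 0.0):
            cfg = ap.SyntheticConfig(
                n_cells=400, n_genes=200, n_proteins=8, n_factors=5,
                sparsity_target=0.0, adt_noise_sd=noise, seed=11,
            )
            ds = ap.generate(cfg)
            train, test = ap.train_test_split(ds, 0.5, seed=2)
            pipe = ap.fit_pipeline(
                train.gex, train.adt, ap.PipelineConfig(n_components=5, random_seed=1)
            )
            pred = ap.predict_adt(pipe, test.gex)
            truth = ap.clr_transform(test.adt)
            medians.append(float(np.median(_pearson_rows(pred.values.T, truth.values.T))))
        assert medians[0] < medians[1] < medians[2]
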