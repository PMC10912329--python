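import logging

import numpy as np
import pytest

import adtpred as ap

# degenerate-case warnings (constant rows, zero-filled genes) are expected
# in several fixtures and would otherwise flood the output
logging.getLogger("adtpred").setLevel(logging.ERROR)

REF_SEED = 7


@pytest.fixture(scope="session")
def ref_config():
    """Reference study conditions used by the recovery/robustness checks."""
    return ap.SyntheticConfig(seed=REF_SEED)


@pytest.fixture(scope="session")
def ref_dataset(ref_config):
    return ap.generate(ref_config)


@pytest.fixture(scope="session")
def ref_split(ref_dataset):
    return ap.train_test_split(ref_dataset, 0.5, seed=REF_SEED)


@pytest.fixture(scope="session")
def ref_pipeline(ref_split):
    train, _ = ref_split
    cfg = ap.PipelineConfig(n_components=10, random_seed=REF_SEED)
    return ap.fit_pipeline(train.gex, train.adt, cfg)


@pytest.fixture(scope="session")
def ref_heldout(ref_split, ref_pipeline):
    """(prediction, CLR truth) on the held-out half of the reference data."""
    _, test = ref_split
    pred = ap.predict_adt(ref_pipeline, test.gex)
    truth = ap.clr_transform(test.adt)
    return pred, truth


@pytest.fixture
def small_counts():
    """Tiny deterministic GEX CountMatrix with a mitochondrial gene."""
    values = np.array(
        [
            [5, 0, 2],
            [0, 0, 0],
            [1, 3, 4],
        ]
    )
    return ap.CountMatrix(
        values, ["MT-CO1", "ACTB", "CD19"], ["AAA", "CCC", "GGG"], "GEX"
    )


def random_pipeline(rng, n_genes=12, k=4, n_proteins=3):
    """Small random trained pipeline for interpretability/prediction tests."""
    loadings, _ = np.linalg.qr(rng.normal(size=(n_genes, k)))
    return ap.TrainedPipeline(
        gene_names=[f"G{i}" for i in range(n_genes)],
        loadings=loadings,
        weights=rng.normal(size=(k, n_proteins)),
        intercepts=rng.normal(size=n_proteins),
        protein_names=[f"P{i}" for i in range(n_proteins)],
        n_components=k,
        normalization_config={"zscore_ddof": "population"},
    )
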