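import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from phenoscape import (CellDataset, CohortDesign, EmbeddingDesign,
                        PipelineConfig, simulate_embedding_cohort)


@pytest.fixture
def config():
    return PipelineConfig(seed=0)


@pytest.fixture
def toy_dataset():
    """3 genes x 4 cells with hand-chosen entries and one 2-D embedding."""
    counts = sp.csr_matrix(np.array([
        [5, 0, 2, 0],
        [0, 1, 0, 0],
        [3, 4, 0, 7],
    ]))
    cells = pd.DataFrame({
        "cell_id": ["c1", "c2", "c3", "c4"],
        "embryo_id": ["e1", "e1", "e2", "e2"],
        "genotype": ["wt", "wt", "mut", "mut"],
        "background": "B6",
    })
    genes = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                          "gene_name": ["A", "B", "C"]})
    emb = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    return CellDataset(counts=counts, cells=cells, genes=genes,
                       embeddings={"pca": emb})


@pytest.fixture
def mixture_cohort():
    """Separated 3-component cohort with component 0 enriched in mutants."""
    design = EmbeddingDesign(
        component_means=np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]]),
        component_weights_wt=np.array([0.1, 0.45, 0.45]),
        component_weights_mut=np.array([0.4, 0.3, 0.3]),
        enriched_component=0, component_cov_scale=1.0, seed=11)
    return simulate_embedding_cohort(design, n_embryos_per_genotype=4,
                                     cells_per_embryo=300)


@pytest.fixture
def exchangeable_cohort():
    """Same mixture for both genotypes: no real signal."""
    w = np.array([1 / 3, 1 / 3, 1 / 3])
    design = EmbeddingDesign(
        component_means=np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]]),
        component_weights_wt=w, component_weights_mut=w,
        seed=13)
    return simulate_embedding_cohort(design, n_embryos_per_genotype=4,
                                     cells_per_embryo=300)


@pytest.fixture
def small_cohort_design():
    return CohortDesign(
        base_proportions=np.array([0.5, 0.3, 0.2]),
        dirichlet_concentration=500.0, n_wt_embryos=4, n_mut_embryos=4,
        cells_per_embryo_mean=2000, cells_per_embryo_sd=200, seed=7)
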