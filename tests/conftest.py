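import numpy as np
import pandas as pd
import pytest

from perturbscope.scoring import score_modality
from perturbscope.sensitivity import fit_all
from perturbscope.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_cells=900,
        n_genes=400,
        n_peaks=600,
        n_tfs=3,
        n_sensitive_genes_per_tf=20,
        n_sensitive_peaks_per_tf=30,
        effect_size_log2fc=1.5,
        editing_efficiency_range=(0.8, 1.0),
        genome_length_bp=6_000_000,
        tad_width_bp=500_000,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(rna, atac, guides, genes, peaks, truth) with strong planted effects."""
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_scores(small_sim):
    rna, atac, guides, *_ = small_sim
    return {
        "RNA": score_modality(rna, guides, seed=0),
        "ATAC": score_modality(atac, guides, seed=0),
    }


@pytest.fixture(scope="session")
def small_st(small_sim, small_scores):
    rna, atac, guides, *_ = small_sim
    return pd.concat(
        [
            fit_all(rna, small_scores["RNA"], guides),
            fit_all(atac, small_scores["ATAC"], guides),
        ],
        ignore_index=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
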