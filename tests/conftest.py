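import numpy as np
import pytest
import scipy.sparse as sp

from gbotools.matrix import CountMatrix
from gbotools import synthetic as syn


@pytest.fixture(scope="session")
def small_barnyard():
    cfg = syn.BarnyardConfig(
        n_human=150,
        n_mouse=150,
        n_doublets=10,
        ambient_fraction=0.01,
        mean_umis_per_cell=2000,
        n_genes_per_species=120,
        seed=7,
    )
    return syn.simulate_barnyard(cfg)


@pytest.fixture(scope="session")
def planted_design_matrix():
    design = syn.PlantedDesign(
        n_cells_per_group=60,
        n_null_genes=300,
        planted_region_genes={f"rg{i}": 1.0 for i in range(12)},
        planted_time_genes={f"tg{i}": 1.0 for i in range(8)},
        seed=11,
    )
    return syn.simulate_grouped_counts(design)


@pytest.fixture()
def random_count_matrix():
    rng = np.random.default_rng(3)
    counts = sp.csr_matrix(rng.poisson(1.0, size=(40, 25)))
    genes = np.array(
        [f"GRCh38_g{i}" for i in range(20)] + [f"mm10_g{i}" for i in range(20)],
        dtype=object,
    )
    species = np.array(["human"] * 20 + ["mouse"] * 20, dtype=object)
    barcodes = np.array([f"BC{i}" for i in range(25)], dtype=object)
    return CountMatrix(counts, genes, barcodes, species=species)


@pytest.fixture(scope="session")
def random_skeletons():
    out = []
    for seed in range(12):
        cfg = syn.SkeletonConfig(
            n_primary=2 + seed % 4,
            branching_depth=1 + seed % 4,
            segment_length=8.0 + seed,
            jitter=1.5,
            seed=seed,
        )
        out.append(syn.simulate_skeleton(cfg))
    return out
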