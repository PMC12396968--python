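import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from atlaskit.core import CellMatrix
from atlaskit.synthetic import AtlasConfig, simulate_atlas


def small_atlas_config(**overrides) -> AtlasConfig:
    """Desk-scale atlas: 6 donors, 2-3 tissue groups, few hundred genes."""
    defaults = dict(
        n_donors=6,
        n_genes=200,
        cells_per_sample=50,
        genes_per_program=8,
        tissue_groups=("BLO", "JEJ"),
        tissue_programs={},
        doublet_rate=0.0,
        erythrocyte_rate=0.0,
        lineages={"T": ("cd4", "cd8")},
        adt_markers=("CD69", "CD103"),
    )
    defaults.update(overrides)
    return AtlasConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_atlas():
    """One shared small simulated atlas with a planted tissue program."""
    cfg = small_atlas_config(
        n_genes=260, tissue_programs={"trm_gut": "JEJ"}, tissue_activity_ratio=5.0
    )
    return simulate_atlas(cfg, seed=0)


@pytest.fixture()
def toy_cell_matrix():
    """Hand-built 10-cell x 20-gene matrix with ADTs and QC flags."""
    rng = np.random.default_rng(42)
    counts = sp.csr_matrix(rng.poisson(2.0, size=(10, 20)))
    adt = sp.csr_matrix(rng.poisson(5.0, size=(10, 3)))
    cell_meta = pd.DataFrame({
        "donor_id": [f"D{i % 2}" for i in range(10)],
        "tissue_group": ["BLO"] * 5 + ["JEJ"] * 5,
        "lineage": ["T"] * 10,
        "subset": ["cd4"] * 6 + ["cd8"] * 4,
        "age_group": ["young"] * 10,
        "sex": ["F"] * 10,
    })
    gene_meta = pd.DataFrame({"symbol": [f"G{i:03d}" for i in range(20)]})
    for flag in ("is_heat_shock", "is_ribosomal", "is_metallothionein",
                 "is_hemoglobin", "is_stress"):
        gene_meta[flag] = False
    qc = pd.DataFrame({
        "scrublet_prob": np.zeros(10),
        "hashsolo_prob": np.zeros(10),
        "erythro_fraction": np.zeros(10),
        "dual_receptor": np.zeros(10, dtype=int),
        "erythro_pred": np.zeros(10, dtype=int),
        "mito_frac": np.full(10, 0.05),
    })
    adt_meta = pd.DataFrame({"marker": ["CD3", "CD4", "CD8"]})
    return CellMatrix(gex_counts=counts, cell_meta=cell_meta,
                      gene_meta=gene_meta, adt_counts=adt, adt_meta=adt_meta,
                      qc_flags=qc)
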