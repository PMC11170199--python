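"""Shared fixtures: small synthetic datasets and crafted QC matrices."""

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

from tomomap import SimulationConfig, generate_cell_matrix, generate_section_reference


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=300, n_sections=40, n_cells=400,
                            n_clusters=5, count_noise=5.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ref, section_truth = generate_section_reference(small_config)
    adata, cell_truth = generate_cell_matrix(small_config, section_truth)
    return {"config": small_config, "reference": ref,
            "section_truth": section_truth, "adata": adata,
            "cell_truth": cell_truth}


def _crafted_cell(n_ordinary, mito_count=0, hb_count=0):
    """(ordinary gene count vector spec, mito, hb) for the QC boundary grid."""
    return n_ordinary, mito_count, hb_count


@pytest.fixture(scope="session")
def qc_boundary_fixture():
    """Ten crafted cells spanning every QC threshold boundary.

    Hand-derived truth under the strict rule
    200 < n_genes < 2500 & mito% < 30 & hb% < 10.
    """
    specs = [
        # (cell_id, n_ordinary_genes, mito_count, hb_count, retained, reason)
        ("low150", 150, 0, 0, False, "low_genes"),
        ("low200", 200, 0, 0, False, "low_genes"),    # boundary, strict
        ("ok201", 201, 0, 0, True, "none"),
        ("ok2499", 2499, 0, 0, True, "none"),
        ("high2500", 2500, 0, 0, False, "high_genes"),
        ("mito29.9", 701, 299, 0, True, "none"),      # mito 29.9%
        ("mito30", 700, 300, 0, False, "mito"),       # boundary, strict
        ("mito35", 650, 350, 0, False, "mito"),
        ("hb9.9", 901, 0, 99, True, "none"),          # hb 9.9%
        ("hb10", 900, 0, 100, False, "hemoglobin"),   # boundary, strict
    ]
    n_ordinary_genes = 2600
    genes = [f"g{i:05d}" for i in range(n_ordinary_genes)] + ["mt-nd1", "hbae1.1"]
    X = sparse.lil_matrix((len(specs), len(genes)), dtype=np.int64)
    for row, (_, n_ord, m, h, _, _) in enumerate(specs):
        X[row, :n_ord] = 1
        X[row, n_ordinary_genes] = m
        X[row, n_ordinary_genes + 1] = h
    adata = AnnData(X=X.tocsr(),
                    obs=pd.DataFrame(index=[s[0] for s in specs]),
                    var=pd.DataFrame(index=genes))
    truth = pd.DataFrame(
        {"retained": [s[4] for s in specs],
         "removal_reason": [s[5] for s in specs]},
        index=[s[0] for s in specs])
    return adata, truth
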