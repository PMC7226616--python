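import numpy as np
import pandas as pd
import pytest

import metabyield as mb


@pytest.fixture(scope="session")
def cell_scenario():
    """One organ–stage cell with 10 planted yield effects (the recovery unit)."""
    matrix, truth, traits = mb.simulate_cell(seed=11)
    return matrix, truth, traits


@pytest.fixture(scope="session")
def small_matrix():
    """Tiny complete matrix with design annotations, for plumbing tests."""
    design = mb.build_design(2, 2, 2, organs=["flag_leaf"], stages=["anthesis"])
    matrix, truth = mb.simulate_metabolome(
        design, n_metabolites=6, n_blocks=2, block_rho=0.3, seed=7,
        n_true_effects=2, target_r2=0.5,
    )
    return matrix, truth


def matrix_from_values(values: np.ndarray, mask: np.ndarray | None = None, scale="raw"):
    """Wrap a plain array into a MetabolomeMatrix with a generic design."""
    n, p = values.shape
    cond = ["WS" if i < n // 2 else "HY" for i in range(n)]
    design = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "organ": "flag_leaf",
            "stage": "anthesis",
            "condition": cond,
            "genotype": "G1",
            "trial": "T1",
            "replicate": 1,
        }
    )
    vdf = pd.DataFrame(values, index=pd.Index(design["sample_id"], name="sample_id"),
                       columns=[f"M{j}" for j in range(p)])
    mdf = pd.DataFrame(mask if mask is not None else np.zeros_like(values, bool),
                       index=vdf.index, columns=vdf.columns)
    return mb.MetabolomeMatrix(design=design, values=vdf, mask=mdf, scale=scale)
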