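import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from stressstates.matrix import CountMatrix
from stressstates.simulate import (
    SimConfig,
    TreatmentSpec,
    make_signature_library,
    simulate_experiment,
)


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 cells x 4 genes with hand-checkable totals."""
    X = np.array(
        [
            [1, 3, 0, 0],
            [2, 2, 2, 2],
            [0, 0, 5, 5],
        ]
    )
    meta = pd.DataFrame(
        {"chemical": ["DMSO", "DMSO", "drugA"], "conc": [0.0, 0.0, 1.0]},
        index=pd.Index(["c1", "c2", "c3"], name="cell_id"),
    )
    return CountMatrix(sp.csr_matrix(X), meta, pd.Index(["g1", "g2", "g3", "g4"]))


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated experiment with one responsive treatment.

    500 genes, 150 control + 150 treated cells; the treatment doubles the
    mean (l2fc=1) of the UPR signature's 40 genes in 60% of its cells.
    """
    lib = make_signature_library(
        n_srps=2, genes_per_srp=40, overlap_fraction=0.0,
        universe_size=500, seed=3, names=("UPR", "OSR"),
    )
    cfg = SimConfig(
        n_genes=500,
        n_control_cells=150,
        treatments=[
            TreatmentSpec(
                chemical="drugA", conc=1.0, target_srps=("UPR",),
                l2fc=1.0, responsive_fraction=0.6, n_cells=150,
            )
        ],
        signatures=lib,
        seed=11,
    )
    cm, truth = simulate_experiment(cfg)
    return cfg, cm, truth
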