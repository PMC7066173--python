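import numpy as np
import pandas as pd
import pytest

import nephrokit as nk
from nephrokit.simulate import gen_sc_counts, gen_signature_set


@pytest.fixture(scope="session")
def sigset():
    """A small dissimilar reference set with forced SBS1/SBS5."""
    return gen_signature_set(8, seed=7, max_cosine=0.5)


@pytest.fixture(scope="session")
def sc_data():
    """One generated single-cell dataset taken through QC and normalization."""
    cm, truth = gen_sc_counts(seed=3)
    cell_qc, cm_cells = nk.compute_qc(cm)
    gene_qc, cm_f = nk.filter_genes(cm_cells)
    norm = nk.lognormalize(cm_f)
    return {"cm": cm, "truth": truth, "cell_qc": cell_qc, "gene_qc": gene_qc, "norm": norm}


@pytest.fixture()
def toy_counts():
    """A tiny hand-checkable count matrix: 4 genes (one mito) x 4 cells."""
    genes = pd.DataFrame(
        {
            "symbol": ["GA", "GB", "GC", "MT-1"],
            "chromosome": ["1", "2", "X", "MT"],
            "is_mito": [False, False, False, True],
        },
        index=pd.Index(["GA", "GB", "GC", "MT-1"], name="gene"),
    )
    counts = np.array(
        [
            [10, 0, 3, 5],
            [0, 2, 3, 5],
            [5, 1, 0, 5],
            [1, 1, 6, 85],
        ]
    )
    return nk.CountMatrix(genes, ["c1", "c2", "c3", "c4"], counts)
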