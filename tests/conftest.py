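import numpy as np
import pandas as pd
import pytest

from onepotseq.io import MatrixBundle


def make_bundle(dense, barcodes=None, genes=None, species=None):
    """MatrixBundle from a dense count array (rows = barcodes)."""
    dense = np.asarray(dense)
    n_bc, n_g = dense.shape
    if barcodes is None:
        barcodes = [f"BC{i:04d}" for i in range(n_bc)]
    if genes is None:
        genes = [f"g{j:04d}" for j in range(n_g)]
    if species is None:
        species = ["A"] * n_g
    return MatrixBundle(
        matrix=dense,
        barcodes=np.array(barcodes, dtype=object),
        genes=pd.DataFrame({"gene": genes, "species": species}),
    )


@pytest.fixture
def bundle_factory():
    return make_bundle
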