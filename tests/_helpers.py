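import numpy as np
import pandas as pd

from boolpath.expression import BinaryExpressionMatrix, ExpressionMatrix


def make_binary(states, genes, groups=None, subjects=None, continuous=None):
    """Binary matrix helper with optional metadata and continuous values."""
    states = np.asarray(states, dtype=np.int8)
    cell_ids = [f"c{i}" for i in range(states.shape[0])]
    meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell"))
    meta["cluster"] = "c0"
    if groups is not None:
        meta["group"] = list(groups)
    if subjects is not None:
        meta["subject"] = list(subjects)
    cont = None
    if continuous is not None:
        cont = ExpressionMatrix(
            values=np.asarray(continuous, dtype=float),
            cell_ids=cell_ids,
            gene_symbols=list(genes),
            metadata=meta.copy(),
        )
    return BinaryExpressionMatrix(
        values=states,
        cell_ids=cell_ids,
        gene_symbols=list(genes),
        metadata=meta,
        continuous=cont,
    )
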