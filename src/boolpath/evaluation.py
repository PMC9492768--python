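"""In-silico evaluation harnesses for the rule-determination stage.

The main harness measures how equivalent-rule-set (ERS) size responds to
training-set size: inference is re-run on the same population downsampled
to small fractions of its cells (and optionally augmented beyond 100% by
resampling from a pool), and the mean observed ERS size is reported per
in-degree class.  Less data constrains the rule space less, so mean ERS
size should not decrease as cells are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import BinaryExpressionMatrix
from .inference import GAParams, infer
from .network import SignedNetwork

DEFAULT_FRACTIONS = (0.01, 0.5, 1.0, 2.0)


@dataclass
class ErsVsCellsResult:
    """Mean observed ERS size per cell fraction and in-degree class."""

    table: pd.DataFrame  # columns: fraction, n_cells, indegree, mean_ers, n_nodes

    def mean_ers(self, fraction: float, indegree: int | None = None) -> float:
        t = self.table[np.isclose(self.table["fraction"], fraction)]
        if indegree is not None:
            t = t[t["indegree"] == indegree]
        if t.empty:
            return float("nan")
        return float(np.average(t["mean_ers"], weights=t["n_nodes"]))


def downsample_cells(
    data: BinaryExpressionMatrix, fraction: float, seed: int
) -> BinaryExpressionMatrix:
    """Random cell subset at ``fraction`` <= 1, or augmentation beyond it.

    Fractions above 1 resample additional cells (with replacement) from the
    same population, emulating augmentation from a neighboring pool.
    """
    rng = np.random.default_rng(seed)
    n = data.n_cells
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    if fraction <= 1.0:
        k = max(1, int(round(n * fraction)))
        idx = sorted(rng.choice(n, size=k, replace=False))
    else:
        extra = int(round(n * (fraction - 1.0)))
        idx = list(range(n)) + list(rng.choice(n, size=extra, replace=True))
    out = data.take_cells(idx)
    if len(set(out.cell_ids)) != len(out.cell_ids):
        # augmentation resamples cells: disambiguate the duplicate ids
        seen: dict[str, int] = {}
        new_ids = []
        for cid in out.cell_ids:
            k = seen.get(cid, 0)
            seen[cid] = k + 1
            new_ids.append(cid if k == 0 else f"{cid}-aug{k}")
        out.cell_ids = new_ids
        out.metadata.index = pd.Index(new_ids, name="cell")
        if out.continuous is not None:
            out.continuous.cell_ids = list(new_ids)
            out.continuous.metadata.index = pd.Index(new_ids, name="cell")
    return out


def ers_vs_cells(
    net: SignedNetwork,
    data: BinaryExpressionMatrix,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
    ga_params: GAParams | None = None,
) -> ErsVsCellsResult:
    """Re-run rule inference at several training-set sizes.

    Returns mean observed ERS size per in-degree class at each fraction;
    the GA seed is re-derived per fraction so runs are independent but
    reproducible.
    """
    rows = []
    for j, frac in enumerate(fractions):
        sub = downsample_cells(data, frac, seed=seed * 1009 + j)
        params = ga_params or GAParams()
        params = GAParams(**{**params.__dict__, "seed": seed * 31 + j})
        res = infer(net, sub, ga_params=params)
        by_k: dict[int, list[int]] = {}
        for node, rs in res.rulespaces.items():
            k = len(net.regulators_of(node))
            by_k.setdefault(k, []).append(rs.ers_size)
        for k, sizes in sorted(by_k.items()):
            rows.append(
                {
                    "fraction": frac,
                    "n_cells": sub.n_cells,
                    "indegree": k,
                    "mean_ers": float(np.mean(sizes)),
                    "n_nodes": len(sizes),
                }
            )
    return ErsVsCellsResult(table=pd.DataFrame(rows))
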