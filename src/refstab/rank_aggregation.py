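"""Consensus ranking of candidate reference genes across stability methods.

Each method contributes a rank per gene (fractional/average ranks for tied
statistics); the consensus score is the unweighted geometric mean of those
ranks, and the final ordering ascends by that score with lexicographic gene-id
tie-breaking. The geometric mean of a gene's ranks always lies between its
best and worst method rank, and a gene dominated by another in every method
can never overtake it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import CoverageError, DimensionError
from .stability_methods import StabilityTable


def aggregate_ranks(tables: list[StabilityTable]) -> pd.DataFrame:
    """Geometric-mean consensus over 2-4 stability tables on one gene set.

    Returns a DataFrame with one row per gene: gene_id, rank_<method> for each
    input method, geomean_rank and final_rank (a 1-based permutation), sorted
    by final_rank.
    """
    if not (2 <= len(tables) <= 4):
        raise DimensionError("consensus aggregation expects between 2 and 4 stability tables")
    methods = [t.method for t in tables]
    if len(set(methods)) != len(methods):
        raise CoverageError(f"duplicate methods in input: {sorted(methods)}")

    base = set(tables[0].table["gene_id"])
    for t in tables[1:]:
        other = set(t.table["gene_id"])
        if other != base:
            diff = sorted(base.symmetric_difference(other))
            raise CoverageError(f"gene sets differ between methods (symmetric difference: {diff})")

    ranks = pd.DataFrame({f"rank_{t.method}": t.rank_series() for t in tables})
    log_ranks = np.log(ranks.to_numpy(dtype=float))
    out = ranks.copy()
    out["geomean_rank"] = np.exp(log_ranks.mean(axis=1))
    out = out.reset_index().rename(columns={"index": "gene_id"})
    out = out.sort_values(["geomean_rank", "gene_id"], kind="mergesort").reset_index(drop=True)
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out
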