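"""Transcriptome-wide screen for candidate reference genes.

From a genes x samples FPKM matrix, computes per gene the mean (MV), standard
deviation (SD, n-1 denominator), coefficient of variation (CV = SD/MV) and
maximum fold change (MFC = max FPKM / min FPKM), and flags the genes passing
the housekeeping screen: MV strictly above a floor, SD rank within the top N
of the MV-passing genes, CV and MFC strictly below their ceilings. Genes with
a zero FPKM in any sample have an undefined MFC and never pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DimensionError
from .tabular_io import ExpressionMatrix

DEFAULT_MV_MIN = 30.0
DEFAULT_TOP_N_SD = 500
DEFAULT_CV_MAX = 0.5
DEFAULT_MFC_MAX = 6.3


def screen_candidates(
    expr: ExpressionMatrix,
    mv_min: float = DEFAULT_MV_MIN,
    top_n_sd: int = DEFAULT_TOP_N_SD,
    cv_max: float = DEFAULT_CV_MAX,
    mfc_max: float = DEFAULT_MFC_MAX,
) -> pd.DataFrame:
    """Per-gene screening statistics, sorted by SD ascending.

    Columns: gene_id, mv, sd, cv, mfc, sd_rank, passes. ``sd_rank`` is the
    1-based ascending SD rank over all genes (ties broken by gene id); the
    top-N condition is evaluated on the SD ranking restricted to genes that
    already meet the MV floor, matching a screen that filters on abundance
    first. All threshold comparisons are strict.
    """
    if expr.data.shape[1] < 2:
        raise DimensionError("screening needs at least 2 samples")
    values = expr.values
    mv = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mv > 0, sd / mv, np.nan)
    vmin = values.min(axis=1)
    vmax = values.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mfc = np.where(vmin > 0, vmax / vmin, np.nan)

    out = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "mv": mv,
            "sd": sd,
            "cv": cv,
            "mfc": mfc,
        }
    )
    out = out.sort_values(["sd", "gene_id"], kind="mergesort").reset_index(drop=True)
    out["sd_rank"] = np.arange(1, len(out) + 1)

    mv_pass = out["mv"] > mv_min
    # SD rank within the MV-passing subset drives the top-N cut.
    rank_in_pass = mv_pass.cumsum()
    top_ok = mv_pass & (rank_in_pass <= top_n_sd)
    cv_ok = out["cv"].notna() & (out["cv"] < cv_max)
    mfc_ok = out["mfc"].notna() & (out["mfc"] < mfc_max)
    out["passes"] = (mv_pass & top_ok & cv_ok & mfc_ok).to_numpy()
    return out
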