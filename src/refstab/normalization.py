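"""Relative quantification of target genes by the 2^-ddCt method.

For each biological sample, dCt = Ct_target - Ct_reference; ddCt subtracts the
control group's mean dCt; the fold change is 2^(-ddCt). With several reference
genes the per-reference ddCt values are averaged on the Ct scale (equivalently,
the fold change is the geometric mean of the per-reference fold changes) — the
two-reference case is the familiar

    ddCt = [ (dCt_ref1)_exp - (dCt_ref1)_ctl ] / 2
         + [ (dCt_ref2)_exp - (dCt_ref2)_ctl ] / 2.

Group-level results average ddCt over biological replicates before
exponentiation and report the replicate SD of ddCt alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import GroupingError, IdentifierError, TableValueError
from .tabular_io import CtMatrix


def _check_genes(ct: CtMatrix, genes: list[str]) -> None:
    missing = [g for g in genes if g not in ct.data.index]
    if missing:
        raise IdentifierError(f"genes absent from the Ct matrix: {missing}")


def _ddct_per_sample(ct: CtMatrix, target: str, references: list[str], control_group: str) -> pd.Series:
    """Per-sample ddCt averaged over the reference genes."""
    if not references:
        raise TableValueError("at least one reference gene is required")
    if target in references:
        raise IdentifierError(f"reference list contains the target gene {target!r}")
    _check_genes(ct, [target] + list(references))
    groups = ct.meta["group"]
    if control_group not in set(groups):
        raise GroupingError(f"control group {control_group!r} not present in the metadata")
    control_cols = [s for s in ct.sample_ids if groups[s] == control_group]
    ddct_per_ref = []
    for ref in references:
        dct = ct.data.loc[target] - ct.data.loc[ref]
        baseline = dct[control_cols].mean()
        ddct_per_ref.append(dct - baseline)
    return sum(ddct_per_ref) / len(references)


def _group_summary(ct: CtMatrix, ddct: pd.Series, target: str, references: list[str]) -> pd.DataFrame:
    rows = []
    groups = ct.meta["group"]
    for group in dict.fromkeys(groups):
        vals = ddct[[s for s in ct.sample_ids if groups[s] == group]]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(
            {
                "target_gene": target,
                "sample_group": group,
                "delta_delta_ct": mean,
                "ddct_sd": sd,
                "fold_change": float(2.0 ** (-mean)),
                "references_used": "+".join(references),
                "n_replicates": len(vals),
            }
        )
    return pd.DataFrame(rows)


def ddct_single(ct: CtMatrix, target: str, reference: str, control_group: str) -> pd.DataFrame:
    """Single-reference 2^-ddCt, one row per sample group (control fold = 1)."""
    ddct = _ddct_per_sample(ct, target, [reference], control_group)
    return _group_summary(ct, ddct, target, [reference])


def ddct_multi(ct: CtMatrix, target: str, references: list[str], control_group: str) -> pd.DataFrame:
    """Multi-reference 2^-ddCt; with one reference this equals :func:`ddct_single`."""
    ddct = _ddct_per_sample(ct, target, list(references), control_group)
    return _group_summary(ct, ddct, target, list(references))


def expression_profile(
    ct: CtMatrix,
    targets: list[str],
    stable_refs: list[str],
    unstable_ref: str,
    control_group: str,
) -> pd.DataFrame:
    """Concordance table: each target normalized several ways.

    For every target gene and sample group, reports the fold change under each
    stable reference alone, under their combination, and under the unstable
    reference, so concordant (stable) versus discordant (unstable) profiles
    can be contrasted directly. The ``normalizer`` column labels the scheme.
    """
    _check_genes(ct, list(targets) + list(stable_refs) + [unstable_ref])
    frames = []
    for target in targets:
        for ref in stable_refs:
            part = ddct_single(ct, target, ref, control_group)
            part.insert(1, "normalizer", ref)
            frames.append(part)
        if len(stable_refs) > 1:
            part = ddct_multi(ct, target, list(stable_refs), control_group)
            part.insert(1, "normalizer", "+".join(stable_refs))
            frames.append(part)
        part = ddct_single(ct, target, unstable_ref, control_group)
        part.insert(1, "normalizer", f"{unstable_ref} (unstable)")
        frames.append(part)
    return pd.concat(frames, ignore_index=True)
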