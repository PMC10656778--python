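"""The four expression-stability statistics for candidate reference genes.

All four operate on a technical-replicate-collapsed Ct matrix and return a
:class:`StabilityTable` in which a LOWER statistic always means a MORE stable
gene:

* comparative delta-Ct — for every ordered gene pair, the sample SD of the
  pairwise Ct difference; a gene's statistic is its mean pairwise SD. Pairwise
  differences cancel per-sample loading offsets.
* BestKeeper — descriptive per-gene dispersion of raw Ct (SD, with CV% as a
  companion). Sensitive to loading offsets by construction.
* geNorm — average pairwise variation M of log2 expression ratios, with
  iterative exclusion of the least stable gene and the V(n/n+1) pairwise
  variation between normalization factors built from the n and n+1 most
  stable genes.
* NormFinder — a model-based variance decomposition separating intra-group
  (noise) variance from inter-group (condition-dependent) deviations; the
  stability value combines the shrunken inter-group deviation magnitude with
  the intra-group standard error, averaged over groups.

Ties in any statistic are broken by gene id (lexicographic), so every report
is deterministic. ``rank`` is an integer permutation of 1..n; ``frac_rank``
assigns tied statistics their average rank and is the column consumed by the
consensus aggregation (the geNorm terminal pair, reported jointly, sits at
frac_rank 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, GroupingError, TableValueError
from .tabular_io import CtMatrix

METHODS = ("delta_ct", "bestkeeper", "genorm", "normfinder")


@dataclass
class StabilityTable:
    """Per-gene stability statistics and ranks for one method."""

    method: str
    table: pd.DataFrame  # columns: gene_id, statistic, rank, frac_rank
    extras: dict = field(default_factory=dict)

    def rank_series(self) -> pd.Series:
        """Fractional ranks indexed by gene id (input to consensus aggregation)."""
        return self.table.set_index("gene_id")["frac_rank"]


@dataclass
class GeNormResult:
    """Full geNorm trajectory: removal order, M values, pairwise variations."""

    initial_m: pd.Series             # per-gene M on the full candidate set
    m_values_final: pd.Series        # per-gene M at the step the gene was removed
    removal_order: list[str]         # least stable first; excludes the final pair
    final_pair: tuple[str, str]
    pairwise_variation: pd.Series    # V(n/n+1) indexed by n = 2..n_genes-1
    ranking: list[str]               # most stable first (final pair alphabetical)


def _finalize(method: str, gene_ids: list[str], stats: np.ndarray, extras: dict | None = None,
              frac_override: pd.Series | None = None) -> StabilityTable:
    """Sort by (statistic, gene_id), attach integer and fractional ranks."""
    df = pd.DataFrame({"gene_id": gene_ids, "statistic": np.asarray(stats, dtype=float)})
    df = df.sort_values(["statistic", "gene_id"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if frac_override is not None:
        df["frac_rank"] = df["gene_id"].map(frac_override).astype(float)
    else:
        df["frac_rank"] = df["statistic"].rank(method="average").to_numpy()
    return StabilityTable(method=method, table=df, extras=extras or {})


def _require(ct: CtMatrix, min_genes: int, min_samples: int, what: str) -> np.ndarray:
    values = ct.values
    if values.shape[0] < min_genes:
        raise DimensionError(f"{what} needs at least {min_genes} genes")
    if values.shape[1] < min_samples:
        raise DimensionError(f"{what} needs at least {min_samples} samples")
    return values


# ---------------------------------------------------------------------------
# comparative delta-Ct
# ---------------------------------------------------------------------------

def delta_ct_stability(ct: CtMatrix) -> StabilityTable:
    """Mean sample-SD of pairwise Ct differences, per gene.

    For genes i, k and samples j, compute dCt_ik(j) = Ct_ij - Ct_kj; the
    statistic of gene i is the mean over k != i of SD_j(dCt_ik) (n-1
    denominator). With only two genes both statistics equal the single
    pairwise SD.
    """
    values = _require(ct, 2, 2, "delta-Ct")
    g = values.shape[0]
    diffs = values[:, None, :] - values[None, :, :]          # g x g x samples
    sds = diffs.std(axis=2, ddof=1)                          # diagonal is 0
    stats = sds.sum(axis=1) / (g - 1)
    return _finalize("delta_ct", ct.gene_ids, stats)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper_stability(ct: CtMatrix, variant: str = "plain_sd") -> StabilityTable:
    """Descriptive per-gene Ct dispersion.

    ``plain_sd``: SD = sample standard deviation of Ct, CV% = 100*SD/mean(Ct).
    ``mad_geomean``: SD = mean absolute deviation of Ct from the gene's
    geometric-mean Ct, CV% = 100*SD/geomean(Ct) (the descriptive statistics of
    the original spreadsheet tool). The statistic is the SD in either variant;
    extras carry per-gene CV% and a "CV ± SD" display string.
    """
    values = _require(ct, 1, 2, "BestKeeper")
    if variant == "plain_sd":
        sd = values.std(axis=1, ddof=1)
        center = values.mean(axis=1)
    elif variant == "mad_geomean":
        if (values <= 0).any():
            raise TableValueError("mad_geomean variant requires strictly positive Ct")
        center = np.exp(np.log(values).mean(axis=1))
        sd = np.abs(values - center[:, None]).mean(axis=1)
    else:
        raise TableValueError(f"unknown BestKeeper variant {variant!r}")
    cv_pct = 100.0 * sd / center
    detail = pd.DataFrame(
        {
            "gene_id": ct.gene_ids,
            "sd": sd,
            "cv_pct": cv_pct,
            "cv_sd": [f"{c:.2f} ± {s:.2f}" for c, s in zip(cv_pct, sd)],
        }
    )
    return _finalize("bestkeeper", ct.gene_ids, sd, extras={"variant": variant, "detail": detail})


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def _log2_quantities(ct: CtMatrix, efficiencies: dict | None) -> np.ndarray:
    """log2 relative quantities: (minCt_i - Ct_ij) * log2(E_i), E default 2."""
    values = ct.values
    if efficiencies is None:
        e = np.full(values.shape[0], 2.0)
    else:
        missing = [gid for gid in ct.gene_ids if gid not in efficiencies]
        if missing:
            raise TableValueError(f"no efficiency for genes: {missing}")
        e = np.array([1.0 + efficiencies[gid] / 100.0 for gid in ct.gene_ids])
        if (e <= 1.0).any():
            raise TableValueError("efficiencies must be positive percentages")
    return (values.min(axis=1, keepdims=True) - values) * np.log2(e)[:, None]


def _genorm_m(logq: np.ndarray) -> np.ndarray:
    """M_j = mean over k != j of SD_samples(logq_j - logq_k)."""
    g = logq.shape[0]
    diffs = logq[:, None, :] - logq[None, :, :]
    sds = diffs.std(axis=2, ddof=1)
    return sds.sum(axis=1) / (g - 1)


def genorm_stability(
    ct: CtMatrix,
    efficiencies: dict | None = None,
) -> tuple[GeNormResult, StabilityTable]:
    """geNorm M values with iterative exclusion and V(n/n+1) pairwise variation.

    Quantities are Q_ij = E_i^(minCt_i - Ct_ij) (E = 2 for every gene unless a
    gene_id -> efficiency%% mapping is given). At each step the gene with the
    largest average pairwise variation M is removed (ties: larger gene id goes
    first) until two genes remain; those two are reported jointly at the
    terminal M value and share frac_rank 1.5. V(n/n+1) is the sample SD of
    log2(NF_n / NF_{n+1}), NF_n being the per-sample geometric mean of the n
    most stable genes' quantities, for n = 2 .. n_genes-1.
    """
    _require(ct, 3, 2, "geNorm")
    logq_full = _log2_quantities(ct, efficiencies)
    gene_ids = list(ct.gene_ids)
    initial_m = pd.Series(_genorm_m(logq_full), index=gene_ids, name="M_initial")

    active = list(range(len(gene_ids)))
    removal_order: list[str] = []
    m_at_removal: dict[str, float] = {}
    while len(active) > 2:
        m = _genorm_m(logq_full[active])
        # worst gene: largest M; ties removed larger-gene-id first so the
        # lexicographically smaller id ends up ranked more stable
        worst_local = max(range(len(active)), key=lambda t: (m[t], gene_ids[active[t]]))
        worst_gene = gene_ids[active[worst_local]]
        removal_order.append(worst_gene)
        m_at_removal[worst_gene] = float(m[worst_local])
        del active[worst_local]

    m_final = _genorm_m(logq_full[active])
    pair = tuple(sorted(gene_ids[t] for t in active))
    for t, local_m in zip(active, m_final):
        m_at_removal[gene_ids[t]] = float(local_m)

    ranking = list(pair) + removal_order[::-1]

    # V(n/n+1): NF built from the n most stable genes, in log2 space.
    idx_by_rank = [gene_ids.index(gid) for gid in ranking]
    v_entries = {}
    for n in range(2, len(gene_ids)):
        nf_n = logq_full[idx_by_rank[:n]].mean(axis=0)
        nf_n1 = logq_full[idx_by_rank[: n + 1]].mean(axis=0)
        v_entries[n] = float(np.std(nf_n - nf_n1, ddof=1))
    pairwise_variation = pd.Series(v_entries, name="V")
    pairwise_variation.index.name = "n"

    m_series = pd.Series({gid: m_at_removal[gid] for gid in gene_ids}, name="M")
    frac = {}
    for pos, gid in enumerate(ranking, start=1):
        frac[gid] = 1.5 if gid in pair else float(pos)
    # integer ranks follow the ranking order directly
    df = pd.DataFrame(
        {
            "gene_id": ranking,
            "statistic": [m_at_removal[gid] for gid in ranking],
            "rank": np.arange(1, len(ranking) + 1),
            "frac_rank": [frac[gid] for gid in ranking],
        }
    )
    result = GeNormResult(
        initial_m=initial_m,
        m_values_final=m_series,
        removal_order=removal_order,
        final_pair=pair,  # type: ignore[arg-type]
        pairwise_variation=pairwise_variation,
        ranking=ranking,
    )
    table = StabilityTable(
        method="genorm",
        table=df,
        extras={"pairwise_variation": pairwise_variation, "final_pair": pair},
    )
    return result, table


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def normfinder_stability(ct: CtMatrix, group_by: str = "group") -> StabilityTable:
    """Model-based stability value from a variance decomposition.

    Within each group the gene x sample Ct block is two-way centered (gene
    means and sample means removed); the per-gene intra-group variance is
    estimated from the residuals with the small-sample bias correction

        sigma2_ig = max(0, (s2_ig - mean_i(s2_ig) / (k - 1)) * k / (k - 2)),

    where s2_ig is the residual mean square (n_g - 1 denominator) and k the
    number of genes. Inter-group deviations d_ig = (group gene mean - gene
    grand mean), centered to sum to zero across genes within each group, are
    shrunk by their sampling variance v_ig = sigma2_ig / n_g toward zero using
    the method-of-moments estimate gamma2 of the true deviation variance:

        d~_ig = d_ig * gamma2 / (gamma2 + v_ig).

    The per-gene stability value is mean_g(|d~_ig| + sqrt(v~_ig)) with
    v~_ig = v_ig * gamma2 / (gamma2 + v_ig); when gamma2 truncates to zero the
    value degenerates to mean_g sqrt(v_ig) (pure intra-group standard error).
    With a single group the stability value is the intra-group SD alone.
    Requires >= 3 genes; in multi-group mode every group needs >= 2 samples.
    """
    values = _require(ct, 3, 2, "NormFinder")
    if group_by not in ct.meta.columns:
        raise GroupingError(f"no metadata column {group_by!r}")
    labels = ct.meta[group_by].to_numpy()
    uniq = list(dict.fromkeys(labels))
    k = values.shape[0]

    if len(uniq) == 1:
        sigma2 = _intra_group_variance(values)
        return _finalize("normfinder", ct.gene_ids, np.sqrt(sigma2),
                         extras={"mode": "single_group", "group_by": group_by})

    sizes = {g: int((labels == g).sum()) for g in uniq}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise GroupingError(
            f"groups with a single sample: {small}; merge them or run with a single group label"
        )

    n_groups = len(uniq)
    sigma2 = np.empty((k, n_groups))
    group_means = np.empty((k, n_groups))
    n_per = np.empty(n_groups)
    for gi, g in enumerate(uniq):
        block = values[:, labels == g]
        sigma2[:, gi] = _intra_group_variance(block)
        group_means[:, gi] = block.mean(axis=1)
        n_per[gi] = block.shape[1]

    grand = values.mean(axis=1)
    d = group_means - grand[:, None]
    d = d - d.mean(axis=0, keepdims=True)          # deviations sum to 0 across genes
    v = sigma2 / n_per[None, :]

    df_d = (k - 1) * (n_groups - 1)
    gamma2 = max(0.0, float((d ** 2).sum() / df_d - v.mean()))
    if gamma2 > 0.0:
        shrink = gamma2 / (gamma2 + v)
        rho = np.abs(d * shrink) + np.sqrt(v * shrink)
    else:
        rho = np.sqrt(v)
    stability = rho.mean(axis=1)
    per_group = pd.DataFrame(rho, index=ct.gene_ids, columns=[str(g) for g in uniq])
    return _finalize(
        "normfinder",
        ct.gene_ids,
        stability,
        extras={
            "mode": "multi_group",
            "group_by": group_by,
            "gamma2": gamma2,
            "per_group": per_group,
            "intra_group_variance": pd.DataFrame(sigma2, index=ct.gene_ids,
                                                 columns=[str(g) for g in uniq]),
        },
    )


def _intra_group_variance(block: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene residual variance of one two-way-centered block."""
    k, n = block.shape
    if k < 3:
        raise DimensionError("the variance decomposition needs at least 3 genes")
    if n < 2:
        raise DimensionError("each group needs at least 2 samples")
    z = block - block.mean(axis=1, keepdims=True) - block.mean(axis=0, keepdims=True) + block.mean()
    s2 = (z ** 2).sum(axis=1) / (n - 1)
    sigma2 = (s2 - s2.mean() / (k - 1)) * k / (k - 2)
    return np.maximum(sigma2, 0.0)


def run_all_methods(
    ct: CtMatrix,
    methods: tuple[str, ...] = METHODS,
    bestkeeper_variant: str = "plain_sd",
    efficiencies: dict | None = None,
    group_by: str = "group",
) -> dict[str, StabilityTable]:
    """Convenience: run the requested methods on one collapsed Ct matrix."""
    tables: dict[str, StabilityTable] = {}
    for m in methods:
        if m == "delta_ct":
            tables[m] = delta_ct_stability(ct)
        elif m == "bestkeeper":
            tables[m] = bestkeeper_stability(ct, variant=bestkeeper_variant)
        elif m == "genorm":
            _, tables[m] = genorm_stability(ct, efficiencies=efficiencies)
        elif m == "normfinder":
            tables[m] = normfinder_stability(ct, group_by=group_by)
        else:
            raise TableValueError(f"unknown stability method {m!r}")
    return tables
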