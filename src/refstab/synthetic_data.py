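"""Simulators with known ground truth for every downstream stage.

The Ct simulator mirrors the design of a multi-condition qRT-PCR screen:
each gene i has a baseline Ct mu_i; each (gene, condition-group) pair gets a
random biological effect beta_ig ~ N(0, tau_i^2) — tau_i is the planted
instability, smaller = more stable; each sample j in group g carries a loading
offset phi_gj ~ N(0, lambda^2) shared by ALL genes (template-amount variation,
which ratio-based stability methods cancel and raw-Ct methods do not); and
every cell gets technical noise eps ~ N(0, sigma_eps^2).

    Ct_igj = mu_i + beta_ig + phi_gj + eps_igj

Defaults reproduce the stated world of the emulated study: 14 treatment groups
plus a control, 3 biological replicates per group, sigma_eps = 0.2 cycles
(typical qPCR technical noise) and loading SD 1.0 cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TableValueError
from .tabular_io import CtMatrix, DilutionSeries, ExpressionMatrix


@dataclass
class SimSpec:
    """Parameters of one simulated Ct experiment."""

    mu: np.ndarray                 # per-gene baseline Ct, cycles, in [15, 35]
    tau: np.ndarray                # per-gene group-effect SD, cycles (instability)
    n_groups: int = 14
    n_bio_reps: int = 3
    loading_sd: float = 1.0        # lambda, cycles
    noise_sd: float = 0.2          # sigma_eps, cycles
    seed: int = 0
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.mu.shape != self.tau.shape or self.mu.ndim != 1 or self.mu.size == 0:
            raise TableValueError("mu and tau must be 1-d arrays of equal length")
        if (self.mu < 15).any() or (self.mu > 35).any():
            raise TableValueError("baseline Ct mu must lie in [15, 35]")
        if (self.tau < 0).any() or self.loading_sd < 0 or self.noise_sd < 0:
            raise TableValueError("all SDs must be >= 0")
        if self.n_groups < 1:
            raise TableValueError("n_groups must be >= 1")
        if self.n_bio_reps < 2:
            raise TableValueError("n_bio_reps must be >= 2")
        if not self.gene_ids:
            width = len(str(self.mu.size))
            self.gene_ids = [f"G{i + 1:0{width}d}" for i in range(self.mu.size)]
        if len(self.gene_ids) != self.mu.size:
            raise TableValueError("gene_ids length must match mu")

    @property
    def n_genes(self) -> int:
        return self.mu.size


def simulate_ct(spec: SimSpec) -> tuple[CtMatrix, pd.DataFrame]:
    """Draw a Ct matrix from ``spec``.

    Returns the matrix (one column per biological sample, tech_rep = 1; the
    first group is labelled as the control condition) and a ground-truth table
    with per-gene tau sorted ascending — smaller tau means more stable.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    g, ng, nr = spec.n_genes, spec.n_groups, spec.n_bio_reps
    beta = rng.normal(0.0, 1.0, size=(g, ng)) * spec.tau[:, None]
    phi = rng.normal(0.0, spec.loading_sd, size=ng * nr)
    eps = rng.normal(0.0, spec.noise_sd, size=(g, ng * nr))
    group_idx = np.repeat(np.arange(ng), nr)
    ct = spec.mu[:, None] + beta[:, group_idx] + phi[None, :] + eps

    width = len(str(ng))
    group_labels = [f"group{k + 1:0{width}d}" for k in range(ng)]
    sample_ids, groups, conditions, bio_reps = [], [], [], []
    for k in range(ng):
        for r in range(nr):
            sample_ids.append(f"{group_labels[k]}_r{r + 1}")
            groups.append(group_labels[k])
            conditions.append("control" if k == 0 else "treatment")
            bio_reps.append(r + 1)
    meta = pd.DataFrame(
        {
            "group": groups,
            "condition": conditions,
            "bio_rep": bio_reps,
            "tech_rep": 1,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    data = pd.DataFrame(np.clip(ct, 1e-3, 45.0), index=spec.gene_ids, columns=sample_ids)
    truth = pd.DataFrame({"gene_id": spec.gene_ids, "tau": spec.tau})
    truth = truth.sort_values(["tau", "gene_id"], kind="mergesort").reset_index(drop=True)
    return CtMatrix(data, meta), truth


def simulate_fpkm(
    n_genes: int,
    n_samples: int,
    n_stable: int,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Draw an FPKM matrix with a planted set of housekeeping-like genes.

    Stable genes have mean FPKM in [35, 195] with log-normal per-sample scatter
    of sigma = 0.1 (CV ~ 0.1, max fold change well under 2); unstable genes are
    split between lowly expressed ones (mean < 25, same small scatter, so they
    fail the mean filter) and variable ones (sigma = 1.2, so they fail the CV
    and fold-change filters by a wide margin). The margins are chosen so the
    planted set and the screening thresholds (mean > 30, CV < 0.5, MFC < 6.3)
    cannot straddle each other. Returns the matrix and the planted gene ids.
    """
    if n_stable > n_genes:
        raise TableValueError("n_stable cannot exceed n_genes")
    if n_samples < 2:
        raise TableValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    sample_ids = [f"S{j + 1:02d}" for j in range(n_samples)]
    values = np.empty((n_genes, n_samples))
    stable_ids = gene_ids[:n_stable]
    n_unstable = n_genes - n_stable
    for i in range(n_stable):
        mean = rng.uniform(35.0, 195.0)
        values[i] = mean * np.exp(rng.normal(0.0, 0.1, n_samples))
    for k in range(n_unstable):
        i = n_stable + k
        if k % 2 == 0:  # lowly expressed: fails the mean filter
            mean = rng.uniform(0.1, 25.0)
            values[i] = mean * np.exp(rng.normal(0.0, 0.1, n_samples))
        else:  # highly variable: fails CV and max fold change
            mean = rng.uniform(35.0, 195.0)
            values[i] = mean * np.exp(rng.normal(0.0, 1.2, n_samples))
    data = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(data), stable_ids


def simulate_dilution(
    gene_id: str,
    true_efficiency: float,
    intercept: float = 25.0,
    n_points: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Generate a 10-fold dilution series for a primer pair of known efficiency.

    Points are (x_k, Ct_k) with x_k = 0, -1, -2, ... (log10 relative template
    amount, most concentrated tube at 0) and

        Ct_k = intercept - slope * x_k + noise,
        slope = 1 / log10(1 + true_efficiency / 100),

    so a perfectly doubling assay (E = 100%) has slope 3.3219.
    """
    if not (50.0 < true_efficiency <= 150.0):
        raise TableValueError("true_efficiency must lie in (50, 150] percent")
    if n_points < 3:
        raise TableValueError("need at least 3 dilution points")
    rng = np.random.default_rng(seed)
    slope = 1.0 / np.log10(1.0 + true_efficiency / 100.0)
    xs = -np.arange(n_points, dtype=float)
    cts = intercept - slope * xs + rng.normal(0.0, noise_sd, n_points)
    return DilutionSeries(gene_id, list(zip(xs.tolist(), cts.tolist())))
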