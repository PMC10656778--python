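# Methods

## Scope and data model

All analyses operate on two containers: a genes × samples FPKM matrix
(`ExpressionMatrix`) and a genes × samples Ct matrix (`CtMatrix`) whose
columns carry (group, condition, biological replicate, technical replicate)
metadata. Ct values must be finite and in (0, 45]; missing cells are a hard
error rather than being imputed, because all four stability statistics assume
complete matrices and no principled imputation rule exists for Ct. Technical
replicates are collapsed by arithmetic mean **on the Ct scale** (Ct is already
a log2-scale quantity; averaging on the linear 2^−Ct scale would weight the
replicates by template abundance). Delimiters are explicit, never guessed.

## Candidate screening

Per gene across samples: MV (mean FPKM), SD (sample standard deviation, n−1
denominator — the sample sets used in such screens are samples, not
populations, and the choice is documented so SD ranks are reproducible), CV =
SD/MV, MFC = max/min FPKM. A gene passes when MV > `mv_min`, its SD rank
among MV-passing genes is ≤ `top_n_sd`, CV < `cv_max`, and MFC < `mfc_max`
(defaults 30, 500, 0.5, 6.3; all comparisons strict). Genes with a zero FPKM
have an undefined MFC and never pass. The abundance (MV) filter is applied
before the SD-rank cut, matching the usual "abundant first, then least
variable" screening order. The final, manual curation step of such screens
(functional annotation) is intentionally not automated.

## Standard curves

OLS of Ct on log10 relative template amount (`scipy.stats.linregress`);
R² is the squared Pearson correlation; the slope is reported as a positive
magnitude. Efficiency is E% = (10^(1/|slope|) − 1) × 100. This relation is
not always printed in application papers, but it reproduces every published
(slope, E) pair we test against to ≤ 0.01 percentage points, which is itself
a shipped test. The dilution x-axis convention (most concentrated point at
x = 0, 10-fold steps at −1, −2, …) only affects the intercept, never the
slope or efficiency.

## Stability statistics

Lower always means more stable. Ties in any statistic are broken by gene id
(lexicographic), making every report deterministic. Each method returns both
an integer rank permutation and fractional (average-for-ties) ranks; the
consensus consumes the fractional ranks, which preserve rank-sum invariance
under tie splitting.

**Comparative ΔCt.** For genes i, k: ΔCt_ik(j) = Ct_ij − Ct_kj per sample j;
the statistic of gene i is the mean over k ≠ i of the sample SD (n−1) of
ΔCt_ik. Pairwise differencing cancels per-sample loading offsets exactly.

**BestKeeper.** Descriptive per-gene dispersion of raw Ct. The default
`plain_sd` variant reports the sample SD and CV% = 100·SD/mean(Ct); the
`mad_geomean` variant reports the mean absolute deviation from the gene's
geometric-mean Ct and CV% against that geometric mean (the descriptive
statistics of the original spreadsheet tool). The default is `plain_sd`
because published "CV ± SD" pairs are generally consistent with
CV% = 100·SD/mean and raw data to discriminate the variants are rarely
available. BestKeeper is deliberately *not* loading-invariant — it measures
raw Ct dispersion — and the test suite asserts that asymmetry.

**geNorm.** Relative quantities Q_ij = E_i^(minCt_i − Ct_ij) with E_i = 2 for
every gene unless per-gene efficiencies are supplied (whether published runs
used efficiency correction is typically unstated, so perfect doubling is the
default). M_j is the mean over k ≠ j of the sample SD of log2(Q_j/Q_k). The
gene with the largest M is removed (ties: larger gene id removed first) and M
is recomputed until two genes remain; those are reported jointly at the
terminal M and share fractional rank 1.5. V(n/n+1) is the sample SD of
log2(NF_n/NF_{n+1}), where NF_n is the per-sample geometric mean of the n
most stable genes' quantities, for n = 2 … n_genes−1. The conventional
V < 0.15 guidance is reported, never enforced.

**NormFinder.** Within each group g the gene × sample block is two-way
centered; with k genes and n_g samples the residual mean square s²_ig
(n_g − 1 denominator) has expectation σ²_ig(1 − 2/k) + σ̄²_g/k, giving the
bias-corrected, zero-truncated estimator

    σ̂²_ig = max(0, (s²_ig − s̄²_g/(k−1)) · k/(k−2)).

Inter-group deviations d_ig = (group gene mean − gene grand mean), centered
to sum to zero across genes within each group, have sampling variance
approximated by v_ig = σ̂²_ig/n_g (gene-centering and group-weight correction
factors are ignored; with ≥ 4 groups and ≥ 8 genes they are second-order).
The variance of the true deviations is estimated by method of moments,
γ̂² = max(0, Σd²/((k−1)(G−1)) − mean(v)), and the deviations are shrunk,
d̃ = d·γ̂²/(γ̂² + v). The per-gene stability value is

    mean over groups of ( |d̃_ig| + sqrt(v_ig · γ̂²/(γ̂² + v_ig)) ),

i.e. shrunken inter-group bias plus the posterior standard error. When γ̂²
truncates to zero (no detectable condition dependence) the value degenerates
to the intra-group standard error mean_g sqrt(v_ig), which still orders genes
by noise. With a single group the stability value is the intra-group SD
σ̂_i alone. Multi-group mode requires every group to have ≥ 2 samples and the
decomposition needs ≥ 3 genes.

Because the method authors' original reference script could not be obtained
in this environment, the implementation is validated against an independent
plain-loop transcription of the formulas above plus a frozen synthetic
fixture (8 genes × 4 groups × 6 samples, seed 7, agreement to 1e−6). This
checks internal consistency of the vectorized path, not bit-compatibility
with the original tool.

## Consensus ranking

The consensus score of a gene is the unweighted geometric mean of its
(fractional) ranks across 2–4 methods; the final ranking ascends by that
score with lexicographic tie-breaking. The score always lies between the
gene's best and worst method rank (strictly, unless all methods agree), and a
gene dominated in every method can never overtake its dominator. The original
web tool's exact tie handling is unpublished; this module aggregates whatever
stability tables it is given and records method provenance in the output
header rather than claiming bit-compatibility with the web service.

## 2^−ΔΔCt normalization

Per biological sample, ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the
*mean* ΔCt of the control group's biological replicates (the standard reading
of "control" as a single quantity); fold change = 2^−ΔΔCt, so the control
group's fold change is 1 by construction. With several references the
per-reference ΔΔCt values are averaged on the Ct scale — equivalently the
fold change is the geometric mean of per-reference fold changes — whose
two-reference case is the familiar halved-sum formula. Group-level values
average ΔΔCt over biological replicates **before** exponentiation (the
replicate SD of ΔΔCt is reported alongside); averaging folds after
exponentiation would bias them upward under replicate noise. Fold changes
are invariant to per-sample loading offsets and to reference order.
Efficiency-corrected (Pfaffl-type) quantification is out of scope.

## Synthetic data: what it emulates, and what a green test establishes

`simulate_ct` draws Ct_igj = μ_i + β_ig + φ_gj + ε_igj with β_ig ~ N(0, τ_i²)
per (gene, group), φ_gj ~ N(0, λ²) per sample shared across genes, and
ε ~ N(0, σ_ε²). Group effects are independent across groups (treatments are
unordered conditions, not a dose series). Defaults: 14 groups × 3 biological
replicates (the design of a typical multi-stress screen, the first group
labelled control), λ = 1.0 cycle, σ_ε = 0.2 cycles (typical qPCR technical
noise). The shared loading offset is the mechanism that makes ratio-based
methods (ΔCt, geNorm) outperform raw-Ct methods (BestKeeper); this asymmetry
is deliberate and tested. Not emulated: amplification curves, efficiency
heterogeneity between genes, missing/censored Ct, outlier wells, or
correlated group effects — so green tests establish correct *mathematics* and
correct *ordering under the stated noise model*, not robustness to real-world
pathology.

`simulate_fpkm` plants housekeeping-like genes (mean in [35, 195], log-normal
scatter σ = 0.1) against lowly expressed (mean < 25) and highly variable
(σ = 1.2) decoys. The margins are wide enough that the planted set and the
screening thresholds cannot straddle each other, which is what makes the
exact-recovery test meaningful rather than brittle.

`simulate_dilution` produces Ct_k = intercept − slope·x_k (+ noise) at
x = 0, −1, −2, … with slope = 1/log10(1 + E/100); the default 5 points.

## Numerical choices and degenerate inputs

* All SDs use the n−1 denominator; sample means over a power-of-two number of
  samples are exact in binary floating point, which the loading-invariance
  tests exploit to assert bitwise identity.
* NormFinder variance estimates are truncated at zero before square roots
  (the unbiased estimators can go negative at small n).
* geNorm requires ≥ 3 genes; ΔCt accepts 2 (both genes then share the single
  pairwise SD); a group with one sample is rejected by NormFinder's
  multi-group mode with a pointer to single-group mode.
* A dilution series with < 3 distinct dilutions is rejected as rank-deficient.
* CSV outputs use 4 fractional digits by default (6 for dilution points), and
  pipeline runs are byte-reproducible at a fixed seed.

## Known limitations

* NormFinder agreement is demonstrated against an internal oracle, not the
  original publication's script (unavailable here); the shrinkage variance
  uses the σ̂²/n approximation discussed above.
* BestKeeper's Pearson-correlation-to-index machinery of the original tool is
  not reproduced — only its descriptive SD/CV layer, which is what published
  rankings of this kind quote.
* The RefFinder-style consensus aggregates the four methods' ranks as given;
  it does not reproduce the web service's internal sub-method re-runs.
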