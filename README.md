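# refstab

Systematic selection and validation of qRT-PCR reference (housekeeping)
genes, and relative quantification against them. The package implements the
complete workflow a plant-molecular lab uses to establish reference genes for
a species with no prior qRT-PCR groundwork:

1. **Candidate screening** from RNA-seq: per-gene mean FPKM (MV), standard
   deviation (SD), coefficient of variation (CV = SD/MV) and maximum fold
   change (MFC = max/min FPKM) across samples, with the housekeeping filters
   MV > 30, SD rank within the top N, CV < 0.5, MFC < 6.3 (all strict).
2. **Standard curves**: OLS fit of Ct against log10 template amount of a
   10-fold dilution series; amplification efficiency
   E% = (10^(1/|slope|) − 1) × 100, with |slope| = 3.3219 ⇔ E = 100%.
3. **Four stability statistics** (lower = more stable throughout):
   comparative ΔCt (mean SD of pairwise Ct differences), BestKeeper
   (descriptive Ct SD and CV%), geNorm (average pairwise variation *M* with
   iterative exclusion and the V(n/n+1) pairwise variation between
   normalization factors), and NormFinder (model-based decomposition into
   intra-group variance and shrunken inter-group deviations).
4. **Consensus ranking**: the unweighted geometric mean of the four methods'
   ranks, as popularized by the RefFinder web tool.
5. **2^−ΔΔCt normalization** of target genes against one or several reference
   genes (multi-reference ΔΔCt is the mean of per-reference ΔΔCt values,
   i.e. the geometric mean of per-reference fold changes), including the
   stable-vs-unstable reference concordance contrast used to validate a
   reference choice.

Because public studies of this kind rarely publish their raw Ct matrices, the
package ships a first-class synthetic-data module: Ct matrices are drawn from
Ct<sub>igj</sub> = μ<sub>i</sub> + β<sub>ig</sub> + φ<sub>gj</sub> + ε<sub>igj</sub>
with per-(gene, group) effects β ~ N(0, τ<sub>i</sub>²) (τ is the planted
instability), per-sample loading offsets φ ~ N(0, λ²) shared across genes, and
technical noise ε ~ N(0, σ<sub>ε</sub>²) — so every downstream stage is tested
against known ground truth.

## Worked example

```sh
refstab simulate -o demo --seed 1            # ct.csv, meta.csv, fpkm.csv, truth.csv, dilutions
refstab screen --fpkm demo/fpkm.csv -o demo/screening.csv
# -> 30 of 500 genes pass
refstab stability --ct demo/ct.csv --meta demo/meta.csv -o demo/stab
refstab aggregate --stability demo/stab -o demo/consensus.csv
```

`demo/consensus.csv` then starts and ends (simulated data, seed 1, one gene
planted with a 2-cycle group-effect SD against 0.05 for the rest):

```
gene_id,rank_delta_ct,rank_bestkeeper,rank_genorm,rank_normfinder,geomean_rank,final_rank
G07,1.0000,5.0000,1.5000,1.0000,1.6549,1
...
G10,10.0000,10.0000,10.0000,10.0000,10.0000,10
```

G07 is the consensus best reference (geometric mean of its four method ranks
= 1.65); the planted unstable gene G10 is ranked last by every method and by
the consensus — exactly the behaviour a reference-gene screen must show.
Fractional ranks appear where a method reports ties (geNorm reports its final
pair jointly, both at rank 1.5).

The same analyses are available as library calls (`screen_candidates`,
`fit_standard_curve`, `delta_ct_stability`, `bestkeeper_stability`,
`genorm_stability`, `normfinder_stability`, `aggregate_ranks`, `ddct_single`,
`ddct_multi`, `expression_profile`), and `refstab run --config run.yaml`
executes the whole pipeline with a JSON run manifest.

## Acceptance script

`scripts/acceptance.py` regenerates, from scratch, the headline
amplification-efficiency figures: for each reported primer pair it builds a
noise-free dilution series with the published standard-curve slope, refits
the curve by OLS, and converts the fitted slope back to an efficiency
percentage. Run it from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the statistical details, default parameters, and
the limits of what the synthetic data can establish.
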