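# synlet

Synthetic-lethality discovery around an anchor gene, from two complementary
data types:

1. **Isogenic RNAi screen analytics.** Given per-gene cell viabilities after
   knockdown in a wild-type line and an isogenic knockout line (e.g.
   MCF10A vs MCF10A-*CDH1*⁻/⁻), the package computes per-gene viability
   ratios KO/WT, classifies genes as synthetic lethal (SL, ratio < 1) or
   reverse synthetic lethal (RSL, ratio ≥ 1.3), summarises gene-class ratio
   distributions with kernel densities and peak localisation, and tests each
   class against the genome-wide background with the two-sample
   Kolmogorov–Smirnov test.
2. **Pathway-metagene association scan.** Given a tumour expression cohort
   (genes × samples) and a gene-set collection (GMT), each pathway with ≥ 5
   genes is summarised by a *metagene* — the first right-singular vector of
   the per-gene standardized member submatrix, one score per sample. Samples
   are binned into tertiles of the metagene and of the anchor gene's
   expression, and their association is measured by the 3×3 Pearson
   chi-squared statistic. Because cohort-wide inter-gene correlation inflates
   χ² far beyond its nominal df = 4 distribution, significance comes from a
   size-matched resampling null: random sets of the same size *k* pushed
   through the identical metagene → tertile → χ² path (500,000 iterations per
   pathway size at full scale). Empirical exceedance p-values are adjusted by
   Benjamini–Hochberg and pathways are called at FDR 0.2.

A seeded synthetic-data module generates both inputs with known ground truth
(planted SL/RSL gene classes; planted anchor-coupled pathways via a Gaussian
copula on expression ranks), so every stage of the pipeline is testable end
to end without any external download.

## The statistic in brief

For a pathway with member submatrix *X* (k genes × n samples, rows
z-scored), the metagene is the first right-singular vector *v₁* of
*X = UΣVᵀ*, sign-fixed to correlate non-negatively with the mean member
expression. With tertile labels *T(v₁)* and *T(anchor)*,

χ² = Σᵢⱼ (Oᵢⱼ − Eᵢⱼ)² / Eᵢⱼ  over the 3×3 table, Eᵢⱼ from the margins,

and the empirical p-value is (1 + #{χ²ₙᵤₗₗ > χ²ₒᵦₛ}) / (1 + N) over N
resampled random sets of the same k (anchor excluded from the sampling
universe). No asymptotic χ² p-value is used anywhere.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data. Step 3 builds a 20,502-gene × 415-tumour cohort with 20 planted
synthetic-lethal pathways (k = 50, copula coupling ρ = 0.6) among 200 null
pathways; step 4 scans it:

```text
$ python analysis/03_simulate_cohort.py --seed 1
cohort: 20502 genes x 415 tumours (seed 1)
pathways: 20 planted among 220 total
anchor 10%-rank expression is 36.0% of the cohort median (the planted low-expression inflexion)

$ python analysis/04_sl_scan.py --seed 1
scan over 220 pathways, 5000 resampling iterations
significant at FDR 0.2: 20 pathways (20/20 planted recovered, 0 false)
```

The anchor line reports the calibrated low-expression tail: the sample at
ascending rank 0.10·n expresses the anchor at ~36% of the cohort median —
the inflexion that motivates rank-based thresholds for anchor deficiency.
The scan line shows that all 20 planted pathways (and nothing else) fall
below the FDR-0.2 threshold. Step 5 confirms calibration: with nothing
planted, empirical p-values are uniform (pooled KS distance ≈ 0.03) and the
FDR step rarely calls anything.

Steps 1–2 run the screen side: a simulated 18,120-gene screen with planted
protein-class effects yields, per class, its density peaks, KS statistic and
direction call — e.g. a bimodal GPCR class with peaks at 0.83/1.39 and a
phosphatase class called RSL with median ratio 1.36.

The same functionality is exposed as a CLI:

```bash
synlet scan --matrix expr.tsv --sets pathways.gmt --anchor CDH1 \
    --iters 500000 --seed 42 --fdr 0.2 --out scan_out/
synlet screen --table screen.tsv --classes class_lists/ --out screen_out/
synlet simulate screen --seed 1 --out sim_out/
```

Every run writes a JSON manifest (seed, parameters, versions, per-stage
filter counts) and stamps each output TSV with the manifest hash.

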