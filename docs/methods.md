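# Methods

## The scan model

The scan asks whether a pathway's coordinated expression is associated with
an anchor gene's expression across a tumour cohort — the transcriptomic
footprint expected of a synthetic-lethal partner (tumours with low anchor
expression should avoid also losing the pathway). Three choices define it:

* **Metagene = first right-singular vector.** Rows (genes) are z-scored
  first, so every gene contributes on the same scale; the first right
  singular vector of the k × n member submatrix is then the single
  per-sample summary that captures the largest shared variance component.
  "Right" (sample-space) is the only reading that yields one value per
  sample, which tertile binning requires. The reported
  `explained_variance` is σ₁²/Σσᵢ². The singular vector's sign is
  arbitrary; we fix it by non-negative correlation with the mean member
  expression so that reports and heatmaps are oriented ("metagene up =
  pathway up"). The χ² statistic is exactly sign-invariant, so this
  convention never affects inference. (No convention based on the input
  matrix can also be invariant to negating the whole matrix; we prefer the
  biologically interpretable orientation.)
* **Tertiles + 3×3 Pearson χ², df = 4.** Samples are sorted ascending
  (stable sort, ties broken by input order — a measure-zero event for
  continuous expression but the contract must be deterministic); the first
  ⌊n/3⌋ are "low", the last ⌊n/3⌋ "high", the remainder "mid". Expected
  counts come from the margins; no continuity correction.
* **Size-matched resampling null.** Tumour transcriptomes carry pervasive
  inter-gene correlation (proliferation and stromal programmes, modules
  co-expressed with the anchor itself). A random k-gene set therefore does
  *not* behave like k independent vectors: its metagene can pick up
  anchor-linked structure, inflating χ² far beyond the df = 4 asymptotic
  law (the test suite demonstrates a >2× inflation of the 95th percentile
  with 50% anchor-coupled genes). The null is therefore built by pushing
  random same-size gene sets through the identical pipeline. Pathways that
  share k share one null by default — distributionally identical to
  per-pathway resampling (verified by two-sample KS in the tests) and much
  cheaper; per-pathway nulls remain available (`share_nulls=False`).
  Sampling is without replacement from the full post-filter universe with
  the anchor excluded; the anchor is also removed from any pathway that
  contains it before the SVD, so the association can never be driven by
  the anchor's own row.

Empirical p-values use the add-one rule p = (1 + #{null > obs})/(1 + N):
it is a valid conservative p-value, never returns 0, and keeps the BH
step-up well behaved; the literal counting rule (`correction="raw"`) is
available. Exceedance is strict — ties do not count against the observed
statistic. BH adjustment is the standard step-up with monotonicity
enforcement (statsmodels); significance means adjusted p below the FDR
threshold, default 0.2. Full-scale runs use N = 500,000 iterations per
pathway size; desk-scale analyses and tests use N = 5,000, which resolves
p-values to 2 × 10⁻⁴ — ample for an FDR-0.2 decision over a few hundred
pathways.

## Expression preparation

Counts are filtered (CPM ≥ 1 in ≥ 1 sample by default, boundary inclusive)
and transformed to log₂(CPM + 0.5). TMM scale factors (doubly trimmed
weighted mean of M-values, 30%/5% trims) are available behind a flag,
default off: the scan operates on within-gene z-scores, which are invariant
to per-gene monotone affine transforms, so exact normalisation parity does
not change the statistic. Standardisation uses the population sd
(denominator n) — the choice is a per-gene scalar and cannot change the
SVD direction, but it is fixed for reproducibility. Anchor tertiles are
taken from log-expression. The anchor rank profile reports linear-scale
expression at ascending rank ⌈q·n⌉ divided by the linear-scale median,
because "x% of median expression" is a linear-scale statement.

## Screen analytics

Ratios are always recomputed as KO/WT from the two viability columns and
never trusted from input. The orientation follows every results-level
convention for this assay (RSL threshold ratio ≥ 1.3 refers to KO/WT).
Classification is a complete partition: RSL iff ratio ≥ 1.3 (boundary
inclusive), SL iff ratio < 1, else neutral. Densities use a Gaussian
kernel on a 512-point grid spanning [min − 3h, max + 3h] with the
rule-of-thumb bandwidth h = 0.9·min(sd, IQR/1.34)·n^(−1/5) — the default
of the statistical environment such screens are conventionally analysed
in, so peak locations are comparable. Peaks are interior local maxima at
≥ 25% of the global maximum (configurable); the threshold separates
genuine bimodality from KDE ripple. The KS test is two-sided with the
asymptotic p-value (intended sample sizes ≥ 20); the reference includes
the class's own members, mirroring set-versus-all-genes comparisons, and
reported p-values are floored at 2.2 × 10⁻¹⁶. Classes with fewer than two
matched genes are flagged, not tested.

## What the generators emulate

**Screen.** Per-gene log viability ratios: background ~ N(0, 0.25²)
(ratio peak at 1.0), planted classes from Gaussian mixtures on the log
scale so SL and RSL shifts are symmetric; WT viability log-normal around
1, KO = WT · exp(log-ratio) · noise. The default 18,120-gene configuration
plants the four class signatures the analysis targets (RSL phosphatases
~1.34, mildly SL kinases ~0.95, RSL ion channels ~1.14, bimodal GPCRs
~0.82/1.37).

**Cohort.** 415 samples × 20,502 genes by default. The anchor is
two-component on the log₂ scale: 90% Gaussian around the cohort median
level (sd 0.5) and a 10% low tail built as a downward half-normal whose
top sits at 36% of the cohort median on the linear scale (after a small
analytic correction for the median shift the tail itself induces). This
produces the sharp low-expression inflexion at the 10% rank that motivates
rank-based anchor-deficiency thresholds. Planted pathway factors couple to
the anchor through a Gaussian copula on ranks, f = ρ·g + √(1−ρ²)·ε with g
the anchor's normal scores: the weakest assumption that still plants a
tertile-level association, since the statistic only sees ranks. An
alternative `low_low_depletion` mode plants the SL signature directly
(anchor-low samples avoid the factor's bottom tertile with probability
|ρ|). Member genes load on their factor with loadings ~ N(0.5, 0.25)
against unit noise; background genes belong to independent co-expression
modules (size 25 by default) plus an optional cohort-wide global factor.

Two generator choices deserve emphasis because the scan's behaviour depends
on them:

* **Modular background.** With an unstructured (iid) background, a random
  resampled set has no coherent competition and its leading component is
  free to lock onto whatever weak anchor-linked structure it contains;
  with a single dominant global factor, every resampled set returns the
  same direction and the null collapses to a near-point mass. Real
  transcriptomes are in between — many independent modules — and that is
  what makes the resampling null exchange correctly with true null
  pathways. The default background therefore carries fine-grained
  independent modules.
* **Loading strength 0.5 (≈ 20% factor variance per gene).** This is the
  coherence of typical tumour co-expression modules, and it is also the
  regime in which the method itself is well posed: a full k = 50 pathway
  has leading eigenvalue ≈ 1 + (k−1)·0.2 ≈ 11, far above the
  Marchenko–Pastur noise edge (≈ 1.8 for 50 × 415), so its metagene
  recovers the factor; the 2–5-gene fragments of any one module that land
  in a random resampled set stay below that edge and cannot dominate a
  random draw. With much stronger per-gene loadings, the planted pathways
  jointly form a genome-scale anchor-correlated block that random draws
  sample too — the resampling null then (correctly, by its own logic)
  absorbs the signal as "cohort-wide correlation", and no method of this
  family can separate planted from resampled sets. The generator defaults
  deliberately sit in the realistic, well-posed regime.

What the generators do **not** emulate: overlapping pathway membership
(each simulated gene belongs to one set), count-level noise and library
size variation entering the scan (the cohort is generated at the
log-expression stage), tumour purity/stromal gradients correlated with the
anchor, and batch structure. Passing tests therefore certify the
statistical machinery on data satisfying the stated generative model, not
performance on any real cohort.

## Problem sizes used in tests and the acceptance script

Oracle checks use 1,000 random instances each (3×3 tables, sample pairs,
p-vectors). Null calibration uses 200 null pathways per cohort at n_iter =
5,000 over 10–15 seeds with p-values pooled across seeds (pooling measures
the same distribution with smaller Monte-Carlo error than a single-seed
KS). Parameter recovery uses 20 planted (ρ = 0.6, k = 50) among 200 null
pathways over 8–10 replicates at n_iter = 5,000. Metagene fidelity uses
k = 50, n = 415 at loading 1/noise 1 (per-gene SNR 1), where the factor
correlation is ≈ 0.99. These sizes keep a full run to a few minutes on one
CPU while leaving wide statistical margins.

## Known limitations

* The asymptotic KS p-value is inaccurate below ~20 samples per side;
  exact small-sample p-values are out of scope.
* The resampling null conditions on the observed cohort; it does not
  model uncertainty in the cohort itself.
* Degenerate tertiles (massive ties) are resolved deterministically by
  input order and flagged, but the χ² is then hard to interpret; the scan
  assumes continuous expression.
* Flat-cluster cut heights in the heatmap layout default to 0.7× the
  maximum merge height — a display convention, not an inferential claim.
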