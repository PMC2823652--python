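# Methods

This note records the statistical procedures implemented in
`stromasig`, the defaults and why they were chosen, the numerical
conventions, and what the synthetic-data generators do and do not
emulate.

## Preprocessing

Input values are log2 ratios of sample over common-reference
fluorescence. The fixed stage order is: spot quality control →
presence filter → variation filter → standardization to unstimulated
samples → clone collapse. Filters only remove rows or mask
measurements; values are changed only by standardization (mean
subtraction) and clone collapse (averaging).

* A spot is kept when its regression correlation is **strictly**
  greater than 0.6 AND at least one channel's mean intensity is
  strictly greater than 1.5× its median background ("bigger than" is
  implemented as `>`, not `≥`); manually flagged spots are removed.
  The presence filter is evaluated after manual spot removal.
* Presence: a gene is kept when its non-missing fraction is ≥ 0.60 —
  the comparison is on the fraction itself, not on a rounded count.
* Variation: kept when |value − row mean| ≥ log2(1.5) in at least two
  samples. The 1.5-fold deviation is interpreted on the log2 scale
  because fold-change semantics on ratio data imply the log
  interpretation. The row mean uses non-missing values only.
* Standardization subtracts, per gene and per cell type, the mean over
  that cell type's unstimulated samples, so unstimulated group means
  become exactly zero; a gene with no unstimulated value in a group is
  missing for the whole group.
* Clone collapse averages non-missing values per gene symbol (or
  Unigene id); a cell is missing only when every constituent is.

## Paired SAM

The paired two-class design reduces to per-gene pair differences
z₁…z_m. The statistic is d = z̄/(s + s₀) with
s = √(Σ(zⱼ−z̄)²/(m(m−1))). Genes with fewer than two complete pairs
are excluded with a logged count; a gene's statistic uses only its
complete pairs.

* **s₀** is chosen from the percentiles 0, 5, …, 100 of the gene
  scatters s, minimising the coefficient of variation of the
  normal-scaled MAD of d across (up to ten) quantile bins of s; ties
  resolve to the smallest candidate. If every scatter is zero the
  floor 1e-8 is used with a warning.
* **Null distribution**: sign flips of the pair differences. All 2^m
  flip vectors are enumerated when 2^m ≤ 4096 (making results
  deterministic and seed-independent); above that, flips are sampled
  uniformly and a seed is mandatory and recorded.
* **Calling**: with observed order statistics d₍ᵢ₎ and
  permutation-expected d̄₍ᵢ₎, the walk starts at the sign crossing of
  d; the first index above it with d₍ᵢ₎ − d̄₍ᵢ₎ ≥ Δ sets the upper cut
  (all genes with d at or above it are up-called), symmetrically below
  for down-calls. This construction makes negating the data swap the
  up and down call sets exactly.
* **FDR**: π₀ × median over permutations of the number of null
  statistics beyond the cut points, divided by the number called, and
  clamped to [0, 1]. The median (not the mean) is used because
  permutations that leave most of a strong signal intact (few flips)
  would otherwise dominate the numerator. The flip side, visible in
  the tests, is granularity: once more than half the permutations have
  zero exceedances the estimate is exactly 0, so under a pure null a
  few observed-tail genes can be called even at a 0.05% target. The
  call fraction stays small (≤ ~2% measured over seeds).
* **π₀** = min(1, #{d within the pooled-null interquartile range} /
  (n/2)). Under strong contamination (a large fraction of truly
  changed genes) the flipped alternatives widen the pooled quartiles
  and π₀ is biased upward — conservative for the FDR. The tests
  characterise this: a 50% planted mixture yields π₀ ≈ 0.6.
* **Δ** is the smallest value on a 101-point linear grid over
  [0, max|d₍ᵢ₎ − d̄₍ᵢ₎|] whose estimated FDR is at or below the
  target (default 0.0005, i.e. 0.05%).

## Clustering and the two-group cut

Distance is 1 − r with r the centred Pearson correlation over
pairwise-complete positions (centred is the default; uncentred is
configurable). Pairs sharing fewer than 3 positions receive the
maximum observed distance plus ε, with a warning. Agglomeration is
UPGMA; ties in the minimum merge distance (tolerance 1e-12) are broken
toward the pair containing the lexicographically smallest leaf labels,
which makes the tree invariant to input row/column order. Patient
stratification by clustering takes the two children of the sample
tree's root. The published analysis selected signature cluster nodes
"based on the correlation within the cluster nodes" without a stated
threshold; the root split is the reproducible formalisation used here
and should be read as a stand-in for that manual step.

## Signatures, projection, scoring

The fold-change signature takes genes whose **mean** log2 ratio over
stimulated samples (on the standardized matrix) strictly exceeds
log2(1.5); requiring the induction in every replicate instead of the
mean is a stricter alternative the source text leaves open — the mean
rule is implemented. The SAM signature is the up- (or down-) call set,
collapsed to unique symbols, with Δ, FDR, s₀ and seed recorded as
provenance.

Projection matches by upper-cased gene symbol with Unigene id as a
fallback; unmatched genes are listed in the report, never silently
dropped. Multiple probes per gene are averaged, rows are kept at
strictly more than 80% presence, then mean-centred across the cohort.
The continuous score is the per-patient mean over non-missing
signature rows; scores strictly above the median are "high", ties at
the median go to "low" (deterministic and documented). Clustering
groups are named high/low by their mean signature expression, ties
broken toward the larger group with a warning.

## Survival

Endpoint policies map raw event logs to (time, event): overall = death
from any cause; disease-specific = death from disease, with
other-cause deaths treated as event-free through follow-up (the source
wording "considered alive and not censored" is self-contradictory; the
implementation records event 0 at the last follow-up time and does not
assert this was the original intent); distant-metastasis = first
distant metastasis, with local/axillary/contralateral/second-primary
events censoring at their time and an ipsilateral supra-clavicular
recurrence counting as the metastatic event.

Kaplan–Meier estimation and the two-group log-rank test are delegated
to lifelines; Cox partial-likelihood maximisation to statsmodels PHReg
with **Breslow** tie handling (the era's default; configurable).
P-values for Cox coefficients are Wald; 95% CIs are exp(β ± 1.96 se).
Non-convergence or monotone likelihood raises an error — Firth-type
penalisation is out of scope.

## Enrichment

For a query of n annotated genes in an annotated background of N, a
term annotating K background genes and k query genes scores
P = Σᵢ₌ₖ C(K,i)C(N−K,n−i)/C(N,n), evaluated through the scipy
hypergeometric survival function (stable for extreme tails). Genes
without any annotation are excluded from both n and N — this is why a
370-gene list can appear as 325 and a 208-gene list as 186 in the
published tables. Bonferroni uses T = number of terms annotating at
least one query gene, recorded per row. The resampling FDR draws
n-gene queries uniformly from the annotated background (default 50
draws), counts random-run terms at or below each observed corrected-P
threshold, and reports expected false positives / observed count,
clamped to [0, 1] and made monotone down the sorted table (step-up
convention). Term maps are assumed pre-propagated; no ontology-graph
handling.

## Synthetic data

The generators are pure functions of (config, seed) and exist to give
the pipeline inputs with the statistical structure the analysis
assumes, plus ground truth.

* **Stimulation experiment** — defaults: 5000 genes, 6
  stimulated/unstimulated pairs (three donors each contributing a
  normal and a tumour-derived fibroblast culture, matching the paired
  design the method targets; 2⁶ = 64 sign flips also give the
  permutation FDR enough resolution for a 0.05% target, which 2³ = 8
  would not), 4% induced genes (200), fold induction drawn
  Normal(2.35, 0.45) on the fold scale and converted to log2,
  measurement noise 0.15 log2 (typical replicate noise of two-colour
  arrays for well-measured spots), 2% missing cells, 5% of spots drawn
  to fail QC. Induced genes shift only in stimulated samples; gene
  baselines are shared within pairs and cancel in the differences.
* **Cohort** — defaults: 295 patients (the early-breast-cancer cohort
  scale), 2000 genes, a 50-gene signature with per-gene loadings
  Normal(1.0, 0.3) on a latent per-patient activity (sd 1, optionally
  bimodal for planted two-cluster tests), residual noise 0.5 log2.
  Survival is exponential with hazard 0.08/yr ×
  exp(0.9 × standardized activity) — log-HR 0.9 per sd (HR ≈ 2.5,
  the scale of the published cohort contrasts) — with independent
  exponential censoring (0.05/yr) capped at 15 years of follow-up; an
  optional binary ER-like covariate can be linked to activity.
* **Annotations** — 30 random terms of 10–120 genes over the supplied
  background plus one planted term whose query overlap is inflated by
  a configurable enrichment factor (factor 1 reproduces the null).

What the generators do **not** emulate: dye bias and intensity-dependent
(loess-type) effects, spatial/print-tip artifacts, correlated gene
modules beyond the single signature factor, cohort batch effects,
non-proportional hazards, and informative censoring. Passing the
recovery tests therefore shows the estimators are correct and
well-calibrated under the stated model, not that the pipeline is robust
to every artifact of real arrays.

## Problem sizes in the test and acceptance runs

The suites run the stimulation recovery at the full default scale
(5000 × 12, 10 seeds), Cox recovery at n = 2000 over 20 seeds, null
calibration of the log-rank p over 200 small cohorts (80 patients,
12-gene signature), end-to-end signature recovery over 3 seeds, and
stratification agreement over 10 cohorts of 80 patients — sizes chosen
so each property is measured with comfortable margins while the whole
suite stays fast on a single CPU.

## Known limitations

* The two-group clustering cut is the root split; published heat-map
  analyses chose cluster nodes manually.
* The resampling FDR and the median-based SAM FDR are both granular at
  small permutation/resample counts; targets far below 1/(number of
  permutations) are met only where the exceedance median reaches zero.
* Cross-platform gene matching is by symbol/Unigene string equality
  after upper-casing; no alias resolution.
* Unpaired or multi-class SAM, quantile normalisation, competing-risks
  and time-dependent survival models are out of scope.
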