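# Methods

This note documents the statistical procedures implemented in `armsl`, the
assumptions behind them, the synthetic data they are validated on, and the
design choices made where the procedures were genuinely open.

## Arm-deletion classification

Copy number enters as per-gene log2 ratios (0 = copy-neutral). The per-line
arm burden score is

    S = 10 · (1/N) · Σ_g min(x_g, 0)

over the arm's annotated genes g with non-missing values. Gains never offset
losses (the `min(·, 0)`), so the score is a pure deletion burden that mixes
depth ("copy-number value") and breadth ("deletion size"): a whole-arm
one-copy loss (x ≈ −1) scores −10, a half-arm loss at the same depth −5. The
default call threshold is −2.5 with a strict less-than rule ("below" the
threshold), so a score exactly at the threshold is nonDEL. Arm-level calls of
this kind are not standardised across studies; the scoring function is
therefore pluggable (`arm_deletion_score(..., score_fn=...)`) and the score
definition is stamped into the output. SCNA frequency summaries count
samples above +0.1 / below −0.1 on the same log2 scale; the loss cutoff is
−0.1 (a symmetric threshold), with the literal sign convention available via
configuration.

## Differential dependency

CERES scores are per-gene, per-line fitness effects from CRISPR knockout
screens (more negative = stronger fitness defect). Genes are tested only if
expressed — mean log2(TPM+1) strictly greater than 1 in the DEL **or** the
nonDEL group — because unexpressed genes cannot be actionable dependencies.
For each tested gene:

* effect size: dCERES = mean(DEL) − mean(nonDEL), over non-missing values;
* significance: two-sided Wilcoxon rank-sum. Exact enumeration of the
  rank-sum null is used when min(n₁, n₂) ≤ 8 and the data are tie-free
  (enumeration is cheap there); otherwise the normal approximation with tie
  correction and continuity correction. Genes identical across both groups
  get p = 1.

### Covariate-weighted FDR

Strongly essential genes have compressed CERES variance and little room for
a differential effect, so the per-gene mean nonDEL CERES score is an
informative, null-independent covariate. The adjustment learns per-bin
hypothesis weights in the independent-hypothesis-weighting framework:

1. the covariate is cut into `n_bins` (default 5) quantile bins;
2. hypotheses are split into `n_folds` (default 5) random folds; for each
   fold, per-bin weights are learned **on the other folds** by a greedy
   coordinate search over the multiplier grid {¼, ½, 1, 2, 4}, maximising
   the number of weighted-BH discoveries at the FDR level (default 0.1)
   subject to the budget Σ_b w_b·m_b = m; ties prefer the weight closest to
   1, so a signal-free training set stays at plain BH;
3. out-of-fold weights are applied and adjusted p-values are the BH step-up
   values of p_i / w_i, clipped to [0, 1].

Cross-fitting keeps the applied weight of each hypothesis independent of its
own p-value, which is what preserves FDR control; a complete-null simulation
(m = 1000) keeps the fraction of runs with any rejection at ≈ the nominal
0.1. With one bin — or fewer hypotheses than bins — the procedure reduces
exactly (bitwise) to Benjamini–Hochberg. Learned weights are always returned
for audit. Bin/fold counts and the grid are configuration, not claims about
any particular published run.

Hits are prefilter-passing genes with adjusted p < 0.25 **and**
dCERES < −0.075, both strict; a strict tier at adjusted p < 0.1 is flagged
separately. By default the 0.25 cut is applied to the α = 0.1-adjusted
values; a second weighting run at α = 0.25 is available via
`ihw_rerun_at_hit_level`. Arm enrichment of the hit set is the upper-tail
hypergeometric probability P(X ≥ k) with fold (k/n)/(K/N) on the prefiltered
universe.

### Lineage-corrected single-gene dependency

For one gene, lineage is regressed out of the CERES scores by least squares
on lineage indicators (equivalently within-lineage centering; with a single
lineage the scores are grand-mean-centred, with a warning). "Dependent"
lines are the lowest decile of residuals; partner expression and copy number
are compared between dependent and non-dependent lines by group means and a
rank-sum p.

## Balanced-correlation (BaCoN) pair ranking

Buffering predicts a **positive** correlation between the partner's
expression and the buffered gene's CERES score (low partner expression ↔
more negative score), so competition is computed on signed correlations and
pairs are sorted by signed score, descending.

Candidate filters (all strict except the line count): expression-side genes
need SD > 1 across lines and log2(TPM+1) > 3 in ≥ 100 lines; fitness-side
genes need mean log2(TPM+1) > 2 and |mean CERES| > 0.3 or CERES SD > 0.2.
On cohorts smaller than 100 lines a desk-scale flag rescales the count rule
to 20% of lines; it is never rescaled implicitly. Pairwise-complete Pearson
correlations require ≥ 3 complete observations and non-degenerate variance;
failing pairs are missing and invisible to competition (denominators shrink
accordingly).

For each pair (e, f) with correlation r, the competition fraction is

    w = (#{r(e, f') > r} + #{r(e', f) > r}) / ((n_fit − 1) + (n_expr − 1))

with strict "greater than" (ties are not competitors — deterministic and
permutation-safe) and `score = r · (1 − w)`. The multiplicative form
preserves sign, keeps |score| ≤ |r|, and leaves the global maximum of the
matrix untouched (w = 0); a subtractive variant (r − w) ships behind a
switch, and the variant is logged in output metadata. Monotone dominance —
raising one correlation cannot raise its competition counts or lower its
score — holds on the positive half of the scale, which is where buffering
ranking happens (for negative r, shrinking w moves the product toward 0 from
below).

Ranking drops pairs whose fitness-side gene is pan-essential (mean CERES
< −0.75 across all lines; such genes are lethal everywhere and carry no
selective signal) and, in the pipeline, keeps pairs whose fitness-side gene
is in the differential-dependency hit set. Because the unrestricted global
maximum always retains its full correlation, the discriminating power of the
weighting appears **within this restricted ranking**: a confounded hit's
best pairs face many stronger competitors elsewhere in their rows/columns
and are down-weighted, while a specific buffering pair keeps w ≈ 0.

## Proteomics differential abundance

Stage order is fixed and logged: valid-value filter → quantile
normalization → downshifted imputation → moderated test. "Quantified" means
non-missing and non-zero; a protein is kept if quantified in ≥ 70%
(inclusive) of at least one condition's samples. Quantile normalization maps
each column's observed values, by average rank, onto the across-column mean
quantile profile (for complete columns this is exactly rank → mean of sorted
columns; ties averaged; missing entries stay missing). Missing intensities
are modelled as censoring at the detection limit: each missing entry in
sample s is drawn from Normal(μ_s − 1.8σ_s, (0.3σ_s)²) with μ_s, σ_s the
sample's observed moments — the Perseus convention, seeded and reproducible.

The moderated test shrinks per-protein variances s² (d residual df) toward a
prior (d₀, s₀²) fitted by moment matching on log s² (digamma/trigamma
inversion; an infinite estimated d₀ is capped at 10⁷ with a warning):
s̃² = (d₀s₀² + d·s²)/(d₀ + d), t = log2FC / (s̃·√(1/n₁+1/n₂)) on d₀ + d df,
two-sided p, BH adjustment. With d₀ = 0 this is exactly the pooled
two-sample t. The implementation reproduces the reference R implementation
of moderated statistics to ~1e-14 on a frozen fixture. Calls: up if
log2FC ≥ 0.6 and adjusted p < 0.05; down if ≤ −0.6; otherwise ns.

## Synthetic cohorts and what they do (and do not) show

The generator plants known structure at the package's standard study
conditions: 600 lines × 2000 genes, 10 lineages, an arm of 100 genes deleted
in 20% of lines at depth −0.7 (log2 of a one-copy loss near diploidy, SD
0.1), arm-gene expression shifted down by 0.7 in deleted lines, expression
noise 0.5 (1.1 for designated high-variance genes), lineage expression
spread 0.4, CERES noise 0.15. Planted signals: 12 deletion-specific
dependencies at Δ = 0.4 (4 on the arm, matching the observation that a
third of real hits map to the deleted arm); one buffering pair with a
threshold effect γ = 0.5 applied where the partner's expression is below its
cohort median (a loss-of-function reading of paralog buffering; a linear
dosage coupling is available via `linear_buffering`); and lineage-confounded
decoys.

Confounding is a single lineage-indexed factor carried, with gene-specific
positive loadings, by 200 expression-program genes (loadings U(0.7, 1.5))
and 450 fitness-program genes (U(0.5, 2.0) at fitness strength 0.4·κ,
κ = 1). Decoy expression genes load at 1.4 (top of the range → strong
spurious correlations that out-correlate the planted pair in most seeds)
while decoy fitness genes load at 0.7–0.85, in the lower quartile of the
program range, so roughly 80% of program pairs out-correlate any decoy pair
and the competition fraction rises to ≈ 0.45–0.5. These proportions were
fixed once, at design time, to realise the intended regime — raw correlation
ranks a decoy above the planted pair while the balanced score does not — and
an early smaller program (≈ 20 co-confounded fitness genes) was found
insufficient: with the weight denominator spanning the full candidate sets,
a confounded gene must compete with a large share of the matrix for the
weighting to bind, which is exactly the tissue-of-origin regime in real
screens. Expression is truncated at 0 after noise to stay in the
log2(TPM+1) domain.

One seed drives everything, with per-component substreams (line assignment,
gene parameters, each matrix, the confounding factor) derived
deterministically so that adding genes never perturbs line assignments.
Truth (deleted lines, pairs, dependencies) serialises to JSON alongside the
matrices.

What passing these simulations shows: the pipeline's inference machinery —
classification, rank tests, weighted FDR, competition weighting — recovers
exactly the structure it targets under realistic noise, lineage structure,
and adversarial confounding. What it does not show: robustness to
segmentation artefacts, copy-number-correlated screening bias, non-normal
expression marginals, or the paralog annotation structure of real genomes;
the generator makes no attempt to match DepMap's empirical marginal
distributions.

The proteome simulator plants 20 of 200 proteins at |log2FC| = 1 (balanced
up/down) with σ = 0.3 at n = 3 vs 3 and optional intensity-dependent
(left-censored) missingness. At these conditions the two-sided
information-theoretic power limit of a 5%-FDR procedure is ≈ 0.90 recall, so
recovery is evaluated at the 10% false-discovery operating point, where the
moderated test reaches ≈ 0.93 recall at ≈ 0.08 observed FDP.

## Numerical choices and degenerate inputs

* Boundary comparisons are strict wherever a rule says "greater"/"below";
  inclusive only for the proteomics 70% valid-value rule and the ≥-100-lines
  count rule.
* Correlations are clipped to [−1, 1]; zero-variance vectors are detected
  with a relative 1e-12 tolerance.
* Rank-sum p-values with fully tied data return 1 rather than NaN.
* Classification accepts ±∞ thresholds (strict rule applies); only NaN is
  rejected.
* Trigamma inversion uses Newton iterations from the standard asymptotic
  start; d₀ estimates without excess log-variance spread are capped at 10⁷.
* All tables ride on pandas; matrices align by gene symbol with Entrez IDs
  carried alongside (collisions are errors, not merges), and cell-line IDs
  match exactly after whitespace trimming — no fuzzy matching.

## Problem sizes

Default test and acceptance runs use 600 × 2000 cohorts (10–20 replicates),
80 × 400 cohorts for unit tests, 500 complete-null runs at m = 1000 for FDR
calibration, and 50 proteome replicates — sizes chosen so the full
validation suite completes in well under a minute per component while
keeping Monte-Carlo error far below the decision margins.

## Known limitations

* The arm score is one defensible reading of "adjusted for copy-number value
  and deletion size"; reproducing any particular published DEL/nonDEL split
  on real data may require a different pluggable score.
* The weighting variant behind "balanced correlation" (multiplicative vs
  subtractive) is an interpretation; both ship, neither is claimed original.
* The weight learner's small multiplier grid trades power for stability; it
  will not find extreme weightings.
* `lineage_corrected_dependency` uses indicator regression only — no
  continuous covariates.
* Proteomics assumes exactly two conditions and a single batch.
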