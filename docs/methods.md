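# Methods

This note documents the models, defaults and design choices behind
`screpurpose`, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic study design

The generator (`screpurpose.simulate`) is a first-class, tested component:
it defines the study conditions under which every downstream stage is
validated. Counts are negative-binomial with per-gene dispersion drawn
uniformly from 0.1–0.5 — the overdispersion regime the moderated-t stage
assumes — without explicit zero inflation: at the simulated depths the NB
zero mass already yields realistic per-gene detection rates, and dropout
modeling would not change what the tests measure.

Default conditions (`SimConfig`): 300 genes; 4 cell types × 120 cells
(half case, half control); 15 marker genes per type (disjoint blocks,
+2 log₂ units in their type); 25 DE genes per type (disjoint from markers
and across types; case cells shifted ±1 log₂ unit, half up, half down);
library-size factors log-normal (σ = 0.2). Doublets (6% of singlets) sum
the counts of two same-condition parents of distinct types and are
multinomially downsampled to the median singlet depth, so both parents'
marker signal survives at singlet scale — the property the re-annotation
stage must exploit. A doublet fraction ≥ 0.5 is rejected as a degenerate
mixture. One sample per condition is simulated; batch effects are out of
scope.

The drug library holds 50 drugs, each covering a random 80% of genes. The
planted reverser carries the sign-flip of the pooled disease signature
(magnitude 1) plus N(0, 0.15²) noise on covered disease genes; the planted
mimic copies the signature; decoys are N(0,1). Context labels ("CNS" /
"non-CNS") support the tissue-restriction filter; the planted drugs are
always CNS so that the filtered screen can find them.

Patient cohorts are pseudobulk NB profiles (low dispersion, shape 20),
balanced case/control (20 per class; fewer than 3 is rejected since the
bootstrap could not resample both classes). Case patients shift the union
of planted DE genes by the same ±1 log₂ units.

The ortholog study simulates 2,000 strictly 1:1 pairs; 15% of species-A
genes are significant (p ~ U(0, 1e-4), |log₂FC| = 0.8 + Exp(0.5)); a
fraction `conserved_fraction` (default 0.7) of them are significant in
species B with the log₂FC copied plus N(0, 0.2²) noise, the rest of B's
significant set drawn independently. At `conserved_fraction = 0` the two
significant sets are fully independent, which is what makes the
hypergeometric null-uniformity check meaningful.

The spatial grid is 15×15 spots in 4 contiguous vertical bands; in one
band every gene of the overlay set gains `effect × (1 + 0.5·N(0,1))`
log-units — a shared per-spot factor that makes the enrichment coherent, so
the leading principal component (not just the mean) carries it. Spatial
autocorrelation beyond region blocks is not simulated.

These defaults were chosen once as a realistic desk-scale emulation of a
case/control brain snRNA-seq study; passing tests show the algorithms
recover structure *of this kind* — they do not certify performance on real
tissue, where marker overlap, ambient RNA, batch structure and non-discrete
cell states all erode the planted separations.

## Moderated differential expression

For groups of sizes n_A, n_B on log₂-normalized values (counts scaled to
10⁴ per cell, then log₂(x+1)): log₂FC = mean_A − mean_B; pooled residual
variance s² with d = n_A + n_B − 2 degrees of freedom. The prior (d₀, s₀²)
is moment-matched on z = log s² using
Var(z) = ψ′(d/2) + ψ′(d₀/2) and
E(z) = log s₀² + [ψ(d/2) − log(d/2)] − [ψ(d₀/2) − log(d₀/2)],
with the trigamma equation inverted by Newton iteration. When the empirical
Var(z) does not exceed ψ′(d/2) the estimator diverges and d₀ is capped at
10⁶ (the shared-variance limit). The posterior variance is
s̃² = (d₀s₀² + ds²)/(d₀ + d) and t = log₂FC / (s̃·√(1/n_A + 1/n_B)) with
d₀ + d degrees of freedom. This closed-form moment approach (rather than a
profile-likelihood fit) was chosen for its testable limits: d₀ = 0 recovers
the ordinary two-sample t exactly, d₀ → ∞ the pure-prior form, and the test
suite verifies full numerical agreement with the Bioconductor `limma`
eBayes implementation on a fixture. Zero-variance genes are reported with
t = 0, p = 1 and a flag. Cells are treated as replicates within a cell
type, matching the analyses this pipeline reproduces; a per-sample
pseudobulk workflow is possible by passing patient-level matrices, but
pooled cells are the default.

Thresholds are strict inequalities (a gene at |log₂FC| = 0.58 exactly is
excluded); the signed-set provenance records whether raw p or FDR was
thresholded, because stratified DE uses p < 0.05 while the convergence
intersection uses FDR < 0.05 — the intersection checks this provenance
rather than silently coercing.

## Drug scoring

The reversal-ratio denominator is the number of DEGs *measured* in the
drug's signature: with partial gene coverage an all-DEG denominator would
conflate coverage with inactivity; coverage is reported so the alternative
is recomputable. Per-type significance is an exact upper-tail binomial test
against ½ — distribution-free and oracle-checkable; a seeded permutation
alternative (shuffling the drug's gene assignment) is provided for
sensitivity analysis. The combining formula
`Σ proportion × ratio × min(−log₁₀FDR, 4)` over cell types passing the
FDR < 0.1 gate is monotone in all three ingredients and exactly zero
without any significant cell type; the −log₁₀FDR factor is capped at 4 so a
single extreme FDR cannot dominate. Absolute score values are
implementation-defined; only ordering and gating semantics are contractual.
Candidate selection keeps gated drugs at or above the 0.9 quantile of
nonzero scores (degenerate all-equal ties return every gated drug).

## Transfer scoring

The published transfer approach uses a deep classifier; this package
substitutes a 5-fold bootstrap-aggregated L2-regularized logistic scorer
with the same preprocessing (per sample: log₂(x+1), z-score across
features, min-max to [0,1]; constant samples map to 0.5; each cell is
preprocessed as its own sample) and the same output contract (per-cell
score in [0,1], mean of the bootstrap fits' logistic outputs). No
weight-level equivalence with the neural model is claimed — the bootstrap
count, preprocessing and output semantics are the specified surface. The
feature panel is a required input; the synthetic default is the union of
planted DE genes. Median-split ties go to the "low" stratum ("above the
median" read literally). Query similarity is the cosine between the ±1
signed DEG indicator and the drug's response values on shared genes
(≥ 5 required); reverse mode ranks ascending, mimic descending, so
`reverse(sig)` and `mimic(flip(sig))` are provably identical rankings.

A calibration subtlety: when cells are stratified by a score computed from
their own expression, genes inside the scoring feature panel are selected
on — even under a perfect null their strata contrast is inflated by
construction, which is a property of median-split-on-own-data designs, not
an implementation artifact. The null-calibration test therefore measures
the type-I error of strata DE on genes *outside* the feature panel, where
the nominal level is exact. Interpretations of strata-DE results on feature
genes in real analyses deserve the same caution.

## Cross-species conservation

The background is the set of 1:1 ortholog pairs present in both DE tables
("tested in both" as the detection criterion). The overlap test is run per
direction — successes = species A's Up (resp. Down) significant set, draws
= species B's same-direction set, upper-tail hypergeometric — because the
directional sets are the scientifically compared objects and the
per-direction draw is exactly hypergeometric under independence (a pooled
signed-overlap draw against all of A's significant genes would be
conservative once random signs halve the expected match). The Up-direction
p is reported as primary. Percent shares and fold conversions round
half-up at the configured precision.

## Spatial eigengene

The overlay gene set defaults to the upregulated portion of a drug's
library signature at or above the 0.9 magnitude quantile. Genes are
z-scored across spots before the SVD (constant genes dropped with a
warning), making the eigengene invariant to per-gene affine rescaling; the
leading component's sign is anchored so the eigengene correlates
non-negatively with the per-spot mean of the standardized set, fixing the
otherwise arbitrary polarity. Region enrichment permutes region labels
(default 1,000 permutations, add-one p estimator, BH across regions,
Monte Carlo SE reported); regions with fewer than 10 spots are flagged
low-confidence rather than dropped; a single-region grid has no contrast
and reports p = 1.

## Numerical and procedural choices

- QC filters cells before genes (both orders are defensible; the choice is
  logged per run). The operation is idempotent.
- Marker scores are computed on log-normalized values: the score's
  additive-shift invariance — the property that makes it a relative
  enrichment — only holds on the log scale.
- Doublet re-annotation breaks score ties lexicographically by type label
  and canonicalizes pair labels lexicographically, so outputs are
  deterministic.
- BH-FDR is the standard step-up (verified against
  `statsmodels.stats.multitest` on 1,000 random vectors); AUROC uses
  midrank ties, U/(n₁n₂), and the tie-corrected normal approximation for
  the Mann–Whitney p.
- All generators and permutation tests draw from `numpy` Generators seeded
  from a single configuration seed; identical seeds give byte-identical
  outputs, and output tables are deterministically sorted.
- Calibration tests compare against the *achievable* level of discrete
  tests (the exact binomial tail cannot reject at precisely 5%), using a
  99.5% binomial interval around it.

## Problem sizes

Benchmarks run at desk scale by design: 300–500 genes, a few hundred cells
per dataset, 50 drugs, 2,000 ortholog pairs, 225 spots, 20 replicates for
rate estimates (10 in the acceptance script), 200–1,000 permutations. These
sizes give the rate estimates enough precision for the stated tolerances
while keeping the full suite fast; all stages scale to realistic inputs
through the same APIs.

## Known limitations

- The moderated-t stage assumes roughly symmetric, unimodal log-expression
  within groups; heavy zero inflation at very low depth would distort its
  calibration (the generator operates above that regime).
- The log-odds B statistic, covariate adjustment and precision-weight
  (voom-style) variants are not implemented; the moderated-t stage stands
  in for those workflows.
- The drug-score combining formula is one monotone choice among several
  defensible ones; scores are comparable within a run, not across tools.
- The linear transfer scorer matches the published preprocessing and
  output contract, not the published architecture; per-compound similarity
  values from external query services are not reproducible here.
- Ambient RNA, batch integration, clustering and embedding are outside the
  package's scope and must come from upstream tools.
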