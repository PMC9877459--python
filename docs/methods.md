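# Methods

## Scope and data model

`fflscope` operates on log2-scale feature × sample matrices
(`ExpressionDataset`) with per-sample annotations (subtype, optional batch,
survival time in months with an event flag, optional mutation flag).
Matched mRNA and miRNA matrices must share ordered sample ids. Gene sets
travel as GMT; interaction and prediction priors as typed tab-separated
edge lists (PPI with confidence in [0,1]; TF→target with a normalized
enrichment score, NES; miRNA→target with a supporting-tool count).
Duplicate feature rows are collapsed to the highest-mean row (the common
probe-collapse convention), features with > 20% missing values are
dropped, and remaining missing values are excluded pairwise in rank
statistics.

## Differential expression

Each contrast is a two-group comparison with empirical-Bayes variance
moderation. Writing s²_g for the pooled sample variance with d_g residual
degrees of freedom, the prior (d₀, s₀²) is estimated by moment matching on
z_g = log s²_g: with e_g = z_g − ψ(d_g/2) + log(d_g/2),

    ψ′(d₀/2) = var(e) − ψ′(d_g/2),
    s₀² = exp( mean(e) + ψ(d₀/2) − log(d₀/2) ),

the trigamma inverse solved by Newton iteration. The moderated statistic
divides the mean difference by s̃_g·√(1/n_a + 1/n_b) with
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) on d₀ + d_g df; d₀ → 0 recovers the
pooled t-test and d₀ → ∞ a common-variance test. Only two-group contrasts
are supported — the pipeline needs nothing else — so no design-matrix REML
is attempted. p-values are BH-adjusted per contrast.

DEG calling is strict on the adjusted p (< cut) and inclusive on the fold
change (|log2FC| ≥ cut); defaults 0.05/1.0 for mRNA and 0.1/0.58 for
miRNA. Exclusivity subtracts the union of all comparator DEG lists from
the target list, direction-agnostically (a gene DE anywhere else, in any
direction, is disqualified); the comparator merge plan unions the
well-differentiated carcinomas (PTC, FTC, OTC → WDTC) and the adenomas
(FTA, OTA → TA) at the DEG-set level, not the sample level. An optional
second-cohort DEG list is subtracted afterwards. Batch handling is an
optional per-batch median centering flag; full empirical-Bayes batch
correction is out of scope.

## Hub ranking and modules

The PPI subgraph keeps edges with confidence strictly > 0.4 restricted to
the exclusive DEGs. MCC is computed by exact maximal-clique enumeration
(Bron–Kerbosch with pivoting via networkx); an isolated node scores
0! = 1. Ties are broken by degree, then lexicographic id, so rankings are
deterministic. MCODE stage 1 weights each node by k·density(k-core of its
closed neighborhood) where k is that neighborhood's highest core number;
stage 2 seeds at the highest unassigned weight and expands breadth-first
over neighbors with weight > (1 − vwp)·seed weight (vwp = 0.2), never
revisiting assigned nodes; the haircut is applied iteratively until no
member has fewer than two in-module edges (the published description says
"remove singly-connected nodes" without stating iteration; iterating keeps
module scores stable). Modules below 3 nodes are dropped; score =
density × size with density 2E/(n(n−1)). Fluff is off and not implemented.
Exact clique enumeration is exponential in the worst case but the input
graphs here are DEG-sized (≲ a few hundred nodes).

## Regulatory network and feed-forward loops

Prediction filters are applied exactly as stated: NES strictly > 5.0 for
TF→gene candidates; tool count ≥ 2 *and* membership in the down-regulated
miRNA list for miRNA→gene candidates; both restricted to hub-gene targets.
Validation computes Spearman ρ per pair on tumor samples (a flag includes
normals): miRNA→gene edges are retained when ρ < 0 with p < α, TF→miRNA
edges when ρ > 0 with p < α, and TF→gene edges at p < α with either sign,
the sign carried into the network (repressor vs activator). α defaults to
0.05; a config option widens retention to 0.1 with the significance tier
(0.1 / 0.05 / 0.01 / 0.001) recorded per edge, because heat-map-style
reporting often annotates the looser tier. TF→miRNA candidates are the
(TF, miRNA) pairs that co-target at least one gene in the validated TF and
miRNA layers — the TF-for-miRNA prediction step restricted to network
members. Every complete triple is emitted and classified coherent iff
s_tg = s_tm·s_mg; the planted repressor pattern (−1, +1, −1) is coherent.
Filters and validation commute, so their order is immaterial (tested).

## Signature and immune scoring

ssGSEA, for one sample: rank all features by expression (descending,
average ranks for ties, so the highest-expressed feature carries rank N);
walk the ranked list accumulating the weighted in-set cumulative (weights
rank^α, α = 0.25, normalized to 1) minus the unweighted out-of-set
cumulative; the enrichment score is the sum of that running difference
(not its maximum). TF/hub/miRNA signature scores are range-normalized
across the sample batch (score / (max − min)); stromal and immune scores
are left unnormalized — the ESTIMATE convention — and combined as
ESTIMATE = stromal + immune with purity = cos(0.6049872018 +
0.0001467884·ESTIMATE). The cosine constants come from the original
ESTIMATE publication and were calibrated on a specific array platform, so
purity outputs are indicative rather than calibrated here. Set members
missing from the matrix are dropped with a warning and scoring proceeds on
the remainder (a 9-of-13 signature is a legitimate score); scoring aborts
only when no member remains. Samples are split high/low at the strict
mean; Wilcoxon rank-sum contrasts and Spearman correlations quantify
associations, annotated at the 0.1/0.05/0.01/0.001 tiers.

## Survival

The univariate route scans every midpoint between consecutive distinct
score values whose split leaves ≥ 10% of samples on each side and returns
the cutoff maximizing the two-group log-rank statistic (ties broken toward
the more balanced split, then the lower cutoff). The reported p is the
plain log-rank p at that cutoff; the maximally-selected-statistic
correction is *not* applied, so these p-values are anti-conservative — a
deliberate, documented caveat. Multivariate adjustment fits a proportional-
hazards model (partial-likelihood Newton iteration with Efron tie
handling, via lifelines) of the signature score plus stromal score, immune
score and tumor purity. Zero-variance covariates are rejected; suspected
separation is flagged when any per-SD coefficient |β·sd(x)| exceeds 15 —
the per-SD scale matters because purity spans only ~0.05 units, making
large per-unit coefficients legitimate.

## Synthetic cohort

The generator emulates an integrated multi-subtype thyroid cohort of 362
samples (ATC 24, MTC 54, PTC 142, FTC 22, OTC 8, FTA 27, OTA 16, normal
69) with 2000 genes and 300 miRNAs, Gaussian on the log2 scale: baseline
per feature N(7, 1), residual noise sd 0.7. Planted structure:

- 80 up- and 20 down-regulated MTC-exclusive genes, effects uniform in
  [1.2, 2.5] log2 units — above the |log2FC| ≥ 1 threshold so calling is
  exercised on both sides of the boundary by sampling noise;
- 40 genes DE in MTC *and* one comparator (testing the subtraction) and 60
  genes DE in each other tumor subtype only;
- a 15-gene hub block (a subset of the up-genes, effects [1.8, 2.5])
  sharing a latent factor with loading 1.0 → pairwise correlations ≈ 0.67;
- one repressor TF (one of the down-genes, shift 1.8) loading −0.8 on the
  hub factor and +0.8 on a miRNA latent factor;
- 13 regulator miRNAs, down-shifted by [1.5, 2.2] in MTC (comfortably past
  the 0.58 miRNA threshold so the DE-intersection filter is reliable),
  loading −0.7 on the hub factor and +0.7 on the miRNA factor — giving the
  planted negative miRNA–target, negative TF–hub and positive TF–miRNA
  correlation signs;
- stromal/immune/28-TIL/14-checkpoint gene programs on an infiltration
  factor correlated −0.6 with the hub factor;
- exponential survival with log-hazard −0.7·z_hub + 0.7·z_miR (z scores of
  the hub factor and of the regulator-miRNA systematic component), baseline
  hazard 0.02/month, independent uniform censoring on (0, 120] months
  (≈ 35% censoring).

Latent-factor construction guarantees a positive-semidefinite dependence
structure by design. Exported fixtures mirror the external inputs the real
study consumed: a PPI list wiring the hub block near-completely (pair
probability 0.95, confidences [0.6, 0.95]) over sparse background edges
straddling the 0.4 threshold; TF priors with NES ∈ [5.5, 9] for true pairs
and [2, 5] for decoys; miRNA priors with 2–6 supporting tools for true
pairs and 1 for decoys — so the stated filters separate true from decoy
exactly, and recovery failures isolate the correlation-validation step.

What the generator does **not** emulate: array physics and probe effects,
batch structure, count-based (RNA-seq) noise, realistic gene-set overlap
or pathway topology, competing risks, or non-proportional hazards. Passing
recovery tests therefore demonstrate the pipeline's logic and statistics
under the planted monotone dependence structure, not performance on real
microarray data.

## Numerical choices

Average ranks everywhere ties arise (correlation, rank-sum, ROC, ssGSEA
ordering uses a stable index tie-break). Spearman p uses the t
approximation uniformly, with |ρ| = 1 reported at the smallest positive
double; exact permutation p-values are not implemented. The exact rank-sum
enumeration is used up to 20 pooled tie-free observations, otherwise the
normal approximation with tie and continuity corrections. BH output order
matches input order. Cox convergence follows lifelines defaults
(coefficient change < 1e−7); non-convergence raises rather than returning
silently. Problem sizes in the test and acceptance suites (20 cohort draws
for loop recovery, 50 draws of n = 500 for coefficient recovery, oracle
suites of 40–200 random instances) were chosen to make sampling
variability negligible relative to the asserted margins. The
immune-direction and survival-direction checks score the cohort with the
planted signature sets: set *recovery* is what the DEG- and loop-recovery
suites measure, so conditioning the direction checks on recovered sets
would conflate the two questions.

## Known limitations

Two-group DE only; no direction-aware exclusivity mode switch at the CLI
(the library function accepts it); the optimal-cutpoint p lacks the
selection correction; ESTIMATE purity constants are platform-calibrated
elsewhere; MCODE fluff is unimplemented; prediction priors are inputs —
no motif scanning or target prediction is performed.
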