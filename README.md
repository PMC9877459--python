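# fflscope

Inference of subtype-exclusive tumor biomarkers and TF–mRNA–miRNA
feed-forward loops from matched expression cohorts.

## The problem

Medullary thyroid carcinoma (MTC) arises from neuroendocrine C cells and is
molecularly distinct from the follicular-cell-derived thyroid tumors it is
usually grouped with. Finding what is aberrant *only* in MTC — and how those
genes are wired into transcription-factor and miRNA circuitry — takes a
multi-stage analysis: differential expression against normal tissue in
every subtype, Venn-style exclusivity set algebra, protein-interaction hub
ranking, prediction-filtered and correlation-validated regulatory network
assembly, immune-environment scoring, and survival stratification.
`fflscope` implements that entire arc as a tested, reusable Python library,
with a synthetic-cohort generator (planted ground truth included) standing
in for the public microarray cohorts, so every stage is verifiable end to
end without downloads.

It is aimed at computational biologists who want either the individual
building blocks (moderated-t DE, MCC, MCODE, ssGSEA, ESTIMATE-style
scoring, optimal-cutpoint log-rank, Cox adjustment) or the assembled
pipeline.

## Methods at a glance

- **Moderated differential expression.** Per gene, a two-sample contrast on
  log2 data with empirical-Bayes variance moderation: the posterior
  variance is s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with (d₀, s₀²)
  moment-matched on the log sample variances across genes; t uses
  d₀ + d_g df. DEGs: adjusted p < 0.05 (BH) and |log2FC| ≥ 1 for mRNA;
  adjusted p < 0.1 and |log2FC| ≥ 0.58 for miRNA. Exclusive DEGs are the
  target subtype's calls minus every comparator's calls (direction-
  agnostic), with well-differentiated carcinomas and adenomas merged.
- **Hub ranking.** PPI edges with confidence > 0.4; MCC(v) = Σ_{C∋v}
  (|C|−1)! over maximal cliques by exact enumeration; MCODE modules via
  core-clustering vertex weights, seeded expansion and haircut, scored
  density × size.
- **Regulatory network.** TF→gene pairs pass NES > 5.0; miRNA→gene pairs
  need ≥ 2 prediction tools and a down-regulated miRNA. Surviving pairs are
  Spearman-validated on tumor samples (miRNA→gene ρ < 0, TF→miRNA ρ > 0,
  TF→gene either sign, recorded). A loop (TF, g, m) is **coherent** iff
  sign(TF→g) = sign(TF→m) · sign(m→g).
- **Immune scoring.** ssGSEA per sample (rank-weighted running sum,
  exponent 0.25); ESTIMATE = stromal + immune score, purity =
  cos(0.6049872018 + 0.0001467884·ESTIMATE); mean-split high/low groups,
  Wilcoxon contrasts, 28 infiltrating-cell sets, 14 checkpoint genes.
- **Survival.** Optimal-cutpoint log-rank per signature; multivariate Cox
  (Efron ties) adjusting for stromal score, immune score and purity.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (seed 1) and write tables under `results/run/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_exclusive_degs.py
...
python analysis/06_survival_analysis.py
```

Selected output:

```
MTC vs normal: 98 up, 42 down
after subtracting 398 comparator DEGs: 81 exclusive up, 20 exclusive down
...
validated edges: {'mirna_mrna': 20, 'tf_mirna': 13, 'tf_mrna': 9}
20 feed-forward loops, 20 coherent
...
hub score is protective (HR 0.28), miRNA score adverse (HR 4.97)
```

Reading this: of 140 genes called DE in MTC, 101 survive subtraction of
every other subtype's DEG list (the generator planted 100). The validated
network contains one repressor TF, nine of its hub-gene targets and 13
miRNAs; all 20 complete loops are coherent — the TF represses its targets
both directly and by promoting the repressing miRNAs. High hub-gene-score
samples are immune-cold (immune-score contrast p ≈ 8e-15, ρ ≈ −0.48, higher
purity) and live longer (univariate HR 0.28; multivariate HR 0.07 after
immune adjustment), while a high miRNA score is adverse — matching the
planted biology.

The same stages are exposed as a CLI over one run directory:

```bash
fflscope simulate --seed 1 --out runs/demo
fflscope degs     --seed 1 --out runs/demo
fflscope network  --seed 1 --out runs/demo   # then ffl, score, survive, report
```

Repeated runs with the same seed are byte-identical.

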