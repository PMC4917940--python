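# multide

Differential-expression (DE) analysis of RNA-seq read counts across **D ≥ 2
treatment conditions** with a single-degree-of-freedom test per gene.

## The problem and the model

Classical multi-group DE tests (negative-binomial ANOVA / GLM likelihood
ratio) spend D − 1 degrees of freedom per gene, and their power drops as the
number of conditions grows.  `multide` instead models the normalized count
Y<sub>idg</sub> (sample *i*, condition *d*, gene *g*) as negative binomial
with dispersion φ<sub>g</sub> and a two-factor log-linear mean whose
interaction is **rank-1**:

```
log mu_dg = mu + alpha_d + beta_g + u_d * v_g
```

with the identifiability constraints Σ<sub>d</sub> n<sub>d</sub>α<sub>d</sub> = 0,
Σ<sub>g</sub>β<sub>g</sub> = 0, Σ<sub>d</sub> n<sub>d</sub>u<sub>d</sub> = 0,
u<sub>1</sub> = 1, Σ<sub>g</sub>v<sub>g</sub> = 0.  The per-condition factor
u<sub>d</sub> is shared by all genes; the per-gene score v<sub>g</sub>
carries each gene's association with condition, so "gene g is differentially
expressed" becomes the 1-df hypothesis **H<sub>g</sub>: v<sub>g</sub> = 0**,
tested by a Wald statistic T<sub>g</sub> = v̂<sub>g</sub>²/var(v̂<sub>g</sub>)
against χ²₁.  Matched designs (every subject measured in every condition)
are supported through an estimated between-condition correlation
ρ<sub>d₁d₂</sub> of the latent expressions, which enters the variance of
v̂<sub>g</sub> and captures the efficiency gain of pairing.

The package provides:

- four between-lane size-factor methods (median, total-count, upper-quartile,
  TMM) and normalization Y = [X/δ];
- a pluggable per-gene NB dispersion estimator (method-of-moments with
  empirical-Bayes-style shrinkage, or user-supplied values from a file);
- moment estimation of the main effects and constrained alternating weighted
  least squares for (u, v), with an optional second pass restricted to a
  DE gene set;
- Wald tests with Benjamini–Hochberg or Bonferroni adjustment;
- a fully seeded simulator for matched/unmatched multi-condition counts
  (rank-1, saturated-interaction, and spike-in designs) with ground truth,
  plus ROC/AUC and top-N empirical-FDR scoring.

## Worked example

Simulate a matched three-condition study (10 000 genes, 4 subjects, 10 % DE
genes), run the end-to-end test, and score it against the truth:

```
$ multide simulate --design matched -D 3 -G 10000 --seed 7 --out sim
wrote sim.counts.tsv, sim.meta.tsv, sim.truth.tsv

$ multide test --counts sim.counts.tsv --meta sim.meta.tsv --method median --out results.tsv
u = [1.0, 0.0705, -1.0705]
586 genes significant at adjusted alpha 0.05 (bh); wrote results.tsv

$ multide evaluate --results results.tsv --truth sim.truth.tsv --out eval
AUC = 0.8428; wrote eval.roc.tsv and eval.fdr.tsv
```

The fitted condition factors û = (1, 0.07, −1.07) recover the generative
(1, 0.2, −1.2) up to sampling noise: conditions 1 and 2 behave similarly
while condition 3 moves opposite, and each gene's direction and magnitude
along that axis is its v̂<sub>g</sub> (reported with its standard error,
Wald statistic and BH-adjusted p-value in `results.tsv`).  586 genes are
called at BH-adjusted 0.05 — 504 of them among the 1 000 truly DE genes —
and the p-value ranking separates DE from EE genes with AUC 0.84.

The same stages are available as library calls (`multide.run_de`,
`multide.simulate_rank1`, ...) returning numpy/pandas objects.

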