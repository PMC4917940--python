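# Methods

## Model

For sample *i* of condition *d* (of *D*) and gene *g* (of *G*), the raw read
count X<sub>idg</sub> is normalized by a per-sample size factor,
Y<sub>idg</sub> = [X<sub>idg</sub>/δ<sub>id</sub>], where [·] rounds to the
nearest integer.  Y is modeled as negative binomial: a latent gamma
expression Z<sub>idg</sub> with mean μ<sub>dg</sub> and variance
φ<sub>g</sub>μ<sub>dg</sub>², observed through Poisson sampling, so
Var(Y) = μ + φμ².  The mean structure is a two-factor log-linear model whose
gene × condition interaction is constrained to rank 1:

log μ<sub>dg</sub> = μ + α<sub>d</sub> + β<sub>g</sub> + u<sub>d</sub>v<sub>g</sub>

subject to Σ n<sub>d</sub>α<sub>d</sub> = 0, Σ β<sub>g</sub> = 0,
Σ n<sub>d</sub>u<sub>d</sub> = 0 with u₁ = 1, and Σ v<sub>g</sub> = 0.
All logs are natural; per-gene fold changes shown to users are converted to
log2 at the interface only.  In matched designs the latent Z of the same
subject are correlated across conditions with a gene-free coefficient
ρ<sub>d₁d₂</sub>; unmatched samples are independent (ρ = 0).

The model assumes a substantial fraction of genes are truly DE in a
direction pattern shared across genes (otherwise u is weakly identified),
and at least two biological replicates per condition.

## Estimation

1. **Size factors** — one of: sample median over the geometric mean of all
   medians; sample total over the arithmetic mean of totals; 75th percentile
   (linear-interpolation convention) over its mean; or TMM — the
   inverse-variance-weighted mean of gene-wise M-values
   M = log2((X/N)/(X_ref/N_ref)) after discarding zero-count genes and
   trimming the upper and lower 30 % of M-values, exponentiated from log2
   scale and rescaled to geometric mean 1.  The reference is the sample
   whose upper quartile is closest to the mean upper quartile.  Only the
   M-values are trimmed; no trim on absolute expression is applied.  Note
   that this size factor is a pure composition correction relative to the
   reference: a sample with every count doubled and its library size doubled
   gets δ = 1.
2. **Normalization** — Y = [X/δ] with round-half-to-even, fixed so half-way
   ties are reproducible.
3. **Cell means** — μ̂<sub>dg</sub> is the within-condition mean of Y;
   η̂<sub>dg</sub> = log μ̂<sub>dg</sub> (an error is raised if a cell mean
   is zero; filter low-count genes first).
4. **Moment effects** — μ̂ is the n<sub>d</sub>-weighted grand mean of η̂;
   α̂<sub>d</sub> the gene-averaged row deviation; β̂<sub>g</sub> the
   n<sub>d</sub>-weighted column deviation; γ̂ the double-centered residual.
5. **Rank-1 factors** — (û, v̂) minimize Σ n<sub>d</sub>(γ̂<sub>dg</sub> −
   u<sub>d</sub>v<sub>g</sub>)², the weights reflecting Var(γ̂) ∝ 1/n<sub>d</sub>,
   by alternating closed-form updates with û rescaled to û₁ = 1 each cycle.
   Because γ̂ is doubly centered, the constraints on û and v̂ hold
   automatically at every iterate.  Optionally the û-update sums only over a
   previously identified DE gene set (the `two_pass` pipeline option uses
   the first pass's BH-significant genes), suppressing the pure-noise
   contribution of EE genes.
6. **Dispersion** — per gene and condition, the moment estimate
   (s² − ȳ)/ȳ², pooled across conditions with weights n<sub>d</sub> − 1 and
   clamped at 10⁻⁸; then each log φ̂<sub>g</sub> is shrunk toward a common
   value with weight prior_df/(prior_df + Σ(n<sub>d</sub> − 1)).
   Externally computed per-gene dispersions can be supplied instead.
7. **Matched correlation** — per condition pair, the subject-paired sample
   correlation of Y per gene, bias-corrected (Olkin–Pratt-type,
   r(1 + (1 − r²)/(2(n − 3))) for n ≥ 4; disable with `correction="none"`),
   rescaled by √((μ̂₁+μ̂₁²φ̂)(μ̂₂+μ̂₂²φ̂))/(μ̂₁μ̂₂φ̂) to undo the
   count-level attenuation, averaged over genes and clamped to [−1, 1].
   Genes with zero paired variance or with φ̂ at the numerical floor (the
   rescaling divides by φ̂) are excluded, with a logged count.

## Inference

Treating μ̂, α̂ and û as known — they pool information across all genes, so
their variance is negligible next to the per-gene terms — the delta method
gives, for unmatched samples,

var(v̂<sub>g</sub>) = Σ n<sub>d</sub>û<sub>d</sub>²(μ̂<sub>dg</sub>⁻¹+φ̂<sub>g</sub>) / (Σ n<sub>d</sub>û<sub>d</sub>²)²

and for matched samples (n per condition) the analogous expression with the
cross term 2Σ<sub>d₁<d₂</sub> û<sub>d₁</sub>û<sub>d₂</sub>φ̂<sub>g</sub>ρ̂<sub>d₁d₂</sub>
added to the numerator and n(Σ û<sub>d</sub>²)² in the denominator; at
ρ = 0 the two coincide exactly.  The cross term is negative for mixed-sign û
with positive ρ — the matched design's efficiency gain — and a non-positive
variance (possible under extreme ρ̂ noise) is clamped at 10⁻¹² with a
warning rather than raised, since it reflects estimation noise.  This is
deliberately plug-in inference: no bootstrap or higher-order correction.
T<sub>g</sub> = v̂²/var(v̂) is referred to χ²₁; p-values are adjusted by
Benjamini–Hochberg (default) or Bonferroni.

## Numerical and design choices

- **WLS iteration**: v is initialized from the leading right singular vector
  of the √n<sub>d</sub>-row-scaled γ̂ (deterministic; a power-iteration-style
  `init="means"` fallback exists), the u-update runs first, and convergence
  is declared when the objective's relative change drops below 10⁻¹⁰
  (max 500 iterations).  The objective is recorded once per full cycle and
  is non-increasing.  The converged objective agrees with an independent
  weighted rank-1 SVD oracle to 10⁻⁸ in the test suite; with D = 2 the
  constrained γ̂ is exactly rank 1 and the residual vanishes.
- **Anchoring**: û₁ = 1 by convention; if the first condition's factor is
  numerically zero an error suggests re-anchoring via
  `reference`/`--reference-condition`.
- **Dispersion shrinkage target and strength**: the common value is the log
  of the *arithmetic* (optionally trimmed, default untrimmed) mean of the
  raw dispersions, and the pipeline default is prior_df = 100 (weight ≈ 0.9
  at four replicates per condition).  Raw moment estimates at a handful of
  replicates are both noisy and right-skewed; averaging their logs, trimming
  aggressively, or leaving substantial weight on the tagwise values biases
  the plug-in variance low and makes the Wald test visibly anti-conservative
  (empirical type-I error near 0.09 at nominal 0.05 in the packaged null
  simulations), while the strong-shrinkage default keeps EE-gene p-values
  uniform and type-I error near nominal.  `prior_df` remains fully
  adjustable for designs with many replicates.
- **Gene filter**: "maximum count greater than the threshold in every
  condition" with a strict inequality, applied to raw counts before
  normalization (the threshold used in practice is 50).  Both orders
  (filter-then-normalize vs the reverse) are defensible; raw-count filtering
  is the package's fixed choice.
- **Error handling**: data problems raise typed exceptions
  (`multide.errors`); the CLI maps them to exit code 3, usage errors to 2.

## Simulator

`simulate_rank1` draws, in fixed order from one seeded generator:
β<sub>g</sub> ~ N(0, 0.25²); φ<sub>g</sub> ~ Gamma(shape 5, rate 20);
v<sub>g</sub> = 0 for EE genes, −|N(0, s²)| for up-regulated and +|N(0, s²)|
for down-regulated genes; matched pair correlations ρ<sub>d₁d₂</sub> ~
U(0.2, 0.4); δ<sub>id</sub> ~ LogNormal(0, 0.25²); then latent Z from gamma
marginals (mean μ<sub>dg</sub>, variance φμ²) coupled across conditions by a
Gaussian copula with the drawn ρ, and X ~ Poisson(Z·δ).  Defaults are the
reference study conditions: G = 10⁴ with 9 000 EE / 500 up / 500 down,
μ = 4, α = 0, fixed u-vectors per D and design (e.g. (1, 0.2, −1.2) for
matched D = 3), n = 4 matched subjects or n<sub>d</sub> = D + d − 1
unmatched samples.  Three conventions to note:

- the v-scale "0.32" is interpreted as a *variance* (sd ≈ 0.566) by default;
  `v_scale_is_sd=True` switches the reading, since the notation is genuinely
  ambiguous;
- the copula family is Gaussian with correlation applied on the copula
  scale; the induced Pearson correlation of Z is verified in tests to sit
  within 0.05 of the nominal value;
- δ scales the Poisson mean (X ~ Poisson(Zδ)), so dividing by the true δ
  recovers the modeled Y exactly.

`simulate_saturated` breaks the rank-1 assumption: DE genes draw
γ<sub>dg</sub> i.i.d. uniform on (−0.75, 0.75), re-centered per gene
(n<sub>d</sub>-weighted) so Σ n<sub>d</sub>γ<sub>dg</sub> = 0 and the fitted
interaction targets a well-defined quantity.  `spike_in_perturbation` turns
any real count matrix into a benchmark by permuting condition labels and
multiplying a random gene subset's counts by per-condition factors (default
1.0/1.1/0.9).

**What the simulator does not emulate**: lane effects and GC-content bias
(each sample is treated as its own lane), gene length, outlier samples,
unbalanced matched designs, or library-size-dependent technical noise.
Passing tests on simulated data therefore validates the estimators under
the model's own assumptions (and, via the saturated design, under interaction
misspecification), not robustness to those artefacts.

## Scales used in the packaged checks

The acceptance script and test suite run at the generative scale G = 10⁴
with 50 replicates for the u-recovery means, 20 for the grand mean, and 10
for the null-calibration checks; simulator moment checks use 3 × 10⁴ draws
per cell.  A full suite run is a few minutes on one CPU.

## Known limitations

- The rank-1 test is powered for the dominant shared expression axis; genes
  whose true interaction is orthogonal to û can be missed (the saturated
  design quantifies this: ranking quality degrades but remains well above
  chance).
- Type-I error control relies on the dispersion level being well estimated;
  with very few genes (< a few hundred) the pooled estimate is itself noisy.
- The ρ estimator assumes a gene-free correlation; strong gene-specific
  correlation structure violates (and is averaged over by) the model.
- The moment dispersion estimator is a deliberate stand-in for external
  empirical-Bayes estimators; per-gene agreement with those packages is not
  a goal, and users who have such estimates can supply them via
  `--phi-file`/`dispersion=`.
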