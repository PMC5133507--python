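# Methods

## Model and pipeline

The package treats biomarker selection for blood pressure as a two-stage
regression. Stage one removes the linear effects of four clinical
covariates — age (years), sex (0/1), medication status MS (0/1), smoking
status SS (0/1) — from the phenotype by ordinary least squares. An
intercept is always included by default even though the covariate model can
be written without one: without it the residual is not mean-free, and a
mean-free residual is required for the centered, unit-norm genetic columns
to correlate sensibly with it. The fit uses `numpy.linalg.lstsq`
(minimum-norm pseudoinverse), so a rank-deficient design — e.g. a covariate
that is constant in a small cohort — degrades to a warning rather than an
error. The pipeline analyzes the systolic (SBP) residual; the diastolic
model is fitted only for the before/after correlation report.

Stage two solves the underdetermined sparse regression y = Xδ + ε on the
merged design (expression columns first, then SNPs; each column
mean-centered and scaled to unit L2 norm, constant columns zeroed and
flagged) with the SRVS ensemble: Fisher–Yates shuffle, width-k partition,
per-block L_p solve, accumulate, average. Centering before unit-norm
scaling is a deliberate choice: the residual phenotype is mean-free, and
without centering a column's inner product with y would mix its association
with its mean level.

## Block solver

Both norms share the constraint form min ‖δ_l‖_p s.t. ‖y − X_l δ_l‖₂ ≤ ε
with ε = `epsilon_rel` · ‖y‖₂ (default 0.1). A relative tolerance keeps the
solver scale-equivariant: scaling the phenotype by c scales every
coefficient by c.

- **p = 0 (OMP)** is implemented directly: greedily add the column most
  correlated with the running residual, refit least squares on the active
  set, stop when the residual norm reaches ε or `max_sparsity` columns are
  active. All-zero (constant) columns are excluded from selection.
- **p = 1 (LASSO, default)** delegates the homotopy path to scikit-learn's
  `lars_path`, then walks the path from sparse to dense, refitting ordinary
  least squares on each support (removing the L1 shrinkage) and returning
  the first debiased solution meeting the residual constraint; if none does
  within `max_sparsity` path steps, the densest capped solution is
  returned. Debiasing makes the two solvers agree exactly on orthonormal
  designs and makes the reported coefficients interpretable as mmHg per
  unit column.

`max_sparsity` defaults to 10 nonzeros per block. This encodes the model's
own premise — only a small number of variables are truly associated with
the phenotype — and bounds the per-block work; with the default tight ε the
cap is usually what terminates a block solve on noisy data, making each
block solve effectively a "best ≤ 10 columns" fit.

## Stopping rules

Rule (a) compares successive ensemble averages:
‖δ^(l)/l − δ^(l−1)/(l−1)‖₂ / ‖y‖₂ < α, default α = 1e-3. The division by
‖y‖₂ puts the threshold on a normalized-phenotype scale so the default
transfers across units. The distance decays roughly like 1/l, so α
effectively sets the iteration budget; at the default on cohort-scale
problems runs may reach `max_iter` (default 500) first, which is reported
via a warning and the `converged_rule_a` flag rather than hidden.

Rule (b) is a coverage requirement: every pair of columns should have
appeared in a common block, so that every pair has competed directly at
least once. Under a uniform shuffle the probability that a fixed pair lands
in the same width-k block is q = (k−1)/(n−1) (exact when k divides n),
giving L_min = ⌈ln p_stop / ln(1−q)⌉ iterations for per-pair non-coverage ≤
p_stop (default 0.05). The rule is interpreted per-pair; a simultaneous
guarantee over all n(n−1)/2 pairs (union bound, pair count inside the
logarithm) is available via `union_bound_coverage`. A remainder block of
width 1 is merged into its predecessor, since a one-column "sparse" solve
is degenerate; remainder blocks of width ≥ 2 are kept.

The run terminates at the first iteration where rule (a) holds **and** the
iteration count has reached L_min.

## Ranking

Variables are ranked by |averaged coefficient|, ties broken by higher
selection count and then original column index, so rankings are
deterministic and permutation-equivariant. An alternative
frequency-weighted score (|coefficient| × selection fraction) is exposed
for users who prefer stability-weighted ranking; the default is the direct
reading of the ensemble average. Recovery against known truth is scored by
precision@k, recall@k and a rank AUC computed from the Mann–Whitney U
statistic on rank positions.

## Synthetic cohort generator

The generator produces the data structure the pipeline assumes, with known
ground truth:

- **Genotypes**: per SNP a global MAF uniform in `maf_range` (default
  0.05–0.5); per family an allele frequency from the Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F) with divergence F = `fst` (default 0.05);
  genotypes binomial(2, family frequency). One divergence parameter stands
  in for explicit pedigrees — enough to test robustness to within-family
  correlation without modelling transmission. Families are near-equal-sized
  and deterministic given the config.
- **Expression**: standard-normal baseline plus `n_eqtl_links` random
  (SNP, probe) cis effects of `eqtl_effect` expression units per alternate
  allele, so some null probes are genetically correlated with SNP columns
  as in real data.
- **Covariates**: age ~ Normal(47.7, 14.1) truncated positive; sex, MS, SS
  Bernoulli with rates 167/397, 113/397, 66/397 — plausible cohort
  demographics, configurable.
- **Phenotype**: SBP = covariate effects (default (1.7, 25.5, −8.9, 13.4)
  mmHg for age, sex, MS, SS) + sparse genetic effects + Normal(0,
  `noise_sd`²) noise, with `noise_sd` = 10 mmHg by default. Causal effects
  are applied to **standardized** (zero-mean, unit-SD) causal columns with
  magnitudes from `effect_size_range` (default 5–15 mmHg per SD) and random
  signs, so `effect/noise_sd` is a standardized effect size (default
  0.5–1.5) comparable across allele frequencies. DBP shares the genetic
  signal at 0.6 amplitude with its own covariate effects
  ((0.8, 19.7, −14.2, 10.7)) and 0.6× noise.

What the generator does **not** emulate: linkage-disequilibrium blocks and
recombination maps (SNPs are independent given family frequencies),
non-MCAR missingness, probe-level measurement artefacts, or cohorts where
the raw SBP–DBP correlation is low but the residual correlation is high —
here the shared sparse genetic signal dominates both, so both correlations
are high. Passing recovery tests therefore demonstrates correctness of the
machinery under the stated generative model, not performance on real
cohorts with LD and confounding.

## Validation experiment design

- The greedy-vs-exhaustive check uses row-orthonormalized random tight
  frames (8 orthonormal rows of a random 10×10 orthogonal matrix, columns
  rescaled to unit norm) with geometrically separated coefficient
  magnitudes (ratio 4, random signs). Greedy selection provably matches
  exhaustive search only in a low-coherence, separated-coefficient regime;
  these instances sit inside it, so disagreement indicates an
  implementation defect rather than an expected greedy failure.
- The single-block collapse check runs the ensemble with k = n for one
  forced iteration and compares against one direct full-matrix solve; this
  exercises the shuffle/partition/scatter machinery, which must be exactly
  permutation-equivariant.
- The coverage Monte Carlo uses 10⁴ independent shuffle sequences per
  (n, k) grid and checks empirical pair non-coverage after L_min iterations
  against p_stop plus three binomial standard errors.
- Recovery experiments run the full pipeline on 20 cohorts of 300 subjects
  with 2000 SNPs + 200 probes — large enough that n ≫ m and the ensemble
  matters, small enough to run in minutes on one CPU.

## Numerical choices and degenerate inputs

- Constant design columns normalize to all-zero, are flagged, and can never
  be selected; a constant phenotype yields an intercept-only fit with zero
  residual; ‖y‖₂ = 0 short-circuits every block solve to zero and the run
  terminates at the coverage bound.
- Missing genotypes are imputed to the column mean (TSV and VCF); missing
  expression or SBP values are errors — imputation of the phenotype or of
  continuous expression is out of scope.
- TSV readers use round-trip float parsing so write-then-read reproduces
  matrices bit-for-bit; manifests record config, seed and SHA-256 input
  digests, and all randomness flows from explicit seeds (identical configs
  give bit-identical results).
- VCF input (via cyvcf2) keeps biallelic records only, converts GT to
  alt-dosage 0/1/2, and skips multi-allelic records with a warning.

## Known limitations

- Sequential block solves only; the contract is order-independence within
  an iteration, and parallelism is future work.
- p strictly between 0 and 1 is not supported.
- Rule (a)'s 1/l decay means α controls cost as much as convergence; runs
  that hit `max_iter` are valid but flagged, and users wanting guaranteed
  rule-(a) convergence should raise α or `max_iter`.
- The ranking's "contribution" score is the averaged coefficient magnitude;
  no significance or error bars are attached to ranks.
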