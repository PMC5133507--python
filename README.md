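# srvs — ensemble sparse-representation variable selection for multi-omics biomarker discovery

`srvs` implements a biomarker-selection pipeline for blood-pressure
phenotypes that integrates SNP genotypes and gene-expression measurements
from the same subjects into a single design matrix and ranks all variables
by their contribution to the phenotype. It is aimed at statistical
geneticists who want a reproducible, testable implementation of
sparse-representation variable selection (SRVS) together with a synthetic
cohort generator for benchmarking, since real cohorts of this kind are
usually access-restricted.

## The method

Blood pressure is modelled in two stages. First, clinical covariates are
removed by ordinary least squares:

    BP = b0 + b1*Age + b2*Sex + b3*MS + b4*SS + y

where MS and SS are medication and smoking status, and the residual *y*
becomes the phenotype for genetic analysis. Second, *y* is regressed on the
merged genetic matrix **X** ∈ ℝ^{m×n} (expression block then SNP block,
columns mean-centered and scaled to unit L2 norm; n ≫ m), under the
assumption that only a few variables matter:

    y = X δ + ε,   δ sparse.

Because the full problem is massively underdetermined, SRVS solves it as an
ensemble. Per iteration *l*:

1. shuffle the n columns with a Fisher–Yates permutation;
2. cut the permutation into blocks of width k, giving sub-matrices X_l ∈ ℝ^{m×k};
3. solve min ‖δ_l‖_p subject to ‖y − X_l δ_l‖₂ ≤ ε for each block
   (p = 0 via orthogonal matching pursuit, p = 1 via the LASSO/LARS path
   with least-squares debiasing);
4. add each δ_l into a global accumulator δ^(l) at the block's column indices.

The run stops when both rules hold: (a) ‖δ^(l)/l − δ^(l−1)/(l−1)‖₂ falls
below a threshold α, and (b) enough iterations have run that any fixed pair
of columns has shared a block with probability ≥ 1 − p_stop (closed form
L_min = ⌈ln p_stop / ln(1 − (k−1)/(n−1))⌉). The final score of a variable is
|δ^(l)/l|: variables that enter blocks with a consistent coefficient
accumulate weight, while variables that fit noise average toward zero.

## Worked example

```sh
python examples/03_ensemble_selection.py
```

generates a synthetic cohort (150 subjects, 400 SNPs + 100 expression
probes, 10 causal variables) and runs the pipeline:

```
iterations: 102 (coverage rule needed 9; rule-a distance 4.92e-03)
variables with nonzero averaged coefficient: 203 of 500

top 10 variables (true causal ids marked *):
 rank variable_id     source   score  selection_count causal
    1      snp225        SNP 212.737              102      *
    2      expr17 expression 162.872              102      *
    3      expr99 expression 150.676              102      *
    ...
    9      snp373        SNP 115.721              102      *
   10      snp313        SNP  84.850              102
```

Nine of the ten causal variables fill the top nine ranks. `score` is the
magnitude of the averaged coefficient (mmHg of residual SBP per unit
normalized column); `selection_count` says in how many of the 102
iterations the variable received a nonzero block coefficient — a stability
diagnostic. The other examples cover cohort simulation
(`01_simulate_cohort.py`), covariate adjustment and the before/after
SBP–DBP correlations (`02_covariate_adjustment.py`), and recovery scoring
plus top-N composition (`04_ranking_and_recovery.py`).

The same pipeline is available as a thin CLI for file-based runs:

```sh
srvs simulate --seed 1 --out data/
srvs select --genotypes data/genotypes.tsv --expression data/expression.tsv \
            --phenotypes data/phenotypes.tsv --seed 1 --out results/
srvs evaluate --ranking results/ranking.tsv --truth data/truth.tsv --out metrics.tsv
```

`select` accepts genotype TSVs or VCF 4.x (`--genotype-format vcf`,
biallelic GT dosages), writes a ranked TSV, a top-N composition table, the
covariate coefficient table, and a manifest (config, input digests, seed)
sufficient to replay the run byte-for-byte.

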