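"""Run the SRVS ensemble on a merged SNP + expression design matrix.

Each iteration shuffles the columns (Fisher-Yates), cuts them into blocks
of width k, solves a sparsity-constrained regression per block
(min ||d||_p s.t. ||y - X_block d||_2 <= eps), and accumulates the block
coefficients; the average across iterations scores each variable. The run
stops once successive averages settle (rule a) and every column pair has
likely shared a block (rule b).
"""

from srvs.core import SRVSConfig
from srvs.pipeline import run_selection
from srvs.synthetic import SyntheticConfig, generate_dataset

ds = generate_dataset(SyntheticConfig(n_subjects=150, n_snps=400, n_expr=100,
                                      n_families=15, seed=3))
geno, expr, pheno = ds.as_pipeline_inputs()

cfg = SRVSConfig(p=1, epsilon_rel=0.1, alpha=5e-3, p_stop=0.05, seed=3)
run = run_selection(geno, expr, pheno, cfg)
res = run.srvs_result

print(f"iterations: {res.n_iterations} "
      f"(coverage rule needed {res.min_iterations}; rule-a distance {res.rule_a_distance:.2e})")
print(f"variables with nonzero averaged coefficient: {(res.delta_avg != 0).sum()} of {len(res.delta_avg)}")
print("\ntop 10 variables (true causal ids marked *):")
frame = run.ranking.to_frame().head(10)
frame["causal"] = ["*" if v in ds.truth else "" for v in frame["variable_id"]]
print(frame.round(3).to_string(index=False))
# score = |averaged coefficient| (mmHg of residual SBP explained per unit
# L2-normalized column); selection_count = iterations in which the variable
# got a nonzero block coefficient, a stability diagnostic.
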