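"""Validation experiments for the selection pipeline.

Each function runs a self-contained, seeded experiment that checks one
property the method relies on: greedy block solves matching exhaustive
best-subset search, the ensemble collapsing to a single solve when one
block spans all columns, the closed-form coverage bound holding under
Monte-Carlo shuffling, unbiased covariate-coefficient recovery, and causal
variables being recovered from synthetic cohorts. They return measured
quantities; asserting thresholds is left to the caller.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np

from srvs.core import SRVSConfig, coverage_min_iterations, run_srvs, solve_block
from srvs.covariates import fit_lls
from srvs.pipeline import run_selection
from srvs.ranking import recovery_metrics
from srvs.synthetic import SyntheticConfig, generate_dataset

__all__ = [
    "omp_vs_best_subset", "single_block_collapse", "coverage_monte_carlo",
    "covariate_recovery", "variable_recovery",
]


def _tight_frame(m: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random m x k design with orthonormal rows (minimal-coherence columns)."""
    q, _ = np.linalg.qr(rng.standard_normal((k, k)))
    X = q[:, :m].T.copy()
    return X / np.linalg.norm(X, axis=0)


def _best_subset_support(X: np.ndarray, y: np.ndarray, max_s: int) -> set[int]:
    """Exhaustive least-squares search over all supports of size <= max_s."""
    best_resid, best = np.inf, set()
    for s in range(1, max_s + 1):
        for S in combinations(range(X.shape[1]), s):
            beta, *_ = np.linalg.lstsq(X[:, S], y, rcond=None)
            resid = np.linalg.norm(y - X[:, S] @ beta)
            if resid < best_resid - 1e-12:
                best_resid, best = resid, set(S)
        if best_resid < 1e-9:       # noiseless: exact representation found
            break
    return best


def omp_vs_best_subset(n_instances: int = 200, m: int = 8, k: int = 10,
                       max_support: int = 3, seed: int = 0) -> float:
    """Fraction of noiseless instances where OMP finds the best-subset support.

    Instances use row-orthonormalized tight-frame designs with unit-norm
    columns and geometrically separated coefficient magnitudes (ratio 4,
    random signs) — the low-coherence, separated regime where greedy
    selection provably matches exhaustive search.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    cfg = SRVSConfig(p=0, max_sparsity=max_support)
    for _ in range(n_instances):
        X = _tight_frame(m, k, rng)
        s = int(rng.integers(1, max_support + 1))
        support = rng.choice(k, size=s, replace=False)
        beta = np.zeros(k)
        beta[support] = (4.0 ** np.arange(s, 0, -1)) * rng.choice([-1.0, 1.0], size=s)
        y = X @ beta
        coef = solve_block(y, X, cfg, eps=1e-8 * np.linalg.norm(y))
        if set(np.flatnonzero(coef)) == _best_subset_support(X, y, max_support):
            agree += 1
    return agree / n_instances


def single_block_collapse(n_instances: int = 20, m: int = 20, n: int = 40,
                          seed: int = 0) -> float:
    """Max L2 gap between the k=n ensemble average and one direct LASSO solve."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        X = rng.standard_normal((m, n))
        X -= X.mean(axis=0)
        X /= np.linalg.norm(X, axis=0)
        beta = np.zeros(n)
        beta[rng.choice(n, 3, replace=False)] = rng.normal(0, 5, 3)
        y = X @ beta + 0.1 * rng.standard_normal(m)
        cfg = SRVSConfig(k=n, p=1, max_iter=1, seed=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")     # single forced iteration
            result = run_srvs(y, X, cfg)
        direct = solve_block(y, X, cfg)
        worst = max(worst, float(np.linalg.norm(result.delta_avg - direct)))
    return worst


def coverage_monte_carlo(n: int, k: int, p_stop: float = 0.05,
                         n_sequences: int = 10_000, seed: int = 0) -> dict:
    """Empirical pair non-coverage after the closed-form minimum iteration count.

    Runs ``n_sequences`` independent shuffle sequences of ``L_min``
    iterations each and measures how often a fixed column pair never shared
    a width-k block. Requires k | n (blocks of exactly width k).
    """
    if n % k:
        raise ValueError("coverage Monte Carlo assumes k divides n")
    l_min = coverage_min_iterations(n, k, p_stop)
    rng = np.random.default_rng(seed)
    template = np.broadcast_to(np.arange(n), (n_sequences, n))
    covered = np.zeros(n_sequences, dtype=bool)
    for _ in range(l_min):
        perms = rng.permuted(template, axis=1)
        pos0 = np.argmax(perms == 0, axis=1)
        pos1 = np.argmax(perms == 1, axis=1)
        covered |= (pos0 // k) == (pos1 // k)
    rate = float(1.0 - covered.mean())
    se = float(np.sqrt(p_stop * (1 - p_stop) / n_sequences))
    return {"l_min": l_min, "non_coverage_rate": rate, "p_stop": p_stop,
            "binomial_se": se, "n_sequences": n_sequences}


def covariate_recovery(n_replicates: int = 50, n_subjects: int = 397,
                       noise_sd: float = 10.0, seed: int = 0) -> dict:
    """Coefficient bias of the covariate fit over synthetic replicates.

    Each replicate draws a fresh cohort with the default generative
    covariate effects, refits the least-squares model, and records the
    coefficient estimates. Genetic effects are present and act as extra
    (independent) phenotype noise, so estimates stay unbiased.
    """
    estimates = []
    cfg0 = SyntheticConfig()
    for i in range(n_replicates):
        cfg = SyntheticConfig(n_subjects=n_subjects, n_snps=300, n_expr=100,
                              noise_sd=noise_sd, seed=seed * 1000 + i)
        ds = generate_dataset(cfg)
        model = fit_lls(ds.phenotype["SBP"], ds.covariates)
        estimates.append(model.coefficients)
    estimates = np.array(estimates)
    true = np.array(cfg0.covariate_effects)
    bias = estimates.mean(axis=0) - true
    se_mean = estimates.std(axis=0, ddof=1) / np.sqrt(n_replicates)
    return {"names": ("AGE", "SEX", "MS", "SS"), "true": true,
            "mean_bias": bias, "se_mean": se_mean,
            "bias_se_ratio": np.abs(bias) / se_mean}


def variable_recovery(n_seeds: int = 20, seed: int = 0,
                      synthetic_overrides: dict | None = None,
                      srvs_config: SRVSConfig | None = None) -> dict:
    """Causal-variable recovery of the full pipeline over synthetic cohorts.

    Per seed: generate a cohort (n=300 subjects, 2000 SNPs, 200 probes,
    5 + 5 causal variables with standardized effects 0.5–1.5, family
    divergence fst=0.05 by default), run covariate adjustment plus the SRVS
    ensemble, rank, and score precision@10 and the causal-vs-null rank AUC.
    """
    params = dict(n_subjects=300, n_snps=2000, n_expr=200, fst=0.05,
                  n_causal_snps=5, n_causal_expr=5,
                  effect_size_range=(5.0, 15.0), noise_sd=10.0)
    params.update(synthetic_overrides or {})
    precisions, aucs = [], []
    for i in range(n_seeds):
        ds = generate_dataset(SyntheticConfig(seed=seed * 1000 + i, **params))
        geno, expr, pheno = ds.as_pipeline_inputs()
        cfg = srvs_config or SRVSConfig(seed=seed * 1000 + i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")     # max_iter runs are acceptable here
            run = run_selection(geno, expr, pheno, cfg)
        metrics = recovery_metrics(run.ranking, set(ds.truth), [10])
        precisions.append(metrics.precision_at[10])
        aucs.append(metrics.rank_auc)
    return {"precision_at_10": np.array(precisions), "rank_auc": np.array(aucs),
            "mean_precision_at_10": float(np.mean(precisions)),
            "mean_rank_auc": float(np.mean(aucs))}
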