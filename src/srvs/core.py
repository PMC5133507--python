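"""The SRVS ensemble sparse-selection algorithm.

Given a phenotype residual y (length m) and a column-normalized design X
(m x n with n >> m), each iteration shuffles the columns with a
Fisher–Yates permutation, partitions them into blocks of width k, and
solves a sparsity-penalized regression per block:

    min ||d||_p   subject to   ||y - X_block d||_2 <= eps,   p in {0, 1}

with eps expressed as a fraction of ||y||_2. Block coefficients are added
into a length-n accumulator at the block's global column indices; the
running average over iterations is the selection score. Two stopping rules
must both hold: (a) the L2 distance between successive averaged vectors
(relative to ||y||_2) falls below ``alpha``, and (b) enough iterations have
run that any fixed pair of columns has co-occurred in some block with
probability at least 1 - ``p_stop``.

Averaging across random partitions is what distinguishes the ensemble from
a single sparse solve: a column that only ever enters with a small,
sign-varying coefficient is averaged toward zero, while columns genuinely
correlated with y accumulate consistent weight no matter which competitors
they are blocked with.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import lars_path

from srvs.io import OmicsMatrix

__all__ = [
    "SRVSConfig", "SRVSState", "SRVSResult",
    "fisher_yates_permutation", "partition", "solve_block",
    "coverage_min_iterations", "check_convergence", "run_srvs",
]


@dataclass
class SRVSConfig:
    """Algorithm parameters.

    Attributes
    ----------
    k
        Block width (columns per sub-matrix); ``None`` means the subject
        count m, which keeps each block solve well-conditioned yet
        underdetermined enough to need sparsity.
    p
        Norm selector: 0 = orthogonal matching pursuit, 1 = LASSO path
        (default — the convex, reproducible choice).
    epsilon_rel
        Residual tolerance as a fraction of ||y||_2, in (0, 1).
    alpha
        Stopping-rule (a) threshold on the successive-average distance,
        measured relative to ||y||_2.
    p_stop
        Stopping-rule (b) bound on the probability that a fixed column pair
        has never shared a block.
    max_sparsity
        Cap on nonzeros per block solve (the working assumption that only a
        few variables matter); ``None`` means min(m, k).
    max_iter
        Hard iteration cap; reaching it raises a non-convergence warning.
    seed
        Seed for the shuffle sequence; fixes the run bit-for-bit.
    union_bound_coverage
        Interpret rule (b) simultaneously over all pairs (union bound)
        rather than per pair.
    """

    k: int | None = None
    p: int = 1
    epsilon_rel: float = 0.1
    alpha: float = 1e-3
    p_stop: float = 0.05
    max_sparsity: int | None = 10
    max_iter: int = 500
    seed: int = 0
    union_bound_coverage: bool = False

    def validate(self, m: int | None = None, n: int | None = None) -> None:
        if self.p not in (0, 1):
            raise ValueError("p must be 0 (OMP) or 1 (LASSO)")
        if not (0 < self.epsilon_rel < 1):
            raise ValueError("epsilon_rel must be in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 < self.p_stop < 1):
            raise ValueError("p_stop must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.k is not None:
            if self.k < 2:
                raise ValueError("block width k must be >= 2")
            if n is not None and self.k > n:
                raise ValueError(f"block width k={self.k} exceeds variable count n={n}")

    def effective_k(self, m: int, n: int) -> int:
        k = m if self.k is None else self.k
        return min(k, n)

    def effective_sparsity(self, m: int, k: int) -> int:
        s = min(m, k) if self.max_sparsity is None else self.max_sparsity
        return max(1, min(s, m, k))


@dataclass
class SRVSState:
    """Mutable accumulator state across iterations.

    ``delta_accum`` is the running sum of block coefficients scattered to
    global indices; ``prev_avg`` holds the previous iteration's average for
    stopping-rule (a); ``selection_count`` counts, per variable, the
    iterations in which it received a nonzero block coefficient.
    """

    delta_accum: np.ndarray
    iteration: int
    prev_avg: np.ndarray | None
    selection_count: np.ndarray
    y_norm: float
    last_distance: float = math.inf


@dataclass
class SRVSResult:
    """Averaged sparse coefficients and run diagnostics."""

    delta_avg: np.ndarray
    n_iterations: int
    selection_count: np.ndarray
    converged_rule_a: bool
    coverage_satisfied: bool
    min_iterations: int
    rule_a_distance: float


def fisher_yates_permutation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of 0..n-1 by in-place swaps from the end down."""
    if n < 1:
        raise ValueError("n must be >= 1")
    perm = np.arange(n)
    for i in range(n - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        perm[i], perm[j] = perm[j], perm[i]
    return perm


def partition(perm: np.ndarray, k: int) -> list[np.ndarray]:
    """Slice a permutation into consecutive blocks of width k.

    A remainder block of width >= 2 is kept; a single leftover column is
    merged into the preceding block (a 1-column sparse solve is degenerate).
    """
    n = len(perm)
    if k < 2:
        raise ValueError("block width k must be >= 2")
    if k > n:
        raise ValueError(f"block width k={k} exceeds n={n}")
    blocks = [perm[i:i + k] for i in range(0, n, k)]
    if len(blocks) > 1 and len(blocks[-1]) == 1:
        blocks[-2] = np.concatenate([blocks[-2], blocks[-1]])
        blocks.pop()
    return blocks


def _omp(y: np.ndarray, X: np.ndarray, eps: float, max_s: int) -> np.ndarray:
    """Orthogonal matching pursuit with least-squares refits on the active set."""
    k = X.shape[1]
    coef = np.zeros(k)
    col_norms = np.linalg.norm(X, axis=0)
    selectable = col_norms > 0
    residual = y.copy()
    active: list[int] = []
    beta = np.empty(0)
    while len(active) < max_s and np.linalg.norm(residual) > eps:
        corr = np.abs(X.T @ residual)
        corr[~selectable] = -np.inf
        corr[active] = -np.inf
        j = int(np.argmax(corr))
        if not np.isfinite(corr[j]):
            break
        active.append(j)
        beta, *_ = np.linalg.lstsq(X[:, active], y, rcond=None)
        residual = y - X[:, active] @ beta
    if active:
        coef[active] = beta
    return coef


def _lasso_path_solve(y: np.ndarray, X: np.ndarray, eps: float, max_s: int) -> np.ndarray:
    """Sparsest LASSO-path support meeting the residual constraint, LS-debiased.

    Walks the LARS/LASSO homotopy path, refits ordinary least squares on
    each support (removing the L1 shrinkage), and returns the first refit
    whose residual norm is <= eps; if none qualifies within ``max_s`` path
    steps, the densest (sparsity-capped) refit is returned.
    """
    k = X.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LARS emits benign collinearity notices
        _, _, coefs = lars_path(X, y, method="lasso", max_iter=max_s)
    best = np.zeros(k)
    if np.linalg.norm(y) <= eps:
        return best
    for step in range(1, coefs.shape[1]):
        support = np.flatnonzero(coefs[:, step])
        if support.size == 0:
            continue
        beta, *_ = np.linalg.lstsq(X[:, support], y, rcond=None)
        refit = np.zeros(k)
        refit[support] = beta
        best = refit
        if np.linalg.norm(y - X[:, support] @ beta) <= eps:
            return refit
    return best


def solve_block(y: np.ndarray, X_block: np.ndarray, config: SRVSConfig,
                eps: float | None = None) -> np.ndarray:
    """Solve the per-block sparsity-constrained regression.

    Columns of ``X_block`` must be unit-norm or all-zero (zero columns are
    never selected). ``eps`` defaults to ``config.epsilon_rel * ||y||_2``;
    a zero phenotype returns the zero vector.
    """
    y = np.asarray(y, dtype=float)
    X_block = np.asarray(X_block, dtype=float)
    m, k = X_block.shape
    if len(y) != m:
        raise ValueError("y length does not match block row count")
    y_norm = np.linalg.norm(y)
    if eps is None:
        eps = config.epsilon_rel * y_norm
    if y_norm == 0:
        return np.zeros(k)
    max_s = config.effective_sparsity(m, k)
    if config.p == 0:
        return _omp(y, X_block, eps, max_s)
    return _lasso_path_solve(y, X_block, eps, max_s)


def coverage_min_iterations(n: int, k: int, p_stop: float,
                            union_bound: bool = False) -> int:
    """Minimal iterations so a fixed column pair has shared a block w.p. >= 1 - p_stop.

    Under a uniform shuffle the per-iteration probability that two given
    columns land in the same width-k block is q = (k-1)/(n-1); the bound
    (1-q)^L <= p_stop gives L_min = ceil(ln p_stop / ln(1-q)). With
    ``union_bound`` the guarantee is simultaneous over all n(n-1)/2 pairs.
    """
    if not (2 <= k <= n):
        raise ValueError("need 2 <= k <= n")
    if not (0 < p_stop < 1):
        raise ValueError("p_stop must be in (0, 1)")
    if k == n:
        return 1
    q = (k - 1) / (n - 1)
    target = p_stop / (n * (n - 1) / 2) if union_bound else p_stop
    return int(math.ceil(math.log(target) / math.log(1.0 - q)))


def check_convergence(state: SRVSState, alpha: float) -> bool:
    """Stopping rule (a): successive averaged vectors closer than ``alpha``.

    The distance ||d^(l)/l - d^(l-1)/(l-1)||_2 is measured relative to
    ||y||_2 so the threshold transfers across phenotype scales. Returns
    False before iteration 2 (no history to compare).
    """
    if state.iteration < 2 or state.prev_avg is None:
        return False
    avg = state.delta_accum / state.iteration
    scale = state.y_norm if state.y_norm > 0 else 1.0
    state.last_distance = float(np.linalg.norm(avg - state.prev_avg)) / scale
    return state.last_distance < alpha


def run_srvs(y: np.ndarray, X: OmicsMatrix | np.ndarray,
             config: SRVSConfig | None = None) -> SRVSResult:
    """Run the full ensemble: shuffle, partition, block solves, accumulate.

    ``X`` must be column-normalized (an :class:`~srvs.io.OmicsMatrix` with
    its ``normalized`` flag set, or a bare array with unit-norm/zero
    columns). Terminates at the first iteration where rule (a) holds AND
    the coverage iteration count is reached, or at ``max_iter`` with a
    warning. Fully deterministic given the config seed.
    """
    config = config or SRVSConfig()
    if isinstance(X, OmicsMatrix):
        if not X.normalized:
            raise ValueError("X must be normalized (call normalize_columns first)")
        values = X.values
    else:
        values = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    m, n = values.shape
    if len(y) != m:
        raise ValueError(f"y has length {len(y)} but X has {m} rows")
    config.validate(m, n)
    k = config.effective_k(m, n)
    if k < 2:
        raise ValueError("need at least 2 variables")

    y_norm = float(np.linalg.norm(y))
    eps = config.epsilon_rel * y_norm
    l_min = coverage_min_iterations(n, k, config.p_stop, config.union_bound_coverage)
    rng = np.random.default_rng(config.seed)
    state = SRVSState(delta_accum=np.zeros(n), iteration=0, prev_avg=None,
                      selection_count=np.zeros(n, dtype=int), y_norm=y_norm)

    converged = False
    for l in range(1, config.max_iter + 1):
        perm = fisher_yates_permutation(n, rng)
        for block in partition(perm, k):
            delta_l = solve_block(y, values[:, block], config, eps)
            state.delta_accum[block] += delta_l
            state.selection_count[block[delta_l != 0]] += 1
        state.iteration = l
        converged = check_convergence(state, config.alpha)
        if converged and l >= l_min:
            break
        state.prev_avg = state.delta_accum / l
    else:
        l = config.max_iter

    if not (converged and state.iteration >= l_min):
        warnings.warn(
            f"SRVS stopped at max_iter={config.max_iter} before both stopping rules "
            f"were satisfied (rule-a distance {state.last_distance:.3g}, "
            f"coverage needs {l_min} iterations)")
    return SRVSResult(
        delta_avg=state.delta_accum / state.iteration,
        n_iterations=state.iteration,
        selection_count=state.selection_count,
        converged_rule_a=converged,
        coverage_satisfied=state.iteration >= l_min,
        min_iterations=l_min,
        rule_a_distance=state.last_distance if state.iteration >= 2 else math.inf,
    )
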