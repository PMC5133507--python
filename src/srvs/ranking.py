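"""Variable ranking, top-N composition summaries, and recovery scoring.

Variables are ranked by the magnitude of their averaged ensemble
coefficient (ties broken by selection count, then original column order),
the top-N lists are summarized by source type (how many SNPs vs expression
probes), and — on synthetic data with known causal variables — the ranking
is scored by precision/recall at k and by the probability that a causal
variable outranks a non-causal one (rank AUC, the Mann–Whitney statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from srvs.core import SRVSResult

__all__ = ["VariableRanking", "RecoveryMetrics", "rank_variables",
           "top_n_summary", "recovery_metrics"]


@dataclass
class VariableRanking:
    """All variables in descending score order.

    ``order`` maps rank position to original column index; ``scores`` are
    non-increasing along the order.
    """

    variable_ids: list[str]
    scores: np.ndarray
    sources: list[str]
    selection_counts: np.ndarray
    order: np.ndarray
    ties_broken_by: str = "selection_count,column_index"

    def __len__(self) -> int:
        return len(self.variable_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self) + 1),
            "variable_id": self.variable_ids,
            "source": self.sources,
            "score": self.scores,
            "selection_count": self.selection_counts,
        })


@dataclass
class RecoveryMetrics:
    """Precision/recall at requested cutoffs and the causal-vs-null rank AUC."""

    precision_at: dict[int, float]
    recall_at: dict[int, float]
    rank_auc: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"k": k, "precision": self.precision_at[k], "recall": self.recall_at[k]}
                for k in sorted(self.precision_at)]
        frame = pd.DataFrame(rows)
        frame["rank_auc"] = self.rank_auc
        return frame


def rank_variables(result: SRVSResult, metadata: pd.DataFrame,
                   score_mode: str = "coefficient") -> VariableRanking:
    """Descending sort on the contribution score.

    ``score_mode="coefficient"`` (default) scores by |averaged coefficient|;
    ``"frequency_weighted"`` multiplies by the fraction of iterations in
    which the variable was selected, down-weighting unstable picks. Ties are
    broken by higher selection count, then by original column index, so the
    ranking is deterministic.
    """
    n = len(result.delta_avg)
    if len(metadata) != n:
        raise ValueError(f"metadata has {len(metadata)} rows for {n} variables")
    if score_mode == "coefficient":
        scores = np.abs(result.delta_avg)
    elif score_mode == "frequency_weighted":
        freq = result.selection_count / max(result.n_iterations, 1)
        scores = np.abs(result.delta_avg) * freq
    else:
        raise ValueError(f"unknown score_mode {score_mode!r}")
    # lexsort: last key is primary
    order = np.lexsort((np.arange(n), -result.selection_count, -scores))
    return VariableRanking(
        variable_ids=[metadata["variable_id"].iat[i] for i in order],
        scores=scores[order],
        sources=[metadata["source"].iat[i] for i in order],
        selection_counts=result.selection_count[order],
        order=order,
    )


def top_n_summary(ranking: VariableRanking, n_values: list[int]) -> pd.DataFrame:
    """Count SNPs and expression probes among the first N entries, per N."""
    n_total = len(ranking)
    sources = np.asarray(ranking.sources)
    rows = []
    for n in n_values:
        if not (0 < n <= n_total):
            raise ValueError(f"top-N cutoff {n} outside 1..{n_total}")
        head = sources[:n]
        rows.append({"N": n,
                     "n_snps": int((head == "SNP").sum()),
                     "n_expr": int((head == "expression").sum())})
    return pd.DataFrame(rows)


def recovery_metrics(ranking: VariableRanking, truth: set[str],
                     k_values: list[int]) -> RecoveryMetrics:
    """Score the ranking against the known causal variable ids.

    precision@k = |top-k ∩ truth| / k; recall@k = |top-k ∩ truth| / |truth|;
    rank_auc = P(causal variable outranks a random non-causal one), computed
    from the Mann–Whitney U statistic on rank positions.
    """
    if not truth:
        raise ValueError("truth set is empty")
    ids = ranking.variable_ids
    unknown = truth - set(ids)
    if unknown:
        raise ValueError(f"truth ids not present in ranking: {sorted(unknown)[:5]}")
    is_causal = np.array([v in truth for v in ids])
    precision_at, recall_at = {}, {}
    for k in k_values:
        if not (0 < k <= len(ids)):
            raise ValueError(f"cutoff k={k} outside 1..{len(ids)}")
        hits = int(is_causal[:k].sum())
        precision_at[k] = hits / k
        recall_at[k] = hits / len(truth)
    # better rank = smaller position; AUC from U on negated positions
    positions = np.arange(len(ids))
    u = stats.mannwhitneyu(-positions[is_causal], -positions[~is_causal],
                           alternative="two-sided").statistic
    auc = float(u) / (is_causal.sum() * (~is_causal).sum())
    return RecoveryMetrics(precision_at=precision_at, recall_at=recall_at, rank_auc=auc)
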