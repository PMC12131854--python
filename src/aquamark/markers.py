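"""Marker validation statistics: Wilcoxon rank-sum, ROC/AUC, multiplicity
adjustment, and tier classification.

All comparisons are rank-based, so marker calls are invariant under any
strictly monotone transform of the peptide quantities.  The AUC is
computed through the Mann-Whitney identity (probability that a random
case exceeds a random control), which ties it exactly to the rank-sum
statistic used for the p value.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

#: Combined sample size at or below which the exact rank-sum null is used
#: (ties force the normal approximation regardless).
EXACT_SWITCHOVER = 12


@dataclass(frozen=True)
class MarkerResult:
    """Per-peptide validation outcome for one group contrast."""

    peptide: str
    protein: str
    contrast: tuple[str, str]  # (case, control)
    log2fc: float
    p_raw: float
    p_adj: float
    auc: float
    auc_flipped: bool
    tier: str  # "none" | "candidate" | "strong"
    significant: bool
    direction_concordant: bool | None  # None when no profiling direction known


@lru_cache(maxsize=None)
def _exact_rank_sum_counts(n1: int, n: int) -> tuple[np.ndarray, int]:
    """Distribution of the rank sum of ``n1`` items among ranks 1..n.

    Dynamic program over the number of arrangements with each achievable
    rank sum; returns (counts indexed by rank sum, total C(n, n1)).
    """
    max_sum = n1 * n
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            counts[k, rank:] += counts[k - 1, : max_sum + 1 - rank]
    total = int(counts[n1].sum())
    return counts[n1], total


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the rank-sum null when the combined sample size
    is at most 12 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns
    ``(U, p)`` with U the Mann-Whitney statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return n1 * n2 / 2.0, 1.0
    ranks = _st.rankdata(combined)
    rank_sum_x = ranks[:n1].sum()
    u = rank_sum_x - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(combined).size < combined.size
    n = n1 + n2
    if n <= EXACT_SWITCHOVER and not has_ties:
        counts, total = _exact_rank_sum_counts(n1, n)
        w = int(round(rank_sum_x))
        mean_w = n1 * (n + 1) / 2.0
        # two-sided: arrangements at least as far from the mean
        dev = abs(w - mean_w)
        sums = np.arange(counts.size)
        p = counts[np.abs(sums - mean_w) >= dev - 1e-9].sum() / total
        return u, float(min(p, 1.0))
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return u, 1.0
    z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)  # continuity correction
    p = 2.0 * _st.norm.sf(max(z, 0.0))
    return u, float(min(p, 1.0))


def roc_auc(case_values, control_values) -> tuple[float, bool]:
    """AUC via the rank-sum identity, orientation-corrected.

    AUC = (#{case > control} + 0.5 * #{ties}) / (n_case * n_control).
    If the raw AUC is below 0.5 the orientation is flipped and the flip
    flag is set, so the reported AUC is always >= 0.5.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = case.size, control.size
    ranks = _st.rankdata(np.concatenate([case, control]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n2)
    if auc < 0.5:
        return 1.0 - auc, True
    return float(auc), False


def bh_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (Bonferroni via ``method``)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def log2_fold_change(case_values, control_values, *, geometric: bool = False) -> float:
    """log2 of the ratio of group means (geometric means optional)."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if geometric:
        return float(np.mean(np.log2(case)) - np.mean(np.log2(control)))
    return float(np.log2(case.mean() / control.mean()))


def evaluate_contrast(
    quantities,
    group_labels,
    contrast: tuple[str, str],
    *,
    peptide: str = "",
    protein: str = "",
) -> dict:
    """Raw per-peptide statistics for one (case, control) contrast."""
    q = np.asarray(quantities, dtype=float)
    labels = np.asarray(group_labels)
    case, control = contrast
    xv = q[labels == case]
    yv = q[labels == control]
    u, p = wilcoxon_rank_sum(xv, yv)
    auc, flipped = roc_auc(xv, yv)
    return {
        "peptide": peptide,
        "protein": protein,
        "contrast": contrast,
        "log2fc": log2_fold_change(xv, yv),
        "p_raw": p,
        "auc": auc,
        "auc_flipped": flipped,
    }


def classify_markers(
    results: list[dict],
    profiling_directions: dict[str, int] | None = None,
    *,
    auc_candidate: float = 0.7,
    auc_strong: float = 0.9,
    alpha: float = 0.05,
    adjust_method: str = "fdr_bh",
) -> list[MarkerResult]:
    """Tier peptides from raw contrast statistics.

    ``candidate`` requires AUC strictly above 0.7 and a fold-change
    direction concordant with the profiling experiment; ``strong``
    additionally requires AUC strictly above 0.9.  Significance is a
    separate flag: adjusted p below ``alpha``.  Peptides whose protein is
    absent from the direction map skip the concordance check (flagged
    ``None``).
    """
    if not results:
        return []
    directions = profiling_directions or {}
    p_adj = bh_adjust([r["p_raw"] for r in results], method=adjust_method)
    out = []
    for r, padj in zip(results, p_adj):
        key = r["protein"] or r["peptide"]
        expected = directions.get(key)
        if expected is None:
            concordant: bool | None = None
        else:
            concordant = bool(np.sign(r["log2fc"]) == np.sign(expected))
        direction_ok = concordant is not False
        tier = "none"
        if r["auc"] > auc_candidate and direction_ok:
            tier = "strong" if r["auc"] > auc_strong else "candidate"
        out.append(
            MarkerResult(
                peptide=r["peptide"],
                protein=r["protein"],
                contrast=tuple(r["contrast"]),
                log2fc=r["log2fc"],
                p_raw=r["p_raw"],
                p_adj=float(padj),
                auc=r["auc"],
                auc_flipped=r["auc_flipped"],
                tier=tier,
                significant=bool(padj < alpha),
                direction_concordant=concordant,
            )
        )
    return out
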