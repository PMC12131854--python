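"""Stage-wise single-sample gene-set enrichment.

Each disease stage contributes one expression profile; for every gene
set the single-sample enrichment score (ES) is the integrated difference
between the weighted hit ECDF and the miss ECDF along the
descending-rank gene list.  Scores are normalized against a gene-
permutation null (size-matched random sets), giving a normalized
enrichment score NES = ES / mean |null ES|, and the per-stage statistic
is the NES difference: each stage's NES minus the mean NES across
stages, so the differences sum to zero per set by construction.  Gene
(not sample) permutation is used because the stage profiles are single
pooled measurements without replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .markers import bh_adjust

DEFAULT_ALPHA = 0.25
MIN_SET_SIZE = 5


@dataclass
class EnrichmentResult:
    gene_set: str
    es: dict[str, float]  # per stage
    nes: dict[str, float]
    nes_difference: dict[str, float]
    fdr: float


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + list(members)) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def ssgsea_es(
    sample_expression: pd.Series,
    gene_set,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Single-sample enrichment score for one profile and one gene set.

    Genes are ranked by descending expression.  At each list position
    the hit ECDF (weighted by |expression|^alpha, normalized over the
    set's hits) is compared with the uniform miss ECDF; the ES is the
    sum of the differences over all positions.  With ``alpha = 0`` the
    score depends only on ranks and is invariant under strictly
    monotone transforms.
    """
    expr = sample_expression.dropna()
    members = set(gene_set) & set(expr.index)
    if not members:
        raise ValueError("gene set does not intersect the measured universe")
    if len(members) == len(expr):
        raise ValueError("gene set covers the entire universe; miss ECDF undefined")
    order = expr.sort_values(ascending=False)
    hit = order.index.isin(members)
    weights = np.abs(order.to_numpy(dtype=float)) ** alpha
    hit_w = np.where(hit, weights, 0.0)
    hit_cdf = np.cumsum(hit_w) / hit_w.sum()
    miss = (~hit).astype(float)
    miss_cdf = np.cumsum(miss) / miss.sum()
    return float(np.sum(hit_cdf - miss_cdf))


def es_matrix(
    expression: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    *,
    alpha: float = DEFAULT_ALPHA,
    min_size: int = MIN_SET_SIZE,
) -> pd.DataFrame:
    """ES for every (gene set, stage); sets below ``min_size`` after
    intersection with the universe are skipped."""
    universe = set(expression.index)
    rows = {}
    for name, members in gene_sets.items():
        usable = [g for g in members if g in universe]
        if len(usable) < min_size or len(usable) == len(universe):
            continue
        rows[name] = {
            stage: ssgsea_es(expression[stage], usable, alpha)
            for stage in expression.columns
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(expression.columns)]


def nes_and_fdr(
    expression: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    *,
    alpha: float = DEFAULT_ALPHA,
    min_size: int = MIN_SET_SIZE,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Normalize ES against a gene-permutation null and estimate FDR.

    For each distinct set size, ``n_permutations`` random same-size sets
    are scored on every stage; the null pool is shared across sets of
    equal size.  NES = ES / mean |null ES| (sign preserved); the
    empirical p of each set is the fraction of null |NES| at or above
    the observed max-over-stages |NES|, BH-adjusted across sets into an
    FDR.  The NES difference (stage NES minus cross-stage mean NES) is
    the stage-wise statistic.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; FDR estimates are unstable")
    observed = es_matrix(expression, gene_sets, alpha=alpha, min_size=min_size)
    if observed.empty:
        return []
    rng = np.random.default_rng(seed)
    universe = list(expression.index)
    sizes = {
        name: len(set(gene_sets[name]) & set(universe)) for name in observed.index
    }
    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted(set(sizes.values())):
        null = np.empty((n_permutations, expression.shape[1]))
        for b in range(n_permutations):
            members = rng.choice(universe, size=size, replace=False)
            for j, stage in enumerate(expression.columns):
                null[b, j] = ssgsea_es(expression[stage], members, alpha)
        null_by_size[size] = null

    results = []
    p_values = []
    for name in observed.index:
        null = null_by_size[sizes[name]]
        denom = np.mean(np.abs(null), axis=0)  # per stage
        nes = observed.loc[name].to_numpy() / denom
        null_nes = null / denom
        stat = np.max(np.abs(nes))
        p = float(np.mean(np.max(np.abs(null_nes), axis=1) >= stat))
        p = max(p, 1.0 / (null.shape[0] + 1))
        p_values.append(p)
        nes_s = dict(zip(observed.columns, nes))
        mean_nes = float(np.mean(nes))
        results.append(
            EnrichmentResult(
                gene_set=name,
                es=observed.loc[name].to_dict(),
                nes=nes_s,
                nes_difference={k: v - mean_nes for k, v in nes_s.items()},
                fdr=np.nan,
            )
        )
    fdr = bh_adjust(p_values)
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Long-format export (set, stage, ES, NES, NES difference, FDR)."""
    rows = []
    for r in results:
        for stage in r.nes:
            rows.append(
                {
                    "gene_set": r.gene_set,
                    "stage": stage,
                    "es": r.es[stage],
                    "nes": r.nes[stage],
                    "nes_difference": r.nes_difference[stage],
                    "fdr": r.fdr,
                }
            )
    return pd.DataFrame(rows)
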