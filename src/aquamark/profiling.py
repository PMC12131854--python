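"""Profiling-stage differential expression across the LFQ and TMT platforms.

The two discovery platforms carry different evidence and therefore use
different calling rules on log2 intensities:

* LFQ (pooled, depleted samples; missing values common): a protein is
  differentially expressed when |log2 fold change| >= 1.  When one group
  has missing values, its available intensities are compared against the
  mean of the fully observed group; proteins entirely missing in one
  group are reported as group-specific with a capped fold change.
* TMT (two reporter channels per group, complete matrix): called when
  the two-sample t test gives p < 0.05 and |log2 fold change| >= 0.58.

Final candidates are proteins called on both platforms in either of the
stage contrasts (PDR vs NPDR, NVG vs PDR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

CONTRASTS = (("PDR", "NPDR"), ("NVG", "PDR"))

LFQ_FC_CUTOFF = 1.0
TMT_FC_CUTOFF = 0.58
TMT_P_CUTOFF = 0.05
MAX_ABS_FC = 10.0  # cap for group-specific (all-missing-in-one-group) proteins


@dataclass
class IntensityMatrix:
    """Proteins x samples log2 intensity table with group annotations."""

    values: pd.DataFrame  # proteins x samples, log2 scale, NaN = missing
    platform: str  # "LFQ" | "TMT"
    group_labels: pd.Series  # sample -> group

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.group_labels.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        if self.platform.upper() == "TMT" and self.values.isna().any().any():
            raise ValueError("TMT matrices must be complete (no missing values)")

    def group_columns(self, group: str) -> list:
        labels = self.group_labels.reindex(self.values.columns)
        return list(self.values.columns[labels == group])


@dataclass
class ContrastResult:
    protein: str
    contrast: tuple[str, str]
    log2fc: float
    p_value: float | None
    call: bool
    basis: str  # "normal" | "missing-fallback" | "group-specific"


def two_sample_t(x_values, y_values) -> tuple[float, float]:
    """Pooled-variance (Student) two-sided two-sample t test.

    The equal-variance form matches the balanced channel design; Welch
    is available through ``scipy`` directly if unequal variances are
    suspected.  Requires >= 2 observations per side.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 non-missing values per side for the t test")
    t, p = _st.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def _contrast_one(
    case_vals: np.ndarray,
    ctrl_vals: np.ndarray,
    platform: str,
    *,
    max_abs_fc: float = MAX_ABS_FC,
) -> tuple[float, float | None, bool, str]:
    case_obs = case_vals[~np.isnan(case_vals)]
    ctrl_obs = ctrl_vals[~np.isnan(ctrl_vals)]
    if case_obs.size == 0 and ctrl_obs.size == 0:
        return np.nan, None, False, "group-specific"
    if case_obs.size == 0 or ctrl_obs.size == 0:
        fc = max_abs_fc if ctrl_obs.size == 0 else -max_abs_fc
        call = platform.upper() == "LFQ"  # FC cap exceeds the LFQ cutoff
        return fc, None, call, "group-specific"
    basis = "normal"
    p: float | None = None
    if np.isnan(case_vals).any() or np.isnan(ctrl_vals).any():
        basis = "missing-fallback"
    fc = float(case_obs.mean() - ctrl_obs.mean())
    if case_obs.size >= 2 and ctrl_obs.size >= 2:
        _, p = two_sample_t(case_obs, ctrl_obs)
    if platform.upper() == "LFQ":
        call = abs(fc) >= LFQ_FC_CUTOFF
    else:
        call = p is not None and p < TMT_P_CUTOFF and abs(fc) >= TMT_FC_CUTOFF
    return fc, p, call, basis


def dep_call(
    matrix: IntensityMatrix,
    contrast: tuple[str, str],
    *,
    max_abs_fc: float = MAX_ABS_FC,
) -> list[ContrastResult]:
    """Call differentially expressed proteins for one (case, control) contrast."""
    case, control = contrast
    case_cols = matrix.group_columns(case)
    ctrl_cols = matrix.group_columns(control)
    if not case_cols or not ctrl_cols:
        raise ValueError(f"contrast group absent from matrix: {contrast}")
    results = []
    for protein, row in matrix.values.iterrows():
        fc, p, call, basis = _contrast_one(
            row[case_cols].to_numpy(dtype=float),
            row[ctrl_cols].to_numpy(dtype=float),
            matrix.platform,
            max_abs_fc=max_abs_fc,
        )
        results.append(
            ContrastResult(str(protein), contrast, fc, p, call, basis)
        )
    return results


def _called_union(results_by_contrast: dict[tuple, list[ContrastResult]]) -> dict[str, float]:
    """Union of called proteins over contrasts, with max |log2fc| per protein."""
    called: dict[str, float] = {}
    for results in results_by_contrast.values():
        for r in results:
            if r.call and np.isfinite(r.log2fc):
                prev = called.get(r.protein, 0.0)
                called[r.protein] = max(prev, abs(r.log2fc))
    return called


def candidate_selection(
    lfq_results_by_contrast: dict[tuple, list[ContrastResult]],
    tmt_results_by_contrast: dict[tuple, list[ContrastResult]],
    *,
    rule: str = "intersection",
) -> list[str]:
    """Cross-platform candidate list.

    Per platform, take the union of called proteins over the two stage
    contrasts; final candidates are the intersection (default) or union
    of the two platform sets, ordered by descending max |log2fc| then
    lexicographically.
    """
    lfq = _called_union(lfq_results_by_contrast)
    tmt = _called_union(tmt_results_by_contrast)
    if rule == "intersection":
        names = set(lfq) & set(tmt)
    elif rule == "union":
        names = set(lfq) | set(tmt)
    else:
        raise ValueError(f"unknown candidate rule: {rule!r}")
    score = {n: max(lfq.get(n, 0.0), tmt.get(n, 0.0)) for n in names}
    return sorted(names, key=lambda n: (-score[n], n))


def platform_overlap(lfq_proteins, tmt_proteins) -> tuple[int, int, int]:
    """(common, lfq_only, tmt_only) identification counts."""
    a, b = set(lfq_proteins), set(tmt_proteins)
    return len(a & b), len(a - b), len(b - a)


def results_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": r.protein,
                "case": r.contrast[0],
                "control": r.contrast[1],
                "log2fc": r.log2fc,
                "p_value": np.nan if r.p_value is None else r.p_value,
                "call": r.call,
                "basis": r.basis,
            }
            for r in results
        ]
    )


def profiling_directions(
    results_by_contrast: dict[tuple, list[ContrastResult]],
) -> dict[tuple, dict[str, int]]:
    """Per-contrast map protein -> sign(log2fc) for called proteins."""
    out: dict[tuple, dict[str, int]] = {}
    for contrast, results in results_by_contrast.items():
        out[contrast] = {
            r.protein: int(np.sign(r.log2fc))
            for r in results
            if r.call and np.isfinite(r.log2fc) and r.log2fc != 0
        }
    return out
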