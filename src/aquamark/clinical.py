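"""Clinical-covariate statistics for the diabetic-retinopathy cohorts.

Covers the a-priori sample-size formula, frequency-table tests for the
patient-characteristics table (Pearson chi-square without continuity
correction, and the Freeman-Halton exact test for sparse tables), odds
ratios with Woolf confidence intervals, covariate-adjusted regression of
peptide quantities on clinical variables, and stratified re-testing of
group contrasts (e.g. by the median age of 60 or by cataract grade).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, exp, lgamma, sqrt

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _st

from .markers import bh_adjust, wilcoxon_rank_sum

GROUPS = ("NPDR", "PDR", "NVG")


@dataclass(frozen=True)
class SampleSizeDesign:
    """Two-group power design: n = (z_alpha + z_beta)^2 * 2 / d^2."""

    effect_size: float
    z_alpha: float = 1.96  # two-sided alpha = 0.05
    z_beta: float = 1.28  # power = 0.90

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect size d must be positive")


def sample_size(design: SampleSizeDesign) -> tuple[int, int]:
    """Per-group and total sample size, rounded up."""
    n_raw = (design.z_alpha + design.z_beta) ** 2 * 2.0 / design.effect_size**2
    # guard the ceiling against floating-point noise at exact integers
    return ceil(round(n_raw, 9)), ceil(round(2.0 * n_raw, 9))


def empirical_power(
    n_per_group: int,
    effect_size: float,
    *,
    alpha: float = 0.05,
    n_reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-sided two-sample t test.

    Simulates ``n_reps`` pairs of normal samples (unit SD, means apart by
    ``effect_size``) of size ``n_per_group`` each and returns the
    fraction rejected at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(effect_size, 1.0, size=(n_reps, n_per_group))
    y = rng.normal(0.0, 1.0, size=(n_reps, n_per_group))
    _, p = _st.ttest_ind(x, y, axis=1)
    return float(np.mean(p < alpha))


def chi_square_rc(table) -> tuple[float, int, float]:
    """Pearson chi-square on an RxC count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table must be 2-D with positive row and column sums")
    chi2, p, df, _ = _st.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def _log_factorial(x: int) -> float:
    return lgamma(x + 1)


def _table_log_prob(table: np.ndarray) -> float:
    """Multivariate hypergeometric log-probability under fixed margins."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return (
        sum(_log_factorial(int(v)) for v in r)
        + sum(_log_factorial(int(v)) for v in c)
        - _log_factorial(int(n))
        - sum(_log_factorial(int(v)) for v in table.ravel())
    )


def fisher_exact(table, *, max_tables: int = 2_000_000) -> float:
    """Two-sided exact test: Fisher for 2x2, Freeman-Halton for 2xK.

    The Freeman-Halton p value sums the probabilities of all tables with
    the observed margins whose probability does not exceed that of the
    observed table.  Enumeration is feasible only for small margins;
    larger tables raise with a pointer to the chi-square test.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2x2 or 2xK count table")
    if t.shape[1] == 2:
        return float(_st.fisher_exact(t)[1])
    row0 = int(t.sum(axis=1)[0])
    cols = t.sum(axis=0)
    n_tables = np.prod([min(row0, int(c)) + 1 for c in cols[:-1]])
    if n_tables > max_tables:
        raise ValueError(
            "margins too large for exact enumeration; use chi_square_rc instead"
        )
    lp_obs = _table_log_prob(t)
    p_total = 0.0
    k = t.shape[1]

    def recurse(j: int, remaining: int, cells: list[int]) -> float:
        if j == k - 1:
            if remaining > cols[j]:
                return 0.0
            top = np.array(cells + [remaining])
            cand = np.vstack([top, cols - top])
            if np.any(cand < 0):
                return 0.0
            lp = _table_log_prob(cand)
            nonlocal p_total
            p_total += exp(lp)
            return exp(lp) if lp <= lp_obs + 1e-12 else 0.0
        acc = 0.0
        for x in range(min(remaining, int(cols[j])) + 1):
            acc += recurse(j + 1, remaining - x, cells + [x])
        return acc

    p = recurse(0, row0, [])
    assert abs(p_total - 1.0) < 1e-9
    return float(min(p, 1.0))


def odds_ratio(table_2x2) -> tuple[float, float, tuple[float, float]]:
    """Odds ratio ad/bc with 95% Woolf CI; +0.5 correction on zero cells.

    Returns ``(or, log2_or, (ci_low, ci_high))`` with the CI on the OR
    scale.
    """
    t = np.asarray(table_2x2, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t == 0):
        t = t + 0.5  # Haldane-Anscombe
    a, b = t[0]
    c, d = t[1]
    or_ = (a * d) / (b * c)
    se_log = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = exp(np.log(or_) - 1.96 * se_log)
    hi = exp(np.log(or_) + 1.96 * se_log)
    return float(or_), float(np.log2(or_)), (float(lo), float(hi))


def covariate_regression(
    quantities: pd.DataFrame,
    clinical: pd.DataFrame,
    covariate: str,
    *,
    adjust_for: tuple[str, ...] = ("group", "age"),
    min_observations: int = 10,
    standardize: bool = False,
) -> pd.DataFrame:
    """OLS of each peptide's log2 quantity on a clinical covariate.

    ``quantities`` is samples x peptides (log2 scale, index = patient
    id); ``clinical`` carries the covariates indexed the same way.
    Disease group and age are included as adjustment terms by default so
    the reported estimate isolates the covariate of interest.  P values
    are BH-adjusted across peptides.  Collinear designs (covariate
    duplicated among the adjusters, or zero-variance covariate) are
    flagged and the estimate withheld.
    """
    shared = quantities.index.intersection(clinical.index)
    rows = []
    for peptide in quantities.columns:
        df = pd.concat(
            [quantities.loc[shared, peptide].rename("y"), clinical.loc[shared]],
            axis=1,
        ).dropna(subset=["y", covariate])
        if len(df) < min_observations:
            rows.append({"peptide": peptide, "estimate": np.nan, "p_raw": np.nan,
                         "flag": "insufficient observations"})
            continue
        design_cols = [covariate] + [c for c in adjust_for if c != covariate and c in df]
        X_parts = []
        for col in design_cols:
            series = df[col]
            if series.dtype == object or str(series.dtype) == "category":
                X_parts.append(pd.get_dummies(series, prefix=col, drop_first=True,
                                              dtype=float))
            else:
                vals = series.astype(float)
                if standardize and col != covariate:
                    sd = vals.std(ddof=1)
                    vals = (vals - vals.mean()) / sd if sd > 0 else vals * 0.0
                X_parts.append(vals.rename(col).to_frame())
        X = pd.concat(X_parts, axis=1)
        X = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
        if rank < X.shape[1] or df[covariate].astype(float).nunique() < 2:
            rows.append({"peptide": peptide, "estimate": np.nan, "p_raw": np.nan,
                         "flag": "collinear design"})
            continue
        fit = sm.OLS(df["y"].astype(float), X.astype(float)).fit()
        target = covariate if covariate in fit.params.index else next(
            c for c in fit.params.index if c.startswith(f"{covariate}_")
        )
        rows.append({"peptide": peptide, "estimate": float(fit.params[target]),
                     "p_raw": float(fit.pvalues[target]), "flag": ""})
    out = pd.DataFrame(rows).set_index("peptide")
    ok = out["p_raw"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p_raw"].to_numpy())
    return out


def stratified_recheck(
    quantities: pd.Series,
    clinical: pd.DataFrame,
    stratify_by: str,
    *,
    contrasts: tuple[tuple[str, str], ...] = (("PDR", "NPDR"), ("NVG", "PDR")),
    min_stratum_size: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-test group contrasts within strata of a clinical variable.

    For each stratum of ``stratify_by`` and each (case, control)
    contrast, recomputes the Wilcoxon rank-sum p and log2 fold change
    and reports whether significance and direction persist.  Strata with
    fewer than ``min_stratum_size`` patients on either side are reported
    as not evaluable.
    """
    shared = quantities.index.intersection(clinical.index)
    q = quantities.loc[shared]
    cl = clinical.loc[shared]
    rows = []
    for stratum, sub in cl.groupby(stratify_by, observed=True):
        for case, control in contrasts:
            xv = q[sub.index[sub["group"] == case]].dropna()
            yv = q[sub.index[sub["group"] == control]].dropna()
            if len(xv) < min_stratum_size or len(yv) < min_stratum_size:
                rows.append({"stratum": stratum, "contrast": f"{case}_vs_{control}",
                             "n_case": len(xv), "n_control": len(yv),
                             "log2fc": np.nan, "p": np.nan, "evaluable": False,
                             "significant": False})
                continue
            _, p = wilcoxon_rank_sum(xv.to_numpy(), yv.to_numpy())
            fc = float(np.log2(xv.mean() / yv.mean()))
            rows.append({"stratum": stratum, "contrast": f"{case}_vs_{control}",
                         "n_case": len(xv), "n_control": len(yv),
                         "log2fc": fc, "p": p, "evaluable": True,
                         "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def summarize_table1(clinical: pd.DataFrame) -> pd.DataFrame:
    """Group-wise descriptive summary in the style of a patient table."""
    rows = []
    for group, sub in clinical.groupby("group", observed=True):
        row = {"group": group, "n": len(sub),
               "age_mean": sub["age"].mean(), "age_sd": sub["age"].std(ddof=1)}
        for col in ("sex_male", "hypertension", "macular_edema", "prp"):
            if col in sub:
                row[f"{col}_n"] = int(sub[col].sum())
                row[f"{col}_pct"] = 100.0 * sub[col].mean()
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
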