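"""Targeted-MS (dynamic MRM) quantification QC cascade.

Raw transition peak areas pass through a fixed-order cascade:

1. spike-in normalization — per (sample, replicate) scaling factor from
   the geometric mean of the beta-galactosidase spike-in areas;
2. detection flagging — a transition observation counts as detected only
   when its raw area exceeds 10^3 (strict), an instrument-scale floor;
3. sample filter — samples in which fewer than 50% of the target
   transitions are detected are excluded;
4. CV filter — transitions whose technical-duplicate coefficient of
   variation (median across samples) is 20% or more are excluded
   cohort-wide;
5. peptide roll-up — a peptide is quantified in a sample when at least
   three of its surviving transitions are detected; its quantity is the
   replicate mean of the summed transition areas on the normalized
   scale.

Each stage only removes rows, so the cascade is idempotent on its own
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transitions import SPIKEIN_PEPTIDES

PEAK_COLUMNS = ["sample", "replicate", "protein", "peptide", "transition", "area"]

DETECTION_AREA_THRESHOLD = 1e3
CV_THRESHOLD = 0.20
SAMPLE_DETECTION_FRACTION = 0.5
MIN_TRANSITIONS_PER_PEPTIDE = 3


@dataclass
class QCReport:
    """Audit trail of the cascade: what was removed at each stage and why."""

    n_input_rows: int = 0
    excluded_samples: dict[str, str] = field(default_factory=dict)
    excluded_transitions: dict[str, str] = field(default_factory=dict)
    excluded_peptides: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    transition_cv: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input_rows": self.n_input_rows,
            "excluded_samples": self.excluded_samples,
            "excluded_transitions": self.excluded_transitions,
            "excluded_peptides": self.excluded_peptides,
            "stage_counts": self.stage_counts,
            "transition_cv": self.transition_cv,
        }


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peak-area table missing columns: {missing}")
    if table.duplicated(["sample", "replicate", "transition"]).any():
        raise ValueError("duplicate (sample, replicate, transition) rows")
    if not np.isfinite(table["area"]).all() or (table["area"] < 0).any():
        raise ValueError("areas must be finite and non-negative")
    return table


def normalize_spikein(
    table: pd.DataFrame,
    spikein_peptides: tuple[str, ...] = SPIKEIN_PEPTIDES,
    report: QCReport | None = None,
) -> pd.DataFrame:
    """Divide every area by a per-(sample, replicate) loading factor.

    The factor is the geometric mean of that injection's spike-in
    transition areas divided by the cohort-wide median of those
    geometric means, so the median injection is left unchanged.
    Geometric (not arithmetic) means suit the log-normal area scale and
    resist single-transition outliers.  Injections with no positive
    spike-in area cannot be normalized and are excluded.
    """
    table = _validate(table).copy()
    report = report if report is not None else QCReport()
    is_spike = table["peptide"].isin(spikein_peptides)
    table["is_spikein"] = is_spike
    spikes = table[is_spike & (table["area"] > 0)]
    geo = (
        spikes.assign(log_area=np.log(spikes["area"]))
        .groupby(["sample", "replicate"])["log_area"]
        .mean()
        .pipe(np.exp)
    )
    bad = []
    for key in table.groupby(["sample", "replicate"]).groups:
        if key not in geo.index:
            bad.append(key)
    for sample, replicate in bad:
        report.excluded_samples[str(sample)] = "no positive spike-in areas"
    if bad:
        keep = ~table.set_index(["sample", "replicate"]).index.isin(bad)
        table = table[keep].copy()
    factors = geo / geo.median()
    idx = pd.MultiIndex.from_frame(table[["sample", "replicate"]])
    table["raw_area"] = table["area"]
    table["area"] = table["area"].to_numpy() / factors.reindex(idx).to_numpy()
    return table


def detection_filter(
    table: pd.DataFrame,
    *,
    area_threshold: float = DETECTION_AREA_THRESHOLD,
    on_raw: bool = True,
) -> pd.DataFrame:
    """Flag detected transition observations (area strictly above 10^3).

    Detection is assessed on the pre-normalization areas by default,
    since the threshold is an instrument-scale constant.
    """
    table = table.copy()
    basis = table["raw_area"] if (on_raw and "raw_area" in table) else table["area"]
    table["detected"] = basis > area_threshold
    return table


def sample_filter(
    table: pd.DataFrame,
    report: QCReport | None = None,
    *,
    min_fraction: float = SAMPLE_DETECTION_FRACTION,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop samples detecting fewer than 50% of target transitions.

    Spike-in transitions are excluded from both numerator and
    denominator.  Exactly 50% is retained (the rule is "fewer than").
    """
    report = report if report is not None else QCReport()
    targets = table[~table["is_spikein"]]
    n_target_transitions = targets["transition"].nunique()
    frac = (
        targets.groupby("sample", observed=True)
        .apply(
            lambda g: g.loc[g["detected"], "transition"].nunique()
            / n_target_transitions,
            include_groups=False,
        )
    )
    dropped = frac.index[frac < min_fraction]
    for s in dropped:
        report.excluded_samples[str(s)] = (
            f"detected fraction {frac[s]:.2f} < {min_fraction:.2f}"
        )
    out = table[~table["sample"].isin(dropped)].copy()
    report.stage_counts["after_sample_filter"] = len(out)
    return out, report


def duplicate_cv(areas: np.ndarray) -> float:
    """Coefficient of variation of technical duplicates (n-1 SD / mean)."""
    m = areas.mean()
    if m == 0:
        return np.nan
    return float(areas.std(ddof=1) / m)


def cv_filter(
    table: pd.DataFrame,
    report: QCReport | None = None,
    *,
    cv_threshold: float = CV_THRESHOLD,
    min_samples: int = 3,
) -> tuple[pd.DataFrame, QCReport]:
    """Remove transitions with irreproducible technical duplicates.

    Per transition and sample the CV is computed over the two replicate
    areas; the transition's summary CV is the median over samples where
    it is detected.  Transitions with summary CV >= 20% are removed
    cohort-wide; transitions detected in fewer than ``min_samples``
    samples are removed for insufficient observations.  Spike-ins are
    exempt (they are audit rows, already flagged).
    """
    report = report if report is not None else QCReport()
    targets = table[~table["is_spikein"]]
    removed: dict[str, str] = {}
    for transition, g in targets.groupby("transition", observed=True):
        per_sample = []
        for _, sg in g.groupby("sample", observed=True):
            if not sg["detected"].all() or len(sg) < 2:
                continue
            per_sample.append(duplicate_cv(sg["area"].to_numpy()))
        if len(per_sample) < min_samples:
            removed[str(transition)] = "insufficient observations"
            continue
        cv = float(np.nanmedian(per_sample))
        report.transition_cv[str(transition)] = cv
        if cv >= cv_threshold:
            removed[str(transition)] = f"duplicate CV {cv:.3f} >= {cv_threshold:.2f}"
    report.excluded_transitions.update(removed)
    out = table[
        table["is_spikein"] | ~table["transition"].astype(str).isin(removed)
    ].copy()
    report.stage_counts["after_cv_filter"] = len(out)
    return out, report


def peptide_quantity(
    table: pd.DataFrame,
    report: QCReport | None = None,
    *,
    min_transitions: int = MIN_TRANSITIONS_PER_PEPTIDE,
) -> tuple[pd.DataFrame, QCReport]:
    """Roll surviving transitions up to per-(sample, peptide) quantities.

    A peptide is quantified in a sample when at least ``min_transitions``
    of its surviving transitions are detected in both replicates there;
    the quantity is the mean over replicates of the summed normalized
    transition areas.  Peptides left with fewer surviving transitions
    than the minimum anywhere are recorded in the report.
    """
    report = report if report is not None else QCReport()
    targets = table[~table["is_spikein"]]
    n_surviving = targets.groupby("peptide", observed=True)["transition"].nunique()
    for peptide, n in n_surviving.items():
        if n < min_transitions:
            report.excluded_peptides[str(peptide)] = (
                f"only {n} surviving transition(s)"
            )
    rows = []
    for (sample, peptide), g in targets.groupby(["sample", "peptide"], observed=True):
        protein = g["protein"].iloc[0]
        det_in_all_reps = g.groupby("transition", observed=True)["detected"].all()
        usable = det_in_all_reps.index[det_in_all_reps]
        detected = g[g["transition"].isin(usable)]
        n_det = len(usable)
        if n_det < min_transitions:
            continue
        per_rep = detected.groupby("replicate", observed=True)["area"].sum()
        rows.append(
            {
                "sample": sample,
                "protein": protein,
                "peptide": peptide,
                "n_transitions": n_det,
                "quantity": float(per_rep.mean()),
            }
        )
    out = pd.DataFrame(rows, columns=["sample", "protein", "peptide",
                                      "n_transitions", "quantity"])
    report.stage_counts["quantified_rows"] = len(out)
    return out, report


def run_cascade(
    table: pd.DataFrame,
    spikein_peptides: tuple[str, ...] = SPIKEIN_PEPTIDES,
    *,
    area_threshold: float = DETECTION_AREA_THRESHOLD,
    cv_threshold: float = CV_THRESHOLD,
    min_transitions: int = MIN_TRANSITIONS_PER_PEPTIDE,
) -> tuple[pd.DataFrame, QCReport]:
    """Full cascade: normalize -> detect -> sample filter -> CV filter -> quantify."""
    report = QCReport(n_input_rows=len(table))
    t = normalize_spikein(table, spikein_peptides, report)
    t = detection_filter(t, area_threshold=area_threshold)
    t, report = sample_filter(t, report)
    t, report = cv_filter(t, report, cv_threshold=cv_threshold)
    quantities, report = peptide_quantity(t, report, min_transitions=min_transitions)
    return quantities, report


def quantities_to_matrix(quantities: pd.DataFrame) -> pd.DataFrame:
    """Pivot long quantities to a samples x peptides table (NaN = not quantified)."""
    return quantities.pivot(index="sample", columns="peptide", values="quantity")
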