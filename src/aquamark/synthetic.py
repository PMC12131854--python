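"""Synthetic cohort generator for the diabetic-retinopathy pipeline.

Emulates the statistical structure the downstream stages assume, for the
three disease groups (NPDR, PDR, NVG):

* a clinical covariate table with the validation-cohort group sizes
  (37/38/9), truncated-normal ages, and per-group covariate prevalences;
* pooled LFQ and duplicate-channel TMT profiling matrices: log-normal
  (log2-additive) intensities, planted marker effects, platform
  location/scale shifts, and abundance-dependent (left-censoring-like)
  missingness on the LFQ side only;
* a long-format MRM peak-area table with two technical replicates per
  injection, a per-sample log-normal loading factor, the four constant
  beta-galactosidase spike-in peptides, and a tunable duplicate CV.

Ground truth (which proteins carry which log2 effects) is carried
alongside so recovery tests can score the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .profiling import IntensityMatrix
from .transitions import (
    SPIKEIN_PEPTIDES,
    Peptide,
    TransitionRecord,
    select_transitions,
)

GROUPS = ("NPDR", "PDR", "NVG")

#: Validation-cohort per-group sizes.
DEFAULT_N = {"NPDR": 37, "PDR": 38, "NVG": 9}
#: Per-group age mean/SD in years (validation cohort).
DEFAULT_AGE = {"NPDR": (66.1, 8.3), "PDR": (54.9, 8.9), "NVG": (53.3, 12.1)}
#: Per-group covariate prevalences (sex and hypertension follow the
#: validation cohort; macular edema and PRP rise with stage, reflecting
#: the clinical course — PRP is near-universal by the NVG stage).
DEFAULT_PREVALENCE = {
    "NPDR": {"sex_male": 18 / 37, "hypertension": 21 / 37, "macular_edema": 0.30, "prp": 0.10},
    "PDR": {"sex_male": 23 / 38, "hypertension": 21 / 38, "macular_edema": 0.55, "prp": 0.70},
    "NVG": {"sex_male": 5 / 9, "hypertension": 5 / 9, "macular_edema": 0.55, "prp": 0.90},
}
#: Per-group distribution over cataract grades {0, 1, 2}; NPDR patients
#: (older, enrolled at cataract surgery) carry more advanced grades.
DEFAULT_CATARACT = {
    "NPDR": (0.2, 0.4, 0.4),
    "PDR": (0.4, 0.4, 0.2),
    "NVG": (0.5, 0.3, 0.2),
}

AGE_BOUNDS = (30.0, 90.0)


@dataclass
class CohortDesign:
    """Cohort layout and covariate distributions for one simulation."""

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N))
    age_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE)
    )
    covariate_prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_PREVALENCE.items()}
    )
    cataract_grade_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CATARACT)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"group size for {g} must be >= 1, got {n}")
        for g, prevs in self.covariate_prevalences.items():
            for name, p in prevs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence {name} for {g} outside [0, 1]")
        for g, probs in self.cataract_grade_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"cataract grade probabilities for {g} must sum to 1")


@dataclass
class GroundTruth:
    """Planted effects and nuisance structure for one simulation.

    ``true_marker_effects`` maps protein -> {(case, control): log2
    effect} for the two stage contrasts.  ``batch_shifts`` maps platform
    -> (additive log2 location, multiplicative noise scale).
    ``missingness_params`` are (midpoint log2 abundance, slope) of the
    logistic detection-probability model for LFQ; ``cv_target`` is the
    expected technical-duplicate CV; ``spikein_level`` the constant log2
    area of the spike-in peptides.
    """

    true_marker_effects: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=dict
    )
    batch_shifts: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"LFQ": (0.0, 1.0), "TMT": (2.0, 1.5)}
    )
    missingness_params: tuple[float, float] = (17.0, 1.0)  # midpoint, slope
    cv_target: float = 0.10
    spikein_level: float = 19.0  # log2 area, ~5e5 raw

    def __post_init__(self) -> None:
        if not 0.0 <= self.cv_target < 1.0:
            raise ValueError("cv_target must lie in [0, 1)")
        if self.missingness_params[1] < 0:
            raise ValueError("detection slope must be >= 0")

    def group_effect(self, protein: str, group: str) -> float:
        """Cumulative log2 effect of ``group`` relative to the NPDR baseline."""
        effects = self.true_marker_effects.get(protein, {})
        pdr = effects.get(("PDR", "NPDR"), 0.0)
        if group == "NPDR":
            return 0.0
        if group == "PDR":
            return pdr
        if group == "NVG":
            return pdr + effects.get(("NVG", "PDR"), 0.0)
        raise ValueError(f"unknown group {group!r}")


def _rng(design: CohortDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng([design.seed, stream])


def generate_clinical_table(design: CohortDesign) -> pd.DataFrame:
    """One row per simulated patient, indexed by patient id.

    Covariates are drawn independently at the per-group prevalences;
    ages come from a normal truncated to [30, 90] years.
    """
    rng = _rng(design, 1)
    rows = []
    counter = 0
    for group in GROUPS:
        n = design.n_per_group.get(group, 0)
        if n == 0:
            continue
        mean, sd = design.age_means_sds[group]
        a, b = (AGE_BOUNDS[0] - mean) / sd, (AGE_BOUNDS[1] - mean) / sd
        ages = _st.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        prevs = design.covariate_prevalences[group]
        grades = design.cataract_grade_probs[group]
        for i in range(n):
            counter += 1
            rows.append(
                {
                    "patient_id": f"S{counter:03d}",
                    "group": group,
                    "age": round(float(ages[i]), 1),
                    "sex_male": bool(rng.random() < prevs["sex_male"]),
                    "hypertension": bool(rng.random() < prevs["hypertension"]),
                    "macular_edema": bool(rng.random() < prevs["macular_edema"]),
                    "prp": bool(rng.random() < prevs["prp"]),
                    "cataract_cortical": int(rng.choice(3, p=grades)),
                    "cataract_nuclear": int(rng.choice(3, p=grades)),
                    "cataract_posterior": int(rng.choice(3, p=grades)),
                    "phakic": bool(rng.random() < 0.8),
                }
            )
    return pd.DataFrame(rows).set_index("patient_id")


def generate_profiling_matrices(
    design: CohortDesign,
    truth: GroundTruth,
    *,
    protein_universe: Sequence[str] | None = None,
    n_proteins: int = 300,
    baseline_mean: float = 20.0,
    baseline_sd: float = 2.0,
    noise_sd: float = 0.3,
    protein_platform_shift_sd: float = 0.3,
) -> tuple[IntensityMatrix, IntensityMatrix]:
    """Pooled LFQ and duplicate-channel TMT profiling matrices.

    Log2 intensity = protein baseline + cumulative group effect (true
    markers only) + platform location shift (+ a per-protein platform
    offset) + Gaussian noise scaled by the platform's noise factor.  The
    LFQ matrix has one pooled column per group and abundance-dependent
    missingness (detection probability logistic in the true log2
    abundance); the TMT matrix has two replicate channels per group and
    no missingness.
    """
    if protein_universe is None:
        protein_universe = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    universe = list(protein_universe)
    unknown = set(truth.true_marker_effects) - set(universe)
    if unknown:
        raise ValueError(f"truth references proteins absent from universe: {sorted(unknown)}")
    rng = _rng(design, 2)
    G = len(universe)
    baseline = rng.normal(baseline_mean, baseline_sd, size=G)
    effects = np.array(
        [[truth.group_effect(p, g) for g in GROUPS] for p in universe]
    )  # G x 3

    def platform_values(platform: str, n_reps: int) -> np.ndarray:
        loc, scale = truth.batch_shifts.get(platform, (0.0, 1.0))
        prot_shift = rng.normal(0.0, protein_platform_shift_sd, size=G) if loc or scale != 1 else np.zeros(G)
        cols = []
        for gi in range(len(GROUPS)):
            mu = baseline + effects[:, gi] + loc + prot_shift
            for _ in range(n_reps):
                cols.append(mu + scale * rng.normal(0.0, noise_sd, size=G))
        return np.column_stack(cols)

    lfq_vals = platform_values("LFQ", 1)
    lfq_cols = [f"LFQ_{g}" for g in GROUPS]
    midpoint, slope = truth.missingness_params
    true_abund = baseline[:, None] + effects  # G x 3, pre-noise abundance
    if slope > 0:
        p_detect = 1.0 / (1.0 + np.exp(-slope * (true_abund - midpoint)))
    else:
        p_detect = np.ones_like(true_abund)
    detected = rng.random(size=true_abund.shape) < p_detect
    lfq_vals = np.where(detected, lfq_vals, np.nan)
    lfq = IntensityMatrix(
        values=pd.DataFrame(lfq_vals, index=universe, columns=lfq_cols),
        platform="LFQ",
        group_labels=pd.Series(dict(zip(lfq_cols, GROUPS))),
    )

    # TMT channel layout mirrors the 6-plex labeling: two channels per group.
    channels = {"NPDR": (126, 129), "PDR": (127, 130), "NVG": (128, 131)}
    tmt_vals = platform_values("TMT", 2)
    tmt_cols = []
    tmt_groups = {}
    k = 0
    order = []
    for gi, g in enumerate(GROUPS):
        for ch in channels[g]:
            name = f"TMT_{ch}"
            tmt_cols.append(name)
            tmt_groups[name] = g
            order.append(k)
            k += 1
    tmt = IntensityMatrix(
        values=pd.DataFrame(tmt_vals[:, order], index=universe, columns=tmt_cols),
        platform="TMT",
        group_labels=pd.Series(tmt_groups),
    )
    return lfq, tmt


_PEPTIDE_ALPHABET = "ADEFGHILNPQSTVWY"  # no C/M (eligibility) or K/R (internal)


def marker_transitions(
    proteins: Sequence[str],
    *,
    peptides_per_protein: int = 2,
    length: int = 9,
    seed: int = 12345,
) -> list[TransitionRecord]:
    """Deterministic synthetic tryptic peptides + transitions for markers.

    Draws random eligible peptide sequences (canonical residues, no
    Cys/Met, C-terminal R) until each yields three product ions above
    the precursor m/z, mimicking what a transition designer would emit
    for real marker proteins.
    """
    rng = np.random.default_rng(seed)
    records: list[TransitionRecord] = []
    seen: set[str] = set()
    for protein in proteins:
        made = 0
        while made < peptides_per_protein:
            seq = "".join(rng.choice(list(_PEPTIDE_ALPHABET), size=length - 1)) + "R"
            if seq in seen:
                continue
            recs = select_transitions(Peptide(seq, frozenset({protein})))
            if recs:
                seen.add(seq)
                records.extend(recs)
                made += 1
    return records


def spikein_transitions() -> list[TransitionRecord]:
    """Designed transitions for the four beta-galactosidase spike-ins."""
    records = []
    for pep in SPIKEIN_PEPTIDES:
        records.extend(select_transitions(Peptide(pep, frozenset({"BGAL_ECOLI"}))))
    return records


def generate_mrm_peak_areas(
    design: CohortDesign,
    transitions: Sequence[TransitionRecord],
    truth: GroundTruth,
    *,
    clinical: pd.DataFrame | None = None,
    peptide_base_mean: float = 17.0,
    peptide_base_sd: float = 1.0,
    transition_offset_sd: float = 1.0,
    biological_sd: float = 0.5,
    loading_sd: float = 0.25,
    spikein_noise_fraction: float = 0.3,
    poor_samples: Sequence[str] = (),
    poor_fraction: float = 0.6,
    detection_floor: float = 1e3,
) -> pd.DataFrame:
    """Long-format MRM peak areas with technical duplicates and spike-ins.

    Log2 area = peptide baseline + transition offset + cumulative group
    effect of the parent protein + per-sample biological deviation +
    per-sample loading factor + duplicate noise.  The loading factor is
    log-normal (normal on log2) so spike-in normalization is its exact
    inverse.  Spike-in peptides sit at ``truth.spikein_level`` plus the
    loading factor and small duplicate noise (a fraction
    ``spikein_noise_fraction`` of the analyte duplicate noise: the
    concentrated exogenous standard is more reproducible than low-level
    analytes).  In designated poor
    samples a fraction ``poor_fraction`` of target transitions is forced
    below the detection floor.
    """
    if not transitions:
        raise ValueError("transition list must be non-empty")
    ids = [f"{t.peptide_sequence}_{t.ion_type}{t.fragment_index}" for t in transitions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transition identifiers")
    if clinical is None:
        clinical = generate_clinical_table(design)
    rng = _rng(design, 3)
    # duplicate CV -> log2 replicate noise SD (CV of a log-normal ~ sigma_ln)
    rep_sd = truth.cv_target / np.log(2)
    spike_set = set(SPIKEIN_PEPTIDES)

    peptides = sorted({(t.protein_id, t.peptide_sequence) for t in transitions})
    pep_base = {}
    for protein, pep in peptides:
        if pep in spike_set:
            pep_base[pep] = truth.spikein_level
        else:
            pep_base[pep] = rng.normal(peptide_base_mean, peptide_base_sd)
    trans_offset = {
        tid: rng.normal(0.0, transition_offset_sd) for tid in ids
    }
    samples = list(clinical.index)
    loading = {s: rng.normal(0.0, loading_sd) for s in samples}
    bio_dev = {
        (s, pep): rng.normal(0.0, biological_sd)
        for s in samples
        for _, pep in peptides
        if pep not in spike_set
    }
    poor = set(poor_samples)
    rows = []
    for s in samples:
        group = clinical.loc[s, "group"]
        poor_hits = set()
        if s in poor:
            target_ids = [
                tid for tid, t in zip(ids, transitions)
                if t.peptide_sequence not in spike_set
            ]
            n_poor = int(round(poor_fraction * len(target_ids)))
            poor_hits = set(rng.choice(target_ids, size=n_poor, replace=False))
        for tid, t in zip(ids, transitions):
            pep = t.peptide_sequence
            is_spike = pep in spike_set
            mu = pep_base[pep] + trans_offset[tid] + loading[s]
            noise_sd = rep_sd * spikein_noise_fraction if is_spike else rep_sd
            if not is_spike:
                mu += truth.group_effect(t.protein_id, group) + bio_dev[(s, pep)]
            for rep in (1, 2):
                log2_area = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                area = float(2.0**log2_area)
                if tid in poor_hits:
                    area = float(rng.uniform(0.0, detection_floor * 0.5))
                rows.append(
                    {
                        "sample": s,
                        "replicate": rep,
                        "protein": t.protein_id,
                        "peptide": pep,
                        "transition": tid,
                        "area": area,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text output
# ---------------------------------------------------------------------------

def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, na_rep="NA")


def write_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, na_rep="NA")


def write_annotations(matrices: Sequence[IntensityMatrix], path: str | Path) -> None:
    rows = []
    for m in matrices:
        for col in m.values.columns:
            rows.append(
                {"sample": col, "group": m.group_labels[col], "platform": m.platform}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_peak_areas(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, na_rep="NA")


def write_truth_manifest(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_marker_effects": {
            protein: {f"{case}_vs_{control}": fc for (case, control), fc in eff.items()}
            for protein, eff in truth.true_marker_effects.items()
        },
        "batch_shifts": truth.batch_shifts,
        "missingness_params": list(truth.missingness_params),
        "cv_target": truth.cv_target,
        "spikein_level": truth.spikein_level,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
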