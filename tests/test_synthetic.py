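"""Synthetic cohort generator: design invariants, planted structure,
reproducibility, and null calibration."""

import numpy as np
import pandas as pd
import pytest

from aquamark import mrm, profiling, synthetic
from aquamark.synthetic import (
    CohortDesign,
    GroundTruth,
    generate_clinical_table,
    generate_mrm_peak_areas,
    generate_profiling_matrices,
)
from aquamark.transitions import SPIKEIN_PEPTIDES


class TestClinicalTable:
    def test_group_counts_match_design(self, small_design):
        table = generate_clinical_table(small_design)
        assert len(table) == 84
        counts = table["group"].value_counts()
        assert counts["NPDR"] == 37 and counts["PDR"] == 38 and counts["NVG"] == 9

    def test_degenerate_prevalence_forces_covariate(self):
        design = CohortDesign(seed=3)
        for g in design.covariate_prevalences:
            design.covariate_prevalences[g]["sex_male"] = 1.0
        table = generate_clinical_table(design)
        assert table["sex_male"].all()

    def test_ages_within_bounds(self, small_design):
        table = generate_clinical_table(small_design)
        assert table["age"].between(30, 90).all()

    def test_hypertension_prevalence_calibrated(self):
        """Across replicates the empirical prevalence matches the design."""
        target = (21 * 2 + 5) / 84  # mixture of per-group prevalences
        hits = total = 0
        for seed in range(200):
            t = generate_clinical_table(CohortDesign(seed=seed))
            hits += t["hypertension"].sum()
            total += len(t)
        se = np.sqrt(target * (1 - target) / total)
        assert abs(hits / total - target) < 3 * se

    def test_nonpositive_group_size_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(n_per_group={"NPDR": 0, "PDR": 38, "NVG": 9})

    def test_same_seed_bit_identical(self, small_design):
        a = generate_clinical_table(small_design)
        b = generate_clinical_table(CohortDesign(seed=small_design.seed))
        pd.testing.assert_frame_equal(a, b)


class TestProfilingMatrices:
    def test_zero_variation_gives_constant_rows(self, small_design):
        truth = GroundTruth(
            batch_shifts={"LFQ": (0.0, 1.0), "TMT": (0.0, 1.0)},
            missingness_params=(0.0, 1.0),  # midpoint far below abundances
        )
        lfq, tmt = generate_profiling_matrices(
            small_design, truth, n_proteins=50, noise_sd=0.0,
            protein_platform_shift_sd=0.0,
        )
        assert np.allclose(lfq.values.var(axis=1), 0.0)
        assert np.allclose(tmt.values.var(axis=1), 0.0)
        assert not lfq.values.isna().any().any()

    def test_low_midpoint_means_no_missingness(self, small_design):
        truth = GroundTruth(missingness_params=(0.0, 50.0))
        lfq, _ = generate_profiling_matrices(small_design, truth, n_proteins=100)
        assert not lfq.values.isna().any().any()

    def test_high_midpoint_censors_low_abundance(self, small_design):
        truth = GroundTruth(missingness_params=(20.0, 2.0))
        lfq, _ = generate_profiling_matrices(small_design, truth, n_proteins=300)
        assert lfq.values.isna().mean().mean() > 0.2

    def test_tmt_layout_two_channels_per_group(self, small_design, marker_truth):
        _, tmt = generate_profiling_matrices(
            small_design, marker_truth, protein_universe=["P0001", "P0002", "P0003"]
        )
        assert tmt.values.shape[1] == 6
        assert tmt.group_labels.value_counts().eq(2).all()
        assert not tmt.values.isna().any().any()

    def test_unknown_marker_protein_rejected(self, small_design):
        truth = GroundTruth(true_marker_effects={"NOPE": {("PDR", "NPDR"): 1.0}})
        with pytest.raises(ValueError):
            generate_profiling_matrices(small_design, truth, n_proteins=10)

    def test_null_tmt_call_rate_controlled(self, small_design):
        """With no planted effects the TMT rule fires at most ~alpha."""
        truth = GroundTruth(batch_shifts={"LFQ": (0.0, 1.0), "TMT": (0.0, 1.0)})
        rates = []
        for seed in range(5):
            d = CohortDesign(seed=seed)
            _, tmt = generate_profiling_matrices(d, truth, n_proteins=400)
            res = profiling.dep_call(tmt, ("PDR", "NPDR"))
            rates.append(np.mean([r.call for r in res]))
        assert np.mean(rates) <= 0.06


class TestMrmPeakAreas:
    def test_replicate_and_spikein_structure(self, small_design, marker_truth, marker_transition_list):
        peaks = generate_mrm_peak_areas(
            small_design, marker_transition_list, marker_truth
        )
        per = peaks.groupby(["sample", "transition"]).size()
        assert (per == 2).all()
        for pep in SPIKEIN_PEPTIDES:
            assert peaks[peaks["peptide"] == pep]["sample"].nunique() == 84

    def test_zero_cv_gives_identical_duplicates(self, small_design, marker_transition_list):
        truth = GroundTruth(cv_target=0.0)
        peaks = generate_mrm_peak_areas(small_design, marker_transition_list, truth)
        wide = peaks.pivot_table(
            index=["sample", "transition"], columns="replicate", values="area"
        )
        assert np.allclose(wide[1], wide[2], rtol=1e-12)

    def test_loading_factor_scales_spikeins(self, small_design, marker_truth, marker_transition_list):
        peaks = generate_mrm_peak_areas(
            small_design, marker_transition_list, marker_truth, loading_sd=0.0
        )
        spikes = peaks[peaks["peptide"].isin(SPIKEIN_PEPTIDES)]
        geo = (
            spikes.assign(l=np.log2(spikes["area"]))
            .groupby("sample")["l"]
            .mean()
        )
        # zero loading spread -> every sample's spike-in geometric mean agrees
        assert geo.std() < 0.05

    def test_normalization_shrinks_spikein_spread(self, small_design, marker_truth, marker_transition_list):
        peaks = generate_mrm_peak_areas(
            small_design, marker_transition_list, marker_truth, loading_sd=0.25
        )
        normalized = mrm.normalize_spikein(peaks)
        spikes = normalized[normalized["is_spikein"]]
        cv_before = spikes.groupby("transition")["raw_area"].apply(
            lambda a: a.std() / a.mean()
        )
        cv_after = spikes.groupby("transition")["area"].apply(
            lambda a: a.std() / a.mean()
        )
        assert (cv_after / cv_before).median() < 0.2

    def test_duplicate_transition_ids_rejected(self, small_design, marker_truth, marker_transition_list):
        with pytest.raises(ValueError):
            generate_mrm_peak_areas(
                small_design,
                marker_transition_list + marker_transition_list[:1],
                marker_truth,
            )

    def test_empty_transition_list_rejected(self, small_design, marker_truth):
        with pytest.raises(ValueError):
            generate_mrm_peak_areas(small_design, [], marker_truth)

    def test_same_seed_bit_identical(self, small_design, marker_truth, marker_transition_list):
        a = generate_mrm_peak_areas(small_design, marker_transition_list, marker_truth)
        b = generate_mrm_peak_areas(small_design, marker_transition_list, marker_truth)
        pd.testing.assert_frame_equal(a, b)


class TestNullCalibration:
    def test_wilcoxon_false_positive_rate_under_null(self, marker_transition_list):
        """No planted effects: per-peptide Wilcoxon p < 0.05 at ~nominal rate."""
        from aquamark.markers import wilcoxon_rank_sum

        truth = GroundTruth()  # no effects
        p_values = []
        for seed in range(12):
            design = CohortDesign(seed=seed)
            clinical = generate_clinical_table(design)
            peaks = generate_mrm_peak_areas(
                design, marker_transition_list, truth, clinical=clinical
            )
            q, _ = mrm.run_cascade(peaks)
            groups = clinical["group"]
            for pep, sub in q.groupby("peptide"):
                s = sub.set_index("sample")["quantity"]
                labels = groups.loc[s.index]
                x = s[labels == "PDR"].to_numpy()
                y = s[labels == "NPDR"].to_numpy()
                if len(x) > 2 and len(y) > 2:
                    p_values.append(wilcoxon_rank_sum(x, y)[1])
        rate = np.mean(np.asarray(p_values) < 0.05)
        se = np.sqrt(0.05 * 0.95 / len(p_values))
        assert rate < 0.05 + 3 * se
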