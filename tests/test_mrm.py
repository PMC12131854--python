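"""MRM QC cascade: spike-in normalization, detection, sample/CV filters,
peptide roll-up."""

import numpy as np
import pandas as pd
import pytest

from aquamark import mrm
from aquamark.transitions import SPIKEIN_PEPTIDES


def _table(rows):
    return pd.DataFrame(rows, columns=mrm.PEAK_COLUMNS)


def _spike_rows(sample, level=5e5, factor=1.0):
    rows = []
    for pep in SPIKEIN_PEPTIDES:
        for rep in (1, 2):
            rows.append([sample, rep, "BGAL", pep, f"{pep}_y5", level * factor])
    return rows


def _target_rows(sample, peptide="TARGETPEP", protein="P1", areas=(5e4, 6e4, 7e4), factor=1.0):
    rows = []
    for i, area in enumerate(areas):
        for rep in (1, 2):
            rows.append([sample, rep, protein, peptide, f"{peptide}_y{i+3}", area * factor])
    return rows


class TestNormalizeSpikein:
    def test_equal_spikeins_leave_table_unchanged(self):
        t = _table(_spike_rows("A") + _spike_rows("B") + _target_rows("A") + _target_rows("B"))
        out = mrm.normalize_spikein(t)
        assert np.allclose(out["area"], out["raw_area"])

    def test_doubled_spikeins_halve_that_sample(self):
        t = _table(
            _spike_rows("A") + _target_rows("A")
            + _spike_rows("B", factor=2.0) + _target_rows("B", factor=1.0)
            + _spike_rows("C") + _target_rows("C")
        )
        out = mrm.normalize_spikein(t)
        a = out[(out["sample"] == "A") & ~out["is_spikein"]]["area"]
        b = out[(out["sample"] == "B") & ~out["is_spikein"]]["area"]
        assert np.allclose(b.to_numpy(), a.to_numpy() / 2.0)

    def test_within_sample_ratios_preserved(self, rng):
        t = _table(_spike_rows("A", factor=1.7) + _target_rows("A", areas=(1e4, 3e4, 9e4)))
        out = mrm.normalize_spikein(t)
        targ = out[~out["is_spikein"]].sort_values("transition")
        areas = targ[targ["replicate"] == 1]["area"].to_numpy()
        raw = targ[targ["replicate"] == 1]["raw_area"].to_numpy()
        assert np.allclose(areas / areas[0], raw / raw[0])

    def test_sample_without_spikeins_excluded(self):
        report = mrm.QCReport()
        t = _table(_spike_rows("A") + _target_rows("A") + _target_rows("B"))
        out = mrm.normalize_spikein(t, report=report)
        assert "B" not in set(out["sample"])
        assert "B" in report.excluded_samples

    def test_duplicate_rows_rejected(self):
        rows = _spike_rows("A")
        t = _table(rows + rows[:1])
        with pytest.raises(ValueError):
            mrm.normalize_spikein(t)


class TestDetectionFilter:
    def test_strict_threshold_boundary(self):
        t = _table(
            _spike_rows("A")
            + [["A", 1, "P1", "PEP", "PEP_y3", 1000.0],
               ["A", 2, "P1", "PEP", "PEP_y3", 1000.1]]
        )
        out = mrm.detection_filter(mrm.normalize_spikein(t))
        flags = out[out["transition"] == "PEP_y3"].sort_values("replicate")["detected"]
        assert flags.tolist() == [False, True]

    def test_all_zero_sample_detects_nothing(self):
        t = _table(
            _spike_rows("A")
            + [["A", r, "P1", "PEP", f"PEP_y{i}", 0.0] for r in (1, 2) for i in (3, 4, 5)]
        )
        out = mrm.detection_filter(mrm.normalize_spikein(t))
        assert not out[~out["is_spikein"]]["detected"].any()


class TestSampleFilter:
    def _with_detected(self, n_detected, n_total=10, sample="A"):
        rows = _spike_rows(sample)
        for i in range(n_total):
            area = 5e4 if i < n_detected else 10.0
            for rep in (1, 2):
                rows.append([sample, rep, "P1", "PEP", f"T{i}", area])
        return rows

    def test_forty_percent_detection_excluded(self):
        t = _table(self._with_detected(4) + self._with_detected(10, sample="B"))
        flagged = mrm.detection_filter(mrm.normalize_spikein(t))
        out, report = mrm.sample_filter(flagged)
        assert set(out["sample"]) == {"B"}
        assert "A" in report.excluded_samples

    def test_exactly_half_detected_retained(self):
        t = _table(self._with_detected(5) + self._with_detected(10, sample="B"))
        flagged = mrm.detection_filter(mrm.normalize_spikein(t))
        out, _ = mrm.sample_filter(flagged)
        assert set(out["sample"]) == {"A", "B"}

    def test_fully_detected_cohort_untouched(self):
        t = _table(self._with_detected(10) + self._with_detected(10, sample="B"))
        flagged = mrm.detection_filter(mrm.normalize_spikein(t))
        out, report = mrm.sample_filter(flagged)
        assert len(report.excluded_samples) == 0
        assert len(out) == len(flagged)


class TestCvFilter:
    def _dup_table(self, a1, a2, n_samples=4):
        rows = []
        for s in range(n_samples):
            rows += _spike_rows(f"S{s}")
            rows.append([f"S{s}", 1, "P1", "PEP", "T0", a1])
            rows.append([f"S{s}", 2, "P1", "PEP", "T0", a2])
        return _table(rows)

    def test_moderate_cv_passes(self):
        # duplicates (900, 1100): CV = 141.4/1000 ~ 0.14
        flagged = mrm.detection_filter(
            mrm.normalize_spikein(self._dup_table(900.0, 1100.0)),
            area_threshold=100.0,
        )
        out, report = mrm.cv_filter(flagged)
        assert "T0" in set(out["transition"])
        assert report.transition_cv["T0"] == pytest.approx(0.1414, abs=1e-3)

    def test_identical_duplicates_pass(self):
        flagged = mrm.detection_filter(mrm.normalize_spikein(self._dup_table(5e4, 5e4)))
        out, report = mrm.cv_filter(flagged)
        assert report.transition_cv["T0"] == 0.0

    def test_wild_duplicates_removed(self):
        # (500, 1500): CV = 707/1000 ~ 0.71
        flagged = mrm.detection_filter(
            mrm.normalize_spikein(self._dup_table(500.0, 1500.0)),
            area_threshold=100.0,
        )
        out, report = mrm.cv_filter(flagged)
        assert "T0" not in set(out["transition"])
        assert "T0" in report.excluded_transitions

    def test_sparse_transition_removed_for_insufficient_observations(self):
        flagged = mrm.detection_filter(
            mrm.normalize_spikein(self._dup_table(5e4, 5e4, n_samples=2))
        )
        out, report = mrm.cv_filter(flagged, min_samples=3)
        assert report.excluded_transitions["T0"] == "insufficient observations"


class TestPeptideQuantity:
    def _quant_table(self, n_transitions, areas=None):
        areas = areas or [5e4] * n_transitions
        rows = []
        for s in ("A", "B", "C"):
            rows += _spike_rows(s)
            for i in range(n_transitions):
                for rep in (1, 2):
                    rows.append([s, rep, "P1", "PEP", f"T{i}", areas[i]])
        return _table(rows)

    def test_two_transitions_never_quantified(self):
        flagged = mrm.detection_filter(mrm.normalize_spikein(self._quant_table(2)))
        q, _ = mrm.peptide_quantity(flagged)
        assert q.empty

    def test_quantity_is_sum_of_transitions(self):
        areas = [1e4, 2e4, 3e4]
        flagged = mrm.detection_filter(
            mrm.normalize_spikein(self._quant_table(3, areas))
        )
        q, _ = mrm.peptide_quantity(flagged)
        assert np.allclose(q["quantity"], sum(areas))

    def test_cascade_counts_reconcile(self, small_design, marker_truth, marker_transition_list):
        from aquamark import synthetic

        peaks = synthetic.generate_mrm_peak_areas(
            small_design, marker_transition_list, marker_truth
        )
        q, report = mrm.run_cascade(peaks)
        assert report.n_input_rows == len(peaks)
        assert report.stage_counts["after_cv_filter"] <= report.stage_counts[
            "after_sample_filter"
        ]
        assert not q.empty

    def test_refiltering_filtered_table_is_noop(self, small_design, marker_truth, marker_transition_list):
        """Each stage only removes rows; rerunning the filters removes nothing."""
        from aquamark import synthetic

        peaks = synthetic.generate_mrm_peak_areas(
            small_design, marker_transition_list, marker_truth,
            poor_samples=["S001"],
        )
        t = mrm.detection_filter(mrm.normalize_spikein(peaks))
        t, _ = mrm.sample_filter(t)
        t, _ = mrm.cv_filter(t)
        t2, _ = mrm.sample_filter(t)
        t3, _ = mrm.cv_filter(t2)
        assert len(t3) == len(t)


def test_poor_sample_is_excluded_by_cascade(small_design, marker_truth, marker_transition_list):
    from aquamark import synthetic

    peaks = synthetic.generate_mrm_peak_areas(
        small_design, marker_transition_list, marker_truth,
        poor_samples=["S001", "S002"], poor_fraction=0.7,
    )
    _, report = mrm.run_cascade(peaks)
    assert {"S001", "S002"} <= set(report.excluded_samples)
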