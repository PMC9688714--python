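"""Bench-validation statistics: clone/peak frequencies, detection
summaries, one-tailed t-tests, ddCt fold changes, clinical-course metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from editome import (clone_editing_frequency, peak_editing_frequency,
                     detection_summary, one_tailed_unpaired_t,
                     ddct_fold_change, clinical_course_stats,
                     compare_clinical_groups)
from editome.datasets import b2m_clone_detections


class TestEditingFrequencies:
    @pytest.mark.parametrize("edited,total,expected", [
        (2, 10, [0.20]), (0, 30, [0.0]), ([4, 1], [20, 20], [0.20, 0.05]),
    ])
    def test_clone_fraction(self, edited, total, expected):
        assert clone_editing_frequency(edited, total) == pytest.approx(expected)

    def test_zero_total_clones_rejected(self):
        with pytest.raises(ValueError):
            clone_editing_frequency(0, 0)

    @pytest.mark.parametrize("a,g,expected", [
        (70, 30, 0.30), (0, 50, 1.0), (50, 50, 0.50),
    ])
    def test_peak_ratio(self, a, g, expected):
        assert peak_editing_frequency(a, g) == pytest.approx([expected])

    def test_both_peaks_zero_rejected(self):
        with pytest.raises(ValueError):
            peak_editing_frequency(0, 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(freq=st.floats(0.05, 0.95))
    def test_clone_and_peak_estimators_agree_in_expectation(self, freq):
        # clones as Bernoulli draws, peaks proportional to allele fractions
        rng = np.random.default_rng(12345)
        n = 4000
        clone_est = clone_editing_frequency(rng.binomial(n, freq), n)[0]
        peak_est = peak_editing_frequency(100 * (1 - freq), 100 * freq)[0]
        assert clone_est == pytest.approx(freq, abs=3 * np.sqrt(freq * (1 - freq) / n))
        assert peak_est == pytest.approx(freq, abs=1e-12)


class TestDetectionSummary:
    @pytest.mark.parametrize("tissue,condition,verified,predicted", [
        ("microglia", "naive", 3, 6),
        ("microglia", "acute", 9, 19),
        ("brain", "naive", 3, 3),
        ("brain", "acute", 11, 11),
    ])
    def test_published_detection_lists(self, tissue, condition,
                                       verified, predicted):
        table, n_verified = detection_summary(
            b2m_clone_detections(tissue, condition))
        assert n_verified == verified
        assert len(table) == predicted

    def test_all_zero_clones_verify_nothing(self):
        clones = pd.DataFrame({
            "position": ["p1"] * 3 + ["p2"] * 3, "replicate": [1, 2, 3] * 2,
            "edited": 0, "total": 20})
        table, n_verified = detection_summary(clones)
        assert n_verified == 0 and not table.verified.any()


class TestOneTailedT:
    def test_identical_groups_give_half(self):
        res = one_tailed_unpaired_t([0.2, 0.2], [0.2, 0.2])
        assert res.p == 0.5 and res.degenerate

    def test_hand_computed_case(self):
        res = one_tailed_unpaired_t([0.1, 0.2, 0.3], [0.4, 0.5, 0.6],
                                    direction="greater")
        assert res.t == pytest.approx(3.674, abs=1e-3)
        assert res.df == 4
        assert res.p == pytest.approx(0.0106, abs=2e-4)

    def test_swapped_direction_is_complement(self):
        res = one_tailed_unpaired_t([0.1, 0.2, 0.3], [0.4, 0.5, 0.6],
                                    direction="less")
        assert res.p == pytest.approx(1 - 0.0106, abs=2e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=8),
           st.lists(st.floats(-5, 5), min_size=2, max_size=8))
    def test_direction_complementarity(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        pg = one_tailed_unpaired_t(a, b, "greater").p
        pl = one_tailed_unpaired_t(a, b, "less").p
        assert pg + pl == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_unequal_means_is_degenerate(self):
        res = one_tailed_unpaired_t([0.1, 0.1], [0.5, 0.5])
        assert res.degenerate and res.p == 0.0
        res_rev = one_tailed_unpaired_t([0.5, 0.5], [0.1, 0.1])
        assert res_rev.degenerate and res_rev.p == 1.0


class TestDdct:
    def _table(self, dcts):
        return pd.DataFrame({"Ct_target": [20 + d for d in dcts],
                             "Ct_reference": [20.0] * len(dcts)})

    def test_zero_ddct_is_unit_fold(self):
        assert ddct_fold_change(self._table([1, 1]), self._table([1, 1]))[0] \
            == pytest.approx(1.0)

    def test_two_cycle_gain_is_fourfold(self):
        fold, _ = ddct_fold_change(self._table([2]), self._table([4]))
        assert fold == pytest.approx(4.0)

    def test_three_cycle_loss_is_eighth(self):
        fold, _ = ddct_fold_change(self._table([5]), self._table([2]))
        assert fold == pytest.approx(0.125)

    def test_missing_reference_ct_dropped_with_warning(self):
        case = pd.DataFrame({"Ct_target": [22.0, 23.0],
                             "Ct_reference": [20.0, np.nan]})
        fold, warnings = ddct_fold_change(case, self._table([2]))
        assert warnings and "dropped" in warnings[0]
        assert fold == pytest.approx(1.0)


class TestClinicalCourse:
    def _course(self, animal, group, days, scores):
        return pd.DataFrame({"animal": animal, "group": group,
                             "day": days, "score": scores})

    def test_hand_computed_course(self):
        df = self._course("m1", "wt", range(10, 16), [0, 0, 1, 2, 3, 3])
        table, groups = clinical_course_stats(df)
        row = table.iloc[0]
        assert row.max_score == 3 and row.day_onset == 12 and row.auc == 7.5
        assert groups[0].mms == 3.0 and groups[0].n_onset == 1

    def test_all_zero_course_has_no_onset(self):
        df = self._course("m1", "wt", range(7, 12), [0] * 5)
        table, groups = clinical_course_stats(df)
        assert table.iloc[0].max_score == 0 and table.iloc[0].auc == 0
        assert pd.isna(table.iloc[0].day_onset)
        assert groups[0].ddo is None and groups[0].n_onset == 0

    def test_auc_invariant_to_interpolated_days(self):
        days = [7, 9, 11, 15]
        scores = [0.0, 2.0, 3.0, 1.0]
        df1 = self._course("m1", "wt", days, scores)
        # insert linearly interpolated day 13 (score 2.0): AUC unchanged
        df2 = self._course("m1", "wt", [7, 9, 11, 13, 15],
                           [0.0, 2.0, 3.0, 2.0, 1.0])
        auc1 = clinical_course_stats(df1)[0].iloc[0].auc
        auc2 = clinical_course_stats(df2)[0].iloc[0].auc
        assert auc1 == pytest.approx(auc2)

    def test_identical_groups_compare_at_p_one(self):
        frames = []
        for group in ("wt", "ko"):
            for animal in ("a", "b"):
                frames.append(self._course(f"{group}-{animal}", group,
                                           range(7, 12), [0, 1, 2, 2, 3]))
        table, _ = clinical_course_stats(pd.concat(frames))
        res = compare_clinical_groups(table, "wt", "ko")
        assert res.p == 1.0

    def test_unsorted_days_rejected(self):
        df = self._course("m1", "wt", [7, 7, 8], [0, 1, 1])
        with pytest.raises(ValueError, match="strictly increasing"):
            clinical_course_stats(df)
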