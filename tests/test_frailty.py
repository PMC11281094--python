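"""Frailty phenotype scoring, ROC cutoffs, the four-range map, effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sixmwt.frailty import (
    FRAIL,
    NON_FRAIL,
    PRE_FRAIL,
    FrailtyRange,
    classify_range,
    cohens_d,
    group_compare,
    jchs_score,
    range_occupancy,
    roc_cutoff,
)
from sixmwt.types import AnalysisConfig, SubjectRecord


def _subject(weight_loss=False, exhaustion=False, low_activity=False,
             handgrip=35.0, speed=1.3, gender=1):
    return SubjectRecord(
        subject_id="s", gender=gender, handgrip=handgrip, speed5m=speed,
        q_weight_loss=weight_loss, q_exhaustion=exhaustion,
        q_low_activity=low_activity,
    )


def pair_count_auc(scores, labels):
    """O(n²) oracle: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestJCHS:
    def test_all_items_negative_is_non_frail(self):
        res = jchs_score(_subject())
        assert res.n == 0 and res.category == NON_FRAIL

    def test_weak_grip_slow_gait_exhaustion_is_frail(self):
        res = jchs_score(_subject(exhaustion=True, handgrip=25.9, speed=0.96))
        assert res.n == 3 and res.category == FRAIL
        assert res.weak_handgrip and res.slow_speed and res.exhaustion

    def test_female_handgrip_cutoff_is_18(self):
        assert jchs_score(_subject(handgrip=17.9, gender=2)).weak_handgrip
        assert not jchs_score(_subject(handgrip=25.0, gender=2)).weak_handgrip
        assert jchs_score(_subject(handgrip=25.0, gender=1)).weak_handgrip

    def test_exhaustive_32_combinations(self):
        # every item combination maps to the n>=3 / 1-2 / 0 category rule
        for items in itertools.product([False, True], repeat=5):
            wl, ex, pa, weak, slow = items
            res = jchs_score(_subject(
                weight_loss=wl, exhaustion=ex, low_activity=pa,
                handgrip=20.0 if weak else 35.0, speed=0.8 if slow else 1.3,
            ))
            n = sum(items)
            assert res.n == n
            expected = FRAIL if n >= 3 else (PRE_FRAIL if n >= 1 else NON_FRAIL)
            assert res.category == expected

    def test_missing_items_listed(self):
        subject = SubjectRecord(subject_id="s", gender=1, handgrip=30.0)
        with pytest.raises(ValueError) as err:
            jchs_score(subject)
        assert "speed5m" in str(err.value) and "q_exhaustion" in str(err.value)


class TestRocCutoff:
    def test_perfect_separation(self):
        res = roc_cutoff([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 3 < res.cutoff <= 10

    def test_uninformative_scores(self):
        res = roc_cutoff([5.0] * 8, [0, 1] * 4)
        assert res.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both label classes"):
            roc_cutoff([1, 2, 3], [1, 1, 1])

    def test_direction_less_flips_orientation(self):
        # low stride length predicts the weak-handgrip item
        sl = [0.45, 0.50, 0.55, 0.65, 0.70, 0.72]
        weak = [1, 1, 1, 0, 0, 0]
        res = roc_cutoff(sl, weak, direction="less")
        assert res.auc == 1.0
        assert 0.55 <= res.cutoff < 0.65

    @pytest.mark.parametrize("seed", range(30))
    def test_auc_equals_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        res = roc_cutoff(scores, labels)
        assert res.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_youden_point_on_curve(self):
        rng = np.random.default_rng(3)
        scores = np.r_[rng.normal(0, 1, 40), rng.normal(1.2, 1, 40)]
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        res = roc_cutoff(scores, labels)
        pred = scores >= res.cutoff
        sens = (pred & (labels == 1)).sum() / 40
        spec = (~pred & (labels == 0)).sum() / 40
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)


class TestClassifyRange:
    def test_published_group_means(self, config):
        assert classify_range(0.67, 2.12, config) is FrailtyRange.I   # non-frail means
        assert classify_range(0.52, 1.88, config) is FrailtyRange.III  # frail means

    def test_boundary_point_is_range_iii(self, config):
        # Range I is strict >, Range III inclusive <=
        assert classify_range(0.6, 2.0, config) is FrailtyRange.III

    def test_mixed_quadrants(self, config):
        assert classify_range(0.65, 1.9, config) is FrailtyRange.II
        assert classify_range(0.55, 2.2, config) is FrailtyRange.IV

    @settings(max_examples=300, derandomize=True)
    @given(
        sl=st.one_of(st.floats(0, 1.5), st.just(0.6)),
        sc=st.one_of(st.floats(0, 4.0), st.just(2.0)),
    )
    def test_partition_of_quarter_plane(self, sl, sc):
        # exactly one label, and it matches direct inequality evaluation
        label = classify_range(sl, sc)
        oracle = {
            (True, True): FrailtyRange.I, (True, False): FrailtyRange.II,
            (False, False): FrailtyRange.III, (False, True): FrailtyRange.IV,
        }[(sl > 0.6, sc > 2.0)]
        assert label is oracle


class TestCohensD:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert cohens_d(a, a) == 0.0

    def test_unit_sd_groups_recover_offset(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 10_000)
        b = rng.normal(0.8, 1.0, 10_000)
        assert cohens_d(a, b) == pytest.approx(0.8, abs=0.05)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 50), rng.normal(1, 2, 60)
        assert cohens_d(3 * a + 7, 3 * b + 7) == pytest.approx(cohens_d(a, b), rel=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([2.0, 2.0], [2.0, 2.0])


class TestGroupCompare:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(1.0, 0.1, 30)
        df = pd.DataFrame({
            "category": [FRAIL] * 30 + [PRE_FRAIL] * 30,
            "sl": np.r_[vals, vals],
        })
        out = group_compare(df, ["sl"])
        assert out.p_value.iloc[0] == pytest.approx(1.0)
        assert out.cohens_d.iloc[0] == 0.0

    def test_power_at_published_cadence_contrast(self):
        # frail vs pre-frail cadence (1.88+-0.09 vs 2.15+-0.17, n=8/23)
        # separates at p<0.05 in at least 95% of 200 replicates
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            df = pd.DataFrame({
                "category": [FRAIL] * 8 + [PRE_FRAIL] * 23,
                "sc": np.r_[rng.normal(1.88, 0.09, 8), rng.normal(2.15, 0.17, 23)],
            })
            hits += group_compare(df, ["sc"]).p_value.iloc[0] < 0.05
        assert hits / 200 >= 0.95

    def test_one_row_per_parameter_per_adjacent_pair(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "category": [FRAIL] * 10 + [PRE_FRAIL] * 10 + [NON_FRAIL] * 10,
            "sl": rng.normal(0.6, 0.1, 30),
            "sc": rng.normal(2.0, 0.2, 30),
        })
        out = group_compare(df, ["sl", "sc"])
        assert len(out) == 4  # 2 parameters x 2 adjacent pairs
        assert set(out.parameter) == {"sl", "sc"}

    def test_single_category_rejected(self):
        df = pd.DataFrame({"category": [FRAIL] * 5, "sl": np.arange(5.0)})
        with pytest.raises(ValueError, match="2 categories"):
            group_compare(df, ["sl"])


class TestRangeOccupancy:
    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "category": [FRAIL] * 20 + [NON_FRAIL] * 20,
            "sl": rng.uniform(0.3, 0.9, 40),
            "sc": rng.uniform(1.5, 2.5, 40),
        })
        table = range_occupancy(df)
        assert list(table.columns) == ["I", "II", "III", "IV"]
        np.testing.assert_allclose(table.sum(axis=1), 100.0)

    def test_cutoffs_follow_config(self):
        df = pd.DataFrame({"category": [FRAIL], "sl": [0.7], "sc": [1.9]})
        hi = range_occupancy(df, config=AnalysisConfig(cut_sl=0.65, cut_sc=1.8))
        assert hi.loc[FRAIL, "I"] == 100.0
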