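import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hrvkit.io import RRSeries
from hrvkit.segmentation import (
    SegmentCriteria,
    assess_stationarity,
    detect_ectopics,
    select_segments,
)


def series(rr, **kw):
    meta = dict(animal_id="m", genotype="WT", condition="basal")
    meta.update(kw)
    return RRSeries(rr=np.asarray(rr, float), **meta)


class TestDetectEctopics:
    def test_constant_series_has_no_ectopics(self):
        assert not detect_ectopics(np.full(50, 100.0), 2.0).any()

    def test_single_long_interval_is_flagged(self):
        # 20 x 100 ms + one 200 ms: mean ~104.8, sd ~21.8, and only the
        # 200 ms interval exceeds mean + 2 sd
        rr = np.array([100.0] * 20 + [200.0])
        mask = detect_ectopics(rr, 2.0)
        assert mask.sum() == 1 and mask[20]

    def test_deviation_just_under_threshold_not_flagged(self):
        # 20 x (+1), 20 x (-1) and one spike solved so the spike's
        # deviation is 1.9 sample SD — under the k = 2 threshold
        rr = 100.0 + np.array([1.0] * 20 + [-1.0] * 20 + [2.044])
        dev = np.abs(rr - rr.mean())
        ratio = dev.max() / rr.std(ddof=1)
        assert 1.85 < ratio < 1.95  # construction check
        assert not detect_ectopics(rr, 2.0).any()

    def test_statistics_are_single_pass(self):
        # one huge outlier inflates the SD enough to shelter a milder
        # one; re-estimation after removal would flag both
        rr = np.array([100.0] * 30 + [140.0, 400.0])
        mask = detect_ectopics(rr, 2.0)
        assert mask[31] and not mask[30]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_ectopics(np.array([1.0, 2.0]), 2.0)

    @given(
        hnp.arrays(np.float64, st.integers(5, 80), elements=st.floats(50, 200)),
        st.floats(0.5, 4.0),
        st.floats(-30, 30),
        st.floats(0.1, 10.0),
    )
    def test_shift_invariant_and_scale_equivariant(self, rr, k, shift, scale):
        base = detect_ectopics(rr, k)
        np.testing.assert_array_equal(base, detect_ectopics(rr + shift, k))
        np.testing.assert_array_equal(base, detect_ectopics(rr * scale, k))


class TestStationarity:
    def test_constant_series_passes(self):
        res = assess_stationarity(np.full(100, 100.0))
        assert res.passed and res.slope == 0.0

    def test_white_noise_passes(self, rng):
        passes = sum(
            assess_stationarity(100.0 + rng.normal(0, 3, 500)).passed
            for _ in range(100)
        )
        # fail needs significance AND >5% drift; noise has ~no drift
        assert passes >= 95

    def test_linear_ramp_fails(self, rng):
        n = 500
        ramp = 100.0 + 20.0 * np.arange(n) / n + rng.normal(0, 1.0, n)
        res = assess_stationarity(ramp)
        assert not res.passed
        assert res.drift_fraction > 0.05

    def test_small_but_significant_trend_still_passes(self, rng):
        # a 1% drift over the window is statistically detectable at low
        # noise yet practically negligible: the drift bound saves it
        n = 2000
        ramp = 100.0 + 1.0 * np.arange(n) / n + rng.normal(0, 0.5, n)
        res = assess_stationarity(ramp)
        assert res.p_value < 0.05 and res.passed

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            assess_stationarity(np.full(10, 100.0))


class TestSelectSegments:
    # "clean" = bounded noise whose extremes stay inside 2 SD (uniform:
    # max deviation ~1.73 SD), so the ectopic rule flags nothing

    def test_exactly_one_truncated_segment(self, rng):
        rr = series(100.0 + rng.uniform(-3, 3, 2100))
        segs = select_segments(rr, SegmentCriteria(), mode="remove")
        assert len(segs) == 1 and len(segs[0]) == 2048

    def test_two_segments_from_4200(self, rng):
        rr = series(100.0 + rng.uniform(-3, 3, 4200))
        segs = select_segments(rr, SegmentCriteria(), mode="remove")
        assert len(segs) == 2
        assert [s.offset for s in segs] == [0, 2048]

    def test_ectopic_laden_window_rejected(self, rng):
        base = 100.0 + rng.normal(0, 2, 2100)
        ect = rng.choice(2100, 100, replace=False)
        base[ect] = 200.0
        segs = select_segments(series(base), SegmentCriteria(), mode="remove")
        assert segs == []

    def test_nonstationary_window_rejected(self, rng):
        drift = 100.0 + 20.0 * np.arange(2048) / 2048 + rng.normal(0, 1, 2048)
        assert select_segments(series(drift), SegmentCriteria()) == []

    def test_floor_rule_on_clean_data(self, rng):
        n = 3 * 2048 + 517
        rr = series(100.0 + rng.uniform(-3, 3, n))
        segs = select_segments(rr, SegmentCriteria(), mode="remove")
        assert len(segs) == n // 2048

    def test_zero_replace_marks_masked_positions(self, rng):
        base = 100.0 + rng.normal(0, 2, 2200)
        base[50] = 220.0  # one clear ectopic inside a longer window
        segs = select_segments(series(base), SegmentCriteria(), mode="zero_replace",
                               window_size=2200)
        assert len(segs) == 1
        seg = segs[0]
        assert len(seg) == 2048
        assert seg.rr[50] == 0.0
        assert seg.ectopic_mask[50]

    def test_remove_mode_keeps_exact_clean_count(self, rng):
        base = 100.0 + rng.normal(0, 2, 2200)
        base[[3, 700, 1500]] = 230.0
        segs = select_segments(series(base), SegmentCriteria(), mode="remove",
                               window_size=2200)
        assert len(segs) == 1
        assert len(segs[0]) == 2048
        assert (segs[0].rr < 200).all()

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            select_segments(series(np.full(100, 100.0)), SegmentCriteria())

    def test_unknown_mode_rejected(self, rng):
        rr = series(100.0 + rng.normal(0, 2, 2048))
        with pytest.raises(ValueError):
            select_segments(rr, SegmentCriteria(), mode="drop")


class TestCriteriaValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(min_intervals=8), dict(outlier_sd=0.0), dict(stationarity_alpha=1.5)]
    )
    def test_invalid_criteria_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmentCriteria(**kwargs)
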