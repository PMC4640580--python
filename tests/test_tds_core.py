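import numpy as np
import pytest
from hypothesis import given, strategies as st

from tdsnet.containers import Hypnogram, NodeSeries
from tdsnet.tds import (
    DEFAULT_CONFIG,
    CorrelationFunction,
    SegmentationConfig,
    StabilityMask,
    TauSeries,
    circular_xcorr,
    find_tau0,
    modal_tau,
    normalize_segment,
    percent_tds,
    segment_count,
    stability_mask,
    tds_pair,
)

from oracles import (
    ref_circular_xcorr,
    ref_find_tau0,
    ref_stability,
    ref_tds_pair,
)


def series(values, **kw):
    return NodeSeries("x", np.asarray(values, dtype=float), **kw)


class TestSegmentCount:
    @pytest.mark.parametrize("N,expected", [(120, 3), (60, 1), (3600, 119)])
    def test_default_segmentation(self, N, expected):
        assert segment_count(N) == expected
        # closed form floor(2N/L) - 1 and explicit enumeration agree
        assert expected == 2 * N // 60 - 1
        starts = [s for s in range(0, N, 30) if s + 60 <= N]
        assert len(starts) == expected

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            segment_count(59)


class TestNormalizeSegment:
    def test_ramp_normalizes_to_zero_mean_unit_sd(self):
        z = normalize_segment(np.arange(60.0))
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9

    def test_constant_segment_invalid(self):
        assert normalize_segment(np.full(60, 2.5)) is None

    def test_missing_value_invalid(self):
        seg = np.arange(60.0)
        seg[10] = np.nan
        assert normalize_segment(seg) is None

    def test_affine_invariance(self, rng):
        seg = rng.standard_normal(60)
        assert np.allclose(normalize_segment(seg),
                           normalize_segment(3.2 * seg + 7.0))


class TestCircularXcorr:
    def test_autocorrelation_peaks_at_zero(self, rng):
        a = normalize_segment(rng.standard_normal(60))
        C = circular_xcorr(a, a)
        at0 = C.values[list(C.lags).index(0)]
        assert at0 == pytest.approx(1.0, abs=1e-9)
        assert at0 == pytest.approx(C.values.max(), abs=1e-12)

    @pytest.mark.parametrize("d", [1, 5, -7, 29, -30])
    def test_shift_theorem(self, rng, d):
        a = normalize_segment(rng.standard_normal(60))
        C = circular_xcorr(a, np.roll(a, d))
        stored = d if d >= -30 and d < 30 else ((d + 30) % 60) - 30
        assert find_tau0(C) == stored

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            a = normalize_segment(rng.standard_normal(60))
            b = normalize_segment(rng.standard_normal(60))
            C = circular_xcorr(a, b)
            assert np.allclose(
                C.values, ref_circular_xcorr(a, b, list(C.lags)), atol=1e-12)

    def test_bounded_for_normalized_segments(self, rng):
        a = normalize_segment(rng.standard_normal(60))
        b = normalize_segment(rng.standard_normal(60))
        assert np.all(np.abs(circular_xcorr(a, b).values) <= 1 + 1e-9)


class TestFindTau0:
    def test_unique_peak(self):
        lags = np.arange(-30, 30)
        vals = np.zeros(60)
        vals[list(lags).index(5)] = 0.9
        assert find_tau0(CorrelationFunction(vals, lags)) == 5

    def test_symmetric_tie_prefers_positive(self):
        lags = np.arange(-30, 30)
        vals = np.zeros(60)
        vals[list(lags).index(-3)] = 0.8
        vals[list(lags).index(3)] = -0.8  # |C| ties
        assert find_tau0(CorrelationFunction(vals, lags)) == 3

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            a = normalize_segment(rng.standard_normal(60))
            b = normalize_segment(rng.standard_normal(60))
            C = circular_xcorr(a, b)
            assert find_tau0(C) == ref_find_tau0(C.values, list(C.lags))


def _taus(values, valid=None):
    values = np.asarray(values, dtype=int)
    if valid is None:
        valid = np.ones(values.size, dtype=bool)
    return TauSeries(taus=values, valid=np.asarray(valid, dtype=bool),
                     seg_times=np.arange(values.size) * 30.0)


class TestStabilityMask:
    def test_constant_delays_all_stable(self):
        mask = stability_mask(_taus([4] * 8))
        assert mask.stable.all()

    def test_alternating_delays_never_stable(self):
        mask = stability_mask(_taus([0, 50] * 5))
        assert not mask.stable.any()

    def test_outlier_excluded_from_stable_window(self):
        mask = stability_mask(_taus([7, 7, 8, 30, 7, 6, 7, 7]))
        ref = ref_stability([7, 7, 8, 30, 7, 6, 7, 7], [True] * 8)
        assert np.array_equal(mask.stable, ref)
        assert not mask.stable[3]  # the 30 outlier is never labelled stable

    def test_short_series_all_unstable(self):
        assert not stability_mask(_taus([1, 1, 1])).stable.any()

    def test_invalid_segment_breaks_windows(self):
        valid = [True] * 10
        valid[4] = False
        mask = stability_mask(_taus([5] * 10, valid))
        ref = ref_stability([5] * 10, valid)
        assert np.array_equal(mask.stable, ref)
        assert not mask.stable[4]

    def test_matches_exhaustive_oracle_on_random_series(self, rng):
        for _ in range(25):
            taus = rng.integers(-30, 30, size=rng.integers(5, 40))
            valid = rng.random(taus.size) > 0.1
            mask = stability_mask(_taus(taus, valid))
            assert np.array_equal(mask.stable, ref_stability(taus, valid))

    def test_stable_implies_valid(self, rng):
        taus = rng.integers(-3, 3, size=30)
        valid = rng.random(30) > 0.3
        mask = stability_mask(_taus(taus, valid))
        assert not np.any(mask.stable & ~np.asarray(valid))


class TestPercentTDS:
    def test_fraction_arithmetic(self):
        stable = np.zeros(119, dtype=bool)
        stable[:40] = True
        assert percent_tds(StabilityMask(stable)) == pytest.approx(40 / 119)
        assert percent_tds(StabilityMask(np.ones(5, dtype=bool))) == 1.0
        assert percent_tds(StabilityMask(np.zeros(5, dtype=bool))) == 0.0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            percent_tds(StabilityMask(np.zeros(0, dtype=bool)))


class TestTdsPair:
    def test_circular_delayed_copy_fully_stable(self, rng):
        v = rng.standard_normal(1800)
        r = tds_pair(series(v), NodeSeries("y", np.roll(v, 10)))
        assert r.pct_overall == 1.0
        assert np.all(r.taus.taus == 10)

    def test_exchange_symmetry(self, rng):
        v = rng.standard_normal(900)
        w = 0.5 * np.roll(v, 4) + rng.standard_normal(900)
        rxy = tds_pair(series(v), series(w))
        ryx = tds_pair(series(w), series(v))
        assert rxy.pct_overall == ryx.pct_overall
        # tau series negated (mod the circular lag range)
        neg = (-ryx.taus.taus + 30) % 60 - 30
        assert np.array_equal(rxy.taus.taus, neg)

    def test_affine_invariance_exact(self, rng):
        v = rng.standard_normal(600)
        w = rng.standard_normal(600)
        base = tds_pair(series(v), series(w))
        for a, b in ((2.0, 5.0), (-1.5, 0.25)):
            r = tds_pair(series(a * v + b), series(w))
            assert r.pct_overall == base.pct_overall
            assert np.array_equal(r.taus.taus, base.taus.taus)

    def test_matches_straight_line_reference(self, rng):
        for _ in range(20):
            v = rng.standard_normal(600)
            w = np.roll(v, 3) + rng.standard_normal(600) * rng.uniform(0, 2)
            r = tds_pair(series(v), series(w))
            taus, valid, stable, pct = ref_tds_pair(v, w)
            assert np.array_equal(r.taus.taus, taus)
            assert np.array_equal(r.taus.valid, valid)
            assert np.array_equal(r.mask.stable, stable)
            assert r.pct_overall == pct

    def test_invalid_segments_excluded(self, rng):
        v = rng.standard_normal(600)
        w = np.roll(v, 2).copy()
        w[100:160] = np.nan
        r = tds_pair(series(v), NodeSeries("y", w))
        assert r.n_valid < r.n_segments
        ref = ref_tds_pair(v, w)
        assert np.array_equal(r.taus.valid, ref[1])
        assert r.pct_overall == ref[3]

    def test_noise_ladder_pct_monotone_in_mean(self, rng):
        # increasing i.i.d. noise on a delayed copy degrades stability
        sigmas = [0.0, 0.7, 1.5, 3.0]
        means, ses = [], []
        for s in sigmas:
            vals = []
            for _ in range(50):
                v = rng.standard_normal(600)
                w = np.roll(v, 5) + s * rng.standard_normal(600)
                vals.append(tds_pair(series(v), series(w)).pct_overall)
            means.append(np.mean(vals))
            ses.append(np.std(vals) / np.sqrt(len(vals)))
        for i in range(len(sigmas) - 1):
            tol = 2 * np.hypot(ses[i], ses[i + 1])
            assert means[i + 1] <= means[i] + tol

    def test_mismatched_or_short_inputs_error(self, rng):
        with pytest.raises(ValueError):
            tds_pair(series(np.zeros(100)), series(np.zeros(90)))
        with pytest.raises(ValueError):
            tds_pair(series(np.zeros(30)), series(np.zeros(30)))

    def test_stage_attribution_excludes_transition_segments(self, rng):
        v = rng.standard_normal(300)
        w = rng.standard_normal(300)
        # stages: 5 epochs LS, 5 epochs DS -> segment starting at 120 s
        # spans the 150 s transition and belongs to neither stage
        hyp = Hypnogram(stages=["LS"] * 5 + ["DS"] * 5)
        r = tds_pair(series(v), series(w), hypnogram=hyp)
        assert r.seg_stages == ["LS", "LS", "LS", "LS", None,
                                "DS", "DS", "DS", "DS"]
        assert set(r.pct_by_stage) == {"LS", "DS"}

    def test_minimum_stable_span_is_150_s(self):
        cfg = SegmentationConfig()
        assert cfg.min_stable_span == cfg.stab_window * cfg.step == 150


class TestModalTau:
    def test_mode_and_tie_rule(self):
        r = tds_pair(
            series(np.sin(np.arange(600)) + 0.001 * np.arange(600)),
            series(np.cos(np.arange(600))),
        )
        taus = r.taus.taus[r.taus.valid]
        vals, counts = np.unique(taus, return_counts=True)
        expected = sorted(vals[counts == counts.max()],
                          key=lambda t: (abs(t), t < 0))[0]
        assert modal_tau(r) == expected


@given(st.integers(min_value=60, max_value=4000))
def test_segment_count_matches_enumeration(N):
    starts = [s for s in range(0, N, 30) if s + 60 <= N]
    assert segment_count(N) == len(starts)


@given(st.lists(st.integers(min_value=-30, max_value=29),
                min_size=1, max_size=25))
def test_stability_matches_oracle_property(taus):
    mask = stability_mask(_taus(taus))
    assert np.array_equal(mask.stable, ref_stability(taus, [True] * len(taus)))
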