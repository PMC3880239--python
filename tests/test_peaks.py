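"""Peak candidacy, merit scoring, delimitation, intensity and validation."""

from dataclasses import replace

import numpy as np
import pytest

import caspike as cp
from conftest import make_bump_trace

FP = cp.FilterParams(9, 5)


def manual_trace(f, d1, d2, dt=1.0, n=4):
    """Hand-assembled FilteredTrace for contract-level checks."""
    return cp.FilteredTrace(np.asarray(f, float), np.asarray(d1, float),
                            np.asarray(d2, float), dt, n)


class TestCandidateMaxima:
    def test_monotone_ramp_has_no_candidates(self):
        trace = cp.filter_trace(np.linspace(0, 10, 40), FP, 1.0)
        assert cp.candidate_maxima(trace) == []

    def test_single_bump_localized_within_one_sample(self):
        """The apex is a candidate within +/-1 sample; the polynomial fit's
        onset ripple may add sub-threshold candidates, and merit scoring
        leaves exactly the one planted peak."""
        _, trace = make_bump_trace(apex_index=50, n=120)
        cands = cp.candidate_maxima(trace)
        assert any(abs(i - 50) <= 1 for i in cands)
        peaks = cp.detect_peaks(trace, cp.DetectionParams(delta=1.05))
        assert len(peaks) == 1 and abs(peaks[0].i_max - 50) <= 1

    def test_two_separated_bumps(self):
        raw1, _ = make_bump_trace(apex_index=30, n=150)
        raw2, _ = make_bump_trace(apex_index=100, n=150, baseline=0.0)
        trace = cp.filter_trace(raw1 + raw2, FP, 5.0)
        peaks = cp.detect_peaks(trace, cp.DetectionParams(delta=1.05))
        assert len(peaks) == 2
        assert abs(peaks[0].i_max - 30) <= 1 and abs(peaks[1].i_max - 100) <= 1

    def test_edges_excluded(self):
        _, trace = make_bump_trace(apex_index=50, n=120)
        lo, hi = trace.n, len(trace) - 1 - trace.n
        assert all(lo < i < hi for i in cp.candidate_maxima(trace))

    def test_flat_plateau_resolves_leftmost(self):
        # symmetric pair around the crossing with equal f: left index wins
        f = np.array([0, 1, 2, 3, 3, 2, 1, 0, 0, 0], float)
        d1 = np.array([1, 1, 1, 1, -1, -1, -1, 0, 0, 0], float)
        d2 = -np.ones(10)
        trace = manual_trace(f, d1, d2, n=1)
        assert cp.candidate_maxima(trace) == [3]


class TestPeakMerit:
    def params(self, **kw):
        return cp.DetectionParams(delta=1.0, xi=1.0, gamma=1.0, **kw)

    def test_value_factor_clamps_at_delta(self):
        trace = manual_trace([0, 0, 0.9, 0, 0], [0] * 5, [-1] * 5, n=1)
        assert cp.peak_merit(trace, 2, self.params()) == 0.0

    def test_canonical_reference_point_scores_one(self):
        trace = manual_trace([0, 0, 2.0, 0, 0], [0] * 5, [-1] * 5, n=1)
        assert cp.peak_merit(trace, 2, self.params()) == pytest.approx(1.0)

    def test_each_factor_vanishes_where_logic_fails(self):
        # slope outside (-xi, gamma): trend factor reaches 0
        trace = manual_trace([0, 0, 2.0, 0, 0], [0, 0, 1.0, 0, 0], [-1] * 5, n=1)
        assert cp.peak_merit(trace, 2, self.params()) == 0.0
        # non-negative curvature: curvature factor is 0
        trace = manual_trace([0, 0, 2.0, 0, 0], [0] * 5, [0.5] * 5, n=1)
        assert cp.peak_merit(trace, 2, self.params()) == 0.0

    def test_monotone_in_height_and_curvature(self):
        p = self.params()
        heights = np.linspace(1.0, 5.0, 9)
        merits = [cp.peak_merit(manual_trace([0, 0, h, 0, 0], [0] * 5, [-1] * 5, n=1), 2, p)
                  for h in heights]
        assert np.all(np.diff(merits) >= 0)
        curvs = np.linspace(-3.0, 0.0, 9)
        merits = [cp.peak_merit(manual_trace([0, 0, 2, 0, 0], [0] * 5, [c] * 5, n=1), 2, p)
                  for c in curvs]
        assert np.all(np.diff(merits) <= 0)

    def test_non_interior_index_rejected(self):
        trace = manual_trace([0] * 5, [0] * 5, [-1] * 5, n=1)
        with pytest.raises(ValueError):
            cp.peak_merit(trace, 0, self.params())


class TestDelimitation:
    def triangle(self, n=40, rise=(10, 15), fall=(15, 20), h=2.0):
        y = np.zeros(n)
        y[rise[0]:rise[1] + 1] = np.linspace(0, h, rise[1] - rise[0] + 1)
        y[fall[0]:fall[1] + 1] = np.linspace(h, 0, fall[1] - fall[0] + 1)
        return y

    def test_isolated_triangle_delimited_at_base(self):
        trace = cp.filter_trace(self.triangle(), cp.FilterParams(5, 2), 1.0)
        cands = cp.candidate_maxima(trace)
        assert len(cands) == 1
        t_s, t_e = cp.delimit_peak(trace, cands[0])
        assert 9 <= t_s <= 11 and 19 <= t_e <= 21

    def test_terminal_peak_clamped_to_last_interior_index(self):
        # a peak that never returns to baseline before the record ends
        y = np.concatenate([np.zeros(14), np.linspace(0, 3, 20),
                            np.linspace(2.95, 2.5, 6)])
        trace = cp.filter_trace(y, cp.FilterParams(5, 2), 1.0)
        cands = cp.candidate_maxima(trace)
        assert cands, "apex near the end should still be a candidate"
        _, t_e = cp.delimit_peak(trace, cands[-1])
        assert t_e == len(y) - 1 - trace.n

    def test_adjacent_peaks_share_the_trough(self):
        # two triangles meeting in a V at index 15
        y = np.zeros(30)
        y[5:11] = np.linspace(0, 2, 6)
        y[10:16] = np.linspace(2, 0, 6)
        y[15:21] = np.linspace(0, 2, 6)
        y[20:26] = np.linspace(2, 0, 6)
        trace = cp.filter_trace(y, cp.FilterParams(5, 2), 1.0)
        c = cp.candidate_maxima(trace)
        assert len(c) == 2
        _, t_e_first = cp.delimit_peak(trace, c[0])
        t_s_second, _ = cp.delimit_peak(trace, c[1])
        assert t_e_first == t_s_second

    def test_invariant_order(self):
        _, trace = make_bump_trace()
        i = cp.candidate_maxima(trace)[0]
        t_s, t_e = cp.delimit_peak(trace, i)
        assert t_s < i < t_e


class TestIntensity:
    def test_flat_segment_is_zero(self):
        trace = cp.filter_trace(np.full(30, 2.0), cp.FilterParams(5, 2), 1.0)
        assert cp.peak_intensity(trace, 5, 20) == 0.0

    def test_triangle_area(self):
        y = TestDelimitation().triangle(h=2.0)
        trace = cp.filter_trace(y, cp.FilterParams(5, 2), 1.0)
        # h*d/2 = 2*10/2 = 10, within filter-smearing tolerance
        assert cp.peak_intensity(trace, 10, 20) == pytest.approx(10.0, rel=0.12)

    def test_offset_invariance(self):
        y = TestDelimitation().triangle()
        a = cp.peak_intensity(cp.filter_trace(y, cp.FilterParams(5, 2), 1.0), 8, 22)
        b = cp.peak_intensity(cp.filter_trace(y + 7.3, cp.FilterParams(5, 2), 1.0), 8, 22)
        assert a == pytest.approx(b, abs=1e-9)

    def test_bad_bounds_rejected(self):
        _, trace = make_bump_trace()
        with pytest.raises(ValueError):
            cp.peak_intensity(trace, 20, 20)


class TestDetectPeaks:
    def test_four_planted_spikes_recovered_exactly(self):
        spec = cp.GenSpec(noise_sd=0.0, drift=0.0, seed=11,
                          waiting=cp.Alternating(120.0, 360.0, 0.0))
        vals, apex, _ = cp.gen_trace(spec)
        trace = cp.filter_trace(vals, FP, spec.dt)
        peaks = cp.detect_peaks(trace, cp.DetectionParams(delta=1.1))
        truth = np.round(apex / spec.dt).astype(int)
        assert len(peaks) == len(truth) >= 4
        assert all(min(abs(p.i_max - truth)) <= 1 for p in peaks)

    def test_pure_noise_far_below_delta_gives_nothing(self):
        rng = np.random.default_rng(3)
        trace = cp.filter_trace(rng.normal(0.0, 0.01, 360), FP, 5.0)
        assert cp.detect_peaks(trace, cp.DetectionParams(delta=1.0)) == []

    def test_weak_shoulder_after_maximum_is_excluded(self):
        # an irregular shape: a full spike followed by a weaker rounded
        # oscillation that stays below the merit threshold
        t = np.arange(150) * 5.0
        y = 1.0 + cp.peak_kernel_value(t - 200.0, 5.0, 20.0, 3.0) \
                + cp.peak_kernel_value(t - 320.0, 15.0, 45.0, 0.45)
        trace = cp.filter_trace(y, FP, 5.0)
        dp = cp.DetectionParams(delta=1.05)
        cands = cp.candidate_maxima(trace)
        assert any(abs(i - 69) <= 1 for i in cands), "the shoulder is a candidate"
        peaks = cp.detect_peaks(trace, dp)
        assert len(peaks) == 1 and abs(peaks[0].i_max - 42) <= 1

    def test_determinism(self):
        spec = cp.GenSpec(seed=5)
        vals, _, _ = cp.gen_trace(spec)
        trace = cp.filter_trace(vals, FP, spec.dt)
        dp = cp.DetectionParams(delta=1.1)
        assert cp.detect_peaks(trace, dp) == cp.detect_peaks(trace, dp)


def _mkpeak(intensity):
    return cp.Peak(i_max=10, t_s=5, t_e=15, amplitude=1.0,
                   intensity=intensity, merit=2.0)


class TestValidation:
    def test_threshold_zero_keeps_everything_above_zero(self):
        peaks = [_mkpeak(v) for v in (0.5, 1.5, 3.0)]
        assert cp.validate_peaks(peaks, 0.0) == peaks

    def test_threshold_above_max_empties(self):
        peaks = [_mkpeak(v) for v in (0.5, 1.5, 3.0)]
        assert cp.validate_peaks(peaks, 3.0) == []

    def test_strictly_greater_subset(self):
        peaks = [_mkpeak(v) for v in (0.5, 1.0, 1.5, 2.0)]
        kept = cp.validate_peaks(peaks, 1.0)
        assert [p.intensity for p in kept] == [1.5, 2.0]

    def test_control_threshold_is_quantile_of_harvested_intensities(self):
        """The threshold equals the linear-interpolation q-quantile of the
        false-peak intensities harvested at tau = 0 (q = 0 gives the
        minimum), e.g. intensities {1..10} at q = 0.9 give 9.1."""
        assert np.quantile(np.arange(1.0, 11.0), 0.9, method="linear") == \
            pytest.approx(9.1)  # the documented convention on a known set
        spec = cp.GenSpec(seed=9)
        _, control, _ = cp.gen_cohort(spec, n_cells=6)
        dp = cp.estimate_detection_params(control, FP)
        harvest = []
        for sid in control.sample_ids:
            trace = cp.filter_trace(control.trace(sid), FP, control.dt)
            harvest += [p.intensity for p in
                        cp.detect_peaks(trace, replace(dp, tau=0.0))]
        assert harvest, "a noisy control yields false peaks"
        thr = cp.control_threshold(control, FP, dp)
        assert thr == pytest.approx(np.quantile(harvest, dp.q, method="linear"))
        thr0 = cp.control_threshold(control, FP, replace(dp, q=0.0))
        assert thr0 == pytest.approx(min(harvest))

    def test_flat_zero_control_gives_zero_threshold(self):
        control = cp.TimeSeriesSet(("A", "B"), np.zeros((60, 2)), 5.0)
        thr = cp.control_threshold(control, FP, cp.DetectionParams(delta=0.5))
        assert thr == 0.0

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            cp.TimeSeriesSet((), np.empty((10, 0)), 5.0)


class TestPipelineInvariants:
    def test_control_as_treatment_at_q1_validates_nothing(self):
        """Self-consistency: with the q=1 threshold from the control, the
        control itself carries zero significant peaks."""
        spec = cp.GenSpec(seed=21)
        _, control, _ = cp.gen_cohort(spec, n_cells=6)
        dp = replace(cp.estimate_detection_params(control, FP), q=1.0)
        thr = cp.control_threshold(control, FP, dp)
        total = 0
        for sid in control.sample_ids:
            trace = cp.filter_trace(control.trace(sid), FP, control.dt)
            total += len(cp.validate_peaks(cp.detect_peaks(trace, dp), thr))
        assert total == 0

    def test_validated_count_monotone_in_tau_delta_q(self):
        spec = cp.GenSpec(seed=13)
        treatment, control, _ = cp.gen_cohort(spec, n_cells=5)
        base = cp.estimate_detection_params(control, FP)

        def count(dp):
            thr = cp.control_threshold(control, FP, dp)
            return sum(
                len(cp.validate_peaks(
                    cp.detect_peaks(cp.filter_trace(treatment.trace(s), FP, 5.0), dp),
                    thr))
                for s in treatment.sample_ids
            )

        for field, values in (
            ("tau", [0.25, 0.5, 1.0, 2.0, 4.0]),
            ("delta", [base.delta, base.delta + 1, base.delta + 2, base.delta + 3]),
            ("q", [0.1, 0.5, 0.9, 1.0]),
        ):
            counts = [count(replace(base, **{field: v})) for v in values]
            assert all(a >= b for a, b in zip(counts, counts[1:])), (field, counts)
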