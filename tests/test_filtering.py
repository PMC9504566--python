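"""Beat-unit filtering: slicing geometry, exclusion rules vs a brute-force
oracle, carry-forward bookkeeping, and recovery of known rates."""

import numpy as np
import pytest

from shockwatch.cohort import (CohortConfig, Waveform, inject_artifacts,
                               iter_cohort, synthesize_ecg, synthesize_resp)
from shockwatch.filtering import (EcgUnit, VitalSeries, compute_hr_series,
                                  compute_rr_series, detect_r_peaks,
                                  excluded_spans_s, filter_ecg_units,
                                  filter_patient, slice_units)


def brute_force_invalid_units(units):
    """Literal re-application of the three exclusion rules, recomputing every
    median from scratch; the oracle for filter_ecg_units."""
    lengths = sorted(u.end_idx - u.start_idx for u in units)
    maxima = sorted(u.unit_max for u in units)
    minima = sorted(u.unit_min for u in units)

    def median(xs):
        n = len(xs)
        return xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2.0

    med_len, med_max, med_min = median(lengths), median(maxima), median(minima)
    invalid = set()
    for i, u in enumerate(units):
        if (u.end_idx - u.start_idx) > 1.5 * med_len:
            invalid.add(i)
        if u.unit_max > 2.0 * med_max:
            invalid.add(i)
        if u.unit_min < 2.0 * med_min:
            invalid.add(i)
    return invalid


def _mk_units(lengths=None, maxs=None, mins=None):
    n = len(lengths or maxs or mins)
    lengths = lengths or [200] * n
    maxs = maxs or [1.0] * n
    mins = mins or [-0.1] * n
    units, pos = [], 0
    out = []
    for ln, mx, mn in zip(lengths, maxs, mins):
        out.append(EcgUnit(start_idx=pos, end_idx=pos + ln, r_peak_idx=pos + ln // 2,
                           unit_max=mx, unit_min=mn, hr_value=60.0))
        pos += ln
    return out


class TestRPeakDetection:
    def test_clean_60bpm_peaks_within_20ms_of_truth(self, rng):
        wf = synthesize_ecg([60.0], rng, interval_jitter_rel=0.0)
        peaks = detect_r_peaks(wf)
        truth = wf.meta["peaks"]
        assert abs(len(peaks) - 60) <= 1
        j = np.searchsorted(truth, peaks)
        j = np.clip(j, 1, len(truth) - 1)
        dist = np.minimum(np.abs(peaks - truth[j - 1]), np.abs(peaks - truth[j]))
        assert (dist <= 5).all()  # 20 ms at 250 Hz

    def test_flatline_yields_no_peaks(self):
        wf = Waveform(channel="ECG", sampling_rate=250.0,
                      samples=np.zeros(250 * 10, dtype=np.float32))
        with pytest.warns(UserWarning):
            assert detect_r_peaks(wf).size == 0

    def test_too_short_record_rejected(self, rng):
        wf = Waveform(channel="ECG", sampling_rate=250.0,
                      samples=np.ones(250, dtype=np.float32))
        with pytest.raises(ValueError, match="2 s"):
            detect_r_peaks(wf)

    def test_detection_is_deterministic(self, rng):
        wf = synthesize_ecg([95.0] * 2, rng)
        np.testing.assert_array_equal(detect_r_peaks(wf), detect_r_peaks(wf))


class TestSliceUnits:
    def _record(self, n=1000):
        return Waveform(channel="ECG", sampling_rate=250.0,
                        samples=np.zeros(n, dtype=np.float32))

    def test_midpoint_geometry_on_three_peaks(self):
        units = slice_units(self._record(1000), np.array([250, 500, 750]))
        assert [(u.start_idx, u.end_idx) for u in units] == [(0, 375), (375, 625), (625, 1000)]

    def test_equally_spaced_peaks_give_equal_interior_units(self):
        peaks = np.arange(100, 2000, 150)
        units = slice_units(self._record(2100), peaks)
        interior = {u.length for u in units[1:-1]}
        assert interior == {150}

    def test_units_tile_the_record(self, rng):
        wf = synthesize_ecg([88.0], rng)
        units = slice_units(wf, detect_r_peaks(wf))
        assert units[0].start_idx == 0
        assert units[-1].end_idx == len(wf.samples)
        assert sum(u.length for u in units) == len(wf.samples)
        for a, b in zip(units, units[1:]):
            assert a.end_idx == b.start_idx

    def test_fewer_than_three_peaks_rejected(self):
        with pytest.raises(ValueError, match="3"):
            slice_units(self._record(), np.array([100, 300]))


class TestFilterRules:
    def test_long_unit_excluded_by_length_rule(self):
        units = filter_ecg_units(_mk_units(lengths=[200, 200, 200, 200, 600]))
        assert [u.valid for u in units] == [True, True, True, True, False]
        assert units[-1].rules_violated == ("length",)

    def test_identical_units_all_valid(self):
        units = filter_ecg_units(_mk_units(lengths=[200] * 6))
        assert all(u.valid for u in units)

    def test_high_maximum_excluded_by_amplitude_rule(self):
        units = filter_ecg_units(_mk_units(maxs=[1.0, 1.0, 1.0, 2.5]))
        assert [u.valid for u in units] == [True, True, True, False]
        assert "max_amplitude" in units[-1].rules_violated

    def test_deep_minimum_excluded_by_amplitude_rule(self):
        units = filter_ecg_units(_mk_units(mins=[-0.1, -0.1, -0.1, -0.5]))
        assert [u.valid for u in units] == [True, True, True, False]
        assert "min_amplitude" in units[-1].rules_violated

    def test_oracle_equivalence_on_random_records(self):
        # 50 seeded synthetic records vs the literal brute-force oracle
        for seed in range(50):
            rng = np.random.default_rng(seed)
            hr = float(rng.uniform(60, 140))
            wf = synthesize_ecg([hr] * 3, rng)  # ~180-420 beats
            wf = inject_artifacts(wf, float(rng.uniform(0, 0.2)), rng)
            peaks = detect_r_peaks(wf)
            units = filter_ecg_units(slice_units(wf, peaks))
            got = {i for i, u in enumerate(units) if not u.valid}
            assert got == brute_force_invalid_units(units), f"seed {seed}"

    def test_monotone_artifact_response(self, rng):
        wf = synthesize_ecg([90.0] * 3, np.random.default_rng(17))
        previous = -1
        for rate in (0.0, 0.05, 0.1, 0.2):
            corrupted = inject_artifacts(wf, rate, np.random.default_rng(99))
            units = filter_ecg_units(slice_units(corrupted, detect_r_peaks(corrupted)))
            n_invalid = sum(not u.valid for u in units)
            assert n_invalid >= previous
            previous = n_invalid

    def test_clean_record_flags_under_5pct(self, rng):
        wf = synthesize_ecg([100.0] * 3, rng)
        units = filter_ecg_units(slice_units(wf, detect_r_peaks(wf)))
        assert np.mean([not u.valid for u in units]) < 0.05


class TestHrSeries:
    def test_constant_rr_gives_constant_hr_unimputed(self):
        units = filter_ecg_units(_mk_units(lengths=[125] * 20))
        for u in units:
            u.hr_value = 120.0
        series = compute_hr_series(units, duration_s=10)
        np.testing.assert_array_equal(series.value, 120.0)
        assert not series.imputed.any()

    def test_invalid_span_carries_most_recent_valid_value(self):
        units = _mk_units(lengths=[250] * 6)
        hrs = [80.0, 80.0, 81.0, 82.0, 82.0, 82.0]
        for u, h in zip(units, hrs):
            u.hr_value = h
            u.valid = True
        units[2].valid = False
        series = compute_hr_series(units, duration_s=6)
        assert series.value[2] == 80.0  # second covered by the invalid unit
        assert series.imputed[2] and not series.imputed[1]

    def test_leading_invalid_span_backfills_from_first_valid(self):
        units = _mk_units(lengths=[250] * 4)
        for u, h in zip(units, [90.0, 70.0, 70.0, 70.0]):
            u.hr_value = h
        units[0].valid = False
        series = compute_hr_series(units, duration_s=4)
        assert series.value[0] == 70.0
        assert series.imputed[0]

    def test_all_invalid_rejected(self):
        units = _mk_units(lengths=[250] * 4)
        for u in units:
            u.valid = False
        with pytest.raises(ValueError, match="unusable"):
            compute_hr_series(units, duration_s=4)

    def test_imputed_fraction_equals_invalid_coverage_exactly(self):
        # bookkeeping identity on a corrupted synthetic record
        rng = np.random.default_rng(23)
        wf = inject_artifacts(synthesize_ecg([110.0] * 3, rng), 0.15, rng)
        units = filter_ecg_units(slice_units(wf, detect_r_peaks(wf)))
        duration = int(wf.duration_s)
        series = compute_hr_series(units, duration)
        starts = np.array([u.start_idx for u in units])
        ok = np.array([u.valid for u in units])
        sec_unit = np.clip(np.searchsorted(starts, np.arange(duration) * 250.0,
                                           side="right") - 1, 0, len(units) - 1)
        assert series.imputed.sum() == (~ok[sec_unit]).sum()


class TestRrSeries:
    def _resp(self, rr, seconds=180, jitter=0.0):
        rng = np.random.default_rng(7)
        return synthesize_resp([rr] * (seconds // 60), rng, cycle_jitter_rel=jitter)

    def test_peaks_every_3s_give_rr_20(self):
        series, cycles = compute_rr_series(self._resp(20.0), [], 180)
        assert np.all(np.abs(series.value - 20.0) < 1.0)

    def test_rate_jump_above_1p5x_excluded_and_carried(self):
        # hand-built trajectory: a cycle computing 32 after a valid 20
        series, cycles = compute_rr_series(self._resp(20.0), [], 180)
        from shockwatch.filtering import RESP_HIGH_FACTOR, RESP_LOW_FACTOR
        assert RESP_HIGH_FACTOR * 20 == 30.0 and RESP_LOW_FACTOR * 20 == 10.0
        # literal rule application on synthetic cycle values
        prev_valid = 20.0
        for rr_next, expect_valid in ((32.0, False), (9.0, False), (25.0, True)):
            low = rr_next < RESP_LOW_FACTOR * prev_valid
            high = rr_next > RESP_HIGH_FACTOR * prev_valid
            assert (not (low or high)) == expect_valid

    def test_cycles_overlapping_ecg_exclusions_are_removed_first(self):
        resp = self._resp(20.0)
        series_clean, cycles_clean = compute_rr_series(resp, [], 180)
        spans = [(30.0, 45.0)]
        series, cycles = compute_rr_series(resp, spans, 180)
        for c in cycles:
            lo, hi = c.peak_idx / 25.0, c.next_peak_idx / 25.0
            if lo < 45.0 and hi > 30.0:
                assert not c.valid
        assert series.imputed[31:44].all()

    def test_no_cycles_rejected(self):
        flat = Waveform(channel="RESP", sampling_rate=25.0,
                        samples=np.zeros(25 * 60, dtype=np.float32))
        with pytest.raises(ValueError, match="unusable|cycles"):
            compute_rr_series(flat, [], 60)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("artifact_rate", [0.0, 0.1])
    def test_hr_and_rr_recover_generator_truth(self, artifact_rate):
        cfg = CohortConfig(n_patients=2, seed=31, artifact_rate=artifact_rate,
                           monitoring_minutes_mean=120,
                           monitoring_minutes_bounds=(90, 150))
        hr_ok, hr_n, rr_ok, rr_n = 0, 0, 0, 0
        for p in iter_cohort(cfg):
            res = filter_patient(p.ecg, p.resp)
            n = len(res.hr.value)
            truth_hr = np.repeat(p.trajectory.hr, 60)[:n]
            truth_rr = np.repeat(p.trajectory.rr, 60)[:n]
            sec = (np.arange(n) * 250).astype(int)
            art_e = np.add.reduceat(p.ecg.artifact_mask, sec) > 0
            art_r = np.add.reduceat(p.resp.artifact_mask,
                                    (np.arange(n) * 25).astype(int)) > 0
            good_hr = ~art_e
            good_rr = ~art_r & ~art_e
            hr_ok += (np.abs(res.hr.value - truth_hr)[good_hr] < 2).sum()
            hr_n += good_hr.sum()
            rr_ok += (np.abs(res.rr.value - truth_rr)[good_rr] < 2).sum()
            rr_n += good_rr.sum()
        assert hr_ok / hr_n >= 0.95
        assert rr_ok / rr_n >= 0.90
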