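import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from usvdetect.audio_io import Waveform
from usvdetect.evaluate import (
    global_snr,
    local_snr,
    magnitude,
    match_detections,
    metrics,
)

from helpers import make_table


class TestMagnitude:
    def test_unit_alternating_signal(self):
        assert magnitude(np.array([1.0, -1.0, 1.0, -1.0])) == 1.0

    def test_zeros(self):
        assert magnitude(np.zeros(100)) == 0.0

    def test_equals_mean_of_squares_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0, 2, int(rng.integers(1, 1000)))
            assert abs(magnitude(x) - float(np.mean(x * x))) < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            magnitude(np.array([]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=200))
    def test_magnitude_nonnegative_and_scale_quadratic(self, xs):
        x = np.asarray(xs)
        m = magnitude(x)
        assert m >= 0
        assert np.isclose(magnitude(2 * x), 4 * m, rtol=1e-9, atol=1e-12)


class TestLocalSnr:
    def test_zero_when_signal_equals_surroundings(self):
        # uniform-amplitude file: USV span is as loud as its flanks
        rng = np.random.default_rng(1)
        wave = Waveform(rng.normal(0, 0.1, 30_000), 10_000)
        table = make_table([(1.0, 1.5, "USV")])
        report = local_snr(wave, table)
        assert abs(report.r[0]) < 0.1

    def test_direct_formula(self):
        # M_sig = 3, M_bg = 1 -> R = 2
        rate = 1_000
        x = np.ones(3_000)
        x[1000:2000] = np.sqrt(3.0)
        table = make_table([(1.0, 2.0, "USV")])
        report = local_snr(Waveform(x, rate), table)
        assert np.isclose(report.r[0], 2.0)

    def test_invariant_to_global_amplitude_scaling(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.01, 50_000)
        x[20_000:25_000] += 0.2 * np.sin(np.arange(5_000))
        table = make_table([(20_000 / 250_000, 25_000 / 250_000, "USV")])
        r1 = local_snr(Waveform(x, 250_000), table).r[0]
        r2 = local_snr(Waveform(7.5 * x, 250_000), table).r[0]
        assert np.isclose(r1, r2, rtol=1e-9)

    def test_silent_background_flagged_undefined(self):
        x = np.zeros(3_000)
        x[1000:2000] = 1.0
        report = local_snr(Waveform(x, 1_000), make_table([(1.0, 2.0, "USV")]))
        assert report.undefined[0]
        assert np.isnan(report.r[0])

    def test_flanks_exclude_neighboring_usvs(self):
        # two USVs back to back: the flank between them is the short gap only
        rate = 1_000
        x = np.full(5_000, 0.1)
        x[1000:2000] = 2.0   # USV 1
        x[2500:3500] = 2.0   # USV 2
        table = make_table([(1.0, 2.0, "USV"), (2.5, 3.5, "USV")])
        report = local_snr(Waveform(x, rate), table)
        # background for USV 1 = [0,1) and (2.0, 2.5): all 0.1 amplitude
        expected = (4.0 - 0.01) / 0.01
        assert np.isclose(report.r[0], expected, rtol=1e-6)


class TestGlobalSnr:
    def test_no_usvs_is_undefined(self):
        wave = Waveform(np.ones(1000), 1_000)
        assert np.isnan(global_snr(wave, make_table([])))

    def test_zero_for_uniform_amplitude(self):
        rng = np.random.default_rng(3)
        wave = Waveform(rng.normal(0, 0.1, 30_000), 10_000)
        r = global_snr(wave, make_table([(0.5, 1.0, "USV"), (2.0, 2.4, "USV")]))
        assert abs(r) < 0.1

    def test_equals_local_snr_for_single_spanning_event(self):
        rate = 1_000
        x = np.full(3_000, 0.5)
        x[1000:2000] = 1.5
        table = make_table([(1.0, 2.0, "USV")])
        wave = Waveform(x, rate)
        assert np.isclose(global_snr(wave, table), local_snr(wave, table).r[0])


class TestMatching:
    def test_exact_matches_all_usv(self):
        truth = make_table([(0.1, 0.2, "USV"), (0.5, 0.6, "USV")])
        matches = match_detections([(0.1, 0.2), (0.5, 0.6)], truth)
        cats = [m.category for m in matches]
        assert cats == ["USV", "USV"]

    def test_second_tag_of_same_truth_is_partial(self):
        truth = make_table([(0.1, 0.4, "USV")])
        matches = match_detections([(0.1, 0.2), (0.3, 0.4)], truth)
        assert [m.category for m in matches] == ["USV", "Partial"]
        rep = metrics(matches)
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)

    def test_one_detection_spanning_two_truths_is_multi_counted_once(self):
        truth = make_table([(0.1, 0.2, "USV"), (0.3, 0.4, "USV")])
        matches = match_detections([(0.05, 0.45)], truth)
        assert [m.category for m in matches] == ["Multi"]
        rep = metrics(matches)
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)

    def test_unmatched_detection_and_truth(self):
        truth = make_table([(0.1, 0.2, "USV")])
        matches = match_detections([(0.5, 0.6)], truth)
        cats = sorted(m.category for m in matches)
        assert cats == ["FalsePositive", "Missed"]

    def test_ac_truths_excluded(self):
        truth = make_table([(0.1, 0.2, "AC")])
        matches = match_detections([(0.1, 0.2)], truth)
        assert [m.category for m in matches] == ["FalsePositive"]

    def test_partial_as_fp_flag(self):
        truth = make_table([(0.1, 0.4, "USV")])
        matches = match_detections([(0.1, 0.2), (0.3, 0.4)], truth)
        assert metrics(matches, partial_as_fp=True).fp == 1

    def test_min_iou_rule_rejects_slim_overlaps(self):
        truth = make_table([(0.0, 1.0, "USV")])
        matches = match_detections([(0.99, 2.0)], truth, min_iou=0.25)
        assert [m.category for m in matches] == ["FalsePositive", "Missed"]


class TestSnrStratified:
    def test_bins_partition_truths_and_count_misses(self):
        from usvdetect.evaluate import snr_stratified_metrics

        rate = 1_000
        x = np.full(8_000, 0.1)
        x[1000:2000] = 0.5   # loud USV, R ~ 24
        x[4000:5000] = 0.11  # faint USV, R ~ 0.2
        table = make_table([(1.0, 2.0, "USV"), (4.0, 5.0, "USV")])
        wave = Waveform(x, rate)
        # only the loud one is detected
        df = snr_stratified_metrics(wave, table, [(1.1, 1.9)],
                                    bin_edges=(0.0, 1.0, np.inf))
        assert df["n_usvs"].sum() == 2
        low = df.iloc[0]
        high = df.iloc[1]
        assert low["n_usvs"] == 1 and low["detected"] == 0 and low["recall"] == 0.0
        assert high["n_usvs"] == 1 and high["detected"] == 1 and high["recall"] == 1.0


class TestMetrics:
    def test_formula_example(self):
        # tp=8, fp=2, fn=2 -> recall 0.8, precision 0.8, f1 0.8
        from usvdetect.evaluate import DetectionMatch
        matches = (
            [DetectionMatch("USV", (0, 1)) for _ in range(8)]
            + [DetectionMatch("FalsePositive", (0, 1)) for _ in range(2)]
            + [DetectionMatch("Missed", None) for _ in range(2)]
        )
        rep = metrics(matches)
        assert np.isclose(rep.recall, 0.8)
        assert np.isclose(rep.precision, 0.8)
        assert np.isclose(rep.f1, 0.8)

    def test_perfect_detection_gives_ones(self):
        truth = make_table([(0.1, 0.2, "USV")])
        rep = metrics(match_detections([(0.1, 0.2)], truth))
        assert rep.recall == rep.precision == rep.f1 == 1.0

    def test_zero_tp_convention(self):
        from usvdetect.evaluate import DetectionMatch
        matches = [DetectionMatch("FalsePositive", (0, 1)),
                   DetectionMatch("Missed", None)]
        rep = metrics(matches)
        assert rep.recall == rep.precision == rep.f1 == 0.0

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(4)
        from usvdetect.evaluate import DetectionMatch
        for _ in range(30):
            tp, fp, fn = rng.integers(1, 10, 3)
            matches = (
                [DetectionMatch("USV", (0, 1))] * int(tp)
                + [DetectionMatch("FalsePositive", (0, 1))] * int(fp)
                + [DetectionMatch("Missed", None)] * int(fn)
            )
            rep = metrics(matches)
            lo, hi = sorted([rep.precision, rep.recall])
            assert lo - 1e-12 <= rep.f1 <= hi + 1e-12

    def test_exhaustive_small_configurations_match_bruteforce(self):
        """All overlap layouts of <= 3 detections x <= 3 truths agree with
        a brute-force count of matched truths / unmatched detections."""
        # events live on a grid; enumerate all subsets of candidate spans
        det_candidates = [(0.0, 1.0), (1.5, 2.5), (3.0, 4.0)]
        truth_candidates = [(0.5, 1.2), (1.4, 1.6), (3.5, 5.0)]
        for det_mask in itertools.product([0, 1], repeat=3):
            for truth_mask in itertools.product([0, 1], repeat=3):
                dets = [d for d, m in zip(det_candidates, det_mask) if m]
                truths = [t for t, m in zip(truth_candidates, truth_mask) if m]
                table = make_table([(a, b, "USV") for a, b in truths])
                rep = metrics(match_detections(dets, table))
                # brute force: bipartite any-overlap
                overlap = lambda a, b: min(a[1], b[1]) - max(a[0], b[0]) > 0
                covered = [any(overlap(d, t) for d in dets) for t in truths]
                matched_d = [any(overlap(d, t) for t in truths) for d in dets]
                assert rep.fn == covered.count(False)
                assert rep.fp == matched_d.count(False)
                assert rep.tp <= len(truths)
                assert rep.tp + rep.fn == len(truths)
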