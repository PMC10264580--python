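"""Ordinal P1/N1/P2 marking: oracle equivalence, implicit times, quality flags."""

import numpy as np
import pytest

from vepwave import (
    AcquisitionSpec,
    NoiseSpec,
    VEPMarks,
    detect_components,
    implicit_times,
    mark_reproducibility,
)
from vepwave.components import HyperpolarizationRule, SearchWindows
from vepwave.preprocess import AverageTrace

from hypothesis import given, strategies as st

from conftest import (
    mark_simulated_session,
    oracle_detect,
    oracle_extrema,
    random_bump_fixture,
)


def bump(times, latency, amplitude, width):
    sigma = width / np.sqrt(2 * np.log(2))
    return amplitude * np.exp(-0.5 * ((times - latency) / sigma) ** 2)


def trace_of(samples, fs=4096.0):
    return AverageTrace(samples=samples, sampling_rate=fs, n_sweeps=1)


@pytest.fixture(scope="module")
def times(acq):
    return AcquisitionSpec().times_ms


class TestDetection:
    def test_noise_free_truth_recovered_within_one_sample(self, acq, components, silent_noise):
        marks, truth = mark_simulated_session(components, silent_noise, acq, seed=0)
        dt = 1000.0 / acq.sampling_rate
        for comp in ("P1", "N1", "P2"):
            assert marks.quality[comp] == "ok"
            # one sample of quantization + at most one sample of filter shift
            assert abs(marks.latency(comp) - truth[comp]) <= 2 * dt

    def test_polarity_inversion_gives_identical_latencies(self, acq, components, silent_noise):
        marks, _ = mark_simulated_session(components, silent_noise, acq, seed=0)
        from conftest import filtered_grand
        from vepwave import simulate_session

        epochs, _ = simulate_session(components, silent_noise, acq, seed=0)
        grand = filtered_grand(epochs)
        flipped = trace_of(-grand.samples)
        inv = detect_components(flipped, polarity=-1)
        for comp in ("P1", "N1", "P2"):
            assert inv.latency(comp) == marks.latency(comp)

    def test_p1_is_first_positive_peak_not_largest(self, times):
        # two positive bumps before the trough: the earlier, smaller one is P1
        samples = (
            bump(times, 18.0, 6.0, 4.0)
            + bump(times, 38.0, 12.0, 4.0)
            + bump(times, 60.0, -15.0, 8.0)
            + bump(times, 95.0, 10.0, 10.0)
        )
        marks = detect_components(trace_of(samples), windows=SearchWindows(n1=(40.0, 80.0)))
        assert marks.p1_latency == pytest.approx(18.0, abs=0.3)
        assert marks.n1_latency == pytest.approx(60.0, abs=0.3)

    def test_flat_trace_flagged_no_signal(self, times):
        marks = detect_components(trace_of(np.zeros_like(times)))
        assert marks.p1_latency is None and marks.n1_latency is None and marks.p2_latency is None
        assert set(marks.quality.values()) == {"no_signal"}

    def test_missing_p1_reports_n1_and_p2(self, times):
        samples = bump(times, 50.0, -15.0, 8.0) + bump(times, 90.0, 10.0, 10.0)
        marks = detect_components(trace_of(samples))
        assert marks.quality["P1"] == "absent" and marks.p1_latency is None
        assert marks.n1_latency == pytest.approx(50.0, abs=0.3)
        assert marks.p2_latency == pytest.approx(90.0, abs=0.3)
        assert marks.p1_n1_time is None and marks.n1_p2_time is not None

    def test_hyperpolarization_bounds_p2_search(self, times):
        # deep sustained negativity from ~65 ms; the positive bump at 120 ms
        # lies beyond the hyperpolarization onset and must not become P2
        hyper = -14.0 / (1 + np.exp(-(times - 70.0) / 3.0))  # sigmoid to -14 uV
        samples = (
            bump(times, 25.0, 8.0, 5.0)
            + bump(times, 50.0, -10.0, 6.0)
            + hyper
            + bump(times, 120.0, 6.0, 6.0)
        )
        marks = detect_components(trace_of(samples))
        assert marks.quality["P2"] == "absent"

    def test_shallow_interpeak_trough_does_not_bound_p2(self, times):
        # trough hovers just below zero between N1 and a late P2: depth rule
        # keeps the P2 search open
        samples = (
            bump(times, 25.0, 8.0, 5.0)
            + bump(times, 50.0, -15.0, 8.0)
            - 0.5 * np.exp(-0.5 * ((times - 85.0) / 15.0) ** 2)
            + bump(times, 115.0, 10.0, 10.0)
        )
        marks = detect_components(trace_of(samples))
        assert marks.p2_latency == pytest.approx(115.0, abs=0.5)

    def test_small_ripples_below_prominence_floor_ignored(self, times):
        rng = np.random.default_rng(5)
        ripple = 0.8 * np.sin(2 * np.pi * times / 7.0 + rng.uniform(0, 6))
        samples = (
            bump(times, 25.0, 8.0, 5.0)
            + bump(times, 50.0, -15.0, 8.0)
            + bump(times, 103.0, 10.0, 12.0)
            + ripple
        )
        marks = detect_components(trace_of(samples))
        # the ripple may nudge the P2 apex slightly but must not spawn an
        # earlier spurious P2 between the trough and the genuine peak
        assert marks.p2_latency == pytest.approx(103.0, abs=3.0)

    def test_noisy_recovery_median_within_two_ms(self, acq, components):
        errors = {c: [] for c in ("P1", "N1", "P2")}
        for seed in range(20):
            marks, truth = mark_simulated_session(components, NoiseSpec(), acq, seed=seed)
            for comp in errors:
                assert marks.latency(comp) is not None
                errors[comp].append(abs(marks.latency(comp) - truth[comp]))
        for comp, errs in errors.items():
            assert np.median(errs) <= 2.0


class TestOracleEquivalence:
    def test_detection_matches_brute_force_scan(self, times):
        rng = np.random.default_rng(2024)
        windows = SearchWindows()
        # depth fraction > 1 disables the hyperpolarization bound on both
        # routes; the ordinal scan itself is what is compared here
        hyper = HyperpolarizationRule(min_depth_fraction=2.0)
        for _ in range(100):
            samples = random_bump_fixture(rng, times)
            got = detect_components(
                trace_of(samples), windows=windows, hyperpolarization=hyper
            )
            min_prom = 0.15 * np.max(np.abs(samples))
            exp = oracle_detect(samples, times, windows, min_prominence=min_prom)
            assert (got.p1_latency, got.n1_latency, got.p2_latency) == exp


class TestExtremumScanner:
    @given(st.lists(st.integers(min_value=-4, max_value=4), min_size=3, max_size=30))
    def test_local_maxima_match_naive_scan_with_plateaus(self, values):
        from vepwave.components import local_maxima

        x = np.array(values, dtype=float)
        assert list(local_maxima(x)) == oracle_extrema(x, "max")

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=3, max_size=30))
    def test_minima_are_maxima_of_negated_trace(self, values):
        from vepwave.components import local_maxima, local_minima

        x = np.array(values)
        assert list(local_minima(x)) == list(local_maxima(-x))


class TestImplicitTimes:
    def test_subtraction_identities(self):
        marks = VEPMarks(p1_latency=25.0, n1_latency=50.0, p2_latency=90.0)
        marks = implicit_times(marks)
        assert marks.p1_n1_time == 25.0
        assert marks.n1_p2_time == 40.0
        assert marks.p1_p2_time == 65.0

    def test_absence_propagates(self):
        marks = implicit_times(VEPMarks(n1_latency=50.0, p2_latency=90.0))
        assert marks.p1_n1_time is None and marks.p1_p2_time is None
        assert marks.n1_p2_time == 40.0

    def test_identity_holds_exactly_on_noisy_marks(self, acq, components):
        # latencies are exact sample multiples, so the closure identity
        # P1-N1 + N1-P2 = P1-P2 holds to the bit
        for seed in range(5):
            marks, _ = mark_simulated_session(components, NoiseSpec(), acq, seed=seed)
            assert marks.p1_n1_time + marks.n1_p2_time == marks.p1_p2_time
            assert marks.p1_latency < marks.n1_latency < marks.p2_latency
            assert marks.n1_p2_amplitude >= 0


class TestReproducibility:
    def marks_at(self, n1):
        return implicit_times(VEPMarks(p1_latency=25.0, n1_latency=n1, p2_latency=90.0))

    def test_identical_blocks_spread_zero(self):
        report = mark_reproducibility([self.marks_at(50.0)] * 3)
        assert report["N1"] == {"spread_ms": 0.0, "stable": True, "flag": "ok"}

    def test_small_spread_within_tolerance(self):
        report = mark_reproducibility(
            [self.marks_at(50.0), self.marks_at(51.0), self.marks_at(52.0)], tolerance_ms=5.0
        )
        assert report["N1"]["spread_ms"] == 2.0 and report["N1"]["stable"]

    def test_missing_component_flagged_unstable(self):
        blocks = [self.marks_at(50.0), self.marks_at(51.0), VEPMarks(p1_latency=25.0)]
        report = mark_reproducibility(blocks)
        assert report["N1"]["flag"] == "unstable"

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            mark_reproducibility([self.marks_at(50.0)])
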