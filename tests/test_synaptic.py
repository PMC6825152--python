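"""IPSC detection and kinetic measurements against closed forms."""

import numpy as np
import pytest

from fastspike.synaptic import (
    average_events,
    detect_events,
    event_train_stats,
    measure_event,
    rising_slope,
    train_analysis,
)
from fastspike.synth import biexp_event
from fastspike.traces import Trace


def trace_of(samples, dt=0.1):
    return Trace(dt=dt, samples=np.asarray(samples, dtype=float), unit="pA")


def biexp_trace(onsets, amps, dur=500.0, dt=0.1, tau_rise=1.5, tau_decay=15.0):
    t = np.arange(0.0, dur, dt)
    v = np.zeros_like(t)
    for t0, a in zip(onsets, amps):
        v += biexp_event(t - t0, a, tau_rise, tau_decay)
    return trace_of(v, dt)


class TestDetectEvents:
    def test_flat_trace_no_events(self):
        assert detect_events(trace_of(np.zeros(20000))).size == 0

    def test_close_events_merge(self):
        """Two events 4 ms apart with a 5 ms merge window -> one detection."""
        tr = biexp_trace([100.0, 104.0], [80.0, 80.0])
        assert detect_events(tr).size == 1

    def test_separated_events_both_found(self):
        tr = biexp_trace([100.0, 200.0, 320.0], [80.0, 60.0, 100.0])
        on = detect_events(tr)
        assert on.size == 3
        assert np.allclose(on, [100.0, 200.0, 320.0], atol=2.0)


class TestMeasureEvent:
    def test_rectangular_event_charge(self):
        """100 pA x 10 ms -> 1.0 pC."""
        t = np.arange(0.0, 300.0, 0.1)
        tr = trace_of(np.where((t >= 10.0) & (t < 20.0), 100.0, 0.0))
        m = measure_event(tr, 10.0)
        assert m.amplitude == pytest.approx(100.0, rel=0.01)
        assert m.charge == pytest.approx(1.0, rel=0.01)

    def test_single_exponential_tau_and_charge(self):
        """A = 100 pA, tau = 15 ms -> tau within 2%, charge ~ A·tau = 1.5 pC."""
        t = np.arange(0.0, 300.0, 0.1)
        tr = trace_of(np.where(t >= 10.0, 100.0 * np.exp(-(t - 10.0) / 15.0), 0.0))
        m = measure_event(tr, 10.0)
        assert m.decay_fit_ok
        assert m.decay_tau == pytest.approx(15.0, rel=0.02)
        assert m.charge == pytest.approx(1.5, rel=0.02)

    def test_biexponential_amplitude_matches_analytic_peak(self):
        tr = biexp_trace([10.0], [100.0])
        m = measure_event(tr, 10.0)
        assert m.amplitude == pytest.approx(100.0, rel=0.01)

    def test_charge_additivity_for_disjoint_events(self):
        """Charge of two well-separated events sums to the individual charges."""
        single = biexp_trace([50.0], [100.0], dur=900.0)
        both = biexp_trace([50.0, 500.0], [100.0, 100.0], dur=900.0)
        q1 = measure_event(single, 50.0).charge
        qa = measure_event(both, 50.0).charge
        qb = measure_event(both, 500.0).charge
        assert qa + qb == pytest.approx(2.0 * q1, rel=0.02)

    def test_peak_at_boundary_rejected(self):
        t = np.arange(0.0, 20.0, 0.1)
        tr = trace_of(np.clip(t - 15.0, 0, None) * 50.0)  # still rising at end
        with pytest.raises(ValueError):
            measure_event(tr, 19.8)


class TestRisingSlope:
    def test_linear_rise(self):
        """0 -> 100 pA over 2 ms -> 50 pA/ms."""
        t = np.arange(0.0, 100.0, 0.1)
        tr = trace_of(np.clip((t - 10.0) / 2.0, 0.0, 1.0) * 100.0)
        assert rising_slope(tr, 10.0) == pytest.approx(50.0, rel=0.01)

    def test_invariant_to_sampling_rate(self):
        """The same linear rise sampled at twice the rate: slope unchanged
        within 1%."""
        vals = []
        for dt in (0.1, 0.05):
            t = np.arange(0.0, 100.0, dt)
            v = np.clip((t - 10.0) / 2.0, 0.0, 1.0) * 100.0
            vals.append(rising_slope(Trace(dt=dt, samples=v, unit="pA"), 10.0))
        assert vals[0] == pytest.approx(vals[1], rel=0.01)

    def test_matches_dense_grid_oracle(self):
        """Slope within 2% of the same measurement on a 20x-finer grid."""
        fine_dt = 0.005
        t = np.arange(0.0, 200.0, fine_dt)
        v = biexp_event(t - 20.0, 100.0, 1.5, 15.0)
        oracle = rising_slope(Trace(dt=fine_dt, samples=v, unit="pA"), 20.0)
        coarse = rising_slope(biexp_trace([20.0], [100.0], dur=200.0), 20.0)
        assert coarse == pytest.approx(oracle, rel=0.02)

    def test_too_coarse_sampling_names_required_dt(self):
        t = np.arange(0.0, 100.0, 2.0)
        v = np.where(t >= 20.0, 100.0, 0.0)  # instant rise at 2 ms sampling
        with pytest.raises(ValueError, match="sampling interval"):
            rising_slope(trace_of(v, dt=2.0), 20.0)


class TestAverageEvents:
    def test_identical_events_average_exactly(self):
        # spacing >> tau_decay so window overlap is below float tolerance
        onsets = [100.0, 500.0, 900.0]
        tr = biexp_trace(onsets, [80.0] * 3, dur=1300.0)
        avg = average_events(tr, onsets, pre_ms=5.0, post_ms=60.0)
        single = biexp_trace([5.0], [80.0], dur=65.0)
        assert np.allclose(avg.samples, single.samples[: avg.n], atol=1e-9)

    def test_noise_suppressed_as_root_n(self):
        rng = np.random.default_rng(2)
        onsets = np.arange(100.0, 2600.0, 100.0)  # 25 events
        tr = biexp_trace(onsets, [80.0] * len(onsets), dur=2700.0)
        noisy = Trace(dt=tr.dt, samples=tr.samples + rng.normal(0, 5.0, tr.n),
                      unit="pA")
        avg = average_events(noisy, onsets, pre_ms=5.0, post_ms=60.0)
        clean = average_events(tr, onsets, pre_ms=5.0, post_ms=60.0)
        resid = np.std(avg.samples - clean.samples)
        assert resid == pytest.approx(5.0 / np.sqrt(25), rel=0.35)

    def test_single_onset_rejected(self):
        tr = biexp_trace([100.0], [80.0])
        with pytest.raises(ValueError, match="at least 2"):
            average_events(tr, [100.0])


class TestTrainAnalysis:
    def test_constant_amplitudes(self):
        tr = biexp_trace([100.0, 200.0, 300.0], [90.0] * 3, dur=500.0)
        tm = train_analysis(tr, [100.0, 200.0, 300.0])
        assert np.allclose(tm.normalized, 1.0, atol=0.01)
        assert tm.ppr == pytest.approx(1.0, abs=0.01)

    def test_facilitating_pair(self):
        tr = biexp_trace([100.0, 200.0], [100.0, 150.0], dur=400.0)
        tm = train_analysis(tr, [100.0, 200.0])
        assert tm.ppr == pytest.approx(1.5, rel=0.02)
        assert tm.inter_pulse_interval == 100.0

    def test_ppr_agrees_with_event_measurements(self):
        """On a clean two-pulse trace the train PPR equals the ratio of the
        per-event amplitudes."""
        tr = biexp_trace([100.0, 200.0], [120.0, 80.0], dur=400.0)
        tm = train_analysis(tr, [100.0, 200.0])
        a1 = measure_event(tr, 100.0).amplitude
        a2 = measure_event(tr, 200.0).amplitude
        assert tm.ppr == pytest.approx(a2 / a1, rel=0.005)

    def test_overlap_flagged(self):
        tr = biexp_trace([100.0, 130.0], [100.0, 100.0], dur=400.0)
        tm = train_analysis(tr, [100.0, 130.0], window_ms=50.0)
        assert tm.overlapping_windows

    def test_bad_pulse_times(self):
        tr = biexp_trace([100.0], [100.0])
        with pytest.raises(ValueError):
            train_analysis(tr, [100.0])
        with pytest.raises(ValueError, match="increasing"):
            train_analysis(tr, [200.0, 100.0])


class TestEventTrainStats:
    def test_frequency_from_given_onsets(self):
        tr = biexp_trace([10.0], [50.0], dur=60_000.0 + 0.1)
        onsets = np.linspace(10.0, 59_000.0, 300)
        st = event_train_stats(tr, onsets=onsets)
        assert st.frequency == pytest.approx(300 / 60.0, rel=0.001)
        assert st.n_events == 300

    def test_empty_detection(self):
        st = event_train_stats(trace_of(np.zeros(50000)))
        assert st.frequency == 0.0
        assert np.isnan(st.mean_amplitude)
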