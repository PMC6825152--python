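"""Intrinsic and single-AP feature extraction against analytic ground truth."""

import numpy as np
import pytest

from fastspike.intrinsic import (
    FeatureUndefinedError,
    ap_features,
    compute_rmp,
    cv,
    detect_spikes,
    extract_profile,
    firing_curve,
    input_resistance,
    max_firing_frequency,
    rheobase,
    sag_rebound,
    sfa,
)
from fastspike.traces import StimulusStep, Sweep, SweepSet, Trace


class TestRMP:
    def test_constant_trace(self, make_step_sweepset):
        ss = make_step_sweepset([0.0], lambda t, a: np.full_like(t, -65.0))
        assert compute_rmp(ss) == pytest.approx(-65.0)

    def test_noisy_baseline_recovers_generated_mean(self, make_step_sweepset):
        rng = np.random.default_rng(3)
        noise = {}

        def resp(t, a):
            v = rng.normal(-70.0, 0.2, t.size)
            noise[a] = v
            return v

        ss = make_step_sweepset([0.0], resp, dt=0.1, onset=500.0)
        rmp = compute_rmp(ss, baseline_window=(0.0, 500.0))
        # oracle: mean of the actual generated baseline samples
        expected = noise[0.0][:5000].mean()
        assert rmp == pytest.approx(expected, abs=1e-12)
        assert rmp == pytest.approx(-70.0, abs=0.05)

    def test_empty_window_rejected(self, make_step_sweepset):
        ss = make_step_sweepset([0.0], lambda t, a: np.full_like(t, -65.0))
        with pytest.raises(ValueError, match="empty baseline window"):
            compute_rmp(ss, baseline_window=(0.0, 0.0))


class TestInputResistance:
    def test_ideal_ohmic_cell(self, make_step_sweepset):
        # 0.1 mV per pA -> 100 MΩ
        def resp(t, a):
            v = np.full_like(t, -70.0)
            v[t >= 0] += 0.1 * a
            return v

        ss = make_step_sweepset([-50.0, -30.0, -10.0, 10.0], resp)
        assert input_resistance(ss) == pytest.approx(100.0, rel=1e-9)

    def test_rc_membrane_within_one_percent(self, make_step_sweepset, rc_response):
        amps = np.arange(-50.0, 21.0, 10.0)
        ss = make_step_sweepset(list(amps), rc_response(r_mohm=150.0, tau_ms=20.0))
        assert input_resistance(ss) == pytest.approx(150.0, rel=0.01)

    def test_flat_responses_give_zero(self, make_step_sweepset):
        ss = make_step_sweepset([-50.0, -25.0, 25.0],
                                lambda t, a: np.full_like(t, -70.0))
        assert input_resistance(ss) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_sweeps_rejected(self, make_step_sweepset):
        ss = make_step_sweepset([-50.0, -25.0],
                                lambda t, a: np.full_like(t, -70.0))
        with pytest.raises(FeatureUndefinedError, match="3"):
            input_resistance(ss)


class TestDetectSpikes:
    def test_three_triangular_spikes(self, make_spike_trace):
        tr = make_spike_trace([100.0, 200.0, 300.0])
        assert np.allclose(detect_spikes(tr), [100.0, 200.0, 300.0], atol=0.11)

    def test_subthreshold_trace_empty(self, make_step_sweepset, rc_response):
        ss = make_step_sweepset([20.0], rc_response())
        assert detect_spikes(ss.sweeps[0].trace).size == 0

    def test_noise_invariance_of_count(self, make_spike_trace):
        """Counts are unchanged by σ ≤ 0.2 mV noise when spikes are ≥40 mV."""
        tr = make_spike_trace(list(np.arange(50.0, 951.0, 50.0)))
        n_clean = detect_spikes(tr).size
        rng = np.random.default_rng(11)
        for _ in range(3):
            noisy = Trace(dt=tr.dt, samples=tr.samples + rng.normal(0, 0.2, tr.n),
                          unit="mV")
            assert detect_spikes(noisy).size == n_clean

    def test_matches_brute_force_oracle_on_simulation(self):
        """Same count as a scan of every sample for dV/dt-crossing-then-peak."""
        from fastspike.models import load_model
        from fastspike.simulate import SimProtocol, run_current_step

        sw = run_current_step(
            load_model("rs_a"), 300.0,
            SimProtocol(dt=0.05, step_duration=400.0, onset=50.0, tail=50.0,
                        settle=300.0),
        )
        v = sw.trace.samples
        dvdt = np.diff(v) / sw.trace.dt
        oracle_peaks = []
        i = 1
        while i < dvdt.size:
            if dvdt[i] >= 20.0 and dvdt[i - 1] < 20.0:
                j = i
                while j + 1 < v.size and v[j + 1] >= v[j]:
                    j += 1
                if j + 1 < v.size:
                    oracle_peaks.append(j)
                i = j
            i += 1
        assert detect_spikes(sw.trace).size == len(oracle_peaks)


class TestFiringCurveAndRheobase:
    def _counted_set(self, make_spike_trace, counts, duration=800.0):
        sweeps = []
        for amp, n in counts.items():
            times = np.linspace(150.0, 800.0, n) if n else []
            tr = make_spike_trace(times, duration=1000.0)
            sweeps.append(Sweep(trace=tr, sweep_id=f"s{amp}",
                                stimulus=StimulusStep(amplitude=amp, onset=100.0,
                                                      duration=duration)))
        return SweepSet(cell_id="c", sweeps=sweeps, mode="current_clamp")

    def test_counts_and_frequency(self, make_spike_trace):
        ss = self._counted_set(make_spike_trace, {100.0: 40})
        assert firing_curve(ss) == {100.0: 40}
        assert max_firing_frequency(ss) == pytest.approx(50.0)  # 40 / 0.8 s

    def test_max_over_sweeps(self, make_spike_trace):
        ss = self._counted_set(make_spike_trace, {100.0: 10, 200.0: 44, 300.0: 30})
        assert max_firing_frequency(ss) == pytest.approx(55.0)

    def test_one_second_step(self, make_spike_trace):
        ss = self._counted_set(make_spike_trace, {100.0: 40}, duration=850.0)
        assert max_firing_frequency(ss) == pytest.approx(40.0 / 0.85)

    def test_rheobase_is_smallest_spiking_amplitude(self, make_spike_trace):
        ss = self._counted_set(make_spike_trace,
                               {25.0: 0, 50.0: 0, 75.0: 2, 100.0: 5})
        assert rheobase(ss) == 75.0

    def test_rheobase_undefined_without_spikes(self, make_spike_trace):
        ss = self._counted_set(make_spike_trace, {25.0: 0, 50.0: 0})
        with pytest.raises(FeatureUndefinedError, match="rheobase undefined"):
            rheobase(ss)


class TestAPFeatures:
    def _triangle_ap_sweep(self, dt=0.01, fahp_depth=None):
        """Triangular AP: −40 → +30 mV over 0.6 ms and back (70 mV, hw 0.6)."""
        t = np.arange(0.0, 50.0, dt)
        v = np.full_like(t, -40.0)
        tp = 20.0
        tri = 70.0 - np.abs(t - tp) * 70.0 / 0.6
        v += np.clip(tri, 0.0, None)
        if fahp_depth is not None:
            dip = (fahp_depth) * np.exp(-((t - (tp + 3.0)) / 1.0) ** 2)
            v -= np.where(t > tp + 0.6, dip, 0.0)
        tr = Trace(dt=dt, samples=v, unit="mV")
        return Sweep(trace=tr, stimulus=StimulusStep(amplitude=100.0, onset=5.0,
                                                     duration=40.0))

    def test_triangular_geometry(self):
        sw = self._triangle_ap_sweep()
        ap = ap_features(None, sweep=sw)
        assert ap.amplitude == pytest.approx(70.0, rel=0.01)
        assert ap.half_width == pytest.approx(0.6, rel=0.02)

    def test_fahp_is_threshold_to_trough(self):
        sw = self._triangle_ap_sweep(fahp_depth=15.0)
        ap = ap_features(None, sweep=sw)
        # threshold −40 mV, post-spike minimum −55 mV
        assert ap.fahp == pytest.approx(15.0, abs=0.5)

    def test_threshold_matches_dense_third_derivative_oracle(self):
        """Sigmoidal upstroke: threshold within 0.5 mV of a brute-force
        dense finite-difference third-derivative maximum."""
        dt_dense, dt = 0.002, 0.02
        t_dense = np.arange(0.0, 40.0, dt_dense)

        def wave(t):
            rise = 1.0 / (1.0 + np.exp(-(t - 20.0) / 0.4))
            fall = np.exp(-np.clip(t - 20.0, 0, None) / 4.0)
            return -65.0 + 90.0 * rise * fall

        v_dense = wave(t_dense)
        i_peak = int(np.argmax(v_dense))
        d3 = np.gradient(np.gradient(np.gradient(v_dense, dt_dense), dt_dense), dt_dense)
        lo = i_peak - int(3.0 / dt_dense)
        thr_oracle = v_dense[lo + int(np.argmax(d3[lo:i_peak + 1]))]

        t = np.arange(0.0, 40.0, dt)
        tr = Trace(dt=dt, samples=wave(t), unit="mV")
        sw = Sweep(trace=tr, stimulus=StimulusStep(amplitude=100.0, onset=5.0,
                                                   duration=30.0))
        ap = ap_features(None, sweep=sw)
        assert ap.threshold_v == pytest.approx(thr_oracle, abs=0.5)

    def test_no_spike_in_sweep_rejected(self, make_step_sweepset, rc_response):
        ss = make_step_sweepset([50.0], rc_response())
        with pytest.raises(FeatureUndefinedError):
            ap_features(None, sweep=ss.sweeps[0])


class TestTrainStatistics:
    def test_sfa_examples(self):
        assert sfa([0.0, 10.0, 20.0, 30.0]) == pytest.approx(1.0)
        assert sfa([0.0, 10.0, 25.0, 55.0]) == pytest.approx(3.0)
        with pytest.raises(FeatureUndefinedError, match="SFA undefined"):
            sfa([0.0, 10.0])

    def test_cv_examples(self):
        assert cv([5.0, 5.0, 5.0]) == 0.0
        assert cv([1.0, 3.0]) == pytest.approx(np.sqrt(2.0) / 2.0, rel=1e-6)
        with pytest.raises(FeatureUndefinedError):
            cv([1.0])
        with pytest.raises(FeatureUndefinedError, match="zero mean"):
            cv([-1.0, 1.0])

    def test_cv_of_poisson_isis_near_one(self):
        rng = np.random.default_rng(5)
        isis = rng.exponential(20.0, 1000)
        assert cv(isis) == pytest.approx(1.0, abs=0.1)


class TestSagRebound:
    def test_pure_rc_has_no_sag(self, make_step_sweepset, rc_response):
        ss = make_step_sweepset([-50.0], rc_response())
        sag, reb = sag_rebound(ss)
        assert sag == pytest.approx(1.0, abs=0.02)
        assert reb == pytest.approx(0.0, abs=0.5)

    def test_arithmetic_example(self, make_step_sweepset):
        # V_min −80, V_ss −75, baseline −65 -> (−75+65)/(−80+65) = 2/3
        def resp(t, a):
            v = np.full_like(t, -65.0)
            on = (t >= 0) & (t < 800.0)
            v[on] = -75.0 - 5.0 * np.exp(-t[on] / 30.0)
            return v

        ss = make_step_sweepset([-50.0], resp)
        sag, _ = sag_rebound(ss)
        assert sag == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_h_conductance_produces_sag(self):
        """A hyperpolarization-activated conductance makes sag_ratio < 1."""
        from fastspike.models import load_model
        from fastspike.simulate import SimProtocol, run_protocol

        m = load_model("rs_a")
        m.channels["hcn"] = 0.0002
        p = SimProtocol(dt=0.05, step_currents=(-50.0,), step_duration=800.0,
                        onset=100.0, tail=200.0, settle=500.0)
        ss = run_protocol(m, p)
        sag, reb = sag_rebound(ss)
        assert sag < 0.97
        assert reb > 0.0

    def test_requires_hyperpolarizing_sweep(self, make_step_sweepset, rc_response):
        ss = make_step_sweepset([25.0, 50.0], rc_response())
        with pytest.raises(FeatureUndefinedError, match="hyperpolarizing"):
            sag_rebound(ss)


class TestDeterminism:
    def test_identical_sweepset_identical_profile(self):
        from fastspike.synth import CohortSpec, generate_cohort

        spec = CohortSpec(n_cells=1, fs_fraction=0.0, seed=9)
        sets, _ = generate_cohort(spec)
        p1 = extract_profile(sets[0])
        p2 = extract_profile(sets[0])
        assert p1.feature_row() == p2.feature_row()
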