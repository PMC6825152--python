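"""Shared fixtures: analytic waveforms with closed-form ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from fastspike.traces import StimulusStep, Sweep, SweepSet, Trace


@pytest.fixture
def make_spike_trace():
    """Factory for voltage traces with triangular APs at given peak times.

    Spikes rise from baseline to ``peak_v`` over ``rise_ms`` and fall
    back symmetrically — steep enough (>100 mV/ms) to satisfy any
    sensible upstroke criterion.
    """

    def _make(peak_times_ms, dt=0.05, duration=1000.0, baseline=-70.0,
              peak_v=20.0, rise_ms=0.5):
        t = np.arange(0.0, duration, dt)
        v = np.full_like(t, baseline)
        for tp in peak_times_ms:
            tri = peak_v - baseline - np.abs(t - tp) * (peak_v - baseline) / rise_ms
            v += np.clip(tri, 0.0, None)
        return Trace(dt=dt, samples=v, unit="mV")

    return _make


@pytest.fixture
def make_step_sweepset():
    """Factory for current-clamp step families with a voltage function.

    ``response(t, amplitude)`` gives the voltage at time ``t`` (ms,
    relative to step onset; negative = baseline) for each step.
    """

    def _make(amplitudes, response, dt=0.1, onset=100.0, duration=800.0,
              tail=100.0, cell_id="cell"):
        t = np.arange(0.0, onset + duration + tail, dt)
        sweeps = []
        for amp in amplitudes:
            v = response(t - onset, amp)
            sweeps.append(
                Sweep(
                    trace=Trace(dt=dt, samples=v, unit="mV"),
                    stimulus=StimulusStep(amplitude=amp, onset=onset, duration=duration),
                    sweep_id=f"s{amp:+.0f}",
                )
            )
        return SweepSet(cell_id=cell_id, sweeps=sweeps, mode="current_clamp")

    return _make


@pytest.fixture
def rc_response():
    """Exponential charging of an RC membrane: V = V0 + I·R·(1 − e^(−t/τ))."""

    def _resp(r_mohm=150.0, tau_ms=20.0, v_rest=-70.0, duration=800.0):
        def response(t, amp_pa):
            dv = amp_pa * r_mohm / 1000.0  # pA·MΩ -> mV
            v = np.full_like(t, v_rest, dtype=float)
            on = (t >= 0) & (t < duration)
            off = t >= duration
            v[on] += dv * (1.0 - np.exp(-t[on] / tau_ms))
            v_end = dv * (1.0 - np.exp(-duration / tau_ms))
            v[off] += v_end * np.exp(-(t[off] - duration) / tau_ms)
            return v

        return response

    return _resp
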