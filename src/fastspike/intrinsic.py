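"""Intrinsic and single-action-potential feature extraction.

Implements the measurements commonly reported for current-clamp step
families in cortical interneurons:

* resting membrane potential (RMP) — mean pre-stimulus voltage;
* input resistance — slope of the steady-state V–I relation over
  subthreshold steps, in MΩ;
* rheobase — smallest tested step amplitude that elicits a spike;
* firing curve and maximum firing frequency (spikes per second of
  stimulus);
* single-AP features measured on the first spike of the sweep 50 pA
  above rheobase: threshold (maximum of the third derivative of voltage
  with time on the upstroke), amplitude (threshold to peak), half-width
  (width at half amplitude, linearly interpolated), maximum dV/dt, and
  fast afterhyperpolarization (threshold to post-spike trough);
* spike-frequency accommodation (SFA, last/first inter-spike interval)
  and the coefficient of variation of the inter-spike intervals;
* sag ratio and rebound on a hyperpolarizing step.

Spike times are the times of AP peaks.  Detection uses an upstroke
criterion (dV/dt crossing, default 20 mV/ms) followed by the next local
maximum; the criterion is configurable because acquisition systems
differ but the default is robust for spikes of ≥40 mV amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .traces import Sweep, SweepSet, Trace

__all__ = [
    "APFeatures",
    "IntrinsicProfile",
    "FeatureConfig",
    "compute_rmp",
    "input_resistance",
    "detect_spikes",
    "firing_curve",
    "max_firing_frequency",
    "rheobase",
    "ap_features",
    "sfa",
    "cv",
    "sag_rebound",
    "extract_profile",
]


class FeatureUndefinedError(ValueError):
    """A feature's preconditions are not met (e.g. too few spikes)."""


@dataclass
class APFeatures:
    """Single-action-potential waveform features.

    ``fahp`` is stored as a non-negative magnitude: threshold voltage
    minus the post-spike voltage minimum.
    """

    peak_time: float      # ms
    threshold_v: float    # mV
    amplitude: float      # mV, threshold to peak
    half_width: float     # ms at half amplitude
    max_dvdt: float       # mV/ms on the upstroke
    fahp: float           # mV, threshold - trough
    sweep_amplitude: float = float("nan")  # pA of the sweep actually used


@dataclass
class IntrinsicProfile:
    """All scalar intrinsic features of one cell."""

    rmp: float                      # mV
    r_in: float                     # MΩ
    rheobase: float                 # pA
    firing_curve: dict              # pA -> spike count
    max_freq: float                 # Hz
    sfa: float                      # last ISI / first ISI
    cv_isi: float                   # sd/mean of ISIs
    ap: APFeatures
    sag_ratio: float | None = None
    rebound: float | None = None
    cell_id: str = ""

    def feature_row(self) -> dict:
        """Flat dict suitable for a one-row-per-cell table."""
        row = {
            "cell_id": self.cell_id,
            "rmp_mv": self.rmp,
            "r_in_mohm": self.r_in,
            "rheobase_pa": self.rheobase,
            "max_freq_hz": self.max_freq,
            "sfa": self.sfa,
            "cv_isi": self.cv_isi,
            "ap_threshold_mv": self.ap.threshold_v,
            "ap_amplitude_mv": self.ap.amplitude,
            "half_width_ms": self.ap.half_width,
            "max_dvdt_mv_per_ms": self.ap.max_dvdt,
            "fahp_mv": self.ap.fahp,
            "ap_sweep_pa": self.ap.sweep_amplitude,
            "sag_ratio": self.sag_ratio,
            "rebound_mv": self.rebound,
        }
        return row


@dataclass
class FeatureConfig:
    """Tunable windows and thresholds of the extraction pipeline.

    All times in ms, voltages in mV.  Defaults match the package's
    documented conventions; every knob is overridable per run.
    """

    dvdt_threshold: float = 20.0        # upstroke criterion, mV/ms
    spike_smooth_ms: float = 0.25       # pre-smoothing for the upstroke criterion
    refractory: float = 1.0             # merge window between peaks, ms
    baseline_window: float = 50.0       # RMP/baseline averaging, ms before onset
    steady_state_fraction: float = 0.25  # last fraction of step for steady state
    threshold_search: float = 3.0       # pre-peak window for AP threshold, ms
    smooth_window_ms: float = 0.5       # Savitzky-Golay window for d3V/dt3
    fahp_window: float = 10.0           # post-peak trough search bound, ms
    ap_current_above_rheobase: float = 50.0  # pA
    sfa_min_spikes: int = 10            # sweep choice for SFA/CV
    sag_amplitude: float = -50.0        # pA sweep for sag/rebound


# ---------------------------------------------------------------------------
# Passive properties


def compute_rmp(sweep_set: SweepSet, baseline_window: tuple[float, float] | None = None) -> float:
    """Resting membrane potential: mean pre-stimulus voltage, mV.

    Averages the voltage over ``baseline_window`` (ms interval) of every
    sweep; the window must precede stimulus onset in all sweeps.  By
    default the last 50 ms before the earliest onset are used.
    """
    _require_current_clamp(sweep_set)
    onset = min(s.stimulus.onset for s in sweep_set.sweeps)
    if baseline_window is None:
        baseline_window = (max(sweep_set.sweeps[0].trace.t0, onset - 50.0), onset)
    lo, hi = baseline_window
    if hi <= lo:
        raise ValueError(f"empty baseline window [{lo}, {hi})")
    if hi > onset + 1e-9:
        raise ValueError("baseline window must precede stimulus onset")
    vals = [s.trace.slice(lo, hi).mean() for s in sweep_set.sweeps]
    return float(np.mean(vals))


def input_resistance(
    sweep_set: SweepSet,
    steady_state_fraction: float = 0.25,
    config: FeatureConfig | None = None,
) -> float:
    """Input resistance in MΩ from the subthreshold V–I relation.

    The steady-state voltage of each spike-free sweep (mean over the
    last ``steady_state_fraction`` of the step) is regressed against the
    injected current; the least-squares slope in mV/pA is converted to
    MΩ (×1000).  Sweeps containing spikes are excluded.
    """
    _require_current_clamp(sweep_set)
    cfg = config or FeatureConfig()
    amps, dvs = [], []
    for sw in sweep_set.sweeps:
        if detect_spikes(sw.trace, config=cfg).size:
            continue
        stim = sw.stimulus
        base = sw.trace.slice(max(sw.trace.t0, stim.onset - cfg.baseline_window), stim.onset).mean()
        ss_start = stim.offset - steady_state_fraction * stim.duration
        v_ss = sw.trace.slice(ss_start, stim.offset).mean()
        amps.append(stim.amplitude)
        dvs.append(v_ss - base)
    if len(amps) < 3:
        raise FeatureUndefinedError(
            f"input resistance needs ≥3 spike-free sweeps, got {len(amps)}"
        )
    if np.ptp(amps) == 0:
        raise FeatureUndefinedError("all usable stimulus amplitudes are equal")
    slope = np.polyfit(amps, dvs, 1)[0]  # mV/pA
    return float(slope * 1000.0)  # → MΩ


# ---------------------------------------------------------------------------
# Spikes


def detect_spikes(trace: Trace, config: FeatureConfig | None = None) -> np.ndarray:
    """Spike peak times (ms), deterministic for a fixed trace.

    A spike is an upward crossing of the dV/dt criterion followed by the
    next local voltage maximum; peaks closer than the refractory merge
    window are collapsed onto the larger one.  The derivative is taken
    on a lightly smoothed copy (``spike_smooth_ms`` moving average) so
    recording noise of a few hundred µV cannot forge upstrokes; real AP
    upstrokes are orders of magnitude steeper than the criterion.
    """
    cfg = config or FeatureConfig()
    v = trace.samples
    w = max(1, int(round(cfg.spike_smooth_ms / trace.dt)))
    vs = uniform_filter1d(v, w) if w > 1 else v
    dvdt = np.diff(vs) / trace.dt
    above = dvdt >= cfg.dvdt_threshold
    onsets = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    peaks = []
    n = v.size
    for i0 in onsets:
        j = i0
        while j + 1 < n and vs[j + 1] >= vs[j]:
            j += 1
        if j + 1 >= n:
            continue  # truncated upstroke at trace end: not a resolvable peak
        # refine onto the raw samples around the smoothed maximum
        lo, hi = max(0, j - w), min(n, j + w + 1)
        peaks.append(lo + int(np.argmax(v[lo:hi])))
    if not peaks:
        return np.array([])
    # merge within refractory window, keeping the higher peak
    merged = [peaks[0]]
    min_sep = cfg.refractory / trace.dt
    for p in peaks[1:]:
        if p - merged[-1] < min_sep:
            if v[p] > v[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    return trace.t0 + trace.dt * np.asarray(merged, dtype=float)


def _spikes_in_stimulus(sweep: Sweep, config: FeatureConfig | None = None) -> np.ndarray:
    t = detect_spikes(sweep.trace, config=config)
    stim = sweep.stimulus
    return t[(t >= stim.onset) & (t <= stim.offset)]


def firing_curve(sweep_set: SweepSet, config: FeatureConfig | None = None) -> dict:
    """Spike count per depolarizing step amplitude, within the stimulus window."""
    _require_current_clamp(sweep_set)
    out = {}
    for sw in sweep_set.sorted_by_amplitude():
        if sw.stimulus.amplitude > 0:
            out[sw.stimulus.amplitude] = int(_spikes_in_stimulus(sw, config).size)
    if not out:
        raise FeatureUndefinedError("no depolarizing sweeps in set")
    return out


def max_firing_frequency(sweep_set: SweepSet, config: FeatureConfig | None = None) -> float:
    """Maximum firing frequency over sweeps: spike count / stimulus duration, Hz."""
    _require_current_clamp(sweep_set)
    best = None
    for sw in sweep_set.sweeps:
        if sw.stimulus.amplitude <= 0:
            continue
        f = _spikes_in_stimulus(sw, config).size / (sw.stimulus.duration / 1000.0)
        best = f if best is None else max(best, f)
    if best is None:
        raise FeatureUndefinedError("no depolarizing sweeps in set")
    return float(best)


def rheobase(sweep_set: SweepSet, config: FeatureConfig | None = None) -> float:
    """Smallest tested amplitude whose sweep contains ≥1 spike, pA.

    Resolution is limited to the tested grid (25 pA in the standard
    protocol).
    """
    for sw in sweep_set.sorted_by_amplitude():
        if sw.stimulus.amplitude <= 0:
            continue
        if _spikes_in_stimulus(sw, config).size:
            return float(sw.stimulus.amplitude)
    raise FeatureUndefinedError("rheobase undefined: no sweep elicited a spike")


# ---------------------------------------------------------------------------
# Single-AP features


def _select_ap_sweep(sweep_set: SweepSet, config: FeatureConfig) -> Sweep:
    """Sweep at rheobase + 50 pA if tested, else nearest tested amplitude above rheobase."""
    rb = rheobase(sweep_set, config)
    target = rb + config.ap_current_above_rheobase
    candidates = [s for s in sweep_set.sweeps if s.stimulus.amplitude >= rb]
    return min(candidates, key=lambda s: (abs(s.stimulus.amplitude - target), s.stimulus.amplitude))


def ap_features(
    sweep_set: SweepSet,
    config: FeatureConfig | None = None,
    sweep: Sweep | None = None,
) -> APFeatures:
    """Features of the first AP of the sweep ~50 pA above rheobase.

    Threshold is the voltage at the maximum of the third derivative of
    voltage with time, searched from ``threshold_search`` ms before the
    peak to the peak, after Savitzky–Golay smoothing (window
    ``smooth_window_ms``, order 3); ties break to the earliest time.
    Amplitude is threshold→peak; half-width is the trace width at
    threshold + amplitude/2, linearly interpolated between samples;
    max dV/dt is the steepest upstroke slope; fAHP is threshold minus
    the voltage minimum between the peak and min(peak + ``fahp_window``,
    next spike's upstroke).
    """
    cfg = config or FeatureConfig()
    if sweep is None:
        sweep = _select_ap_sweep(sweep_set, cfg)
    trace = sweep.trace
    spike_times = _spikes_in_stimulus(sweep, cfg)
    if spike_times.size == 0:
        raise FeatureUndefinedError(
            f"no AP in selected sweep ({sweep.stimulus.amplitude} pA)"
        )
    return _measure_ap(trace, spike_times, 0, cfg, sweep.stimulus.amplitude)


def _measure_ap(
    trace: Trace,
    spike_times: np.ndarray,
    which: int,
    cfg: FeatureConfig,
    sweep_amplitude: float = float("nan"),
) -> APFeatures:
    v = trace.samples
    dt = trace.dt
    peak_t = spike_times[which]
    i_peak = trace.index_at(peak_t)
    i_lo = max(0, i_peak - int(round(cfg.threshold_search / dt)))
    if i_peak - i_lo < 4:
        raise FeatureUndefinedError("pre-peak window truncated by trace start")
    seg = v[i_lo : i_peak + 1]

    # Threshold: maximum of the third derivative of voltage with time.
    # On effectively noise-free traces a cubic spline evaluated densely
    # recovers the true maximum to well under 0.1 mV; measured noise
    # switches to polynomial least-squares (Savitzky-Golay) smoothing,
    # which is robust but biases the estimate up the rise by ~the
    # window width, acceptable at recording noise levels.
    # The last ~quarter millisecond before the peak is excluded from the
    # search: there the discrete third derivative is dominated by the
    # sharp AP apex (a sampling artifact) rather than the take-off
    # curvature the threshold is meant to capture.
    i_excl = max(3, int(round(0.25 / dt)))
    i_top = max(4, seg.size - 1 - i_excl)
    noise = 1.4826 * np.median(np.abs(np.diff(v))) / np.sqrt(2.0)
    if noise < 0.02:
        ts = np.arange(seg.size) * dt
        spline = CubicSpline(ts, seg)
        t_fine = np.arange(0.0, ts[min(i_top, seg.size - 1)], dt / 20.0)
        t_star = t_fine[int(np.argmax(spline(t_fine, 3)))]  # earliest on ties
        i_thr = i_lo + int(round(t_star / dt))
        threshold_v = float(spline(t_star))
    else:
        win = max(5, int(round(cfg.smooth_window_ms / dt)) | 1)
        if win > seg.size:
            win = (seg.size - 1) | 1
            if win < 5:
                raise FeatureUndefinedError(
                    "too few samples for third-derivative threshold"
                )
        d3 = savgol_filter(seg, window_length=win, polyorder=3, deriv=3, delta=dt)
        i_thr = i_lo + int(np.argmax(d3[: i_top + 1]))  # earliest on ties
        threshold_v = float(v[i_thr])

    amplitude = float(v[i_peak] - threshold_v)
    if amplitude <= 0:
        raise FeatureUndefinedError("non-positive AP amplitude; threshold search failed")

    half_level = threshold_v + amplitude / 2.0
    half_width = _width_at_level(v, dt, i_thr, i_peak, half_level)

    upstroke = np.diff(v[i_thr : i_peak + 1]) / dt
    max_dvdt = float(upstroke.max()) if upstroke.size else float("nan")

    # fAHP trough: peak → min(peak + window, next spike's upstroke)
    i_hi = min(v.size, i_peak + int(round(cfg.fahp_window / dt)) + 1)
    if which + 1 < spike_times.size:
        i_next = trace.index_at(spike_times[which + 1])
        # back off to the start of the next upstroke (local minimum before next peak)
        i_min_before_next = i_peak + int(np.argmin(v[i_peak:i_next + 1]))
        i_hi = min(i_hi, i_min_before_next + 1)
    if i_hi <= i_peak + 1:
        raise FeatureUndefinedError("post-peak window truncated by trace end")
    trough = float(v[i_peak:i_hi].min())
    fahp = float(threshold_v - trough)

    return APFeatures(
        peak_time=float(peak_t),
        threshold_v=threshold_v,
        amplitude=amplitude,
        half_width=half_width,
        max_dvdt=max_dvdt,
        fahp=max(fahp, 0.0),
        sweep_amplitude=sweep_amplitude,
    )


def _width_at_level(v: np.ndarray, dt: float, i_thr: int, i_peak: int, level: float) -> float:
    """Width (ms) of the spike at ``level``, linearly interpolated at both flanks."""
    # rising crossing: last sample ≤ level before the peak
    rise = None
    for i in range(i_peak, i_thr - 1, -1):
        if v[i - 1] <= level < v[i] or v[i - 1] < level <= v[i]:
            frac = (level - v[i - 1]) / (v[i] - v[i - 1])
            rise = (i - 1 + frac) * dt
            break
    # falling crossing: first sample ≤ level after the peak
    fall = None
    for i in range(i_peak + 1, v.size):
        if v[i] <= level < v[i - 1] or v[i] < level <= v[i - 1]:
            frac = (v[i - 1] - level) / (v[i - 1] - v[i])
            fall = (i - 1 + frac) * dt
            break
    if rise is None or fall is None:
        raise FeatureUndefinedError("half-width crossing truncated by trace bounds")
    return float(fall - rise)


# ---------------------------------------------------------------------------
# Train statistics


def sfa(spike_times: np.ndarray) -> float:
    """Spike-frequency accommodation: last ISI / first ISI. Needs ≥3 spikes."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 3:
        raise FeatureUndefinedError(f"SFA undefined with {spike_times.size} spikes (<3)")
    isis = np.diff(spike_times)
    return float(isis[-1] / isis[0])


def cv(values) -> float:
    """Coefficient of variation: sample (n−1) standard deviation / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise FeatureUndefinedError("CV undefined with fewer than 2 values")
    m = values.mean()
    if m == 0:
        raise FeatureUndefinedError("CV undefined for zero mean")
    return float(values.std(ddof=1) / m)


def _select_train_sweep(sweep_set: SweepSet, cfg: FeatureConfig) -> tuple[Sweep, np.ndarray] | None:
    """Lowest-amplitude sweep with ≥ sfa_min_spikes spikes; falls back to the
    sweep with the most spikes if none reaches the minimum."""
    best = None
    for sw in sweep_set.sorted_by_amplitude():
        if sw.stimulus.amplitude <= 0:
            continue
        st = _spikes_in_stimulus(sw, cfg)
        if st.size >= cfg.sfa_min_spikes:
            return sw, st
        if best is None or st.size > best[1].size:
            best = (sw, st)
    return best


# ---------------------------------------------------------------------------
# Sag / rebound


def sag_rebound(
    sweep_set: SweepSet,
    amplitude: float | None = None,
    config: FeatureConfig | None = None,
) -> tuple[float, float]:
    """Sag ratio and rebound on a hyperpolarizing step.

    ``sag_ratio = (V_ss − V_baseline) / (V_min − V_baseline)`` — the
    steady-state deflection as a fraction of the peak deflection, where
    V_min is the voltage trough during the step and V_ss the
    steady-state mean.  1.0 means no sag (pure RC relaxation); an
    h-conductance that pulls the voltage back toward rest gives < 1.
    ``rebound`` is the post-stimulus peak voltage minus baseline, mV.
    """
    cfg = config or FeatureConfig()
    amp = cfg.sag_amplitude if amplitude is None else amplitude
    try:
        sw = sweep_set.sweep_at(amp)
    except KeyError:
        hyp = [s for s in sweep_set.sweeps if s.stimulus.amplitude < 0]
        if not hyp:
            raise FeatureUndefinedError("no hyperpolarizing sweep in set")
        sw = min(hyp, key=lambda s: s.stimulus.amplitude)
    stim = sw.stimulus
    tr = sw.trace
    base = tr.slice(max(tr.t0, stim.onset - cfg.baseline_window), stim.onset).mean()
    during = tr.slice(stim.onset, stim.offset)
    v_min = during.min()
    ss_start = stim.offset - cfg.steady_state_fraction * stim.duration
    v_ss = tr.slice(ss_start, stim.offset).mean()
    denom = v_min - base
    sag_ratio = float((v_ss - base) / denom) if abs(denom) > 1e-12 else 1.0
    t_end = tr.t0 + tr.span
    rebound = float(tr.slice(stim.offset, t_end).max() - base) if t_end > stim.offset else 0.0
    return sag_ratio, rebound


# ---------------------------------------------------------------------------
# Full profile


def extract_profile(sweep_set: SweepSet, config: FeatureConfig | None = None) -> IntrinsicProfile:
    """Extract the complete intrinsic profile of one cell.

    Deterministic: identical sweep sets yield identical profiles.
    SFA and CV of the inter-spike intervals are measured on the
    lowest-amplitude sweep with at least ``sfa_min_spikes`` spikes.
    """
    cfg = config or FeatureConfig()
    rmp = compute_rmp(sweep_set)
    try:
        r_in = input_resistance(sweep_set, cfg.steady_state_fraction, cfg)
    except FeatureUndefinedError:
        r_in = float("nan")
    rb = rheobase(sweep_set, cfg)
    curve = firing_curve(sweep_set, cfg)
    max_f = max_firing_frequency(sweep_set, cfg)
    ap = ap_features(sweep_set, cfg)

    train = _select_train_sweep(sweep_set, cfg)
    if train is not None and train[1].size >= 3:
        st = train[1]
        sfa_val = sfa(st)
        cv_val = cv(np.diff(st))
    else:
        sfa_val = float("nan")
        cv_val = float("nan")

    try:
        sag_ratio, rebound = sag_rebound(sweep_set, config=cfg)
    except FeatureUndefinedError:
        sag_ratio, rebound = None, None

    return IntrinsicProfile(
        rmp=rmp,
        r_in=r_in,
        rheobase=rb,
        firing_curve=curve,
        max_freq=max_f,
        sfa=sfa_val,
        cv_isi=cv_val,
        ap=ap,
        sag_ratio=sag_ratio,
        rebound=rebound,
        cell_id=sweep_set.cell_id,
    )


def _require_current_clamp(sweep_set: SweepSet) -> None:
    if sweep_set.mode != "current_clamp":
        raise ValueError("operation requires a current-clamp sweep set")
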