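"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:

* current-clamp cohorts of regular- and fast-spiking model cells with a
  controllable mixture proportion (:func:`generate_cohort`), standing in
  for slice recordings that are not publicly deposited;
* spontaneous/miniature IPSC recordings — Poisson event trains of
  biexponential outward currents in Gaussian noise
  (:func:`generate_ipsc_recording`);
* evoked IPSC trains whose per-pulse amplitudes follow the
  Tsodyks–Markram short-term plasticity recursion
  (:func:`generate_evoked_train`), so release probability is a dial.

Determinism: every generator draws from a stream derived from
``SeedSequence(seed, spawn_key=(index,))``, so cell ``i`` of a cohort is
identical whether cells are generated singly, chunked or all at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .models import load_model
from .simulate import NeuronModel, SimProtocol, SimulationError, run_protocol_batch
from .traces import Trace

__all__ = [
    "CohortSpec",
    "SynapticScenario",
    "default_cohort_profile",
    "generate_cohort",
    "iter_cohort",
    "generate_ipsc_recording",
    "generate_evoked_train",
    "tm_amplitudes",
    "biexp_event",
]


def default_cohort_profile() -> dict:
    ref = resources.files("fastspike") / "configs" / "cohort_default.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic current-clamp cohort.

    ``fs_fraction`` is the Bernoulli probability that a cell is drawn
    from the fast-spiking class; ``noise_sd`` the recording noise added
    to every voltage sample (mV).  ``profile`` holds the per-class
    parameter distributions and the step protocol (see
    ``configs/cohort_default.yaml``).
    """

    n_cells: int
    fs_fraction: float
    noise_sd: float = 0.2
    seed: int = 0
    profile: dict = field(default_factory=default_cohort_profile)

    def __post_init__(self) -> None:
        if not 0 <= self.fs_fraction <= 1:
            raise ValueError("fs_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")

    def protocol(self) -> SimProtocol:
        p = self.profile["protocol"]
        dep = p["depolarizing_currents"]
        currents = list(p["subthreshold_currents"]) + list(
            np.arange(dep["start"], dep["stop"] + dep["step"] / 2, dep["step"])
        )
        return SimProtocol(
            dt=float(p["dt"]),
            step_currents=tuple(float(c) for c in currents),
            step_duration=float(p["step_duration"]),
            onset=float(p["onset"]),
            tail=float(p["tail"]),
            settle=float(p["settle"]),
        )


def _draw_cell(spec: CohortSpec, index: int, attempt: int = 0) -> tuple[NeuronModel, dict]:
    """Deterministically draw one cell's model from its class distribution."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(index, attempt))
    )
    is_fs = rng.random() < spec.fs_fraction
    cls_name = "fs" if is_fs else "rs"
    cls = spec.profile["classes"][cls_name]
    base_name = cls["base_models"][rng.integers(len(cls["base_models"]))]
    model = load_model(base_name)
    jitter_sd = float(cls.get("jitter_sd", 0.0))
    for f in cls.get("jitter_fields", []):
        factor = float(np.exp(rng.normal(0.0, jitter_sd)))
        if f in model.channels:
            model.channels[f] *= factor
        elif f == "g_leak":
            model.g_leak *= factor
        elif f == "area":
            model.area *= factor
        else:
            raise ValueError(f"unknown jitter field {f!r}")
    lo, hi = cls["kv31_range"]
    kv31 = float(rng.uniform(lo, hi))
    model = model.with_gbar("kv31", kv31)
    model.name = f"cell_{index:04d}"
    truth = {
        "cell_id": model.name,
        "true_class": "FS" if is_fs else "RS",
        "base_model": base_name,
        "kv31_nominal": kv31,
        "noise_seed_key": index,
        "redraws": attempt,
    }
    return model, truth


def iter_cohort(spec: CohortSpec, chunk_size: int = 25):
    """Yield ``(sweep_sets, truth_rows)`` chunks of the cohort.

    Chunked generation keeps the working set small for large cohorts;
    results are identical to :func:`generate_cohort` cell for cell.
    A cell whose simulation diverges is redrawn from its class
    distribution (new substream), with the redraw count recorded.
    """
    protocol = spec.protocol()
    for start in range(0, spec.n_cells, chunk_size):
        idx = range(start, min(start + chunk_size, spec.n_cells))
        cells = [_draw_cell(spec, i) for i in idx]
        try:
            sweep_sets = run_protocol_batch([m for m, _ in cells], protocol)
        except SimulationError:
            # isolate and redraw offending cells one by one
            sweep_sets = []
            for j, (m, tr) in enumerate(cells):
                for attempt in range(1, 6):
                    try:
                        sweep_sets.append(run_protocol_batch([m], protocol)[0])
                        break
                    except SimulationError:
                        m, tr = _draw_cell(spec, idx[j], attempt)
                        cells[j] = (m, tr)
                else:
                    raise SimulationError(
                        f"cell {idx[j]} diverged after 5 redraws"
                    )
        truths = []
        for (model, truth), ss in zip(cells, sweep_sets):
            if spec.noise_sd > 0:
                noise_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=spec.seed,
                                           spawn_key=(truth["noise_seed_key"], 999))
                )
                for sw in ss.sweeps:
                    sw.trace.samples = sw.trace.samples + noise_rng.normal(
                        0.0, spec.noise_sd, sw.trace.n
                    )
            ss.metadata["true_class"] = truth["true_class"]
            truths.append(truth)
        yield sweep_sets, pd.DataFrame(truths)


def generate_cohort(spec: CohortSpec, chunk_size: int = 25):
    """Generate the full cohort: ``(list of SweepSet, ground-truth table)``."""
    all_sets, truths = [], []
    for sets, truth in iter_cohort(spec, chunk_size):
        all_sets.extend(sets)
        truths.append(truth)
    return all_sets, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# Synaptic generators


@dataclass
class SynapticScenario:
    """Generative parameters for IPSC recordings and evoked trains.

    Events are outward (positive) currents, matching recordings at a
    +10 mV holding potential.  Amplitudes are log-normal with median
    ``amp_median`` pA and log-space sd ``amp_sigma``; kinetics are a
    difference of exponentials with ``tau_rise`` < ``tau_decay`` (ms).
    The plasticity block (``U``, ``tau_rec``, ``tau_fac``) drives evoked
    trains through the Tsodyks–Markram recursion; ``tau_fac = 0``
    disables facilitation.
    """

    rate_hz: float = 5.0
    amp_median: float = 40.0
    amp_sigma: float = 0.3
    tau_rise: float = 1.5
    tau_decay: float = 15.0
    noise_sd: float = 3.0
    duration_s: float = 60.0
    dt: float = 0.1
    U: float = 0.5
    tau_rec: float = 200.0
    tau_fac: float = 0.0
    evoked_amp: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz < 0 or self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("rates and time constants must be positive")
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        if not 0 < self.U <= 1:
            raise ValueError("U must lie in (0, 1]")
        if self.noise_sd < 0 or self.duration_s <= 0 or self.dt <= 0:
            raise ValueError("invalid noise/duration/dt")


def biexp_event(t: np.ndarray, amplitude: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials waveform, normalized to peak = ``amplitude``.

    ``w(t) = A·(exp(−t/τ_d) − exp(−t/τ_r)) / w_peak`` for t ≥ 0, 0 before.
    """
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be smaller than tau_decay")
    t = np.asarray(t, dtype=float)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    norm = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                   - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    return amplitude * out / norm


def _render_events(times_ms, amps, n, dt, tau_rise, tau_decay) -> np.ndarray:
    trace = np.zeros(n)
    # render each event over a finite support (12 decay constants)
    n_sup = int(np.ceil(12 * tau_decay / dt))
    sup_t = np.arange(n_sup) * dt
    for t0, a in zip(times_ms, amps):
        i0 = int(np.round(t0 / dt))
        if i0 >= n:
            continue
        seg = biexp_event(sup_t, a, tau_rise, tau_decay)
        i1 = min(n, i0 + n_sup)
        trace[i0:i1] += seg[: i1 - i0]
    return trace


def generate_ipsc_recording(s: SynapticScenario) -> tuple[Trace, pd.DataFrame]:
    """Poisson train of biexponential IPSCs in Gaussian noise.

    Returns the current trace (pA) and the ground-truth event table
    (onset ms, amplitude pA).  ``noise_sd = 0`` yields the analytic sum
    of events exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=s.seed, spawn_key=(0,)))
    dur_ms = s.duration_s * 1000.0
    n = int(round(dur_ms / s.dt))
    n_events = rng.poisson(s.rate_hz * s.duration_s)
    onsets = np.sort(rng.uniform(0.0, dur_ms, n_events))
    amps = s.amp_median * np.exp(rng.normal(0.0, s.amp_sigma, n_events))
    samples = _render_events(onsets, amps, n, s.dt, s.tau_rise, s.tau_decay)
    if s.noise_sd > 0:
        samples = samples + rng.normal(0.0, s.noise_sd, n)
    truth = pd.DataFrame({"onset_ms": onsets, "amplitude_pa": amps})
    return Trace(dt=s.dt, samples=samples, unit="pA"), truth


def tm_amplitudes(pulse_times, U: float, tau_rec: float, tau_fac: float = 0.0) -> np.ndarray:
    """Per-pulse relative amplitudes from the Tsodyks–Markram recursion.

    With resources ``R`` (R₁ = 1) and utilization ``u`` (u₁ = U):

        u_{n+1} = U + u_n (1 − U) e^(−Δt/τ_fac)   (if τ_fac > 0, else u = U)
        R_{n+1} = 1 − (1 − R_n (1 − u_n)) e^(−Δt/τ_rec)

    Pulse n releases u_n·R_n; amplitudes are normalized to pulse 1.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_times.size < 1:
        raise ValueError("need at least one pulse")
    if np.any(np.diff(pulse_times) <= 0):
        raise ValueError("pulse times must be strictly increasing")
    if not 0 < U <= 1:
        raise ValueError("U must lie in (0, 1]")
    u, R = U, 1.0
    rel = [u * R]
    for dt_ms in np.diff(pulse_times):
        R = 1.0 - (1.0 - R * (1.0 - u)) * np.exp(-dt_ms / tau_rec)
        if tau_fac > 0:
            u = U + u * (1.0 - U) * np.exp(-dt_ms / tau_fac)
        else:
            u = U
        rel.append(u * R)
    rel = np.asarray(rel)
    return rel / rel[0]


def generate_evoked_train(
    s: SynapticScenario, pulse_times
) -> tuple[Trace, np.ndarray]:
    """Evoked IPSC train with short-term plasticity.

    Pulse ``n`` produces a biexponential event scaled by the
    Tsodyks–Markram relative amplitude; the first pulse has amplitude
    ``evoked_amp`` pA.  Returns the trace and the per-pulse true
    amplitudes (pA).
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    rel = tm_amplitudes(pulse_times, s.U, s.tau_rec, s.tau_fac)
    amps = s.evoked_amp * rel
    rng = np.random.default_rng(np.random.SeedSequence(entropy=s.seed, spawn_key=(1,)))
    dur_ms = pulse_times[-1] + 12 * s.tau_decay + 50.0
    n = int(round(dur_ms / s.dt))
    samples = _render_events(pulse_times, amps, n, s.dt, s.tau_rise, s.tau_decay)
    if s.noise_sd > 0:
        samples = samples + rng.normal(0.0, s.noise_sd, n)
    return Trace(dt=s.dt, samples=samples, unit="pA"), amps
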