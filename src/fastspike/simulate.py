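"""Reduced single-compartment conductance-based neuron simulator.

The membrane equation is the standard current balance

    C·dV/dt = i_inj − Σ_c ḡ_c·Π_g x_g^p_g·(V − E_c) − g_L·(V − E_L)

with first-order gate dynamics dx/dt = (x∞(V) − x)/τ_x(V).  C is the
specific capacitance (µF/cm²), conductance densities are S/cm², and the
injected current (pA) is converted to a density via the membrane area.

Integration is fixed-step: gates advance by the exponential (analytic)
update x ← x∞ + (x − x∞)·exp(−dt/τ), and the voltage by a semi-implicit
step that treats the conductances as frozen over dt,

    V ← (V + (dt/C)·(Σ g·E + i_inj/A)) / (1 + (dt/C)·Σ g),

which is stable for stiff spiking systems at dt = 0.025 ms.  Convergence
is tested against a half-step reference, not assumed.

The integrator is batched: a whole stimulus family (and, for cohort
generation, many cells) advances in one vectorized time loop.  Single-
sweep calls are the batch-of-one special case, so every code path is the
same code path the tests exercise.

The shipped model configurations (see :mod:`fastspike.models`) pair
Traub-type spike kinetics and an M-type potassium conductance — the
regular-spiking (RS) phenotype with spike-frequency accommodation —
with a Kv3.1 conductance whose density is the experimental dial:
raising ḡ_Kv3.1 toward 1.5 S/cm² speeds repolarization, deepens the
fast afterhyperpolarization, narrows the spike and relieves
accommodation, moving the model toward the fast-spiking (FS) phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .channels import default_registry, gate_rates, validate_channel
from .traces import StimulusStep, Sweep, SweepSet, Trace

__all__ = [
    "ChannelSpec",
    "NeuronModel",
    "SimProtocol",
    "SimulationError",
    "run_current_step",
    "run_protocol",
    "run_protocol_batch",
    "instantaneous_frequency",
    "kv31_sweep",
]

MS_PER_S = 1000.0


class SimulationError(RuntimeError):
    """Numerical divergence or an unusable protocol."""


@dataclass
class ChannelSpec:
    """One conductance: name, maximal density (S/cm²) and kinetics dict."""

    name: str
    gbar: float
    kinetics: dict

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError(f"gbar of {self.name!r} must be non-negative")
        validate_channel(self.name, self.kinetics)

    @property
    def reversal(self) -> float:
        return float(self.kinetics["reversal"])

    @property
    def gates(self) -> list[dict]:
        return self.kinetics.get("gates", [])


@dataclass
class NeuronModel:
    """Single-compartment model: passive parameters plus a channel set.

    Parameters
    ----------
    cm : float
        Specific membrane capacitance, µF/cm².
    area : float
        Membrane area, cm².  With g_leak it sets the input resistance
        ``R_in = 1/(g_leak·area)``.
    g_leak, e_leak : float
        Leak conductance density (S/cm²) and reversal (mV).
    channels : dict
        Channel name → ḡ (S/cm²); kinetics resolved from ``registry``.
    v_init : float
        Initial voltage, mV.
    channel_scale : dict
        Optional per-channel density multiplier.  In a single
        compartment, a channel confined to the soma of the original
        geometry would otherwise act over the whole membrane; the scale
        is the somatic area fraction it occupies, so nominal densities
        stay on the scale reported for morphologically detailed models.
    """

    cm: float = 1.0
    area: float = 1e-4
    g_leak: float = 5e-5
    e_leak: float = -70.0
    channels: dict = field(default_factory=dict)
    v_init: float = -70.0
    registry: dict = field(default_factory=default_registry)
    name: str = "model"
    channel_scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError("capacitance must be positive")
        if self.area <= 0:
            raise ValueError("area must be positive")
        for cname in self.channels:
            if cname not in self.registry:
                raise ValueError(f"channel {cname!r} not in registry")
        for spec in self.channel_specs():
            _ = spec  # construction validates

    def channel_specs(self) -> list[ChannelSpec]:
        return [
            ChannelSpec(name=c, gbar=g * self.channel_scale.get(c, 1.0),
                        kinetics=self.registry[c])
            for c, g in self.channels.items()
        ]

    def with_gbar(self, channel: str, gbar: float) -> "NeuronModel":
        """Copy of the model with one channel's nominal density replaced."""
        ch = dict(self.channels)
        if channel not in ch:
            raise ValueError(f"channel {channel!r} not present in model {self.name!r}")
        ch[channel] = gbar
        return NeuronModel(cm=self.cm, area=self.area, g_leak=self.g_leak,
                           e_leak=self.e_leak, channels=ch, v_init=self.v_init,
                           registry=self.registry, name=self.name,
                           channel_scale=dict(self.channel_scale))

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cm": self.cm,
            "area": self.area,
            "g_leak": self.g_leak,
            "e_leak": self.e_leak,
            "v_init": self.v_init,
            "channels": dict(self.channels),
            "channel_scale": dict(self.channel_scale),
            "registry": self.registry,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronModel":
        reg = d.get("registry") or default_registry()
        return cls(cm=d["cm"], area=d["area"], g_leak=d["g_leak"],
                   e_leak=d["e_leak"], channels=dict(d["channels"]),
                   v_init=d.get("v_init", -70.0), registry=reg,
                   name=d.get("name", "model"),
                   channel_scale=dict(d.get("channel_scale", {})))

    @classmethod
    def from_yaml(cls, path) -> "NeuronModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SimProtocol:
    """Current-step protocol.

    ``settle`` ms are integrated at zero current before recording starts,
    so the recorded trace begins at rest; ``onset`` ms of recorded
    baseline precede the step, and ``tail`` ms follow it.
    """

    dt: float = 0.025
    step_currents: tuple = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0)
    step_duration: float = 1000.0
    onset: float = 100.0
    tail: float = 100.0
    settle: float = 300.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.step_duration <= 0:
            raise ValueError("step duration must be positive")
        if len(set(self.step_currents)) != len(self.step_currents):
            raise ValueError("step currents must be unique")

    @property
    def total_duration(self) -> float:
        return self.onset + self.step_duration + self.tail


# ---------------------------------------------------------------------------
# Core integrator


class _BatchedSystem:
    """Vectorized state for B parallel compartments sharing a channel list."""

    def __init__(self, specs_per_member: list[list[ChannelSpec]],
                 cm: np.ndarray, area: np.ndarray,
                 g_leak: np.ndarray, e_leak: np.ndarray, v0: np.ndarray):
        names = [tuple(s.name for s in specs) for specs in specs_per_member]
        if len(set(names)) != 1:
            raise ValueError("all batch members must share the same channel list")
        self.B = len(specs_per_member)
        self.cm = cm
        self.area = area
        self.g_leak_ms = g_leak * 1000.0  # S/cm² -> mS/cm²
        self.e_leak = e_leak
        self.v = v0.astype(float).copy()
        # per channel: gbar (mS/cm², B), reversal, gates (shared kinetics)
        self.chan_gbar = []
        self.chan_erev = []
        self.chan_gates = []
        n_chan = len(specs_per_member[0])
        for ci in range(n_chan):
            self.chan_gbar.append(
                np.array([specs[ci].gbar for specs in specs_per_member]) * 1000.0
            )
            self.chan_erev.append(specs_per_member[0][ci].reversal)
            self.chan_gates.append(specs_per_member[0][ci].gates)
        # gate state at steady state for v0
        self.gate_x = []
        for gates in self.chan_gates:
            xs = []
            for g in gates:
                inf, _ = gate_rates(g, self.v)
                xs.append(np.asarray(inf, dtype=float).copy())
            self.gate_x.append(xs)

    def step(self, dt: float, i_density: np.ndarray) -> None:
        """One semi-implicit step. ``i_density`` in µA/cm², shape (B,)."""
        v = self.v
        g_sum = self.g_leak_ms.copy()
        ge_sum = self.g_leak_ms * self.e_leak
        for ci, gates in enumerate(self.chan_gates):
            g_open = self.chan_gbar[ci].copy()
            for gi, gate in enumerate(gates):
                inf, tau = gate_rates(gate, v)
                if tau is None:
                    x = inf
                else:
                    x = inf + (self.gate_x[ci][gi] - inf) * np.exp(-dt / tau)
                self.gate_x[ci][gi] = x
                p = gate["exponent"]
                g_open = g_open * (x if p == 1 else x ** p)
            g_sum += g_open
            ge_sum += g_open * self.chan_erev[ci]
        k = dt / self.cm
        self.v = (v + k * (ge_sum + i_density)) / (1.0 + k * g_sum)

    def run(self, dt: float, i_pa: np.ndarray, n_steps: int,
            record: bool = True) -> np.ndarray | None:
        """Advance ``n_steps``; ``i_pa`` is (B,) injected current in pA.

        Returns the recorded voltage array of shape (n_steps + 1, B)
        including the initial state, or None when not recording.
        """
        i_density = i_pa * 1e-6 / self.area  # pA -> µA, per cm²
        out = np.empty((n_steps + 1, self.B)) if record else None
        if record:
            out[0] = self.v
        for n in range(n_steps):
            self.step(dt, i_density)
            if record:
                out[n + 1] = self.v
            if (n & 0x3FF) == 0 and np.any(np.abs(self.v) > 200.0):
                bad = int(np.argmax(np.abs(self.v)))
                raise SimulationError(
                    f"voltage diverged (|V| > 200 mV) in batch member {bad} "
                    f"at step {n} (t = {n * dt:.2f} ms)"
                )
        if np.any(np.abs(self.v) > 200.0):
            raise SimulationError("voltage diverged (|V| > 200 mV) at end of run")
        return out


def _settle(system: _BatchedSystem, dt: float, settle_ms: float) -> float:
    """Integrate at zero current; returns the largest terminal |dV/dt| (mV/ms)."""
    n = int(round(settle_ms / dt))
    if n <= 0:
        return float("inf")
    zero = np.zeros(system.B)
    system.run(dt, zero, n - 1, record=False)
    v_before = system.v.copy()
    system.step(dt, zero)
    return float(np.max(np.abs(system.v - v_before) / dt))


def run_protocol_batch(models: list[NeuronModel], protocol: SimProtocol,
                       currents_per_model: list | None = None) -> list[SweepSet]:
    """Run the step protocol for many models in one vectorized time loop.

    All models must share the same channel name list (densities may
    differ).  Returns one current-clamp :class:`SweepSet` per model.
    """
    if not models:
        raise ValueError("no models to simulate")
    if currents_per_model is None:
        currents_per_model = [list(protocol.step_currents)] * len(models)
    specs, cm, area, gl, el, v0, i_step, owner = [], [], [], [], [], [], [], []
    for mi, (m, curr) in enumerate(zip(models, currents_per_model)):
        ms = m.channel_specs()
        for I in curr:
            specs.append(ms)
            cm.append(m.cm)
            area.append(m.area)
            gl.append(m.g_leak)
            el.append(m.e_leak)
            v0.append(m.v_init)
            i_step.append(I)
            owner.append(mi)
    sys_ = _BatchedSystem(specs, np.array(cm), np.array(area), np.array(gl),
                          np.array(el), np.array(v0))
    dt = protocol.dt
    resid = _settle(sys_, dt, protocol.settle)
    settled = resid < 0.01

    i_step = np.array(i_step)
    n_on = int(round(protocol.onset / dt))
    n_dur = int(round(protocol.step_duration / dt))
    n_tail = int(round(protocol.tail / dt))
    zero = np.zeros(len(i_step))

    segs = []
    if n_on:
        segs.append(sys_.run(dt, zero, n_on))
    segs.append(sys_.run(dt, i_step, n_dur))
    if n_tail:
        segs.append(sys_.run(dt, zero, n_tail))
    # drop the duplicated junction samples
    v_all = np.concatenate([segs[0]] + [s[1:] for s in segs[1:]], axis=0)

    out = []
    for mi, m in enumerate(models):
        cols = [bi for bi, o in enumerate(owner) if o == mi]
        sweeps = []
        for bi in cols:
            tr = Trace(dt=dt, samples=v_all[:, bi], unit="mV", t0=0.0)
            stim = StimulusStep(amplitude=float(i_step[bi]),
                                onset=protocol.onset,
                                duration=protocol.step_duration)
            sweeps.append(Sweep(trace=tr, stimulus=stim,
                                sweep_id=f"step_{i_step[bi]:+.0f}pA"))
        out.append(SweepSet(
            cell_id=m.name, sweeps=sweeps, mode="current_clamp",
            metadata={"settled": bool(settled), "settle_residual_mv_per_ms": resid,
                      "dt_ms": dt},
        ))
    return out


def run_protocol(model: NeuronModel, protocol: SimProtocol) -> SweepSet:
    """Run the full step family for one model."""
    return run_protocol_batch([model], protocol)[0]


def run_current_step(model: NeuronModel, amplitude_pa: float,
                     protocol: SimProtocol | None = None) -> Sweep:
    """Simulate a single current step and return the sweep.

    Fully deterministic; the voltage settles to rest before the recorded
    window starts, and non-settled rest is reported in the sweep set
    metadata of :func:`run_protocol`.
    """
    p = protocol or SimProtocol()
    p = SimProtocol(dt=p.dt, step_currents=(amplitude_pa,),
                    step_duration=p.step_duration, onset=p.onset,
                    tail=p.tail, settle=p.settle)
    return run_protocol(model, p).sweeps[0]


def instantaneous_frequency(spike_times) -> np.ndarray:
    """Instantaneous firing frequency, Hz, per consecutive spike pair."""
    st = np.asarray(spike_times, dtype=float)
    if st.size < 2:
        raise ValueError("instantaneous frequency needs at least 2 spikes")
    return MS_PER_S / np.diff(st)


def kv31_sweep(model: NeuronModel, gbar_values, protocol: SimProtocol | None = None,
               feature_config=None):
    """Sweep the Kv3.1 conductance density and profile each condition.

    For each ḡ value the full step protocol runs and the resulting sweep
    family goes through the same feature-extraction code path used for
    recordings.  Returns a DataFrame with one row per ḡ: maximum firing
    frequency, SFA, AP half-width, fAHP, rheobase and the FS/RS label.
    """
    import pandas as pd

    from .classify import classify
    from .intrinsic import extract_profile

    if "kv31" not in model.channels:
        raise ValueError(f"model {model.name!r} has no kv31 channel")
    p = protocol or SimProtocol()
    gbar_values = list(gbar_values)
    models = [model.with_gbar("kv31", g) for g in gbar_values]
    for m, g in zip(models, gbar_values):
        m.name = f"{model.name}_kv31_{g:g}"
    sweep_sets = run_protocol_batch(models, p)
    rows = []
    for g, ss in zip(gbar_values, sweep_sets):
        prof = extract_profile(ss, feature_config)
        label = classify(prof).label
        rows.append({
            "gbar_kv31": g,
            "max_freq_hz": prof.max_freq,
            "sfa": prof.sfa,
            "half_width_ms": prof.ap.half_width,
            "fahp_mv": prof.ap.fahp,
            "rheobase_pa": prof.rheobase,
            "ap_threshold_mv": prof.ap.threshold_v,
            "max_dvdt_mv_per_ms": prof.ap.max_dvdt,
            "label": label,
        })
    return pd.DataFrame(rows)
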