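"""Voltage-gated channel kinetics as a data-driven registry.

Every channel is described by a plain dict (serializable to YAML): a
reversal potential and a list of gates.  Each gate has an integer
exponent and either

* ``alpha``/``beta`` rate functions (classic Hodgkin–Huxley form, with
  an optional temperature-like rate multiplier ``phi``), or
* ``inf``/``tau`` steady-state and time-constant functions; ``tau`` may
  be omitted for an instantaneous gate.

Rate and curve functions are small named functional forms with
parameters, so a model configuration file can swap or re-parameterize
kinetics without touching code:

``linoid``    ``a·(v−vt) / (1 − exp(−(v−vt)/q))``  (singularity handled)
``expf``      ``a·exp((v−vt)/q)``
``sigmoid``   ``a / (1 + exp(−(v−vt)/q))``
``bell``      ``a / (exp((v−vt)/q1) + exp(−(v−vt)/q2))``
``constant``  ``a``

All voltages in mV, times in ms, rates in 1/ms.

The default registry ships four channels:

``na_t``   transient sodium (Traub-type kinetics with threshold shift),
           the spike generator;
``kdr_t``  delayed-rectifier potassium, the baseline repolarizer;
``km``     slow non-inactivating (M-type) potassium, source of
           spike-frequency accommodation in the regular-spiking
           phenotype;
``kv31``   the fast, high-threshold Kv3.1 delayed rectifier
           (first-order activation, no inactivation):
           ``m∞(V) = 1/(1+exp(−(V−18.7)/9.7))``,
           ``τ(V) = 4/(1+exp(−(V+46.56)/44.14))`` ms — the public
           Allen Cell Types "Kv3_1" description;
``hcn``    optional hyperpolarization-activated cation conductance for
           sag/rebound experiments.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = ["eval_curve", "gate_rates", "default_registry", "validate_channel"]

_TAU_FLOOR = 1e-3  # ms; keeps exponential-Euler updates finite


def eval_curve(spec: dict, v: np.ndarray) -> np.ndarray:
    """Evaluate a named functional form at membrane voltage ``v`` (mV)."""
    form = spec["form"]
    if form == "linoid":
        a, vt, q = spec["a"], spec["vt"], spec["q"]
        x = (v - vt) / q
        # lim x->0 of a*q*x/(1-exp(-x)) = a*q
        with np.errstate(over="ignore"):
            out = np.where(
                np.abs(x) < 1e-7,
                a * q * (1.0 + x / 2.0),
                a * q * x / (1.0 - np.exp(-np.clip(x, -500, 500))),
            )
        return out
    if form == "expf":
        return spec["a"] * np.exp(np.clip((v - spec["vt"]) / spec["q"], -500, 500))
    if form == "sigmoid":
        return spec["a"] / (1.0 + np.exp(np.clip(-(v - spec["vt"]) / spec["q"], -500, 500)))
    if form == "bell":
        e1 = np.exp(np.clip((v - spec["vt"]) / spec["q1"], -500, 500))
        e2 = np.exp(np.clip(-(v - spec["vt"]) / spec["q2"], -500, 500))
        return spec["a"] / (e1 + e2)
    if form == "constant":
        return np.full_like(np.asarray(v, dtype=float), spec["a"])
    raise ValueError(f"unknown functional form {form!r}")


def gate_rates(gate: dict, v: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Steady state and time constant (ms) of one gate at voltage ``v``.

    Returns ``(inf, tau)``; ``tau`` is ``None`` for instantaneous gates.
    """
    if "alpha" in gate:
        a = eval_curve(gate["alpha"], v)
        b = eval_curve(gate["beta"], v)
        phi = gate.get("phi", 1.0)
        s = a + b
        inf = a / s
        tau = 1.0 / (phi * s)
        return inf, np.maximum(tau, _TAU_FLOOR)
    inf = eval_curve(gate["inf"], v)
    if "tau" not in gate or gate["tau"] is None:
        return inf, None
    tau = eval_curve(gate["tau"], v)
    return inf, np.maximum(tau, _TAU_FLOOR)


def validate_channel(name: str, chan: dict) -> None:
    """Check structural validity and that time constants stay positive on
    the physiological range [−100, +60] mV."""
    if "reversal" not in chan:
        raise ValueError(f"channel {name!r} missing reversal potential")
    gates = chan.get("gates", [])
    v = np.linspace(-100.0, 60.0, 161)
    for i, g in enumerate(gates):
        if "exponent" not in g:
            raise ValueError(f"channel {name!r} gate {i} missing exponent")
        inf, tau = gate_rates(g, v)
        if np.any(~np.isfinite(inf)) or np.any(inf < -1e-9) or np.any(inf > 1 + 1e-9):
            raise ValueError(f"channel {name!r} gate {i}: steady state outside [0,1]")
        # evaluate tau without the runtime floor so bad kinetics are caught
        raw_tau = eval_curve(g["tau"], v) if "tau" in g and g["tau"] else tau
        if raw_tau is not None and (np.any(~np.isfinite(raw_tau)) or np.any(raw_tau <= 0)):
            raise ValueError(f"channel {name!r} gate {i}: non-positive time constant")


# ---------------------------------------------------------------------------
# Default registry

_VT = -56.2  # threshold shift of the Traub-type spike kinetics, mV

_DEFAULT_REGISTRY = {
    # Transient Na+: m^3 h, Traub kinetics shifted to cortical threshold.
    "na_t": {
        "reversal": 50.0,
        "gates": [
            {
                "exponent": 3,
                "alpha": {"form": "linoid", "a": 0.32 / 4.0 * 4.0, "vt": _VT + 13.0, "q": 4.0},
                "beta": {"form": "linoid", "a": -0.28, "vt": _VT + 40.0, "q": -5.0},
            },
            {
                "exponent": 1,
                "alpha": {"form": "expf", "a": 0.128, "vt": _VT + 17.0, "q": -18.0},
                "beta": {"form": "sigmoid", "a": 4.0, "vt": _VT + 40.0, "q": 5.0},
            },
        ],
    },
    # Delayed-rectifier K+: n^4.
    "kdr_t": {
        "reversal": -90.0,
        "gates": [
            {
                "exponent": 4,
                "alpha": {"form": "linoid", "a": 0.032, "vt": _VT + 15.0, "q": 5.0},
                "beta": {"form": "expf", "a": 0.5, "vt": _VT + 10.0, "q": -40.0},
            }
        ],
    },
    # Slow non-inactivating K+ (M-type): first-order, slow tau -> accommodation.
    "km": {
        "reversal": -90.0,
        "gates": [
            {
                "exponent": 1,
                "inf": {"form": "sigmoid", "a": 1.0, "vt": -35.0, "q": 10.0},
                "tau": {"form": "bell", "a": 400.0, "vt": -35.0, "q1": 20.0, "q2": 20.0},
            }
        ],
    },
    # Kv3.1: fast high-threshold delayed rectifier, first-order activation.
    "kv31": {
        "reversal": -90.0,
        "gates": [
            {
                "exponent": 1,
                "inf": {"form": "sigmoid", "a": 1.0, "vt": 18.7, "q": 9.7},
                "tau": {"form": "sigmoid", "a": 4.0, "vt": -46.56, "q": 44.14},
            }
        ],
    },
    # Hyperpolarization-activated cation conductance (sag/rebound).
    "hcn": {
        "reversal": -30.0,
        "gates": [
            {
                "exponent": 1,
                "inf": {"form": "sigmoid", "a": 1.0, "vt": -80.0, "q": -6.0},
                "tau": {"form": "constant", "a": 50.0},
            }
        ],
    },
}


def default_registry() -> dict:
    """A deep copy of the shipped channel registry (safe to mutate)."""
    return copy.deepcopy(_DEFAULT_REGISTRY)
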