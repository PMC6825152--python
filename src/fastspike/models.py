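"""Shipped neuron-model configurations.

Four regular-spiking (RS) single-compartment configurations ship with
the package (``rs_a`` … ``rs_d``).  They share the Traub-type spike
kinetics, an M-type potassium conductance that produces spike-frequency
accommodation, and a Kv3.1 conductance whose nominal density differs
per model (0.25, 0.009, 0.29 and 0.56 S/cm² — spanning the range found
in published detailed models of somatostatin-positive layer 5
interneurons).  Raising the nominal Kv3.1 density to 1.5 S/cm² moves
every configuration to the fast-spiking (FS) side of the classifier.

Configuration files are YAML; the ``phi`` block holds per-gate rate
multipliers applied on top of the default channel registry, and
``channel_scale`` the somatic area fraction of channels that are
somatically confined in the original geometry (see
:class:`~fastspike.simulate.NeuronModel`).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .channels import default_registry
from .simulate import NeuronModel

__all__ = ["MODEL_NAMES", "load_model", "load_shipped_models", "model_from_config"]

MODEL_NAMES = ("rs_a", "rs_b", "rs_c", "rs_d")


def model_from_config(cfg: dict) -> NeuronModel:
    """Build a :class:`NeuronModel` from a configuration dict.

    The dict may carry a full channel ``registry``; otherwise the
    default registry is used, optionally adjusted by a ``phi`` map of
    per-gate rate multipliers (``channel name -> [phi per gate]``).
    """
    registry = cfg.get("registry") or default_registry()
    for chan, phis in (cfg.get("phi") or {}).items():
        gates = registry[chan]["gates"]
        if len(phis) != len(gates):
            raise ValueError(
                f"phi list for {chan!r} has {len(phis)} entries, channel has {len(gates)} gates"
            )
        for gate, phi in zip(gates, phis):
            if "alpha" not in gate:
                raise ValueError(f"phi only applies to alpha/beta gates ({chan!r})")
            gate["phi"] = float(phi)
    return NeuronModel(
        cm=float(cfg.get("cm", 1.0)),
        area=float(cfg["area"]),
        g_leak=float(cfg["g_leak"]),
        e_leak=float(cfg["e_leak"]),
        channels={k: float(v) for k, v in cfg["channels"].items()},
        v_init=float(cfg.get("v_init", -70.0)),
        registry=registry,
        name=cfg.get("name", "model"),
        channel_scale={k: float(v) for k, v in (cfg.get("channel_scale") or {}).items()},
    )


def load_model(name_or_path: str | Path) -> NeuronModel:
    """Load a shipped configuration by name, or any YAML config by path."""
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        with open(p) as fh:
            return model_from_config(yaml.safe_load(fh))
    name = str(name_or_path)
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; shipped models: {MODEL_NAMES}")
    ref = resources.files("fastspike") / "configs" / f"{name}.yaml"
    with ref.open() as fh:
        return model_from_config(yaml.safe_load(fh))


def load_shipped_models() -> list[NeuronModel]:
    """All four shipped RS configurations, in name order."""
    return [load_model(n) for n in MODEL_NAMES]
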