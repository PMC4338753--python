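"""Structured-text configuration and reproducibility manifests.

A configuration file is YAML with up to four top-level sections:

.. code-block:: yaml

    morphology:            # surrogate-generator controls
      n_dend: 48
      seed: 1
      target_area: 70000.0
    passive:               # overrides of PassiveParams fields
      ra: 122.0
      e_leak: -55.0
      cm: {soma: 0.77, myelin: 0.06}
      g_leak: {terminal_dendrite: 1.367e-4}
    channels:              # gmax overrides / knockouts
      - {channel: Nav1.6, region: AIS, gmax: 0.0}
      - {channel: Kv3.4, region: soma, scale: 1.08}
    simulation:            # SimConfig fields
      dt: 0.025
      duration: 1000.0

An empty file (or missing sections) yields the canonical defaults: the
published conductance table on the surrogate morphology.  Unknown keys and
negative conductances are rejected with the offending key path.
"""

from __future__ import annotations

import getpass
import hashlib
import json
import platform
import time
from pathlib import Path

import yaml

from .channels import build_default_channelome, get_channel
from .morphology import PassiveParams, RegionTag, build_cell
from .solver import Model, SimConfig


def _version() -> str:
    import purkinje
    return getattr(purkinje, "__version__", "unknown")


class ConfigError(ValueError):
    """Schema violation; the message carries the key path."""


_MORPH_KEYS = {"n_dend", "seed", "target_area"}
_PASSIVE_KEYS = {"ra", "e_leak", "cm_default", "g_leak_default",
                 "cm", "g_leak"}
_SIM_KEYS = {"dt", "temperature", "duration", "v_init", "decim", "record",
             "pump_on"}
_CHAN_KEYS = {"channel", "region", "gmax", "scale", "erev"}


def _check_keys(d: dict, allowed: set, path: str) -> None:
    for k in d:
        if k not in allowed:
            raise ConfigError(f"unknown key {path}.{k}")


def _region(name: str, path: str) -> RegionTag:
    try:
        return RegionTag(name)
    except ValueError:
        raise ConfigError(f"{path}: unknown region {name!r}") from None


def load_config(path=None):
    """Parse a config file into ``(Model, SimConfig)``.

    ``path=None`` or an empty file gives the canonical defaults.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping")
    _check_keys(raw, {"morphology", "passive", "channels", "simulation"},
                "config")

    morph = dict(raw.get("morphology") or {})
    _check_keys(morph, _MORPH_KEYS, "morphology")
    n_dend = int(morph.get("n_dend", 48))
    seed = int(morph.get("seed", 1))
    target = float(morph.get("target_area", 70000.0))

    p = PassiveParams()
    pas = dict(raw.get("passive") or {})
    _check_keys(pas, _PASSIVE_KEYS, "passive")
    for k in ("ra", "e_leak", "cm_default", "g_leak_default"):
        if k in pas:
            setattr(p, k, float(pas[k]))
    for k, v in dict(pas.get("cm") or {}).items():
        p.cm_specific[_region(k, "passive.cm")] = float(v)
    for k, v in dict(pas.get("g_leak") or {}).items():
        if float(v) < 0:
            raise ConfigError(f"passive.g_leak.{k}: negative conductance")
        p.g_leak[_region(k, "passive.g_leak")] = float(v)

    chans = build_default_channelome()
    for i, row in enumerate(raw.get("channels") or []):
        pathi = f"channels[{i}]"
        if not isinstance(row, dict):
            raise ConfigError(f"{pathi}: expected a mapping")
        _check_keys(row, _CHAN_KEYS, pathi)
        try:
            spec = get_channel(chans, str(row["channel"]))
        except KeyError:
            raise ConfigError(
                f"{pathi}: unknown channel {row.get('channel')!r}") from None
        regions = ([_region(row["region"], pathi)] if row.get("region")
                   else list(spec.gmax_by_region))
        if "gmax" in row:
            g = float(row["gmax"])
            if g < 0:
                raise ConfigError(f"{pathi}: negative gmax")
            for r in regions:
                spec.gmax_by_region[r] = g
        if "scale" in row:
            s = float(row["scale"])
            if s < 0:
                raise ConfigError(f"{pathi}: negative scale")
            for r in regions:
                if r in spec.gmax_by_region:
                    spec.gmax_by_region[r] *= s
        if "erev" in row and spec.erev != "ca_ghk":
            spec.erev = float(row["erev"])

    sim = dict(raw.get("simulation") or {})
    _check_keys(sim, _SIM_KEYS, "simulation")
    cfg = SimConfig(
        dt=float(sim.get("dt", 0.025)),
        temperature=float(sim.get("temperature", 37.0)),
        duration=float(sim.get("duration", 1000.0)),
        v_init=float(sim.get("v_init", -65.0)),
        decim=int(sim.get("decim", 4)),
        pump_on=bool(sim.get("pump_on", True)),
    )
    if sim.get("record"):
        cfg.record = [tuple(r) for r in sim["record"]]

    morphology = build_cell(n_dend=n_dend, seed=seed, target_area=target,
                            passive=p)
    model = Model(morphology, p, chans, t_sim=cfg.temperature)
    return model, cfg


def parse_edit(spec: str):
    """Parse a ``channel:region:scale`` command-line edit (region ``all``
    scales every placement; ``dendrites`` covers the three dendritic
    tags)."""
    parts = spec.split(":")
    if len(parts) != 3:
        raise ConfigError(f"edit {spec!r}: expected channel:region:scale")
    name, region, scale = parts
    region = None if region == "all" else region
    try:
        return (name, region, float(scale))
    except ValueError:
        raise ConfigError(f"edit {spec!r}: bad scale") from None


def run_manifest(model: Model, cfg: SimConfig, extra: dict | None = None,
                 seed: int | None = None) -> dict:
    """Everything needed to reproduce a run bitwise on the same platform."""
    man = {
        "package_version": _version(),
        "channel_table_hash": model.table_hash(),
        "morphology": model.morphology.metadata,
        "passive": {
            "ra": model.passive.ra,
            "e_leak": model.passive.e_leak,
            "cm_default": model.passive.cm_default,
            "cm": {t.value: v for t, v in model.passive.cm_specific.items()},
            "g_leak_default": model.passive.g_leak_default,
            "g_leak": {t.value: v for t, v in model.passive.g_leak.items()},
        },
        "simulation": {
            "dt": cfg.dt, "temperature": cfg.temperature,
            "duration": cfg.duration, "v_init": cfg.v_init,
            "decim": cfg.decim,
        },
        "seed": seed,
        "platform": platform.platform(),
        "python": platform.python_version(),
        "wall_time": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        man.update(extra)
    man["manifest_hash"] = hashlib.sha256(
        json.dumps({k: v for k, v in man.items()
                    if k not in ("wall_time", "manifest_hash")},
                   sort_keys=True, default=str).encode()).hexdigest()
    return man


def write_manifest(man: dict, path) -> None:
    Path(path).write_text(json.dumps(man, indent=1, default=str))
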