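"""Configuration files, tabular output and run manifests.

Configs are YAML (or JSON, a YAML subset) with sections mirroring the
parameter dataclasses: ``neuron``, ``plasticity``, ``connectivity``,
``noise``, ``sim``.  Unknown keys are rejected by name; missing keys fall
back to the model defaults; cross-field sanity checks warn (e.g. a
plasticity threshold at or below the single-spike trace maximum would
defeat singlet nullification).  Output CSVs are RFC-4180, UTF-8, '.'
decimal; times in integer ms.  Every run directory carries a manifest
JSON tracing each file to the resolved config and seed scheme.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .params import (ConfigError, ConnectivitySpec, ModelConfig, NeuronParams,
                     NoiseSpec, PlasticityParams, SimParams)

__all__ = ["load_config", "dump_config", "write_outputs", "build_manifest"]

_SECTIONS = {
    "neuron": NeuronParams,
    "plasticity": PlasticityParams,
    "connectivity": ConnectivitySpec,
    "noise": NoiseSpec,
    "sim": SimParams,
}


def _build_section(name: str, cls, data: Dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key '{name}.{sorted(unknown)[0]}'")
    return cls(**data)


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[Dict] = None) -> ModelConfig:
    """Load and validate a config file; all defaults filled in.

    An empty (or absent) file resolves to the full default configuration.
    Schema violations raise :class:`ConfigError` naming the key and
    constraint; suspicious-but-legal settings warn.
    """
    data: Dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got "
                              f"{type(loaded).__name__}")
        data = loaded
    if overrides:
        for sec, vals in overrides.items():
            data.setdefault(sec, {}).update(vals)
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config section '{sorted(unknown)[0]}'")
    sections = {name: _build_section(name, cls, data.get(name, {}) or {})
                for name, cls in _SECTIONS.items()}
    config = ModelConfig(**sections).validate()
    _cross_checks(config)
    return config


def _cross_checks(config: ModelConfig) -> None:
    p = config.plasticity
    if p.eps_ltp <= p.a_plus or p.eps_ltd <= p.a_minus:
        warnings.warn(
            "plasticity threshold at or below the single-spike trace maximum "
            "(eps <= A): singlet spike pairings would trigger plasticity")
    if config.neuron.tau_s != p.tau_s:
        warnings.warn("neuron.tau_s and plasticity.tau_s differ; the EPSP "
                      "kernel and STDP traces use separate time constants")


def dump_config(config: ModelConfig) -> str:
    """Serialize the resolved config to YAML (round-trips via load)."""
    out = {name: dataclasses.asdict(getattr(config, name))
           for name in _SECTIONS}
    return yaml.safe_dump(out, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_manifest(config: ModelConfig, master_seed: int,
                   files: List[Path], out_dir: Path) -> Dict:
    from . import __version__
    return {
        "package": "thetastdp",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "master_seed": int(master_seed),
        "seed_scheme": ("SeedSequence(entropy=master_seed, "
                        "spawn_key=(crc32(condition_id), trial_index)); "
                        "per-consumer child streams: connectivity, "
                        "background, phases, noise, init"),
        "config": yaml.safe_load(dump_config(config)),
        "files": [{"name": f.name, "sha256": _sha256(f)} for f in files],
    }


def write_outputs(out_dir: str | Path, config: ModelConfig, master_seed: int,
                  spikes: Optional[pd.DataFrame] = None,
                  weights: Optional[pd.DataFrame] = None,
                  summary: Optional[pd.DataFrame] = None) -> Dict[str, Path]:
    """Write the run's CSV tables and manifest; idempotent overwrite.

    ``spikes``: (trial, time_ms, region, subgroup, neuron_id);
    ``weights``: (trial, time_ms, pre_subgroup, post_subgroup, mean_rho);
    ``summary``: one row per trial/condition.  Empty frames still produce
    headers.  Returns the written file inventory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    tables = {"spikes.csv": spikes, "weights.csv": weights,
              "summary.csv": summary}
    for name, df in tables.items():
        if df is None:
            continue
        path = out / name
        try:
            df.to_csv(path, index=False, lineterminator="\r\n")
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        written[name] = path
    manifest = build_manifest(config, master_seed, list(written.values()), out)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    written["manifest.json"] = mpath
    return written


def read_spikes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_accuracy_table(path: str | Path) -> Dict[float, float]:
    """Read a user-supplied empirical accuracy CSV (offset_deg, accuracy)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        off = cols["offset_deg"] if "offset_deg" in cols else cols["offset"]
        acc = cols["accuracy"]
    except KeyError:
        raise ConfigError("accuracy table needs columns offset_deg (or "
                          "offset) and accuracy") from None
    return {float(o): float(a) for o, a in zip(df[off], df[acc])}
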