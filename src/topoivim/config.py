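"""YAML run configuration.

A config file mirrors the dataclasses field-for-field, grouped in
sections::

    topopro:
      bounds_D: [1.0e-5, 0.02]
      penalty_weight: 1.0
    baselines:
      b_threshold: 200
    phantom:
      shape: [64, 64, 1]
      snr_per_slice: [10]
    evaluation:
      normalization: range
    output_dir: out
    verbosity: 1

Every field has a documented default (the dataclass defaults); unknown
keys are rejected with an error naming the key.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .baselines import BaselineConfig
from .ivim import ConfigurationError
from .phantom import PhantomSpec
from .topopro import TopoProConfig

__all__ = ["RunConfig", "load_config"]

_TUPLE_FIELDS = {"bounds_D", "bounds_Dstar", "bounds_f", "shape",
                 "snr_per_slice", "proposal_scales"}


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in section '{name}': {sorted(unknown)}")
    kwargs = {}
    for k, v in section.items():
        if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)):
            v = tuple(v)
        if k == "bvalues":
            v = np.asarray(v, dtype=float)
        kwargs[k] = v
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Merged configuration for the command-line pipeline."""

    topopro: TopoProConfig = field(default_factory=TopoProConfig)
    baselines: BaselineConfig = field(default_factory=BaselineConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    normalization: str = "range"
    output_dir: str = "."
    verbosity: int = 1

    def hash(self) -> str:
        """Stable digest of the full configuration, logged with every run."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return [float(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        return {
            "topopro": clean(dataclasses.asdict(self.topopro)),
            "baselines": clean(dataclasses.asdict(self.baselines)),
            "phantom": clean(dataclasses.asdict(self.phantom)),
            "evaluation": {"normalization": self.normalization},
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
        }


def load_config(path=None, seed=None) -> RunConfig:
    """Load a YAML run configuration; ``seed`` overrides every section's seed."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
    known = {"topopro", "baselines", "phantom", "evaluation",
             "output_dir", "verbosity"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    ev = raw.get("evaluation", {}) or {}
    ev_unknown = set(ev) - {"normalization"}
    if ev_unknown:
        raise ConfigurationError(
            f"unknown key(s) in section 'evaluation': {sorted(ev_unknown)}")
    topo = dict(raw.get("topopro", {}) or {})
    base = dict(raw.get("baselines", {}) or {})
    phan = dict(raw.get("phantom", {}) or {})
    if seed is not None:
        topo["seed"] = base["seed"] = phan["seed"] = int(seed)
    return RunConfig(
        topopro=_build(TopoProConfig, topo, "topopro"),
        baselines=_build(BaselineConfig, base, "baselines"),
        phantom=_build(PhantomSpec, phan, "phantom"),
        normalization=ev.get("normalization", "range"),
        output_dir=str(raw.get("output_dir", ".")),
        verbosity=int(raw.get("verbosity", 1)),
    )
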