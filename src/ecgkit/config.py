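"""Run configuration, seed derivation, and stage manifests.

A run is described by one YAML file with per-stage sections; CLI flags
override file values.  A single global seed deterministically derives every
stage seed through ``numpy.random.SeedSequence``, so one integer reproduces
a whole pipeline run.  Each stage writes a JSON manifest (inputs, seed,
parameters, output digests) sufficient for an exact re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._exceptions import ValidationError

logger = logging.getLogger(__name__)

# Fixed stage indices keep seed derivation stable across versions.
_STAGE_INDEX = {
    "simulate": 1, "preprocess": 2, "split": 3,
    "train": 4, "optimize": 5, "evaluate": 6,
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage seed = first word of SeedSequence([global_seed, stage_index]).

    Kept below 2**31 so the value fits any downstream integer-seed API.
    """
    if stage not in _STAGE_INDEX:
        raise ValidationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Pipeline-wide configuration with per-stage parameter dicts."""

    output_dir: Path = Path("ecgkit_run")
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    optimize: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file {path!s} does not exist")
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" in raw:
            raw["output_dir"] = Path(raw["output_dir"])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, stage: str, seed: int, params: dict,
                   inputs: list, outputs: list) -> Path:
    """Record one stage's provenance next to its outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": params,
        "inputs": [str(p) for p in inputs],
        "outputs": {str(p): file_digest(p) for p in outputs if Path(p).exists()},
    }
    path = out_dir / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
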