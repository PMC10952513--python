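"""Configuration files, run manifests and result serialization.

Design configurations and scenarios are human-edited YAML; trial results
and operating characteristics are machine-read JSON.  Every result file
embeds a manifest (config/scenario hashes, package version, master seed,
timestamp) plus a checksum of its own payload so that truncated or edited
files are detected on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone

import yaml

from .opchar import OperatingCharacteristics
from .trial import DesignConfig, TrialResult


class ConfigError(ValueError):
    pass


class CorruptResultError(RuntimeError):
    pass


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def config_hash(d: dict) -> str:
    return hashlib.sha256(_canonical_json(d).encode()).hexdigest()[:16]


def load_config(path) -> DesignConfig:
    """Load a design configuration; missing fields take the design defaults.

    Field-level validation errors are collected and reported together.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = set(DesignConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config fields: {unknown}; known fields: {sorted(known)}")
    try:
        return DesignConfig.from_dict(raw)
    except (ValueError, TypeError) as err:
        raise ConfigError(f"invalid design configuration in {path}: {err}") from err


def save_config(config: DesignConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    config_hash: str
    scenario_hash: str
    master_seed: int
    package_version: str
    created: str

    @classmethod
    def build(cls, config_dict: dict, scenario_dict: dict, seed: int) -> "RunManifest":
        from . import __version__
        return cls(config_hash=config_hash(config_dict),
                   scenario_hash=config_hash(scenario_dict),
                   master_seed=int(seed),
                   package_version=__version__,
                   created=datetime.now(timezone.utc).isoformat(timespec="seconds"))

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "scenario_hash": self.scenario_hash,
                "master_seed": self.master_seed, "package_version": self.package_version,
                "created": self.created}


def write_results(payload: dict, manifest: RunManifest, path) -> None:
    """Write a result JSON with an embedded payload checksum."""
    body = {"manifest": manifest.to_dict(), "payload": payload}
    body["checksum"] = config_hash(payload)
    with open(path, "w") as fh:
        json.dump(body, fh, indent=1, sort_keys=True)


def read_results(path) -> dict:
    with open(path) as fh:
        body = json.load(fh)
    if config_hash(body.get("payload", {})) != body.get("checksum"):
        raise CorruptResultError(f"checksum mismatch in {path}; file is corrupt or edited")
    return body


def write_trial_result(result: TrialResult, manifest: RunManifest, path) -> None:
    write_results({"kind": "trial", "result": result.to_dict()}, manifest, path)


def read_trial_result(path) -> TrialResult:
    body = read_results(path)
    return TrialResult.from_dict(body["payload"]["result"])


def write_opchar(oc: OperatingCharacteristics, manifest: RunManifest, path) -> None:
    write_results({"kind": "opchar", "metrics": oc.to_dict()}, manifest, path)


def read_opchar(path) -> OperatingCharacteristics:
    body = read_results(path)
    return OperatingCharacteristics.from_dict(body["payload"]["metrics"])
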