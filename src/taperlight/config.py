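"""Configuration I/O: fiber specs and run configs as flat YAML/JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .modal import PRESETS, FiberSpec

__all__ = ["load_fiber_spec", "save_fiber_spec", "load_run_config", "config_hash"]

_SPEC_KEYS = {
    "core_um", "clad_um", "na", "n_core", "n_clad",
    "taper_angle_deg", "wavelength_nm", "name",
}


def load_fiber_spec(source: str | Path | dict) -> FiberSpec:
    """Load a fiber spec from a preset name, a YAML/JSON file, or a dict."""
    if isinstance(source, dict):
        data = source
    elif isinstance(source, str) and source in PRESETS:
        return PRESETS[source]
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"fiber spec '{source}' is neither a preset "
                f"({', '.join(PRESETS)}) nor an existing file"
            )
        data = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    unknown = set(data) - _SPEC_KEYS
    if unknown:
        raise ValueError(f"unknown fiber spec fields: {sorted(unknown)}")
    return FiberSpec(**data)


def save_fiber_spec(spec: FiberSpec, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(spec.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))


def load_run_config(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"run config {path} must be a mapping")
    return data


def config_hash(config: dict) -> str:
    """Stable short hash embedded in output metadata for reproducibility."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
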