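"""Configuration loading, experiment presets, result writers, and logging.

Configs are YAML (or JSON) mappings with one section per sub-model::

    hippo:   {prod_fat: 1.0, ...}        # nM, minutes
    bell:    {kf10: ..., kBT: 4.1, ...}  # pN, nm, seconds
    mech:    {KN: 1200.0, FA_belt: 255.0, ...}
    growth:  {g0: 2.0e-5, Y0: 4.0, ...}
    coupler: {boundary_force: 100.0, catenin_per_cell: [...], ...}

Unknown keys are rejected with the offending key named; omitted keys take
the package defaults, so an empty file yields the fully-default coupled
model.  Every experiment preset (fig4, fig10, fig11, fig13, fig15, fig16,
fig17, fig18, fig19) is expressed as such a mapping with the published
settings pre-filled — e.g. fig16 fixes boundary alpha-catenin at 30
molecules/node and boundary forces of -100 and +100 pN per node.

Results are written as tidy RFC-4180 CSV plus a JSON run manifest whose
checksum is derived from the canonicalized (key-sorted) configuration, so
reordering keys in a config file does not change the manifest checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bsm_coupler import BSMConfig, GrowthParams, N_CELLS
from .catenin_gate import BellParams
from .hippo_network import HippoParams
from .tissue_mechanics import MechParams

__all__ = [
    "RunManifest",
    "PRESETS",
    "load_config",
    "config_to_dict",
    "config_checksum",
    "make_preset",
    "write_results",
    "get_logger",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"

_SECTION_TYPES = {
    "hippo": HippoParams,
    "bell": BellParams,
    "mech": MechParams,
    "growth": GrowthParams,
}
#: coupler-level keys (everything in BSMConfig that is not a sub-model)
_COUPLER_KEYS = {
    "edge_length", "catenin_per_cell", "vinculin", "jub_production",
    "jub_degradation", "jub_affinity", "conv_jub", "kJW_on", "kJW_off",
    "boundary_force", "horizon", "coupling_dt", "tension_mode",
    "fixed_tension",
}


def get_logger(level: str = "INFO") -> logging.Logger:
    """Package logger writing to stderr."""
    logger = logging.getLogger("hippomech")
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(h)
    logger.setLevel(level.upper())
    return logger


def _build_section(cls, data: dict, section: str, base):
    """Layer user keys over the coupled-model default for this section."""
    valid = {f.name for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown key {section}.{key}")
        if key != "ex_stabilization_mode" and isinstance(value, str):
            raise ValueError(f"{section}.{key} must be numeric, got {value!r}")
    try:
        return dataclasses.replace(base, **data)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid section {section!r}: {exc}") from exc


def _expand_per_cell(value, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(N_CELLS, float(arr[0]))
    if arr.size != N_CELLS:
        raise ValueError(f"{name} must be a scalar or length-{N_CELLS} list")
    return arr


def config_from_dict(data: dict) -> BSMConfig:
    """Validate a nested mapping and build the coupled-model config."""
    data = dict(data or {})
    base = BSMConfig()
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        sub = data.pop(section, {})
        if not isinstance(sub, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        kwargs[section] = _build_section(cls, sub, section,
                                         getattr(base, section))
    coupler = data.pop("coupler", {})
    if data:
        raise ValueError(f"unknown top-level key {sorted(data)[0]!r}")
    for key in coupler:
        if key not in _COUPLER_KEYS:
            raise ValueError(f"unknown key coupler.{key}")
    coupler = dict(coupler)
    for name in ("catenin_per_cell", "jub_production"):
        if name in coupler:
            coupler[name] = _expand_per_cell(coupler[name], name)
    if "jub_affinity" in coupler:
        coupler["jub_affinity"] = tuple(coupler["jub_affinity"])
    try:
        return BSMConfig(**kwargs, **coupler)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid coupler config: {exc}") from exc


def load_config(path) -> BSMConfig:
    """Load and validate a YAML/JSON config file; defaults fill the gaps."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return config_from_dict(data)


def config_to_dict(config: BSMConfig) -> dict:
    """Nested plain-python representation of a config (JSON-serializable)."""
    out = {}
    for section, cls in _SECTION_TYPES.items():
        obj = getattr(config, section)
        out[section] = {f.name: getattr(obj, f.name)
                        for f in dataclasses.fields(cls)}
    coupler = {}
    for key in sorted(_COUPLER_KEYS):
        v = getattr(config, key)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        coupler[key] = v
    out["coupler"] = coupler
    return out


def config_checksum(config: BSMConfig) -> str:
    """SHA-256 of the canonicalized (sorted-keys) config JSON."""
    blob = json.dumps(config_to_dict(config), sort_keys=True,
                      separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written beside every result set."""

    experiment: str
    config_checksum: str
    schema_version: str = SCHEMA_VERSION
    tolerances: dict = field(default_factory=lambda: {
        "hippo_steady_residual": 1e-8,
        "mech_speed_tol": 1e-4,
        "occupancy_settling_band": 0.01,
    })
    timestamp: str = ""
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# experiment presets: the published settings, pre-filled

def _preset_fig16() -> dict:
    return {"coupler": {"catenin_per_cell": 30.0, "jub_production": 250.0,
                        "boundary_force": 100.0}}


PRESETS: dict[str, dict] = {
    # Fat-production dose response of the biochemical network
    "fig4": {},
    # single-junction force sweeps and Vinculin dependence
    "fig10": {},
    "fig11": {},
    # purely mechanical demonstration (module-default soft network)
    "fig13": {"mech": {"KN": 100.0, "KT": 100.0, "damping": 100.0,
                       "FA_belt": 100.0}},
    # coupled scans
    "fig15": {"coupler": {"tension_mode": "fixed"}},
    "fig16": _preset_fig16(),
    "fig17": {"coupler": {"catenin_per_cell": 30.0, "jub_production": 250.0,
                          "boundary_force": 800.0}},
    "fig18": {"coupler": {"catenin_per_cell": 30.0, "jub_production": 250.0,
                          "boundary_force": 800.0}},
    # boundary Jub production fixed at 250 nM/min, environmental force 800 pN
    "fig19": {"coupler": {"jub_production": 250.0, "boundary_force": 800.0}},
}


def make_preset(name: str) -> BSMConfig:
    """Validated config for a named figure preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return config_from_dict(json.loads(json.dumps(PRESETS[name])))


def write_results(result: pd.DataFrame, out_dir, experiment: str,
                  config: BSMConfig | None = None) -> RunManifest:
    """Write a tidy CSV plus a JSON manifest; returns the manifest.

    The CSV round-trips exactly through ``pandas.read_csv``; the manifest
    checksum depends only on the canonicalized config, so repeated writes
    of the same configuration agree.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{experiment}.csv"
    result.to_csv(csv_path, index=False)
    manifest = RunManifest(
        experiment=experiment,
        config_checksum=(config_checksum(config) if config is not None
                         else config_checksum(BSMConfig())),
        timestamp=pd.Timestamp.now().isoformat(),
        outputs=[csv_path.name],
    )
    (out_dir / f"{experiment}_manifest.json").write_text(manifest.to_json())
    return manifest
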