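"""Config-file (YAML/JSON) serialization of :class:`SystemSpec`.

A config mirrors ``SystemSpec`` field-for-field in the package unit system.
A ``preset:`` key names a literature preset whose values are then overridden
block-by-block, e.g.::

    preset: pdu
    strategy: scaffold
    conditions:
      S1_out: 5.0e4

JSON files are accepted transparently (JSON is a YAML subset).
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from typing import Optional

import yaml

from .core import (
    EnzymeKinetics,
    ExternalConditions,
    Geometry,
    RateLaw,
    Strategy,
    SystemSpec,
    TransportParams,
)
from .errors import InvalidParameterError
from .presets import preset

__all__ = ["spec_to_dict", "spec_from_dict", "load_config", "save_config"]

_BLOCKS = {
    "enzyme1": EnzymeKinetics,
    "enzyme2": EnzymeKinetics,
    "transport": TransportParams,
    "geometry": Geometry,
    "conditions": ExternalConditions,
    "reverse1": EnzymeKinetics,
}


def _block_to_dict(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dc_fields(obj)}


def spec_to_dict(spec: SystemSpec) -> dict:
    d = {name: _block_to_dict(getattr(spec, name))
         for name in _BLOCKS if getattr(spec, name) is not None}
    d["strategy"] = spec.strategy.value
    d["rate_law"] = spec.rate_law.value
    return d


def _block_from_dict(cls, name: str, data: dict, base=None):
    if not isinstance(data, dict):
        raise InvalidParameterError(f"config block {name!r} must be a mapping")
    known = {f.name for f in dc_fields(cls)}
    bad = sorted(set(data) - known)
    if bad:
        raise InvalidParameterError(
            f"config block {name!r} has unknown fields {bad}; expected {sorted(known)}"
        )
    values = _block_to_dict(base) if base is not None else {}
    # coerce YAML-ambiguous scalars like "1.0e4" (string under YAML 1.1)
    for key, val in data.items():
        try:
            values[key] = float(val)
        except (TypeError, ValueError):
            raise InvalidParameterError(
                f"config field {name}.{key} must be a number, got {val!r}"
            ) from None
    missing = sorted(known - set(values))
    if missing:
        raise InvalidParameterError(
            f"config block {name!r} is missing fields {missing}"
        )
    return cls(**values)


def spec_from_dict(data: dict) -> SystemSpec:
    """Build a :class:`SystemSpec` from a config mapping.

    With a ``preset`` key the named preset supplies defaults and the
    remaining blocks act as overrides; otherwise every block is required.
    """
    if not isinstance(data, dict):
        raise InvalidParameterError("config root must be a mapping")
    data = dict(data)
    base: Optional[SystemSpec] = None
    if "preset" in data:
        base = preset(data.pop("preset"))
    known = set(_BLOCKS) | {"strategy", "rate_law"}
    bad = sorted(set(data) - known)
    if bad:
        raise InvalidParameterError(
            f"config has unknown top-level keys {bad}; expected {sorted(known | {'preset'})}"
        )
    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            base_block = getattr(base, name, None) if base is not None else None
            kwargs[name] = _block_from_dict(cls, name, data[name], base_block)
        elif base is not None:
            kwargs[name] = getattr(base, name)
        elif name != "reverse1":
            raise InvalidParameterError(f"config is missing required block {name!r}")
    kwargs["strategy"] = Strategy(
        data.get("strategy", base.strategy.value if base else Strategy.ORGANELLE)
    )
    kwargs["rate_law"] = RateLaw(
        data.get("rate_law", base.rate_law.value if base else RateLaw.IRREVERSIBLE_MM)
    )
    return SystemSpec(**kwargs)


def load_config(path) -> SystemSpec:
    """Load a YAML (or JSON) config file into a :class:`SystemSpec`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return spec_from_dict(data)


def save_config(spec: SystemSpec, path) -> None:
    """Write a spec as a YAML config that round-trips to identical values."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=True)
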