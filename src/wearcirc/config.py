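"""Pipeline configuration: versioned defaults plus user overrides.

All numeric defaults live in ``defaults.yaml`` shipped with the package.
A :class:`PipelineConfig` is a validated nested mapping; unknown keys are
rejected so a typo in a user config cannot silently fall back to a default.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "load_defaults"]


def load_defaults() -> dict[str, Any]:
    """Return a deep copy of the packaged default parameter tree."""
    text = resources.files("wearcirc").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base: dict[str, Any], override: Mapping[str, Any], path: str = "") -> dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


class PipelineConfig:
    """Nested configuration with attribute-free, mapping-style access.

    Construct with :meth:`default`, :meth:`from_dict` or :meth:`from_yaml`.
    Sections are plain dicts; ``cfg["rhythm"]["hr_mesor_mean"]`` etc.
    """

    def __init__(self, tree: dict[str, Any]):
        self._tree = tree

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls(load_defaults())

    @classmethod
    def from_dict(cls, overrides: Mapping[str, Any]) -> "PipelineConfig":
        return cls(_merge(load_defaults(), overrides))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        return cls.from_dict(overrides)

    def __getitem__(self, key: str) -> Any:
        return self._tree[key]

    def __contains__(self, key: str) -> bool:
        return key in self._tree

    def to_dict(self) -> dict[str, Any]:
        return copy.deepcopy(self._tree)

    def dump(self, path: str | Path) -> None:
        """Write the fully resolved configuration next to run outputs."""
        with open(path, "w") as fh:
            yaml.safe_dump(self._tree, fh, sort_keys=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PipelineConfig({list(self._tree)})"
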