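"""Declarative parameter configuration: loading, validation, round-trip.

A catalogue configuration is a YAML document that declares every model
parameter with its base value and plausible range (``{base, low, high}``),
split into blocks: the cytologist's accuracy, the two per-pass adequacy
levels, the enumerated stopping rules, parameters shared by all procedure
types, and the per-procedure-type blocks.  Key names carry explicit units
(``t_setup_min``, ``c_var_o_per_hr``) to keep unit bugs out of configs.

Two configurations ship with the package and are loadable by name:

* ``paper-base`` -- the base values and sensitivity ranges used throughout
  the package's worked examples;
* ``paper-prose-variant`` -- an alternate set (higher specificity, shorter
  setup times, a direct ROSE rate total for complex procedures) useful for
  exploring how sensitive conclusions are to those choices.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Any, Mapping

import yaml

PACKAGED_CONFIGS = ("paper-base", "paper-prose-variant")

#: config key -> canonical model symbol
KEY_TO_SYMBOL = {
    "t_setup_min": "t_setup",
    "t_pass_F_min": "t_pass_F",
    "t_pass_R_min": "t_pass_R",
    "c_var_o_per_hr": "c_var_o",
    "c_var_c_per_hr": "c_var_c",
    "c_pat_per_hr": "c_pat",
    "c_np_per_pass": "c_np",
    "c_fixed": "c_fixed",
}

_SHARED_KEYS = ("t_pass_F_min", "t_pass_R_min", "c_var_c_per_hr", "c_pat_per_hr")
_TYPE_KEYS = ("t_setup_min", "c_var_o_per_hr", "c_np_per_pass", "c_fixed")
_TYPE_OPTIONAL_KEYS = ("rose_adds_cytologist", "c_var_R_total_per_hr")
_TOP_KEYS = (
    "name",
    "description",
    "cytologist",
    "adequacy_levels",
    "stopping_rules",
    "shared",
    "procedure_types",
)

__all__ = ["ConfigError", "load_config", "save_config", "validate_config", "PACKAGED_CONFIGS", "KEY_TO_SYMBOL"]


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


def _check_range(path: str, node: Any, *, integer: bool = False) -> None:
    if not isinstance(node, Mapping):
        raise ConfigError(f"{path}: expected a mapping with base/low/high, got {node!r}")
    unknown = set(node) - {"base", "low", "high"}
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}; valid keys: base, low, high")
    missing = {"base", "low", "high"} - set(node)
    if missing:
        raise ConfigError(f"{path}: missing keys {sorted(missing)}")
    base, low, high = node["base"], node["low"], node["high"]
    for key, value in (("base", base), ("low", low), ("high", high)):
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"{path}.{key}: expected a number, got {value!r}")
        if integer and int(value) != value:
            raise ConfigError(f"{path}.{key}: expected an integer, got {value!r}")
    if not low <= base <= high:
        raise ConfigError(f"{path}: require low <= base <= high, got {low}, {base}, {high}")


def validate_config(cfg: Any) -> None:
    """Validate the schema of a catalogue configuration; raise ConfigError with itemized messages."""
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    unknown = set(cfg) - set(_TOP_KEYS)
    if unknown:
        raise ConfigError(
            f"unknown top-level keys {sorted(unknown)}; valid keys: {', '.join(_TOP_KEYS)}"
        )
    for key in ("cytologist", "adequacy_levels", "stopping_rules", "shared", "procedure_types"):
        if key not in cfg:
            raise ConfigError(f"missing required section {key!r}")

    cyt = cfg["cytologist"]
    for key in ("sn", "sp"):
        if key not in cyt:
            raise ConfigError(f"cytologist: missing {key!r}")
        _check_range(f"cytologist.{key}", cyt[key])
    unknown = set(cyt) - {"sn", "sp"}
    if unknown:
        raise ConfigError(f"cytologist: unknown keys {sorted(unknown)}; valid keys: sn, sp")

    levels = cfg["adequacy_levels"]
    if set(levels) != {"low", "high"}:
        raise ConfigError(f"adequacy_levels must define exactly low and high, got {sorted(levels)}")
    for name, node in levels.items():
        _check_range(f"adequacy_levels.{name}", node)

    rules = cfg["stopping_rules"]
    if set(rules) != {"n_F", "n_R"}:
        raise ConfigError(f"stopping_rules must define exactly n_F and n_R, got {sorted(rules)}")
    for name, node in rules.items():
        _check_range(f"stopping_rules.{name}", node, integer=True)

    shared = cfg["shared"]
    unknown = set(shared) - set(_SHARED_KEYS)
    if unknown:
        raise ConfigError(
            f"shared: unknown parameter keys {sorted(unknown)}; "
            f"valid symbols: {', '.join(_SHARED_KEYS)}"
        )
    for key in _SHARED_KEYS:
        if key not in shared:
            raise ConfigError(f"shared: missing parameter {key!r}")
        _check_range(f"shared.{key}", shared[key])

    types = cfg["procedure_types"]
    if not isinstance(types, Mapping) or not types:
        raise ConfigError("procedure_types must be a non-empty mapping")
    for tname, block in types.items():
        unknown = set(block) - set(_TYPE_KEYS) - set(_TYPE_OPTIONAL_KEYS)
        if unknown:
            raise ConfigError(
                f"procedure_types.{tname}: unknown parameter keys {sorted(unknown)}; "
                f"valid symbols: {', '.join(_TYPE_KEYS + _TYPE_OPTIONAL_KEYS)}"
            )
        for key in _TYPE_KEYS:
            if key not in block:
                raise ConfigError(f"procedure_types.{tname}: missing parameter {key!r}")
            _check_range(f"procedure_types.{tname}.{key}", block[key])
        if "rose_adds_cytologist" in block and not isinstance(block["rose_adds_cytologist"], bool):
            raise ConfigError(f"procedure_types.{tname}.rose_adds_cytologist: expected a boolean")
        if "c_var_R_total_per_hr" in block:
            value = block["c_var_R_total_per_hr"]
            if not isinstance(value, (int, float)) or isinstance(value, bool) or value < 0:
                raise ConfigError(
                    f"procedure_types.{tname}.c_var_R_total_per_hr: expected a non-negative number"
                )


def load_config(name_or_path: str | Path) -> dict:
    """Load a catalogue configuration by packaged name or file path."""
    if isinstance(name_or_path, str) and name_or_path in PACKAGED_CONFIGS:
        resource = importlib.resources.files("rosecost.data") / f"{name_or_path}.yaml"
        text = resource.read_text(encoding="utf-8")
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ConfigError(
                f"config {name_or_path!r} is neither a packaged name "
                f"({', '.join(PACKAGED_CONFIGS)}) nor an existing file"
            )
        text = path.read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    validate_config(cfg)
    return cfg


def save_config(cfg: Mapping, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    validate_config(cfg)
    Path(path).write_text(yaml.safe_dump(dict(cfg), sort_keys=False), encoding="utf-8")
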