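"""Water-quality parameters and standard sets.

A *standard* is the safe threshold a monitored concentration is screened
against. Thresholds come in three shapes: an upper limit (most pollutants:
BOD, suspended solids, coliforms, ammonia nitrogen, total phosphorus), a
lower limit (dissolved oxygen, where *low* values are the hazard) and a
two-sided range (pH). A :class:`StandardRegistry` holds one or more named
sets of standards — the built-in defaults carry the Taiwan EPA Class A
surface-water criteria alongside the drinking-water quality standards, the
two sets used to screen raw water in the Taipei Source Water Area (TSWA).

Monitoring files and regulatory tables label the same parameter differently
("TP" vs "total phosphorus"), so all lookups go through a normalising alias
table. Total coliform counts are screened against the Class A *E. coli*
row (50 CFU/100 mL), the convention used in the TSWA screening tables.
Suspended solids (surface-water criterion) and total dissolved solids
(drinking-water criterion) are deliberately distinct parameters and are
never cross-compared.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Union

import yaml

__all__ = [
    "StandardKind",
    "Parameter",
    "Standard",
    "StandardRegistry",
    "ConfigError",
    "StandardNotFoundError",
    "normalize_parameter",
    "load_standards",
    "default_registry",
]


class ConfigError(ValueError):
    """A standards configuration is malformed."""


class StandardNotFoundError(KeyError):
    """No standard exists for the requested (parameter, set) pair."""


class StandardKind(str, Enum):
    UPPER_LIMIT = "upper_limit"
    LOWER_LIMIT = "lower_limit"
    RANGE = "range"


# canonical name -> squashed aliases (lowercase, punctuation/space stripped)
_ALIASES: dict[str, tuple[str, ...]] = {
    "pH": ("ph",),
    "DO": ("do", "dissolvedoxygen", "oxygen"),
    "BOD": ("bod", "biochemicaloxygendemand"),
    "SS": ("ss", "suspendedsolids", "solids"),
    "TDS": ("tds", "totaldissolvedsolids"),
    "E. coli": ("ecoli", "escherichiacoli", "totalcoliforms", "coliforms"),
    "NH3-N": ("nh3n", "ammonianitrogen", "ammonia"),
    "TP": ("tp", "totalphosphorus", "phosphorus"),
}

_ALIAS_LOOKUP: dict[str, str] = {
    alias: canon for canon, aliases in _ALIASES.items() for alias in aliases
}


def _squash(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


def normalize_parameter(name: str) -> str:
    """Map a free-text parameter label onto its canonical name.

    Unknown labels are returned squashed-but-unmapped so that user-defined
    parameters still key consistently.
    """
    squashed = _squash(name)
    return _ALIAS_LOOKUP.get(squashed, squashed)


@dataclass(frozen=True)
class Parameter:
    name: str
    units: str
    kind: StandardKind


@dataclass(frozen=True)
class Standard:
    """One parameter's threshold within a named standard set."""

    parameter: Parameter
    standard_set: str
    upper: float | None = None
    lower: float | None = None

    def __post_init__(self) -> None:
        kind = self.parameter.kind
        if kind in (StandardKind.UPPER_LIMIT, StandardKind.RANGE):
            if self.upper is None:
                raise ConfigError(
                    f"{self.parameter.name} ({self.standard_set}): kind "
                    f"{kind.value} requires an upper limit"
                )
        elif self.upper is not None:
            raise ConfigError(
                f"{self.parameter.name}: upper limit given for kind {kind.value}"
            )
        if kind in (StandardKind.LOWER_LIMIT, StandardKind.RANGE):
            if self.lower is None:
                raise ConfigError(
                    f"{self.parameter.name} ({self.standard_set}): kind "
                    f"{kind.value} requires a lower limit"
                )
        elif self.lower is not None:
            raise ConfigError(
                f"{self.parameter.name}: lower limit given for kind {kind.value}"
            )
        if self.upper is not None and self.lower is not None:
            if not self.lower < self.upper:
                raise ConfigError(
                    f"{self.parameter.name}: lower {self.lower} must be "
                    f"< upper {self.upper}"
                )
        for limit in (self.upper, self.lower):
            if limit is not None and limit <= 0:
                raise ConfigError(
                    f"{self.parameter.name}: limits must be positive, got {limit}"
                )


class StandardRegistry:
    """Lookup table of standards keyed by (canonical parameter, set)."""

    def __init__(self) -> None:
        self._standards: dict[tuple[str, str], Standard] = {}

    def add(self, standard: Standard) -> None:
        key = (normalize_parameter(standard.parameter.name), standard.standard_set)
        if key in self._standards:
            raise ConfigError(
                f"duplicate standard for parameter {standard.parameter.name!r} "
                f"in set {standard.standard_set!r}"
            )
        self._standards[key] = standard

    def lookup(self, parameter: str, standard_set: str) -> Standard:
        key = (normalize_parameter(parameter), standard_set)
        try:
            return self._standards[key]
        except KeyError:
            raise StandardNotFoundError(
                f"no standard for parameter {parameter!r} in set {standard_set!r}"
            ) from None

    def get(self, parameter: str, standard_set: str) -> Standard | None:
        return self._standards.get((normalize_parameter(parameter), standard_set))

    def __contains__(self, key: tuple[str, str]) -> bool:
        parameter, standard_set = key
        return (normalize_parameter(parameter), standard_set) in self._standards

    def __iter__(self) -> Iterator[Standard]:
        return iter(self._standards.values())

    def __len__(self) -> int:
        return len(self._standards)

    @property
    def standard_sets(self) -> list[str]:
        return sorted({s.standard_set for s in self})

    def to_dict(self) -> dict:
        """Serialise to the sets -> parameters -> limits config mapping."""
        out: dict[str, dict[str, dict]] = {}
        for std in self._standards.values():
            entry: dict[str, object] = {
                "kind": std.parameter.kind.value,
                "units": std.parameter.units,
            }
            if std.upper is not None:
                entry["upper"] = std.upper
            if std.lower is not None:
                entry["lower"] = std.lower
            out.setdefault(std.standard_set, {})[std.parameter.name] = entry
        return {"sets": out}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def _registry_from_mapping(doc: Mapping) -> StandardRegistry:
    if not isinstance(doc, Mapping) or "sets" not in doc:
        raise ConfigError("standards config must be a mapping with a 'sets' key")
    registry = StandardRegistry()
    for set_name, params in doc["sets"].items():
        if not isinstance(params, Mapping):
            raise ConfigError(f"set {set_name!r} must map parameters to limits")
        for pname, entry in params.items():
            if not isinstance(entry, Mapping):
                raise ConfigError(f"{set_name}/{pname}: entry must be a mapping")
            if "upper" not in entry and "lower" not in entry:
                raise ConfigError(f"{set_name}/{pname}: at least one limit required")
            try:
                kind = StandardKind(entry.get("kind", _infer_kind(entry)))
            except ValueError as exc:
                raise ConfigError(f"{set_name}/{pname}: {exc}") from None
            parameter = Parameter(
                name=str(pname), units=str(entry.get("units", "")), kind=kind
            )
            registry.add(
                Standard(
                    parameter=parameter,
                    standard_set=str(set_name),
                    upper=_opt_float(entry.get("upper")),
                    lower=_opt_float(entry.get("lower")),
                )
            )
    return registry


def _infer_kind(entry: Mapping) -> str:
    if "upper" in entry and "lower" in entry:
        return "range"
    return "upper_limit" if "upper" in entry else "lower_limit"


def _opt_float(x: object) -> float | None:
    return None if x is None else float(x)


def load_standards(source: Union[str, Path, io.TextIOBase, Mapping]) -> StandardRegistry:
    """Build a registry from a YAML file/path/stream or an in-memory mapping."""
    if isinstance(source, Mapping):
        return _registry_from_mapping(source)
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    return _registry_from_mapping(doc)


#: Class A surface-water criteria vs drinking-water quality standards.
#: Cells the regulation leaves unspecified are simply absent and raise
#: StandardNotFoundError on lookup.
_DEFAULT_CONFIG: dict = {
    "sets": {
        "class_a": {
            "pH": {"kind": "range", "lower": 6.5, "upper": 8.5, "units": "pH units"},
            "DO": {"kind": "lower_limit", "lower": 6.5, "units": "mg/L"},
            "BOD": {"kind": "upper_limit", "upper": 1.0, "units": "mg/L"},
            "SS": {"kind": "upper_limit", "upper": 25.0, "units": "mg/L"},
            "E. coli": {"kind": "upper_limit", "upper": 50.0, "units": "CFU/100 mL"},
            "NH3-N": {"kind": "upper_limit", "upper": 0.1, "units": "mg/L"},
            "TP": {"kind": "upper_limit", "upper": 0.02, "units": "mg/L"},
        },
        "drinking": {
            "pH": {"kind": "range", "lower": 6.0, "upper": 8.5, "units": "pH units"},
            "TDS": {"kind": "upper_limit", "upper": 500.0, "units": "mg/L"},
            "E. coli": {"kind": "upper_limit", "upper": 6.0, "units": "CFU/100 mL"},
            "NH3-N": {"kind": "upper_limit", "upper": 0.1, "units": "mg/L"},
        },
    }
}


def default_registry() -> StandardRegistry:
    """The built-in Class A / drinking-water standard sets."""
    return _registry_from_mapping(_DEFAULT_CONFIG)
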