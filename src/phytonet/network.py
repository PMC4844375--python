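"""Photosynthetic network structure: variables, pairs, modules.

The network is data, not code: a :class:`NetworkSpec` names the measured
physiological variables and groups the pairwise relationships of interest
into modules (by default a *gas exchange* module and a *photochemical*
module) plus the single pair linking them (ETR with light-saturated
assimilation). :func:`default_network` builds the canonical published
network of 9 gas-exchange pairs, 6 photochemical pairs and 1 linking pair;
:func:`load_network` / :func:`serialize_network` round-trip any valid
network through a YAML config.

Variable names are plain ASCII identifiers safe for CSV headers; the
mapping to the field's usual symbols is in :data:`FIELD_SYMBOLS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ValidationError

#: ASCII column name -> conventional symbol used in the plant-physiology literature.
FIELD_SYMBOLS = {
    "AmaxL": "A_maxL (light-saturated net assimilation, µmol CO2 m-2 s-1)",
    "gs": "g_s (stomatal conductance, mol H2O m-2 s-1)",
    "E": "E (transpiration, mmol H2O m-2 s-1)",
    "Rd": "R_d (dark respiration, µmol CO2 m-2 s-1)",
    "Pr": "Pr (photorespiration, µmol CO2 m-2 s-1)",
    "Ci": "Ci (intercellular CO2, µmol mol-1)",
    "FvFm": "Fv/Fm (potential PSII quantum efficiency, dimensionless)",
    "dF_Fm": "ΔF/Fm' (effective PSII quantum efficiency, dimensionless)",
    "NPQ": "NPQ (non-photochemical quenching, dimensionless)",
    "ETR": "ETR (apparent electron transport rate, µmol m-2 s-1)",
}

_MODULE_HINTS = ("gas_exchange", "photochemical", "growth", "other")


@dataclass(frozen=True)
class PhysVariable:
    """A measured physiological variable."""

    name: str
    unit: str
    module_hint: str = "other"

    def __post_init__(self):
        if not self.name or not self.name.isidentifier():
            raise ValidationError(f"variable name {self.name!r} is not a valid identifier")
        if not self.unit:
            raise ValidationError(f"variable {self.name!r}: unit must be non-empty")
        if self.module_hint not in _MODULE_HINTS:
            raise ValidationError(
                f"variable {self.name!r}: module_hint {self.module_hint!r} "
                f"not one of {_MODULE_HINTS}"
            )


@dataclass(frozen=True, order=True)
class VariablePair:
    """An unordered pair of variable names, stored in lexicographic order."""

    a: str
    b: str

    def __post_init__(self):
        if self.a == self.b:
            raise ValidationError(f"self-pair ({self.a}, {self.b}) is not allowed")
        if self.a > self.b:  # canonicalize: unordered pair
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)

    @property
    def label(self) -> str:
        return f"{self.a}-{self.b}"


@dataclass(frozen=True)
class NetworkSpec:
    """Variables plus named modules of pairs plus the module-linking pairs."""

    variables: tuple[PhysVariable, ...]
    modules: dict[str, tuple[VariablePair, ...]]
    linking_pairs: tuple[VariablePair, ...] = field(default_factory=tuple)

    def __post_init__(self):
        # canonical lexicographic pair order, so equal networks compare equal
        object.__setattr__(
            self, "modules",
            {name: tuple(sorted(pairs)) for name, pairs in self.modules.items()})
        object.__setattr__(self, "linking_pairs", tuple(sorted(self.linking_pairs)))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate variable names: {dupes}")
        known = set(names)
        seen: dict[VariablePair, str] = {}
        for where, pairs in [*self.modules.items(), ("linking", self.linking_pairs)]:
            for p in pairs:
                for end in (p.a, p.b):
                    if end not in known:
                        raise ValidationError(
                            f"pair {p.label} in {where!r} references unknown variable {end!r}"
                        )
                if p in seen:
                    raise ValidationError(
                        f"duplicate pair {p.label} (in {seen[p]!r} and {where!r})"
                    )
                seen[p] = where

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def all_pairs(self) -> tuple[VariablePair, ...]:
        out: list[VariablePair] = []
        for pairs in self.modules.values():
            out.extend(pairs)
        out.extend(self.linking_pairs)
        return tuple(out)


def default_network() -> NetworkSpec:
    """The canonical photosynthetic network.

    Gas-exchange module (9 pairs among AmaxL, gs, E, Rd, Pr, Ci):
    AmaxL-gs, AmaxL-E, AmaxL-Rd, AmaxL-Pr, AmaxL-Ci, Ci-gs, Ci-Rd, Ci-Pr, gs-E.
    Photochemical module (6 pairs among dF_Fm, FvFm, NPQ, ETR): all pairwise
    relationships. The single ETR-AmaxL pair links the two modules and is
    reported separately; it enters neither module average nor the global mean.
    """
    units = {
        "AmaxL": "µmol CO2 m-2 s-1",
        "gs": "mol H2O m-2 s-1",
        "E": "mmol H2O m-2 s-1",
        "Rd": "µmol CO2 m-2 s-1",
        "Pr": "µmol CO2 m-2 s-1",
        "Ci": "µmol mol-1",
        "FvFm": "dimensionless",
        "dF_Fm": "dimensionless",
        "NPQ": "dimensionless",
        "ETR": "µmol m-2 s-1",
    }
    hints = dict.fromkeys(["AmaxL", "gs", "E", "Rd", "Pr", "Ci"], "gas_exchange")
    hints.update(dict.fromkeys(["FvFm", "dF_Fm", "NPQ", "ETR"], "photochemical"))
    variables = tuple(
        PhysVariable(name, unit, hints[name]) for name, unit in units.items()
    )
    ge = [
        ("AmaxL", "gs"), ("AmaxL", "E"), ("AmaxL", "Rd"), ("AmaxL", "Pr"),
        ("AmaxL", "Ci"), ("Ci", "gs"), ("Ci", "Rd"), ("Ci", "Pr"), ("gs", "E"),
    ]
    pho = [
        ("dF_Fm", "ETR"), ("dF_Fm", "FvFm"), ("dF_Fm", "NPQ"),
        ("ETR", "NPQ"), ("FvFm", "NPQ"), ("FvFm", "ETR"),
    ]
    return NetworkSpec(
        variables=variables,
        modules={
            "gas_exchange": tuple(VariablePair(a, b) for a, b in ge),
            "photochemical": tuple(VariablePair(a, b) for a, b in pho),
        },
        linking_pairs=(VariablePair("ETR", "AmaxL"),),
    )


def serialize_network(spec: NetworkSpec) -> str:
    """YAML text for a NetworkSpec; pairs are emitted in canonical order."""
    doc = {
        "variables": [
            {"name": v.name, "unit": v.unit, "module_hint": v.module_hint}
            for v in spec.variables
        ],
        "modules": {
            name: [[p.a, p.b] for p in sorted(pairs)]
            for name, pairs in spec.modules.items()
        },
        "linking": [[p.a, p.b] for p in sorted(spec.linking_pairs)],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def load_network(config_text: str) -> NetworkSpec:
    """Parse and validate a YAML network config.

    Raises :class:`ValidationError` for self-pairs, duplicate pairs (within
    or across modules), and pairs naming unknown variables.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"network config is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "variables" not in doc or "modules" not in doc:
        raise ValidationError("network config must declare 'variables' and 'modules'")

    variables = tuple(
        PhysVariable(
            name=str(v["name"]),
            unit=str(v.get("unit", "")),
            module_hint=str(v.get("module_hint", "other")),
        )
        for v in doc["variables"]
    )

    def parse_pairs(raw, where):
        pairs = []
        for item in raw or []:
            if not isinstance(item, (list, tuple)) or len(item) != 2:
                raise ValidationError(f"{where}: each pair must be a 2-item list, got {item!r}")
            pairs.append(VariablePair(str(item[0]), str(item[1])))
        # duplicates *within* one listing are caught here so the error names the pair
        seen = set()
        for p in pairs:
            if p in seen:
                raise ValidationError(f"{where}: duplicate pair {p.label}")
            seen.add(p)
        return tuple(pairs)

    modules = {
        str(name): parse_pairs(raw, f"module {name!r}")
        for name, raw in doc["modules"].items()
    }
    linking = parse_pairs(doc.get("linking"), "linking")
    return NetworkSpec(variables=variables, modules=modules, linking_pairs=linking)


def load_network_file(path) -> NetworkSpec:
    with open(path, encoding="utf-8") as fh:
        return load_network(fh.read())
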