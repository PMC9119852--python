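"""Model configuration: variable bindings per age group.

A configuration binds every engine input variable, for each of the ten
age groups, to a :class:`~soildust.distributions.DistributionSpec` with a
sampling scope:

``per_person``
    sampled once per simulated person (e.g. the blanket barrier factor);
``per_event``
    re-evaluated on every diary event.  Probability-valued per-event
    variables (``p_blanket``, ``p_pacifier``, ``p_home_soft``) are handled
    as Bernoulli checks: the probability itself is drawn once per person,
    then each diary event flips a coin with that probability.

Configurations are TOML files.  The compact dialect groups entries by
variable (``[vars.<name>]`` with a ``default`` spec and ``by_age``
overrides); the expanded dialect written by :func:`write_config` lists one
``[age."<group>"."<var>"]`` table per binding.  Both parse to the same
in-memory object, and a written config re-parses to identical bindings.
"""

from __future__ import annotations

import io
import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .distributions import DistributionSpec, SpecError

__all__ = [
    "AGE_GROUPS",
    "REQUIRED_VARS",
    "PROBABILITY_CHECK_VARS",
    "ConfigError",
    "VariableBinding",
    "PersonParams",
    "ModelConfig",
    "parse_config",
    "parse_config_str",
    "default_config",
    "write_config",
    "draw_person_params",
]

#: The ten modelled age groups, youngest first.
AGE_GROUPS = (
    "0-<1m", "1-<3m", "3-<6m", "6m-<1y", "1-<2y",
    "2-<3y", "3-<6y", "6-<11y", "11-<16y", "16-<21y",
)

AGE_GROUP_INDEX = {g: i for i, g in enumerate(AGE_GROUPS)}

#: Age groups assumed to have no direct soil contact (under one year).
UNDER_ONE_YEAR = AGE_GROUPS[:4]

#: Age groups for which the pacifier pathway is modelled (under two years).
PACIFIER_AGE_GROUPS = AGE_GROUPS[:5]

#: Every variable the exposure engine requires for every age group.
REQUIRED_VARS = (
    "p_blanket", "f_blanket", "pacifier_size", "pacifier_frac_hard",
    "pacifier_frac_soft", "pacifier_transfer", "pacifier_washing",
    "pacifier_drop", "p_pacifier",
    "adherence_soil", "hand_mouth_fraction", "hand_mouth_freq",
    "object_mouth_area", "object_mouth_freq_indoor",
    "object_mouth_freq_outdoor", "hand_surface_area",
    "dust_home_soft", "dust_home_hard", "dust_object", "p_home_soft",
    "dust_transfer_hand", "saliva_removal", "handwash_removal",
    "bath_removal", "hand_contact_fraction",
)

#: Per-event probability checks: the probability is drawn per person, the
#: coin is flipped per event.
PROBABILITY_CHECK_VARS = frozenset({"p_blanket", "p_pacifier", "p_home_soft"})

#: Variables whose support must lie within [0, 1].
UNIT_INTERVAL_VARS = frozenset({
    "p_blanket", "p_pacifier", "p_home_soft",
    "f_blanket", "pacifier_frac_hard", "pacifier_frac_soft",
    "pacifier_transfer", "pacifier_washing",
    "hand_mouth_fraction", "dust_transfer_hand", "saliva_removal",
    "handwash_removal", "bath_removal", "hand_contact_fraction",
})

SCOPES = ("per_person", "per_event", "per_day")


class ConfigError(ValueError):
    """One or more configuration problems; ``.problems`` lists them all."""

    def __init__(self, problems: Iterable[str]):
        self.problems = list(problems)
        super().__init__("configuration invalid:\n  " + "\n  ".join(self.problems))


@dataclass(frozen=True)
class VariableBinding:
    """One variable bound to a distribution for one age group."""

    name: str
    age_group: str
    spec: DistributionSpec
    scope: str
    units: str = ""
    note: str = ""


@dataclass
class PersonParams:
    """One simulated child's sampled inputs.

    ``values`` holds everything resolved per person — per-person draws and
    the per-person probabilities behind the Bernoulli checks.
    ``event_specs`` carries the specs of variables resampled per event.
    """

    age_group: str
    values: dict[str, float]
    event_specs: dict[str, DistributionSpec]

    def sample_event(self, name: str, rng) -> float:
        return self.event_specs[name].sample(rng)


@dataclass
class ModelConfig:
    """Full set of bindings plus diary-generator parameters."""

    bindings: dict[tuple[str, str], VariableBinding]
    diary: dict
    schema_version: int = 1

    def binding(self, age_group: str, name: str) -> VariableBinding:
        return self.bindings[(age_group, name)]

    def spec(self, age_group: str, name: str) -> DistributionSpec:
        return self.bindings[(age_group, name)].spec

    def with_spec(self, name: str, spec: DistributionSpec,
                  age_groups: Iterable[str] | None = None) -> "ModelConfig":
        """Copy of this config with ``name`` rebound to ``spec``.

        Applies to all age groups unless ``age_groups`` narrows it.  Used
        by the sensitivity analyses to perturb one variable at a time.
        """
        groups = tuple(age_groups) if age_groups is not None else AGE_GROUPS
        new = dict(self.bindings)
        for g in groups:
            b = new[(g, name)]
            new[(g, name)] = replace(b, spec=spec)
        return ModelConfig(new, self.diary, self.schema_version)

    def validate(self) -> None:
        problems: list[str] = []
        for g in AGE_GROUPS:
            for v in REQUIRED_VARS:
                b = self.bindings.get((g, v))
                if b is None:
                    problems.append(f"missing binding: {v} @ {g}")
                    continue
                if b.scope not in SCOPES:
                    problems.append(f"{v} @ {g}: unknown scope {b.scope!r}")
                lo, hi = b.spec.support()
                if v in UNIT_INTERVAL_VARS and (lo < 0.0 or hi > 1.0):
                    problems.append(
                        f"{v} @ {g}: support [{lo}, {hi}] outside [0, 1]")
                elif lo < 0.0:
                    problems.append(f"{v} @ {g}: support extends below zero")
            if g not in self.diary.get("age", {}):
                problems.append(f"missing diary parameters for {g}")
        if problems:
            raise ConfigError(problems)


# ---------------------------------------------------------------- parsing --

def _spec_from_table(table: Mapping, var: str, where: str,
                     problems: list[str], units: str = "") -> DistributionSpec | None:
    try:
        trunc = table.get("truncation")
        return DistributionSpec(
            family=table["family"],
            params=tuple(table["params"]),
            truncation=tuple(trunc) if trunc is not None else None,
            units=table.get("units", units),
        )
    except (KeyError, SpecError, TypeError) as exc:
        problems.append(f"{var} @ {where}: {exc}")
        return None


def _parse(doc: Mapping) -> ModelConfig:
    problems: list[str] = []
    bindings: dict[tuple[str, str], VariableBinding] = {}

    for var, entry in doc.get("vars", {}).items():
        scope = entry.get("scope", "per_person")
        units = entry.get("units", "")
        note = entry.get("note", "")
        default = entry.get("default")
        by_age = entry.get("by_age", {})
        for g in AGE_GROUPS:
            table = by_age.get(g, default)
            if table is None:
                continue
            spec = _spec_from_table(table, var, g, problems, units)
            if spec is not None:
                bindings[(g, var)] = VariableBinding(var, g, spec, scope,
                                                     units, note)

    # expanded dialect: [age."<group>"."<var>"] tables override
    for g, vars_table in doc.get("age", {}).items():
        if g not in AGE_GROUP_INDEX:
            problems.append(f"unknown age group {g!r}")
            continue
        for var, table in vars_table.items():
            spec = _spec_from_table(table, var, g, problems)
            if spec is not None:
                bindings[(g, var)] = VariableBinding(
                    var, g, spec,
                    table.get("scope", "per_person"),
                    table.get("units", ""), table.get("note", ""))

    if problems:
        raise ConfigError(problems)

    cfg = ModelConfig(
        bindings=bindings,
        diary=doc.get("diary", {}),
        schema_version=int(doc.get("schema_version", 1)),
    )
    cfg.validate()
    return cfg


def parse_config(path: str | Path) -> ModelConfig:
    """Parse and validate a TOML configuration file.

    All schema and validation problems are aggregated into a single
    :class:`ConfigError` so a broken config is reported in one pass.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return _parse(doc)


def parse_config_str(text: str) -> ModelConfig:
    return _parse(tomllib.loads(text))


def default_config() -> ModelConfig:
    """The bundled default configuration."""
    text = (resources.files("soildust.data") / "default_config.toml").read_text()
    return parse_config_str(text)


# ---------------------------------------------------------------- writing --

def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int,)):
        return str(v)
    if isinstance(v, float):
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if isinstance(v, dict):
        inner = ", ".join(f"{k} = {_toml_value(x)}" for k, x in v.items())
        return "{ " + inner + " }"
    raise TypeError(f"cannot serialize {type(v)!r} to TOML")


def _emit_tables(out: io.StringIO, prefix: str, table: Mapping) -> None:
    scalars = {k: v for k, v in table.items()
               if not isinstance(v, dict) or k == "outdoor_frac"}
    subtables = {k: v for k, v in table.items() if k not in scalars}
    if scalars or not subtables:
        out.write(f"[{prefix}]\n")
        for k, v in scalars.items():
            key = k if k.isidentifier() else _toml_value(k)
            out.write(f"{key} = {_toml_value(v)}\n")
        out.write("\n")
    for k, v in subtables.items():
        key = k if k.isidentifier() else _toml_value(k)
        _emit_tables(out, f"{prefix}.{key}", v)


def config_to_toml(config: ModelConfig) -> str:
    """Serialize a config in the expanded per-binding dialect."""
    out = io.StringIO()
    out.write(f"schema_version = {config.schema_version}\n\n")
    if config.diary:
        _emit_tables(out, "diary", config.diary)
    for g in AGE_GROUPS:
        for v in REQUIRED_VARS:
            b = config.bindings.get((g, v))
            if b is None:
                continue
            out.write(f'[age."{g}"."{v}"]\n')
            out.write(f'family = {_toml_value(b.spec.family)}\n')
            out.write(f'params = {_toml_value(list(b.spec.params))}\n')
            if b.spec.truncation is not None:
                out.write(f'truncation = {_toml_value(list(b.spec.truncation))}\n')
            out.write(f'scope = {_toml_value(b.scope)}\n')
            if b.units:
                out.write(f'units = {_toml_value(b.units)}\n')
            if b.note:
                out.write(f'note = {_toml_value(b.note)}\n')
            out.write("\n")
    return out.getvalue()


def write_config(config: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(config_to_toml(config))


# --------------------------------------------------------------- sampling --

def draw_person_params(age_group: str, config: ModelConfig, streams) -> PersonParams:
    """Sample one person's input values from their bound distributions.

    Per-person variables are drawn once from their own named substream.
    Probability-check variables are also drawn per person (the per-event
    Bernoulli uses the sampled probability).  Remaining per-event variables
    are carried as specs for event-level sampling.  The person's age group
    is fixed for the whole simulated year.
    """
    if age_group not in AGE_GROUP_INDEX:
        raise ConfigError([f"unknown age group {age_group!r}; "
                           f"valid: {', '.join(AGE_GROUPS)}"])
    values: dict[str, float] = {}
    event_specs: dict[str, DistributionSpec] = {}
    for var in REQUIRED_VARS:
        b = config.binding(age_group, var)
        if b.scope == "per_person" or var in PROBABILITY_CHECK_VARS:
            values[var] = b.spec.sample(streams.var(var))
        else:
            event_specs[var] = b.spec
    return PersonParams(age_group, values, event_specs)
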