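"""Data model, loader and validator for WEB planning models.

A *WEB model* (Workforce Evidence-Based planning model) describes a
regional population by a four-level taxonomy of patient attributes:

1. prevention/screening strata of the general or at-risk population,
2. type or stage of the diagnosed disease (mutually exclusive categories
   that partition the diagnosed population),
3. complications (independent binary flags), and
4. threats to self-care capacity (independent binary flags).

Each attribute carries a prevalence per 10,000 of its reference
population and a clinical care protocol: an annual schedule of consults
(count x duration) itemised by clinical competency.  Levels 2-4 are
expressed per 10,000 *diagnosed* persons; level 1 per 10,000 of the
*general* regional population.

Model files are JSON (YAML accepted as a convenience dialect) with a
versioned ``schema_version`` key; see ``docs/methods.md`` for the schema
reference.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ModelValidationError, SchemaError, UnknownIdError

SCHEMA_VERSION = "1.0"

#: Scale of all prevalence fields: cases per 10,000 of the reference population.
PREVALENCE_DENOMINATOR = 10_000.0

#: Tolerance on the level-2 partition invariant (per-10,000 units).
PARTITION_TOL = 1e-6


class Competency(BaseModel):
    """A defined clinical capability at a stated skill level."""

    model_config = ConfigDict(extra="forbid")

    id: str = Field(min_length=1)
    description: str = ""
    skill_level: str = Field(min_length=1)


class Attribute(BaseModel):
    """One patient characteristic at a WEB level.

    ``prevalence_per_10k`` is relative to the attribute's reference
    population: the general regional population for level 1, the
    diagnosed population for levels 2-4.  ``provenance`` records whether
    the value was taken from published sources, is a documented
    placeholder, or was supplied by the user.
    """

    model_config = ConfigDict(extra="forbid")

    id: str = Field(min_length=1)
    name: str = ""
    level: Literal[1, 2, 3, 4]
    prevalence_per_10k: float = Field(ge=0.0, le=PREVALENCE_DENOMINATOR)
    provenance: Literal["paper", "placeholder", "user"] = "user"

    @property
    def probability(self) -> float:
        """Prevalence as a probability in [0, 1]."""
        return self.prevalence_per_10k / PREVALENCE_DENOMINATOR


class ConsultItem(BaseModel):
    """One line of a care protocol: consults/year x minutes/consult for
    a single competency."""

    model_config = ConfigDict(extra="forbid")

    competency_id: str = Field(min_length=1)
    consults_per_year: float = Field(ge=0.0, allow_inf_nan=False)
    minutes_per_consult: float = Field(gt=0.0, allow_inf_nan=False)

    @property
    def annual_minutes(self) -> float:
        return self.consults_per_year * self.minutes_per_consult


class CareProtocol(BaseModel):
    """Annual consult schedule attached to one attribute.

    Duplicate items for the same competency are merged at validation
    time by summing their annual minutes, so a protocol holds at most
    one item per competency.
    """

    model_config = ConfigDict(extra="forbid")

    attribute_id: str = Field(min_length=1)
    items: list[ConsultItem] = Field(default_factory=list)

    @model_validator(mode="after")
    def _merge_duplicates(self) -> "CareProtocol":
        seen: dict[str, ConsultItem] = {}
        for item in self.items:
            prev = seen.get(item.competency_id)
            if prev is None:
                seen[item.competency_id] = item
            else:
                total = prev.annual_minutes + item.annual_minutes
                seen[item.competency_id] = ConsultItem(
                    competency_id=item.competency_id,
                    consults_per_year=total / prev.minutes_per_consult,
                    minutes_per_consult=prev.minutes_per_consult,
                )
        if len(seen) != len(self.items):
            object.__setattr__(self, "items", list(seen.values()))
        return self

    def annual_minutes_by_competency(self) -> dict[str, float]:
        return {it.competency_id: it.annual_minutes for it in self.items}


class RegionProfile(BaseModel):
    """Regional population and diagnosed-disease prevalence."""

    model_config = ConfigDict(extra="forbid")

    population: int = Field(ge=0)
    diagnosed_prevalence: float = Field(ge=0.0, le=1.0)


class MappingScenario(BaseModel):
    """A delivery scenario: per competency, the share of its hours that
    each occupation delivers.  Shares per competency must sum to one."""

    model_config = ConfigDict(extra="forbid")

    name: str = Field(min_length=1)
    mapping: dict[str, dict[str, float]]

    @model_validator(mode="after")
    def _check_shares(self) -> "MappingScenario":
        for comp_id, shares in self.mapping.items():
            if not shares:
                raise ModelValidationError(
                    f"scenario '{self.name}': competency '{comp_id}' has no occupation shares"
                )
            total = sum(shares.values())
            if any(s < 0.0 for s in shares.values()) or abs(total - 1.0) > 1e-9:
                raise ModelValidationError(
                    f"scenario '{self.name}': shares for competency '{comp_id}' "
                    f"sum to {total!r}, expected 1.0"
                )
        return self


class WorkforceParams(BaseModel):
    """Per-occupation workforce parameters.

    ``effective annual clinical hours`` = contracted_hours_per_week x
    weeks_per_year x clinical_activity_fraction; demand hours divided by
    this give FTE, and FTE divided by ``participation_rate`` gives
    headcount.
    """

    model_config = ConfigDict(extra="forbid")

    contracted_hours_per_week: float = Field(gt=0.0)
    weeks_per_year: float = Field(gt=0.0)
    clinical_activity_fraction: float = Field(gt=0.0, le=1.0)
    participation_rate: float = Field(gt=0.0, le=1.0)

    @property
    def effective_annual_clinical_hours(self) -> float:
        return (
            self.contracted_hours_per_week
            * self.weeks_per_year
            * self.clinical_activity_fraction
        )


class ModelMetadata(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = ""
    version: str = ""
    notes: str = ""


class ModelDefinition(BaseModel):
    """A complete WEB model: competencies, attributes, protocols, the
    region, and optional delivery scenarios / workforce parameters.

    Invariants enforced at construction:

    * competency and attribute ids are unique;
    * every consult item references a declared competency;
    * every attribute has exactly one protocol and vice versa;
    * at least one level-2 attribute exists and level-2 prevalences sum
      to 10,000 per 10,000 (level 2 partitions the diagnosed
      population);
    * every competency's ``skill_level`` is drawn from ``skill_levels``.
    """

    model_config = ConfigDict(extra="forbid")

    schema_version: str = SCHEMA_VERSION
    metadata: ModelMetadata = Field(default_factory=ModelMetadata)
    skill_levels: list[str] = Field(default_factory=lambda: ["basic", "advanced"])
    region: RegionProfile
    competencies: list[Competency]
    attributes: list[Attribute]
    protocols: list[CareProtocol]
    scenarios: list[MappingScenario] = Field(default_factory=list)
    workforce: dict[str, WorkforceParams] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _validate_model(self) -> "ModelDefinition":
        comp_ids = [c.id for c in self.competencies]
        if len(set(comp_ids)) != len(comp_ids):
            dup = sorted({i for i in comp_ids if comp_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate competency ids: {dup}")
        attr_ids = [a.id for a in self.attributes]
        if len(set(attr_ids)) != len(attr_ids):
            dup = sorted({i for i in attr_ids if attr_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate attribute ids: {dup}")

        levels = set(self.skill_levels)
        for comp in self.competencies:
            if comp.skill_level not in levels:
                raise ModelValidationError(
                    f"competency '{comp.id}': skill_level '{comp.skill_level}' "
                    f"not in declared skill_levels {self.skill_levels}"
                )

        comp_set = set(comp_ids)
        attr_set = set(attr_ids)
        proto_attrs = [p.attribute_id for p in self.protocols]
        if len(set(proto_attrs)) != len(proto_attrs):
            dup = sorted({i for i in proto_attrs if proto_attrs.count(i) > 1})
            raise ModelValidationError(f"multiple protocols for attribute(s): {dup}")
        for proto in self.protocols:
            if proto.attribute_id not in attr_set:
                raise ModelValidationError(
                    f"protocol references unknown attribute '{proto.attribute_id}'"
                )
            for item in proto.items:
                if item.competency_id not in comp_set:
                    raise ModelValidationError(
                        f"protocol for '{proto.attribute_id}' references "
                        f"unknown competency '{item.competency_id}'"
                    )
        missing = attr_set - set(proto_attrs)
        if missing:
            raise ModelValidationError(
                f"attribute without protocol: {sorted(missing)}"
            )

        level2 = [a for a in self.attributes if a.level == 2]
        if not level2:
            raise ModelValidationError("model has no level-2 attributes")
        total = sum(a.prevalence_per_10k for a in level2)
        if abs(total - PREVALENCE_DENOMINATOR) > PARTITION_TOL:
            raise ModelValidationError(
                f"level-2 prevalences must partition the diagnosed population: "
                f"sum is {total!r} per 10,000, expected 10000"
            )

        for scenario in self.scenarios:
            unknown = set(scenario.mapping) - comp_set
            if unknown:
                raise ModelValidationError(
                    f"scenario '{scenario.name}' maps unknown competencies: "
                    f"{sorted(unknown)}"
                )
        return self

    # -- lookups -----------------------------------------------------------

    def attribute(self, attribute_id: str) -> Attribute:
        for a in self.attributes:
            if a.id == attribute_id:
                return a
        raise UnknownIdError(f"unknown attribute id '{attribute_id}'")

    def competency(self, competency_id: str) -> Competency:
        for c in self.competencies:
            if c.id == competency_id:
                return c
        raise UnknownIdError(f"unknown competency id '{competency_id}'")

    def protocol_for(self, attribute_id: str) -> CareProtocol:
        for p in self.protocols:
            if p.attribute_id == attribute_id:
                return p
        raise UnknownIdError(f"no protocol for attribute '{attribute_id}'")

    def attributes_at_level(self, level: int) -> list[Attribute]:
        """Attributes at one WEB level, in declaration order."""
        return [a for a in self.attributes if a.level == level]

    def annual_minutes(self, attribute_id: str) -> dict[str, float]:
        """Annual consult minutes by competency for one attribute's protocol."""
        return self.protocol_for(attribute_id).annual_minutes_by_competency()

    def scenario(self, name: str) -> MappingScenario:
        for s in self.scenarios:
            if s.name == name:
                return s
        raise UnknownIdError(f"unknown scenario '{name}'")


# -- operations -------------------------------------------------------------


def diagnosed_count(model: ModelDefinition) -> int:
    """Number of diagnosed persons in the region.

    ``round(population x diagnosed_prevalence)`` with round-half-to-even
    (the IEEE default), e.g. a region of 250,000 at 4% known prevalence
    has 10,000 diagnosed persons.
    """
    return round(model.region.population * model.region.diagnosed_prevalence)


def attribute_counts_by_level(model: ModelDefinition) -> dict[int, int]:
    """Count of attributes per WEB level, with all four levels present."""
    counts = {level: 0 for level in (1, 2, 3, 4)}
    for a in model.attributes:
        counts[a.level] += 1
    return counts


# -- serialisation ----------------------------------------------------------


def load_model(path: str | Path) -> ModelDefinition:
    """Load and validate a model-definition file (JSON, or YAML when the
    suffix is .yaml/.yml).

    Raises :class:`SchemaError` on parse/schema failure (the message
    names the offending key) and :class:`ModelValidationError` on a
    semantic invariant violation.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"model file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise SchemaError(f"cannot parse {path.name}: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{path.name}: top level must be a mapping")
    return model_from_dict(raw, source=path.name)


def model_from_dict(raw: dict, source: str = "<dict>") -> ModelDefinition:
    """Validate a raw mapping into a :class:`ModelDefinition`."""
    try:
        return ModelDefinition.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(part) for part in first["loc"]) or "<root>"
        raise SchemaError(
            f"{source}: invalid value at key '{loc}': {first['msg']}"
        ) from exc


def serialize(model: ModelDefinition) -> dict:
    """Plain-dict form of a model; ``model_from_dict`` inverts it."""
    return model.model_dump(mode="json")


def save_model(model: ModelDefinition, path: str | Path) -> None:
    """Write a model definition to JSON (or YAML by suffix)."""
    path = Path(path)
    data = serialize(model)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def packaged_model_path(name: str) -> Path:
    """Path to a model definition shipped with the package
    (``diabetes_exemplar`` or ``minimal``)."""
    from importlib.resources import files

    resource = files("webforce").joinpath("models", f"{name}.json")
    return Path(str(resource))


def load_packaged_model(name: str) -> ModelDefinition:
    return load_model(packaged_model_path(name))
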