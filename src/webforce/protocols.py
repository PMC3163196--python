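"""Per-patient care need under the WEB combination calculus.

A patient type is one level-2 category plus any subset of level-3
complications and level-4 threats to self-care capacity.  The annual
care need of a patient type, in minutes per competency, combines the
attribute protocols in two stages:

* **within a level** the conservative rule takes, per competency, the
  highest annual consultation time over the attributes present (related
  issues can share a consult), making the result a minimum estimate of
  need; an additive within-level rule is provided as a sensitivity
  variant;
* **across levels** contributions are strictly additive, each level
  addressing a distinct kind of need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

from .errors import LevelMixError, UnknownIdError
from .schema import ModelDefinition

#: competency_id -> annual minutes
NeedVector = dict[str, float]

Rule = Literal["max", "add"]


@dataclass(frozen=True)
class PatientType:
    """One diagnosed patient type: a level-2 category plus subsets of
    level-3 and level-4 attributes.  Level-1 strata describe the general
    population and do not participate in patient types."""

    level2_id: str
    level3_ids: frozenset[str] = field(default_factory=frozenset)
    level4_ids: frozenset[str] = field(default_factory=frozenset)

    def attribute_ids(self) -> set[str]:
        return {self.level2_id} | set(self.level3_ids) | set(self.level4_ids)

    def label(self) -> str:
        parts = [self.level2_id]
        parts += sorted(self.level3_ids) + sorted(self.level4_ids)
        return "+".join(parts)


def _check_rule(rule: str) -> None:
    if rule not in ("max", "add"):
        raise ValueError(f"rule must be 'max' or 'add', got {rule!r}")


def combine_within_level(
    minute_maps: Iterable[NeedVector], rule: Rule = "max"
) -> NeedVector:
    """Combine per-attribute minute maps from a single level.

    ``max``: per competency, the highest annual minutes over attributes.
    ``add``: per competency, the sum.
    """
    _check_rule(rule)
    out: NeedVector = {}
    for minutes in minute_maps:
        for comp_id, mins in minutes.items():
            if rule == "max":
                out[comp_id] = max(out.get(comp_id, 0.0), mins)
            else:
                out[comp_id] = out.get(comp_id, 0.0) + mins
    return out


def level_need(
    attribute_ids: Iterable[str], model: ModelDefinition, rule: Rule = "max"
) -> NeedVector:
    """Combined need of a set of attributes that share one WEB level.

    An empty set yields an all-zero (empty) vector; mixed levels raise
    :class:`LevelMixError`.
    """
    ids = list(attribute_ids)
    levels = {model.attribute(i).level for i in ids}
    if len(levels) > 1:
        raise LevelMixError(
            f"attributes span multiple WEB levels {sorted(levels)}: {sorted(ids)}"
        )
    return combine_within_level((model.annual_minutes(i) for i in ids), rule)


def add_vectors(*vectors: NeedVector) -> NeedVector:
    out: NeedVector = {}
    for vec in vectors:
        for comp_id, mins in vec.items():
            out[comp_id] = out.get(comp_id, 0.0) + mins
    return out


def validate_patient(patient: PatientType, model: ModelDefinition) -> None:
    """Check that a patient type's ids exist and sit at the right levels."""
    if model.attribute(patient.level2_id).level != 2:
        raise LevelMixError(
            f"'{patient.level2_id}' is not a level-2 attribute"
        )
    for ids, want in ((patient.level3_ids, 3), (patient.level4_ids, 4)):
        for attr_id in ids:
            if model.attribute(attr_id).level != want:
                raise LevelMixError(
                    f"'{attr_id}' is not a level-{want} attribute"
                )


def patient_care_need(
    patient: PatientType, model: ModelDefinition, rule: Rule = "max"
) -> NeedVector:
    """Annual care need (minutes per competency) for one patient type.

    The three per-level vectors are combined within-level by ``rule``
    (vacuous at level 2, which contributes a single category) and summed
    across levels.
    """
    _check_rule(rule)
    validate_patient(patient, model)
    return add_vectors(
        level_need([patient.level2_id], model, rule),
        level_need(patient.level3_ids, model, rule),
        level_need(patient.level4_ids, model, rule),
    )


@dataclass(frozen=True)
class PatientTypeEnumeration:
    """Lazy enumeration of every patient type of a model.

    ``count`` = |L2| x 2^|L3| x 2^|L4| (exact integer arithmetic).
    Iteration order: level-2 attributes in declaration order, then the
    level-3 subset bitmask ascending, then the level-4 subset bitmask
    ascending (bit *i* of a mask selects the *i*-th attribute of that
    level in declaration order).
    """

    model: ModelDefinition

    @property
    def count(self) -> int:
        n3 = len(self.model.attributes_at_level(3))
        n4 = len(self.model.attributes_at_level(4))
        return len(self.model.attributes_at_level(2)) * (1 << n3) * (1 << n4)

    def __len__(self) -> int:
        return self.count

    def __iter__(self) -> Iterator[PatientType]:
        l2 = [a.id for a in self.model.attributes_at_level(2)]
        l3 = [a.id for a in self.model.attributes_at_level(3)]
        l4 = [a.id for a in self.model.attributes_at_level(4)]
        subsets3 = [_subset(l3, mask) for mask in range(1 << len(l3))]
        subsets4 = [_subset(l4, mask) for mask in range(1 << len(l4))]
        for level2_id in l2:
            for s3 in subsets3:
                for s4 in subsets4:
                    yield PatientType(level2_id, s3, s4)


def _subset(ids: list[str], mask: int) -> frozenset[str]:
    return frozenset(ids[i] for i in range(len(ids)) if mask >> i & 1)


def enumerate_patient_types(model: ModelDefinition) -> PatientTypeEnumeration:
    """All patient types of a model: ``.count`` plus a lazy iterator."""
    return PatientTypeEnumeration(model)


def parse_patient(spec: str, model: ModelDefinition) -> PatientType:
    """Parse a ``'+'``-joined attribute-id string such as
    ``"t2_established+eye_disease+low_english"`` into a
    :class:`PatientType`.

    Exactly one id must be a level-2 attribute; level-1 ids are
    rejected (patient types describe diagnosed persons only).
    """
    ids = [token.strip() for token in spec.split("+") if token.strip()]
    if not ids:
        raise UnknownIdError("empty patient specification")
    by_level: dict[int, list[str]] = {1: [], 2: [], 3: [], 4: []}
    for attr_id in ids:
        by_level[model.attribute(attr_id).level].append(attr_id)
    if by_level[1]:
        raise LevelMixError(
            f"level-1 strata cannot appear in a patient type: {by_level[1]}"
        )
    if len(by_level[2]) != 1:
        raise LevelMixError(
            f"a patient type needs exactly one level-2 attribute, got {by_level[2]}"
        )
    return PatientType(
        by_level[2][0], frozenset(by_level[3]), frozenset(by_level[4])
    )
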