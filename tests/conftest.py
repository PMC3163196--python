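from __future__ import annotations

import pytest

from webforce import load_packaged_model
from webforce.schema import (
    Attribute,
    CareProtocol,
    Competency,
    ConsultItem,
    ModelDefinition,
    RegionProfile,
)

#: spec: id -> (prevalence_per_10k, {competency_id: annual_minutes})
LevelSpec = dict[str, tuple[float, dict[str, float]]]


def make_model(
    l2: LevelSpec,
    l3: LevelSpec | None = None,
    l4: LevelSpec | None = None,
    l1: LevelSpec | None = None,
    population: int = 250_000,
    diagnosed_prevalence: float = 0.04,
    **kwargs,
) -> ModelDefinition:
    """Build a small model from per-level {id: (prev/10k, {comp: annual
    minutes})} specs.  Competencies are declared implicitly; an annual
    minutes value of m becomes one consult of m minutes (0 -> zero
    consults)."""
    levels = {2: l2, 3: l3 or {}, 4: l4 or {}, 1: l1 or {}}
    comp_ids: list[str] = []
    attributes, protocols = [], []
    for level, spec in levels.items():
        for attr_id, (prev, minutes) in spec.items():
            attributes.append(
                Attribute(
                    id=attr_id, name=attr_id, level=level, prevalence_per_10k=prev
                )
            )
            items = []
            for comp_id, mins in minutes.items():
                if comp_id not in comp_ids:
                    comp_ids.append(comp_id)
                items.append(
                    ConsultItem(
                        competency_id=comp_id,
                        consults_per_year=1.0 if mins > 0 else 0.0,
                        minutes_per_consult=mins if mins > 0 else 1.0,
                    )
                )
            protocols.append(CareProtocol(attribute_id=attr_id, items=items))
    competencies = [
        Competency(id=c, skill_level="basic") for c in comp_ids
    ] or [Competency(id="unused", skill_level="basic")]
    return ModelDefinition(
        region=RegionProfile(
            population=population, diagnosed_prevalence=diagnosed_prevalence
        ),
        competencies=competencies,
        attributes=attributes,
        protocols=protocols,
        **kwargs,
    )


@pytest.fixture(scope="session")
def exemplar() -> ModelDefinition:
    return load_packaged_model("diabetes_exemplar")


@pytest.fixture(scope="session")
def minimal() -> ModelDefinition:
    return load_packaged_model("minimal")
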