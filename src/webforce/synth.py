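"""Random, valid WEB models for property-based testing and oracle
comparisons.

The generator emulates the *structure* of a chronic-disease planning
model — a handful of mutually exclusive disease categories, independent
complication and self-care-threat flags, per-attribute consult
protocols — without attempting to mimic any real epidemiology.
Prevalences are drawn log-uniformly within their ranges so both rare
and common attributes are exercised.  Every generated model passes full
validation by construction, and generation is reproducible given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .schema import (
    Attribute,
    CareProtocol,
    Competency,
    ConsultItem,
    MappingScenario,
    ModelDefinition,
    ModelMetadata,
    PREVALENCE_DENOMINATOR,
    RegionProfile,
    WorkforceParams,
)

_MINUTE_CHOICES = (10.0, 15.0, 20.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Size and distribution parameters for a random model.

    Prevalence ranges are per 10,000 of the level's reference
    population and are sampled log-uniformly.  ``sparsity`` is the
    probability that a protocol includes any given competency (at least
    one item is always present).  ``n_occupations > 0`` additionally
    equips the model with generalist/specialist delivery scenarios and
    workforce parameters.
    """

    seed: int
    n_level2: int = 5
    n_level3: int = 10
    n_level4: int = 9
    n_level1: int = 0
    n_competencies: int = 12
    n_occupations: int = 0
    level1_prevalence_range: tuple[float, float] = (200.0, 3000.0)
    prevalence_range: tuple[float, float] = (50.0, 4000.0)
    consults_range: tuple[int, int] = (1, 12)
    sparsity: float = 0.35
    region_population: int = 250_000
    diagnosed_prevalence: float = 0.04

    def __post_init__(self) -> None:
        if self.n_level2 < 1:
            raise ValueError("n_level2 must be >= 1")
        if self.n_competencies < 1:
            raise ValueError("n_competencies must be >= 1")
        if min(self.n_level1, self.n_level3, self.n_level4) < 0:
            raise ValueError("level sizes must be non-negative")
        for lo, hi in (
            self.level1_prevalence_range,
            self.prevalence_range,
            (float(self.consults_range[0]), float(self.consults_range[1])),
        ):
            if not 0 < lo <= hi:
                raise ValueError(f"range ({lo}, {hi}) is not well-ordered")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must be in [0, 1]")


def _log_uniform(
    rng: np.random.Generator, lo: float, hi: float, size: int
) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _random_protocol(
    rng: np.random.Generator, attr_id: str, comp_ids: list[str], spec: GeneratorSpec
) -> CareProtocol:
    include = rng.random(len(comp_ids)) < spec.sparsity
    if not include.any():
        include[rng.integers(len(comp_ids))] = True
    items = [
        ConsultItem(
            competency_id=comp_ids[i],
            consults_per_year=float(
                rng.integers(spec.consults_range[0], spec.consults_range[1] + 1)
            ),
            minutes_per_consult=float(rng.choice(_MINUTE_CHOICES)),
        )
        for i in np.flatnonzero(include)
    ]
    return CareProtocol(attribute_id=attr_id, items=items)


def _random_shares(rng: np.random.Generator, occ_ids: list[str]) -> dict[str, float]:
    k = int(rng.integers(1, min(3, len(occ_ids)) + 1))
    chosen = rng.choice(len(occ_ids), size=k, replace=False)
    weights = rng.dirichlet(np.ones(k))
    # shares must sum to 1 exactly within 1e-9; pin the last share
    shares = {occ_ids[int(i)]: float(w) for i, w in zip(chosen[:-1], weights[:-1])}
    shares[occ_ids[int(chosen[-1])]] = 1.0 - sum(shares.values())
    return shares


def generate_random_model(spec: GeneratorSpec) -> ModelDefinition:
    """Generate a random valid model per ``spec``.

    Level-2 prevalences are drawn then normalised to partition 10,000
    exactly; every attribute receives at least one consult item.
    """
    rng = np.random.default_rng(spec.seed)
    skill_levels = ["basic", "advanced"]
    competencies = [
        Competency(
            id=f"c{i:02d}",
            description=f"synthetic competency {i}",
            skill_level=skill_levels[i % 2],
        )
        for i in range(spec.n_competencies)
    ]
    comp_ids = [c.id for c in competencies]

    attributes: list[Attribute] = []
    w2 = rng.dirichlet(np.ones(spec.n_level2)) * PREVALENCE_DENOMINATOR
    w2[-1] = PREVALENCE_DENOMINATOR - float(w2[:-1].sum())
    for i in range(spec.n_level2):
        attributes.append(
            Attribute(
                id=f"l2_{i:02d}",
                name=f"disease category {i}",
                level=2,
                prevalence_per_10k=float(w2[i]),
                provenance="user",
            )
        )
    for level, n, (lo, hi) in (
        (3, spec.n_level3, spec.prevalence_range),
        (4, spec.n_level4, spec.prevalence_range),
        (1, spec.n_level1, spec.level1_prevalence_range),
    ):
        prevs = _log_uniform(rng, lo, min(hi, PREVALENCE_DENOMINATOR), n)
        kind = {1: "stratum", 3: "complication", 4: "threat"}[level]
        for i in range(n):
            attributes.append(
                Attribute(
                    id=f"l{level}_{i:02d}",
                    name=f"{kind} {i}",
                    level=level,
                    prevalence_per_10k=float(prevs[i]),
                    provenance="user",
                )
            )

    protocols = [
        _random_protocol(rng, a.id, comp_ids, spec) for a in attributes
    ]

    scenarios: list[MappingScenario] = []
    workforce: dict[str, WorkforceParams] = {}
    if spec.n_occupations > 0:
        occ_ids = [f"occ{i:02d}" for i in range(spec.n_occupations)]
        for name in ("generalist", "specialist"):
            scenarios.append(
                MappingScenario(
                    name=name,
                    mapping={c: _random_shares(rng, occ_ids) for c in comp_ids},
                )
            )
        for occ in occ_ids:
            workforce[occ] = WorkforceParams(
                contracted_hours_per_week=38.0,
                weeks_per_year=float(rng.integers(42, 49)),
                clinical_activity_fraction=float(rng.uniform(0.5, 0.95)),
                participation_rate=float(rng.uniform(0.6, 1.0)),
            )

    return ModelDefinition(
        metadata=ModelMetadata(
            name=f"synthetic-{spec.seed}",
            version="1",
            notes="randomly generated test model",
        ),
        skill_levels=skill_levels,
        region=RegionProfile(
            population=spec.region_population,
            diagnosed_prevalence=spec.diagnosed_prevalence,
        ),
        competencies=competencies,
        attributes=attributes,
        protocols=protocols,
        scenarios=scenarios,
        workforce=workforce,
    )


def perturb_model(
    model: ModelDefinition,
    what: Literal["prevalence", "minutes"],
    factor: float,
) -> ModelDefinition:
    """Scale all level-1/3/4 prevalences, or all consult minutes, by
    ``factor`` (prevalences clipped at 10,000; level-2 prevalences are
    re-normalised, i.e. left partitioning).  Used for monotonicity and
    linearity sweeps."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    if what == "prevalence":
        attributes = [
            a
            if a.level == 2
            else a.model_copy(
                update={
                    "prevalence_per_10k": min(
                        a.prevalence_per_10k * factor, PREVALENCE_DENOMINATOR
                    )
                }
            )
            for a in model.attributes
        ]
        return model.model_copy(update={"attributes": attributes})
    if what == "minutes":
        protocols = [
            CareProtocol(
                attribute_id=p.attribute_id,
                items=[
                    ConsultItem(
                        competency_id=it.competency_id,
                        consults_per_year=it.consults_per_year,
                        minutes_per_consult=it.minutes_per_consult * factor,
                    )
                    for it in p.items
                ],
            )
            for p in model.protocols
        ]
        return model.model_copy(update={"protocols": protocols})
    raise ValueError(f"what must be 'prevalence' or 'minutes', got {what!r}")
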