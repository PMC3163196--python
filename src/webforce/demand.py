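"""Regional annual demand per competency.

Three routes from a model to the same quantity — expected annual hours
of each competency for the region:

* :func:`regional_demand` — analytic.  Treats level-3 and level-4
  attributes as independent Bernoulli flags with the model's marginal
  prevalences and level 2 as a categorical draw, and computes the exact
  expectation of per-patient need.  Under the ``max`` rule the
  within-level term is the expectation of the maximum of independently
  present values: with per-competency minutes sorted descending
  ``m_1 >= m_2 >= ...`` and presence probabilities ``p_i``,

      E[max] = sum_i m_i * p_i * prod_{j<i} (1 - p_j),

  each term being the probability that attribute *i* is present and no
  larger-minutes attribute is (ties commute, so their order is
  irrelevant).  Under ``add`` the term is ``sum_i p_i * m_i``.

* :func:`brute_force_demand` — exhaustive enumeration of every patient
  type with its joint probability; exact, guarded by a cap on the type
  count.  The verification oracle for the analytic route.

* :func:`monte_carlo_demand` — microsimulation of a synthetic patient
  population, with per-competency standard errors.

All three add :func:`level1_demand` — prevention/screening programs for
the general-population strata, strictly additive across disjoint strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EnumerationCapError
from .protocols import NeedVector, Rule, _check_rule
from .schema import ModelDefinition, PREVALENCE_DENOMINATOR, diagnosed_count

MINUTES_PER_HOUR = 60.0

#: Default cap on |L2| x 2^|L3| x 2^|L4| for exhaustive enumeration.
DEFAULT_ENUMERATION_CAP = 2**22


@dataclass
class DemandTable:
    """Annual hours per competency for the region.

    ``provenance`` records which route produced it; Monte-Carlo tables
    also carry the sample size, the seed, and per-competency standard
    errors (in hours).
    """

    hours: dict[str, float]
    provenance: str
    n_patients: int | None = None
    seed: int | None = None
    se: dict[str, float] = field(default_factory=dict)

    def total_hours(self) -> float:
        return sum(self.hours.values())

    def to_frame(self, model: ModelDefinition | None = None) -> pd.DataFrame:
        """Tabular form: competency_id, skill_level, annual_hours[, se]."""
        rows = []
        for comp_id in sorted(self.hours):
            row = {"competency_id": comp_id}
            if model is not None:
                row["skill_level"] = model.competency(comp_id).skill_level
            row["annual_hours"] = self.hours[comp_id]
            if self.se:
                row["se"] = self.se.get(comp_id, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


# -- helpers ----------------------------------------------------------------


def _level_arrays(
    model: ModelDefinition, level: int, comp_index: dict[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(k x C) annual-minutes matrix and length-k probability vector for
    one level's attributes, in declaration order."""
    attrs = model.attributes_at_level(level)
    minutes = np.zeros((len(attrs), len(comp_index)))
    probs = np.empty(len(attrs))
    for i, attr in enumerate(attrs):
        probs[i] = attr.probability
        for comp_id, mins in model.annual_minutes(attr.id).items():
            minutes[i, comp_index[comp_id]] = mins
    return minutes, probs


def _comp_index(model: ModelDefinition) -> dict[str, int]:
    return {c.id: i for i, c in enumerate(model.competencies)}


def _vector_from_array(arr: np.ndarray, comp_index: dict[str, int]) -> NeedVector:
    return {comp_id: float(arr[i]) for comp_id, i in comp_index.items()}


def _expected_max_minutes(minutes: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Per competency, E[max of independently present attribute minutes]
    by the sorted survival-product formula (absent attributes contribute
    zero, the empty maximum)."""
    k, n_comp = minutes.shape
    out = np.zeros(n_comp)
    for c in range(n_comp):
        order = np.argsort(-minutes[:, c], kind="stable")
        survive = 1.0
        acc = 0.0
        for i in order:
            m = minutes[i, c]
            if m <= 0.0:
                break  # remaining attributes cannot raise the maximum
            acc += m * probs[i] * survive
            survive *= 1.0 - probs[i]
        out[c] = acc
    return out


# -- operations -------------------------------------------------------------


def expected_need_per_patient(
    model: ModelDefinition, rule: Rule = "max"
) -> NeedVector:
    """Exact expected annual minutes per diagnosed person, by competency.

    Level 2 contributes its categorical mean; levels 3 and 4 contribute
    the expectation of the within-level combination over independent
    Bernoulli presence; levels sum.
    """
    _check_rule(rule)
    comp_index = _comp_index(model)
    m2, p2 = _level_arrays(model, 2, comp_index)
    total = p2 @ m2
    for level in (3, 4):
        minutes, probs = _level_arrays(model, level, comp_index)
        if minutes.size == 0:
            continue
        if rule == "max":
            total = total + _expected_max_minutes(minutes, probs)
        else:
            total = total + probs @ minutes
    return _vector_from_array(total, comp_index)


def level1_demand(model: ModelDefinition) -> DemandTable:
    """Annual hours of prevention/screening programs for the level-1
    population strata: per competency, sum over strata of
    stratum persons x annual minutes / 60.  Strata are disjoint
    programs, so contributions add (no max rule)."""
    hours: dict[str, float] = {c.id: 0.0 for c in model.competencies}
    population = model.region.population
    for attr in model.attributes_at_level(1):
        persons = population * attr.prevalence_per_10k / PREVALENCE_DENOMINATOR
        for comp_id, mins in model.annual_minutes(attr.id).items():
            hours[comp_id] += persons * mins / MINUTES_PER_HOUR
    return DemandTable(hours=hours, provenance="analytic")


def regional_demand(model: ModelDefinition, rule: Rule = "max") -> DemandTable:
    """Analytic regional demand: expected per-patient need times the
    diagnosed count, plus level-1 program demand, in hours/year."""
    per_patient = expected_need_per_patient(model, rule)
    n = diagnosed_count(model)
    base = level1_demand(model).hours
    hours = {
        comp_id: base[comp_id]
        + per_patient.get(comp_id, 0.0) * n / MINUTES_PER_HOUR
        for comp_id in base
    }
    return DemandTable(hours=hours, provenance="analytic")


def _subset_tables(
    minutes: np.ndarray, probs: np.ndarray, rule: Rule
) -> tuple[np.ndarray, np.ndarray]:
    """Need vector and probability of every subset of one level's
    attributes, indexed by bitmask (bit i = attribute i present)."""
    k, n_comp = minutes.shape
    needs = np.zeros((1 << k, n_comp))
    prob = np.empty(1 << k)
    prob[0] = np.prod(1.0 - probs) if k else 1.0
    for mask in range(1, 1 << k):
        low = (mask & -mask).bit_length() - 1
        rest = mask & (mask - 1)
        if rule == "max":
            needs[mask] = np.maximum(needs[rest], minutes[low])
        else:
            needs[mask] = needs[rest] + minutes[low]
        prob[mask] = (
            prob[rest] * probs[low] / (1.0 - probs[low])
            if probs[low] < 1.0
            else 0.0
        )
    if np.any(probs >= 1.0):  # recompute exactly when some p == 1
        for mask in range(1 << k):
            p = 1.0
            for i in range(k):
                p *= probs[i] if mask >> i & 1 else 1.0 - probs[i]
            prob[mask] = p
    return needs, prob


def brute_force_demand(
    model: ModelDefinition,
    rule: Rule = "max",
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> DemandTable:
    """Exact regional demand by exhaustive enumeration of every patient
    type, weighting each type's need by its joint probability
    P(type) = p_level2 x prod(present p) x prod(absent 1-p).

    Refuses (:class:`EnumerationCapError`) when the type count exceeds
    ``cap``.  Exists as the independent oracle for
    :func:`regional_demand`.
    """
    _check_rule(rule)
    from .protocols import enumerate_patient_types

    count = enumerate_patient_types(model).count
    if count > cap:
        raise EnumerationCapError(
            f"model has {count:,} patient types, above the enumeration "
            f"cap of {cap:,}; raise the cap or use the analytic method"
        )
    comp_index = _comp_index(model)
    m2, p2 = _level_arrays(model, 2, comp_index)
    needs3, prob3 = _subset_tables(*_level_arrays(model, 3, comp_index), rule)
    needs4, prob4 = _subset_tables(*_level_arrays(model, 4, comp_index), rule)

    expected = np.zeros(len(comp_index))
    for i2 in range(m2.shape[0]):
        for mask3 in range(len(prob3)):
            base = m2[i2] + needs3[mask3]
            w = p2[i2] * prob3[mask3] * prob4  # joint P of each type
            expected += w @ (base[None, :] + needs4)

    n = diagnosed_count(model)
    base_hours = level1_demand(model).hours
    hours = {
        comp_id: base_hours[comp_id]
        + float(expected[idx]) * n / MINUTES_PER_HOUR
        for comp_id, idx in comp_index.items()
    }
    return DemandTable(hours=hours, provenance="brute_force")


def sample_patient_need(
    model: ModelDefinition,
    n_patients: int,
    rng: np.random.Generator,
    rule: Rule = "max",
    chunk: int = 20_000,
) -> np.ndarray:
    """Simulate ``n_patients`` diagnosed persons and return their annual
    need minutes as an (n_patients x n_competencies) array.

    Level 2 is drawn categorically; levels 3 and 4 as independent
    Bernoulli flags.  Draw order is fixed (level 2, then 3, then 4,
    chunk by chunk) so results are reproducible for a given generator
    state.
    """
    _check_rule(rule)
    comp_index = _comp_index(model)
    m2, p2 = _level_arrays(model, 2, comp_index)
    m3, p3 = _level_arrays(model, 3, comp_index)
    m4, p4 = _level_arrays(model, 4, comp_index)

    out = np.empty((n_patients, len(comp_index)))
    for start in range(0, n_patients, chunk):
        n = min(chunk, n_patients - start)
        idx2 = rng.choice(len(p2), size=n, p=p2 / p2.sum())
        need = m2[idx2].copy()
        for minutes, probs in ((m3, p3), (m4, p4)):
            if len(probs) == 0:
                continue
            present = rng.random((n, len(probs))) < probs
            if rule == "max":
                need += (present[:, :, None] * minutes[None, :, :]).max(axis=1)
            else:
                need += present @ minutes
        out[start : start + n] = need
    return out


def monte_carlo_demand(
    model: ModelDefinition,
    n_patients: int,
    seed: int,
    rule: Rule = "max",
) -> DemandTable:
    """Monte-Carlo regional demand from ``n_patients`` simulated
    diagnosed persons, scaled to the region, with per-competency
    standard errors (level-1 program demand is deterministic and enters
    without error)."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    comp_index = _comp_index(model)
    rng = np.random.default_rng(seed)
    need = sample_patient_need(model, n_patients, rng, rule)
    scale = diagnosed_count(model) / MINUTES_PER_HOUR
    mean = need.mean(axis=0) * scale
    if n_patients > 1:
        sem = need.std(axis=0, ddof=1) / math.sqrt(n_patients) * scale
    else:
        sem = np.zeros(len(comp_index))
    base = level1_demand(model).hours
    hours = {c: base[c] + float(mean[i]) for c, i in comp_index.items()}
    se = {c: float(sem[i]) for c, i in comp_index.items()}
    return DemandTable(
        hours=hours,
        provenance="monte_carlo",
        n_patients=n_patients,
        seed=seed,
        se=se,
    )


def sample_attribute_indicators(
    model: ModelDefinition, n_patients: int, seed: int
) -> pd.DataFrame:
    """Simulate patient attribute vectors and return a 0/1 DataFrame
    with one column per level-2/3/4 attribute (level 2 one-hot).

    Used to verify that sampled marginal frequencies recover the
    specified prevalences.
    """
    rng = np.random.default_rng(seed)
    l2 = model.attributes_at_level(2)
    l3 = model.attributes_at_level(3)
    l4 = model.attributes_at_level(4)
    p2 = np.array([a.probability for a in l2])
    idx2 = rng.choice(len(l2), size=n_patients, p=p2 / p2.sum())
    cols: dict[str, np.ndarray] = {}
    for i, attr in enumerate(l2):
        cols[attr.id] = (idx2 == i).astype(np.int8)
    for attrs in (l3, l4):
        for attr in attrs:
            cols[attr.id] = (rng.random(n_patients) < attr.probability).astype(
                np.int8
            )
    return pd.DataFrame(cols)
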