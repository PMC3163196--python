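"""Mapping competency demand to occupations, FTE, and headcount.

A delivery scenario distributes each competency's annual hours over the
occupations allowed to deliver it (a share matrix with rows summing to
one), so total clinical hours are conserved and only the occupational
split varies between, say, a specialist-led and a generalist-led
service.  FTE divides occupation hours by effective annual clinical
hours per provider (contracted hours/week x weeks/year x clinical
activity fraction); headcount divides FTE by the participation rate.
Neither is rounded by default — planning aggregates should not
accumulate rounding — but reports may round headcount up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .demand import DemandTable, regional_demand
from .errors import MappingCoverageError, MissingParamsError
from .protocols import Rule
from .schema import MappingScenario, ModelDefinition, WorkforceParams


def map_to_occupations(
    demand: DemandTable, scenario: MappingScenario
) -> dict[str, float]:
    """Distribute competency hours over occupations per the scenario's
    share matrix.  Total hours are conserved exactly; a competency with
    nonzero demand that the scenario does not cover is an error."""
    hours: dict[str, float] = {}
    for comp_id, comp_hours in demand.hours.items():
        shares = scenario.mapping.get(comp_id)
        if shares is None:
            if comp_hours > 0.0:
                raise MappingCoverageError(
                    f"scenario '{scenario.name}' does not cover competency "
                    f"'{comp_id}' which has {comp_hours:g} h of demand"
                )
            continue
        for occ_id, share in shares.items():
            hours[occ_id] = hours.get(occ_id, 0.0) + comp_hours * share
    return hours


def fte_requirements(
    occupation_hours: Mapping[str, float],
    params: Mapping[str, WorkforceParams],
    round_up: bool = False,
) -> pd.DataFrame:
    """FTE and headcount per occupation.

    ``fte = hours / effective annual clinical hours`` and
    ``headcount = fte / participation_rate``; with ``round_up`` the
    headcount is ceiled to whole providers.
    """
    rows = []
    for occ_id in sorted(occupation_hours):
        hours = occupation_hours[occ_id]
        p = params.get(occ_id)
        if p is None:
            if hours > 0.0:
                raise MissingParamsError(
                    f"no workforce parameters for occupation '{occ_id}'"
                )
            fte = headcount = 0.0
        else:
            fte = hours / p.effective_annual_clinical_hours
            headcount = fte / p.participation_rate
            if round_up:
                headcount = float(math.ceil(headcount))
        rows.append(
            {
                "occupation": occ_id,
                "annual_hours": hours,
                "fte": fte,
                "headcount": headcount,
            }
        )
    return pd.DataFrame(
        rows, columns=["occupation", "annual_hours", "fte", "headcount"]
    )


@dataclass
class ScenarioComparison:
    """Side-by-side scenario report: the shared per-competency demand
    plus FTE per occupation under every scenario."""

    demand: pd.DataFrame
    occupations: pd.DataFrame  # scenario, occupation, annual_hours, fte, headcount

    def occupation_pivot(self) -> pd.DataFrame:
        """Occupation rows x scenario columns, values = FTE."""
        return self.occupations.pivot_table(
            index="occupation", columns="scenario", values="fte", fill_value=0.0
        )


def compare_scenarios(
    model: ModelDefinition,
    scenarios: list[MappingScenario] | None = None,
    rule: Rule = "max",
    round_up: bool = False,
) -> ScenarioComparison:
    """Run the full planning chain for each scenario over one analytic
    demand table.  Ordering is deterministic: scenarios as given (or as
    declared in the model), occupations alphabetical."""
    if scenarios is None:
        scenarios = model.scenarios
    if not scenarios:
        raise MappingCoverageError("no delivery scenarios to compare")
    demand = regional_demand(model, rule)
    frames = []
    for scenario in scenarios:
        occ_hours = map_to_occupations(demand, scenario)
        table = fte_requirements(occ_hours, model.workforce, round_up=round_up)
        table.insert(0, "scenario", scenario.name)
        frames.append(table)
    return ScenarioComparison(
        demand=demand.to_frame(model),
        occupations=pd.concat(frames, ignore_index=True),
    )
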