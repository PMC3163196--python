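"""Regional demand: analytic expectation, brute-force oracle,
Monte-Carlo cross-check, level-1 programs."""

from __future__ import annotations

import math

import numpy as np
import pytest

from webforce import (
    EnumerationCapError,
    brute_force_demand,
    expected_need_per_patient,
    level1_demand,
    monte_carlo_demand,
    regional_demand,
)
from webforce.synth import GeneratorSpec, generate_random_model, perturb_model

from conftest import make_model


def _max_rel_err(a: dict, b: dict) -> float:
    keys = set(a) | set(b)
    return max(
        abs(a.get(k, 0.0) - b.get(k, 0.0)) / max(abs(b.get(k, 0.0)), 1e-300)
        if (a.get(k, 0.0) or b.get(k, 0.0))
        else 0.0
        for k in keys
    )


@pytest.fixture()
def two_attr_model():
    """Level-3 A(p=0.5, {X:60}) and B(p=0.5, {X:30}) over a silent
    level-2 category; 10,000 diagnosed persons."""
    return make_model(
        l2={"d": (10_000.0, {"X": 0.0})},
        l3={"A": (5000.0, {"X": 60.0}), "B": (5000.0, {"X": 30.0})},
    )


class TestExpectedNeed:
    def test_single_bernoulli_mean(self):
        model = make_model(
            l2={"d": (10_000.0, {"X": 0.0})}, l3={"A": (5000.0, {"X": 60.0})}
        )
        assert expected_need_per_patient(model, "max")["X"] == pytest.approx(30.0)

    def test_expected_max_equals_subset_enumeration(self, two_attr_model):
        """E[max] over the four subsets: (0 + 30 + 60 + 60)/4 = 37.5."""
        assert expected_need_per_patient(two_attr_model, "max")["X"] == pytest.approx(
            37.5
        )

    def test_add_rule_is_sum_of_means(self, two_attr_model):
        assert expected_need_per_patient(two_attr_model, "add")["X"] == pytest.approx(
            45.0
        )

    def test_level2_categorical_mean(self):
        model = make_model(
            l2={"a": (3000.0, {"X": 100.0}), "b": (7000.0, {"X": 10.0, "Y": 20.0})}
        )
        need = expected_need_per_patient(model, "max")
        assert need["X"] == pytest.approx(0.3 * 100 + 0.7 * 10)
        assert need["Y"] == pytest.approx(0.7 * 20)

    def test_tied_minutes_commute(self):
        """Equal minutes across attributes give m * P(any present)
        regardless of sort order among the ties."""
        model = make_model(
            l2={"d": (10_000.0, {})},
            l3={"A": (2000.0, {"X": 45.0}), "B": (3000.0, {"X": 45.0})},
        )
        p_any = 1 - (1 - 0.2) * (1 - 0.3)
        assert expected_need_per_patient(model, "max")["X"] == pytest.approx(
            45.0 * p_any
        )


class TestRegionalDemand:
    def test_worked_example(self, two_attr_model):
        """37.5 expected minutes across 10,000 diagnosed persons is
        6,250 hours of that competency per year."""
        table = regional_demand(two_attr_model, "max")
        assert table.hours["X"] == pytest.approx(6250.0)
        assert table.provenance == "analytic"

    def test_degenerate_levels_reduce_to_level2(self):
        model = make_model(
            l2={"d": (10_000.0, {"X": 120.0})},
            l3={"A": (0.0, {"X": 600.0})},
            l4={"B": (0.0, {"Y": 600.0})},
        )
        table = regional_demand(model, "max")
        assert table.hours["X"] == pytest.approx(120.0 * 10_000 / 60)
        assert table.hours["Y"] == pytest.approx(0.0)

    def test_hours_are_minutes_over_sixty(self, exemplar):
        per_patient = expected_need_per_patient(exemplar, "max")
        table = regional_demand(exemplar, "max")
        for comp, mins in per_patient.items():
            assert table.hours[comp] == pytest.approx(mins * 10_000 / 60.0)


class TestLevel1Demand:
    def test_stratum_arithmetic(self):
        """A 2,000/10k stratum of 250,000 persons on a 1 x 20 min
        program needs 50,000 x 20/60 = 16,666.67 h."""
        model = make_model(
            l2={"d": (10_000.0, {"X": 0.0})},
            l1={"screen": (2000.0, {"S": 20.0})},
        )
        assert level1_demand(model).hours["S"] == pytest.approx(50_000 * 20 / 60)

    def test_no_level1_is_zero(self, exemplar):
        assert all(h == 0.0 for h in level1_demand(exemplar).hours.values())

    def test_strata_are_additive(self):
        one = make_model(
            l2={"d": (10_000.0, {"X": 0.0})}, l1={"a": (1000.0, {"S": 20.0})}
        )
        other = make_model(
            l2={"d": (10_000.0, {"X": 0.0})}, l1={"b": (500.0, {"S": 60.0})}
        )
        both = make_model(
            l2={"d": (10_000.0, {"X": 0.0})},
            l1={"a": (1000.0, {"S": 20.0}), "b": (500.0, {"S": 60.0})},
        )
        assert level1_demand(both).hours["S"] == pytest.approx(
            level1_demand(one).hours["S"] + level1_demand(other).hours["S"]
        )

    def test_level1_included_in_regional_demand(self):
        model = make_model(
            l2={"d": (10_000.0, {"X": 60.0})},
            l1={"screen": (2000.0, {"S": 20.0})},
        )
        table = regional_demand(model, "max")
        assert table.hours["S"] == pytest.approx(50_000 * 20 / 60)
        assert table.hours["X"] == pytest.approx(10_000.0)


class TestBruteForceOracle:
    @pytest.mark.parametrize("rule", ["max", "add"])
    def test_matches_analytic_on_random_models(self, rule):
        for seed in range(30):
            model = generate_random_model(
                GeneratorSpec(
                    seed=seed, n_level2=2, n_level3=3, n_level4=2, n_competencies=4
                )
            )
            analytic = regional_demand(model, rule)
            brute = brute_force_demand(model, rule)
            assert _max_rel_err(analytic.hours, brute.hours) < 1e-9

    def test_deterministic_model_single_type(self):
        """With every p in {0,1} only one patient type exists and the
        expectation collapses to its need."""
        model = make_model(
            l2={"d": (10_000.0, {"X": 30.0})},
            l3={"A": (10_000.0, {"X": 60.0}), "B": (0.0, {"X": 600.0})},
            l4={"C": (10_000.0, {"Y": 15.0})},
        )
        table = brute_force_demand(model, "max")
        assert table.hours["X"] == pytest.approx((30 + 60) * 10_000 / 60)
        assert table.hours["Y"] == pytest.approx(15 * 10_000 / 60)

    def test_subset_probabilities_normalised(self):
        from webforce.demand import _comp_index, _level_arrays, _subset_tables

        model = generate_random_model(
            GeneratorSpec(seed=3, n_level2=2, n_level3=4, n_level4=3)
        )
        for level in (3, 4):
            _, prob = _subset_tables(
                *_level_arrays(model, level, _comp_index(model)), "max"
            )
            assert prob.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cap_refusal_reports_count(self, exemplar):
        with pytest.raises(EnumerationCapError, match="2,621,440"):
            brute_force_demand(exemplar, cap=2**20)

    def test_exemplar_within_cap_matches_analytic(self, exemplar):
        analytic = regional_demand(exemplar, "max")
        brute = brute_force_demand(exemplar, "max")
        assert _max_rel_err(analytic.hours, brute.hours) < 1e-9


class TestMonteCarlo:
    def test_same_seed_identical(self, two_attr_model):
        a = monte_carlo_demand(two_attr_model, 5000, seed=11)
        b = monte_carlo_demand(two_attr_model, 5000, seed=11)
        assert a.hours == b.hours and a.se == b.se

    def test_zero_variance_exact(self):
        model = make_model(l2={"d": (10_000.0, {"X": 120.0})})
        table = monte_carlo_demand(model, 1000, seed=0)
        assert table.hours["X"] == pytest.approx(120.0 * 10_000 / 60)
        assert table.se["X"] == 0.0

    def test_within_statistical_tolerance(self, two_attr_model):
        table = monte_carlo_demand(two_attr_model, 100_000, seed=42)
        assert table.se["X"] > 0
        assert abs(table.hours["X"] - 6250.0) <= 4 * table.se["X"]

    def test_se_scales_inversely_with_sqrt_n(self, two_attr_model):
        small = monte_carlo_demand(two_attr_model, 2_000, seed=5)
        large = monte_carlo_demand(two_attr_model, 32_000, seed=5)
        ratio = small.se["X"] / large.se["X"]
        assert ratio == pytest.approx(4.0, rel=0.25)

    def test_invalid_n_rejected(self, two_attr_model):
        with pytest.raises(ValueError):
            monte_carlo_demand(two_attr_model, 0, seed=1)


class TestScaling:
    def test_linear_in_minutes(self):
        model = generate_random_model(GeneratorSpec(seed=9, n_level3=3, n_level4=2))
        doubled = perturb_model(model, "minutes", 2.0)
        base = regional_demand(model, "max").hours
        twice = regional_demand(doubled, "max").hours
        for comp, hours in base.items():
            assert twice[comp] == pytest.approx(2 * hours, rel=1e-12)

    def test_linear_in_diagnosed_count(self):
        small = make_model(
            l2={"d": (10_000.0, {"X": 60.0})}, population=100_000
        )
        big = make_model(l2={"d": (10_000.0, {"X": 60.0})}, population=200_000)
        assert regional_demand(big, "max").hours["X"] == pytest.approx(
            2 * regional_demand(small, "max").hours["X"]
        )

    def test_dominance_add_over_max(self):
        for seed in range(10):
            model = generate_random_model(GeneratorSpec(seed=seed))
            dmax = regional_demand(model, "max").hours
            dadd = regional_demand(model, "add").hours
            assert all(dmax[c] <= dadd[c] + 1e-9 for c in dmax)

    def test_prevalence_increase_monotone_under_max(self):
        model = generate_random_model(GeneratorSpec(seed=21, n_level3=4, n_level4=3))
        up = perturb_model(model, "prevalence", 1.5)
        base = regional_demand(model, "max").hours
        more = regional_demand(up, "max").hours
        assert all(more[c] >= base[c] - 1e-9 for c in base)
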