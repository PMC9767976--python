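"""Drug costing, cost/QALY accumulation and incremental comparison."""

import numpy as np
import pytest

from psmcea import (CostSettings, DosingSchedule, Param, accumulate_costs,
                    accumulate_qalys, compare, cost_breakdown, cycle_drug_cost,
                    expected_time, wtp_from_gdp)
from psmcea.economics import CEAResult, StrategyResult, weighted_sae_cost

from test_psm import make_trace


@pytest.fixture
def zeroed_inputs(econ_inputs):
    """All unit costs zeroed; tests switch individual components back on."""
    z = econ_inputs.copy()
    for dp in z.drug_prices.values():
        dp.price = Param(0.0)
    for k in z.unit_costs:
        z.unit_costs[k] = Param(0.0)
    z.sae_costs = {}
    z.sae_incidence = {s: {} for s in z.sae_incidence}
    for k in z.subsequent_tx_share:
        z.subsequent_tx_share[k] = Param(0.0)
    return z


class TestCycleDrugCost:
    def test_linear_per_mg_pricing(self, econ_inputs):
        # 175 mg/m2 x 1.72 m2 = 301 mg paclitaxel at 11.44 US$ per 30 mg pack,
        # plus 129 mg cisplatin at 11.78 US$ per 50 mg
        cost = cycle_drug_cost(DosingSchedule(), "chemo", econ_inputs,
                               include_administration=False)
        expected = 301 * 11.44 / 30 + 129 * 11.78 / 50
        assert cost == pytest.approx(expected, abs=1e-9)
        assert cost == pytest.approx(114.78 + 30.39, abs=0.01)

    def test_whole_pack_rounding(self, econ_inputs):
        cost = cycle_drug_cost(DosingSchedule(), "chemo", econ_inputs,
                               rounding="whole_pack", include_administration=False)
        # cisplatin 129 mg -> 3 x 50 mg packs; paclitaxel 301 mg -> 11 x 30 mg
        assert cost == pytest.approx(3 * 11.78 + 11 * 11.44, abs=1e-9)

    def test_zero_dose_regimen_charges_administration_only(self, econ_inputs):
        cost = cycle_drug_cost(DosingSchedule(), "none", econ_inputs)
        assert cost == pytest.approx(4.01 + 2.78, abs=1e-9)

    def test_sintilimab_flat_dose_uses_100mg_vial_price(self, econ_inputs):
        with_s = cycle_drug_cost(DosingSchedule(), "sintilimab_chemo", econ_inputs,
                                 include_administration=False)
        without = cycle_drug_cost(DosingSchedule(), "chemo", econ_inputs,
                                  include_administration=False)
        assert with_s - without == pytest.approx(200 * 167.40 / 100, abs=1e-9)

    def test_fluorouracil_regimen_hospitalizes_five_days(self, econ_inputs):
        c5 = cycle_drug_cost(DosingSchedule(), "chemo_5fu", econ_inputs)
        drugs = cycle_drug_cost(DosingSchedule(), "chemo_5fu", econ_inputs,
                                include_administration=False)
        assert c5 - drugs == pytest.approx(4.01 + 2.78 + 5 * 19.86, abs=1e-9)

    def test_unknown_regimen_rejected(self, econ_inputs):
        with pytest.raises(KeyError):
            cycle_drug_cost(DosingSchedule(), "triplet", econ_inputs)


class TestAccumulateCosts:
    def test_bsc_only_progressed_cohort(self, zeroed_inputs):
        zeroed_inputs.unit_costs["bsc_per_cycle"] = Param(117.0)
        trace = make_trace([0.0] * 10, [1.0] * 10, rate=0.0)
        assert accumulate_costs(trace, zeroed_inputs, "chemo") == pytest.approx(1170.0)

    def test_one_off_sae_cost(self, zeroed_inputs):
        zeroed_inputs.sae_costs = {"anemia": Param(100.0)}
        zeroed_inputs.sae_incidence = {"chemo": {"anemia": 1.0},
                                       "sintilimab_chemo": {"anemia": 1.0}}
        trace = make_trace([0.0] * 6, [0.0] * 6, rate=0.0)
        assert accumulate_costs(trace, zeroed_inputs, "chemo") == pytest.approx(100.0)

    def test_missing_sae_incidence_is_a_config_error(self, econ_inputs):
        broken = econ_inputs.copy()
        del broken.sae_incidence["chemo"]["anemia"]
        with pytest.raises(KeyError, match="anemia"):
            weighted_sae_cost(broken, "chemo")

    def test_zero_discount_never_decreases_totals(self, reference_evaluator):
        base = reference_evaluator.run()
        undiscounted = reference_evaluator.run({"discount_rate": 0.0})
        assert undiscounted.intervention.cost >= base.intervention.cost
        assert undiscounted.intervention.qaly >= base.intervention.qaly

    def test_costs_monotone_in_horizon(self, overall_models, econ_inputs):
        from psmcea import build_grid, state_occupancy
        m = overall_models["sintilimab_chemo"]
        totals = []
        for q in (0.90, 0.99):
            grid = build_grid(m["os"], stop_quantile=q)
            trace = state_occupancy(m["os"], m["pfs"], grid, 0.05)
            totals.append(accumulate_costs(trace, econ_inputs, "sintilimab_chemo"))
        assert totals[1] >= totals[0]

    def test_breakdown_components_sum_to_total(self, econ_inputs, reference_evaluator):
        trace = reference_evaluator.traces["sintilimab_chemo"]
        parts = cost_breakdown(trace, econ_inputs, "sintilimab_chemo")
        assert set(parts) == {"first_line", "routine", "imaging", "bsc",
                              "subsequent_treatment", "sae"}
        assert sum(parts.values()) == pytest.approx(
            accumulate_costs(trace, econ_inputs, "sintilimab_chemo"))
        assert all(v >= 0 for v in parts.values())


class TestAccumulateQALYs:
    def test_one_year_in_pfs(self, zeroed_inputs):
        zeroed_inputs.utilities["pfs"] = Param(0.741)
        zeroed_inputs.ae_incidence_g12 = {}
        zeroed_inputs.ae_incidence_g34 = {}
        trace = make_trace([1.0] * 16, [0.0] * 16, rate=0.0, months_per_cycle=0.75)
        assert accumulate_qalys(trace, zeroed_inputs, "chemo") == pytest.approx(0.741)

    def test_zero_utilities_give_zero(self, zeroed_inputs):
        zeroed_inputs.utilities["pfs"] = Param(0.0)
        zeroed_inputs.utilities["pd"] = Param(0.0)
        zeroed_inputs.ae_incidence_g12 = {}
        zeroed_inputs.ae_incidence_g34 = {}
        trace = make_trace([0.5] * 10, [0.3] * 10)
        assert accumulate_qalys(trace, zeroed_inputs, "chemo") == 0.0

    def test_unit_utilities_reduce_to_life_years(self, econ_inputs, reference_evaluator):
        perfect = econ_inputs.copy()
        perfect.utilities["pfs"] = Param(1.0)
        perfect.utilities["pd"] = Param(1.0)
        perfect.ae_incidence_g12 = {}
        perfect.ae_incidence_g34 = {}
        trace = reference_evaluator.traces["chemo"]
        q = accumulate_qalys(trace, perfect, "chemo")
        assert q == pytest.approx(expected_time(trace, "alive") / 12.0, abs=1e-12)


class TestCompare:
    def test_simple_icer(self):
        res = compare([("a", 200.0, 2.0), ("b", 100.0, 1.0)], wtp=150.0)
        assert res.icer == pytest.approx(100.0)
        assert res.cost_effective and res.dominance is None

    def test_dominant_intervention_reports_no_icer(self):
        res = compare([("a", 50.0, 2.0), ("b", 100.0, 1.0)], wtp=150.0)
        assert res.dominance == "intervention_dominant"
        assert np.isnan(res.icer) and res.cost_effective

    def test_equal_effect_flagged(self):
        res = compare([("a", 200.0, 1.0), ("b", 100.0, 1.0)], wtp=150.0)
        assert res.dominance == "equivalent_effect"
        assert np.isnan(res.icer) and not res.cost_effective

    def test_antisymmetry_under_strategy_swap(self):
        fwd = compare([("a", 200.0, 2.0), ("b", 100.0, 1.0)], wtp=150.0)
        rev = compare([("b", 100.0, 1.0), ("a", 200.0, 2.0)], wtp=150.0)
        assert rev.incremental_cost == -fwd.incremental_cost
        assert rev.incremental_qaly == -fwd.incremental_qaly
        assert rev.cost_effective != fwd.cost_effective

    def test_requires_exactly_two_strategies(self):
        with pytest.raises(ValueError):
            compare([("a", 1.0, 1.0)], wtp=1.0)

    def test_nmb(self):
        res = compare([("a", 200.0, 2.0), ("b", 100.0, 1.0)], wtp=150.0)
        assert res.nmb(res.intervention) == pytest.approx(150 * 2 - 200)


def test_wtp_threshold_is_three_times_gdp():
    assert wtp_from_gdp(12551.50) == pytest.approx(37654.50, abs=1e-9)
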