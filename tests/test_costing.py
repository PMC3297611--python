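"""Drug, adverse-event and state-cost accrual."""

import numpy as np
import pytest

from mrcc_cea import (
    DoseBlock,
    DosingSchedule,
    PriceTable,
    SAEProfile,
    SecondLineMix,
    UnitCost,
    accumulate_costs,
    apply_hr,
    compute_trace,
    cycle_drug_cost,
    ps_cycle_cost,
    sae_expected_cost,
)
from mrcc_cea.model import DecisionModel


def scaled_prices(prices, factor):
    out = PriceTable()
    for item, uc in prices.items():
        out[item] = UnitCost(item, uc.median * factor, uc.low * factor,
                             uc.high * factor, uc.fixed)
    return out


class TestCycleDrugCost:
    def test_sunitinib_full_price_cycle(self, config):
        # 50 mg/day = 4 x 12.5 mg units x $71.5 x 28 days
        cost = cycle_drug_cost(config.dosing["sunitinib"], config.prices, 1)
        assert cost == pytest.approx(8008.0)

    def test_spap_donated_phase_is_free(self, config):
        cost = cycle_drug_cost(
            config.dosing["sunitinib"], config.prices, 5, spap=True, spap_eligible=True
        )
        assert cost == 0.0

    def test_spap_paid_phase_charged(self, config):
        cost = cycle_drug_cost(
            config.dosing["sunitinib"], config.prices, 2, spap=True, spap_eligible=True
        )
        assert cost == pytest.approx(8008.0)

    def test_zero_administrations_cost_nothing(self, config):
        sched = DosingSchedule(
            drug="x", price_item="sunitinib_12_5mg", pack_size=12.5, route="oral",
            steady_cycle=(DoseBlock(dose=50, n_admin=0),),
        )
        assert cycle_drug_cost(sched, config.prices, 0) == 0.0

    def test_whole_pack_discard_rounds_up(self, config):
        # bevacizumab 650 mg needs 7 whole 100 mg vials, 3 times per cycle,
        # plus an iv administration fee per infusion
        cost = cycle_drug_cost(config.dosing["bevacizumab"], config.prices, 1)
        assert cost == pytest.approx(7 * 815.1 * 3 + 3 * 18.5)

    def test_interferon_titration_cheaper_than_steady_state(self, config):
        sched = config.dosing["interferon"]
        first = cycle_drug_cost(sched, config.prices, 0)
        steady = cycle_drug_cost(sched, config.prices, 1)
        # week 1 at 3 MU and week 2 at 6 MU replace full 9 MU dosing
        assert steady - first == pytest.approx((3 - 1) * 6.5 * 3 + (3 - 2) * 6.5 * 3)

    def test_unknown_drug_rejected(self, config):
        sched = DosingSchedule(
            drug="x", price_item="no_such_item", pack_size=1, route="oral",
            steady_cycle=(DoseBlock(1, 1),),
        )
        with pytest.raises(KeyError):
            cycle_drug_cost(sched, config.prices, 0)


class TestSaeCost:
    def test_zero_probabilities_cost_nothing(self, config):
        profile = SAEProfile({"neutropenia": 0.0, "nausea": 0.0})
        assert sae_expected_cost(profile, config.prices) == 0.0

    def test_single_event_product(self, config):
        # 12% grade>=3 neutropenia on sunitinib at $461.5 per event
        profile = SAEProfile({"neutropenia": 0.12})
        assert sae_expected_cost(profile, config.prices) == pytest.approx(55.38)

    def test_full_profile_matches_hand_summed_oracle(self, config):
        strat = config.strategy("sunitinib")
        expected = sum(
            p * config.prices.price(f"sae_{name}")
            for name, p in strat.sae.probabilities.items()
        )
        assert sae_expected_cost(strat.sae, config.prices) == pytest.approx(expected)
        assert expected == pytest.approx(
            0.12 * 461.5 + 0.04 * 531.7 + 0.08 * 3551.7
            + 0.04 * 44.3 + 0.07 * 115.4 + 0.08 * 12.9
        )


class TestPsCycleCost:
    def test_no_uptake_no_bsc_no_followup_is_free(self, config):
        prices = scaled_prices(config.prices, 1.0)
        prices["morphine_300mg"] = UnitCost("morphine_300mg", 0, 0, 0)
        cost = ps_cycle_cost(
            SecondLineMix(shares={}), prices, config.dosing, include_followup=False
        )
        assert cost == 0.0

    def test_best_supportive_care_arithmetic(self, config):
        # morphine 300 mg twice daily: 2 x $1.4 x 42 days before weighting
        bsc = cycle_drug_cost(config.dosing["morphine"], config.prices, 1)
        assert bsc == pytest.approx(117.6)

    def test_spap_reduces_only_the_second_line_sunitinib_share(self, config):
        base = ps_cycle_cost(config.second_line, config.prices, config.dosing)
        spap = ps_cycle_cost(
            config.second_line, config.prices, config.dosing,
            spap=True, spap_second_line_paid_fraction=0.4,
        )
        sun_share = config.second_line.shares["sunitinib"]
        expected_drop = sun_share * 8008.0 * (1 - 0.4)
        assert base - spap == pytest.approx(expected_drop)

    def test_overfull_mix_rejected(self):
        with pytest.raises(ValueError):
            SecondLineMix(shares={"sunitinib": 0.8, "sorafenib": 0.4})


class TestAccumulateCosts:
    def _trace(self, config, name="sunitinib"):
        strat = config.strategy(name)
        model = DecisionModel(config)
        return compute_trace(
            apply_hr(model.reference_pfs, strat.hr_pfs.mean),
            apply_hr(model.reference_os, strat.hr_os.mean),
            config.engine.horizon,
        )

    def test_zero_prices_zero_costs(self, config):
        trace = self._trace(config)
        costs = accumulate_costs(
            trace, config.strategy("sunitinib"), scaled_prices(config.prices, 0.0),
            config.dosing, config.second_line,
        )
        assert costs.cost_total == 0.0

    def test_price_scaling_is_linear(self, config):
        trace = self._trace(config)
        kwargs = dict(
            schedules=config.dosing, mix=config.second_line,
            second_line_intensity=config.engine.second_line_intensity,
        )
        for spap in (False, True):
            one = accumulate_costs(
                trace, config.strategy("sunitinib"), config.prices,
                spap=spap, **kwargs,
            )
            two = accumulate_costs(
                trace, config.strategy("sunitinib"), scaled_prices(config.prices, 2.0),
                spap=spap, **kwargs,
            )
            assert two.cost_pfs == pytest.approx(2 * one.cost_pfs, rel=1e-12)
            assert two.cost_ps == pytest.approx(2 * one.cost_ps, rel=1e-12)

    def test_costs_monotone_in_every_unit_price(self, config):
        trace = self._trace(config, "bevacizumab_interferon")
        strat = config.strategy("bevacizumab_interferon")
        base = accumulate_costs(
            trace, strat, config.prices, config.dosing, config.second_line
        ).cost_total
        for item in config.prices:
            bumped = scaled_prices(config.prices, 1.0)
            uc = bumped[item]
            bumped[item] = UnitCost(item, uc.median * 1.5, uc.low, uc.high * 1.5, uc.fixed)
            total = accumulate_costs(
                trace, strat, bumped, config.dosing, config.second_line
            ).cost_total
            assert total >= base - 1e-9, item

    def test_spap_never_raises_any_strategy_cost(self, base_results):
        no_spap = {r.name: r.cost for r in base_results[False][0]}
        spap = {r.name: r.cost for r in base_results[True][0]}
        for name in no_spap:
            assert spap[name] <= no_spap[name] + 1e-9, name

    def test_spap_flat_and_occupancy_charges_bracket_three_cycles(self, config):
        # the flat convention charges three full cycles; the occupancy
        # convention weights them by PFS occupancy, so it must cost less
        from dataclasses import replace as dc_replace

        trace = self._trace(config)
        strat = config.strategy("sunitinib")
        args = (config.prices, config.dosing, config.second_line)
        flat = accumulate_costs(trace, strat, *args, spap=True, spap_charge="flat")
        occ = accumulate_costs(trace, strat, *args, spap=True, spap_charge="occupancy")
        assert occ.cost_pfs < flat.cost_pfs
        no_spap = accumulate_costs(trace, strat, *args, spap=False)
        assert flat.cost_pfs < no_spap.cost_pfs
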