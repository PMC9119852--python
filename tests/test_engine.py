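"""Exposure engine: event algebra, mass balance, and whole-day simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soildust import draw_person_params
from soildust.engine import (HandState, dust_per_drop, effective_loading,
                             exp_pacifier_daily, exp_pacifier_event,
                             hand_contact_event, hand_to_mouth_event,
                             object_to_mouth_event, pacifier_soil_event,
                             removal_event, simulate_person_day)
from soildust.rng import PersonStreams
from tests.conftest import one_hour_indoor_diary

frac = st.floats(0.0, 1.0)
loading = st.floats(0.0, 1e4)


class TestEventAlgebra:
    def test_effective_loading(self):
        assert effective_loading(10, True, 0.25) == 2.5
        assert effective_loading(10, False, 0.25) == 10
        assert effective_loading(0, True, 0.4) == 0

    def test_dust_per_drop_printed_equation(self):
        assert dust_per_drop(10, 9.5, 0.375, 0.5) == pytest.approx(17.8125)
        assert dust_per_drop(10, 9.5, 0.25, 0.5) == pytest.approx(11.875)
        assert dust_per_drop(123, 9, 0.3, 0) == 0

    def test_pacifier_event_equation(self):
        assert exp_pacifier_event(17.8125, 5, 1.0, 0) == pytest.approx(89.0625)
        assert exp_pacifier_event(17.8125, 5, 1.0, 1.0) == 0
        assert exp_pacifier_event(17.8125, 0, 1.0, 0) == 0

    def test_daily_rollup_is_sum_over_events_in_mg(self):
        assert exp_pacifier_daily([89.0625] * 10) == pytest.approx(0.890625)
        assert exp_pacifier_daily([]) == 0
        assert exp_pacifier_daily([1000.0]) == pytest.approx(1.0)

    def test_pacifier_soil_variant(self):
        """Adherence (mg/cm^2 -> ug/cm^2) replaces loading x transfer."""
        amt = pacifier_soil_event(0.055, 9.5, 0.375, 2, 1.0, 0, "1-<2y")
        assert amt == pytest.approx(391.875)
        assert pacifier_soil_event(0.055, 9.5, 0.375, 2, 1.0, 1.0, "1-<2y") == 0

    @pytest.mark.parametrize("age", ["0-<1m", "1-<3m", "3-<6m", "6m-<1y"])
    def test_pacifier_soil_rejected_under_one_year(self, age):
        with pytest.raises(ValueError, match="no soil contact"):
            pacifier_soil_event(0.055, 9.5, 0.375, 2, 1.0, 0, age)


class TestHandDynamics:
    def test_single_dust_contact_closed_form(self):
        hand = hand_contact_event(HandState(), "dust", 10, 0.5, 1.0)
        assert hand.dust == pytest.approx(5.0)

    def test_contact_through_blanket(self):
        hand = hand_contact_event(HandState(), "dust", 10, 0.5, 1.0,
                                  blanket_in_use=True, f_blanket=0.25)
        assert hand.dust == pytest.approx(1.25)

    def test_soil_contact_sets_adherence_loading(self):
        hand = hand_contact_event(HandState(), "soil", 110.0, 1.0, 1.0)
        assert hand.soil == pytest.approx(110.0)  # 0.11 mg/cm^2 sampled

    def test_contacts_saturate_rather_than_accumulate(self):
        hand = HandState()
        for _ in range(50):
            hand_contact_event(hand, "dust", 10, 0.5, 0.2)
        assert hand.dust <= 5.0 + 1e-12

    def test_hand_to_mouth_ingestion_and_depletion(self):
        hand = HandState(dust=5.0)
        hand, ing = hand_to_mouth_event(hand, 0.10, 100, 0.5)
        assert ing["dust"] == pytest.approx(25.0)
        assert hand.dust == pytest.approx(5.0 * 0.95)

    def test_zero_loading_ingests_nothing(self):
        _, ing = hand_to_mouth_event(HandState(), 0.10, 100, 0.5)
        assert ing["dust"] == 0 and ing["soil"] == 0

    def test_full_mouthing_removes_everything_once(self):
        hand = HandState(dust=5.0)
        hand, ing1 = hand_to_mouth_event(hand, 1.0, 100, 1.0)
        hand, ing2 = hand_to_mouth_event(hand, 1.0, 100, 1.0)
        assert ing1["dust"] == pytest.approx(500.0)
        assert ing2["dust"] == 0.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(load=loading, hmf=frac, sal=frac, area=st.floats(1, 500))
    def test_ingested_never_exceeds_mass_on_mouthed_area(self, load, hmf, sal, area):
        """Conservation: one mouthing cannot ingest more than the mass
        present on the contacted fraction of the hand."""
        hand = HandState(dust=load, soil=load / 2)
        before_d, before_s = hand.dust * area * hmf, hand.soil * area * hmf
        _, ing = hand_to_mouth_event(hand, hmf, area, sal)
        assert ing["dust"] <= before_d * (1 + 1e-12)
        assert ing["soil"] <= before_s * (1 + 1e-12)
        assert hand.dust >= 0 and hand.soil >= 0

    def test_removal_events(self):
        hand = removal_event(HandState(dust=10, soil=4), "handwash", 0.9, 1.0)
        assert hand.dust == pytest.approx(1.0)
        hand = removal_event(hand, "bath", 0.9, 1.0)
        assert hand.dust == 0.0 and hand.soil == 0.0
        hand = removal_event(HandState(dust=7), "handwash", 0.0, 0.0)
        assert hand.dust == 7.0


class TestObjectToMouth:
    def test_printed_chain_with_pacifier_adjustment(self):
        raw = object_to_mouth_event(10, 10, 0.5, 0.5)
        assert raw == pytest.approx(25.0)
        adj = object_to_mouth_event(10, 10, 0.5, 0.5, pacifier_adjustment=True)
        assert adj == pytest.approx(24.0)

    def test_zero_area_zero_exposure(self):
        assert object_to_mouth_event(10, 0, 0.5, 0.5) == 0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(load=loading, area=st.floats(0, 50), tr=frac, sal=frac)
    def test_object_ingestion_bounded_by_available_mass(self, load, area, tr, sal):
        assert object_to_mouth_event(load, area, tr, sal) <= load * area + 1e-9


class TestSimulatedDay:
    def test_all_point_day_matches_printed_equation_chain(self, point_cfg, hour_diary):
        """One indoor awake hour with every input at its analytic point:
        the simulated pacifier dust equals the closed-form 0.0890625 mg."""
        streams = PersonStreams(1, "6m-<1y", 0)
        person = draw_person_params("6m-<1y", point_cfg, streams)
        led = simulate_person_day(hour_diary, person,
                                  streams.engine("spring", "weekday"),
                                  var_rng=streams.var)
        assert led.daily_mg()[("pacifier", "dust")] == pytest.approx(
            0.0890625, rel=1e-12)
        assert led.medium_mg("soil") == 0.0

    def test_degenerate_day_is_bit_identical_across_seeds(self, point_cfg, hour_diary):
        """With all distributions at points and probabilities at 0/1, the
        Bernoulli/Poisson draws cannot matter (frequencies are zero)."""
        results = []
        for seed in (1, 2):
            streams = PersonStreams(seed, "6m-<1y", 0)
            person = draw_person_params("6m-<1y", point_cfg, streams)
            led = simulate_person_day(hour_diary, person,
                                      streams.engine("spring", "weekday"),
                                      var_rng=streams.var)
            results.append(led.daily_mg())
        assert results[0] == results[1]

    def test_newborn_ingests_no_soil_ever(self, cfg):
        from soildust.diary import generate_diary
        from soildust.rng import substream
        for i in range(10):
            streams = PersonStreams(7, "0-<1m", i)
            person = draw_person_params("0-<1m", cfg, streams)
            d = generate_diary("0-<1m", "summer", "weekend", cfg.diary,
                               substream(7, "nb", i))
            led = simulate_person_day(d, person, streams.engine("summer", "weekend"),
                                      var_rng=streams.var)
            assert led.medium_mg("soil") == 0.0

    def test_sleep_only_day_has_no_ingestion(self, point_cfg):
        from soildust.diary import Diary, DiaryEvent
        events = [DiaryEvent(t, 60, "indoor", "sleep") for t in range(0, 1440, 60)]
        d = Diary(events, "6m-<1y", "winter", "weekday")
        streams = PersonStreams(1, "6m-<1y", 0)
        person = draw_person_params("6m-<1y", point_cfg, streams)
        led = simulate_person_day(d, person, streams.engine("winter", "weekday"))
        assert led.total_mg() == 0.0

    def test_washing_one_annihilates_pacifier_ingestion(self, point_cfg, hour_diary):
        from soildust.analytic import analytic_config
        cfg = analytic_config({"pacifier_washing": 1.0})
        streams = PersonStreams(1, "6m-<1y", 0)
        person = draw_person_params("6m-<1y", cfg, streams)
        led = simulate_person_day(hour_diary, person,
                                  streams.engine("spring", "weekday"),
                                  var_rng=streams.var)
        assert led.daily_mg()[("pacifier", "dust")] == 0.0

    def test_blanket_with_unit_factor_equals_no_blanket(self, hour_diary):
        """F_blanket = 1 makes blanket use a no-op: identical ledgers."""
        from soildust.analytic import analytic_config
        always = analytic_config({"p_blanket": 1.0, "f_blanket": 1.0})
        never = analytic_config({"p_blanket": 0.0, "f_blanket": 1.0})
        out = []
        for cfg in (always, never):
            streams = PersonStreams(3, "6m-<1y", 0)
            person = draw_person_params("6m-<1y", cfg, streams)
            led = simulate_person_day(hour_diary, person,
                                      streams.engine("spring", "weekday"),
                                      var_rng=streams.var)
            out.append(led.daily_mg())
        assert out[0] == out[1]

    def test_ingestion_monotone_in_surface_loading(self, hour_diary):
        from soildust.analytic import analytic_config
        totals = []
        for load in (5.0, 10.0, 20.0):
            cfg = analytic_config({"dust_home_soft": load, "dust_home_hard": load,
                                   "dust_object": load,
                                   "hand_mouth_freq": 10.0})
            streams = PersonStreams(11, "6m-<1y", 0)
            person = draw_person_params("6m-<1y", cfg, streams)
            led = simulate_person_day(hour_diary, person,
                                      streams.engine("spring", "weekday"),
                                      var_rng=streams.var)
            totals.append(led.total_mg())
        assert totals[0] < totals[1] < totals[2]

    def test_event_records_match_totals(self, cfg, hour_diary):
        streams = PersonStreams(5, "6m-<1y", 4)
        person = draw_person_params("6m-<1y", cfg, streams)
        led = simulate_person_day(hour_diary, person,
                                  streams.engine("spring", "weekday"),
                                  var_rng=streams.var, record_events=True)
        by_key = {}
        for e in led.events:
            by_key[(e.pathway, e.medium)] = by_key.get((e.pathway, e.medium), 0.0) \
                + e.amount_ug
        for k, v in by_key.items():
            assert v == pytest.approx(led.totals_ug[k])
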