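"""Event taxonomy, support constraints, and state transitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lekrem.events import (
    Actor,
    Category,
    Event,
    EventHistory,
    EventKind,
    EventType,
    LekState,
    Roster,
    RosterError,
    SupportViolation,
    apply_event,
    enumerate_event_types,
    support_set,
    validate_history,
)

from conftest import ev, make_state, toy_fight


class TestEnumeration:
    def test_full_taxonomy_30_actors(self, roster30):
        types = enumerate_event_types(roster30)
        assert len(types) == 1115
        assert sum(1 for t in types if t.kind is EventKind.ATTACK) == 870
        assert sum(1 for t in types if t.kind.is_response) == 90
        assert sum(1 for t in types if t.kind.is_global) == 5

    def test_two_actor_roster(self):
        # n(n-1) + 8n + 5 at n=2: 2 attacks, 6 responses, 10 per-actor, 5 global
        r = Roster([Actor("A"), Actor("X", Category.X_BULK)])
        assert len(enumerate_event_types(r)) == 23

    def test_six_male_experiment_roster_without_bulk(self):
        r = Roster([Actor(f"M{i}") for i in range(6)], require_bulk=False)
        types = enumerate_event_types(r)
        assert len(types) == 83
        assert sum(1 for t in types if t.kind is EventKind.ATTACK) == 30
        assert sum(1 for t in types if t.kind.is_response) == 18

    @settings(deadline=None, max_examples=20)
    @given(n=st.integers(min_value=2, max_value=40))
    def test_closed_form_count(self, n):
        actors = [Actor(f"M{i}") for i in range(n - 1)]
        actors.append(Actor("X", Category.X_BULK))
        r = Roster(actors)
        assert len(enumerate_event_types(r)) == n * (n - 1) + 8 * n + 5

    def test_roster_errors(self):
        with pytest.raises(RosterError):
            Roster([Actor("A"), Actor("A"), Actor("X", Category.X_BULK)])
        with pytest.raises(RosterError):
            Roster([Actor("A"), Actor("B")])  # bulk required by default
        with pytest.raises(RosterError):
            Roster([Actor("X1", Category.X_BULK), Actor("X2", Category.X_BULK)])


class TestSupportSet:
    def test_no_solicit_without_females(self, roster4):
        s = make_state(roster4, females=False)
        assert not any(t.kind is EventKind.SOLICIT for t in support_set(s))
        s.females_present = True
        assert any(t.kind is EventKind.SOLICIT for t in support_set(s))

    def test_fighting_pair_unavailable_others_act(self, roster4):
        s = make_state(roster4, females=True)
        for e in toy_fight(100.0, "A", "B",
                           EventKind.RESPONSE_SHORT_FIGHT)[:2]:
            apply_event(s, e)
        sup = support_set(s)
        # engaged males neither attack, receive, solicit, nor depart
        assert not any(t.sender in ("A", "B") or t.receiver in ("A", "B")
                       for t in sup if t.kind is EventKind.ATTACK)
        assert EventType(EventKind.DISENGAGE, "A") in sup
        assert EventType(EventKind.DISENGAGE, "B") in sup
        assert EventType(EventKind.SOLICIT, "C") in sup
        assert EventType(EventKind.SOLICIT, "A") not in sup
        # unengaged males still fight each other
        assert EventType(EventKind.ATTACK, "C", "X") in sup

    def test_only_attacker_disengages_chase(self, roster4):
        s = make_state(roster4)
        apply_event(s, ev(EventKind.ATTACK, 10.0, 1, "A", "B"))
        apply_event(s, ev(EventKind.RESPONSE_CHASE, 10.0, 1, "B"))
        sup = support_set(s)
        assert EventType(EventKind.DISENGAGE, "A") in sup
        assert EventType(EventKind.DISENGAGE, "B") not in sup

    def test_pending_attack_collapses_to_three_responses(self, roster4):
        s = make_state(roster4)
        apply_event(s, ev(EventKind.ATTACK, 5.0, 1, "C", "A"))
        sup = support_set(s)
        assert len(sup) == 3
        assert all(t.kind.is_response and t.sender == "A" for t in sup)

    def test_attack_on_copulating_male_supported(self, roster4):
        s = make_state(roster4, females=True)
        apply_event(s, ev(EventKind.SOLICIT, 50.0, 1, "A"))
        sup = support_set(s)
        assert EventType(EventKind.ATTACK, "B", "A") in sup  # interruption
        assert EventType(EventKind.ATTACK, "A", "B") not in sup
        assert EventType(EventKind.COPULATION_END, "A") in sup
        assert EventType(EventKind.DEPART, "A") not in sup

    def test_bulk_actor_fights_while_engaged(self, roster4):
        s = make_state(roster4)
        apply_event(s, ev(EventKind.ATTACK, 10.0, 1, "X", "A"))
        apply_event(s, ev(EventKind.RESPONSE_FACE_OFF, 10.0, 1, "A"))
        sup = support_set(s)
        # X may open a second fight with C; A is locked
        assert EventType(EventKind.ATTACK, "X", "C") in sup
        assert EventType(EventKind.ATTACK, "C", "X") in sup
        assert EventType(EventKind.ATTACK, "C", "A") not in sup

    def test_absent_males_do_nothing(self, roster4):
        s = make_state(roster4, present=["A", "B"])
        sup = support_set(s)
        actors = {t.sender for t in sup} | {t.receiver for t in sup}
        assert "C" not in actors and "X" not in actors


class TestTransitions:
    def test_attack_sets_pending_response(self, roster4):
        s = make_state(roster4)
        apply_event(s, ev(EventKind.ATTACK, 10.0, 1, "A", "B"))
        assert s.awaiting_response == (s.idx("A"), s.idx("B"), 10.0)

    def test_interruption_supplants_copulation(self, roster4):
        s = make_state(roster4, females=True)
        apply_event(s, ev(EventKind.SOLICIT, 50.0, 1, "A"))
        apply_event(s, ev(EventKind.ATTACK, 55.0, 1, "C", "A"))
        assert not s.copulation_registry
        assert s.awaiting_response is not None
        c = s.counters
        assert c.gen[("interruption_perpetrated", "today", False)][s.idx("C")] == 1
        assert c.gen[("copulation_interrupted", "today", False)][s.idx("A")] == 1
        assert c.gen[("copulation", "today", False)][s.idx("A")] == 0

    def test_disengager_wins_partner_loses(self, roster4):
        s = make_state(roster4)
        for e in toy_fight(100.0, "A", "B", EventKind.RESPONSE_FACE_OFF):
            apply_event(s, e)
        c = s.counters
        i, j = s.idx("A"), s.idx("B")
        assert c.gen[("receive_win", "today", False)][j] == 1
        assert c.gen[("attack_lose", "today", False)][i] == 1
        assert not s.fight_registry
        assert s.available(i) and s.available(j)

    def test_chase_loss_recorded_for_receiver(self, roster4):
        s = make_state(roster4)
        apply_event(s, ev(EventKind.ATTACK, 10.0, 1, "A", "B"))
        apply_event(s, ev(EventKind.RESPONSE_CHASE, 10.0, 1, "B"))
        apply_event(s, ev(EventKind.DISENGAGE, 30.0, 1, "A"))
        c = s.counters
        assert c.gen[("attack_win", "today", False)][s.idx("A")] == 1
        assert c.gen[("lose_chase", "today", False)][s.idx("B")] == 1
        assert c.gen[("receive_lose", "today", False)][s.idx("B")] == 1

    def test_disturbance_flushes_everyone(self, roster4):
        s = make_state(roster4, females=True)
        for e in toy_fight(100.0, "A", "B", EventKind.RESPONSE_SHORT_FIGHT)[:2]:
            apply_event(s, e)
        apply_event(s, ev(EventKind.DISTURBANCE, 200.0))
        assert not s.fight_registry and not s.present.any()
        assert s.last_disturbance == 200.0

    def test_day_roll_moves_today_to_yesterday(self, roster4):
        s = make_state(roster4)
        for e in toy_fight(100.0, "A", "B"):
            apply_event(s, e)
        i = s.idx("B")
        s.start_day(2, consecutive=True)
        c = s.counters
        assert c.gen[("receive_win", "yesterday", False)][i] == 1
        assert c.gen[("receive_win", "today", False)][i] == 0
        assert c.gen[("receive_win", "cumulative", False)][i] == 1
        # a day with no observed predecessor starts yesterday from zero
        s.start_day(4, consecutive=False)
        assert c.gen[("receive_win", "yesterday", False)][i] == 0
        assert c.gen[("receive_win", "cumulative", False)][i] == 1

    def test_unsupported_event_names_constraint(self, roster4):
        s = make_state(roster4, females=False)
        with pytest.raises(SupportViolation, match="females"):
            apply_event(s, ev(EventKind.SOLICIT, 10.0, 1, "A"))


class TestValidateHistory:
    def _with_arrivals(self, roster, events, females=True):
        pre = [ev(EventKind.ARRIVE, 0.0, 1, a.id) for a in roster]
        if females:
            pre.append(ev(EventKind.FEMALE_ENTER, 1.0))
        return EventHistory(pre + events)

    def test_toy_fight_clean(self, roster4):
        h = self._with_arrivals(roster4, toy_fight(100.0, "A", "B"))
        rep = validate_history(h, roster4)
        assert rep.ok and rep.counts["attack"] == 1

    def test_solicit_without_females_flagged(self, roster4):
        h = self._with_arrivals(roster4, [ev(EventKind.SOLICIT, 10.0, 1, "A")],
                                females=False)
        rep = validate_history(h, roster4)
        assert not rep.ok
        assert "females" in rep.first_violation[2]

    def test_decreasing_times_flagged(self, roster4):
        h = self._with_arrivals(
            roster4, [ev(EventKind.CLOCK, 900.0), ev(EventKind.CLOCK, 400.0)])
        rep = validate_history(h, roster4)
        assert not rep.ok and "decrease" in rep.first_violation[2]


class TestConservation:
    """Every opened cycle closes exactly once with one win and one loss."""

    def test_random_walks_conserve_outcomes(self, roster4):
        rng = np.random.default_rng(7)
        for _ in range(25):
            s = make_state(roster4, females=True)
            opened = closed = 0
            t = 0.0
            for _step in range(200):
                sup = support_set(s)
                if not sup:
                    break
                et = sup[rng.integers(len(sup))]
                if et.kind is EventKind.ATTACK:
                    opened += 1
                if et.kind is EventKind.DISENGAGE:
                    closed += 1
                t += 1.0
                apply_event(s, Event(et, t, 1))
            c = s.counters
            wins = (c.gen[("attack_win", "cumulative", False)].sum()
                    + c.gen[("receive_win", "cumulative", False)].sum())
            losses = (c.gen[("attack_lose", "cumulative", False)].sum()
                      + c.gen[("receive_lose", "cumulative", False)].sum())
            assert wins == losses == closed
            assert opened - closed == len(s.fight_registry) + (
                1 if s.awaiting_response else 0)

    def test_no_double_entry_after_dyadic_event(self, roster4):
        s = make_state(roster4)
        atk = ev(EventKind.ATTACK, 10.0, 1, "A", "B")
        apply_event(s, atk)
        apply_event(s, ev(EventKind.RESPONSE_SHORT_FIGHT, 10.0, 1, "B"))
        assert atk.type not in support_set(s)
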