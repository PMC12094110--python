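import numpy as np
import pytest

from lekrem.events import (
    Actor,
    Category,
    Event,
    EventHistory,
    EventKind,
    EventType,
    LekState,
    Roster,
    apply_event,
)


@pytest.fixture
def roster30():
    """29 named males plus the X-bulk actor."""
    actors = [Actor(f"M{i:02d}", Category.IDENTIFIED) for i in range(1, 30)]
    actors.append(Actor("X", Category.X_BULK))
    return Roster(actors)


@pytest.fixture
def roster4():
    """Three named males plus bulk, everyone present on day 1, spaced 10 m."""
    actors = [
        Actor("A", Category.IDENTIFIED, frozenset({1, 2, 3}), {}, {1: (0.0, 0.0)}),
        Actor("B", Category.IDENTIFIED, frozenset({1, 2, 3}), {}, {1: (10.0, 0.0)}),
        Actor("C", Category.IDENTIFIED, frozenset({1, 2, 3}), {}, {1: (0.0, 10.0)}),
        Actor("X", Category.X_BULK, frozenset({1, 2, 3}), {}, {1: (30.0, 30.0)}),
    ]
    return Roster(actors)


def make_state(roster, day=1, females=False, present=None):
    s = LekState(roster)
    s.start_day(day, False)
    if present is None:
        s.present[:] = True
    else:
        for a in present:
            s.present[s.idx(a)] = True
    s.females_present = females
    return s


@pytest.fixture
def state4(roster4):
    return make_state(roster4, females=True)


def ev(kind, t, day=1, sender=None, receiver=None):
    return Event(EventType(kind, sender, receiver), t, day)


def toy_fight(t0=100.0, a="A", b="B", response=EventKind.RESPONSE_FACE_OFF,
              dt=10.0, day=1):
    """attack -> instantaneous response -> disengage-by-b sequence."""
    return [
        ev(EventKind.ATTACK, t0, day, a, b),
        ev(response, t0, day, b),
        ev(EventKind.DISENGAGE, t0 + dt, day, b),
    ]
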