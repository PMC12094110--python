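"""Event taxonomy and the lek-state machine.

A lek is modelled as a continuous-time system whose state changes only at
events.  Endogenous events (attacks, fight responses, disengagements,
solicitations, copulation ends, departures) carry modelled hazards; exogenous
events (arrivals, female entry/exit, clock ticks, disturbances, day ends) are
scheduled inputs that nevertheless update the state.

The central bookkeeping object is :class:`LekState`: who is present, which
pairs are locked in fights, who is copulating, and running tallies of fight
outcomes at several timescales.  :func:`support_set` enforces the hard
constraints that give impossible events zero hazard, and :func:`apply_event`
is the deterministic transition function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Optional

import numpy as np

__all__ = [
    "Category",
    "EventKind",
    "Actor",
    "Roster",
    "EventType",
    "Event",
    "EventHistory",
    "LekState",
    "RosterError",
    "StateError",
    "SupportViolation",
    "enumerate_event_types",
    "support_set",
    "apply_event",
    "validate_history",
    "ValidationReport",
    "COUNT_PATTERNS",
    "WINDOWS",
]

NEG_INF = float("-inf")


class RosterError(ValueError):
    """Raised for malformed actor rosters."""


class StateError(ValueError):
    """Raised when a LekState is internally inconsistent."""


class SupportViolation(ValueError):
    """An endogenous event was applied outside the support set."""

    def __init__(self, message: str, constraint: str = ""):
        super().__init__(message)
        self.constraint = constraint


class Category(str, Enum):
    IDENTIFIED = "identified"
    U = "U"
    X_BULK = "X"


class EventKind(str, Enum):
    ATTACK = "attack"
    RESPONSE_FACE_OFF = "response_face_off"
    RESPONSE_SHORT_FIGHT = "response_short_fight"
    RESPONSE_CHASE = "response_chase"
    DISENGAGE = "disengage"
    SOLICIT = "solicit"
    COPULATION_END = "copulation_end"
    DEPART = "depart"
    ARRIVE = "arrive"
    FEMALE_ENTER = "female_enter"
    FEMALE_EXIT = "female_exit"
    CLOCK = "clock"
    DISTURBANCE = "disturbance"
    DAY_END = "day_end"

    @property
    def is_response(self) -> bool:
        return self in _RESPONSES

    @property
    def is_endogenous(self) -> bool:
        return self in _ENDOGENOUS

    @property
    def is_global(self) -> bool:
        return self in _GLOBAL

    @property
    def is_dyadic(self) -> bool:
        return self is EventKind.ATTACK


_RESPONSES = frozenset(
    {EventKind.RESPONSE_FACE_OFF, EventKind.RESPONSE_SHORT_FIGHT, EventKind.RESPONSE_CHASE}
)
# Departures are endogenous (lek events influence them); arrivals are not.
_ENDOGENOUS = frozenset(
    {
        EventKind.ATTACK,
        EventKind.RESPONSE_FACE_OFF,
        EventKind.RESPONSE_SHORT_FIGHT,
        EventKind.RESPONSE_CHASE,
        EventKind.DISENGAGE,
        EventKind.SOLICIT,
        EventKind.COPULATION_END,
        EventKind.DEPART,
    }
)
_GLOBAL = frozenset(
    {
        EventKind.FEMALE_ENTER,
        EventKind.FEMALE_EXIT,
        EventKind.CLOCK,
        EventKind.DISTURBANCE,
        EventKind.DAY_END,
    }
)
# Per-actor, non-dyadic kinds (the acting male is stored in ``sender``).
ACTOR_KINDS = (
    EventKind.RESPONSE_FACE_OFF,
    EventKind.RESPONSE_SHORT_FIGHT,
    EventKind.RESPONSE_CHASE,
    EventKind.DISENGAGE,
    EventKind.SOLICIT,
    EventKind.COPULATION_END,
    EventKind.DEPART,
    EventKind.ARRIVE,
)
GLOBAL_KINDS = (
    EventKind.FEMALE_ENTER,
    EventKind.FEMALE_EXIT,
    EventKind.CLOCK,
    EventKind.DISTURBANCE,
    EventKind.DAY_END,
)

FIGHT_KINDS = {
    EventKind.RESPONSE_FACE_OFF: "face_off",
    EventKind.RESPONSE_SHORT_FIGHT: "short_fight",
    EventKind.RESPONSE_CHASE: "chase",
}


@dataclass(frozen=True)
class Actor:
    """A male on the lek.

    ``centroids`` maps day -> (x, y) in metres from the stake-grid origin.
    ``present_days`` is the set of days the male appears (used by scaffolds);
    territory-holder status on a day follows the two-consecutive-previous-days
    rule unless given explicitly.
    """

    id: str
    category: Category = Category.IDENTIFIED
    present_days: frozenset = frozenset()
    territory_holder_by_day: dict = field(default_factory=dict)
    centroids: dict = field(default_factory=dict)
    mean_absence_s: float = 1800.0

    def is_territory_holder(self, day: int) -> bool:
        if day in self.territory_holder_by_day:
            return bool(self.territory_holder_by_day[day])
        return (day - 1) in self.present_days and (day - 2) in self.present_days

    def centroid(self, day: int):
        if day in self.centroids:
            return self.centroids[day]
        if self.centroids:
            # fall back to the nearest recorded day (territories are stable)
            k = min(self.centroids, key=lambda d: abs(d - day))
            return self.centroids[k]
        return (0.0, 0.0)


class Roster:
    """Ordered collection of actors with id -> index lookup.

    Exactly one X-bulk actor is required unless ``require_bulk=False`` (the
    simplified experiment configuration excludes juveniles/transients).
    """

    def __init__(self, actors: Iterable[Actor], require_bulk: bool = True):
        self.actors = list(actors)
        ids = [a.id for a in self.actors]
        if len(ids) != len(set(ids)):
            raise RosterError("duplicate actor ids in roster")
        if len(self.actors) < 2:
            raise RosterError("roster needs at least 2 actors")
        bulk = [a for a in self.actors if a.category is Category.X_BULK]
        if len(bulk) > 1:
            raise RosterError("at most one X-bulk actor allowed")
        if require_bulk and not bulk:
            raise RosterError("roster requires exactly one X-bulk actor")
        self.index = {a.id: i for i, a in enumerate(self.actors)}
        self.ids = ids
        self.bulk_id: Optional[str] = bulk[0].id if bulk else None
        self.bulk_idx: Optional[int] = self.index[bulk[0].id] if bulk else None

    def __len__(self) -> int:
        return len(self.actors)

    def __iter__(self):
        return iter(self.actors)

    def __getitem__(self, actor_id: str) -> Actor:
        return self.actors[self.index[actor_id]]

    def distance(self, a: str, b: str, day: int) -> float:
        xa, ya = self[a].centroid(day)
        xb, yb = self[b].centroid(day)
        return math.hypot(xa - xb, ya - yb)


class EventType(NamedTuple):
    """A categorised event label: (kind, sender, receiver).

    For per-actor kinds the acting male is ``sender`` and ``receiver`` is
    None; global kinds carry neither.
    """

    kind: EventKind
    sender: Optional[str] = None
    receiver: Optional[str] = None

    def __str__(self) -> str:
        if self.kind is EventKind.ATTACK:
            return f"attack:{self.sender}->{self.receiver}"
        if self.sender is not None:
            return f"{self.kind.value}:{self.sender}"
        return self.kind.value


class Event(NamedTuple):
    type: EventType
    time: float  # seconds from session start, within day
    day: int


class EventHistory:
    """Ordered event sequence A_t; events sorted by (day, time, input order)."""

    def __init__(self, events: Iterable[Event] = ()):
        self.events = list(events)

    def append(self, event: Event) -> None:
        self.events.append(event)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventHistory) and self.events == other.events

    def days(self):
        return sorted({e.day for e in self.events})

    def counts_by_kind(self) -> dict:
        out: dict = {}
        for e in self.events:
            out[e.type.kind.value] = out.get(e.type.kind.value, 0) + 1
        return out


def enumerate_event_types(roster: Roster) -> list:
    """Full event-type taxonomy for a roster of n actors.

    n(n-1) dyadic attacks, 3n responses, n each of disengage / solicit /
    copulation-end / depart / arrive, plus 5 global kinds:
    n(n-1) + 8n + 5 types in total (1115 for n = 30).
    """
    types = []
    for s in roster.ids:
        for r in roster.ids:
            if s != r:
                types.append(EventType(EventKind.ATTACK, s, r))
    for kind in ACTOR_KINDS:
        for a in roster.ids:
            types.append(EventType(kind, a))
    for kind in GLOBAL_KINDS:
        types.append(EventType(kind))
    return types


# ---------------------------------------------------------------------------
# Counters
# ---------------------------------------------------------------------------

# Count-like fight/outcome patterns recorded per focal male (and per pair).
COUNT_PATTERNS = (
    "attack_win",
    "attack_lose",
    "receive_win",
    "receive_lose",
    "lose_chase",
    "interruption_perpetrated",
    "copulation",
    "copulation_interrupted",
)
WINDOWS = ("today", "yesterday", "cumulative")


class Counters:
    """Per-male and per-pair tallies over today / yesterday / cumulative
    windows, kept both unrestricted and restricted to female-present moments
    (the latter feed solicitation-channel statistics).  Also last-event times
    per pattern for recency statistics."""

    def __init__(self, n: int):
        self.n = n
        self.gen: dict = {}
        self.pair: dict = {}
        for p in COUNT_PATTERNS:
            for w in WINDOWS:
                for fp in (False, True):
                    self.gen[(p, w, fp)] = np.zeros(n)
                    self.pair[(p, w, fp)] = np.zeros((n, n))
        self.last: dict = {
            (p, fp): np.full(n, NEG_INF) for p in COUNT_PATTERNS for fp in (False, True)
        }

    def record(self, pattern: str, focal: int, partner: Optional[int], t: float,
               females_present: bool) -> None:
        variants = (False, True) if females_present else (False,)
        for fp in variants:
            for w in ("today", "cumulative"):
                self.gen[(pattern, w, fp)][focal] += 1.0
                if partner is not None:
                    self.pair[(pattern, w, fp)][focal, partner] += 1.0
            self.last[(pattern, fp)][focal] = t

    def roll_day(self, consecutive: bool) -> None:
        for p in COUNT_PATTERNS:
            for fp in (False, True):
                g_t = self.gen[(p, "today", fp)]
                self.gen[(p, "yesterday", fp)][:] = g_t if consecutive else 0.0
                g_t[:] = 0.0
                p_t = self.pair[(p, "today", fp)]
                self.pair[(p, "yesterday", fp)][:] = p_t if consecutive else 0.0
                p_t[:] = 0.0
        # event times are per-session seconds: recency does not span days
        for arr in self.last.values():
            arr[:] = NEG_INF

    def copy(self) -> "Counters":
        c = Counters.__new__(Counters)
        c.n = self.n
        c.gen = {k: v.copy() for k, v in self.gen.items()}
        c.pair = {k: v.copy() for k, v in self.pair.items()}
        c.last = {k: v.copy() for k, v in self.last.items()}
        return c


@dataclass
class Fight:
    attacker: int
    receiver: int
    kind: str  # face_off | short_fight | chase
    start: float


@dataclass
class LekState:
    """Piecewise-constant system state between events."""

    roster: Roster
    day: int = 0
    time: float = 0.0
    present: np.ndarray = None  # bool (n,)
    females_present: bool = False
    fight_registry: dict = field(default_factory=dict)  # (att_idx, rec_idx) -> Fight
    copulation_registry: dict = field(default_factory=dict)  # male idx -> start time
    awaiting_response: Optional[tuple] = None  # (att_idx, rec_idx, time)
    counters: Counters = None
    clock_time: float = 0.0
    last_disturbance: float = NEG_INF

    def __post_init__(self):
        n = len(self.roster)
        if self.present is None:
            self.present = np.zeros(n, dtype=bool)
        if self.counters is None:
            self.counters = Counters(n)

    # -- identity helpers ---------------------------------------------------
    def idx(self, actor_id: str) -> int:
        return self.roster.index[actor_id]

    def is_bulk(self, i: int) -> bool:
        return self.roster.bulk_idx == i

    def in_fight(self, i: int) -> bool:
        return any(i in pair for pair in self.fight_registry)

    def is_copulating(self, i: int) -> bool:
        return i in self.copulation_registry

    def available(self, i: int) -> bool:
        """Free to start/receive attacks, solicit, or depart.  The bulk actor
        may hold several fights at once, so fight engagement never blocks it."""
        if not self.present[i]:
            return False
        if self.is_copulating(i):
            return False
        if self.is_bulk(i):
            return True
        return not self.in_fight(i)

    def fights_of(self, i: int):
        return [f for pair, f in sorted(self.fight_registry.items()) if i in pair]

    def check_consistent(self) -> None:
        for (a, r) in self.fight_registry:
            if not (self.present[a] and self.present[r]):
                raise StateError("fighting male not present")
        for m in self.copulation_registry:
            if not self.present[m]:
                raise StateError("copulating male not present")
            if self.in_fight(m) and not self.is_bulk(m):
                raise StateError("male both fighting and copulating")
        if self.awaiting_response is not None:
            a, r, _ = self.awaiting_response
            if not (self.present[a] and self.present[r]):
                raise StateError("pending attack involves absent male")

    def start_day(self, day: int, consecutive: bool) -> None:
        """Roll to a new session.  Today-counters move to yesterday (zeroed
        instead when the previous calendar day was not observed)."""
        self.counters.roll_day(consecutive)
        self.day = day
        self.time = 0.0
        self.clock_time = 0.0
        self.present[:] = False
        self.females_present = False
        self.fight_registry.clear()
        self.copulation_registry.clear()
        self.awaiting_response = None
        self.last_disturbance = NEG_INF

    def copy(self) -> "LekState":
        s = LekState(self.roster, self.day, self.time, self.present.copy(),
                     self.females_present, dict(self.fight_registry),
                     dict(self.copulation_registry), self.awaiting_response,
                     self.counters.copy(), self.clock_time, self.last_disturbance)
        return s


# ---------------------------------------------------------------------------
# Support set
# ---------------------------------------------------------------------------

def support_set(state: LekState, kinds: Optional[frozenset] = None) -> list:
    """Endogenous event types possible right now, A(A_t).

    Constraints: only present males interact or depart; no solicitations
    without females; males locked in a cycle neither attack, receive, solicit
    nor depart — except that an attack on a *copulating* male is supported
    (a copulation interruption) and the X-bulk actor may open new fights while
    engaged.  Only the attacker may disengage from a chase.  Immediately after
    an attack the support set collapses to the three response types of the
    attacked male.

    ``kinds`` optionally restricts the result to a subset of endogenous kinds
    (a model's active channels); the response collapse ignores it.
    """
    r = state.roster
    out: list = []
    if state.awaiting_response is not None:
        _, rec, _ = state.awaiting_response
        rid = r.ids[rec]
        return [EventType(k, rid) for k in
                (EventKind.RESPONSE_FACE_OFF, EventKind.RESPONSE_SHORT_FIGHT,
                 EventKind.RESPONSE_CHASE)]

    def want(kind: EventKind) -> bool:
        return kinds is None or kind in kinds

    n = len(r)
    avail = [state.available(i) for i in range(n)]
    if want(EventKind.ATTACK):
        for s in range(n):
            if not avail[s]:
                continue
            sid = r.ids[s]
            for t in range(n):
                if t == s or not state.present[t]:
                    continue
                if avail[t] or state.is_copulating(t):
                    out.append(EventType(EventKind.ATTACK, sid, r.ids[t]))
    if want(EventKind.DISENGAGE):
        can = set()
        for (a, rec), f in state.fight_registry.items():
            can.add(a)  # attacker may always disengage
            if f.kind != "chase":
                can.add(rec)
        for i in sorted(can):
            out.append(EventType(EventKind.DISENGAGE, r.ids[i]))
    if want(EventKind.SOLICIT) and state.females_present:
        for i in range(n):
            if avail[i]:
                out.append(EventType(EventKind.SOLICIT, r.ids[i]))
    if want(EventKind.COPULATION_END):
        for i in sorted(state.copulation_registry):
            out.append(EventType(EventKind.COPULATION_END, r.ids[i]))
    if want(EventKind.DEPART):
        for i in range(n):
            if avail[i]:
                out.append(EventType(EventKind.DEPART, r.ids[i]))
    return out


# ---------------------------------------------------------------------------
# Transition function
# ---------------------------------------------------------------------------

def _close_fight(state: LekState, pair: tuple, disengager: int) -> None:
    """Record win/loss for a concluded fight and free the pair."""
    f = state.fight_registry.pop(pair)
    winner, loser = disengager, (pair[0] if pair[1] == disengager else pair[1])
    fp = state.females_present
    t = state.time
    if winner == f.attacker:
        state.counters.record("attack_win", winner, loser, t, fp)
        state.counters.record("receive_lose", loser, winner, t, fp)
        if f.kind == "chase":
            state.counters.record("lose_chase", loser, winner, t, fp)
    else:
        state.counters.record("receive_win", winner, loser, t, fp)
        state.counters.record("attack_lose", loser, winner, t, fp)


def apply_event(state: LekState, event: Event, check_support: bool = True) -> LekState:
    """Apply one event to the state (in place) and return the state.

    Endogenous events are checked against the support set unless
    ``check_support=False`` (the simulator samples from the support set, so it
    skips the re-check for speed).
    """
    et = event.type
    kind = et.kind
    state.time = event.time
    r = state.roster

    if kind.is_endogenous and check_support:
        if et not in support_set(state):
            constraint = _diagnose(state, et)
            raise SupportViolation(
                f"{et} at day {event.day} t={event.time:.2f} is not in the "
                f"support set: {constraint}",
                constraint=constraint,
            )

    if kind is EventKind.ATTACK:
        s, t = state.idx(et.sender), state.idx(et.receiver)
        if t in state.copulation_registry:
            # copulation interruption: supplants the copulation-end event
            state.copulation_registry.pop(t)
            state.counters.record("interruption_perpetrated", s, t, state.time,
                                  state.females_present)
            state.counters.record("copulation_interrupted", t, s, state.time,
                                  state.females_present)
        state.awaiting_response = (s, t, state.time)
    elif kind.is_response:
        m = state.idx(et.sender)
        if state.awaiting_response is None or state.awaiting_response[1] != m:
            raise SupportViolation(f"response by {et.sender} with no pending attack")
        a, rec, t0 = state.awaiting_response
        state.fight_registry[(a, rec)] = Fight(a, rec, FIGHT_KINDS[kind], state.time)
        state.awaiting_response = None
    elif kind is EventKind.DISENGAGE:
        m = state.idx(et.sender)
        for pair, f in sorted(state.fight_registry.items(), key=lambda kv: kv[1].start):
            if m in pair and (f.kind != "chase" or m == f.attacker):
                _close_fight(state, pair, m)
                break
        else:
            raise SupportViolation(f"disengage by {et.sender} outside any eligible fight")
    elif kind is EventKind.SOLICIT:
        m = state.idx(et.sender)
        state.copulation_registry[m] = state.time
    elif kind is EventKind.COPULATION_END:
        m = state.idx(et.sender)
        state.copulation_registry.pop(m)
        state.counters.record("copulation", m, None, state.time, state.females_present)
    elif kind is EventKind.DEPART:
        state.present[state.idx(et.sender)] = False
    elif kind is EventKind.ARRIVE:
        state.present[state.idx(et.sender)] = True
    elif kind is EventKind.FEMALE_ENTER:
        state.females_present = True
    elif kind is EventKind.FEMALE_EXIT:
        state.females_present = False
        # any open copulation is censored: no success, no interruption
        state.copulation_registry.clear()
    elif kind is EventKind.CLOCK:
        state.clock_time = state.time
    elif kind is EventKind.DISTURBANCE:
        # birds flush: all cycles cleared, everyone off the lek
        state.fight_registry.clear()
        state.copulation_registry.clear()
        state.awaiting_response = None
        state.present[:] = False
        state.last_disturbance = state.time
    elif kind is EventKind.DAY_END:
        state.fight_registry.clear()
        state.copulation_registry.clear()
        state.awaiting_response = None
        state.present[:] = False
    return state


def _diagnose(state: LekState, et: EventType) -> str:
    """Name the constraint an unsupported endogenous event breaches."""
    kind = et.kind
    if state.awaiting_response is not None and not kind.is_response:
        return "pending attack awaits a response (zero-duration window)"
    try:
        ids = [x for x in (et.sender, et.receiver) if x is not None]
        for a in ids:
            if not state.present[state.idx(a)]:
                return "(i) only present males may interact or depart"
    except KeyError:
        return "actor not on roster"
    if kind is EventKind.SOLICIT and not state.females_present:
        return "(ii) solicitations are impossible if females are absent"
    if kind in (EventKind.ATTACK, EventKind.SOLICIT, EventKind.DEPART):
        for a in ids:
            i = state.idx(a)
            if not state.available(i) and not (
                kind is EventKind.ATTACK and a == et.receiver and state.is_copulating(i)
            ):
                return "(iii) males in a cycle are unavailable"
    if kind is EventKind.DISENGAGE:
        return "only the attacker may disengage from a chase / no eligible fight"
    return "unsupported event"


# ---------------------------------------------------------------------------
# History validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    ok: bool
    first_violation: Optional[tuple] = None  # (index, Event, message)
    counts: dict = field(default_factory=dict)
    n_events: int = 0

    def __bool__(self) -> bool:
        return self.ok


def validate_history(events: EventHistory, roster: Roster,
                     day_gaps: Optional[set] = None) -> ValidationReport:
    """Replay a history through the state machine, reporting the first
    support/state violation (or a clean pass) plus per-kind totals.

    ``day_gaps`` lists days whose true previous calendar day was unobserved
    (their yesterday-counters start from zero).
    """
    state = LekState(roster)
    day_gaps = day_gaps or set()
    prev_day: Optional[int] = None
    prev_time = 0.0
    counts: dict = {}
    for i, ev in enumerate(events):
        if prev_day is None or ev.day != prev_day:
            if prev_day is not None and ev.day < prev_day:
                return ValidationReport(False, (i, ev, "days out of order"), counts, i)
            consecutive = prev_day is not None and ev.day == prev_day + 1 \
                and ev.day not in day_gaps
            state.start_day(ev.day, consecutive)
            prev_day, prev_time = ev.day, 0.0
        if ev.time < prev_time - 1e-9:
            return ValidationReport(False, (i, ev, "times decrease within a day"),
                                    counts, i)
        prev_time = ev.time
        try:
            apply_event(state, ev)
        except (SupportViolation, KeyError, StateError) as exc:
            return ValidationReport(False, (i, ev, str(exc)), counts, i)
        counts[ev.type.kind.value] = counts.get(ev.type.kind.value, 0) + 1
    return ValidationReport(True, None, counts, len(events))
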