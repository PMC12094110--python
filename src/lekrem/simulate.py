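"""Forward simulation of lek event streams, and treatment experiments.

Simulation follows the model's own law: in each piecewise-constant stretch,
the waiting time to the next endogenous event is exponential with mean
1/(total hazard of all supported candidates), and the event identity is a
categorical draw weighted by each candidate's share of the total hazard.
Scheduled exogenous events (arrivals, female entry/exit, clock ticks every
15 minutes, disturbances, day end) pre-empt any sampled endogenous event that
would land later than the schedule.  An attack is followed immediately by a
zero-duration response drawn from the competing-risks multinomial.  A
departing male's potential return is scheduled after an exponential delay
with his mean absence interval.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .events import (
    Event,
    EventHistory,
    EventKind,
    EventType,
    LekState,
    Roster,
    apply_event,
)
from .inference import (
    CompiledModel,
    ModelSpec,
    ParameterVector,
    align_theta,
    compile_model,
)

__all__ = [
    "DaySchedule",
    "Scaffold",
    "SimulationRun",
    "MaleMetrics",
    "ExperimentResult",
    "draw_next_event",
    "simulate_day",
    "simulate",
    "summarize",
    "run_experiment",
    "TREATMENTS",
]

CLOCK_PERIOD = 900.0  # 15-minute bookkeeping ticks


@dataclass
class DaySchedule:
    """Exogenous scaffold for one observation day."""

    day: int
    end_time: float
    arrivals: tuple = ()  # (actor_id, time) first arrivals
    female_windows: tuple = ()  # (enter, exit) pairs
    disturbances: tuple = ()  # times
    clock_period: float = CLOCK_PERIOD

    def __post_init__(self):
        for _, t in self.arrivals:
            if not 0 <= t <= self.end_time:
                raise ValueError(f"arrival outside day bounds: {t}")
        for t0, t1 in self.female_windows:
            if not (0 <= t0 < t1 <= self.end_time):
                raise ValueError(f"bad female window ({t0}, {t1})")

    def scheduled(self) -> list:
        """(time, priority, EventType) triples for the day's fixed events."""
        out = []
        for a, t in self.arrivals:
            out.append((t, 0, EventType(EventKind.ARRIVE, a)))
        for t0, t1 in self.female_windows:
            out.append((t0, 1, EventType(EventKind.FEMALE_ENTER)))
            out.append((t1, 1, EventType(EventKind.FEMALE_EXIT)))
        for t in self.disturbances:
            out.append((t, 2, EventType(EventKind.DISTURBANCE)))
        k = 1
        while k * self.clock_period <= self.end_time:
            out.append((k * self.clock_period, 3, EventType(EventKind.CLOCK)))
            k += 1
        out.append((self.end_time, 9, EventType(EventKind.DAY_END)))
        return out


@dataclass
class Scaffold:
    """Per-day exogenous schedules plus day-continuity structure."""

    days: tuple  # DaySchedule, in day order

    def __post_init__(self):
        object.__setattr__(self, "days", tuple(self.days))

    def day_gaps(self) -> set:
        """Days whose previous calendar day is not in the scaffold."""
        have = {d.day for d in self.days}
        return {d.day for d in self.days if d.day - 1 not in have}

    def __iter__(self):
        return iter(self.days)


# ---------------------------------------------------------------------------
# Event drawing
# ---------------------------------------------------------------------------

def draw_next_event(state: LekState, cm: CompiledModel, theta: np.ndarray,
                    rng: np.random.Generator,
                    schedule: Optional[list] = None) -> Optional[Event]:
    """Draw the next event (endogenous or scheduled exogenous) and apply it.

    ``schedule`` is a heap of (time, priority, seq, EventType).  Returns the
    applied Event, or None when nothing remains (no supported endogenous
    event and an empty schedule): the day terminates.
    """
    tv = theta.values if isinstance(theta, ParameterVector) else np.asarray(theta)
    if state.awaiting_response is not None:
        cands = cm.candidates(state)  # exactly the three response types
        eta = np.array([tv @ cm.design_row(state, c) for c in cands])
        eta -= eta.max()
        p = np.exp(eta)
        p /= p.sum()
        et = cands[rng.choice(len(cands), p=p)]
        ev = Event(et, state.time, state.day)
        apply_event(state, ev, check_support=False)
        return ev
    cands = cm.candidates(state)
    if cands:
        eta = np.clip(np.array([tv @ cm.design_row(state, c) for c in cands]),
                      -700.0, 60.0)
        haz = np.exp(eta)
        total = haz.sum()
        t_cand = state.time + rng.exponential(1.0 / total) if total > 0 else math.inf
    else:
        t_cand = math.inf
    if schedule and schedule[0][0] <= t_cand:
        t, _, _, et = heapq.heappop(schedule)
        ev = Event(et, max(t, state.time), state.day)
        apply_event(state, ev, check_support=False)
        return ev
    if not math.isfinite(t_cand):
        return None
    et = cands[rng.choice(len(cands), p=haz / total)]
    ev = Event(et, t_cand, state.day)
    apply_event(state, ev, check_support=False)
    return ev


def simulate_day(schedule: DaySchedule, cm: CompiledModel, theta,
                 state: LekState, rng: np.random.Generator,
                 consecutive: bool, allow_returns: bool = True) -> list:
    """Simulate one session day; mutates ``state`` (carrying counters over)
    and returns the day's events, ending with day_end."""
    state.start_day(schedule.day, consecutive)
    heap: list = []
    seq = 0
    for t, prio, et in schedule.scheduled():
        heapq.heappush(heap, (t, prio, seq, et))
        seq += 1
    events: list = []
    ids = state.roster.ids
    while True:
        present_before = [ids[i] for i in np.flatnonzero(state.present)]
        ev = draw_next_event(state, cm, theta, rng, heap)
        if ev is None:
            end = Event(EventType(EventKind.DAY_END), schedule.end_time, schedule.day)
            apply_event(state, end, check_support=False)
            events.append(end)
            break
        events.append(ev)
        kind = ev.type.kind
        if kind is EventKind.DAY_END:
            break
        if allow_returns and kind in (EventKind.DEPART, EventKind.DISTURBANCE):
            # schedule potential returns after exponential absence intervals
            flushed = ([ev.type.sender] if kind is EventKind.DEPART
                       else present_before)
            for aid in flushed:
                delay = rng.exponential(state.roster[aid].mean_absence_s)
                t_ret = ev.time + delay
                if t_ret < schedule.end_time:
                    heapq.heappush(heap, (t_ret, 0, seq,
                                          EventType(EventKind.ARRIVE, aid)))
                    seq += 1
    return events


@dataclass
class MaleMetrics:
    """Per-male summary of a simulated (or observed) event stream.

    Rate metrics are None when undefined (zero denominator) rather than NaN.
    """

    actor: str
    total_fights: int = 0
    wins: int = 0
    losses: int = 0
    solicitations: int = 0
    copulations: int = 0  # uninterrupted (successful) copulations
    interrupted: int = 0
    interruptions_caused: int = 0
    time_available_to_mate: float = 0.0  # s present, females present, out of cycle
    departures: int = 0

    @property
    def win_rate(self) -> Optional[float]:
        n = self.wins + self.losses
        return self.wins / n if n else None

    @property
    def interruption_rate(self) -> Optional[float]:
        n = self.copulations + self.interrupted
        return self.interrupted / n if n else None


@dataclass
class SimulationRun:
    events: EventHistory
    seed: Optional[int]
    roster: Roster
    scaffold: Optional[Scaffold] = None
    metrics: dict = field(default_factory=dict)  # actor id -> MaleMetrics


def summarize(events: EventHistory, roster: Roster) -> dict:
    """Recompute per-male metrics by replaying the event stream."""
    metrics = {a.id: MaleMetrics(a.id) for a in roster}
    state = LekState(roster)
    prev_day = None
    ids = roster.ids

    def accrue(t_to: float) -> None:
        dt = t_to - state.time
        if dt <= 0 or not state.females_present:
            return
        for i, aid in enumerate(ids):
            if state.present[i] and state.available(i):
                metrics[aid].time_available_to_mate += dt

    for ev in events:
        if prev_day is None or ev.day != prev_day:
            state.start_day(ev.day, prev_day is not None and ev.day == prev_day + 1)
            prev_day = ev.day
        accrue(ev.time)
        et = ev.type
        k = et.kind
        if k is EventKind.ATTACK:
            s, r = et.sender, et.receiver
            metrics[s].total_fights += 1
            metrics[r].total_fights += 1
            if state.is_copulating(state.idx(r)):
                metrics[s].interruptions_caused += 1
                metrics[r].interrupted += 1
        elif k is EventKind.DISENGAGE:
            # mirror apply_event's choice: earliest-started eligible fight
            m = state.idx(et.sender)
            for _, f in sorted(state.fight_registry.items(),
                               key=lambda kv: kv[1].start):
                if m in (f.attacker, f.receiver) and (f.kind != "chase"
                                                      or m == f.attacker):
                    loser = f.receiver if f.attacker == m else f.attacker
                    metrics[et.sender].wins += 1
                    metrics[ids[loser]].losses += 1
                    break
        elif k is EventKind.SOLICIT:
            metrics[et.sender].solicitations += 1
        elif k is EventKind.COPULATION_END:
            metrics[et.sender].copulations += 1
        elif k is EventKind.DEPART:
            metrics[et.sender].departures += 1
        apply_event(state, ev, check_support=False)
    return metrics


def simulate(scaffold: Scaffold, model: ModelSpec, theta, roster: Roster,
             seed: Optional[int] = None,
             rng: Optional[np.random.Generator] = None,
             allow_returns: bool = True,
             skip_days: int = 0) -> SimulationRun:
    """Simulate every day of a scaffold under theta.

    ``skip_days`` drops the first so many days from the returned history and
    metrics (burn-in) while still carrying their counters forward.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cm = compile_model(model, roster)
    theta = align_theta(cm, theta)
    state = LekState(roster)
    gaps = scaffold.day_gaps()
    all_events: list = []
    prev_day = None
    kept_from = None
    for i, sched in enumerate(scaffold):
        consecutive = prev_day is not None and sched.day == prev_day + 1 \
            and sched.day not in gaps
        evs = simulate_day(sched, cm, theta, state, rng, consecutive, allow_returns)
        if i == skip_days:
            kept_from = len(all_events)
        all_events.extend(evs)
        prev_day = sched.day
    kept = all_events[kept_from:] if kept_from is not None else []
    history = EventHistory(kept)
    run = SimulationRun(history, seed, roster, scaffold)
    run.metrics = summarize(history, roster)
    return run


# ---------------------------------------------------------------------------
# Treatment experiments
# ---------------------------------------------------------------------------

TREATMENTS = ("attack", "disengage", "both")
_METRICS = ("total_fights", "win_rate", "time_available_to_mate",
            "interruption_rate", "solicitations", "copulations")


@dataclass
class ExperimentResult:
    focal: str
    susceptibility: str
    n_reps: int
    replicates: "object"  # DataFrame: condition, rep, metric columns (focal male)
    z_scores: dict  # (condition, metric) -> z vs control
    min_solicitations: int = 4  # interruption-rate inclusion threshold


def _apply_treatment(theta: ParameterVector, focal: str, treatment: str,
                     sd_attack: float, sd_disengage: float) -> ParameterVector:
    """Raise the focal male's intrinsic log-hazard(s) by one s.d."""
    updates = {}
    if treatment in ("attack", "both"):
        k = f"attack_init:{focal}"
        updates[k] = theta[k] + sd_attack
    if treatment in ("disengage", "both"):
        k = f"disengage:{focal}"
        updates[k] = theta[k] + sd_disengage
    return theta.replace(**updates)


def run_experiment(scaffold: Scaffold, model: ModelSpec, theta: ParameterVector,
                   roster: Roster, focal: str,
                   treatments: Sequence[str] = TREATMENTS,
                   susceptibility: str = "average",
                   sd_attack: float = 0.5, sd_disengage: float = 0.5,
                   sd_receive: float = 0.5,
                   n_reps: int = 100, seed: int = 0,
                   burn_in_days: int = 1) -> ExperimentResult:
    """Replicated control-vs-treatment simulations for one focal male.

    Treatments raise the focal male's intrinsic attack and/or disengagement
    rate by one s.d. on the log-hazard scale; the high-susceptibility scenario
    additionally raises his intrinsic incoming-attack hazard.  Each replicate
    simulates the full scaffold (burn-in days discarded from metrics).
    z-scores compare treatment replicate means to the control replicate
    distribution; the interruption-rate metric excludes replicates with three
    or fewer solicitations.
    """
    import pandas as pd

    for t in treatments:
        if t not in TREATMENTS:
            raise ValueError(f"unknown treatment {t!r}; choose from {TREATMENTS}")
    if susceptibility not in ("average", "high"):
        raise ValueError(f"unknown susceptibility scenario {susceptibility!r}")
    base = theta
    if susceptibility == "high":
        k = f"attack_recv:{focal}"
        base = base.replace(**{k: base[k] + sd_receive})
    thetas = {"control": base}
    for t in treatments:
        thetas[t] = _apply_treatment(base, focal, t, sd_attack, sd_disengage)
    rows = []
    for cond, th in thetas.items():
        for rep in range(n_reps):
            run = simulate(scaffold, model, th, roster,
                           seed=None, rng=np.random.default_rng(seed + rep),
                           allow_returns=True, skip_days=burn_in_days)
            m = run.metrics[focal]
            rows.append({
                "condition": cond, "rep": rep,
                "total_fights": m.total_fights,
                "win_rate": m.win_rate,
                "time_available_to_mate": m.time_available_to_mate,
                "interruption_rate": m.interruption_rate,
                "solicitations": m.solicitations,
                "copulations": m.copulations,
            })
    df = pd.DataFrame(rows)
    ctrl = df[df.condition == "control"]
    z: dict = {}
    for cond in thetas:
        if cond == "control":
            continue
        trt = df[df.condition == cond]
        for metric in _METRICS:
            c, x = ctrl[metric], trt[metric]
            if metric == "interruption_rate":
                keep_c = ctrl["solicitations"] > 3
                keep_x = trt["solicitations"] > 3
                c, x = c[keep_c], x[keep_x]
            c, x = c.dropna(), x.dropna()
            sd = float(c.std(ddof=1)) if len(c) > 1 else float("nan")
            if not sd or math.isnan(sd) or len(x) == 0:
                z[(cond, metric)] = None
            else:
                z[(cond, metric)] = float((x.mean() - c.mean()) / sd)
    return ExperimentResult(focal, susceptibility, n_reps, df, z)
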