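"""Predictor statistics for event hazards.

Each hazard is exp(theta . u), where u is a vector of predictor statistics
evaluated for a *candidate* event given the current lek state.  A statistic is
described by a :class:`StatisticSpec`: a base pattern (what is counted or
measured), a scope (a male's general record vs his record with the specific
partner), a timescale window (cumulative / yesterday / so-far-today /
recency), and the response channel it applies to (which candidate-event kind
it loads on).

Recency statistics take the form 1/sqrt(seconds since the last qualifying
event); they refresh only at events — including the scheduled 15-minute clock
ticks — so hazards stay piecewise constant.

Context conditioning: interruption-channel statistics evaluate only when the
candidate attack's receiver is currently copulating, and solicitation-channel
statistics count only events that occurred while females were present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .events import NEG_INF, EventKind, EventType, LekState

__all__ = [
    "StatisticSpec",
    "CatalogError",
    "recency",
    "build_catalog",
    "evaluate",
    "spec_from_name",
    "COUNT_BASED",
    "SCOPES",
    "CHANNELS",
    "PATTERNS",
]

SCOPES = ("general", "pairwise")
WINDOWS = ("cumulative", "yesterday", "today", "recency")
CHANNELS = ("attack_received", "attack_initiated", "disengage", "solicit",
            "interrupt", "depart")

# Count-based fight/outcome patterns (windowed histories)
COUNT_BASED = (
    "attack_win",
    "attack_lose",
    "receive_win",
    "receive_lose",
    "lose_chase",
    "win_any",
    "winloss_record",
    "interruption_perpetrated",
    "copulations_today",
)
# Covariate-like patterns (instantaneous state / covariates)
COVARIATE = (
    "female_presence",
    "pairwise_distance",
    "pairwise_winloss_difference_abs",
    "time_of_day",
    "disturbance_recency",
    "territory_holder_interactions",
    "copulation_open",
)
PATTERNS = COUNT_BASED + COVARIATE

_PATTERN_ABBR = {
    "attack_win": "att.win",
    "attack_lose": "att.lose",
    "receive_win": "recv.win",
    "receive_lose": "recv.lose",
    "lose_chase": "lose.chase",
    "win_any": "win.any",
    "winloss_record": "winloss",
    "interruption_perpetrated": "interrupt.perp",
    "copulations_today": "cops",
    "female_presence": "fem.pres",
    "pairwise_distance": "dist",
    "pairwise_winloss_difference_abs": "winloss.diff.abs",
    "time_of_day": "timeofday",
    "disturbance_recency": "disturb",
    "territory_holder_interactions": "terr.holder",
    "copulation_open": "cop.open",
}
_WINDOW_ABBR = {"cumulative": "cum", "yesterday": "yest", "today": "today",
                "recency": "rec"}
_SCOPE_ABBR = {"general": "gen", "pairwise": "pair"}
_CHANNEL_ABBR = {
    "attack_received": "attacked",
    "attack_initiated": "attack.init",
    "disengage": "diseng",
    "solicit": "solicit",
    "interrupt": "interrupt",
    "depart": "depart",
}

# candidate-event kind each channel loads on
_CHANNEL_KIND = {
    "attack_received": EventKind.ATTACK,
    "attack_initiated": EventKind.ATTACK,
    "interrupt": EventKind.ATTACK,
    "disengage": EventKind.DISENGAGE,
    "solicit": EventKind.SOLICIT,
    "depart": EventKind.DEPART,
}


class CatalogError(ValueError):
    """Invalid statistic specification requested."""


def recency(delta_seconds: float) -> float:
    """Reciprocal-square-root recency: 1/sqrt(seconds since the event).

    Clamped to 1.0 below one second so values stay in (0, 1].
    """
    if delta_seconds <= 0:
        raise ValueError(f"recency requires a positive elapsed time, got {delta_seconds}")
    return min(1.0, 1.0 / math.sqrt(delta_seconds))


@dataclass(frozen=True)
class StatisticSpec:
    pattern: str
    scope: str = "general"
    window: str = "today"
    channel: str = "attack_received"

    def __post_init__(self):
        msg = _invalid_reason(self.pattern, self.scope, self.window, self.channel)
        if msg:
            raise CatalogError(msg)

    @property
    def name(self) -> str:
        parts = [_SCOPE_ABBR[self.scope], _PATTERN_ABBR[self.pattern]]
        if self.pattern in COUNT_BASED:
            parts.append(_WINDOW_ABBR[self.window])
        parts.append(_CHANNEL_ABBR[self.channel])
        return ".".join(parts)

    def __str__(self) -> str:
        return self.name


def _invalid_reason(pattern: str, scope: str, window: str, channel: str) -> Optional[str]:
    if pattern not in PATTERNS:
        return f"unknown pattern {pattern!r}"
    if scope not in SCOPES:
        return f"unknown scope {scope!r}"
    if window not in WINDOWS:
        return f"unknown window {window!r}"
    if channel not in CHANNELS:
        return f"unknown channel {channel!r}"
    if pattern in COUNT_BASED:
        if window == "recency":
            if scope == "pairwise":
                return "recency statistics are general-scope only"
            if pattern in ("winloss_record", "copulations_today"):
                return f"{pattern} has no recency form"
        if pattern == "copulations_today" and window not in ("today", "recency"):
            return "copulations_today is a today-window statistic"
        return None
    # covariates: fixed scope/window forms
    fixed = {
        "female_presence": ("general", "today"),
        "pairwise_distance": ("pairwise", "today"),
        "time_of_day": ("general", "today"),
        "disturbance_recency": ("general", "recency"),
        "territory_holder_interactions": ("general", "today"),
        "copulation_open": ("general", "today"),
    }
    if pattern == "pairwise_winloss_difference_abs":
        if scope != "pairwise":
            return "pairwise win-loss difference is pairwise-scope"
        if window == "recency":
            return "pairwise win-loss difference has no recency form"
        return None
    want_scope, want_window = fixed[pattern]
    if scope != want_scope or window != want_window:
        return (f"{pattern} is only defined with scope={want_scope!r}, "
                f"window={want_window!r}")
    if pattern == "copulation_open" and channel != "interrupt":
        return "copulation_open applies to the interrupt channel only"
    return None


def build_catalog(patterns: Sequence[str], scopes: Sequence[str] = SCOPES,
                  windows: Sequence[str] = ("cumulative", "yesterday", "today"),
                  channels: Sequence[str] = CHANNELS) -> list:
    """Cross the requested patterns x scopes x windows x channels into a
    deterministically ordered list of specs, silently dropping combinations
    that are not defined (e.g. a pairwise-scope recency).  An explicitly
    impossible single request raises :class:`CatalogError` via StatisticSpec.
    """
    for p in patterns:
        if p not in PATTERNS:
            raise CatalogError(f"unknown pattern {p!r}")
    out = []
    seen = set()
    for p in patterns:
        for s in scopes:
            for w in windows:
                for c in channels:
                    if _invalid_reason(p, s, w, c):
                        continue
                    spec = StatisticSpec(p, s, w, c)
                    if spec.name not in seen:
                        seen.add(spec.name)
                        out.append(spec)
    return out


def spec_from_name(name: str) -> StatisticSpec:
    """Inverse of ``StatisticSpec.name`` (used by catalog/model files)."""
    rev_scope = {v: k for k, v in _SCOPE_ABBR.items()}
    rev_chan = {v: k for k, v in _CHANNEL_ABBR.items()}
    rev_win = {v: k for k, v in _WINDOW_ABBR.items()}
    rev_pat = {v: k for k, v in _PATTERN_ABBR.items()}
    parts = name.split(".")
    scope = rev_scope.get(parts[0])
    if scope is None:
        raise CatalogError(f"bad statistic name {name!r}")
    # channel abbrev may itself contain a dot (attack.init)
    for clen in (2, 1):
        chan = rev_chan.get(".".join(parts[-clen:]))
        if chan:
            mid = parts[1:-clen]
            break
    else:
        raise CatalogError(f"bad statistic name {name!r}")
    if mid and mid[-1] in rev_win and ".".join(mid) not in rev_pat:
        window = rev_win[mid[-1]]
        pat = rev_pat.get(".".join(mid[:-1]))
    else:
        pat = rev_pat.get(".".join(mid))
        window = {"disturbance_recency": "recency"}.get(pat, "today")
    if pat is None:
        raise CatalogError(f"bad statistic name {name!r}")
    return StatisticSpec(pat, scope, window, chan)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _focal_partner(state: LekState, candidate: EventType, channel: str):
    """Focal male index (whose history the statistic reads) and partner index
    for pairwise scope; (None, None) when the channel does not apply."""
    kind = candidate.kind
    if _CHANNEL_KIND[channel] is not kind:
        return None, None
    if kind is EventKind.ATTACK:
        s, r = state.idx(candidate.sender), state.idx(candidate.receiver)
        if channel == "attack_initiated":
            return s, r
        if channel == "interrupt":
            if not state.is_copulating(r):
                return None, None  # context gate: receiver must be copulating
            return r, s
        return r, s  # attack_received: focal is the male at risk
    m = state.idx(candidate.sender)
    if channel == "disengage":
        fights = state.fights_of(m)
        partner = None
        if fights:
            f = fights[0]
            partner = f.receiver if f.attacker == m else f.attacker
        return m, partner
    return m, None  # solicit / depart: no natural partner


def _count_value(state: LekState, pattern: str, scope: str, window: str,
                 focal: int, partner: Optional[int], fp: bool) -> float:
    c = state.counters

    def g(p, w):
        if scope == "pairwise":
            if partner is None:
                return 0.0
            return c.pair[(p, w, fp)][focal, partner]
        return c.gen[(p, w, fp)][focal]

    if window == "recency":
        base = {"win_any": ("attack_win", "receive_win")}.get(pattern, (pattern,))
        t_last = max(c.last[(p, fp)][focal] for p in base)
        if t_last == NEG_INF:
            return 0.0
        dt = state.time - t_last
        if dt <= 0:
            return 1.0
        return recency(dt)
    if pattern == "win_any":
        return g("attack_win", window) + g("receive_win", window)
    if pattern == "winloss_record":
        wins = g("attack_win", window) + g("receive_win", window)
        losses = g("attack_lose", window) + g("receive_lose", window)
        return wins - losses
    if pattern == "copulations_today":
        return g("copulation", "today")
    return g(pattern, window)


def evaluate_one(state: LekState, candidate: EventType, spec: StatisticSpec) -> float:
    """Value of one statistic for one candidate event in the current state."""
    focal, partner = _focal_partner(state, candidate, spec.channel)
    if focal is None:
        return 0.0
    p = spec.pattern
    if p in COUNT_BASED:
        fp = spec.channel == "solicit"  # solicitation stats: female-present events only
        return _count_value(state, p, spec.scope, spec.window, focal, partner, fp)
    if p == "female_presence":
        return 1.0 if state.females_present else 0.0
    if p == "pairwise_distance":
        if partner is None:
            raise ValueError(
                f"{spec.name} needs a dyadic candidate, got {candidate}")
        return state.roster.distance(state.roster.ids[focal],
                                     state.roster.ids[partner], state.day)
    if p == "pairwise_winloss_difference_abs":
        if partner is None:
            return 0.0
        c = state.counters
        w = spec.window
        wins = c.pair[("attack_win", w, False)][focal, partner] + \
            c.pair[("receive_win", w, False)][focal, partner]
        losses = c.pair[("attack_lose", w, False)][focal, partner] + \
            c.pair[("receive_lose", w, False)][focal, partner]
        return abs(wins - losses)
    if p == "time_of_day":
        return state.clock_time / 3600.0
    if p == "disturbance_recency":
        if state.last_disturbance == NEG_INF:
            return 0.0
        dt = state.time - state.last_disturbance
        return 1.0 if dt <= 0 else recency(dt)
    if p == "territory_holder_interactions":
        if candidate.kind is not EventKind.ATTACK:
            return 0.0
        return 1.0 if state.roster[candidate.sender].is_territory_holder(state.day) else 0.0
    if p == "copulation_open":
        # focal is the copulating receiver (gated in _focal_partner)
        return 1.0
    raise CatalogError(f"unknown pattern {p!r}")


def evaluate(state: LekState, candidate: EventType,
             specs: Iterable[StatisticSpec]) -> np.ndarray:
    """Statistic vector u(c, X, A_t) for a candidate event, aligned to specs."""
    return np.array([evaluate_one(state, candidate, s) for s in specs])


def write_catalog(specs: Sequence[StatisticSpec], path) -> None:
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "pattern", "scope", "window", "channel"])
        for s in specs:
            w.writerow([s.name, s.pattern, s.scope, s.window, s.channel])


def read_catalog(path) -> list:
    import csv
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(StatisticSpec(row["pattern"], row["scope"], row["window"],
                                     row["channel"]))
    return out
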