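"""Readers and writers for event logs, rosters, scaffolds and coefficients.

All formats are plain CSV (or YAML for run configs): human-auditable and
matching field-data practice.  Event times are float seconds from session
start; the 1/30 s video-frame resolution round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .events import (
    Actor,
    Category,
    Event,
    EventHistory,
    EventKind,
    EventType,
    Roster,
)
from .inference import FitResult, ParameterVector
from .simulate import DaySchedule, Scaffold

__all__ = [
    "FormatError",
    "read_events",
    "write_events",
    "read_roster",
    "write_roster",
    "read_scaffold",
    "write_scaffold",
    "read_theta",
    "write_theta",
    "write_fit_report",
    "write_metrics",
]

EVENT_COLUMNS = ["day", "time_s", "kind", "sender", "receiver"]


class FormatError(ValueError):
    """Malformed input file."""


def write_events(events: EventHistory, path) -> None:
    rows = [
        {
            "day": e.day,
            # repr keeps the shortest exact decimal form: bit-lossless round trip
            "time_s": repr(float(e.time)),
            "kind": e.type.kind.value,
            "sender": e.type.sender or "",
            "receiver": e.type.receiver or "",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> EventHistory:
    """Parse an event-log CSV; rejects missing columns and out-of-order times
    with the offending column/row named."""
    df = pd.read_csv(path, dtype={"sender": str, "receiver": str},
                     keep_default_na=False, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event log {path} is missing column(s): "
                          f"{', '.join(missing)}")
    events = []
    prev = None  # (day, time)
    kinds = {k.value: k for k in EventKind}
    for i, row in enumerate(df.itertuples(index=False)):
        if row.kind not in kinds:
            raise FormatError(f"row {i + 2}: unknown event kind {row.kind!r}")
        day, t = int(row.day), float(row.time_s)
        if prev is not None:
            if day < prev[0]:
                raise FormatError(f"row {i + 2}: day {day} before day {prev[0]}")
            if day == prev[0] and t < prev[1] - 1e-9:
                raise FormatError(
                    f"row {i + 2}: time {t} decreases within day {day}")
        prev = (day, t)
        sender = row.sender or None
        receiver = row.receiver or None
        events.append(Event(EventType(kinds[row.kind], sender, receiver), t, day))
    return EventHistory(events)


def write_roster(roster: Roster, path) -> None:
    """Long-format roster: one row per actor-day, plus actor-level fields."""
    rows = []
    for a in roster:
        days = sorted(a.present_days) or sorted(a.centroids) or [0]
        for d in days:
            x, y = a.centroid(d)
            rows.append({
                "id": a.id, "category": a.category.value, "day": d,
                "present": int(d in a.present_days),
                "territory_holder": int(a.is_territory_holder(d)),
                "centroid_x_m": x, "centroid_y_m": y,
                "mean_absence_s": a.mean_absence_s,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_roster(path, require_bulk: Optional[bool] = None) -> Roster:
    df = pd.read_csv(path)
    needed = {"id", "category", "day", "present", "centroid_x_m", "centroid_y_m"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"roster {path} is missing column(s): "
                          f"{', '.join(sorted(missing))}")
    actors = []
    for aid, grp in df.groupby("id", sort=False):
        cat = Category(grp.category.iloc[0])
        present = frozenset(int(r.day) for r in grp.itertuples() if r.present)
        centroids = {int(r.day): (float(r.centroid_x_m), float(r.centroid_y_m))
                     for r in grp.itertuples()}
        terr = ({int(r.day): bool(r.territory_holder) for r in grp.itertuples()}
                if "territory_holder" in grp.columns else {})
        mean_abs = (float(grp.mean_absence_s.iloc[0])
                    if "mean_absence_s" in grp.columns else 1800.0)
        actors.append(Actor(str(aid), cat, present, terr, centroids, mean_abs))
    if require_bulk is None:
        require_bulk = any(a.category is Category.X_BULK for a in actors)
    return Roster(actors, require_bulk=require_bulk)


def write_scaffold(scaffold: Scaffold, path) -> None:
    rows = []
    for d in scaffold:
        rows.append({"day": d.day, "time_s": d.end_time, "kind": "day_end",
                     "actor": ""})
        for a, t in d.arrivals:
            rows.append({"day": d.day, "time_s": t, "kind": "arrive", "actor": a})
        for t0, t1 in d.female_windows:
            rows.append({"day": d.day, "time_s": t0, "kind": "female_enter",
                         "actor": ""})
            rows.append({"day": d.day, "time_s": t1, "kind": "female_exit",
                         "actor": ""})
        for t in d.disturbances:
            rows.append({"day": d.day, "time_s": t, "kind": "disturbance",
                         "actor": ""})
    pd.DataFrame(rows, columns=["day", "time_s", "kind", "actor"]).to_csv(
        path, index=False)


def read_scaffold(path) -> Scaffold:
    df = pd.read_csv(path, dtype={"actor": str}, keep_default_na=False)
    missing = {"day", "time_s", "kind"} - set(df.columns)
    if missing:
        raise FormatError(f"scaffold {path} is missing column(s): "
                          f"{', '.join(sorted(missing))}")
    days = []
    for day, grp in df.groupby("day"):
        end = grp[grp.kind == "day_end"]
        if len(end) != 1:
            raise FormatError(f"scaffold day {day}: need exactly one day_end row")
        arrivals = tuple((r.actor, float(r.time_s))
                         for r in grp[grp.kind == "arrive"].itertuples())
        enters = sorted(float(t) for t in grp[grp.kind == "female_enter"].time_s)
        exits = sorted(float(t) for t in grp[grp.kind == "female_exit"].time_s)
        if len(enters) != len(exits):
            raise FormatError(f"scaffold day {day}: unmatched female windows")
        windows = tuple(zip(enters, exits))
        dist = tuple(float(t) for t in grp[grp.kind == "disturbance"].time_s)
        days.append(DaySchedule(int(day), float(end.time_s.iloc[0]),
                                arrivals, windows, dist))
    days.sort(key=lambda d: d.day)
    return Scaffold(tuple(days))


def write_theta(theta: ParameterVector, path,
                posterior_se: Optional[dict] = None) -> None:
    df = pd.DataFrame({"name": theta.names, "estimate": theta.values})
    if posterior_se:
        df["posterior_se"] = [posterior_se.get(n, np.nan) for n in theta.names]
    df.to_csv(path, index=False)


def read_theta(path) -> ParameterVector:
    df = pd.read_csv(path)
    missing = {"name", "estimate"} - set(df.columns)
    if missing:
        raise FormatError(f"coefficient table {path} is missing column(s): "
                          f"{', '.join(sorted(missing))}")
    return ParameterVector(tuple(df.name), df.estimate.to_numpy(dtype=float))


def write_fit_report(fit: FitResult, path) -> None:
    """Structured text fit report: logL, BIC, k, n, convergence."""
    lines = [
        f"log_likelihood: {fit.log_likelihood:.6f}",
        f"bic: {fit.bic:.6f}",
        f"n_params: {fit.n_params}",
        f"n_events: {fit.n_events}",
        f"converged: {fit.converged}",
        f"grad_norm: {fit.grad_norm:.3e}",
        f"n_iter: {fit.n_iter}",
    ]
    for w in fit.warnings:
        lines.append(f"warning: {w}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_metrics(metrics_by_rep, path) -> None:
    """Metrics CSV, one row per replicate x male (or male for a single run)."""
    rows = []
    for rep, metrics in metrics_by_rep:
        for aid, m in metrics.items():
            rows.append({
                "rep": rep, "actor": aid, "total_fights": m.total_fights,
                "wins": m.wins, "losses": m.losses,
                "win_rate": "" if m.win_rate is None else m.win_rate,
                "solicitations": m.solicitations,
                "copulations": m.copulations, "interrupted": m.interrupted,
                "interruption_rate": ("" if m.interruption_rate is None
                                      else m.interruption_rate),
                "time_available_to_mate": m.time_available_to_mate,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
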