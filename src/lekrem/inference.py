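"""Hazards, event-history likelihood, posterior-mode estimation, BIC.

The hazard of a supported candidate event is exp(theta . x), where x
concatenates fixed-effect indicators (per-kind intercepts, optionally
per-male offsets, and a solicitation scheme) with predictor-statistic values.
Unsupported events have hazard zero.

Because hazards are piecewise constant, the log-likelihood of an observed
history decomposes over inter-event intervals: each interval of length dt
contributes survival -dt * Lambda (Lambda = total hazard of all supported
endogenous candidates), each observed endogenous event adds log of its own
hazard, and each fight response — an instantaneous choice among face-off,
short fight and chase — adds a multinomial log-probability with no waiting
time.  Exogenous events terminate intervals contributing survival only.

Fitting maximises the log-likelihood plus an independent Gaussian log-prior
(posterior mode); standard errors come from the inverse observed-information
matrix at the mode.  Model comparison uses BIC = k ln(n) - 2 logL with n the
number of observed endogenous events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import logsumexp, softmax

from .events import (
    EventHistory,
    EventKind,
    EventType,
    LekState,
    Roster,
    support_set,
    apply_event,
    validate_history,
)
from .statistics import StatisticSpec, evaluate_one

__all__ = [
    "ParameterVector",
    "ModelSpec",
    "FitResult",
    "CompiledModel",
    "CompiledLikelihood",
    "AlignmentError",
    "IdentifiabilityError",
    "hazard",
    "compile_model",
    "compile_history",
    "log_likelihood",
    "fit_posterior_mode",
    "bic",
    "select_model",
    "stepwise_select",
]

# endogenous hazard channels a model may switch on
DEFAULT_ACTIVE = frozenset(
    {
        EventKind.ATTACK,
        EventKind.DISENGAGE,
        EventKind.SOLICIT,
        EventKind.COPULATION_END,
        EventKind.DEPART,
    }
)

_ETA_MAX = 60.0  # linear predictors are clipped here inside exp() for safety


class AlignmentError(ValueError):
    """Parameter vector and statistic vector are not aligned."""


class IdentifiabilityError(ValueError):
    """A design column is degenerate on the supplied data."""


@dataclass
class ParameterVector:
    """Named coefficient vector theta (fixed effects + statistic coefficients)."""

    names: tuple
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise AlignmentError("names and values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficients must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterVector":
        names = tuple(d.keys())
        return cls(names, np.array([d[k] for k in names], dtype=float))

    def as_dict(self) -> dict:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def __len__(self) -> int:
        return self.values.size

    def replace(self, **updates) -> "ParameterVector":
        d = self.as_dict()
        for k, v in updates.items():
            if k not in d:
                raise KeyError(k)
            d[k] = v
        return ParameterVector.from_dict(d)


@dataclass(frozen=True)
class ModelSpec:
    """What goes into the linear predictor.

    ``solicitation_scheme``: "single" fits one solicitation intercept shared
    by all males (the aggression formulation — fighting history must explain
    who gets solicited); "per_male" adds an intercept for every
    ever-solicited male on top of a base rate for never-solicited males
    (the differential-attractiveness formulation).
    """

    statistic_set: tuple = ()
    solicitation_scheme: str = "single"
    active_kinds: frozenset = DEFAULT_ACTIVE
    response_intercepts: bool = True  # face-off is the reference kind
    per_male_attack: bool = False
    per_male_receive: bool = False
    per_male_disengage: bool = False
    per_male_solicited: tuple = ()  # ids with own solicitation intercept

    def __post_init__(self):
        if self.solicitation_scheme not in ("single", "per_male"):
            raise ValueError(f"unknown solicitation scheme {self.solicitation_scheme!r}")
        object.__setattr__(self, "statistic_set", tuple(self.statistic_set))
        object.__setattr__(self, "active_kinds", frozenset(self.active_kinds))
        object.__setattr__(self, "per_male_solicited", tuple(self.per_male_solicited))

    def with_statistics(self, specs: Iterable[StatisticSpec]) -> "ModelSpec":
        return ModelSpec(tuple(specs), self.solicitation_scheme, self.active_kinds,
                         self.response_intercepts, self.per_male_attack,
                         self.per_male_receive, self.per_male_disengage,
                         self.per_male_solicited)


class CompiledModel:
    """ModelSpec bound to a roster: parameter layout + design-row builder."""

    def __init__(self, model: ModelSpec, roster: Roster,
                 ever_solicited: Optional[Sequence[str]] = None):
        self.model = model
        self.roster = roster
        n = len(roster)
        names: list = []

        def col(name: str) -> int:
            names.append(name)
            return len(names) - 1

        active = model.active_kinds
        self.col_attack = col("attack") if EventKind.ATTACK in active else -1
        self.attack_init_col = np.full(n, -1, dtype=int)
        self.attack_recv_col = np.full(n, -1, dtype=int)
        if EventKind.ATTACK in active and model.per_male_attack:
            for i, a in enumerate(roster.ids):
                self.attack_init_col[i] = col(f"attack_init:{a}")
        if EventKind.ATTACK in active and model.per_male_receive:
            for i, a in enumerate(roster.ids):
                self.attack_recv_col[i] = col(f"attack_recv:{a}")
        self.col_resp_sf = self.col_resp_ch = -1
        if model.response_intercepts:
            self.col_resp_sf = col("response_short_fight")
            self.col_resp_ch = col("response_chase")
        self.col_disengage = col("disengage") if EventKind.DISENGAGE in active else -1
        self.disengage_col = np.full(n, -1, dtype=int)
        if EventKind.DISENGAGE in active and model.per_male_disengage:
            for i, a in enumerate(roster.ids):
                self.disengage_col[i] = col(f"disengage:{a}")
        self.col_solicit = -1
        self.solicit_col = np.full(n, -1, dtype=int)
        if EventKind.SOLICIT in active:
            self.col_solicit = col("solicit")
            if model.solicitation_scheme == "per_male":
                solicited = model.per_male_solicited or tuple(ever_solicited or ())
                for a in solicited:
                    self.solicit_col[roster.index[a]] = col(f"solicit:{a}")
        self.col_cop_end = (col("copulation_end")
                            if EventKind.COPULATION_END in active else -1)
        self.col_depart = col("depart") if EventKind.DEPART in active else -1
        self.stat_offset = len(names)
        for s in model.statistic_set:
            col(s.name)
        self.param_names = tuple(names)
        self.n_params = len(names)
        self.active_kinds = active

    def zero_theta(self) -> ParameterVector:
        return ParameterVector(self.param_names, np.zeros(self.n_params))

    def theta_from_dict(self, d: dict, default: float = 0.0) -> ParameterVector:
        vals = np.full(self.n_params, default)
        for k, v in d.items():
            if k not in self.param_names:
                raise KeyError(f"{k!r} is not a parameter of this model")
            vals[self.param_names.index(k)] = v
        return ParameterVector(self.param_names, vals)

    def design_row(self, state: LekState, et: EventType) -> np.ndarray:
        """x such that log hazard(et) = theta . x."""
        x = np.zeros(self.n_params)
        kind = et.kind
        if kind is EventKind.ATTACK:
            if self.col_attack >= 0:
                x[self.col_attack] = 1.0
            s, r = state.idx(et.sender), state.idx(et.receiver)
            if self.attack_init_col[s] >= 0:
                x[self.attack_init_col[s]] = 1.0
            if self.attack_recv_col[r] >= 0:
                x[self.attack_recv_col[r]] = 1.0
        elif kind is EventKind.RESPONSE_SHORT_FIGHT:
            if self.col_resp_sf >= 0:
                x[self.col_resp_sf] = 1.0
        elif kind is EventKind.RESPONSE_CHASE:
            if self.col_resp_ch >= 0:
                x[self.col_resp_ch] = 1.0
        elif kind is EventKind.RESPONSE_FACE_OFF:
            pass  # reference response kind
        elif kind is EventKind.DISENGAGE:
            if self.col_disengage >= 0:
                x[self.col_disengage] = 1.0
            m = state.idx(et.sender)
            if self.disengage_col[m] >= 0:
                x[self.disengage_col[m]] = 1.0
        elif kind is EventKind.SOLICIT:
            if self.col_solicit >= 0:
                x[self.col_solicit] = 1.0
            m = state.idx(et.sender)
            if self.solicit_col[m] >= 0:
                x[self.solicit_col[m]] = 1.0
        elif kind is EventKind.COPULATION_END:
            if self.col_cop_end >= 0:
                x[self.col_cop_end] = 1.0
        elif kind is EventKind.DEPART:
            if self.col_depart >= 0:
                x[self.col_depart] = 1.0
        for j, spec in enumerate(self.model.statistic_set):
            v = evaluate_one(state, et, spec)
            if v != 0.0:
                x[self.stat_offset + j] = v
        return x

    def candidates(self, state: LekState) -> list:
        return support_set(state, self.active_kinds)


def compile_model(model: ModelSpec, roster: Roster,
                  events: Optional[EventHistory] = None) -> CompiledModel:
    """Bind a ModelSpec to a roster; with per-male solicitation and no
    explicit id list, the ever-solicited set is read off the event history."""
    ever = None
    if (model.solicitation_scheme == "per_male" and not model.per_male_solicited
            and events is not None):
        ever = sorted({e.type.sender for e in events
                       if e.type.kind is EventKind.SOLICIT})
    return CompiledModel(model, roster, ever)


def align_theta(cm: CompiledModel, theta) -> np.ndarray:
    """Coefficients as an ndarray in the compiled model's column order.

    A ParameterVector is matched by name (order-insensitive); a bare array
    must already have the right length.
    """
    if isinstance(theta, ParameterVector):
        if set(theta.names) != set(cm.param_names):
            missing = set(cm.param_names) - set(theta.names)
            extra = set(theta.names) - set(cm.param_names)
            raise AlignmentError(
                f"theta does not match model parameters "
                f"(missing: {sorted(missing)}, extra: {sorted(extra)})")
        d = theta.as_dict()
        return np.array([d[n] for n in cm.param_names])
    tv = np.asarray(theta, dtype=float)
    if tv.size != cm.n_params:
        raise AlignmentError(
            f"theta has {tv.size} entries, model has {cm.n_params} parameters")
    return tv


def hazard(theta, u, supported: bool = True) -> float:
    """exp(theta . u) events/second for a supported event, else 0.

    ``theta`` and ``u`` may be ParameterVector / ndarray; they must align.
    """
    if not supported:
        return 0.0
    tv = theta.values if isinstance(theta, ParameterVector) else np.asarray(theta, float)
    uv = np.asarray(getattr(u, "values", u), dtype=float)
    if tv.shape != uv.shape:
        raise AlignmentError(f"theta has {tv.size} entries, u has {uv.size}")
    return float(np.exp(min(float(tv @ uv), _ETA_MAX)))


# ---------------------------------------------------------------------------
# Compiled likelihood
# ---------------------------------------------------------------------------

class CompiledLikelihood:
    """Event history compiled to design arrays.

    Rows stack the supported candidates of every inter-event interval.
    logL(theta) = sum_obs eta - sum_rows w * exp(eta)
                + sum_groups [eta_obs - logsumexp(eta_group)],
    with w the interval length a row survives through (0 for response rows).
    """

    def __init__(self, X, w, obs_idx, groups, n_events, n_params, param_names):
        self.X = X
        self.w = w
        self.obs_idx = obs_idx
        self.groups = groups  # list of (row_slice, obs_row)
        self.n_events = n_events
        self.n_params = n_params
        self.param_names = param_names

    def _eta(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(self.X @ theta, -_ETA_MAX, _ETA_MAX)

    def value(self, theta: np.ndarray) -> float:
        eta = self._eta(theta)
        ll = float(eta[self.obs_idx].sum() - self.w @ np.exp(eta))
        for sl, obs in self.groups:
            ll += float(eta[obs] - logsumexp(eta[sl]))
        return ll

    def grad(self, theta: np.ndarray) -> np.ndarray:
        eta = self._eta(theta)
        g = self.X[self.obs_idx].sum(axis=0) - self.X.T @ (self.w * np.exp(eta))
        for sl, obs in self.groups:
            p = softmax(eta[sl])
            g += self.X[obs] - p @ self.X[sl]
        return g

    def hess(self, theta: np.ndarray) -> np.ndarray:
        eta = self._eta(theta)
        r = self.w * np.exp(eta)
        H = -(self.X.T * r) @ self.X
        for sl, obs in self.groups:
            Xg = self.X[sl]
            p = softmax(eta[sl])
            H -= Xg.T @ (np.diag(p) - np.outer(p, p)) @ Xg
        return H

    def check_identifiable(self) -> None:
        dead = np.all(self.X == 0.0, axis=0)
        if dead.any():
            bad = [self.param_names[i] for i in np.flatnonzero(dead)]
            raise IdentifiabilityError(
                f"design column(s) identically zero on this data: {', '.join(bad)}")


def compile_history(events: EventHistory, compiled: CompiledModel,
                    day_gaps: Optional[set] = None,
                    validate: bool = True) -> CompiledLikelihood:
    """Replay a history once, emitting design rows for every interval."""
    roster = compiled.roster
    if validate:
        rep = validate_history(events, roster, day_gaps)
        if not rep.ok:
            i, ev, msg = rep.first_violation
            raise ValueError(f"invalid history at event {i} ({ev.type}): {msg}")
    day_gaps = day_gaps or set()
    state = LekState(roster)
    rows: list = []
    w: list = []
    obs_idx: list = []
    groups: list = []
    n_endog = 0
    prev_day: Optional[int] = None
    for ev in events:
        if prev_day is None or ev.day != prev_day:
            consecutive = (prev_day is not None and ev.day == prev_day + 1
                           and ev.day not in day_gaps)
            state.start_day(ev.day, consecutive)
            prev_day = ev.day
        et = ev.type
        if state.awaiting_response is not None:
            if not et.kind.is_response:
                raise ValueError(f"expected a response event, got {et}")
            start = len(rows)
            obs_row = None
            for cand in support_set(state):
                rows.append(compiled.design_row(state, cand))
                w.append(0.0)
                if cand == et:
                    obs_row = len(rows) - 1
            groups.append((slice(start, len(rows)), obs_row))
            n_endog += 1
        else:
            dt = ev.time - state.time
            cands = compiled.candidates(state)
            obs_row = None
            if dt > 0 or et.kind.is_endogenous:
                for cand in cands:
                    rows.append(compiled.design_row(state, cand))
                    w.append(dt)
                    if cand == et:
                        obs_row = len(rows) - 1
            if et.kind.is_endogenous:
                if obs_row is None:
                    raise ValueError(
                        f"observed event {et} not among the model's active "
                        f"supported candidates at day {ev.day} t={ev.time:.2f}")
                obs_idx.append(obs_row)
                n_endog += 1
        apply_event(state, ev, check_support=False)
    X = np.vstack(rows) if rows else np.zeros((0, compiled.n_params))
    return CompiledLikelihood(X, np.asarray(w), np.asarray(obs_idx, dtype=int),
                              groups, n_endog, compiled.n_params,
                              compiled.param_names)


def log_likelihood(events: EventHistory, model: ModelSpec, theta,
                   roster: Roster, day_gaps: Optional[set] = None) -> float:
    """Log-likelihood of an event history under theta (convenience wrapper)."""
    cm = compile_model(model, roster, events)
    cl = compile_history(events, cm, day_gaps)
    tv = align_theta(cm, theta)
    ll = cl.value(tv)
    if not math.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood")
    return ll


# ---------------------------------------------------------------------------
# Posterior-mode fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    theta_hat: ParameterVector
    posterior_se: dict
    log_likelihood: float
    bic: float
    n_events: int
    n_params: int
    converged: bool
    grad_norm: float
    n_iter: int
    message: str = ""
    model: Optional[ModelSpec] = None
    warnings: list = field(default_factory=list)

    def coefficient_table(self):
        import pandas as pd
        names = self.theta_hat.names
        return pd.DataFrame({
            "name": names,
            "estimate": self.theta_hat.values,
            "posterior_se": [self.posterior_se[n] for n in names],
        })


def fit_posterior_mode(events: EventHistory, model: ModelSpec, roster: Roster,
                       day_gaps: Optional[set] = None, prior_sd: float = 10.0,
                       init: Optional[np.ndarray] = None, gtol: float = 1e-6,
                       compiled: Optional[CompiledLikelihood] = None,
                       cm: Optional[CompiledModel] = None) -> FitResult:
    """Maximise logL + log N(0, prior_sd^2) prior; SEs from the inverse
    observed-information (pseudo-inverse, with a warning, if near-singular)."""
    if cm is None:
        cm = compile_model(model, roster, events)
    if compiled is None:
        compiled = compile_history(events, cm, day_gaps)
    compiled.check_identifiable()
    p = cm.n_params
    tau = 1.0 / (prior_sd ** 2)

    def neg(theta):
        return -(compiled.value(theta) - 0.5 * tau * theta @ theta)

    def neg_grad(theta):
        return -(compiled.grad(theta) - tau * theta)

    def neg_hess(theta):
        return -(compiled.hess(theta)) + tau * np.eye(p)

    # the Gaussian prior makes the penalised Hessian positive definite, so a
    # trust-region Newton step is robust even on weakly identified ridges
    x0 = np.zeros(p) if init is None else np.asarray(init, dtype=float)
    res = optimize.minimize(neg, x0, jac=neg_grad, hess=neg_hess,
                            method="trust-exact",
                            options={"gtol": gtol, "maxiter": 500})
    theta = res.x
    H = -(compiled.hess(theta)) + tau * np.eye(p)  # observed information, penalised
    warnings_list: list = []
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.diag(cov) > 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        warnings_list.append("information matrix near-singular; SEs use pseudo-inverse")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    ll = compiled.value(theta)
    n = compiled.n_events
    k = p
    fit = FitResult(
        theta_hat=ParameterVector(cm.param_names, theta),
        posterior_se={nm: float(s) for nm, s in zip(cm.param_names, se)},
        log_likelihood=float(ll),
        bic=float(k * math.log(max(n, 1)) - 2.0 * ll),
        n_events=n,
        n_params=k,
        converged=bool(res.success or np.linalg.norm(neg_grad(theta)) < 1e-3),
        grad_norm=float(np.linalg.norm(neg_grad(theta))),
        n_iter=int(res.nit),
        message=str(res.message),
        model=model,
        warnings=warnings_list,
    )
    return fit


def bic(fit: FitResult) -> float:
    """k ln(n_events) - 2 logL (n counts observed endogenous events)."""
    return float(fit.n_params * math.log(max(fit.n_events, 1))
                 - 2.0 * fit.log_likelihood)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def select_model(candidate_models: Sequence[ModelSpec], events: EventHistory,
                 roster: Roster, day_gaps: Optional[set] = None,
                 **fit_kw):
    """Fit every candidate and return (best ModelSpec, FitResult, trace).

    The trace lists (label, bic, converged) per candidate; ties break toward
    the model with fewer parameters, then input order.
    """
    if not candidate_models:
        raise ValueError("at least one candidate model is required")
    trace = []
    best = None
    for i, m in enumerate(candidate_models):
        try:
            fit = fit_posterior_mode(events, m, roster, day_gaps, **fit_kw)
        except (IdentifiabilityError, ValueError, FloatingPointError) as exc:
            trace.append({"candidate": i, "bic": math.inf, "error": str(exc)})
            continue
        trace.append({"candidate": i, "bic": fit.bic, "k": fit.n_params,
                      "logL": fit.log_likelihood, "converged": fit.converged})
        key = (fit.bic, fit.n_params, i)
        if best is None or key < best[0]:
            best = (key, m, fit)
    if best is None:
        raise RuntimeError("all candidate models failed to fit")
    return best[1], best[2], trace


def stepwise_select(base_model: ModelSpec, candidate_specs: Sequence[StatisticSpec],
                    events: EventHistory, roster: Roster,
                    day_gaps: Optional[set] = None, **fit_kw):
    """Greedy forward addition then backward pruning by BIC.

    Starting from ``base_model`` (typically intercepts only), repeatedly add
    the candidate statistic that lowers BIC most; then repeatedly drop the
    included statistic whose removal lowers BIC most.  Ties break toward the
    smaller model.  Returns (ModelSpec, FitResult, trace).
    """

    def fit_with(specs):
        m = base_model.with_statistics(specs)
        return m, fit_posterior_mode(events, m, roster, day_gaps, **fit_kw)

    current: list = list(base_model.statistic_set)
    model, fit = fit_with(current)
    trace = [{"step": "init", "specs": [s.name for s in current], "bic": fit.bic}]
    remaining = [s for s in candidate_specs if s not in current]
    improved = True
    while improved and remaining:
        improved = False
        best_gain = None
        for s in remaining:
            try:
                m_try, f_try = fit_with(current + [s])
            except (IdentifiabilityError, ValueError, FloatingPointError):
                continue
            if f_try.bic < fit.bic - 1e-9:
                if best_gain is None or f_try.bic < best_gain[1].bic:
                    best_gain = (s, f_try, m_try)
        if best_gain is not None:
            s, fit, model = best_gain
            current.append(s)
            remaining.remove(s)
            trace.append({"step": f"+{s.name}", "bic": fit.bic})
            improved = True
    improved = True
    while improved and current:
        improved = False
        best_drop = None
        for s in list(current):
            reduced = [t for t in current if t != s]
            try:
                m_try, f_try = fit_with(reduced)
            except (IdentifiabilityError, ValueError, FloatingPointError):
                continue
            if f_try.bic <= fit.bic + 1e-9:  # ties prefer the smaller model
                if best_drop is None or f_try.bic < best_drop[1].bic:
                    best_drop = (s, f_try, m_try)
        if best_drop is not None:
            s, fit, model = best_drop
            current.remove(s)
            trace.append({"step": f"-{s.name}", "bic": fit.bic})
            improved = True
    return model, fit, trace
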