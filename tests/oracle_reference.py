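"""Independent brute-force likelihood oracle.

Walks an event history one interval at a time, enumerating the supported
candidates explicitly and accumulating exponential-survival and log-hazard
terms with plain floats and dict lookups.  Shares only the state machine and
the single-statistic evaluator with the package; the likelihood assembly
(intervals, survival sums, response multinomials, day handling) is written
from scratch so it can serve as an oracle for the compiled implementation.
"""

import math

from lekrem.events import EventKind, LekState, apply_event, support_set
from lekrem.statistics import evaluate_one


def linear_predictor(state, et, theta_dict, model):
    eta = 0.0
    k = et.kind
    g = theta_dict.get
    if k is EventKind.ATTACK:
        eta += g("attack", 0.0)
        eta += g(f"attack_init:{et.sender}", 0.0)
        eta += g(f"attack_recv:{et.receiver}", 0.0)
    elif k is EventKind.RESPONSE_SHORT_FIGHT:
        eta += g("response_short_fight", 0.0)
    elif k is EventKind.RESPONSE_CHASE:
        eta += g("response_chase", 0.0)
    elif k is EventKind.RESPONSE_FACE_OFF:
        pass
    elif k is EventKind.DISENGAGE:
        eta += g("disengage", 0.0) + g(f"disengage:{et.sender}", 0.0)
    elif k is EventKind.SOLICIT:
        eta += g("solicit", 0.0) + g(f"solicit:{et.sender}", 0.0)
    elif k is EventKind.COPULATION_END:
        eta += g("copulation_end", 0.0)
    elif k is EventKind.DEPART:
        eta += g("depart", 0.0)
    for spec in model.statistic_set:
        c = g(spec.name)
        if c:
            eta += c * evaluate_one(state, et, spec)
    return eta


def loglik_bruteforce(events, model, theta_dict, roster, day_gaps=None):
    """Sum of per-interval survival terms, observed log-hazards, and
    response-choice log-probabilities."""
    day_gaps = day_gaps or set()
    state = LekState(roster)
    prev_day = None
    ll = 0.0
    for e in events:
        if prev_day is None or e.day != prev_day:
            consecutive = (prev_day is not None and e.day == prev_day + 1
                           and e.day not in day_gaps)
            state.start_day(e.day, consecutive)
            prev_day = e.day
        if state.awaiting_response is not None:
            cands = support_set(state)
            hs = [math.exp(linear_predictor(state, c, theta_dict, model))
                  for c in cands]
            h_obs = hs[cands.index(e.type)]
            ll += math.log(h_obs / sum(hs))
        else:
            dt = e.time - state.time
            cands = support_set(state, model.active_kinds)
            total = sum(math.exp(linear_predictor(state, c, theta_dict, model))
                        for c in cands)
            ll -= dt * total
            if e.type.kind.is_endogenous:
                ll += linear_predictor(state, e.type, theta_dict, model)
        apply_event(state, e, check_support=False)
    return ll
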