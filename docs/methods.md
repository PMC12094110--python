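# Methods

## Model

`lekrem` implements a relational event model for a lek: a roster of males
plus an aggregated "X-bulk" actor standing in for transient juveniles, and a
categorised event space of dyadic attacks, per-male fight responses,
disengagements, solicitations, copulation ends, departures and arrivals,
plus global exogenous kinds (female entry/exit, 15-minute clock ticks,
disturbances, day ends). For a roster of n actors the taxonomy has
n(n−1) + 8n + 5 types — 1115 at the field scale of 29 named males plus the
bulk actor.

Each possible event carries hazard exp(θ′u); impossible events have hazard
zero. The system is piecewise constant: hazards change only at events
(including clock ticks), so the waiting time to the next event is
exponential with mean 1/Λ, Λ the summed hazard of the support set, and the
identity of the next event is categorical with probabilities proportional to
hazards. The likelihood of an observed history is the product of these
interval survival terms and observed-event hazards. Fight responses are
instantaneous: the attacked male's choice among face-off / short fight /
chase is a competing-risks multinomial (softmax of the response linear
predictors, face-off as the reference) contributing a choice probability but
no waiting time. Exogenous events terminate intervals, contributing
survival only.

### Support constraints

1. only present males interact or depart;
2. solicitations are impossible when females are absent;
3. males inside an attack or copulation cycle neither attack, receive
   attacks, solicit, nor depart — with the single exception that an attack
   on a *copulating* male is supported and supplants the copulation end
   (an interruption);
4. the bulk actor may hold several simultaneous fights and remains
   available while engaged;
5. either party may disengage a face-off or short fight, only the attacker
   may disengage (and thereby win) a chase;
6. in the zero-duration window after an attack the support set is exactly
   the three response types of the attacked male.

The winner of a fight is the first male to successfully disengage. A
disengagement by the bulk actor, which may hold several fights, closes its
earliest-started eligible fight (the sources do not constrain this case).
A disturbance flushes all birds and clears every cycle; a female exit closes
any open copulation with neither success nor interruption credit (censored).

### Predictor statistics

A statistic is (pattern, scope, window, channel). Patterns cover fight
outcomes (attack+win, attack+lose, receive+win, receive+lose, lost chase,
any win, win−loss record, interruptions perpetrated, copulations today) and
covariates (female presence, pairwise centroid distance in metres, absolute
pairwise win−loss difference, time of day in hours at the last clock tick,
disturbance recency, territory-holder attacker indicator, and a
copulation-in-progress trigger for the interruption channel). Scope is the
male's general record or his record against the specific partner; windows
are cumulative, yesterday, so-far-today, or recency = 1/sqrt(seconds since
the last qualifying event). The win–loss record crossed over both scopes,
the three count windows and its four response channels (solicitation,
interruption, incoming attack, disengagement) yields the canonical set of
24 predictors.

Conventions and numerical choices:

* recency refreshes only at events and clock ticks (piecewise-constancy
  contract) and is clamped to 1.0 below one second so values stay in (0, 1];
  0 encodes "no qualifying past event". Event clocks restart each session,
  so recency does not span days.
* solicitation-channel statistics count only events that occurred with
  females present; interruption-channel statistics evaluate only when the
  candidate attack's receiver is copulating (0 otherwise).
* a pairwise-scope statistic on a channel whose candidate has no partner
  (solicitation, departure) evaluates to 0; such specs are kept in the
  catalog because the canonical 24-predictor cross includes them.
* "today" counters roll into "yesterday" at each session start; when the
  previous calendar day was unobserved, yesterday-counters start from zero.
* pairwise distance enters in raw metres from per-day centroids (stable
  territories; the nearest recorded day is used if a day is missing).

### Inference

Fitting maximises log-likelihood plus an independent Gaussian log-prior,
mean 0, SD 10 (configurable), on every coefficient — a posterior mode. The
history is compiled once into design arrays (one row per supported candidate
per interval), giving exact gradient and Hessian; optimisation is
trust-region Newton (`scipy` trust-exact, gradient tolerance 1e−6, zero
initialisation), which is robust on the weakly identified ridges that arise
when, say, a male never disengages (the prior pins such coefficients).
Linear predictors are clipped at ±60 inside the exponential as an overflow
guard. Standard errors are square roots of the diagonal of the inverse
penalised observed-information matrix; a near-singular matrix falls back to
the pseudo-inverse with a warning. Under weak identification (e.g. a base
intercept plus per-male offsets) marginal SEs are honest posterior widths
along the prior-limited ridge and can be large even when contrasts are
precise.

BIC = k·ln(n) − 2·logL with n the number of observed endogenous events,
responses included. Two solicitation schemes are built in: a single shared
intercept (the "aggression" formulation, which forces fighting history to
explain who gets solicited) and per-male intercepts for ever-solicited males
on top of a base rate for the never-solicited (the "differential
attractiveness" formulation). Model selection fits candidate specifications
and returns the BIC minimiser (ties toward the smaller model); a greedy
forward-addition-then-backward-pruning search over candidate statistics is
provided as `stepwise_select` with a full trace.

### Simulation

The simulator draws waiting times and identities from the model's own law.
Scheduled exogenous events (first arrivals, female windows, clock ticks,
disturbances, day end) come from a scaffold and pre-empt any sampled
endogenous event that would land later — they are treated as fixed inputs.
A departing male's potential return is scheduled after an exponential delay
with his mean absence interval; males flushed by a disturbance return the
same way. Counters carry across days within a run. Treatment experiments
simulate a simplified lek of six territory-holding males over seven days
after a one-day burn-in (burn-in discarded from all metrics), raising the
focal male's intrinsic attack and/or disengagement rate — and, in the
high-susceptibility scenario, his incoming-attack rate — by one standard
deviation on the log-hazard (linear-predictor) scale. Effects are z-scores
of treatment replicate means against the replicate-level control
distribution; the copulation-interruption rate excludes replicates with
three or fewer solicitations. Per-male metrics: total fights, win rate =
wins/(wins+losses), seconds available to mate (present, females present,
not in any cycle), solicitations, uninterrupted copulations, and
interruption rate = interrupted/(interrupted+successful); undefined rates
are reported as missing, never NaN.

## Synthetic data

The generator emulates the structure of a lek observation campaign: daily
sessions a few hours long, staggered male arrivals before one contiguous
female-presence window per day, a 900-s clock grid, occasional disturbances,
males placed on a jittered 10-m stake grid with presence patterns that make
roughly 8–9 males present per day at the field scale, territory-holder
status from the two-consecutive-previous-days rule, and event streams drawn
from a known coefficient vector. Three presets:

* **toy** — two males, one session, three coefficients (attack and
  disengagement intercepts at −3, i.e. ten-second mean waits, and a −1
  female-presence effect on starting fights). One 10800-s session yields
  ~1000 events; session length and day count scale the event budget for
  recovery studies at ~200 / ~1000 / ~5000 events.
* **field_scale** — 14 identified + 15 single-day males + the bulk actor,
  18 sessions with one missing calendar day; the departure intercept
  (−8.54), female-presence-on-departure (−1.37), lost-chase recency (2.84)
  and copulation-trigger (3.8) coefficients are the package's worked-example
  values, and the remaining intercepts are calibrated so one session
  produces roughly 290 events. Copulations last ~12 s on average so that
  the copulation-trigger effect yields interruption exposure comparable to
  the ~30% rates reported for sage-grouse leks.
* **experiment** — six territory males, all present daily, no departures or
  disturbances, used by the treatment experiments; an optional
  `solicit_spread` gives the males evenly spaced per-male solicitation
  offsets (±2 log units is conservative relative to observed lek mating
  skew) for model-class recovery studies.

What the synthetic data deliberately do **not** emulate: female identity and
choice copying, observation error, plumage or display covariates, weather,
spatial movement within a day (centroids are static covariates), and
fatigue. Passing recovery tests therefore demonstrates correctness of the
estimator and simulator under the model's own assumptions — not robustness
to the misspecifications real field data would add.

## Validation strategy

* the compiled likelihood is checked to 1e−9 against an independent
  brute-force per-interval implementation on short histories;
* simulator law checks: Kolmogorov–Smirnov on waiting times and chi-square
  on identity frequencies at 10⁴ draws (alpha = 0.01), plus the 5000-s mean
  wait of the baseline departure hazard;
* parameter recovery on the toy preset: 50 simulate-and-refit datasets of
  ~1000 events for ±2 SE coverage, and 12-dataset grids at ~200/1000/5000
  events for bias and RMSE shrinkage;
* model-class recovery: 20 replicates generated with per-male solicitation
  intercepts, each fit under both schemes and compared by BIC;
* treatment directionality at 200 replicates per condition.

Problem sizes were chosen so the full suite runs in a few minutes on one
CPU while leaving the statistical checks well-powered.

## Known limitations

* The statistic catalog generates families by rule; it does not reproduce
  any particular historical 301-statistic inventory, and a few named effects
  (e.g. "interruption by territory holders") are implemented as the
  indicator/count forms their descriptions imply.
* The stepwise BIC search is greedy and order-independent but not
  exhaustive; with strongly collinear candidate statistics it can keep a
  proxy rather than the generating effect.
* Posterior uncertainty is Laplace (mode + observed information), not MCMC.
* The simulator treats scaffolds as fixed inputs; it does not model the
  feedback of lek activity on female arrival times.
* Whether a within-session disturbance ends observation or birds return is
  left to the scaffold; the default presets re-populate via exponential
  return delays.
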