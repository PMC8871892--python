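# Methods

## The system

A public tertiary-hospital O&G specialist outpatient clinic operating a dual
practice: public patients are seen by a pool of doctors for a nominal fee;
private (fee-for-service) patients are seen, from the early afternoon, by
dual-practice specialists in the same ten consultation rooms.  Registration
infrastructure is shared with five other specialist clinics, so the model also
carries the non-O&G ("general") patient load through the QMS queue-number and
revenue counters.

All times are continuous minutes; multi-day replications lay days end to end
(day *d*, clock *t* → 1440·d + t) and the clinic empties overnight by
construction (work-to-finish staff, no overnight arrivals).

## Input reconstruction

**Service times.** Only median/quartile summaries of station process times are
available, so each (station, class) pair gets a two-parameter lognormal.  The
log-mean is anchored at the printed median (`mu = ln m`, making the model's
validation statistic exact by construction) and the log-sd minimizes the raw
squared error of the two outer quartiles.  An unconstrained two-parameter
least-squares fit over all three quantiles was rejected: for asymmetric
triples (e.g. consultation 10/13/20 min) it shifts the fitted median by more
than 1%, degrading the one statistic everything downstream is compared on.  A
degenerate triple (1/1/1) is a point mass.

**Arrivals.** Two regimes per class and day. *Block* ("random") arrival: the
daily total is allocated to 30-minute slots by a weighted multinomial draw —
the default public weight vector puts ~60% of arrivals between 8:00 and 10:00,
reflecting the observed morning peak — with per-slot caps enforced by pushing
overflow to neighbouring slots; *even/staggered* arrival: the total is split
as evenly as possible across slots (earlier slots take the remainder), never
exceeding the cap.  Within a slot, instants are uniform.  Daily volumes: 86
public (Obs:Gyn ≈ 180:177), 7 private, and 867 general patients — the general
volume is derived from the ~4800 patients registered over the five observed
days minus the O&G load.

**Attributes.** Laboratory need: Obs 51/180, Gyn 0 (the two observed Gyn lab
cases were excluded from the source analysis), private 21/32.  Specialist
case discussion: 10% of public patients, never private (they are already seen
by specialists).  Age group and appointment type are carried but do not affect
flow (no-shows and walk-in dynamics are out of scope).

**Common random numbers.** Each replication derives named substreams from
(master seed, replication index, stream index): one per arrival process, per
station's service times, attributes, doctor assignment, and downtime.  All
attributes and service durations are *pre-drawn at patient-generation time in
a fixed order*, so two scenario configurations run under the same master seed
give every patient identical attributes and service times — scenario contrasts
are paired, which sharply reduces comparison variance.

## The clinic model

Stations and defaults: QMS ×2 servers, revenue ×4, O&G counter ×1, private
counter ×1, vital signs ×2, laboratory ×2, nurses ×2, consultation rooms ×10;
7 doctors and 3 specialists (2 of whom provide private care).  Registration
counters admit only within opening hours; clinic stations are work-to-finish.
Inter-station walking time is a constant (calibrated) 2 minutes.

Consultation rules: the head of the public FIFO queue starts when a room and
an idle doctor are free, never before the scenario's consultation start time;
the doctor is drawn uniformly at random among the idle eligible ones.  A
consultation flagged for specialist discussion is extended by a discussion
draw (default lognormal 5 (3–8) min — an assumption, no duration is
published); the patient holds room and doctor until an idle, not-at-lunch
specialist is co-seized for the extension.  Private consultations are served
only by the two dual-practice specialists, after a 60-minute lunch that
immediately precedes the private session; the session opens at
max(private registration start, 12:30).  By default specialists do **not**
take routine public consultations: giving them the morning public queue makes
the calibrated base case clear public care only late in the afternoon, which
contradicts the observed operation (public provision essentially done by
13:00) and inverts the afternoon crowd comparisons.  The flag
`resources.specialists_see_public` restores the alternative.

**Downtime process (base case only).** Poisson-many episodes per day, each
seizing an idle doctor *together with a room* for U(15, 60) minutes, episode
starts uniform over 9:00–12:00, pending episodes lapsing at the window end.
This is the model's stand-in for atypical/prolonged consultations and
inactive rooms, and it also absorbs the unpublished electronic-record review
and documentation time.  Seizing the doctor+room pair (rather than a room
alone) matters: room-only blocking starves the private specialists of rooms
and inflates private turnaround times far beyond anything observed.  Scenarios
switch the process off ("typical consultation times").

## Calibration

Free parameters — the quantities no table publishes: QMS, revenue and O&G
counter service medians (quartile shape fixed at 0.6/1.0/1.6 × median),
transfer time, downtime rate.  Targets: public-Obs registration TT 45 min,
public-Obs clinic TT 99 min, private clinic TT 66 min.  The response surface
is nearly separable (QMS median → registration TT; downtime rate → clinic TT;
transfer → private TT), so the search cycles monotone 1-D
bracket-plus-log-bisection passes per (target, lever) pair, each evaluation
pooling 30 replications × 5 days; it stops inside a 10% band or when the
evaluation budget is spent, warning loudly if best-effort.  The shipped
defaults (`qms_median` 0.498 min, `revenue` 0.75, `og_counter` 1.5, transfer
2.0 min, downtime 18.97 episodes/day) were produced by this procedure and
validate across unseen master seeds at 45.1±1, 97–103, and 67–68 min for the
three targets.  Obs and Gyn registration processes are exchangeable in the
model, so the published Obs–Gyn registration gap (45 vs 29 min), which stems
from arrival-composition detail that is not published, is not a calibration
target; the Gyn figures are reported but not matched.

## Scenarios and outcomes

The base case and scenarios 1–7 differ only in arrival pattern (block vs
even), public arrival window and slot cap (22, 10 or 7 per 30 min), the
consultation start (9:00 or 8:15), the private opening time (11:00, 11:30 or
13:30, cap 9 or 2), and downtime (base only).  Scenario 5 additionally runs
with 7 consultation rooms, representing doctors' other duties during its
extended (to 15:00) arrival window.  Private slots under the 2-per-slot
schedules continue every 30 min until the daily 7 are placed, keeping totals
scenario-invariant.

Outcome conventions: medians are pooled across all patients of all
replications (per-replication medians are also reported); the crowd series
counts, per integer minute, patients registered, not departed, and not in
service anywhere — people *in* a consultation room or at a counter are not in
the waiting area — then averages left-closed clock hours 07:00–16:00 and
replications.  Percent change is 100·(scenario − base)/base on the pooled
medians (and per hour for the crowd).  Group comparisons use the
Kruskal–Wallis H (≥3 groups) or Mann–Whitney U (2 groups) with tie-corrected
asymptotic p; for combined n ≤ 12 an exact one-sided enumeration p is
reported as a cross-check.  No multiplicity correction is applied (single
planned comparisons).

## What the synthetic inputs do and do not show

The generator reproduces the *published statistical structure*: printed
quartile triples, daily volumes, attribute rates, slot caps and the morning
peak.  It does not reproduce the unpublished empirical arrival histograms,
the original distribution-family selections, or behaviours explicitly outside
scope (no-shows, family-member crowding, provider idle time, pharmacy).
Consequently the *base-case validation medians* and all *directional* scenario
conclusions (which schedule beats which, where crowding moves) are meaningful
model outputs, while the exact scenario percent-changes are
reconstruction-dependent: at this desk scale the package finds, e.g., scenario
3 reducing public median overall TT by ~49% and private by ~40% (observed
study: up to 40% and 21%) — same sign and ordering, larger magnitude.  The
test suite therefore pins the directional comparisons, not those percentages.

## Numerical and testing notes

* Event ordering is (time, insertion sequence); all tie-breaks are
  deterministic, and a replication is bit-reproducible from (config digest,
  master seed) — the manifest written with every study run.
* The engine is verified by exact trace equivalence against an independent
  state-scanning next-event oracle on 500 randomized small systems, by the
  Lindley recursion for single-server FIFO waits, and by
  capacity/FIFO/conservation invariants on simulated logs.
* Patient-wise monotonicity under capacity removal does *not* hold in a
  queueing network (a delayed neighbour can free a server earlier for someone
  else), so the downtime sanity check asserts the aggregate forms: mean and
  median time-in-system and the day's last departure never improve when
  downtime is enabled.
* Scenario regression tests run at 8 replications × 2 days (the asserted gaps
  are tens of percent and stable there); validation-scale checks use the full
  30 × 5.
* Degenerate inputs: zero daily totals give empty arrival streams; a
  point-mass service spec bypasses fitting; infeasible totals (> cap × slots)
  and disordered quantile triples raise validation errors rather than
  simulating nonsense.

## Known limitations

Front-end counter parameters and the downtime process are calibrated, not
measured; they absorb several unpublished quantities at once and should not be
interpreted individually.  The Obs–Gyn registration-time gap is not
reproduced.  Appointment-setting for private patients is subsumed in the
private-counter payment visit.  The model serves scenario *comparison*, not
absolute wait-time prediction.
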