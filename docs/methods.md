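# Methods

## The model

`cataractflow` is a process-oriented discrete event simulation (DES) of a
hospital cataract service, from community referral to same-day discharge.
Patients are individual entities with attributes (age band, referral source,
anaesthesia type) that steer their route; state changes happen only at
discrete events (arrival, start/end of an activity, booking, cancellation);
and every activity competes for counted resources — doctors, nurses,
consultation rooms, pre-surgery rooms, theatres, recovery chairs, recovery
beds — with first-come-first-served queues.

The pathway:

1. **Referral.** Two superposed Poisson streams: community optometrists and
   internal hospital services (e.g. a Diabetes clinic suspecting cataract).
   Arrivals land on working days during outpatient hours.  Each patient is
   *elderly* with probability `p_elderly`; age is behavioural only (no-show
   rate, recovery routing), never a number of years.
2. **Eye examination** (doctor + consultation room), with four outcomes:
   not suitable for surgery (exits), listed directly, listed after a
   pre-operative clinic assessment (nurse + pre-surgery room), or listed
   after a phone assessment (nurse only).
3. **Waiting list and booking.** A strict FIFO waiting list feeds half-day
   theatre *lists* (sessions).  Each session holds `patients_per_list`
   slots and is booked `booking_lead_days` (default 7) ahead from patients
   already listed by then.
4. **Day of surgery.** Each booked patient first either fails to attend
   (probability `p_noshow_elderly` or `p_noshow_other` by age band) or
   undergoes nurse-led pre-surgery tests, after which they may be found
   unfit (`p_unfit_on_day`).  Both events *lose the slot*: these are
   elective surgeries planned in advance, so a vacated slot cannot be
   re-allocated the same day.  Unfit patients re-join the list after
   `unfit_reschedule_delay_weeks`; no-shows re-join with probability
   `p_noshow_rebooked`, otherwise they leave the pathway for good.
5. **Surgery** (~20 min) by a doctor in the theatre, after local
   (usually) or general anaesthesia.
6. **Recovery and discharge.** Local-anaesthetic patients recover on a
   chair; general-anaesthetic patients on a bed; elderly local-anaesthetic
   patients on a bed with probability `p_bed_local_elderly`.  A small
   fraction `p_overnight` stay until 08:00 the next morning; everyone else
   is a day case.  Post-operative follow-up is a counted, zero-resource
   event (it happens in the community, outside the resources modelled) that
   earns the follow-up tariff.

The lost-slot rule is the model's central non-linearity: annual completed
surgeries grow sub-linearly in `patients_per_list` because (i) every extra
slot carries the same per-patient loss probability, and (ii) once capacity
approaches effective demand, lists can no longer be filled.  With the
shipped defaults both levers are active, which reproduces the published
pattern of strictly increasing totals with strictly decreasing percentage
increments and a near-plateau at 9 patients per list.

## Scenarios

Four configurations of `patients_per_list`: 6 (baseline), 7, 8, 9.  The
larger lists are made feasible by process changes — earlier admission for
pre-surgery tests, a 3D eye-imaging machine for lens measurement, earlier
lens preparation — which the model expresses as duration multipliers
(configuration, not code): scenario 1 scales `presurgery_tests` ×0.85,
scenarios 2–3 scale it ×0.6 (earlier admission combined with rapid
imaging), and scenario 3 additionally scales `surgery` ×0.9.  The sources
describing these mechanisms quantify no time savings, so the multipliers
are this package's own assumptions, chosen once so each list's expected
workload fits a half-day session.

## The engine

A minimal kernel of three primitives (no external DES library):

* **Event calendar** — a binary heap keyed by `(time, insertion counter)`.
  The counter makes ties deterministic: equal-time events fire in insertion
  order, so a run is a pure function of configuration and seed.
* **Resource pools** — counted resources with FIFO queues.  Each pool keeps
  the time integral of its busy count; a pluggable monitor callback
  additionally bins busy time by calendar month clipped to the operating
  window (for utilisation reporting).  On release, a waiting request is
  granted at the same instant via the calendar, preserving stable ordering.
* **Random streams** — four named substreams (arrivals, outcomes,
  durations, attendance) derived statelessly from one master seed.  One
  stream per stochastic purpose is the standard common-random-numbers
  setup: scenario comparisons re-use the same seeds, so contrasts are
  sharper than with independent sampling.

Processes are Python generators yielding `hold` / `acquire` / `release`
commands.  Time is in minutes; a run spans `warmup_weeks + weeks_per_year`
weeks (default 6 + 52).

## Calendar and utilisation windows

The 52-week reporting year maps onto 12 calendar months of a non-leap year
starting on a Monday; December is truncated to 30 days so the months tile
the 364-day year exactly.  A session or event belongs to the month of its
start.  Utilisation denominators use the scheduled operating window —
08:00–18:00 on working days — never the wall-clock year; busy time is
clipped to that window before binning, so an overnight bed stay does not
inflate daytime utilisation.  Theatres are excluded from the utilisation
report: during their sessions they are by construction fully used.

## Warm start

The modelled service runs at full capacity with a long waiting list, so an
empty-system start would spend months in an unrealistic transient.  The
waiting list is therefore primed at t=0 with `warmup_weeks × planned weekly
capacity` patients, and the warm-up weeks are excluded from all statistics.
Primed patients are historical — they consume no outpatient resources in
the run and are excluded from the referral-to-discharge mean, which is
computed only over patients whose referral was simulated.

## Synthetic stand-in parameters

The real service's parameter values are unpublished, so
`synthetic.default_parameters()` ships a stand-in marked ASSUMED
throughout.  Values were fixed once by deterministic flow algebra, not by
fitting: 2 theatres × 10 lists/week × 6 patients × 52 weeks plans 6,240
surgeries; the mean loss rate 1 − (1−0.0625)(1−0.04) ≈ 10% thins this to
≈5,620 completed; 153 referrals/week with 88% listed gives ≈7,870 listed
patients/year, which saturates every list size up to 8/list and runs out
just under the 9/list capacity.  Durations (examination 32 min, pre-op
clinic 40 min, phone 20 min, pre-surgery tests 32 min, surgery 20 min,
chair 45 min, bed 120 min; lognormal except triangular anaesthesia times)
and resource counts were chosen so staff hours and utilisations land at the
scale a mid-sized UK service reports.  Tariffs apportion ≈£750 of
reimbursement per completed pathway mostly to the procedure itself, and the
hourly staff rates are fully-absorbed figures (wages plus theatre overheads
and consumables amortised), which is why they exceed raw salary rates; the
optional explicit per-surgery consumables term defaults to zero.

What the generator does *not* emulate: real seasonal demand (the stand-in
`generate_demand_series` adds only a mild ±5% sinusoid and the arrival
process itself is stationary), forecasting of demand from historical
admissions data, gender or comorbidity effects, surgical complications
(≈1% in practice; not a modelled branch), and the true tariff schedule.
Passing tests therefore demonstrate internal correctness and the mechanism
of the scenario non-linearity at a realistic scale — not a forecast for any
particular hospital.

## Numerical choices

* Ties in the event calendar: insertion order (reproducibility).
* Duration draws are truncated below at 0.1 min so a pathological tail
  draw cannot produce a non-positive activity time; lognormal is
  parameterised by real-space mean and SD.
* Money is held as integer pence; monthly surpluses sum to the annual
  surplus exactly.  GBP values in reports are pence/100.
* Utilisation is clamped to [0, 100] after division.
* Sessions spread over working-day mornings first, then afternoons
  (08:00/13:00 starts); with weekly aggregation the exact placement only
  affects which month a boundary-week session lands in.
* Booking at `max(0, session start − lead time)`; a session never books
  patients listed after that instant.
* Replication summaries use Student-t 95% intervals over independent
  replications (n ≥ 2 enforced).
* Default problem sizes: one run simulates 58 weeks (≈9,500 patients,
  ≈10⁵ events, well under a second to a couple of seconds on one core);
  the scenario sweep uses 30 replications per scenario.

## Known limitations

* Session overruns are not modelled: a list's surgeries always complete on
  the day, so session length constrains nothing directly — the feasibility
  of larger lists is carried by the duration multipliers instead.
* Rebooked no-shows re-enter the FIFO queue with a fresh listing time;
  there is no risk-stratified or overbooked list composition (hooks exist
  in configuration, policies out of scope).
* The outpatient examination is staffed by doctors only; nurses carry
  pre-operative assessments and day-of-surgery tests.  The split is a
  simplification of "doctor or specialised nurse".
* Elderly status is a binary attribute; no explicit age distribution.
* One waiting list for the whole service; no per-surgeon lists.
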