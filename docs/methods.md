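# Methods

`adlsim` simulates the daily life of a single elderly resident living alone in
a simulated smart house, in three stages: a motivation-driven activity
scheduler, a waypoint location-trace generator, and a virtual PIR
(passive-infrared) sensor interface. This note documents the model, its
parameters and defaults, the numerical choices, and what the synthetic setup
does and does not capture.

## The motivation model

The resident holds up to 13 motivations, one per *activity sequence* (AS): an
ordered run of activities performed back-to-back (e.g. hunger: take food →
cook → take tableware → eat). Each motivation value `MV_i` is a scalar desire
level; the next AS is sampled from a clamped softmax

    P_i ∝ exp(max(0, MV_i − 0.98·Norm_MV)),

normalized over the ASs performable in the current layout. Relax (AS 13) is
pinned at `1.02·Norm_MV` and acts as the fallback: it wins until some other
motivation climbs past roughly `1.02·Norm_MV`.

**Layout adaptivity.** Which ASs (and which activities within an AS) exist is
decided purely by which of the 13 physical place types are present. An AS
with no available activity gets `MV ≡ 0` forever; an activity with no
available place is omitted from its sequence (a house without a kitchen still
lets the resident *eat* — food prepared elsewhere). Wandering needs no place;
relax falls back to the current position if no bed/sofa/desk exists.

**Growth.** A resident profile fixes, per AS, the nominal per-period duration
`D_i` (h), the period `T_i` (h) and frequency `f_i = 1/T_i`. Linear
motivations grow at `ω_i` per awake hour; while asleep only eat and
toilet-short keep growing, at 10% rate; an AS does not grow while it is
itself being performed. `ω_i` is derived from the stationarity principle —
over one period a motivation should gain exactly what one performance
removes:

    ω_i = Norm_MV / G_i,   G_i = full-rate-equivalent growth hours per period,

with `G_i = T_i − S_i` for the sleep sequences (their performance happens
*during* sleep), `G_i = T_i − D_i − 0.9·S_i` for eat and toilet-short (the
10% sleep growth credited back), and `G_i = T_i − S_i − D_i` otherwise, where
`S_i = (D_1 + D_2)·T_i/T_1` prorates daily sleep into the period. For the
canonical example — TV with `T = 24 h`, 8 h sleep, `D = 4 h` — this gives
`ω = Norm_MV/12`: the motivation recovers over exactly the 12 awake non-TV
hours.

The toilet-long and laundry motivations are step-driven instead: eating
triggers a step of `Norm_MV/(3·T_7)` (T_7 in days) 2.5 h later; loading the
washing machine (the tail of the bath sequence) triggers a full `Norm_MV`
step 1 h later.

**Decrease.** One performance lasts an *actual duration* AT drawn uniformly
from a per-AS factor interval times `D_i` (0.97–1.03 for night sleep, 0.4–0.9
for going out, 0.3–0.7 for TV and reading, 0.95–1.05 otherwise). Completion
removes `(AT / Ê_i)·Norm_MV`, where `Ê_i` is the interval midpoint times
`D_i` — so a nominal-length performance removes exactly `Norm_MV`, which
together with the growth rule makes every linear motivation stationary over
its period (the package's conservation test checks this to 1e-9). Breakfast
(the first meal after night sleep) removes only two thirds. Step-driven ASs
clear exactly one `Norm_MV` quantum per performance. MVs are floored at 0.

**Outings.** While out of the house, the eat/toilet motivations that reach
`Norm_MV` are satisfied outside whenever enough of the outing remains, with
no indoor activity emitted. Eating outside does not trigger the toilet-long
step (the trigger is tied to indoor meals).

**Initialization.** A run starts between 21:30 and 01:00 with the resident
about to sleep (`MV_1 = Norm_MV`). Every other linear motivation is placed so
it first reaches `Norm_MV` after a planned awake gap; breakfast lands 0.5–1.5 h
after waking, and the gaps of long ASs (> 0.5 h) are staggered at least 15
minutes apart so first performances cannot collide.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `Norm_MV` | 200 | motivation scale; sets softmax sharpness (below) |
| noise σ | `0.005·Norm_MV` per update | Gaussian jitter on every linear MV update |
| sub-step | 5 min | MV update resolution inside one performance |
| relax quantum | 10 min | how often the fallback state re-evaluates selection |
| walking speed | 60 cm/s | straight-segment travel between places |
| sensor range | 120 cm | PIR detection radius (Euclidean disc) |
| sampling | 1 Hz | location trace rate |

Profile sampling intervals (uniform, per AS): night sleep D∈[7,9] h T=24 h;
noon nap D∈[0.5,1.5] h T=24 h, present in half of residents; eat D∈[0.75,1.5] h
T=8 h; bath D∈[0.3,0.8] h T=24 h; go out D∈[1,4] h T∈{24,48,72,96} h;
toilet-short D=3 min T∈[3,5] h; toilet-long D∈[0.15,0.3] h T=24 h; TV D∈[2,5] h
T=24 h; read D∈[0.5,2] h T=24 h; clean D∈[0.3,1] h T∈[24,72] h; laundry
unload D=6 min T=24 h; wander D∈[0.1,0.3] h T∈[24,96] h.

**Why `Norm_MV = 200`.** All dynamics are scale-free in `Norm_MV` except
selection sharpness: a sub-threshold AS carries softmax weight `e⁰` against
relax's `e^{0.04·Norm_MV}`. At 100 that is `e⁴`, i.e. each of the ~12
sub-threshold ASs is picked with ≈1.5% probability per draw; with a draw
after every performance this produces a substantial "impulsive" background
(a resident with a four-day going-out period would go out most days). At 200
the background is `e⁻⁸` per draw, so rare activities keep their profile
periodicity while ASs crossing threshold still race stochastically inside the
4%-of-`Norm_MV` competition window. The value is configurable (`norm_mv` in
the run config).

## The scheduler

The event-driven loop starts with night sleep and repeats: sample AT, advance
the MVs over AT in 5-minute sub-steps (so step events and outing satisfaction
fire at the right moments), apply the completion decrease, sample the next AS
from the softmax. Consecutive identical selections merge into one entry;
relax runs in 10-minute quanta so the fallback is re-evaluated frequently.
Because relax is always performable and pinned above threshold, every instant
of the horizon belongs to exactly one activity: schedules are gapless by
construction.

Post-processing expands each AS performance into activity-level entries:
auxiliary steps (taking food or tableware, dressing, washing) get 0.5–2 min,
preparation steps (cooking, running the bath) 10–25 min, and the sequence's
main activity absorbs the remainder; if the side steps would exceed half the
performance they are rescaled proportionally. Each activity is pinned to the
nearest place instance of an allowed type. The night-sleep sequence is a
sandwich (wash → sleep → wash) whose whole block counts as sleeping for the
MV update (the minutes of washing are negligible at the 5-min sub-step
resolution). Breakfast is detected operationally as the first eating
performance after each night-sleep completion.

Time is continuous hours from the run start internally; output files format
timestamps as day number plus a 12-hour clock ("5d PM 1 h 13 m 59 s").

## Locations and PIR sensing

The travel model is deliberately simple: the resident dwells at each
activity's place with ≤10 cm jitter, walks straight segments between places at
constant speed, random-walks inside the bounds while wandering, and is marked
out-of-house during outings (leaving from and returning to the entrance).
Walls, doors and path obstruction are ignored, and the module boundary
accepts alternative path providers.

A PIR sensor is a Euclidean detection disc: ON at the first trace sample in
range after being out of range, OFF at the first sample out of range
(out-of-house counts as out of range). Per sensor, events therefore strictly
alternate starting with ON. The implementation is vectorized over samples; a
naive per-sample scan serves as the test oracle.

## What the synthetic setup does and does not show

The fixture layout generator stands in for an upstream floor-plan generator:
it scatters one instance of each requested place type, non-overlapping, in a
9 m × 6 m rectangle. It has no rooms, walls or semantic adjacency (the
bathroom may sit next to the stove), so passing tests demonstrate the
schedule/location/PIR *mechanics* — adaptivity, gaplessness, stationarity,
detection logic — not the realism of any specific house, travel path or
sensor geometry. Likewise the profile intervals encode plausible elderly
routines, not fitted population data; conclusions about real sensor layouts
need real floor plans and calibrated profiles.

## Numerical choices and degenerate inputs

- All randomness flows from one integer seed fanned out into named
  independent streams (profile, initialization, durations, noise, selection,
  expansion, trace), so each stage is reproducible in isolation.
- MVs are floored at 0 after every update and decrease; the relax MV is
  re-pinned after every update.
- Softmax probabilities are computed with a max-shift (log-sum-exp), so
  transiently large MVs cannot overflow.
- A zero-length horizon yields a schedule with only the initial entry; a
  profile that leaves an AS no growth time raises a configuration error
  naming the AS; unknown place-type labels are rejected at load time against
  the closed 14-label set.
- Noise is drawn per 5-minute sub-step with fixed σ (not √dt-scaled); at the
  default σ it is small against `ω_i·dt` and serves only to desynchronize
  seeds.

## Known limitations

- **Committed performances can overshoot fast motivations.** Once an AS
  starts, its full actual duration is committed; a fast-growing motivation
  (toilet-short has `ω` up to ≈ `Norm_MV`/2 h) can climb past `2·Norm_MV`
  during a long committed TV session if it was just below the competitive
  band at selection time. The overshoot is bounded —
  `≈ Norm_MV·(1 + max AT_TV / G_6)` — and immediately satisfied at the next
  boundary, so it is a transient, not a runaway; but peaks slightly above
  `2·Norm_MV` do occur in multi-week runs (2.11·Norm_MV in the canonical
  60-day run). An interruption rule analogous to the outing satisfaction
  would remove it, at the cost of breaking the committed-duration contract.
- Single resident; no visitors, day-of-week or seasonal structure, no profile
  drift (illness, aging).
- Laundry motivation only rises via the bath sequence; if baths are
  impossible in a layout the washing machine is never loaded.
- PIR detection ignores occlusion and sensor latency; the trace's travel
  segments are straight lines, not room-respecting paths.
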