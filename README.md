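# adlsim

Motivation-driven simulation of the daily life of an elderly person living
alone, for smart-house development. Testing health-monitoring sensor networks
and assistive robots needs long, realistic streams of activities-of-daily-living
(ADL) data with ground truth, but real test beds are expensive and hand-written
scenarios are short and repetitive. `adlsim` generates, from a house layout
and a random seed:

1. **a gapless multi-day activity schedule** for a virtual resident — every
   instant of the timeline is assigned to exactly one activity, the activity
   set adapts to the furniture actually present in the house, and the
   schedule stays statistically stable (but not repetitive) over weeks;
2. **a real-time 2-D location trace** (dwell at places, straight-segment
   walks, wandering, outings);
3. **virtual PIR (passive-infrared) sensor ON/OFF logs**, useful for
   sensor-placement studies and trajectory-analysis pipelines.

## The model

The resident holds up to 13 motivations, one per *activity sequence*
AS₁..AS₁₃ (night sleep, noon nap, eating, bathing, going out, toilet short
and long, TV, reading, cleaning, laundry unloading, wandering, relax). Each
motivation value MVᵢ grows while the sequence is not performed,

    MVᵢ(t+Δt) = MVᵢ(t) + ωᵢΔt + ε        (awake; 10% rate asleep for eating
                                           and toilet, frozen otherwise)

with ωᵢ derived from the resident's profile — per-sequence nominal duration
Dᵢ, period Tᵢ, frequency fᵢ = 1/Tᵢ — so that the gain over one period equals
the Norm_MV removed by one nominal performance (stationarity). Toilet-long
and laundry motivations instead rise in steps triggered by meals and by
loading the washing machine. The next sequence is drawn from a clamped
softmax,

    Pᵢ ∝ exp(max(0, MVᵢ − 0.98·Norm_MV)),

with relax pinned at 1.02·Norm_MV as the fallback. Sequences whose places are
missing from the layout are impossible (MV ≡ 0) and individual activities
without a place are omitted, so the same resident adapts to any house. See
`docs/methods.md` for the full rule set, parameter defaults and limitations.

## Worked example

```sh
adlsim fixtures --seed 1 --out demo            # synthetic layout, sensors, profile
adlsim pipeline --layout demo/layout.json --sensors demo/sensors.json \
       --seed 1 --days 10 --out demo/out
```

prints

```
wrote demo/layout.json sensors.json profile.yaml
wrote demo/out/schedule.csv,.json trace.csv events.csv (422 entries, 19021 PIR events)
```

The schedule CSV starts (seed 1; the run begins at 23:09, the resident is
about to go to bed):

```
activity,start_s,place_id,as_index,start_time
wash and brush teeth,0.0,p0,1,0d PM 11 h 9 m 55 s
sleep (at night),55.468,p1,1,0d PM 11 h 10 m 50 s
wash and brush teeth,29693.83,p0,1,1d AM 7 h 24 m 48 s
relax,29749.021,p12,13,1d AM 7 h 25 m 44 s
go to toilet (short duration),31549.021,p8,6,1d AM 7 h 55 m 44 s
relax,31720.867,p12,13,1d AM 7 h 58 m 35 s
take food,32920.867,p6,3,1d AM 8 h 18 m 35 s
cook,32989.895,p5,3,1d AM 8 h 19 m 45 s
take tableware,33695.195,p5,3,1d AM 8 h 31 m 30 s
eat,33775.612,p3,3,1d AM 8 h 32 m 50 s
```

— roughly 8.2 h of sleep, then toilet and a cooked breakfast about an hour
after waking, each activity pinned to a concrete place instance (`p0` =
bathroom, `p5` = kitchen stove, ...). Each entry lasts until the next one
starts; there is no unassigned time. The PIR log pairs into ON/OFF visits per
sensor:

```
time_s,formatted_time,sensor_id,state
0.0,0d PM 11 h 9 m 55 s,1,ON
58.0,0d PM 11 h 10 m 53 s,1,OFF
58.0,0d PM 11 h 10 m 53 s,2,ON
```

The same can be done from Python:

```python
import adlsim

layout = adlsim.generate_fixture_layout(1)
schedule = adlsim.generate_schedule(layout, total_dur_h=10 * 24, seed=1)
print(schedule.summarize())           # per-sequence counts, hours, mean start time
trace = adlsim.build_trace(schedule, layout)
events = adlsim.simulate_pir(trace, adlsim.default_sensors_for_layout(layout))
```

Layouts are plain JSON (`{"bounds": {"w": 900, "h": 600}, "places":
[{"type": "bed", "x": 120, "y": 80}, ...]}`) against a closed set of 13 place
types; profiles are partial YAML overrides of the sampled defaults.

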