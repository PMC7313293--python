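"""Real-time location traces and virtual PIR sensor records.

A schedule is turned into a fixed-rate 2-D position trace: the resident
dwells at each activity's place (with a little jitter), walks straight
segments between places at a constant speed, random-walks while wandering,
and is out of the house during outings.  A set of PIR sensors — Euclidean
detection discs — then turns the trace into an ON/OFF event log: ON at the
first in-range sample, OFF at the first out-of-range sample after being in
range.  Walls and occlusion are deliberately ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, LayoutError
from .layout import Layout
from .scheduler import Schedule
from .timeformat import format_sim_time

#: Default PIR detection radius (cm) and location sampling rate (Hz).
DEFAULT_SENSOR_RANGE_CM = 120.0
DEFAULT_SAMPLE_HZ = 1.0
DEFAULT_SPEED_CM_S = 60.0
_DWELL_JITTER_CM = 10.0


@dataclass(frozen=True)
class PIRSensor:
    id: int
    x: float
    y: float
    range_cm: float = DEFAULT_SENSOR_RANGE_CM

    def __post_init__(self) -> None:
        if self.range_cm <= 0:
            raise ContractError(f"sensor {self.id}: range_cm must be > 0")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class PIREvent:
    t_s: float
    sensor_id: int
    state: str  # "ON" | "OFF"


@dataclass
class LocationTrace:
    """Fixed-rate samples: times (s), positions (cm), out-of-house flags."""

    t_s: np.ndarray
    xy: np.ndarray       # (n, 2); NaN while out of house
    out: np.ndarray      # bool
    init_tod_h: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.t_s)
        if self.xy.shape != (n, 2) or self.out.shape != (n,):
            raise ContractError("trace arrays have inconsistent shapes")
        if n > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ContractError("trace times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t_s,
                "x_cm": self.xy[:, 0],
                "y_cm": self.xy[:, 1],
                "out_flag": self.out.astype(int),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_trace(path: str | Path) -> LocationTrace:
    df = pd.read_csv(path)
    return LocationTrace(
        t_s=df["time_s"].to_numpy(float),
        xy=df[["x_cm", "y_cm"]].to_numpy(float),
        out=df["out_flag"].to_numpy(int).astype(bool),
    )


# ---------------------------------------------------------------------------
# Trace construction
# ---------------------------------------------------------------------------


def build_trace(
    schedule: Schedule,
    layout: Layout,
    speed_cm_s: float = DEFAULT_SPEED_CM_S,
    sample_hz: float = DEFAULT_SAMPLE_HZ,
    rng: np.random.Generator | int = 0,
) -> LocationTrace:
    """Convert a schedule into a fixed-rate location trace.

    Straight-segment waypoint motion at ``speed_cm_s`` between activity
    places, dwell jitter up to 10 cm, a bounded random walk while wandering,
    and out-of-house markers during outings (the resident leaves from and
    returns to the entrance).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if speed_cm_s <= 0 or sample_hz <= 0:
        raise ContractError("speed_cm_s and sample_hz must be positive")
    if not schedule.entries:
        raise ContractError("cannot build a trace from an empty schedule")

    place_pos = {p.id: p.position for p in layout.places}
    horizon_s = schedule.horizon_h * 3600.0
    n = int(np.floor(horizon_s * sample_hz)) + 1
    t = np.arange(n) / sample_hz
    xy = np.zeros((n, 2))
    out = np.zeros(n, dtype=bool)

    starts = np.array([e.start_h * 3600.0 for e in schedule.entries])
    ends = np.append(starts[1:], horizon_s)
    step_cm = speed_cm_s / sample_hz
    pos = None  # current position; initialized at the first entry's place

    last_idx = len(schedule.entries) - 1
    for idx, (e, t0, t1) in enumerate(zip(schedule.entries, starts, ends)):
        k0 = int(np.ceil(t0 * sample_hz - 1e-9))
        k1 = n if idx == last_idx else min(int(np.ceil(t1 * sample_hz - 1e-9)), n)
        if k1 <= k0:
            continue
        m = k1 - k0

        if e.activity == "go out":
            target = place_pos.get(e.place_id) if e.place_id else pos
            if target is None:
                target = layout.center()
            if pos is None:
                pos = target
            n_travel = _segment_fill(xy, k0, k1, pos, target, step_cm)
            out[k0 + n_travel : k1] = True
            xy[k0 + n_travel : k1] = np.nan
            pos = target  # returns through the entrance
            continue

        if e.activity == "wander":
            if pos is None:
                pos = layout.center()
            walk = _random_walk(pos, m, 0.8 * step_cm, layout, rng)
            xy[k0:k1] = walk
            pos = walk[-1]
            continue

        if e.place_id is not None:
            if e.place_id not in place_pos:
                raise ContractError(
                    f"activity {e.activity!r} references unknown place {e.place_id!r}"
                )
            target = place_pos[e.place_id]
        else:
            target = pos if pos is not None else layout.center()
        if pos is None:
            pos = target
        n_travel = _segment_fill(xy, k0, k1, pos, target, step_cm)
        n_dwell = m - n_travel
        if n_dwell > 0:
            r = _DWELL_JITTER_CM * np.sqrt(rng.uniform(size=n_dwell))
            theta = rng.uniform(0.0, 2 * np.pi, size=n_dwell)
            jitter = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            xy[k0 + n_travel : k1] = target + jitter
        pos = target if n_travel < m or np.allclose(pos, target) else xy[k1 - 1]

    return LocationTrace(t_s=t, xy=xy, out=out, init_tod_h=schedule.init_tod_h)


def _segment_fill(
    xy: np.ndarray, k0: int, k1: int, start: np.ndarray, target: np.ndarray, step_cm: float
) -> int:
    """Fill straight-line travel samples from ``start`` towards ``target``.

    Returns the number of samples used for travel (the walk may not complete
    within the entry, in which case all samples are travel).
    """
    delta = target - start
    dist = float(np.linalg.norm(delta))
    if dist < 1e-9:
        return 0
    m = k1 - k0
    n_travel = min(int(np.ceil(dist / step_cm)), m)
    frac = np.minimum(np.arange(1, n_travel + 1) * step_cm / dist, 1.0)
    xy[k0 : k0 + n_travel] = start + frac[:, None] * delta
    return n_travel


def _random_walk(
    start: np.ndarray,
    m: int,
    step_cm: float,
    layout: Layout,
    rng: np.random.Generator,
) -> np.ndarray:
    theta = rng.uniform(0.0, 2 * np.pi, size=m)
    lengths = rng.uniform(0.0, step_cm, size=m)
    steps = np.column_stack([lengths * np.cos(theta), lengths * np.sin(theta)])
    walk = np.empty((m, 2))
    pos = start.astype(float).copy()
    for k in range(m):
        pos = pos + steps[k]
        pos[0] = min(max(pos[0], 0.0), layout.width)
        pos[1] = min(max(pos[1], 0.0), layout.height)
        walk[k] = pos
    return walk


# ---------------------------------------------------------------------------
# PIR simulation
# ---------------------------------------------------------------------------


def simulate_pir(trace: LocationTrace, sensors: Sequence[PIRSensor]) -> list[PIREvent]:
    """Turn a location trace into PIR ON/OFF events.

    Per sensor: ON at the first sample within ``range_cm`` after being out of
    range, OFF at the first sample out of range after being in range.
    Out-of-house samples count as out of range.  Events are merged across
    sensors, ordered by time with sensor id as tie-break; per sensor they
    strictly alternate starting with ON.
    """
    if len(trace.t_s) == 0:
        raise ContractError("trace is empty")
    ids = [s.id for s in sensors]
    if len(set(ids)) != len(ids):
        raise LayoutError("duplicate sensor ids")
    valid = ~trace.out & ~np.isnan(trace.xy).any(axis=1)
    events: list[PIREvent] = []
    for s in sensors:
        d2 = ((trace.xy - s.position) ** 2).sum(axis=1)
        in_range = valid & (d2 <= s.range_cm**2)
        prev = np.concatenate(([False], in_range[:-1]))
        for k in np.flatnonzero(in_range != prev):
            events.append(
                PIREvent(float(trace.t_s[k]), s.id, "ON" if in_range[k] else "OFF")
            )
    events.sort(key=lambda e: (e.t_s, e.sensor_id, e.state == "ON"))
    return events


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def events_to_frame(events: Sequence[PIREvent], init_tod_h: float = 0.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": [e.t_s for e in events],
            "formatted_time": [
                format_sim_time(e.t_s / 3600.0, init_tod_h) for e in events
            ],
            "sensor_id": [e.sensor_id for e in events],
            "state": [e.state for e in events],
        }
    )


def write_events(
    events: Sequence[PIREvent], path: str | Path, init_tod_h: float = 0.0
) -> None:
    """Write PIR events as CSV: time_s, formatted_time, sensor_id, state."""
    events_to_frame(events, init_tod_h).to_csv(path, index=False)


def read_events(path: str | Path) -> list[PIREvent]:
    df = pd.read_csv(path)
    return [
        PIREvent(float(r.time_s), int(r.sensor_id), str(r.state))
        for r in df.itertuples()
    ]


def load_sensors(path: str | Path) -> list[PIRSensor]:
    """Load a JSON sensor list: [{"id", "x", "y", "range_cm"}, ...]."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise LayoutError("sensors file must contain a JSON list")
    sensors = []
    for k, item in enumerate(data):
        try:
            sensors.append(
                PIRSensor(
                    int(item["id"]),
                    float(item["x"]),
                    float(item["y"]),
                    float(item.get("range_cm", DEFAULT_SENSOR_RANGE_CM)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise LayoutError(f"sensor #{k}: invalid entry: {exc}") from exc
    if len({s.id for s in sensors}) != len(sensors):
        raise LayoutError("duplicate sensor ids")
    return sensors


def save_sensors(sensors: Sequence[PIRSensor], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {"id": s.id, "x": s.x, "y": s.y, "range_cm": s.range_cm}
                for s in sensors
            ],
            indent=2,
        )
        + "\n"
    )


def default_sensors_for_layout(
    layout: Layout, n: int = 5, range_cm: float = DEFAULT_SENSOR_RANGE_CM,
    rng: np.random.Generator | int = 0,
) -> list[PIRSensor]:
    """Spread ``n`` sensors across the layout near its places (synthetic helper)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    anchors = [p.position for p in layout.places] or [layout.center()]
    sensors = []
    for k in range(n):
        base = anchors[k % len(anchors)]
        offs = rng.uniform(-50.0, 50.0, size=2)
        x = float(np.clip(base[0] + offs[0], 0.0, layout.width))
        y = float(np.clip(base[1] + offs[1], 0.0, layout.height))
        sensors.append(PIRSensor(k + 1, x, y, range_cm))
    return sensors
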