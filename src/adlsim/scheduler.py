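"""Event-driven schedule generation: the simulator's main loop.

One loop iteration performs the current AS for a sampled actual duration,
sub-stepping the motivation updates (so mid-performance step events and
out-of-house satisfaction land at the right times), applies the completion
decrease, and samples the next AS from the clamped softmax.  Relax — the
pinned fallback — runs in short quanta so selection is re-evaluated
frequently; consecutive identical selections merge, which is what makes the
schedule gapless: every instant of the horizon belongs to exactly one
activity entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __about__
from .catalog import (
    MAIN_ACTIVITY,
    PREPARATION_ACTIVITIES,
    RELAX_AS,
    SEQUENCES,
    WANDER_AS,
    PlaceType,
)
from .config import RunConfig, rng_streams
from .errors import ContractError
from .layout import Layout, effective_sequence, performable_sequences
from .motivation import (
    MotivationState,
    NoiseSpec,
    advance,
    decrease_on_completion,
    initialize,
    nominal_duration,
    outside_satisfaction,
    sample_actual_duration,
    sample_next_as,
    schedule_step_events,
)
from .profiles import IncreaseRates, ResidentProfile, increase_rates, sample_profile
from .timeformat import format_sim_time


@dataclass(frozen=True)
class ScheduleEntry:
    """One activity start.  The entry lasts until the next entry's start."""

    activity: str
    start_h: float
    place_id: str | None
    as_index: int


@dataclass(frozen=True)
class Performance:
    """One AS-level performance (several may merge into one run of entries)."""

    as_index: int
    start_h: float
    duration_h: float


@dataclass
class Schedule:
    """A gapless multi-day activity schedule plus its provenance.

    ``entries`` are activity-level starts tiling ``[0, horizon_h]`` (each
    entry lasts until the next start; the last until the horizon end).
    ``performances`` keep the AS-level history the entries were expanded from.
    ``mv_max`` records the running maximum of each MV over the whole run.
    """

    entries: list[ScheduleEntry]
    horizon_h: float
    init_tod_h: float
    profile: ResidentProfile
    rates: IncreaseRates
    performances: list[Performance]
    mv_max: np.ndarray
    provenance: dict
    mv_trace: np.ndarray | None = None  # optional (n_substeps, 14): clock + 13 MVs

    def activity_labels(self) -> list[str]:
        return [e.activity for e in self.entries]

    def entry_durations(self) -> np.ndarray:
        starts = np.array([e.start_h for e in self.entries] + [self.horizon_h])
        return np.diff(starts)

    def summarize(self) -> pd.DataFrame:
        """Per-AS statistics: performance count, total hours, mean start time of day."""
        if not self.entries:
            raise ContractError("cannot summarize an empty schedule")
        rows = []
        perf = pd.DataFrame(
            [(p.as_index, p.start_h, p.duration_h) for p in self.performances],
            columns=["as_index", "start_h", "duration_h"],
        )
        durs = self.entry_durations()
        ent = pd.DataFrame(
            {
                "as_index": [e.as_index for e in self.entries],
                "hours": durs,
            }
        )
        for i in sorted(SEQUENCES):
            sub = perf[perf.as_index == i]
            rows.append(
                {
                    "as_index": i,
                    "label": SEQUENCES[i].label,
                    "count": int(len(sub)),
                    "total_hours": float(ent.loc[ent.as_index == i, "hours"].sum()),
                    "mean_start_tod_h": float(
                        ((sub.start_h + self.init_tod_h) % 24.0).mean()
                    )
                    if len(sub)
                    else float("nan"),
                }
            )
        return pd.DataFrame(rows).set_index("as_index")

    def to_frame(self, paper_style_time: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "activity": [e.activity for e in self.entries],
                "start_s": [round(e.start_h * 3600.0, 3) for e in self.entries],
                "place_id": [e.place_id or "" for e in self.entries],
                "as_index": [e.as_index for e in self.entries],
            }
        )
        if paper_style_time:
            df["start_time"] = [
                format_sim_time(e.start_h, self.init_tod_h) for e in self.entries
            ]
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "horizon_h": self.horizon_h,
            "init_tod_h": self.init_tod_h,
            "entries": [
                {
                    "activity": e.activity,
                    "start_h": e.start_h,
                    "place_id": e.place_id,
                    "as_index": e.as_index,
                }
                for e in self.entries
            ],
        }


def read_schedule_json(path: str | Path) -> Schedule:
    """Reload a schedule written by :meth:`Schedule.write_json`.

    Only the fields the downstream stages need (entries, horizon, init time,
    provenance) are restored; profile/rates/MV history are not serialized.
    """
    data = json.loads(Path(path).read_text())
    entries = [
        ScheduleEntry(d["activity"], d["start_h"], d["place_id"], d["as_index"])
        for d in data["entries"]
    ]
    return Schedule(
        entries=entries,
        horizon_h=data["horizon_h"],
        init_tod_h=data["init_tod_h"],
        profile=None,  # type: ignore[arg-type]
        rates=None,  # type: ignore[arg-type]
        performances=[],
        mv_max=np.zeros(13),
        provenance=data.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# Expansion of AS performances into activity entries
# ---------------------------------------------------------------------------

_AUX_MIN_H, _AUX_MAX_H = 0.5 / 60.0, 2.0 / 60.0
_PREP_MIN_H, _PREP_MAX_H = 10.0 / 60.0, 25.0 / 60.0


def expand_sequence(
    as_index: int,
    start_h: float,
    at_h: float,
    layout: Layout,
    rng: np.random.Generator,
    prev_pos: np.ndarray | None = None,
) -> list[ScheduleEntry]:
    """Split one AS performance into activity-level entries.

    Non-main activities get short draws (auxiliary steps 0.5-2 min,
    preparation steps such as cooking or running the bath 10-25 min); the
    sequence's main activity absorbs the remainder.  If the draws would eat
    more than half the performance, they are rescaled proportionally.  Each
    activity is pinned to a place instance of an allowed type, nearest to the
    previous activity's place when there are duplicates; wandering, going out
    and relax-without-a-place carry no place id.
    """
    if at_h <= 0:
        raise ContractError(f"expand_sequence: at must be > 0, got {at_h}")
    acts = effective_sequence(as_index, layout)
    main = MAIN_ACTIVITY[as_index]
    durations = np.zeros(len(acts))
    for k, a in enumerate(acts):
        if a.name == main:
            continue
        lo, hi = (
            (_PREP_MIN_H, _PREP_MAX_H)
            if a.name in PREPARATION_ACTIVITIES
            else (_AUX_MIN_H, _AUX_MAX_H)
        )
        durations[k] = rng.uniform(lo, hi)
    side = durations.sum()
    if side > 0.5 * at_h:
        durations *= 0.5 * at_h / side
        side = 0.5 * at_h
    main_idx = next(
        (k for k, a in enumerate(acts) if a.name == main), len(acts) - 1
    )
    durations[main_idx] += at_h - durations.sum()

    entries: list[ScheduleEntry] = []
    pos = prev_pos if prev_pos is not None else layout.center()
    t = start_h
    for a, d in zip(acts, durations):
        place_id: str | None = None
        if a.name == "wander":
            pass  # no fixed place
        else:
            candidates = layout.places_of(a.allowed_places)
            if candidates:
                nearest = min(
                    candidates, key=lambda p: float(np.linalg.norm(p.position - pos))
                )
                place_id = nearest.id
                pos = nearest.position
            # relax with no relax place: stay at the current position
        entries.append(ScheduleEntry(a.name, t, place_id, as_index))
        t += d
    return entries


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------


def generate_schedule(
    layout: Layout,
    total_dur_h: float,
    seed: int | None = None,
    profile: ResidentProfile | None = None,
    config: RunConfig | None = None,
    track_mv: bool = False,
) -> Schedule:
    """Generate a gapless activity schedule over ``total_dur_h`` hours.

    Follows the event-driven loop: determine performable ASs from the layout,
    sample the resident profile (unless given), derive the increase rates,
    initialize MVs with the resident about to sleep, then repeatedly perform
    the current AS for a sampled actual duration, update MVs (sub-stepping so
    step events and out-of-house satisfaction fire mid-performance), apply
    the completion decrease, and sample the next AS from the clamped softmax.
    Deterministic given ``seed``.
    """
    if total_dur_h < 0:
        raise ContractError("total_dur_h must be >= 0")
    config = config or RunConfig()
    if seed is None:
        seed = config.seed
    streams = rng_streams(seed)
    noise = NoiseSpec(config.noise_sigma)

    perf_layout = performable_sequences(layout)
    if profile is None:
        profile = sample_profile(streams["profile"])
    performable = perf_layout - ({2} if not profile.naps else set())
    rates = increase_rates(profile, performable, config.norm_mv)
    state, init_tod = initialize(profile, rates, performable, streams["init"])

    substep_h = config.substep_min / 60.0
    relax_quantum_h = config.relax_quantum_min / 60.0

    current = 1
    t = 0.0
    performances: list[Performance] = []
    mv_max = state.mv.copy()
    trace_rows: list[np.ndarray] | None = [] if track_mv else None
    awaiting_breakfast = False

    while t < total_dur_h:
        if current == RELAX_AS:
            at = relax_quantum_h
        else:
            at = sample_actual_duration(current, profile, streams["at"])
            at = max(at, 1e-6)
        if current == 3:
            schedule_step_events(state, "eating_started", profile)
        state.sleeping = current in (1, 2)
        state.out_of_house = current == 5

        elapsed = 0.0
        while elapsed < at - 1e-12:
            dt = min(substep_h, at - elapsed)
            advance(state, dt, rates, noise, streams["noise"], performing=current)
            elapsed += dt
            if state.out_of_house:
                outside_satisfaction(state, at - elapsed, profile)
            np.maximum(mv_max, state.mv, out=mv_max)
            if trace_rows is not None:
                trace_rows.append(np.concatenate(([state.clock], state.mv)))
        state.sleeping = False
        state.out_of_house = False

        if current == 4 and any(
            a.name == "put clothes in washing machine"
            for a in effective_sequence(4, layout)
        ):
            schedule_step_events(state, "laundry_loaded", profile)
        is_breakfast = current == 3 and awaiting_breakfast
        decrease_on_completion(state, current, at, profile, is_breakfast=is_breakfast)
        if is_breakfast:
            awaiting_breakfast = False
        if current == 1:
            awaiting_breakfast = True

        performances.append(Performance(current, t, at))
        t += at
        current = sample_next_as(state, streams["selection"])

    # Post-process AS-level history into activity-level entries.
    entries: list[ScheduleEntry] = []
    prev_pos = layout.center()
    if not performances:
        # zero-length horizon: the schedule holds just the initial entry
        first = effective_sequence(1, layout)[0] if 1 in performable else None
        name = first.name if first else "relax"
        places = layout.places_of(first.allowed_places) if first else []
        entries.append(ScheduleEntry(name, 0.0, places[0].id if places else None, 1 if first else RELAX_AS))
    for p in performances:
        if p.start_h >= total_dur_h:
            break
        new = expand_sequence(
            p.as_index, p.start_h, p.duration_h, layout, streams["expand"], prev_pos
        )
        for e in new:
            if e.start_h >= total_dur_h and total_dur_h > 0:
                continue
            if entries and (
                entries[-1].activity == e.activity
                and entries[-1].place_id == e.place_id
            ):
                continue  # merge consecutive identical activities (relax quanta)
            entries.append(e)
        if new:
            last_place = next(
                (e.place_id for e in reversed(new) if e.place_id), None
            )
            if last_place is not None:
                prev_pos = next(
                    pl.position for pl in layout.places if pl.id == last_place
                )

    provenance = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "layout_hash": layout.content_hash(),
        "version": __about__.__version__,
        "profile": {
            "D": profile.D,
            "T": profile.T,
            "naps": profile.naps,
        },
    }
    return Schedule(
        entries=entries,
        horizon_h=total_dur_h,
        init_tod_h=init_tod,
        profile=profile,
        rates=rates,
        performances=performances,
        mv_max=mv_max,
        provenance=provenance,
        mv_trace=np.array(trace_rows) if trace_rows else None,
    )
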