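"""Motivation-value dynamics: growth, step events, completion decreases,
initialization and softmax activity selection.

The 13 motivation values (MVs) evolve by a small set of rules:

* non-performable ASs are pinned at 0; relax (AS 13) is pinned at
  ``1.02 * Norm_MV`` — the constant competitive floor every other motivation
  has to beat;
* linear ASs grow at ``omega_i`` per awake hour (eat and toilet-short keep 10%
  of their rate during sleep, everything else freezes), plus small Gaussian
  noise;
* the toilet-long and laundry motivations grow in steps triggered by eating
  and by loading the washing machine;
* completing an AS removes motivation in proportion to the time actually
  spent, scaled so a nominal-length performance removes exactly ``Norm_MV``
  (breakfast removes only two thirds);
* the next AS is sampled from a clamped softmax over the MVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .catalog import LINEAR_AS, RELAX_AS
from .errors import ConfigurationError, ContractError
from .profiles import DEFAULT_NORM_MV, IncreaseRates, ResidentProfile

#: Rule 3.3 actual-duration factor intervals, applied to the nominal
#: per-performance duration D_i.
AT_FACTORS: dict[int, tuple[float, float]] = {
    1: (0.97, 1.03),
    5: (0.4, 0.9),
    8: (0.3, 0.7),
    9: (0.3, 0.7),
}
_DEFAULT_AT_FACTORS = (0.95, 1.05)

#: Delay (h) between the start of eating and the toilet-long motivation step.
EATING_TO_TOILET_DELAY_H = 2.5
#: Delay (h) between loading the washing machine and the laundry motivation step.
LAUNDRY_DELAY_H = 1.0
#: Softmax clamp: only the part of an MV above this fraction of Norm_MV competes.
SOFTMAX_THRESHOLD_FRACTION = 0.98


def at_factor_interval(as_index: int) -> tuple[float, float]:
    return AT_FACTORS.get(as_index, _DEFAULT_AT_FACTORS)


def nominal_duration(as_index: int, profile: ResidentProfile) -> float:
    """Expected sampled actual duration: the factor-interval midpoint times D_i."""
    lo, hi = at_factor_interval(as_index)
    return 0.5 * (lo + hi) * profile.D[as_index]


def sample_actual_duration(
    as_index: int, profile: ResidentProfile, rng: np.random.Generator
) -> float:
    """Draw the actual duration (h) of one AS performance (AS 1..12).

    Uniform over the per-AS factor interval applied to the nominal duration
    D_i.  Relax (AS 13) is excluded: the scheduler runs it in fixed quanta.
    """
    if as_index not in range(1, 13):
        raise ContractError(f"sample_actual_duration: AS index {as_index} not in 1..12")
    lo, hi = at_factor_interval(as_index)
    return float(rng.uniform(lo, hi)) * profile.D[as_index]


@dataclass(frozen=True)
class StepEvent:
    """A scheduled step increase of a step-driven motivation (AS 7 or 11)."""

    fire_time: float  # simulation hours
    target: int
    amount: float

    def __post_init__(self) -> None:
        if self.target not in (7, 11):
            raise ContractError(f"step events only target AS 7 or 11, got {self.target}")


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian noise added per MV update (MV units)."""

    sigma: float = 0.005 * DEFAULT_NORM_MV

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ContractError("noise sigma must be >= 0")


@dataclass
class MotivationState:
    """The 13 MVs plus pending step events and context flags.

    ``mv`` is indexed 0..12 for AS 1..13.  Invariants: non-performable entries
    are 0; entry 13 is pinned at ``1.02 * norm_mv``; all entries finite and
    non-negative.
    """

    mv: np.ndarray
    performable: frozenset[int]
    norm_mv: float = DEFAULT_NORM_MV
    clock: float = 0.0
    pending_steps: list[StepEvent] = field(default_factory=list)
    sleeping: bool = False
    out_of_house: bool = False

    def __post_init__(self) -> None:
        self.mv = np.asarray(self.mv, dtype=float).copy()
        if self.mv.shape != (13,):
            raise ContractError("mv must have 13 entries")
        self.performable = frozenset(self.performable)
        self._enforce_pins()

    def _enforce_pins(self) -> None:
        for i in range(1, 14):
            if i not in self.performable:
                self.mv[i - 1] = 0.0
        self.mv[RELAX_AS - 1] = 1.02 * self.norm_mv
        np.clip(self.mv, 0.0, None, out=self.mv)

    def value(self, as_index: int) -> float:
        return float(self.mv[as_index - 1])


def advance(
    state: MotivationState,
    dt: float,
    rates: IncreaseRates,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
    performing: int | None = None,
) -> MotivationState:
    """Advance the MVs by ``dt`` hours (in place; also returned).

    Linear performable ASs other than the one currently being performed grow
    at ``omega_i * dt`` while awake; during sleep only eat (3) and
    toilet-short (6) grow, at one tenth of their rate.  Noise is added to
    every linear performable AS in all branches.  Pending step events whose
    fire time falls inside ``(clock, clock + dt]`` fire.  MVs are floored at
    0; the relax MV stays pinned.
    """
    if dt < 0:
        raise ContractError(f"advance: dt must be >= 0, got {dt}")
    new_clock = state.clock + dt
    for i in sorted(state.performable & LINEAR_AS):
        if i == performing:
            gain = 0.0
        elif state.sleeping:
            gain = 0.1 * rates.omega[i] * dt if i in (3, 6) else 0.0
        else:
            gain = rates.omega[i] * dt
        if noise is not None and noise.sigma > 0 and rng is not None:
            gain += float(rng.normal(0.0, noise.sigma))
        state.mv[i - 1] += gain
    remaining: list[StepEvent] = []
    for ev in state.pending_steps:
        if state.clock < ev.fire_time <= new_clock:
            if ev.target in state.performable:
                state.mv[ev.target - 1] += ev.amount
        else:
            remaining.append(ev)
    state.pending_steps = remaining
    state.clock = new_clock
    state._enforce_pins()
    return state


def schedule_step_events(
    state: MotivationState, trigger: str, profile: ResidentProfile
) -> MotivationState:
    """Queue the step increase that follows an eating or laundry trigger.

    ``eating_started`` queues a toilet-long step of ``Norm_MV / (3 * T_7)``
    (T_7 in days) 2.5 h ahead; ``laundry_loaded`` queues a full ``Norm_MV``
    laundry step 1 h ahead.  No event is queued when the target AS is not
    performable in the current layout.
    """
    if trigger == "eating_started":
        target, delay = 7, EATING_TO_TOILET_DELAY_H
        amount = state.norm_mv / (3.0 * profile.T[7] / 24.0)
    elif trigger == "laundry_loaded":
        target, delay = 11, LAUNDRY_DELAY_H
        amount = state.norm_mv
    else:
        raise ContractError(f"unknown trigger {trigger!r}")
    if target in state.performable:
        state.pending_steps.append(StepEvent(state.clock + delay, target, amount))
    return state


def decrease_on_completion(
    state: MotivationState,
    as_index: int,
    at: float,
    profile: ResidentProfile,
    is_breakfast: bool = False,
) -> MotivationState:
    """Apply the completion decrease after performing AS ``as_index`` for ``at`` h.

    For linear ASs the decrease is ``(AT / nominal_duration) * Norm_MV`` so
    that a nominal-length performance removes exactly ``Norm_MV`` (the
    stationarity principle); breakfast — the first meal after night sleep —
    removes only two thirds of that.  Step-driven ASs (7, 11) grow in
    ``Norm_MV``-sized quanta, so completing them clears exactly one quantum
    regardless of the few minutes the routine took.  Relax (13) never
    decreases; results are floored at 0.
    """
    if at <= 0:
        raise ContractError(f"decrease_on_completion: at must be > 0, got {at}")
    if as_index == RELAX_AS:
        return state
    if as_index not in state.performable:
        raise ContractError(f"AS {as_index} is not performable")
    if as_index in (7, 11):
        drop = state.norm_mv
    else:
        drop = (at / nominal_duration(as_index, profile)) * state.norm_mv
    if as_index == 3 and is_breakfast:
        drop *= 2.0 / 3.0
    state.mv[as_index - 1] = max(0.0, state.mv[as_index - 1] - drop)
    return state


def outside_satisfaction(
    state: MotivationState, remaining_out: float, profile: ResidentProfile
) -> MotivationState:
    """Satisfy eat/toilet motivations while the resident is out of the house.

    For i in {3, 6, 7}: when MV_i has reached Norm_MV and enough of the outing
    remains (``remaining_out >= D_i``), the AS is considered performed outside
    (no indoor activity is emitted) and the completion decrease is applied
    with ``AT = D_i``.
    """
    if not state.out_of_house:
        raise ContractError("outside_satisfaction called while not out of house")
    for i in (3, 6, 7):
        if (
            i in state.performable
            and state.mv[i - 1] >= state.norm_mv
            and remaining_out >= profile.D[i]
        ):
            decrease_on_completion(state, i, profile.D[i], profile)
    return state


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

#: Start-of-simulation window, hours of day: 9:30 PM to 1:00 AM next day.
INIT_WINDOW_H = (21.5, 25.0)
#: ASs longer than this are staggered so their first performances don't collide.
_LONG_AS_HOURS = 0.5
_STAGGER_MIN_GAP_H = 0.25


def initialize(
    profile: ResidentProfile,
    rates: IncreaseRates,
    performable: Iterable[int],
    rng: np.random.Generator,
) -> tuple[MotivationState, float]:
    """Initial MV vector and start time of day.

    The simulation starts between 21:30 and 01:00 with the resident about to
    sleep: MV_1 = Norm_MV.  Every other linear AS is positioned so that it
    first reaches Norm_MV after a planned awake gap g_i, i.e.
    ``MV_i = Norm_MV - (sleep gain during the first night) - omega_i * g_i``;
    the sleep-gain term ``0.1 * omega_i * D_1`` exists only for eat and
    toilet-short, the two motivations that grow during sleep.  Gaps of
    long-duration ASs are staggered by at least 15 minutes so their first
    performances cannot collide.  Step-driven MVs (7, 11) start at 0, relax is
    pinned at 1.02 Norm_MV.
    """
    performable = frozenset(performable)
    norm = rates.norm_mv
    init_tod = float(rng.uniform(*INIT_WINDOW_H))
    awake_day = 24.0 - profile.sleep_hours_per_day

    gaps: dict[int, float] = {}
    for i in sorted(performable & LINEAR_AS - {1}):
        omega = rates.omega[i]
        if omega <= 0:
            continue
        sleep_gain = 0.1 * omega * profile.D[1] if i in (3, 6) else 0.0
        if i == 3:
            gaps[i] = float(rng.uniform(0.5, 1.5))  # breakfast ~1 h after waking
        else:
            g_max = min(awake_day, max(0.0, (norm - sleep_gain) / omega))
            gaps[i] = float(rng.uniform(0.1, 0.9)) * g_max

    # stagger first-threshold times of long ASs at least 15 min apart
    long_as = sorted(
        (i for i in gaps if profile.D[i] > _LONG_AS_HOURS), key=lambda i: gaps[i]
    )
    last = -math.inf
    for i in long_as:
        if gaps[i] < last + _STAGGER_MIN_GAP_H:
            gaps[i] = last + _STAGGER_MIN_GAP_H
        last = gaps[i]
        if gaps[i] > 2.0 * max(awake_day, 1.0):
            raise ConfigurationError(
                "cannot stagger first performances: too many long ASs for the "
                f"available awake time ({awake_day:.1f} h)"
            )

    mv = np.zeros(13)
    mv[0] = norm  # about to sleep
    for i, g in gaps.items():
        omega = rates.omega[i]
        sleep_gain = 0.1 * omega * profile.D[1] if i in (3, 6) else 0.0
        mv[i - 1] = max(0.0, norm - sleep_gain - omega * g)
    state = MotivationState(mv=mv, performable=performable, norm_mv=norm)
    return state, init_tod


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def selection_probabilities(state: MotivationState) -> np.ndarray:
    """Clamped-softmax selection probabilities over the 13 ASs.

    ``P_i ∝ exp(max(0, MV_i - 0.98 Norm_MV))`` for performable i, 0 otherwise,
    normalized over the performable set.  Computed with a log-sum-exp shift so
    large MVs cannot overflow.
    """
    idx = np.array(sorted(state.performable), dtype=int)
    if idx.size == 0:
        raise ContractError("no performable AS (relax should always be performable)")
    expo = np.maximum(0.0, state.mv[idx - 1] - SOFTMAX_THRESHOLD_FRACTION * state.norm_mv)
    expo -= expo.max()
    w = np.exp(expo)
    p = np.zeros(13)
    p[idx - 1] = w / w.sum()
    return p


def sample_next_as(state: MotivationState, rng: np.random.Generator) -> int:
    """Sample the next AS index (1..13) from the selection probabilities."""
    p = selection_probabilities(state)
    return int(rng.choice(13, p=p)) + 1
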