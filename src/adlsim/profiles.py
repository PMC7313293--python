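"""Resident behavioural profiles and motivation increase rates.

A profile fixes, per activity sequence i, the nominal duration ``D_i`` (hours
spent per period), the period ``T_i`` (hours between performances) and the
frequency ``f_i = 1/T_i``.  The *increase rate* ``omega_i`` is derived from
the profile so that, in the noise-free ideal case, a motivation gains exactly
``Norm_MV`` over one period and one nominal performance removes exactly
``Norm_MV`` — the stationarity principle that keeps multi-week schedules
stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .catalog import LINEAR_AS, RELAX_AS
from .errors import ConfigurationError, ProfileError

#: Default reference motivation scale.  All dynamics are scale-free in
#: Norm_MV except selection sharpness: the softmax exponentiates absolute MV
#: differences (MV - 0.98*Norm_MV), so the scale decides how often an AS whose
#: motivation is still below threshold gets picked anyway.  At 200 the pinned
#: relax motivation (1.02*Norm_MV) carries weight e^8, so a sub-threshold AS
#: is picked with probability under e^-8 per draw: rare activities keep their
#: profile periodicity (a resident with a four-day going-out period really
#: goes out about every four days) while ASs crossing threshold still race
#: stochastically within the 4%-of-Norm_MV competition window.
DEFAULT_NORM_MV: float = 200.0

#: Per-AS sampling intervals for (D_i, T_i), hours.  ``T`` entries that are
#: tuples are uniform intervals; lists are discrete choices.  AS 13 (relax)
#: has no D/T: it is the fallback state, run in short quanta.
DEFAULT_PROFILE_INTERVALS: dict[int, dict] = {
    1: {"D": (7.0, 9.0), "T": (24.0, 24.0)},       # night sleep, daily
    2: {"D": (0.5, 1.5), "T": (24.0, 24.0)},       # noon nap (50% of residents)
    3: {"D": (0.75, 1.5), "T": (8.0, 8.0)},        # eat, ~3 meals/day
    4: {"D": (0.3, 0.8), "T": (24.0, 24.0)},       # bath, daily
    5: {"D": (1.0, 4.0), "T": [24.0, 48.0, 72.0, 96.0]},  # go out
    6: {"D": (0.05, 0.05), "T": (3.0, 5.0)},       # toilet, short
    7: {"D": (0.15, 0.3), "T": (24.0, 24.0)},      # toilet, long, daily
    8: {"D": (2.0, 5.0), "T": (24.0, 24.0)},       # watch TV, daily
    9: {"D": (0.5, 2.0), "T": (24.0, 24.0)},       # read, daily
    10: {"D": (0.3, 1.0), "T": (24.0, 72.0)},      # clean
    11: {"D": (0.1, 0.1), "T": (24.0, 24.0)},      # unload laundry
    12: {"D": (0.1, 0.3), "T": (24.0, 96.0)},      # wander
}

#: Probability that a sampled resident takes noon naps at all.
NAP_PROBABILITY: float = 0.5

_PROFILE_INDICES = tuple(sorted(DEFAULT_PROFILE_INTERVALS))


@dataclass(frozen=True)
class ResidentProfile:
    """Per-AS nominal durations ``D`` (h), periods ``T`` (h) and nap habit."""

    D: dict[int, float]
    T: dict[int, float]
    naps: bool = True

    def __post_init__(self) -> None:
        for i in _PROFILE_INDICES:
            if i not in self.D or i not in self.T:
                raise ProfileError(f"profile missing AS {i}")
            d, t = self.D[i], self.T[i]
            if not (t > 0):
                raise ProfileError(f"AS {i}: period T must be positive, got {t}")
            if not (0 <= d <= t):
                raise ProfileError(f"AS {i}: need 0 <= D <= T, got D={d}, T={t}")

    @property
    def f(self) -> dict[int, float]:
        """Frequencies f_i = 1/T_i (per hour)."""
        return {i: 1.0 / self.T[i] for i in self.T}

    @property
    def sleep_hours_per_day(self) -> float:
        """Expected daily sleep: night sleep plus the nap when the resident naps."""
        return self.D[1] + (self.D[2] if self.naps else 0.0)

    def with_overrides(self, overrides: Mapping) -> "ResidentProfile":
        D, T = dict(self.D), dict(self.T)
        naps = self.naps
        for key, val in overrides.items():
            if key == "naps":
                naps = bool(val)
                continue
            i = int(key)
            if i not in DEFAULT_PROFILE_INTERVALS:
                raise ProfileError(f"override for unknown AS index {i}")
            if not isinstance(val, Mapping):
                raise ProfileError(f"override for AS {i} must be a mapping")
            if "D_h" in val:
                D[i] = float(val["D_h"])
            if "T_h" in val:
                T[i] = float(val["T_h"])
        return ResidentProfile(D, T, naps)


def sample_profile(
    seed: int | np.random.Generator,
    overrides: Mapping | None = None,
) -> ResidentProfile:
    """Draw a resident profile from the default intervals, then apply overrides.

    Deterministic given the seed.  Overrides are a partial mapping
    ``{as_index: {"D_h": float, "T_h": float}, "naps": bool}`` and are
    validated against the profile invariants.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D: dict[int, float] = {}
    T: dict[int, float] = {}
    for i in _PROFILE_INDICES:
        spec = DEFAULT_PROFILE_INTERVALS[i]
        lo, hi = spec["D"]
        D[i] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        t = spec["T"]
        if isinstance(t, list):
            T[i] = float(rng.choice(t))
        else:
            lo, hi = t
            T[i] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    naps = bool(rng.random() < NAP_PROBABILITY)
    profile = ResidentProfile(D, T, naps)
    if overrides:
        profile = profile.with_overrides(overrides)
    return profile


def load_profile_overrides(path: str | Path) -> dict:
    """Read a YAML/JSON partial-profile file usable as ``overrides``."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ProfileError(f"profile file {path} must contain a mapping")
    return data


def save_profile(profile: ResidentProfile, path: str | Path) -> None:
    data = {
        str(i): {"D_h": profile.D[i], "T_h": profile.T[i]} for i in _PROFILE_INDICES
    }
    data["naps"] = profile.naps
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# Increase rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IncreaseRates:
    """Linear motivation growth rates omega_i (MV units/hour) plus Norm_MV."""

    omega: dict[int, float]
    norm_mv: float = DEFAULT_NORM_MV

    def __post_init__(self) -> None:
        if self.norm_mv <= 0:
            raise ConfigurationError("norm_mv must be positive")


def growth_time_per_period(profile: ResidentProfile, as_index: int) -> float:
    """Full-rate-equivalent hours per period during which MV_i grows.

    Sleep is prorated into each period as ``S_i = sleep_per_day * T_i / 24``.
    While asleep, only the eat and toilet-short motivations keep growing, at
    10% rate; the sleep sequences themselves are performed *during* sleep so
    their own duration is not subtracted twice.
    """
    i = as_index
    T = profile.T[i]
    S = profile.sleep_hours_per_day * T / profile.T[1]
    if i in (1, 2):
        return T - S
    if i in (3, 6):
        return T - profile.D[i] - 0.9 * S
    return T - S - profile.D[i]


def increase_rates(
    profile: ResidentProfile,
    performable: Iterable[int],
    norm_mv: float = DEFAULT_NORM_MV,
) -> IncreaseRates:
    """Derive omega_i so each linear motivation gains Norm_MV per period.

    omega_i = Norm_MV / (growth time per period); zero for step-driven ASs
    (7, 11), for the pinned relax motivation (13), and for non-performable ASs.
    Raises :class:`ConfigurationError` when a profile leaves an AS no awake
    time to grow in.
    """
    performable = set(performable)
    if not profile.naps:
        performable -= {2}
    omega: dict[int, float] = {i: 0.0 for i in range(1, 14)}
    for i in sorted(performable & LINEAR_AS):
        denom = growth_time_per_period(profile, i)
        if denom <= 0:
            raise ConfigurationError(
                f"AS {i}: profile leaves no time for the motivation to grow "
                f"(T={profile.T[i]} h, D={profile.D[i]} h, "
                f"sleep={profile.sleep_hours_per_day} h/day)"
            )
        omega[i] = norm_mv / denom
    return IncreaseRates(omega, norm_mv)
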