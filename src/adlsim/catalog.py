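"""Fixed catalog of places, activities and activity sequences.

A single resident is modelled as holding up to 13 motivations, one per
*activity sequence* (AS): an ordered run of activities performed back-to-back
to satisfy that motivation (e.g. hunger: take food -> cook -> take tableware
-> eat).  Each activity is tied to the set of place types where it can happen;
a house layout that lacks every place of an activity simply cannot host that
activity.  The catalog below is the closed vocabulary the whole simulator is
built on: 14 place labels (13 physical + the pseudo-place ``none``), 19
activities, 13 sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable


class PlaceType(str, Enum):
    """Closed set of place labels: 13 physical place types plus ``none``.

    ``none`` is a pseudo-place for activities (wandering) that need no
    furniture at all.
    """

    BED = "bed"
    BATHROOM = "bathroom"
    REFRIGERATOR = "refrigerator"
    CUPBOARD = "cupboard"
    KITCHEN_STOVE = "kitchen stove"
    DINING_TABLE = "dining table-chair set"
    WASHING_MACHINE = "washing machine"
    TOILET = "toilet"
    SOFA_TV = "sofa-TV set"
    WRITING_DESK = "writing desk-chair set"
    WARDROBE = "wardrobe"
    ENTRANCE = "entrance"
    TRASH_BIN = "trash bin"
    NONE = "none"


#: The 13 physical place types (everything except the pseudo-place).
PHYSICAL_PLACE_TYPES: frozenset[PlaceType] = frozenset(
    p for p in PlaceType if p is not PlaceType.NONE
)


@dataclass(frozen=True)
class Activity:
    """One nameable thing the resident does, and where it can be done."""

    name: str
    allowed_places: frozenset[PlaceType]

    def __post_init__(self) -> None:
        if not self.allowed_places:
            raise ValueError(f"activity {self.name!r} has no allowed place")


def _act(name: str, *places: PlaceType) -> Activity:
    return Activity(name, frozenset(places))


#: Activity -> place mapping.  19 distinct activities.
ACTIVITIES: dict[str, Activity] = {
    a.name: a
    for a in [
        _act("sleep (at night)", PlaceType.BED),
        _act("sleep (at noon)", PlaceType.BED),
        # relax can happen in bed, on the sofa, or at the writing desk
        _act("relax", PlaceType.BED, PlaceType.SOFA_TV, PlaceType.WRITING_DESK),
        _act("wash and brush teeth", PlaceType.BATHROOM),
        _act("take a bath", PlaceType.BATHROOM),
        _act("take food", PlaceType.REFRIGERATOR, PlaceType.KITCHEN_STOVE),
        _act("take tableware", PlaceType.CUPBOARD, PlaceType.KITCHEN_STOVE),
        _act("cook", PlaceType.KITCHEN_STOVE),
        _act("eat", PlaceType.DINING_TABLE),
        _act("put clothes in washing machine", PlaceType.WASHING_MACHINE),
        _act("take clothes out of washing machine", PlaceType.WASHING_MACHINE),
        _act("go to toilet (short duration)", PlaceType.TOILET),
        _act("go to toilet (long duration)", PlaceType.TOILET),
        _act("watch TV", PlaceType.SOFA_TV),
        _act("read", PlaceType.WRITING_DESK),
        _act("get dressed", PlaceType.WARDROBE),
        _act("clean", PlaceType.TRASH_BIN),
        _act("go out", PlaceType.ENTRANCE),
        _act("wander", PlaceType.NONE),
    ]
}


@dataclass(frozen=True)
class ActivitySequence:
    """Ordered list of activities satisfying one motivation (AS_1 .. AS_13)."""

    index: int
    label: str
    activities: tuple[Activity, ...]

    def activity_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.activities)


def _seq(index: int, label: str, *names: str) -> ActivitySequence:
    return ActivitySequence(index, label, tuple(ACTIVITIES[n] for n in names))


#: The 13 motivation-AS pairs, in index order.
SEQUENCES: dict[int, ActivitySequence] = {
    s.index: s
    for s in [
        _seq(1, "night sleep", "wash and brush teeth", "sleep (at night)", "wash and brush teeth"),
        _seq(2, "noon nap", "sleep (at noon)"),
        _seq(3, "eat", "take food", "cook", "take tableware", "eat"),
        _seq(4, "bath", "take a bath", "get dressed", "put clothes in washing machine"),
        _seq(5, "go out", "get dressed", "go out", "get dressed"),
        _seq(6, "toilet (short)", "go to toilet (short duration)"),
        _seq(7, "toilet (long)", "go to toilet (long duration)"),
        _seq(8, "watch TV", "watch TV"),
        _seq(9, "read", "read"),
        _seq(10, "clean", "clean"),
        _seq(11, "unload laundry", "take clothes out of washing machine"),
        _seq(12, "wander", "wander"),
        _seq(13, "relax", "relax"),
    ]
}

ALL_AS_INDICES: frozenset[int] = frozenset(SEQUENCES)

#: The activity that carries an AS's purpose; it absorbs whatever time the
#: short auxiliary steps do not use when an AS performance is expanded.
MAIN_ACTIVITY: dict[int, str] = {
    1: "sleep (at night)",
    2: "sleep (at noon)",
    3: "eat",
    4: "take a bath",
    5: "go out",
    6: "go to toilet (short duration)",
    7: "go to toilet (long duration)",
    8: "watch TV",
    9: "read",
    10: "clean",
    11: "take clothes out of washing machine",
    12: "wander",
    13: "relax",
}

#: Preparation activities get 10-25 min when an AS is expanded; every other
#: non-main activity is a short auxiliary step (0.5-2 min).
PREPARATION_ACTIVITIES: frozenset[str] = frozenset({"cook", "take a bath"})

#: ASs whose motivation rises while the others are active (linear growth);
#: 7 and 11 are step-driven, 13 is pinned constant.
LINEAR_AS: frozenset[int] = frozenset(ALL_AS_INDICES - {7, 11, 13})

#: The relax sequence: the model's fallback, always performable.
RELAX_AS = 13
WANDER_AS = 12


def sequences_performable_from_types(present: Iterable[PlaceType]) -> set[int]:
    """AS indices performable given just the *set* of place types present.

    An AS is performable when at least one of its activities has an allowed
    place available (``none`` is always available).  Relax (AS 13) is always
    performable: it is the fallback state, carried out at the resident's
    current position when no relax place exists.
    """
    present = set(present) | {PlaceType.NONE}
    out: set[int] = set()
    for idx, seq in SEQUENCES.items():
        if idx == RELAX_AS or any(
            a.allowed_places & present for a in seq.activities
        ):
            out.add(idx)
    return out
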