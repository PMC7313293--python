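"""House layouts: place instances with coordinates, layout I/O, fixtures.

Coordinates are centimetres in a 2-D plane.  A layout's ``bounds`` is the
axis-aligned rectangle ``[0, w] x [0, h]``; every place instance must lie
inside it.  Which activity sequences the resident can perform — and which
activities inside each sequence — is decided purely by which place *types*
are present.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .catalog import (
    ACTIVITIES,
    PHYSICAL_PLACE_TYPES,
    RELAX_AS,
    SEQUENCES,
    Activity,
    PlaceType,
    sequences_performable_from_types,
)
from .errors import ContractError, LayoutError


@dataclass(frozen=True)
class Place:
    """One furniture/fixture instance at a position (cm)."""

    place_type: PlaceType
    x: float
    y: float
    id: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise LayoutError(f"place {self.id!r}: coordinates must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Layout:
    """A set of place instances inside rectangular bounds (cm)."""

    places: tuple[Place, ...]
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise LayoutError("layout bounds must be positive")
        for p in self.places:
            if not (0 <= p.x <= self.width and 0 <= p.y <= self.height):
                raise LayoutError(
                    f"place {p.id!r} at ({p.x}, {p.y}) lies outside "
                    f"bounds [0,{self.width}] x [0,{self.height}]"
                )

    @property
    def place_types(self) -> frozenset[PlaceType]:
        return frozenset(p.place_type for p in self.places)

    def places_of(self, types: Iterable[PlaceType]) -> list[Place]:
        wanted = set(types)
        return [p for p in self.places if p.place_type in wanted]

    def center(self) -> np.ndarray:
        return np.array([self.width / 2.0, self.height / 2.0])

    def content_hash(self) -> str:
        import hashlib

        blob = json.dumps(_layout_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def performable_sequences(layout: Layout) -> set[int]:
    """AS indices the resident can perform in ``layout``.

    Presence of place *types* is all that matters; relax (AS 13) is always
    included as the fallback state.
    """
    return sequences_performable_from_types(layout.place_types)


def effective_sequence(as_index: int, layout: Layout) -> list[Activity]:
    """The activities of AS ``as_index`` actually executable in ``layout``.

    Activities whose places are all missing are omitted, preserving order —
    e.g. without stove/refrigerator/cupboard, the eating sequence collapses to
    just ``eat`` (food prepared by someone outside).  Raises
    :class:`ContractError` when the AS is not performable at all.
    """
    if as_index not in SEQUENCES:
        raise ContractError(f"unknown AS index {as_index}")
    present = set(layout.place_types) | {PlaceType.NONE}
    acts = [a for a in SEQUENCES[as_index].activities if a.allowed_places & present]
    if as_index == RELAX_AS and not acts:
        # relax falls back to the current position when no relax place exists
        return [ACTIVITIES["relax"]]
    if not acts:
        raise ContractError(
            f"AS {as_index} ({SEQUENCES[as_index].label}) is not performable "
            "in this layout"
        )
    return acts


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

_TYPE_BY_LABEL = {p.value: p for p in PlaceType}


def _layout_to_dict(layout: Layout) -> dict:
    return {
        "bounds": {"w": layout.width, "h": layout.height},
        "places": [
            {"type": p.place_type.value, "x": p.x, "y": p.y, "id": p.id}
            for p in layout.places
        ],
    }


def layout_from_dict(data: dict) -> Layout:
    """Build and validate a Layout from the JSON structure."""
    if not isinstance(data, dict):
        raise LayoutError("layout file must contain a JSON object")
    try:
        bounds = data["bounds"]
        w, h = float(bounds["w"]), float(bounds["h"])
        raw_places = data["places"]
    except (KeyError, TypeError, ValueError) as exc:
        raise LayoutError(f"layout file missing/invalid field: {exc}") from exc
    if not isinstance(raw_places, list):
        raise LayoutError("'places' must be a list")
    places = []
    for k, item in enumerate(raw_places):
        label = item.get("type")
        if label not in _TYPE_BY_LABEL:
            raise LayoutError(
                f"place #{k}: unknown place type {label!r}; valid types: "
                + ", ".join(sorted(_TYPE_BY_LABEL))
            )
        if _TYPE_BY_LABEL[label] is PlaceType.NONE:
            raise LayoutError(f"place #{k}: the pseudo-place 'none' cannot be placed")
        try:
            x, y = float(item["x"]), float(item["y"])
        except (KeyError, TypeError, ValueError) as exc:
            raise LayoutError(f"place #{k}: invalid coordinates: {exc}") from exc
        places.append(Place(_TYPE_BY_LABEL[label], x, y, str(item.get("id", f"p{k}"))))
    return Layout(tuple(places), w, h)


def load_layout(path: str | Path) -> Layout:
    """Load a layout JSON file, validating against the closed place-type set."""
    path = Path(path)
    if not path.exists():
        raise LayoutError(f"layout file not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LayoutError(f"layout file {path} is not valid JSON: {exc}") from exc
    return layout_from_dict(data)


def save_layout(layout: Layout, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_layout_to_dict(layout), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

#: Fig. 2-style layout: everything except the writing desk and washing machine.
FIG2_STYLE_PLACE_TYPES: frozenset[PlaceType] = frozenset(
    PHYSICAL_PLACE_TYPES - {PlaceType.WRITING_DESK, PlaceType.WASHING_MACHINE}
)


def generate_fixture_layout(
    seed: int | np.random.Generator,
    include: Iterable[PlaceType | str] | None = None,
    width: float = 900.0,
    height: float = 600.0,
    min_separation_cm: float = 80.0,
) -> Layout:
    """Deterministically generate a synthetic house layout.

    One place instance per requested type (default: all 13 physical types),
    positioned by rejection sampling so instances are at least
    ``min_separation_cm`` apart and at least 50 cm from the walls.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if include is None:
        types: list[PlaceType] = sorted(PHYSICAL_PLACE_TYPES, key=lambda p: p.value)
    else:
        types = []
        for t in include:
            if isinstance(t, PlaceType):
                pt = t
            elif isinstance(t, str) and t in _TYPE_BY_LABEL:
                pt = _TYPE_BY_LABEL[t]
            else:
                raise LayoutError(f"unknown place type in include: {t!r}")
            if pt is PlaceType.NONE:
                raise LayoutError("the pseudo-place 'none' cannot be included")
            types.append(pt)
        types = sorted(set(types), key=lambda p: p.value)
    margin = 50.0
    positions: list[np.ndarray] = []
    places: list[Place] = []
    for k, pt in enumerate(types):
        for _ in range(10_000):
            pos = rng.uniform(
                [margin, margin], [width - margin, height - margin]
            )
            if all(np.linalg.norm(pos - q) >= min_separation_cm for q in positions):
                break
        else:  # pragma: no cover - only reachable with absurd bounds
            raise LayoutError("could not place all fixtures without overlap")
        positions.append(pos)
        places.append(Place(pt, round(float(pos[0]), 1), round(float(pos[1]), 1), f"p{k}"))
    return Layout(tuple(places), width, height)
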