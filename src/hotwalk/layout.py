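"""Room layout: nine floor sections, nine household items, five hiding places.

The virtual living room floor is divided into a 3 x 3 grid of sections
(labels ``S1``..``S9``, row-major from the near-left corner).  Five sections
are hiding places holding one or two items each, for nine hidden items total.
The layout doubles as the answer key for scoring: which items exist, where
each was hidden, and the four options shown on each recognition trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import ValidationError
from .trajectory import ArenaConfig

CATEGORIES = ("tools and electronics", "foods", "wearable things", "other things")

#: The nine hidden items with their categories, in presentation order.
ITEMS: tuple[tuple[str, str], ...] = (
    ("Camera", "tools and electronics"),
    ("Baseball", "other things"),
    ("Glasses", "wearable things"),
    ("Apple", "foods"),
    ("Keys", "other things"),
    ("Banana", "foods"),
    ("Table clock", "tools and electronics"),
    ("Shoes", "wearable things"),
    ("Candle", "other things"),
)

SECTION_LABELS = tuple(f"S{i}" for i in range(1, 10))

#: Distractor pool for the 4-option recognition trials: common household
#: objects that were never hidden, three per trial.
DISTRACTOR_POOL: tuple[str, ...] = (
    "Umbrella", "Notebook", "Spoon",
    "Tennis ball", "Dice", "Marble",
    "Hat", "Scarf", "Watch",
    "Orange", "Grape", "Carrot",
    "Coin", "Remote control", "Pen",
    "Bread", "Milk carton", "Egg",
    "Radio", "Flashlight", "Calculator",
    "Slippers", "Gloves", "Belt",
    "Vase", "Photo frame", "Matchbox",
)


def _norm(name: str) -> str:
    """Canonical item-name form: case-folded, whitespace-trimmed."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class RoomLayout:
    """Sections, items and the item -> hiding-section assignment."""

    sections: tuple[str, ...] = SECTION_LABELS
    hiding_sections: tuple[str, ...] = ()
    items: tuple[tuple[str, str], ...] = ITEMS
    item_assignments: dict = field(default_factory=dict)
    recognition_options: tuple[tuple[str, ...], ...] = ()
    arena: ArenaConfig = field(default_factory=ArenaConfig)

    def __post_init__(self):
        if len(self.sections) != 9:
            raise ValidationError("a layout needs exactly 9 sections")
        if len(set(self.hiding_sections)) != 5:
            raise ValidationError("a layout needs exactly 5 distinct hiding sections")
        if not set(self.hiding_sections) <= set(self.sections):
            raise ValidationError("hiding sections must be among the 9 sections")
        if len(self.items) != 9 or len({n for n, _ in self.items}) != 9:
            raise ValidationError("a layout needs 9 distinct items")
        for name, cat in self.items:
            if cat not in CATEGORIES:
                raise ValidationError(f"unknown category {cat!r} for item {name!r}")
        if set(self.item_assignments) != {n for n, _ in self.items}:
            raise ValidationError("every item must be assigned to a hiding section")
        loads = self.section_loads()
        if set(loads) != set(self.hiding_sections):
            raise ValidationError("items may only be assigned to hiding sections")
        if any(not 1 <= k <= 2 for k in loads.values()):
            raise ValidationError("each hiding section must hold 1 or 2 items")
        if len(self.recognition_options) != 9:
            raise ValidationError("need 4 recognition options for each of 9 trials")
        for (name, _), opts in zip(self.items, self.recognition_options):
            if len(opts) != 4 or name not in opts:
                raise ValidationError(
                    f"recognition trial for {name!r} must list 4 options "
                    "including the hidden item"
                )

    def section_loads(self) -> dict[str, int]:
        """Number of items hidden in each hiding section."""
        loads: dict[str, int] = {}
        for sec in self.item_assignments.values():
            loads[sec] = loads.get(sec, 0) + 1
        return loads

    def item_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.items)

    def section_centroid(self, label: str) -> tuple[float, float]:
        """Centroid of a section cell on the 3 x 3 grid over the arena."""
        i = self.sections.index(label)
        row, col = divmod(i, 3)
        w, d = self.arena.width_m / 3, self.arena.depth_m / 3
        return ((col + 0.5) * w, (row + 0.5) * d)

    def section_bounds(self, label: str) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of a section cell."""
        i = self.sections.index(label)
        row, col = divmod(i, 3)
        w, d = self.arena.width_m / 3, self.arena.depth_m / 3
        return (col * w, (col + 1) * w, row * d, (row + 1) * d)

    def to_dict(self) -> dict:
        return {
            "sections": list(self.sections),
            "hiding_sections": list(self.hiding_sections),
            "items": [list(it) for it in self.items],
            "item_assignments": dict(self.item_assignments),
            "recognition_options": [list(o) for o in self.recognition_options],
            "arena": {
                "width_m": self.arena.width_m,
                "depth_m": self.arena.depth_m,
                "rate_hz": self.arena.rate_hz,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoomLayout":
        arena = ArenaConfig(**d.get("arena", {}))
        return cls(
            sections=tuple(d["sections"]),
            hiding_sections=tuple(d["hiding_sections"]),
            items=tuple((n, c) for n, c in d["items"]),
            item_assignments=dict(d["item_assignments"]),
            recognition_options=tuple(tuple(o) for o in d["recognition_options"]),
            arena=arena,
        )


def write_layout(layout: RoomLayout, path) -> None:
    with open(path, "w") as fh:
        json.dump(layout.to_dict(), fh, indent=2, sort_keys=True)


def read_layout(path) -> RoomLayout:
    with open(path) as fh:
        return RoomLayout.from_dict(json.load(fh))


# Fixture assignment: five hiding sections spread over the grid (the center
# section S5 holds the start box and hides nothing), loads 2+2+2+2+1.
_DEFAULT_ASSIGNMENT = {
    "Camera": "S1",
    "Baseball": "S1",
    "Glasses": "S3",
    "Apple": "S3",
    "Keys": "S6",
    "Banana": "S6",
    "Table clock": "S7",
    "Shoes": "S7",
    "Candle": "S9",
}


def default_layout(arena: ArenaConfig | None = None) -> RoomLayout:
    """The packaged room-layout fixture.

    Nine items in four household categories, hidden across five of the nine
    floor sections with one or two items per section.  Recognition trials
    pair each hidden item with three never-hidden distractors.
    """
    arena = arena or ArenaConfig()
    options = tuple(
        (name,) + DISTRACTOR_POOL[3 * i: 3 * i + 3]
        for i, (name, _) in enumerate(ITEMS)
    )
    return RoomLayout(
        hiding_sections=("S1", "S3", "S6", "S7", "S9"),
        item_assignments=dict(_DEFAULT_ASSIGNMENT),
        recognition_options=options,
        arena=arena,
    )
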