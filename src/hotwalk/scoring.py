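"""Scoring of Hidden Objects Test (HOT) response records.

Five subtests with maxima 3 + 9 + 9 + 9 + 9 = 39 points:

* prospective memory — three end-of-test instructions executed (0-3);
* item free-recall   — hidden item names recalled in any order (0-9);
* place free-recall  — hidden placements marked with stickers (0-9);
* item recognition   — nine 4-option forced-choice trials (0-9);
* place-item matching — correct furniture reached for each item (0-9).

Place free-recall is scored per hidden *placement*: a section hiding two
items is worth two points and may be marked twice (one sticker per
placement), which is the only reading consistent with a 9-point maximum
spread over five hiding sections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .layout import RoomLayout, _norm

SUBTESTS = ("prospective", "item_recall", "place_recall", "recognition", "matching")
SUBTEST_MAXIMA = {"prospective": 3, "item_recall": 9, "place_recall": 9,
                  "recognition": 9, "matching": 9}
TOTAL_MAX = 39


@dataclass(frozen=True)
class ResponseRecord:
    """One participant's raw answers to the five subtests."""

    prospective_actions: tuple[bool, bool, bool]
    recalled_items: tuple[str, ...]
    marked_sections: tuple[str, ...]
    recognition_choices: tuple[str, ...]
    matching_reached: tuple[bool, ...]

    def __post_init__(self):
        if len(self.prospective_actions) != 3:
            raise ValidationError("prospective_actions must have exactly 3 entries")
        if len(self.recognition_choices) != 9:
            raise ValidationError("recognition_choices must have exactly 9 entries")
        if len(self.matching_reached) != 9:
            raise ValidationError("matching_reached must have exactly 9 entries")

    def to_dict(self) -> dict:
        return {
            "prospective": list(self.prospective_actions),
            "recalled": list(self.recalled_items),
            "marked": list(self.marked_sections),
            "recognition": list(self.recognition_choices),
            "matching": list(self.matching_reached),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseRecord":
        return cls(
            prospective_actions=tuple(bool(v) for v in d["prospective"]),
            recalled_items=tuple(d["recalled"]),
            marked_sections=tuple(d["marked"]),
            recognition_choices=tuple(d["recognition"]),
            matching_reached=tuple(bool(v) for v in d["matching"]),
        )


@dataclass(frozen=True)
class HotScores:
    """The five subtest scores and their total."""

    prospective: int
    item_recall: int
    place_recall: int
    recognition: int
    matching: int

    @property
    def total(self) -> int:
        return (self.prospective + self.item_recall + self.place_recall
                + self.recognition + self.matching)

    def __post_init__(self):
        for name in SUBTESTS:
            v = getattr(self, name)
            if not 0 <= v <= SUBTEST_MAXIMA[name]:
                raise ValidationError(f"{name} score {v} outside 0..{SUBTEST_MAXIMA[name]}")


def score(record: ResponseRecord, layout: RoomLayout) -> HotScores:
    """Score one response record against the layout's answer key.

    Item names are matched after case-folding and whitespace trimming;
    unknown recalled names are ignored.  A recognition choice that is not
    among that trial's four options raises :class:`ValidationError`.
    """
    key_items = {_norm(n) for n in layout.item_names()}

    prospective = sum(bool(a) for a in record.prospective_actions)

    recalled = {_norm(n) for n in record.recalled_items}
    item_recall = len(recalled & key_items)

    loads = layout.section_loads()
    mark_counts: dict[str, int] = {}
    for sec in record.marked_sections:
        mark_counts[sec] = mark_counts.get(sec, 0) + 1
    place_recall = sum(min(mark_counts.get(sec, 0), load)
                       for sec, load in loads.items())

    recognition = 0
    for k, choice in enumerate(record.recognition_choices):
        options = {_norm(o) for o in layout.recognition_options[k]}
        if _norm(choice) not in options:
            raise ValidationError(
                f"recognition choice {choice!r} is not among trial {k + 1}'s options"
            )
        recognition += _norm(choice) == _norm(layout.items[k][0])

    matching = sum(bool(m) for m in record.matching_reached)

    return HotScores(prospective, item_recall, place_recall, recognition, matching)


def score_cohort(bundle) -> pd.DataFrame:
    """Score every participant of a cohort bundle into a tidy table.

    Returns one row per participant with columns participant_id, group, the
    five subtests and the total.  Raises if any participant with a
    trajectory lacks a response record.
    """
    rows = []
    for pid, traj in bundle.trajectories.items():
        if pid not in bundle.responses:
            raise ValidationError(f"no response record for participant {pid!r}")
        s = score(bundle.responses[pid], bundle.layout)
        rows.append({
            "participant_id": pid,
            "group": traj.group,
            **{name: getattr(s, name) for name in SUBTESTS},
            "total": s.total,
        })
    cols = ["participant_id", "group", *SUBTESTS, "total"]
    return pd.DataFrame(rows, columns=cols)


def write_responses(responses: dict[str, ResponseRecord], path) -> None:
    """Write per-participant responses as a JSON object keyed by id."""
    with open(path, "w") as fh:
        json.dump({pid: r.to_dict() for pid, r in responses.items()},
                  fh, indent=2, sort_keys=True)


def read_responses(path) -> dict[str, ResponseRecord]:
    with open(path) as fh:
        raw = json.load(fh)
    return {pid: ResponseRecord.from_dict(d) for pid, d in raw.items()}
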