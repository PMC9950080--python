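"""Item bank for a VR ultra-low-vision performance instrument.

The instrument consists of 19 activities (m-alternative forced-choice tasks,
2 <= m <= 4) in three categories -- spatial localization/detection, motion
detection, and direction of motion -- each administered at three visibility
levels, giving 57 calibratable items.  This module encodes the bank as
structured data, validates its invariants, and produces per-participant
trial schedules following the administration protocol: activity order
randomized per participant, levels presented easiest first, three trials per
level with the presented alternative drawn uniformly with replacement.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

CATEGORIES = ("spatial_localization", "motion_detection", "direction_of_motion")
VISIBILITY_AXES = (
    "contrast_percent",
    "duration_seconds",
    "flicker_hz",
    "movement_amplitude",
    "grayscale_level",
)

#: canonical level -> visibility value tables per axis
CONTRAST_LEVELS = {1: 100.0, 2: 30.0, 3: 10.0}
DURATION_LEVELS = {1: 2.0, 2: 1.0, 3: 0.5}
FLICKER_LEVELS = {1: 3.5, 2: 11.7, 3: 35.0}


class ItemBankError(ValueError):
    """Raised when an item-bank document violates the instrument's invariants."""


@dataclass(frozen=True)
class ActivityDef:
    """One forced-choice activity (task) of the instrument."""

    activity_id: str
    name: str
    category: str
    m: int
    visibility_axis: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ItemBankError(
                f"activity {self.activity_id!r}: unknown category {self.category!r}"
            )
        if not 2 <= int(self.m) <= 4:
            raise ItemBankError(f"activity {self.activity_id!r}: m out of range ({self.m})")
        if self.visibility_axis not in VISIBILITY_AXES:
            raise ItemBankError(
                f"activity {self.activity_id!r}: unknown visibility_axis "
                f"{self.visibility_axis!r}"
            )


@dataclass(frozen=True)
class ItemDef:
    """One calibratable item: an activity at one visibility level (1 = most visible)."""

    item_id: str
    activity_id: str
    level: int
    visibility_value: float

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise ItemBankError(f"item {self.item_id!r}: level must be 1, 2 or 3")


@dataclass
class ItemBank:
    """Validated collection of activities and their per-level items."""

    activities: list[ActivityDef]
    items: list[ItemDef]

    def __post_init__(self) -> None:
        self._by_activity = {a.activity_id: a for a in self.activities}
        if len(self._by_activity) != len(self.activities):
            raise ItemBankError("duplicate activity_id in bank")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ItemBankError("duplicate item_id in bank")

    # -- lookups -------------------------------------------------------
    def activity(self, activity_id: str) -> ActivityDef:
        return self._by_activity[activity_id]

    def m_of_item(self) -> dict[str, int]:
        """Map item_id -> number of response alternatives of its activity."""
        return {it.item_id: self._by_activity[it.activity_id].m for it in self.items}

    def category_of_item(self) -> dict[str, str]:
        return {it.item_id: self._by_activity[it.activity_id].category for it in self.items}

    def items_frame(self) -> pd.DataFrame:
        """One row per item with activity metadata joined in."""
        rows = []
        for it in self.items:
            act = self._by_activity[it.activity_id]
            rows.append(
                dict(
                    item_id=it.item_id,
                    activity_id=it.activity_id,
                    activity_name=act.name,
                    category=act.category,
                    m=act.m,
                    level=it.level,
                    visibility_axis=act.visibility_axis,
                    visibility_value=it.visibility_value,
                )
            )
        return pd.DataFrame(rows)

    # -- validation ----------------------------------------------------
    def validate(self, canonical_counts: bool = True) -> None:
        """Check structural invariants; raise ItemBankError naming the offender.

        With ``canonical_counts`` the instrument-level counts (19 activities,
        57 items, 13/3/3 category split) are enforced as well; without it only
        the per-record and per-activity invariants are checked, which permits
        validating partial banks.
        """
        for it in self.items:
            if it.activity_id not in self._by_activity:
                raise ItemBankError(
                    f"item {it.item_id!r} references unknown activity {it.activity_id!r}"
                )
        for act in self.activities:
            its = sorted(
                (i for i in self.items if i.activity_id == act.activity_id),
                key=lambda i: i.level,
            )
            if [i.level for i in its] != [1, 2, 3]:
                raise ItemBankError(
                    f"activity {act.activity_id!r}: needs exactly levels 1,2,3 "
                    f"(got {[i.level for i in its]})"
                )
            values = [i.visibility_value for i in its]
            expected = {
                "contrast_percent": CONTRAST_LEVELS,
                "duration_seconds": DURATION_LEVELS,
                "flicker_hz": FLICKER_LEVELS,
            }.get(act.visibility_axis)
            if expected is not None and values != [expected[1], expected[2], expected[3]]:
                raise ItemBankError(
                    f"activity {act.activity_id!r}: visibility values {values} do not "
                    f"match the {act.visibility_axis} ladder {list(expected.values())}"
                )
        if canonical_counts:
            if len(self.activities) != 19:
                raise ItemBankError(f"expected 19 activities, found {len(self.activities)}")
            if len(self.items) != 57:
                raise ItemBankError(f"expected 57 items, found {len(self.items)}")
            split = {c: 0 for c in CATEGORIES}
            for a in self.activities:
                split[a.category] += 1
            if (
                split["spatial_localization"] != 13
                or split["motion_detection"] != 3
                or split["direction_of_motion"] != 3
            ):
                raise ItemBankError(f"category split {split} != 13/3/3")


@dataclass
class TrialSchedule:
    """Ordered trial list for one participant (demo trials annotated, unscored)."""

    person_id: str
    seed: int
    trials: pd.DataFrame  # columns: activity_id, item_id, level, trial, alternative
    demo_activities: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.trials.copy()
        out.insert(0, "person_id", self.person_id)
        return out[["person_id", "activity_id", "item_id", "level", "trial", "alternative"]]


# ----------------------------------------------------------------------
# Canonical bank
# ----------------------------------------------------------------------

def _canonical_document() -> dict:
    with resources.files("ulvfit.data").joinpath("canonical_bank.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


def _bank_from_document(doc: dict) -> ItemBank:
    for key in ("activities", "items"):
        if key not in doc:
            raise ItemBankError(f"document missing top-level key {key!r}")
    acts = []
    for rec in doc["activities"]:
        missing = {"activity_id", "name", "category", "m", "visibility_axis"} - set(rec)
        if missing:
            raise ItemBankError(
                f"activity record {rec.get('activity_id', rec)!r} missing fields {sorted(missing)}"
            )
        acts.append(
            ActivityDef(
                activity_id=str(rec["activity_id"]),
                name=str(rec["name"]),
                category=str(rec["category"]),
                m=int(rec["m"]),
                visibility_axis=str(rec["visibility_axis"]),
            )
        )
    items = []
    for rec in doc["items"]:
        missing = {"item_id", "activity_id", "level", "visibility_value"} - set(rec)
        if missing:
            raise ItemBankError(
                f"item record {rec.get('item_id', rec)!r} missing fields {sorted(missing)}"
            )
        items.append(
            ItemDef(
                item_id=str(rec["item_id"]),
                activity_id=str(rec["activity_id"]),
                level=int(rec["level"]),
                visibility_value=float(rec["visibility_value"]),
            )
        )
    return ItemBank(acts, items)


def load_item_bank(source: str | Path | dict = "canonical") -> ItemBank:
    """Load and validate an item bank.

    Parameters
    ----------
    source
        ``"canonical"`` for the built-in 19-activity instrument; a path to a
        JSON document with top-level ``activities``/``items`` lists; or an
        already-parsed dict with the same schema.

    Returns
    -------
    ItemBank
        Validated bank (19 activities, 57 items, 13/3/3 category split).

    Raises
    ------
    ItemBankError
        On schema or count violations, naming the offending record.
    """
    if isinstance(source, str) and source == "canonical":
        doc = _canonical_document()
    elif isinstance(source, dict):
        doc = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    bank = _bank_from_document(doc)
    bank.validate(canonical_counts=True)
    return bank


# ----------------------------------------------------------------------
# Trial scheduling
# ----------------------------------------------------------------------

def _person_stream(seed: int, person_id: str) -> np.random.Generator:
    # splittable stream keyed by (seed, person_id); stable across runs/platforms
    digest = hashlib.sha256(person_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def make_trial_schedule(bank: ItemBank, person_id: str, seed: int) -> TrialSchedule:
    """Build one participant's 171-trial schedule.

    Activity order is a seed+person keyed permutation (Fisher-Yates via the
    generator's ``permutation``); within each activity the three levels run
    easiest (level 1) first, three trials per level; the presented alternative
    is drawn uniformly from ``1..m`` with replacement, independently per trial.
    The same ``(bank, person_id, seed)`` always yields an identical schedule.
    """
    rng = _person_stream(seed, person_id)
    order = rng.permutation(len(bank.activities))
    items_by_act: dict[str, list[ItemDef]] = {}
    for it in bank.items:
        items_by_act.setdefault(it.activity_id, []).append(it)
    rows = []
    for idx in order:
        act = bank.activities[int(idx)]
        for it in sorted(items_by_act[act.activity_id], key=lambda i: i.level):
            alts = rng.integers(1, act.m + 1, size=3)
            for trial, alt in enumerate(alts, start=1):
                rows.append(
                    dict(
                        activity_id=act.activity_id,
                        item_id=it.item_id,
                        level=it.level,
                        trial=trial,
                        alternative=int(alt),
                    )
                )
    frame = pd.DataFrame(rows)
    return TrialSchedule(
        person_id=person_id,
        seed=int(seed),
        trials=frame,
        demo_activities=[bank.activities[int(i)].activity_id for i in order],
    )


def schedules_to_csv(schedules: list[TrialSchedule], path: str | Path) -> None:
    """Export schedules with header person_id,activity_id,item_id,level,trial,alternative."""
    pd.concat([s.to_frame() for s in schedules], ignore_index=True).to_csv(path, index=False)
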