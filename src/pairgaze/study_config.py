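"""Experimental design: stimulus catalogues, session plans, identity classes.

The paradigm pairs a face image and an anogenital-region (AGR) image of the
same stimulus monkey on every trial.  A catalogue holds one stimulus set
(female or male) with 20 face/AGR image pairs per monkey; a session plan is a
seeded shuffle of that catalogue in which every image appears exactly once and
the face is assigned to the left or right display window with fair probability.

Stimulus monkeys are classified on two binary axes used throughout the
analysis: age (young vs old, boundary at 9 years: 9 and above is old) and
familiarity (familiar iff the stimulus monkey shares a colony room with the
subject, i.e. has continuous visual/auditory contact).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

TREATMENTS = ("SL", "OT", "TE")  # saline control, oxytocin, testosterone
AGE_BOUNDARY_YEARS = 9.0  # age >= boundary -> "old"


class CatalogueError(ValueError):
    """Raised when a stimulus catalogue violates its invariants."""


class ClassificationError(ValueError):
    """Raised when a stimulus monkey cannot be classified."""


@dataclass(frozen=True)
class StimulusMonkey:
    id: str
    sex: str  # "female" | "male"
    age_years: float
    room: str

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise CatalogueError(f"monkey {self.id!r}: sex must be female/male, got {self.sex!r}")
        if not self.age_years > 0:
            raise CatalogueError(f"monkey {self.id!r}: age_years must be > 0, got {self.age_years}")


@dataclass(frozen=True)
class IdentityClass:
    age_class: str  # "young" | "old"
    familiarity: str  # "familiar" | "unfamiliar"


@dataclass
class StimulusCatalogue:
    set_label: str  # "female" | "male"
    monkeys: list[StimulusMonkey]
    images: dict[str, dict[str, list[str]]]  # monkey_id -> {"face": [...], "agr": [...]}
    pairs_per_monkey: int = 20

    def __post_init__(self) -> None:
        if self.set_label not in ("female", "male"):
            raise CatalogueError(f"set_label must be female/male, got {self.set_label!r}")
        ids = [m.id for m in self.monkeys]
        if len(set(ids)) != len(ids):
            raise CatalogueError("duplicate monkey ids in catalogue")
        for m in self.monkeys:
            if m.sex != self.set_label:
                raise CatalogueError(
                    f"monkey {m.id!r} has sex {m.sex!r} but catalogue set_label is {self.set_label!r}"
                )
            imgs = self.images.get(m.id)
            if imgs is None:
                raise CatalogueError(f"monkey {m.id!r} has no image entry")
            n_face, n_agr = len(imgs.get("face", ())), len(imgs.get("agr", ()))
            if n_face != n_agr:
                raise CatalogueError(
                    f"monkey {m.id!r}: {n_face} face vs {n_agr} agr image ids (must be equal)"
                )
            if n_face != self.pairs_per_monkey:
                raise CatalogueError(
                    f"monkey {m.id!r}: {n_face} image pairs, expected {self.pairs_per_monkey}"
                )
        if not self.monkeys:
            raise CatalogueError("catalogue has no monkeys")

    @property
    def n_trials(self) -> int:
        return len(self.monkeys) * self.pairs_per_monkey

    def monkey(self, monkey_id: str) -> StimulusMonkey:
        for m in self.monkeys:
            if m.id == monkey_id:
                return m
        raise KeyError(monkey_id)


@dataclass(frozen=True)
class PlannedTrial:
    trial_index: int
    monkey_id: str
    face_image: str
    agr_image: str
    face_side: str  # "left" | "right"


@dataclass
class SessionPlan:
    session_id: str
    subject_id: str
    treatment: str
    set_label: str
    trials: list[PlannedTrial]
    seed: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")


def classify_identity(monkey: StimulusMonkey, subject_room: str) -> IdentityClass:
    """Classify a stimulus monkey's age class and familiarity to the subject.

    Young means under 9 years (still skeletally immature); 9 years and above is
    old.  Familiar means co-housed in the subject's colony room.
    """
    if monkey.room is None or monkey.room == "":
        raise ClassificationError(f"monkey {monkey.id!r} has no room recorded")
    if monkey.age_years is None or not monkey.age_years > 0:
        raise ClassificationError(f"monkey {monkey.id!r} has invalid age {monkey.age_years!r}")
    age_class = "young" if monkey.age_years < AGE_BOUNDARY_YEARS else "old"
    familiarity = "familiar" if monkey.room == subject_room else "unfamiliar"
    return IdentityClass(age_class=age_class, familiarity=familiarity)


def build_session_plan(
    catalogue: StimulusCatalogue,
    subject_id: str,
    treatment: str,
    seed: int,
    session_id: str | None = None,
) -> SessionPlan:
    """Build a randomized session plan from a catalogue.

    Every face and every AGR image of the catalogue appears exactly once.
    Within each monkey the face/AGR pairing is shuffled, the resulting trial
    list is shuffled across monkeys, and each trial's face side is drawn
    independently and fairly.  Deterministic given ``seed``.
    """
    if not catalogue.monkeys:
        raise CatalogueError("cannot plan a session from an empty catalogue")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str, str]] = []  # (monkey_id, face_image, agr_image)
    for m in catalogue.monkeys:
        faces = list(catalogue.images[m.id]["face"])
        agrs = list(catalogue.images[m.id]["agr"])
        rng.shuffle(agrs)  # re-pair faces with AGRs within the monkey
        pairs.extend((m.id, f, a) for f, a in zip(faces, agrs))
    order = rng.permutation(len(pairs))
    sides = rng.random(len(pairs)) < 0.5
    trials = [
        PlannedTrial(
            trial_index=i,
            monkey_id=pairs[k][0],
            face_image=pairs[k][1],
            agr_image=pairs[k][2],
            face_side="left" if sides[i] else "right",
        )
        for i, k in enumerate(order)
    ]
    return SessionPlan(
        session_id=session_id or f"{subject_id}-{catalogue.set_label}-{treatment}-{seed}",
        subject_id=subject_id,
        treatment=treatment,
        set_label=catalogue.set_label,
        trials=trials,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# JSON round-trip


def load_catalogue(path: str | Path) -> StimulusCatalogue:
    """Load a stimulus catalogue from JSON, enforcing all invariants."""
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("set_label", "monkeys", "images"):
        if key not in raw:
            raise CatalogueError(f"catalogue file missing field {key!r}")
    monkeys = []
    for entry in raw["monkeys"]:
        for key in ("id", "sex", "age_years", "room"):
            if key not in entry:
                raise CatalogueError(f"monkey entry missing field {key!r}: {entry}")
        monkeys.append(
            StimulusMonkey(
                id=str(entry["id"]),
                sex=str(entry["sex"]),
                age_years=float(entry["age_years"]),
                room=str(entry["room"]),
            )
        )
    return StimulusCatalogue(
        set_label=str(raw["set_label"]),
        monkeys=monkeys,
        images={str(k): {"face": list(v["face"]), "agr": list(v["agr"])} for k, v in raw["images"].items()},
        pairs_per_monkey=int(raw.get("pairs_per_monkey", 20)),
    )


def save_catalogue(catalogue: StimulusCatalogue, path: str | Path) -> None:
    payload = {
        "set_label": catalogue.set_label,
        "pairs_per_monkey": catalogue.pairs_per_monkey,
        "monkeys": [
            {"id": m.id, "sex": m.sex, "age_years": m.age_years, "room": m.room}
            for m in catalogue.monkeys
        ],
        "images": catalogue.images,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def save_plan(plan: SessionPlan, path: str | Path) -> None:
    payload = {
        "session_id": plan.session_id,
        "subject_id": plan.subject_id,
        "treatment": plan.treatment,
        "set_label": plan.set_label,
        "seed": plan.seed,
        "trials": [
            {
                "trial_index": t.trial_index,
                "monkey_id": t.monkey_id,
                "face_image": t.face_image,
                "agr_image": t.agr_image,
                "face_side": t.face_side,
            }
            for t in plan.trials
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_plan(path: str | Path) -> SessionPlan:
    with open(path) as fh:
        raw = json.load(fh)
    trials = [PlannedTrial(**t) for t in raw["trials"]]
    return SessionPlan(
        session_id=raw["session_id"],
        subject_id=raw["subject_id"],
        treatment=raw["treatment"],
        set_label=raw["set_label"],
        trials=trials,
        seed=int(raw["seed"]),
    )


# ---------------------------------------------------------------------------
# Default study roster


def default_catalogue(set_label: str, pairs_per_monkey: int = 20) -> StimulusCatalogue:
    """The study roster: 6 female (6-23 y) and 9 male (6-22 y) stimulus monkeys.

    Two colony rooms; female F and males BR, CN, HL, OK, PN share room "A" with
    the subjects, the rest live in room "B".  Image ids are synthetic labels.
    """
    females = [
        ("B", 23.0, "B"), ("C", 14.0, "B"), ("F", 8.0, "A"),
        ("HD", 6.0, "B"), ("HP", 10.0, "B"), ("SR", 12.0, "B"),
    ]
    males = [
        ("AM", 22.0, "B"), ("AR", 6.0, "B"), ("BR", 10.0, "A"),
        ("CN", 8.0, "A"), ("HK", 12.0, "B"), ("HL", 15.0, "A"),
        ("OK", 7.0, "A"), ("PN", 18.0, "A"), ("TM", 9.0, "B"),
    ]
    roster = {"female": females, "male": males}[set_label]
    monkeys = [StimulusMonkey(id=i, sex=set_label, age_years=a, room=r) for i, a, r in roster]
    images = {
        m.id: {
            "face": [f"{m.id}_face_{k:02d}" for k in range(pairs_per_monkey)],
            "agr": [f"{m.id}_agr_{k:02d}" for k in range(pairs_per_monkey)],
        }
        for m in monkeys
    }
    return StimulusCatalogue(
        set_label=set_label, monkeys=monkeys, images=images, pairs_per_monkey=pairs_per_monkey
    )


SUBJECT_ROOM = "A"  # the subjects' colony room in the default roster
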