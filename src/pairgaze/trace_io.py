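"""Sample-log I/O and trial segmentation.

A sample log is a TSV table of 1000 Hz eye-tracker samples with columns
``session  trial  t_ms  x_deg  y_deg  pupil_au  valid``.  Coordinates are
degrees of visual angle with the origin at screen centre; timestamps are
integer milliseconds, strictly increasing within a trial (gaps tolerated).
Invalid samples (blinks, track loss) may carry NaN positions and pupil 0.

Trial layouts describe the display geometry per trial: the face and AGR
windows (axis-aligned rectangles, disjoint), the 3.0 x 3.0 deg central
fixation window, the display onset/offset, and the stimulus/condition labels
(monkey id, image sex, treatment, age class, familiarity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["session", "trial", "t_ms", "x_deg", "y_deg", "pupil_au", "valid"]


class SampleLogError(ValueError):
    """Raised on malformed sample logs."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle: centre (cx, cy), full width/height, degrees."""

    cx: float
    cy: float
    width: float
    height: float

    @property
    def x0(self) -> float:
        return self.cx - self.width / 2

    @property
    def x1(self) -> float:
        return self.cx + self.width / 2

    @property
    def y0(self) -> float:
        return self.cy - self.height / 2

    @property
    def y1(self) -> float:
        return self.cy + self.height / 2

    def contains(self, x: float, y: float) -> bool:
        """Half-open membership: left/top edges inclusive, right/bottom exclusive.

        With y increasing upwards the "top" edge is y1; the included edges are
        x0 and y1, the excluded ones x1 and y0.
        """
        return (self.x0 <= x < self.x1) and (self.y0 < y <= self.y1)

    @property
    def area(self) -> float:
        return self.width * self.height

    def to_list(self) -> list[float]:
        return [self.cx, self.cy, self.width, self.height]


def _rects_disjoint(a: Rect, b: Rect) -> bool:
    return a.x1 <= b.x0 or b.x1 <= a.x0 or a.y1 <= b.y0 or b.y1 <= a.y0


@dataclass
class TrialLayout:
    session: str
    trial: int
    onset_ms: int
    offset_ms: int
    face_window: Rect
    agr_window: Rect
    fix_window: Rect
    monkey_id: str
    image_sex: str  # sex of the monkey depicted
    treatment: str
    age_class: str
    familiarity: str
    face_image: str = ""
    agr_image: str = ""
    face_side: str = ""  # "left" | "right"

    def __post_init__(self) -> None:
        if not _rects_disjoint(self.face_window, self.agr_window):
            raise ValueError(f"trial {self.trial}: face and AGR windows overlap")
        if self.offset_ms <= self.onset_ms:
            raise ValueError(f"trial {self.trial}: offset_ms must exceed onset_ms")


# ---------------------------------------------------------------------------
# Sample log read/write


def validate_samples(df: pd.DataFrame) -> None:
    unknown = [c for c in df.columns if c not in SAMPLE_COLUMNS]
    if unknown:
        raise SampleLogError(f"unknown column(s): {unknown}")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SampleLogError(f"missing column(s): {missing}")
    if len(df) == 0:
        return
    if (df["pupil_au"].fillna(0) < 0).any():
        raise SampleLogError("pupil_au must be non-negative")
    for (sess, trial), grp in df.groupby(["session", "trial"], sort=False):
        t = grp["t_ms"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = grp.index[bad[0] + 1]
            raise SampleLogError(
                f"non-monotone t_ms in session {sess!r} trial {trial} at row {row} (t={t[bad[0] + 1]})"
            )


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample-log TSV; enforces schema and per-trial time monotonicity."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"session": str, "trial": np.int64, "t_ms": np.int64, "valid": np.int64},
    )
    validate_samples(df)
    return df.reset_index(drop=True)


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    """Write a sample log as TSV (canonical form: 4 decimal places)."""
    validate_samples(df)
    df.to_csv(path, sep="\t", index=False, columns=SAMPLE_COLUMNS, float_format="%.4f")


def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Round a log to the on-disk precision (4 decimal places)."""
    out = df.copy()
    for col in ("x_deg", "y_deg", "pupil_au"):
        out[col] = out[col].round(4)
    return out


# ---------------------------------------------------------------------------
# Layout tables


def save_layouts(layouts: Iterable[TrialLayout], path: str | Path) -> None:
    payload = []
    for lay in layouts:
        d = asdict(lay)
        for key in ("face_window", "agr_window", "fix_window"):
            d[key] = lay.__getattribute__(key).to_list()
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_layouts(path: str | Path) -> list[TrialLayout]:
    raw = json.loads(Path(path).read_text())
    layouts = []
    for d in raw:
        for key in ("face_window", "agr_window", "fix_window"):
            d[key] = Rect(*d[key])
        layouts.append(TrialLayout(**d))
    return layouts


# ---------------------------------------------------------------------------
# Segmentation


@dataclass
class TrialSegment:
    layout: TrialLayout
    display: pd.DataFrame  # samples with onset <= t < offset
    baseline: pd.DataFrame  # pre-stimulus samples of the same trial (t < onset)
    flagged: bool  # < 50% of nominal display samples present and valid


def segment_trials(log: pd.DataFrame, layouts: list[TrialLayout]) -> list[TrialSegment]:
    """Split a session log into per-trial display and baseline segments.

    The display segment is clipped to [onset, offset); the trial's earlier
    samples (the central-fixation period) form the baseline segment.  A trial
    with fewer than 50% of its nominal display samples valid is flagged for QC
    but still returned.
    """
    segments = []
    grouped = dict(tuple(log.groupby(["session", "trial"], sort=False)))
    for lay in layouts:
        key = (lay.session, lay.trial)
        if key not in grouped:
            raise SampleLogError(f"trial {lay.trial} of session {lay.session!r} missing from log")
        grp = grouped[key]
        t = grp["t_ms"].to_numpy()
        if lay.onset_ms > t[-1]:
            raise SampleLogError(
                f"trial {lay.trial}: display onset {lay.onset_ms} beyond last sample t={t[-1]}"
            )
        disp = grp[(t >= lay.onset_ms) & (t < lay.offset_ms)]
        base = grp[t < lay.onset_ms]
        expected = lay.offset_ms - lay.onset_ms  # nominal 1 sample / ms
        n_good = int((disp["valid"] == 1).sum())
        segments.append(
            TrialSegment(layout=lay, display=disp, baseline=base, flagged=n_good < 0.5 * expected)
        )
    return segments
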