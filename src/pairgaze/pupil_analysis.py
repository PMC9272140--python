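"""Pupillometry: session baselines and z-scored per-fixation pupil size.

Pupil size is recorded in arbitrary tracker units, so all inference runs on
z-scores against the session's fixation baseline: the pooled valid pupil
samples of every pre-stimulus central-fixation period.  Blink samples (pupil
0 or invalid) never enter a mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .event_detection import FixationEvent


class BaselineError(ValueError):
    pass


@dataclass(frozen=True)
class PupilBaseline:
    session: str
    mean_au: float
    sd_au: float  # ddof=1
    n: int

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.sd_au) or self.sd_au == 0.0


def _valid_pupil(segment: pd.DataFrame) -> np.ndarray:
    p = segment["pupil_au"].to_numpy(dtype=float)
    v = segment["valid"].to_numpy()
    keep = (v == 1) & np.isfinite(p) & (p > 0)
    return p[keep]


def baseline_stats(baseline_segments: list[pd.DataFrame], session: str = "") -> PupilBaseline:
    """Pool a session's pre-stimulus segments into one baseline (mean, SD, n)."""
    parts = [_valid_pupil(seg) for seg in baseline_segments]
    pooled = np.concatenate(parts) if parts else np.array([])
    if pooled.size == 0:
        raise BaselineError(f"session {session!r}: no valid baseline pupil samples")
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    return PupilBaseline(session=session, mean_au=float(pooled.mean()), sd_au=sd, n=int(pooled.size))


def fixation_pupil(fixation: FixationEvent, samples: pd.DataFrame) -> float:
    """Mean pupil over the fixation's valid, non-blink samples; NaN if none."""
    t = samples["t_ms"].to_numpy()
    sel = (t >= fixation.onset_ms) & (t < fixation.offset_ms)
    vals = _valid_pupil(samples[sel])
    return float(vals.mean()) if vals.size else float("nan")


def zscore_pupil(pupil_au: float, baseline: PupilBaseline) -> float:
    """z = (pupil - baseline mean) / baseline SD."""
    if baseline.degenerate:
        raise BaselineError(
            f"session {baseline.session!r}: degenerate baseline (sd = {baseline.sd_au})"
        )
    return (pupil_au - baseline.mean_au) / baseline.sd_au


def zscore_events(events: pd.DataFrame, baseline: PupilBaseline) -> pd.DataFrame:
    """Append a ``pupil_z`` column to an events table with a ``mean_pupil``
    column (rows with missing pupil stay missing)."""
    out = events.copy()
    out["pupil_z"] = (out["mean_pupil"] - baseline.mean_au) / (
        baseline.sd_au if not baseline.degenerate else np.nan
    )
    return out
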