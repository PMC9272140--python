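"""Blink, fixation and saccade detection from gaze sample series.

Fixations are identified with the dispersion-threshold algorithm (I-DT): a
candidate window is grown sample by sample while its dispersion — defined
classically as (max(x) - min(x)) + (max(y) - min(y)) — stays within
``dispersion_deg``; a window is emitted as a fixation once it spans at least
``min_duration_ms``.  The scan is greedy and left-to-right: the window start
advances one sample at a time until a window of minimum duration fits under
the threshold, then the end extends as far as the threshold allows.

Blink intervals (zero pupil or invalid samples, padded on both sides) are
masked out first; a fixation never spans a blink.  Consecutive fixations
separated by less than ``merge_gap_ms`` whose union still satisfies the
dispersion threshold are merged.

Timestamps are integer milliseconds; a sample stamped t is taken to cover
[t, t+1), so a window of samples t_first..t_last has duration
t_last - t_first + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DetectorParams:
    dispersion_deg: float = 1.0
    min_duration_ms: float = 60.0
    blink_pad_ms: float = 50.0
    merge_gap_ms: float = 20.0

    def __post_init__(self) -> None:
        for name in ("dispersion_deg", "min_duration_ms", "blink_pad_ms", "merge_gap_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FixationEvent:
    onset_ms: int
    offset_ms: int  # exclusive: event covers [onset, offset)
    x_deg: float
    y_deg: float
    mean_pupil: float  # NaN when no valid constituent sample
    n_samples: int
    aoi: str = ""  # attached later: face | agr | off
    roi: str = ""  # attached later for aoi == face

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass
class SaccadeEvent:
    onset_ms: int
    offset_ms: int
    x0_deg: float
    y0_deg: float
    x1_deg: float
    y1_deg: float

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


def detect_blinks(series: pd.DataFrame, params: DetectorParams) -> list[tuple[int, int]]:
    """Return padded half-open [start, end) blink intervals of a sample series.

    A blink sample has pupil_au == 0 or valid == 0.  Maximal runs are padded by
    ``blink_pad_ms`` on each side, clipped to the series extent, and merged
    when padding makes them overlap or touch.
    """
    if len(series) == 0:
        return []
    t = series["t_ms"].to_numpy()
    bad = (series["pupil_au"].fillna(0).to_numpy() == 0) | (series["valid"].to_numpy() == 0)
    if not bad.any():
        return []
    # maximal runs of bad samples
    edges = np.diff(bad.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if bad[0]:
        starts = np.concatenate(([0], starts))
    if bad[-1]:
        ends = np.concatenate((ends, [len(bad)]))
    pad = params.blink_pad_ms
    lo, hi = t[0], t[-1] + 1
    intervals = [
        (max(lo, t[s] - pad), min(hi, t[e - 1] + 1 + pad)) for s, e in zip(starts, ends)
    ]
    merged: list[tuple[int, int]] = []
    for a, b in intervals:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return [(int(a), int(b)) for a, b in merged]


def mask_intervals(series: pd.DataFrame, intervals: list[tuple[int, int]]) -> np.ndarray:
    """Boolean mask of samples falling inside any half-open [a, b) interval."""
    t = series["t_ms"].to_numpy()
    mask = np.zeros(len(series), dtype=bool)
    for a, b in intervals:
        mask |= (t >= a) & (t < b)
    return mask


def _contiguous_chunks(t: np.ndarray, max_gap_ms: float) -> list[tuple[int, int]]:
    """Index ranges [i, j) of runs with inter-sample gaps <= max_gap_ms."""
    if len(t) == 0:
        return []
    breaks = np.nonzero(np.diff(t) > max_gap_ms)[0] + 1
    bounds = np.concatenate(([0], breaks, [len(t)]))
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def _idt_scan(t: np.ndarray, x: np.ndarray, y: np.ndarray, params: DetectorParams):
    """Greedy I-DT scan over one contiguous chunk; yields (i, j) index windows."""
    n = len(t)
    disp = params.dispersion_deg
    out = []
    i = 0
    while i < n:
        # smallest j such that the window [i, j) spans >= min_duration
        j = int(np.searchsorted(t, t[i] + params.min_duration_ms - 1, side="left")) + 1
        if j > n:
            break
        xmin = x[i:j].min()
        xmax = x[i:j].max()
        ymin = y[i:j].min()
        ymax = y[i:j].max()
        if (xmax - xmin) + (ymax - ymin) > disp:
            i += 1
            continue
        while j < n:
            xv, yv = x[j], y[j]
            nxmin, nxmax = min(xmin, xv), max(xmax, xv)
            nymin, nymax = min(ymin, yv), max(ymax, yv)
            if (nxmax - nxmin) + (nymax - nymin) > disp:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        out.append((i, j))
        i = j
    return out


def detect_fixations_idt(
    series: pd.DataFrame,
    params: DetectorParams,
    blink_intervals: list[tuple[int, int]] | None = None,
    merge: bool = True,
) -> list[FixationEvent]:
    """Detect fixations in a time-sorted sample series with I-DT.

    ``blink_intervals`` (from :func:`detect_blinks`) are masked out before the
    scan, and a blink always terminates the current window: the scan runs
    independently on each contiguous run of unmasked samples.  With
    ``merge=False`` the raw greedy output is returned (useful for comparing
    against an enumeration oracle).
    """
    if len(series) == 0:
        return []
    if blink_intervals is None:
        blink_intervals = detect_blinks(series, params)
    keep = ~mask_intervals(series, blink_intervals)
    keep &= series["valid"].to_numpy() == 1
    keep &= np.isfinite(series["x_deg"].to_numpy()) & np.isfinite(series["y_deg"].to_numpy())
    sub = series[keep]
    if len(sub) == 0:
        return []
    t = sub["t_ms"].to_numpy().astype(np.int64)
    x = sub["x_deg"].to_numpy().astype(float)
    y = sub["y_deg"].to_numpy().astype(float)
    p = sub["pupil_au"].to_numpy().astype(float)

    events: list[FixationEvent] = []
    # a masked-out region of any length breaks the scan; so does a sampling gap
    for a, b in _contiguous_chunks(t, max_gap_ms=1.5):
        for i, j in _idt_scan(t[a:b], x[a:b], y[a:b], params):
            i += a
            j += a
            events.append(
                FixationEvent(
                    onset_ms=int(t[i]),
                    offset_ms=int(t[j - 1]) + 1,
                    x_deg=float(x[i:j].mean()),
                    y_deg=float(y[i:j].mean()),
                    mean_pupil=float(p[i:j].mean()) if j > i else float("nan"),
                    n_samples=j - i,
                )
            )
    if merge:
        events = merge_fixations(events, t, x, y, params)
    return events


def merge_fixations(
    events: list[FixationEvent],
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    params: DetectorParams,
) -> list[FixationEvent]:
    """Merge adjacent fixations separated by < merge_gap_ms when their union
    (including intervening unmasked samples) still fits the dispersion cap."""
    if not events:
        return events
    merged = [events[0]]
    for ev in events[1:]:
        prev = merged[-1]
        gap = ev.onset_ms - prev.offset_ms
        if gap < params.merge_gap_ms:
            sel = (t >= prev.onset_ms) & (t < ev.offset_ms)
            xs, ys = x[sel], y[sel]
            if (xs.max() - xs.min()) + (ys.max() - ys.min()) <= params.dispersion_deg:
                merged[-1] = FixationEvent(
                    onset_ms=prev.onset_ms,
                    offset_ms=ev.offset_ms,
                    x_deg=float(xs.mean()),
                    y_deg=float(ys.mean()),
                    mean_pupil=(
                        (prev.mean_pupil * prev.n_samples + ev.mean_pupil * ev.n_samples)
                        / (prev.n_samples + ev.n_samples)
                    ),
                    n_samples=prev.n_samples + ev.n_samples,
                )
                continue
        merged.append(ev)
    return merged


def derive_saccades(fixations: list[FixationEvent]) -> list[SaccadeEvent]:
    """One saccade per adjacent fixation pair, spanning the inter-fixation gap."""
    saccades = []
    for a, b in zip(fixations[:-1], fixations[1:]):
        if b.onset_ms < a.offset_ms:
            raise ValueError(
                f"overlapping fixations: [{a.onset_ms},{a.offset_ms}) and [{b.onset_ms},{b.offset_ms})"
            )
        saccades.append(
            SaccadeEvent(
                onset_ms=a.offset_ms,
                offset_ms=b.onset_ms,
                x0_deg=a.x_deg,
                y0_deg=a.y_deg,
                x1_deg=b.x_deg,
                y1_deg=b.y_deg,
            )
        )
    return saccades


def events_frame(fixations: list[FixationEvent], session: str, trial: int) -> pd.DataFrame:
    """Tabulate fixations as one row per event."""
    return pd.DataFrame(
        {
            "session": session,
            "trial": trial,
            "onset_ms": [f.onset_ms for f in fixations],
            "offset_ms": [f.offset_ms for f in fixations],
            "duration_ms": [f.duration_ms for f in fixations],
            "x_deg": [f.x_deg for f in fixations],
            "y_deg": [f.y_deg for f in fixations],
            "mean_pupil": [f.mean_pupil for f in fixations],
            "n_samples": [f.n_samples for f in fixations],
            "aoi": [f.aoi for f in fixations],
            "roi": [f.roi for f in fixations],
        }
    )
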