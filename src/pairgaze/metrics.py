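"""Per-trial viewing-preference metrics and condition aggregates.

The headline statistic is pAGR, the proportion of a trial's in-window
fixations that land on the AGR image:

    pAGR = n_fix_agr / (n_fix_agr + n_fix_face)

Off-image fixations enter no headline metric (they are tallied separately for
QC); a trial with no in-window fixation has pAGR missing.  First gaze is the
AOI of the first post-onset fixation landing in either image window, skipping
off-image landings.  Aggregates report mean +/- SE per condition cell, and
binomial SE for first-gaze proportions.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .aoi_mapping import ROI_NAMES, assign_aoi, assign_roi, RoiMap
from .event_detection import FixationEvent
from .trace_io import TrialLayout

CONDITION_KEYS = ("treatment", "image_sex", "age_class", "familiarity", "face_side", "session")


def label_fixations(
    fixations: list[FixationEvent],
    layout: TrialLayout,
    roi_map: RoiMap | None = None,
) -> list[FixationEvent]:
    """Attach AOI (and, within the face window, ROI) labels to fixations."""
    out = []
    for f in fixations:
        aoi = assign_aoi(f.x_deg, f.y_deg, layout.face_window, layout.agr_window)
        roi = ""
        if aoi == "face" and roi_map is not None:
            roi = assign_roi(
                f.x_deg, f.y_deg, roi_map, (layout.face_window.cx, layout.face_window.cy)
            )
        f.aoi = aoi
        f.roi = roi
        out.append(f)
    return out


def first_gaze(fixations: list[FixationEvent], layout: TrialLayout) -> str:
    """AOI of the first post-onset fixation landing in an image window.

    Fixations still inside the central window, and off-image landings, are
    skipped; ``none`` if gaze never reaches either image window.
    """
    for f in sorted(fixations, key=lambda f: f.onset_ms):
        if f.onset_ms < layout.onset_ms:
            continue
        if f.aoi in ("face", "agr"):
            return f.aoi
    return "none"


def compute_trial_metrics(
    fixations: list[FixationEvent], layout: TrialLayout
) -> dict[str, object]:
    """Counts, dwell, pAGR, first gaze and ROI tallies for one trial.

    ``fixations`` must carry AOI labels (see :func:`label_fixations`) and all
    belong to the layout's trial; only fixations that start at or after the
    display onset are counted.
    """
    disp = [f for f in fixations if f.onset_ms >= layout.onset_ms]
    face = [f for f in disp if f.aoi == "face"]
    agr = [f for f in disp if f.aoi == "agr"]
    off = [f for f in disp if f.aoi == "off"]
    n_face, n_agr = len(face), len(agr)
    total = n_face + n_agr
    dwell_face = sum(f.duration_ms for f in face)
    dwell_agr = sum(f.duration_ms for f in agr)
    roi_counts = {r: sum(1 for f in face if f.roi == r) for r in (*ROI_NAMES, "other")}
    m: dict[str, object] = {
        "session": layout.session,
        "trial": layout.trial,
        "treatment": layout.treatment,
        "image_sex": layout.image_sex,
        "age_class": layout.age_class,
        "familiarity": layout.familiarity,
        "face_side": layout.face_side,
        "monkey_id": layout.monkey_id,
        "n_fix_face": n_face,
        "n_fix_agr": n_agr,
        "n_fix_off": len(off),
        "total_fix": total,
        "dwell_face_ms": dwell_face,
        "dwell_agr_ms": dwell_agr,
        "pagr": (n_agr / total) if total > 0 else np.nan,
        "first_gaze": first_gaze(fixations, layout),
        "mean_fix_len_ms": ((dwell_face + dwell_agr) / total) if total > 0 else np.nan,
        "mean_fix_len_face_ms": (dwell_face / n_face) if n_face > 0 else np.nan,
        "mean_fix_len_agr_ms": (dwell_agr / n_agr) if n_agr > 0 else np.nan,
    }
    for r, c in roi_counts.items():
        m[f"roi_{r}"] = c
    return m


def metrics_table(per_trial: Sequence[dict[str, object]]) -> pd.DataFrame:
    return pd.DataFrame(list(per_trial))


def aggregate(table: pd.DataFrame, keys: Sequence[str]) -> pd.DataFrame:
    """Per-cell mean, SE and n for each numeric metric, plus the first-gaze
    AGR proportion with its binomial SE.

    SE = sd/sqrt(n) over non-missing values, reported missing for n <= 1
    cells; cells with no trials are omitted.
    """
    keys = list(keys)
    unknown = [k for k in keys if k not in table.columns]
    if unknown:
        raise KeyError(f"unknown grouping key(s): {unknown}")
    numeric = [
        c
        for c in table.columns
        if c not in keys and pd.api.types.is_numeric_dtype(table[c]) and c not in ("trial",)
    ]
    rows = []
    for cell, grp in table.groupby(keys, sort=True, dropna=False):
        if not isinstance(cell, tuple):
            cell = (cell,)
        row: dict[str, object] = dict(zip(keys, cell))
        for c in numeric:
            vals = grp[c].dropna().to_numpy(dtype=float)
            n = len(vals)
            row[f"{c}_mean"] = vals.mean() if n else np.nan
            row[f"{c}_se"] = vals.std(ddof=1) / math.sqrt(n) if n > 1 else np.nan
            row[f"{c}_n"] = n
        fg = grp["first_gaze"]
        fg_n = int((fg != "none").sum())
        if fg_n > 0:
            p = float((fg == "agr").sum()) / fg_n
            row["p_first_agr"] = p
            row["p_first_agr_se"] = math.sqrt(p * (1 - p) / fg_n)
            row["p_first_agr_n"] = fg_n
        else:
            row["p_first_agr"] = np.nan
            row["p_first_agr_se"] = np.nan
            row["p_first_agr_n"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def roi_fixation_percentages(face_fixations: list[FixationEvent]) -> dict[str, float]:
    """Percentage of face fixations per ROI (sums to 100; all-missing when
    there are no face fixations)."""
    if any(f.aoi != "face" for f in face_fixations):
        raise ValueError("roi_fixation_percentages expects only AOI=face fixations")
    n = len(face_fixations)
    names = (*ROI_NAMES, "other")
    if n == 0:
        return {r: float("nan") for r in names}
    return {r: 100.0 * sum(1 for f in face_fixations if f.roi == r) / n for r in names}


def roi_percentage_table(table: pd.DataFrame, keys: Sequence[str]) -> pd.DataFrame:
    """Per-cell ROI percentages from the trial-metrics table's roi_* counts."""
    names = (*ROI_NAMES, "other")
    rows = []
    for cell, grp in table.groupby(list(keys), sort=True):
        if not isinstance(cell, tuple):
            cell = (cell,)
        row: dict[str, object] = dict(zip(keys, cell))
        counts = {r: int(grp[f"roi_{r}"].sum()) for r in names}
        total = sum(counts.values())
        for r in names:
            row[f"pct_{r}"] = (100.0 * counts[r] / total) if total else np.nan
        row["n_face_fix"] = total
        rows.append(row)
    return pd.DataFrame(rows)
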