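"""Synthetic 1000 Hz gaze/pupil generator with known ground truth.

Emulates the behavioural structure of a paired-image free-viewing trial: the
subject holds a central fixation (the pre-stimulus baseline), then a face and
an AGR image of one stimulus monkey appear left and right of centre for 3 s,
during which gaze alternates between ~200 ms fixations and 40 ms saccade
sweeps.  The first fixation target is Bernoulli in ``q_first``; each later
fixation targets the AGR window i.i.d. with probability ``theta_pagr`` (an
optional stay-probability turns this into a sticky Markov chain with the same
stationary mean).  Landing points on the face follow a mixture over facial
ROIs; AGR landings are uniform.  Pupil size is a session baseline plus
AR(1) noise plus an AOI/ROI-dependent offset expressed in baseline-SD (z)
units; blinks are zero-pupil gaps.

Every trial draws from its own counter-derived random stream, so any trial is
reproducible in isolation, and the emitted ground truth (true fixation
intervals, targets, first-gaze labels) lets downstream stages be validated by
parameter recovery.

Fixation durations are lognormal.  ``calibrate_lognormal`` maps a target
(mean, median) pair onto (mu, sigma): the lognormal median is exp(mu) and the
mean exp(mu + sigma^2/2), so mu = ln(median) and sigma = sqrt(2 ln(mean/median)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .aoi_mapping import ROI_NAMES, RoiMap, default_roi_map
from .study_config import (
    SUBJECT_ROOM,
    SessionPlan,
    StimulusCatalogue,
    classify_identity,
    default_catalogue,
)
from .trace_io import Rect, TrialLayout

# Reference fixation-length anchors (ms) for free viewing; the defaults below
# calibrate the lognormal to exactly these two numbers.
REFERENCE_MEAN_MS = 246.65
REFERENCE_MEDIAN_MS = 213.00


def calibrate_lognormal(mean_ms: float, median_ms: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) with the requested mean and median, both in ms."""
    if median_ms <= 0:
        raise ValueError("median_ms must be positive")
    if mean_ms < median_ms:
        raise ValueError("a lognormal requires mean >= median (no real sigma otherwise)")
    mu = math.log(median_ms)
    sigma = math.sqrt(2.0 * math.log(mean_ms / median_ms))
    return mu, sigma


_DEFAULT_MU, _DEFAULT_SIGMA = calibrate_lognormal(REFERENCE_MEAN_MS, REFERENCE_MEDIAN_MS)

# Per-condition defaults keyed "TREATMENT:image_sex".  AGR-preference (the
# generative analogue of pAGR) and first-gaze-on-AGR probability.
DEFAULT_THETA = {
    "SL:female": 0.68, "OT:female": 0.70, "TE:female": 0.71,
    "SL:male": 0.69, "OT:male": 0.69, "TE:male": 0.70,
}
DEFAULT_Q_FIRST = {
    "SL:female": 0.78, "OT:female": 0.78, "TE:female": 0.84,
    "SL:male": 0.81, "OT:male": 0.81, "TE:male": 0.81,
}
DEFAULT_ROI_WEIGHTS = {
    "forehead": 0.345, "eyes": 0.35, "nose": 0.08, "mouth": 0.07, "other": 0.155,
}


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """All generative parameters; every probability is in [0, 1].

    ``theta_pagr`` and ``q_first`` are dicts keyed ``"TREATMENT:sex"`` with
    optional finer keys ``"TREATMENT:sex:age_class:familiarity"`` taking
    precedence.  ``pupil_offsets`` are additive offsets in baseline-SD (z)
    units, keyed by AOI (``"face"``/``"agr"``), optionally refined as
    ``"aoi:roi"`` or ``"aoi:age_class:familiarity"``.
    """

    theta_pagr: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THETA))
    q_first: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_Q_FIRST))
    side_bias: float = 0.0  # additive first-gaze probability shift toward the left window
    stay_prob: float = 0.0  # 0 -> i.i.d. targets; >0 -> sticky Markov chain
    duration_mu: float = _DEFAULT_MU
    duration_sigma: float = _DEFAULT_SIGMA
    duration_by_sex: dict[str, tuple[float, float]] | None = None
    saccade_ms: int = 40
    min_fix_floor_ms: int = 80  # durations below this are redrawn
    roi_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROI_WEIGHTS))
    pupil_base_mean: float = 2000.0
    pupil_base_sd: float = 50.0  # session-to-session baseline variation
    pupil_offsets: dict[str, float] = field(default_factory=lambda: {"face": 0.0, "agr": -0.3})
    pupil_noise_sd: float = 100.0  # marginal SD of the AR(1) noise, au
    pupil_ar1: float = 0.9
    blink_rate: float = 0.1  # blinks per second
    blink_dur_ms: int = 100
    trial_ms: int = 3000
    baseline_ms: int = 500
    sample_rate_hz: int = 1000
    fix_jitter_sd_deg: float = 0.0  # optional within-fixation position noise
    min_landing_sep_deg: float = 2.0  # consecutive landings at least this far apart
    window_size_deg: float = 8.0
    window_ecc_deg: float = 8.0  # horizontal eccentricity of window centres
    edge_margin_deg: float = 0.3  # landing inset from window edges
    # probability a non-initial fixation lands off-image, per image sex;
    # male images hold gaze on-image far less than female images do
    p_off: dict[str, float] = field(default_factory=lambda: {"female": 0.12, "male": 0.55})
    # trial-level engagement heterogeneity: the per-trial off-image propensity
    # is Beta-distributed around the sex mean with this concentration
    # (0 disables the overdispersion)
    p_off_concentration: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, table in (("theta_pagr", self.theta_pagr), ("q_first", self.q_first)):
            for key, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{key!r}] = {p} outside [0, 1]")
        if not 0.0 <= self.stay_prob <= 1.0:
            raise ConfigError("stay_prob must be in [0, 1]")
        if not isinstance(self.p_off, dict):
            self.p_off = {"female": float(self.p_off), "male": float(self.p_off)}
        for sex, p in self.p_off.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"p_off[{sex!r}] must be in [0, 1]")
        if self.duration_sigma < 0:
            raise ConfigError("duration_sigma must be >= 0")
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        if self.sample_rate_hz != 1000:
            raise ConfigError("only 1000 Hz sampling is supported (1 sample per ms)")
        w = sum(self.roi_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ConfigError(f"roi_weights sum to {w}, expected 1")
        if self.blink_rate < 0 or self.blink_dur_ms <= 0:
            raise ConfigError("blink_rate must be >= 0 and blink_dur_ms > 0")
        if self.trial_ms < self.min_fix_floor_ms:
            raise ConfigError("trial_ms shorter than one minimal fixation")

    # -- per-condition lookups ------------------------------------------------

    def resolve_theta(self, treatment: str, sex: str, age: str = "", fam: str = "") -> float:
        return self._resolve(self.theta_pagr, treatment, sex, age, fam, "theta_pagr")

    def resolve_q_first(self, treatment: str, sex: str, age: str = "", fam: str = "") -> float:
        return self._resolve(self.q_first, treatment, sex, age, fam, "q_first")

    @staticmethod
    def _resolve(table: dict[str, float], treatment: str, sex: str, age: str, fam: str, name: str) -> float:
        for key in (f"{treatment}:{sex}:{age}:{fam}", f"{treatment}:{sex}"):
            if key in table:
                return table[key]
        raise ConfigError(f"no {name} entry for condition {treatment}:{sex}")

    def resolve_pupil_offset(self, aoi: str, roi: str = "", age: str = "", fam: str = "") -> float:
        for key in (f"{aoi}:{roi}:{age}:{fam}", f"{aoi}:{roi}", f"{aoi}:{age}:{fam}", aoi):
            if key in self.pupil_offsets:
                return self.pupil_offsets[key]
        return 0.0

    def duration_params(self, sex: str) -> tuple[float, float]:
        if self.duration_by_sex and sex in self.duration_by_sex:
            return self.duration_by_sex[sex]
        return self.duration_mu, self.duration_sigma

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        d = asdict(self)
        if d.get("duration_by_sex"):
            d["duration_by_sex"] = {k: list(v) for k, v in d["duration_by_sex"].items()}
        return d


@dataclass
class SimulatedSession:
    samples: pd.DataFrame  # SampleLog schema
    layouts: list[TrialLayout]
    truth_trials: pd.DataFrame  # one row per trial
    truth_fixations: pd.DataFrame  # one row per true fixation


# ---------------------------------------------------------------------------
# Landing-point sampling


def _uniform_in_rect(rng: np.random.Generator, x0, x1, y0, y1) -> tuple[float, float]:
    return float(rng.uniform(x0, x1)), float(rng.uniform(y0, y1))


def _sample_roi_point(rng: np.random.Generator, roi_map: RoiMap, roi: str, margin: float) -> tuple[float, float]:
    """Uniform point (window coordinates) within the named ROI polygon, or in
    the window-minus-polygons remainder for ``other``."""
    from shapely.geometry import Point

    w = roi_map.window.width / 2 - margin
    h = roi_map.window.height / 2 - margin
    if roi == "other":
        for _ in range(10000):
            x, y = _uniform_in_rect(rng, -w, w, -h, h)
            pt = Point(x, y)
            if not any(p.covers(pt) for p in roi_map.polygons.values()):
                return x, y
        raise RuntimeError("could not sample an 'other' landing point")
    poly = roi_map.polygons[roi]
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(10000):
        x, y = _uniform_in_rect(rng, minx, maxx, miny, maxy)
        if poly.covers(Point(x, y)):
            return x, y
    raise RuntimeError(f"could not sample a landing point in ROI {roi!r}")


def _draw_landing(
    rng: np.random.Generator,
    target: str,
    layout: TrialLayout,
    roi_map: RoiMap,
    roi_names: list[str],
    roi_probs: np.ndarray,
    margin: float,
    prev: tuple[float, float] | None,
    min_sep: float,
) -> tuple[float, float, str]:
    """Screen-coordinate landing point and ROI label for a fixation target."""
    if target == "face":
        win = layout.face_window
    elif target == "agr":
        win = layout.agr_window
    else:  # off-image: a band above the central region, outside all windows
        for _ in range(10000):
            x, y = _uniform_in_rect(rng, -2.5, 2.5, 4.0, 5.5)
            if prev is None or math.hypot(x - prev[0], y - prev[1]) >= min_sep:
                return x, y, ""
        return 0.0, 5.0, ""
    for _ in range(10000):
        if target == "face":
            roi = roi_names[rng.choice(len(roi_names), p=roi_probs)]
            wx, wy = _sample_roi_point(rng, roi_map, roi, margin)
            x, y = win.cx + wx, win.cy + wy
        else:
            roi = ""
            x, y = _uniform_in_rect(
                rng, win.x0 + margin, win.x1 - margin, win.y0 + margin, win.y1 - margin
            )
        if prev is None or math.hypot(x - prev[0], y - prev[1]) >= min_sep:
            return x, y, roi
    return x, y, roi  # pragma: no cover - separation nearly always satisfiable


# ---------------------------------------------------------------------------
# Trial simulation


def _draw_duration(rng: np.random.Generator, mu: float, sigma: float, floor: int) -> int:
    for _ in range(1000):
        d = int(round(float(rng.lognormal(mu, sigma))))
        if d >= floor:
            return d
    return floor


def simulate_trial(
    layout: TrialLayout,
    config: GeneratorConfig,
    rng: np.random.Generator,
    roi_map: RoiMap | None = None,
    session_base: float | None = None,
) -> tuple[pd.DataFrame, dict[str, Any], pd.DataFrame]:
    """Simulate one trial.

    Returns ``(samples, truth_trial, truth_fixations)`` where samples cover
    the baseline period [onset - baseline_ms, onset) and the display period
    [onset, offset), one sample per millisecond.
    """
    if roi_map is None:
        roi_map = default_roi_map(window_deg=config.window_size_deg)
    if session_base is None:
        session_base = config.pupil_base_mean
    t_start = layout.onset_ms - config.baseline_ms
    n_total = config.baseline_ms + config.trial_ms
    t = np.arange(t_start, layout.offset_ms, dtype=np.int64)
    assert len(t) == n_total

    age, fam = layout.age_class, layout.familiarity
    theta = config.resolve_theta(layout.treatment, layout.image_sex, age, fam)
    q = config.resolve_q_first(layout.treatment, layout.image_sex, age, fam)
    p_off = config.p_off.get(layout.image_sex, 0.0)
    c = config.p_off_concentration
    if 0.0 < p_off < 1.0 and c > 0:  # per-trial engagement draw
        p_off = float(rng.beta(c * p_off, c * (1.0 - p_off)))
    mu, sigma = config.duration_params(layout.image_sex)

    # --- fixation/saccade schedule over the display period -------------------
    fixations: list[dict[str, Any]] = []  # onset, offset (trial-relative), target, roi, x, y
    remaining = config.trial_ms
    clock = 0
    prev_xy: tuple[float, float] | None = (0.0, 0.0)  # leaving the central spot
    target: str | None = None
    roi_names = list(config.roi_weights.keys())
    roi_probs = np.array([config.roi_weights[r] for r in roi_names])
    first = True
    while remaining >= config.min_fix_floor_ms:
        if first:
            p_agr = q + (config.side_bias if layout.face_side == "right" else -config.side_bias)
            p_agr = min(1.0, max(0.0, p_agr))
            target = "agr" if rng.random() < p_agr else "face"
            # initial saccade away from the central spot
            clock += config.saccade_ms
            remaining -= config.saccade_ms
        else:
            if p_off > 0 and rng.random() < p_off:
                target = "off"
            elif config.stay_prob > 0 and rng.random() < config.stay_prob:
                pass  # keep previous target
            else:
                target = "agr" if rng.random() < theta else "face"
        x, y, roi = _draw_landing(
            rng, target, layout, roi_map, roi_names, roi_probs,
            config.edge_margin_deg, prev_xy, config.min_landing_sep_deg,
        )
        d = _draw_duration(rng, mu, sigma, config.min_fix_floor_ms)
        # extend to the end of the display when no further full fixation fits
        if remaining <= d + config.saccade_ms + config.min_fix_floor_ms:
            d = remaining
        fixations.append(
            {"onset": clock, "offset": clock + d, "target": target, "roi": roi, "x": x, "y": y}
        )
        clock += d
        remaining -= d
        if remaining <= 0:
            break
        clock += config.saccade_ms
        remaining -= config.saccade_ms
        prev_xy = (x, y)
        first = False

    # --- position samples -----------------------------------------------------
    x_pos = np.empty(n_total)
    y_pos = np.empty(n_total)
    # baseline: central fixation
    nb = config.baseline_ms
    x_pos[:nb] = 0.0
    y_pos[:nb] = 0.0
    offset_z = np.zeros(n_total)  # pupil offset per sample, z units
    prev = (0.0, 0.0)
    prev_end = nb
    for fx in fixations:
        a, b = nb + fx["onset"], nb + fx["offset"]
        if prev_end < a:  # saccade sweep: linear interpolation
            frac = np.linspace(0.0, 1.0, a - prev_end + 2)[1:-1]
            x_pos[prev_end:a] = prev[0] + frac * (fx["x"] - prev[0])
            y_pos[prev_end:a] = prev[1] + frac * (fx["y"] - prev[1])
        x_pos[a:b] = fx["x"]
        y_pos[a:b] = fx["y"]
        offset_z[a:b] = config.resolve_pupil_offset(
            fx["target"], fx["roi"], age, fam
        ) if fx["target"] in ("face", "agr") else 0.0
        if prev_end < a:
            offset_z[prev_end:a] = offset_z[a] if a < n_total else 0.0
        prev = (fx["x"], fx["y"])
        prev_end = b
    x_pos[prev_end:] = prev[0]
    y_pos[prev_end:] = prev[1]
    if config.fix_jitter_sd_deg > 0:
        x_pos += rng.normal(0.0, config.fix_jitter_sd_deg, n_total)
        y_pos += rng.normal(0.0, config.fix_jitter_sd_deg, n_total)

    # --- pupil ---------------------------------------------------------------
    sd = config.pupil_noise_sd
    phi = config.pupil_ar1
    if sd > 0:
        from scipy.signal import lfilter

        innov = rng.normal(0.0, sd * math.sqrt(max(0.0, 1.0 - phi * phi)), n_total)
        innov[0] = rng.normal(0.0, sd)  # start at the marginal distribution
        noise = lfilter([1.0], [1.0, -phi], innov)
    else:
        noise = np.zeros(n_total)
    pupil = session_base + offset_z * sd + noise
    np.clip(pupil, 0.0, None, out=pupil)
    # a zero pupil means "blink" downstream; keep clean samples strictly positive
    pupil[pupil == 0.0] = 0.01

    valid = np.ones(n_total, dtype=np.int64)
    # --- blinks ---------------------------------------------------------------
    n_blinks = rng.poisson(config.blink_rate * n_total / 1000.0) if config.blink_rate > 0 else 0
    for _ in range(n_blinks):
        b0 = int(rng.integers(0, n_total))
        b1 = min(n_total, b0 + config.blink_dur_ms)
        pupil[b0:b1] = 0.0
        valid[b0:b1] = 0
        x_pos[b0:b1] = np.nan
        y_pos[b0:b1] = np.nan

    samples = pd.DataFrame(
        {
            "session": layout.session,
            "trial": layout.trial,
            "t_ms": t,
            "x_deg": x_pos,
            "y_deg": y_pos,
            "pupil_au": pupil,
            "valid": valid,
        }
    )
    first_target = fixations[0]["target"] if fixations else "none"
    truth_trial = {
        "session": layout.session,
        "trial": layout.trial,
        "treatment": layout.treatment,
        "image_sex": layout.image_sex,
        "age_class": age,
        "familiarity": fam,
        "face_side": layout.face_side,
        "monkey_id": layout.monkey_id,
        "theta": theta,
        "q_first": q,
        "first_gaze": first_target if first_target in ("face", "agr") else "none",
        "n_fix": len(fixations),
        "n_fix_agr": sum(f["target"] == "agr" for f in fixations),
        "n_fix_face": sum(f["target"] == "face" for f in fixations),
    }
    truth_fix = pd.DataFrame(
        {
            "session": layout.session,
            "trial": layout.trial,
            "fix_index": np.arange(len(fixations)),
            "onset_ms": [layout.onset_ms + f["onset"] for f in fixations],
            "offset_ms": [layout.onset_ms + f["offset"] for f in fixations],
            "target": [f["target"] for f in fixations],
            "roi": [f["roi"] for f in fixations],
            "x_deg": [f["x"] for f in fixations],
            "y_deg": [f["y"] for f in fixations],
        }
    )
    return samples, truth_trial, truth_fix


# ---------------------------------------------------------------------------
# Session simulation


def make_layout(
    plan: SessionPlan,
    trial_index: int,
    config: GeneratorConfig,
    onset_ms: int,
    catalogue: StimulusCatalogue,
    subject_room: str = SUBJECT_ROOM,
) -> TrialLayout:
    entry = plan.trials[trial_index]
    monkey = catalogue.monkey(entry.monkey_id)
    ident = classify_identity(monkey, subject_room)
    ecc, size = config.window_ecc_deg, config.window_size_deg
    left = Rect(-ecc, 0.0, size, size)
    right = Rect(ecc, 0.0, size, size)
    face_win, agr_win = (left, right) if entry.face_side == "left" else (right, left)
    return TrialLayout(
        session=plan.session_id,
        trial=trial_index,
        onset_ms=onset_ms,
        offset_ms=onset_ms + config.trial_ms,
        face_window=face_win,
        agr_window=agr_win,
        fix_window=Rect(0.0, 0.0, 3.0, 3.0),
        monkey_id=monkey.id,
        image_sex=monkey.sex,
        treatment=plan.treatment,
        age_class=ident.age_class,
        familiarity=ident.familiarity,
        face_image=entry.face_image,
        agr_image=entry.agr_image,
        face_side=entry.face_side,
    )


def simulate_session(
    plan: SessionPlan,
    config: GeneratorConfig,
    catalogue: StimulusCatalogue | None = None,
    subject_room: str = SUBJECT_ROOM,
    roi_map: RoiMap | None = None,
) -> SimulatedSession:
    """Simulate a full session: concatenated trials with jittered 2-3 s
    inter-trial gaps (no samples are emitted between trials)."""
    if catalogue is None:
        catalogue = default_catalogue(plan.set_label)
    if plan.set_label != catalogue.set_label:
        raise ConfigError(
            f"plan set_label {plan.set_label!r} does not match catalogue {catalogue.set_label!r}"
        )
    if roi_map is None:
        roi_map = default_roi_map(window_deg=config.window_size_deg)
    rng_session = np.random.default_rng([config.seed, plan.seed, 1_000_003])
    session_base = float(rng_session.normal(config.pupil_base_mean, config.pupil_base_sd))
    clock = config.baseline_ms  # first trial's baseline starts at t = 0... onset at baseline_ms
    frames, layouts, t_trials, t_fixes = [], [], [], []
    for k in range(len(plan.trials)):
        rng = np.random.default_rng([config.seed, plan.seed, k])
        layout = make_layout(plan, k, config, onset_ms=clock, catalogue=catalogue, subject_room=subject_room)
        samples, truth_trial, truth_fix = simulate_trial(
            layout, config, rng, roi_map=roi_map, session_base=session_base
        )
        frames.append(samples)
        layouts.append(layout)
        t_trials.append(truth_trial)
        t_fixes.append(truth_fix)
        iti = int(rng_session.integers(2000, 3001))
        clock = layout.offset_ms + iti + config.baseline_ms
    return SimulatedSession(
        samples=pd.concat(frames, ignore_index=True),
        layouts=layouts,
        truth_trials=pd.DataFrame(t_trials),
        truth_fixations=pd.concat(t_fixes, ignore_index=True) if t_fixes else pd.DataFrame(),
    )
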