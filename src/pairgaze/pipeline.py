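"""End-to-end orchestration: catalogue -> plan -> simulate (or ingest) ->
detect -> map -> metrics -> pupil -> stats -> report.

Every stage reads and writes plain-text artefacts in the output directory, so
stages can be re-run independently; all CSV outputs start with a provenance
comment line carrying the seed and a hash of the configuration, and repeated
runs with the same (config, seed) are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as metrics_mod
from . import pupil_analysis as pupil_mod
from . import stats_battery as stats_mod
from .aoi_mapping import default_roi_map, gaze_heatmap, load_roi_map
from .event_detection import DetectorParams, detect_blinks, detect_fixations_idt, events_frame
from .study_config import (
    SUBJECT_ROOM,
    build_session_plan,
    default_catalogue,
    load_catalogue,
)
from .synthetic_gaze import GeneratorConfig, simulate_session
from .trace_io import read_samples, write_samples, load_layouts, save_layouts, segment_trials

logger = logging.getLogger("pairgaze")

_CONFIG_KEYS = {
    "out_dir", "seed", "subjects", "sets", "treatments", "sessions_per_treatment",
    "generator", "detector", "heatmap", "groupby", "catalogue_paths", "roi_map_path",
    "write_png", "log_level",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "pairgaze-out"
    seed: int = 0
    subjects: list[str] = field(default_factory=lambda: ["M1"])
    sets: list[str] = field(default_factory=lambda: ["female", "male"])
    treatments: list[str] = field(default_factory=lambda: ["SL", "OT", "TE"])
    sessions_per_treatment: int = 3
    generator: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)
    heatmap: dict = field(default_factory=lambda: {"n_bins": 50, "smoothing_sigma_bins": 1.0})
    groupby: list[str] = field(default_factory=lambda: ["treatment", "image_sex"])
    catalogue_paths: dict = field(default_factory=dict)
    roi_map_path: str = ""
    write_png: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise PipelineError("config", f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        # fail fast on bad nested parameter names/values
        cfg.generator_config()
        cfg.detector_params()
        hm_keys = set(cfg.heatmap) - {"n_bins", "smoothing_sigma_bins"}
        if hm_keys:
            raise PipelineError("config", f"unknown heatmap key(s): {sorted(hm_keys)}")
        return cfg

    def generator_config(self) -> GeneratorConfig:
        try:
            gen = dict(self.generator)
            for key in ("theta_pagr", "q_first"):  # YAML merges replace, not update
                if key in gen and isinstance(gen[key], dict):
                    gen[key] = {str(k): float(v) for k, v in gen[key].items()}
            return GeneratorConfig(seed=self.seed, **gen)
        except TypeError as exc:
            raise PipelineError("config", f"bad generator parameter: {exc}") from exc

    def detector_params(self) -> DetectorParams:
        try:
            return DetectorParams(**self.detector)
        except TypeError as exc:
            raise PipelineError("config", f"bad detector parameter: {exc}") from exc

    def config_hash(self) -> str:
        from dataclasses import asdict

        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    header = f"# pairgaze seed={cfg.seed} config={cfg.config_hash()}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6g")


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# In-memory analysis (no intermediate files), the workhorse behind the stages


def detect_and_measure(sim, params: DetectorParams, roi_map=None):
    """Run detection + AOI/ROI labelling + per-trial metrics on a simulated
    (or ingested) session held in memory.

    Returns ``(trial_metrics, labelled_events)`` DataFrames.
    """
    if roi_map is None:
        roi_map = default_roi_map()
    rows, frames = [], []
    groups = {key: g for key, g in sim.samples.groupby(["session", "trial"], sort=False)}
    for lay in sim.layouts:
        grp = groups[(lay.session, lay.trial)]
        fixations = detect_fixations_idt(grp, params)
        fixations = metrics_mod.label_fixations(fixations, lay, roi_map)
        rows.append(metrics_mod.compute_trial_metrics(fixations, lay))
        frames.append(events_frame(fixations, lay.session, lay.trial))
    return metrics_mod.metrics_table(rows), pd.concat(frames, ignore_index=True)


def simulate_and_analyze(
    n_sessions: int,
    treatment: str,
    seed: int,
    set_label: str = "female",
    generator_kwargs: dict | None = None,
    subject: str = "M1",
):
    """Simulate whole sessions and push them through detection, AOI/ROI
    labelling, per-trial metrics and pupil z-scoring, all in memory.

    Returns ``(trial_metrics, labelled_events_with_pupil_z, truth_trials)``
    concatenated over sessions.  Deterministic given ``seed``.
    """
    from .event_detection import mask_intervals
    from .synthetic_gaze import GeneratorConfig, simulate_session

    catalogue = default_catalogue(set_label)
    gen = GeneratorConfig(seed=seed, **(generator_kwargs or {}))
    params = DetectorParams()
    roi_map = default_roi_map(window_deg=gen.window_size_deg)
    tables, events, truths = [], [], []
    for s in range(n_sessions):
        plan = build_session_plan(
            catalogue, subject, treatment, seed=seed * 1000 + s,
            session_id=f"{subject}-{set_label}-{treatment}-{s}",
        )
        sim = simulate_session(plan, gen, catalogue=catalogue, roi_map=roi_map)
        tab, ev = detect_and_measure(sim, params, roi_map)
        base_segs = []
        for seg in segment_trials(sim.samples, sim.layouts):
            keep = ~mask_intervals(seg.baseline, detect_blinks(seg.baseline, params))
            base_segs.append(seg.baseline[keep])
        baseline = pupil_mod.baseline_stats(base_segs, session=plan.session_id)
        tables.append(tab)
        events.append(pupil_mod.zscore_events(ev, baseline))
        truths.append(sim.truth_trials)
    return (
        pd.concat(tables, ignore_index=True),
        pd.concat(events, ignore_index=True),
        pd.concat(truths, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: PipelineConfig) -> None:
    """Generate every planned session; write sample logs, layouts, truth."""
    out = Path(cfg.out_dir)
    (out / "sim").mkdir(parents=True, exist_ok=True)
    gen = cfg.generator_config()
    roi_map = load_roi_map(cfg.roi_map_path) if cfg.roi_map_path else None
    truth_trials, truth_fix = [], []
    manifest = []
    for si, subject in enumerate(cfg.subjects):
        for li, set_label in enumerate(cfg.sets):
            if set_label in cfg.catalogue_paths:
                catalogue = load_catalogue(cfg.catalogue_paths[set_label])
            else:
                catalogue = default_catalogue(set_label)
            for ti, treatment in enumerate(cfg.treatments):
                for rep in range(cfg.sessions_per_treatment):
                    plan_seed = int(
                        np.random.default_rng([cfg.seed, si, li, ti, rep]).integers(2**31)
                    )
                    plan = build_session_plan(
                        catalogue, subject, treatment, plan_seed,
                        session_id=f"{subject}-{set_label}-{treatment}-{rep}",
                    )
                    sim = simulate_session(plan, gen, catalogue=catalogue, roi_map=roi_map)
                    stem = out / "sim" / plan.session_id
                    write_samples(sim.samples, stem.with_suffix(".samples.tsv"))
                    save_layouts(sim.layouts, stem.with_suffix(".layouts.json"))
                    truth_trials.append(sim.truth_trials)
                    truth_fix.append(sim.truth_fixations)
                    manifest.append(plan.session_id)
                    logger.info("simulated session %s (%d trials)", plan.session_id, len(plan.trials))
    _write_csv(pd.concat(truth_trials, ignore_index=True), out / "truth_trials.csv", cfg)
    _write_csv(pd.concat(truth_fix, ignore_index=True), out / "truth_fixations.csv", cfg)
    (out / "sessions.json").write_text(json.dumps(manifest, indent=1))
    (out / "generator_config.json").write_text(json.dumps(gen.to_dict(), indent=1, default=str))


def _iter_sessions(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    manifest_path = out / "sessions.json"
    if not manifest_path.exists():
        raise PipelineError("detect", f"no session manifest at {manifest_path}; run simulate first")
    for session_id in json.loads(manifest_path.read_text()):
        stem = out / "sim" / session_id
        log = read_samples(stem.with_suffix(".samples.tsv"))
        layouts = load_layouts(stem.with_suffix(".layouts.json"))
        yield session_id, log, layouts


def stage_detect(cfg: PipelineConfig) -> None:
    """Blink masking + I-DT fixation detection per trial; events CSV."""
    params = cfg.detector_params()
    frames = []
    for session_id, log, layouts in _iter_sessions(cfg):
        segments = segment_trials(log, layouts)
        for seg in segments:
            trial_samples = pd.concat([seg.baseline, seg.display])
            blinks = detect_blinks(trial_samples, params)
            fixations = detect_fixations_idt(trial_samples, params, blink_intervals=blinks)
            frames.append(events_frame(fixations, session_id, seg.layout.trial))
        logger.info("detected events for session %s", session_id)
    events = pd.concat(frames, ignore_index=True)
    _write_csv(events, Path(cfg.out_dir) / "events.csv", cfg)


def stage_metrics(cfg: PipelineConfig) -> None:
    """AOI/ROI labelling, per-trial metrics, condition aggregates, ROI tables."""
    out = Path(cfg.out_dir)
    events = read_output_csv(out / "events.csv")
    gen = cfg.generator_config()
    roi_map = (
        load_roi_map(cfg.roi_map_path)
        if cfg.roi_map_path
        else default_roi_map(window_deg=gen.window_size_deg)
    )
    rows = []
    labelled_frames = []
    for session_id, log, layouts in _iter_sessions(cfg):
        sess_events = events[events["session"] == session_id]
        for lay in layouts:
            ev = sess_events[sess_events["trial"] == lay.trial]
            fixations = _events_to_fixations(ev)
            fixations = metrics_mod.label_fixations(fixations, lay, roi_map)
            rows.append(metrics_mod.compute_trial_metrics(fixations, lay))
            labelled_frames.append(events_frame(fixations, session_id, lay.trial))
    table = metrics_mod.metrics_table(rows)
    _write_csv(table, out / "trial_metrics.csv", cfg)
    _write_csv(
        pd.concat(labelled_frames, ignore_index=True), out / "events_labelled.csv", cfg
    )
    summary = metrics_mod.aggregate(table, cfg.groupby)
    _write_csv(summary, out / "condition_summary.csv", cfg)
    ident = metrics_mod.aggregate(table, ["treatment", "image_sex", "age_class", "familiarity"])
    _write_csv(ident, out / "identity_summary.csv", cfg)
    roi_pct = metrics_mod.roi_percentage_table(table, cfg.groupby)
    _write_csv(roi_pct, out / "roi_percentages.csv", cfg)


def _events_to_fixations(ev: pd.DataFrame):
    from .event_detection import FixationEvent

    return [
        FixationEvent(
            onset_ms=int(r.onset_ms),
            offset_ms=int(r.offset_ms),
            x_deg=float(r.x_deg),
            y_deg=float(r.y_deg),
            mean_pupil=float(r.mean_pupil),
            n_samples=int(r.n_samples),
        )
        for r in ev.itertuples()
    ]


def stage_pupil(cfg: PipelineConfig) -> None:
    """Session baselines and z-scored per-fixation pupil, by AOI and condition."""
    out = Path(cfg.out_dir)
    events = read_output_csv(out / "events_labelled.csv")
    metrics_table = read_output_csv(out / "trial_metrics.csv")
    cond_cols = ["treatment", "image_sex", "age_class", "familiarity"]
    trial_cond = metrics_table.set_index(["session", "trial"])[cond_cols]
    params = cfg.detector_params()
    baselines = []
    z_frames = []
    for session_id, log, layouts in _iter_sessions(cfg):
        segments = segment_trials(log, layouts)
        base_segs = []
        for seg in segments:
            blinks = detect_blinks(seg.baseline, params)
            from .event_detection import mask_intervals

            keep = ~mask_intervals(seg.baseline, blinks)
            base_segs.append(seg.baseline[keep])
        baseline = pupil_mod.baseline_stats(base_segs, session=session_id)
        baselines.append(
            {
                "session": session_id,
                "mean_au": baseline.mean_au,
                "sd_au": baseline.sd_au,
                "n": baseline.n,
                "degenerate": baseline.degenerate,
            }
        )
        sess_ev = events[events["session"] == session_id]
        z_frames.append(pupil_mod.zscore_events(sess_ev, baseline))
    _write_csv(pd.DataFrame(baselines), out / "pupil_baselines.csv", cfg)
    z = pd.concat(z_frames, ignore_index=True)
    z = z.join(trial_cond, on=["session", "trial"])
    _write_csv(z, out / "events_pupil.csv", cfg)
    in_window = z[z["aoi"].isin(["face", "agr"])]
    agg = (
        in_window.groupby(["treatment", "image_sex", "aoi"])
        .agg(
            pupil_z_mean=("pupil_z", "mean"),
            pupil_z_se=("pupil_z", lambda v: v.std(ddof=1) / np.sqrt(v.notna().sum())),
            pupil_au_mean=("mean_pupil", "mean"),
            n=("pupil_z", "count"),
        )
        .reset_index()
    )
    _write_csv(agg, out / "pupil_summary.csv", cfg)


def stage_heatmap(cfg: PipelineConfig) -> None:
    """Population heat maps per image sex x AOI window, as CSV matrices."""
    out = Path(cfg.out_dir)
    n_bins = int(cfg.heatmap.get("n_bins", 50))
    sigma = float(cfg.heatmap.get("smoothing_sigma_bins", 1.0))
    buckets: dict[tuple[str, str], list[np.ndarray]] = {}
    window = None
    for session_id, log, layouts in _iter_sessions(cfg):
        segments = segment_trials(log, layouts)
        for seg in segments:
            lay = seg.layout
            disp = seg.display[seg.display["valid"] == 1]
            x = disp["x_deg"].to_numpy()
            y = disp["y_deg"].to_numpy()
            for aoi, win in (("face", lay.face_window), ("agr", lay.agr_window)):
                sel = (x >= win.x0) & (x < win.x1) & (y > win.y0) & (y <= win.y1)
                # window coordinates so left/right presentations pool together
                pts = np.stack([x[sel] - win.cx, y[sel] - win.cy], axis=1)
                buckets.setdefault((lay.image_sex, aoi), []).append(pts)
                if window is None:
                    from .trace_io import Rect

                    window = Rect(0.0, 0.0, win.width, win.height)
    for (sex, aoi), parts in sorted(buckets.items()):
        pts = np.concatenate(parts) if parts else np.empty((0, 2))
        grid = gaze_heatmap(pts[:, 0], pts[:, 1], window, n_bins=n_bins, smoothing_sigma_bins=sigma)
        stem = out / f"heatmap_{sex}_{aoi}"
        header = f"# pairgaze seed={cfg.seed} config={cfg.config_hash()}\n"
        with open(stem.with_suffix(".counts.csv"), "w") as fh:
            fh.write(header)
            np.savetxt(fh, grid.counts, fmt="%d", delimiter=",")
        if grid.density is not None:
            with open(stem.with_suffix(".density.csv"), "w") as fh:
                fh.write(header)
                np.savetxt(fh, grid.density, fmt="%.8e", delimiter=",")
        if cfg.write_png and grid.density is not None:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(grid.density.T, origin="lower", cmap="hot")
            ax.set_title(f"{sex} {aoi}")
            fig.savefig(stem.with_suffix(".png"), dpi=120)
            plt.close(fig)


def stage_stats(cfg: PipelineConfig) -> None:
    """The statistical report covering the pipeline's standard comparisons."""
    out = Path(cfg.out_dir)
    table = read_output_csv(out / "trial_metrics.csv")
    results: list[stats_mod.TestResult] = []

    # face-vs-AGR fixation counts, paired per trial
    results.append(
        stats_mod.wilcoxon_signed_rank(
            (table["n_fix_agr"] - table["n_fix_face"]).to_numpy()
        ).renamed("signed_rank[n_fix: agr vs face]")
    )
    # female vs male total fixations (unpaired), when both present
    sexes = set(table["image_sex"])
    if {"female", "male"} <= sexes:
        results.append(
            stats_mod.wilcoxon_rank_sum(
                table.loc[table["image_sex"] == "female", "total_fix"],
                table.loc[table["image_sex"] == "male", "total_fix"],
            ).renamed("rank_sum[total_fix: female vs male]")
        )
    # first-gaze bias vs 0.5 per image sex
    for sex in sorted(sexes):
        fg = table.loc[(table["image_sex"] == sex) & (table["first_gaze"] != "none"), "first_gaze"]
        if len(fg):
            results.append(
                stats_mod.chi2_proportion(int((fg == "agr").sum()), len(fg), 0.5).renamed(
                    f"chi2[first_gaze {sex} vs 0.5]"
                )
            )
    # pAGR ~ treatment per image sex (one-way), if several treatments
    if table["treatment"].nunique() > 1:
        for sex in sorted(sexes):
            sub = table[(table["image_sex"] == sex)].dropna(subset=["pagr"])
            res = stats_mod.anova_factorial(sub["pagr"], {"treatment": sub["treatment"]})
            results.append(res[0].renamed(f"anova[pagr ~ treatment | {sex}]"))
    # three-way ANOVA on fixation counts: image sex x image type x treatment
    if {"female", "male"} <= sexes and table["treatment"].nunique() > 1:
        long = pd.concat(
            [
                table.assign(image_type="face", count=table["n_fix_face"]),
                table.assign(image_type="agr", count=table["n_fix_agr"]),
            ],
            ignore_index=True,
        )
        results.extend(
            r.renamed("threeway_" + r.test)
            for r in stats_mod.anova_factorial(
                long["count"],
                {
                    "image_sex": long["image_sex"],
                    "image_type": long["image_type"],
                    "treatment": long["treatment"],
                },
                include_interactions=True,
            )
        )
    # pAGR correlation structure
    sub = table.dropna(subset=["pagr"])
    for col in ("n_fix_face", "n_fix_agr", "total_fix"):
        results.append(
            stats_mod.pearson_r(sub["pagr"], sub[col]).renamed(f"pearson[pagr, {col}]")
        )
    _write_csv(stats_mod.results_frame(results), out / "stats_report.csv", cfg)
    # Tukey HSD on pAGR across treatments, per image sex
    if table["treatment"].nunique() > 2:
        tk_frames = []
        for sex in sorted(sexes):
            sub = table[table["image_sex"] == sex].dropna(subset=["pagr"])
            tk = stats_mod.tukey_hsd(sub["pagr"], sub["treatment"])
            tk.insert(0, "image_sex", sex)
            tk_frames.append(tk)
        _write_csv(pd.concat(tk_frames, ignore_index=True), out / "tukey_pagr.csv", cfg)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage in order; returns the output directory."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stages = [
        ("simulate", stage_simulate),
        ("detect", stage_detect),
        ("metrics", stage_metrics),
        ("pupil", stage_pupil),
        ("heatmap", stage_heatmap),
        ("stats", stage_stats),
        ("report", lambda c: make_report(Path(c.out_dir))),
    ]
    for name, fn in stages:
        try:
            logger.info("stage %s ...", name)
            fn(cfg)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
    return Path(cfg.out_dir)


# ---------------------------------------------------------------------------
# Report


def make_report(out_dir: Path) -> Path:
    """Render the output bundle as a Markdown summary; idempotent."""
    out_dir = Path(out_dir)
    sections = [
        ("Condition summary (mean +/- SE per cell)", "condition_summary.csv"),
        ("Identity-class summary", "identity_summary.csv"),
        ("ROI fixation percentages", "roi_percentages.csv"),
        ("Pupil summary (z-scored)", "pupil_summary.csv"),
        ("Statistical tests", "stats_report.csv"),
    ]
    lines = ["# pairgaze analysis report", ""]
    for title, fname in sections:
        path = out_dir / fname
        if not path.exists():
            raise PipelineError("report", f"missing table {fname}")
        df = read_output_csv(path)
        lines.append(f"## {title}")
        lines.append("")
        lines.append(_markdown_table(df))
        lines.append("")
    tk = out_dir / "tukey_pagr.csv"
    if tk.exists():
        lines += ["## Tukey HSD: pAGR across treatments", "", _markdown_table(read_output_csv(tk)), ""]
    report = out_dir / "report.md"
    report.write_text("\n".join(lines))
    return report


def _markdown_table(df: pd.DataFrame, max_rows: int = 60) -> str:
    df = df.head(max_rows)

    def fmt(v):
        if isinstance(v, float):
            return "" if pd.isna(v) else f"{v:.4g}"
        return str(v)

    head = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    rows = ["| " + " | ".join(fmt(v) for v in rec) + " |" for rec in df.itertuples(index=False)]
    return "\n".join([head, sep, *rows])
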