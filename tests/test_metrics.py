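import numpy as np
import pandas as pd
import pytest

from pairgaze.event_detection import FixationEvent
from pairgaze.metrics import (
    aggregate,
    compute_trial_metrics,
    first_gaze,
    label_fixations,
    roi_fixation_percentages,
)
from pairgaze.trace_io import Rect, TrialLayout


def layout(onset=500, face_side="left"):
    face = Rect(-8, 0, 8, 8) if face_side == "left" else Rect(8, 0, 8, 8)
    agr = Rect(8, 0, 8, 8) if face_side == "left" else Rect(-8, 0, 8, 8)
    return TrialLayout(
        session="s1",
        trial=0,
        onset_ms=onset,
        offset_ms=onset + 3000,
        face_window=face,
        agr_window=agr,
        fix_window=Rect(0, 0, 3, 3),
        monkey_id="B",
        image_sex="female",
        treatment="SL",
        age_class="old",
        familiarity="unfamiliar",
        face_side=face_side,
    )


def fix(onset, dur, aoi, roi="", x=None, y=0.0):
    if x is None:
        x = {"face": -8.0, "agr": 8.0, "off": 0.0}[aoi]
    f = FixationEvent(onset_ms=onset, offset_ms=onset + dur, x_deg=x, y_deg=y, mean_pupil=2000.0, n_samples=dur)
    f.aoi = aoi
    f.roi = roi
    return f


class TestTrialMetrics:
    def test_counts_dwell_and_pagr(self):
        fxs = [
            fix(600, 200, "agr"),
            fix(850, 200, "face"),
            fix(1100, 200, "agr"),
            fix(1350, 200, "agr"),
        ]
        m = compute_trial_metrics(fxs, layout())
        assert m["n_fix_agr"] == 3
        assert m["n_fix_face"] == 1
        assert m["pagr"] == pytest.approx(0.75)
        assert m["dwell_agr_ms"] == 600
        assert m["dwell_face_ms"] == 200

    def test_all_off_window_pagr_missing(self):
        m = compute_trial_metrics([fix(600, 200, "off"), fix(900, 150, "off")], layout())
        assert m["total_fix"] == 0
        assert np.isnan(m["pagr"])
        assert m["n_fix_off"] == 2

    def test_pure_agr_trial(self):
        m = compute_trial_metrics([fix(600, 180, "agr"), fix(900, 220, "agr")], layout())
        assert m["pagr"] == 1.0

    def test_dwell_and_mean_length_identities(self):
        rng = np.random.default_rng(3)
        fxs = []
        t = 600
        for _ in range(12):
            dur = int(rng.integers(80, 400))
            fxs.append(fix(t, dur, rng.choice(["face", "agr"])))
            t += dur + 40
        m = compute_trial_metrics(fxs, layout())
        assert m["dwell_face_ms"] == sum(f.duration_ms for f in fxs if f.aoi == "face")
        assert m["dwell_agr_ms"] == sum(f.duration_ms for f in fxs if f.aoi == "agr")
        assert m["mean_fix_len_ms"] * m["total_fix"] == pytest.approx(
            m["dwell_face_ms"] + m["dwell_agr_ms"]
        )

    def test_pre_onset_fixations_excluded(self):
        fxs = [fix(0, 400, "off", x=0.0), fix(600, 200, "face")]
        m = compute_trial_metrics(fxs, layout())
        assert m["total_fix"] == 1
        assert m["n_fix_off"] == 0


class TestFirstGaze:
    def test_first_in_window_is_agr(self):
        fxs = [fix(0, 450, "off", x=0.0), fix(600, 200, "agr"), fix(900, 200, "face")]
        assert first_gaze(fxs, layout()) == "agr"

    def test_never_leaves_centre(self):
        fxs = [fix(0, 3400, "off", x=0.0)]
        assert first_gaze(fxs, layout()) == "none"

    def test_off_image_landing_skipped(self):
        fxs = [fix(600, 150, "off", x=0.0, y=5.0), fix(800, 200, "face")]
        assert first_gaze(fxs, layout()) == "face"


class TestAggregate:
    def table(self):
        return pd.DataFrame(
            {
                "treatment": ["SL", "SL", "OT"],
                "image_sex": ["female"] * 3,
                "pagr": [0.6, 0.8, 0.5],
                "total_fix": [10, 12, 9],
                "first_gaze": ["agr", "face", "agr"],
                "trial": [0, 1, 2],
            }
        )

    def test_mean_and_se(self):
        out = aggregate(self.table(), ["treatment"])
        sl = out[out["treatment"] == "SL"].iloc[0]
        assert sl["pagr_mean"] == pytest.approx(0.7)
        assert sl["pagr_se"] == pytest.approx(0.1)
        assert sl["pagr_n"] == 2

    def test_single_trial_cell_se_missing(self):
        out = aggregate(self.table(), ["treatment"])
        ot = out[out["treatment"] == "OT"].iloc[0]
        assert np.isnan(ot["pagr_se"])
        assert ot["pagr_n"] == 1

    def test_first_gaze_proportion_with_binomial_se(self):
        out = aggregate(self.table(), ["treatment"])
        sl = out[out["treatment"] == "SL"].iloc[0]
        assert sl["p_first_agr"] == pytest.approx(0.5)
        assert sl["p_first_agr_se"] == pytest.approx(np.sqrt(0.25 / 2))

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError, match="bogus"):
            aggregate(self.table(), ["bogus"])


class TestRoiPercentages:
    def test_seven_of_ten(self):
        fxs = [fix(600, 200, "face", roi="forehead") for _ in range(7)]
        fxs += [fix(600, 200, "face", roi="eyes") for _ in range(3)]
        pct = roi_fixation_percentages(fxs)
        assert pct["forehead"] == pytest.approx(70.0)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_all_in_one_roi(self):
        fxs = [fix(600, 200, "face", roi="eyes") for _ in range(5)]
        pct = roi_fixation_percentages(fxs)
        assert pct["eyes"] == 100.0
        assert pct["forehead"] == 0.0

    def test_empty_input_all_missing(self):
        pct = roi_fixation_percentages([])
        assert all(np.isnan(v) for v in pct.values())

    def test_non_face_fixations_rejected(self):
        with pytest.raises(ValueError):
            roi_fixation_percentages([fix(600, 200, "agr")])


class TestRecovery:
    def test_pagr_and_first_gaze_recover_generative_values(self, sl_run):
        """Pipeline estimates track the generator's saline-female parameters."""
        table, events, truth = sl_run
        n = len(table)
        theta, q = 0.68, 0.78
        # per-trial pAGR mixes one first fixation (q) with ~k-1 theta draws
        k = table["total_fix"].mean()
        expected = (q + (k - 1) * theta) / k
        se = table["pagr"].std(ddof=1) / np.sqrt(n)
        assert abs(table["pagr"].mean() - expected) < 4 * se + 0.005
        fg = table[table["first_gaze"] != "none"]
        p_hat = (fg["first_gaze"] == "agr").mean()
        assert abs(p_hat - q) < 3 * np.sqrt(q * (1 - q) / len(fg))

    def test_detected_first_gaze_matches_truth(self, sl_run):
        table, events, truth = sl_run
        merged = table.merge(truth, on=["session", "trial"], suffixes=("", "_true"))
        agree = (merged["first_gaze"] == merged["first_gaze_true"]).mean()
        assert agree > 0.99

    def test_pagr_correlation_signs(self, sl_run):
        """pAGR correlates negatively with face counts, positively with AGR
        counts, and is nearly independent of the total count."""
        table, _, _ = sl_run
        sub = table.dropna(subset=["pagr"])
        assert sub["pagr"].corr(sub["n_fix_face"]) < -0.3
        assert sub["pagr"].corr(sub["n_fix_agr"]) > 0.3
        assert abs(sub["pagr"].corr(sub["total_fix"])) < 0.08

    def test_count_and_dwell_strongly_correlated(self, sl_run, male_run):
        """Across female- and male-image trials (male images hold gaze
        on-image far less), in-window count and dwell co-vary strongly."""
        table = pd.concat([sl_run[0], male_run[0]], ignore_index=True)
        dwell = table["dwell_face_ms"] + table["dwell_agr_ms"]
        assert table["total_fix"].corr(dwell) > 0.8

    def test_fixations_per_trial_in_renewal_range(self, sl_run):
        """~3 s of ~247 ms fixations + 40 ms saccades gives 8-13 per trial."""
        table, _, _ = sl_run
        assert 8 < table["total_fix"].mean() + table["n_fix_off"].mean() < 13
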