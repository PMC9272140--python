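import numpy as np
import pandas as pd
import pytest

from pairgaze.event_detection import (
    DetectorParams,
    FixationEvent,
    derive_saccades,
    detect_blinks,
    detect_fixations_idt,
)

from oracles import idt_bruteforce, interval_union


def series(t, x, y, pupil=2000.0, valid=1):
    n = len(t)
    return pd.DataFrame(
        {
            "session": "s",
            "trial": 0,
            "t_ms": np.asarray(t, dtype=np.int64),
            "x_deg": np.asarray(x, dtype=float),
            "y_deg": np.asarray(y, dtype=float),
            "pupil_au": np.broadcast_to(np.asarray(pupil, dtype=float), n).copy(),
            "valid": np.broadcast_to(np.asarray(valid), n).copy(),
        }
    )


def steady(duration, x, y):
    return np.full(duration, x), np.full(duration, y)


class TestBlinks:
    def test_padded_interval(self):
        t = np.arange(300)
        pupil = np.full(300, 2000.0)
        pupil[100:150] = 0.0
        s = series(t, *steady(300, 0, 0), pupil=pupil)
        assert detect_blinks(s, DetectorParams()) == [(50, 200)]

    def test_clean_series_no_blinks(self):
        s = series(np.arange(200), *steady(200, 0, 0))
        assert detect_blinks(s, DetectorParams()) == []

    def test_nearby_runs_merge_after_padding(self):
        t = np.arange(400)
        pupil = np.full(400, 2000.0)
        pupil[100:120] = 0.0
        pupil[130:150] = 0.0  # 10 ms apart; pad 50 makes them overlap
        s = series(t, *steady(400, 0, 0), pupil=pupil)
        assert detect_blinks(s, DetectorParams()) == [(50, 200)]

    @pytest.mark.parametrize("seed", range(5))
    def test_padding_matches_interval_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 1000
        t = np.arange(n)
        pupil = np.full(n, 2000.0)
        raw = []
        for _ in range(rng.integers(1, 6)):
            a = int(rng.integers(0, n - 30))
            b = a + int(rng.integers(1, 30))
            pupil[a:b] = 0.0
        # reconstruct the true maximal zero-runs, then pad + union independently
        z = pupil == 0.0
        k = 0
        while k < n:
            if z[k]:
                a = k
                while k < n and z[k]:
                    k += 1
                raw.append((max(0, a - 50), min(n, k + 50)))
            else:
                k += 1
        s = series(t, *steady(n, 0, 0), pupil=pupil)
        assert detect_blinks(s, DetectorParams()) == interval_union(raw)


class TestIDT:
    def test_two_fixations_with_sweep(self):
        # 100 ms at (0,0), 20 ms linear sweep to (10,0), 150 ms at (10,0)
        x = np.concatenate([np.zeros(100), np.linspace(0, 10, 22)[1:-1], np.full(150, 10.0)])
        y = np.zeros(270)
        s = series(np.arange(270), x, y)
        fx = detect_fixations_idt(s, DetectorParams(dispersion_deg=1.0, min_duration_ms=60), merge=False)
        assert len(fx) == 2
        assert fx[0].onset_ms == 0
        assert abs(fx[0].x_deg) < 0.3 and fx[0].duration_ms >= 100
        assert abs(fx[1].x_deg - 10.0) < 0.3
        assert fx[1].offset_ms == 270

    def test_constant_trace_single_fixation(self):
        s = series(np.arange(300), *steady(300, 2.5, -1.0))
        fx = detect_fixations_idt(s, DetectorParams())
        assert len(fx) == 1
        assert fx[0].duration_ms == 300
        assert fx[0].x_deg == pytest.approx(2.5)
        assert fx[0].y_deg == pytest.approx(-1.0)

    def test_below_min_duration_no_fixation(self):
        s = series(np.arange(50), *steady(50, 0, 0))
        assert detect_fixations_idt(s, DetectorParams(min_duration_ms=60)) == []

    def test_all_masked_series_empty(self):
        s = series(np.arange(100), *steady(100, 0, 0), pupil=0.0, valid=0)
        assert detect_fixations_idt(s, DetectorParams()) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 1200))
        # random walk with occasional jumps: adversarial for window logic
        x = np.cumsum(rng.normal(0, 0.05, n))
        y = np.cumsum(rng.normal(0, 0.05, n))
        jumps = rng.integers(0, n, size=rng.integers(1, 6))
        for j in jumps:
            x[j:] += rng.normal(0, 5)
            y[j:] += rng.normal(0, 5)
        params = DetectorParams(dispersion_deg=1.0, min_duration_ms=60)
        s = series(np.arange(n), x, y)
        got = detect_fixations_idt(s, params, merge=False)
        expected = idt_bruteforce(np.arange(n), x, y, 1.0, 60)
        assert [(f.onset_ms, f.offset_ms) for f in got] == [(i, j) for i, j in expected]


class TestSaccades:
    def fix(self, onset, offset, x=0.0, y=0.0):
        return FixationEvent(onset_ms=onset, offset_ms=offset, x_deg=x, y_deg=y, mean_pupil=0.0, n_samples=offset - onset)

    def test_two_fixations_one_saccade(self):
        sac = derive_saccades([self.fix(0, 100, 0, 0), self.fix(140, 300, 5, 0)])
        assert len(sac) == 1
        assert (sac[0].onset_ms, sac[0].offset_ms) == (100, 140)
        assert sac[0].x1_deg == 5

    def test_single_fixation_no_saccade(self):
        assert derive_saccades([self.fix(0, 100)]) == []

    def test_gap_durations(self):
        fx = [self.fix(0, 100), self.fix(140, 240), self.fix(275, 400)]
        sac = derive_saccades(fx)
        assert [s.duration_ms for s in sac] == [40, 35]

    def test_overlapping_fixations_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            derive_saccades([self.fix(0, 100), self.fix(90, 200)])


class TestRecovery:
    def test_noise_free_counts_and_boundaries(self, clean_session, detector_params):
        sim = clean_session
        for lay in sim.layouts:
            grp = sim.samples[sim.samples["trial"] == lay.trial]
            fx = [
                f
                for f in detect_fixations_idt(grp, detector_params)
                if f.onset_ms >= lay.onset_ms
            ]
            truth = sim.truth_fixations[sim.truth_fixations["trial"] == lay.trial]
            assert len(fx) == len(truth)
            for f, (_, row) in zip(fx, truth.iterrows()):
                assert abs(f.onset_ms - row["onset_ms"]) <= detector_params.merge_gap_ms
                assert abs(f.offset_ms - row["offset_ms"]) <= detector_params.merge_gap_ms

    def test_mean_duration_under_position_noise(self, clean_session, detector_params):
        """Small additive Gaussian position noise leaves the recovered mean
        fixation duration within 5% of the generative value."""
        sim = clean_session
        rng = np.random.default_rng(99)
        noisy = sim.samples.copy()
        sd = detector_params.dispersion_deg / 100  # well under the dispersion cap
        noisy["x_deg"] = noisy["x_deg"] + rng.normal(0, sd, len(noisy))
        noisy["y_deg"] = noisy["y_deg"] + rng.normal(0, sd, len(noisy))
        durs = []
        for lay in sim.layouts:
            grp = noisy[noisy["trial"] == lay.trial]
            durs += [
                f.duration_ms
                for f in detect_fixations_idt(grp, detector_params)
                if f.onset_ms >= lay.onset_ms
            ]
        truth = sim.truth_fixations
        gen_mean = float((truth["offset_ms"] - truth["onset_ms"]).mean())
        assert abs(np.mean(durs) - gen_mean) / gen_mean < 0.05
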