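"""MSD computation, model fits and the four-way motion classifier."""

import numpy as np
import pytest

from mirtrack.motion import (
    ClassifierConfig,
    classify_trajectory,
    compute_msd,
    confined_model,
    estimate_D,
    fit_confined,
    fit_quadratic,
    summarize_counts,
    summarize_fractions,
    MotionClassification,
    MSDCurve,
)
from mirtrack.synthetic import MotionParams, simulate_trajectory
from mirtrack.tracks import Trajectory


def linear_track(v, n=60, dt=0.05):
    t = np.arange(n) * dt
    return Trajectory(0, np.arange(n), np.column_stack([v * t, np.zeros(n)]), dt=dt)


def brute_force_msd(pos, max_lag):
    """Literal double-loop evaluation of the time-averaged MSD."""
    out = []
    for n in range(1, max_lag + 1):
        acc = 0.0
        cnt = 0
        for i in range(len(pos) - n):
            acc += (pos[i + n, 0] - pos[i, 0]) ** 2 + (pos[i + n, 1] - pos[i, 1]) ** 2
            cnt += 1
        out.append(acc / cnt)
    return np.array(out)


class TestComputeMSD:
    def test_stationary_track_has_zero_msd(self):
        t = simulate_trajectory(MotionParams("stationary", n_frames=60))
        assert np.allclose(compute_msd(t).msd, 0.0)

    def test_linear_motion_closed_form(self):
        msd = compute_msd(linear_track(1.0))
        expect = (0.05 * msd.lags) ** 2
        assert np.allclose(msd.msd, expect, rtol=1e-12)
        assert msd.msd[3] == pytest.approx(0.04, rel=1e-12)  # lag 4

    @pytest.mark.parametrize("truncate", [False, True])
    def test_matches_brute_force_double_loop(self, rng, truncate):
        pos = np.cumsum(rng.normal(0, 0.1, size=(80, 2)), axis=0)
        t = Trajectory(0, np.arange(80), pos, dt=0.05)
        msd = compute_msd(t, window=55, truncate=truncate)
        ref_pos = pos[:56] if truncate else pos
        assert np.allclose(msd.msd, brute_force_msd(ref_pos, 55), rtol=1e-12)
        assert np.array_equal(msd.counts, len(ref_pos) - msd.lags)

    def test_short_track_rejected(self):
        t = simulate_trajectory(MotionParams("free", D=0.1, n_frames=30))
        with pytest.raises(ValueError):
            compute_msd(t, window=55)


class TestEstimateD:
    def test_exact_line_recovers_D(self):
        lags = np.arange(1, 56)
        msd = MSDCurve(0.05, lags, 4 * 0.1 * lags * 0.05, 56 - lags, 55)
        assert estimate_D(msd) == pytest.approx(0.1, rel=1e-12)
        assert estimate_D(msd, intercept="free") == pytest.approx(0.1, rel=1e-9)

    def test_zero_msd_gives_zero_D(self):
        lags = np.arange(1, 56)
        msd = MSDCurve(0.05, lags, np.zeros(55), 56 - lags, 55)
        assert estimate_D(msd) == 0.0

    def test_recovery_on_free_ensemble(self):
        rng = np.random.default_rng(8)
        ds = [
            estimate_D(compute_msd(simulate_trajectory(
                MotionParams("free", D=0.5, n_frames=57), seed=rng)))
            for _ in range(500)
        ]
        assert np.median(ds) == pytest.approx(0.5, rel=0.10)


class TestFitConfined:
    def test_noiseless_roundtrip(self):
        lags = np.arange(1, 56)
        y = confined_model(lags.astype(float), 0.3, 10.0)
        fit = fit_confined(MSDCurve(0.05, lags, y, 56 - lags, 55))
        assert fit.converged
        assert fit.R_conf == pytest.approx(0.3, rel=1e-4)
        assert fit.tau == pytest.approx(10.0, rel=1e-4)
        # plateau of the fitted model equals 4 R^2 / 3
        assert confined_model(1e9, fit.R_conf, fit.tau) == pytest.approx(0.12, rel=1e-4)

    def test_recovery_on_confined_ensemble(self):
        # fast but not step-size ~ R exploration: the reflected walk then
        # samples the disc nearly uniformly and the plateau is unbiased
        rng = np.random.default_rng(9)
        rs = []
        for _ in range(200):
            t = simulate_trajectory(
                MotionParams("confined", R_conf=0.25, D=0.05, n_frames=57), seed=rng
            )
            fit = fit_confined(compute_msd(t))
            if fit.converged:
                rs.append(fit.R_conf)
        assert np.median(rs) == pytest.approx(0.25, rel=0.15)


class TestFitQuadratic:
    def test_pure_drift_gives_v_squared(self):
        msd = compute_msd(linear_track(1.0))
        assert fit_quadratic(msd) == pytest.approx(1.0, rel=1e-12)

    def test_zero_msd_gives_zero(self):
        lags = np.arange(1, 56)
        assert fit_quadratic(MSDCurve(0.05, lags, np.zeros(55), 56 - lags, 55)) == 0.0

    def test_equals_normal_equation_oracle(self, rng):
        lags = np.arange(1, 56)
        y = rng.uniform(0, 1, size=55)
        msd = MSDCurve(0.05, lags, y, 56 - lags, 55)
        m = (lags >= 2) & (lags <= 30)
        t = lags[m] * 0.05
        oracle = np.sum(y[m] * t**2) / np.sum(t**4)
        assert fit_quadratic(msd) == pytest.approx(max(oracle, 0.0), rel=1e-12)


class TestClassifier:
    CFG = ClassifierConfig()

    def test_stationary_track(self):
        t = simulate_trajectory(MotionParams("stationary", n_frames=57))
        c = classify_trajectory(t, self.CFG)
        assert c.label == "stationary" and c.D == 0.0

    def test_directed_track(self):
        t = simulate_trajectory(
            MotionParams("directed", v=(1.0, 0.0), D=0.05, n_frames=57), seed=1
        )
        c = classify_trajectory(t, self.CFG)
        assert c.label == "directed"
        assert c.a > 4 * c.D * 1.2

    def test_confined_track(self):
        t = simulate_trajectory(
            MotionParams("confined", R_conf=0.2, D=0.5, n_frames=57), seed=2
        )
        c = classify_trajectory(t, self.CFG)
        assert c.label == "confined" and c.tau <= 30

    def test_free_track(self):
        # free/confined discrimination needs the longer-track statistics
        t = simulate_trajectory(MotionParams("free", D=0.5, n_frames=300), seed=3)
        assert classify_trajectory(t, self.CFG).label == "diffusive"

    def test_every_track_gets_exactly_one_label(self, rng):
        modes = [
            MotionParams("stationary", n_frames=57),
            MotionParams("confined", R_conf=0.2, D=0.5, n_frames=57),
            MotionParams("free", D=0.5, n_frames=57),
            MotionParams("directed", v=(1.0, 0.0), D=0.05, n_frames=57),
        ]
        cls = [
            classify_trajectory(simulate_trajectory(p, seed=rng), self.CFG)
            for p in modes
            for _ in range(5)
        ]
        assert all(c.label in ("stationary", "confined", "diffusive", "directed") for c in cls)
        s = summarize_fractions(cls)
        assert abs(sum(s.fractions_all.values()) - 1.0) < 1e-12

    def test_recovery_at_long_track_length(self):
        """With 500-frame tracks all four modes classify at >= 90% accuracy
        (free/confined confusion decays with the number of averaged pairs)."""
        rng = np.random.default_rng(17)
        conds = {
            "stationary": MotionParams("stationary", n_frames=500),
            "confined": MotionParams("confined", R_conf=0.2, D=0.5, n_frames=500),
            "diffusive": MotionParams("free", D=0.5, n_frames=500),
            "directed": MotionParams("directed", v=(1.0, 0.0), D=0.05, n_frames=500),
        }
        for truth, p in conds.items():
            hits = sum(
                classify_trajectory(simulate_trajectory(p, seed=rng), self.CFG).label == truth
                for _ in range(60)
            )
            assert hits / 60 >= 0.90, truth

    def test_raising_immobile_threshold_monotone(self):
        rng = np.random.default_rng(19)
        tracks = [
            simulate_trajectory(MotionParams("confined", R_conf=0.15, D=0.3, n_frames=57),
                                seed=rng)
            for _ in range(40)
        ]
        counts = []
        for d_imm in (0.005, 0.01, 0.05, 0.5):
            cfg = ClassifierConfig(d_immobile=d_imm)
            cls = [classify_trajectory(t, cfg) for t in tracks]
            counts.append(sum(c.label == "stationary" for c in cls))
        assert counts == sorted(counts)


class TestSummaries:
    def test_worked_example_fractions(self):
        s = summarize_counts(
            {"directed": 778, "diffusive": 417, "confined": 984, "stationary": 4451}
        )
        assert round(100 * s.fractions_all["directed"]) == 12
        assert round(100 * s.fractions_mobile["directed"]) == 36

    def test_all_stationary_flags_mobile_undefined(self):
        s = summarize_counts({"stationary": 5})
        assert s.fractions_mobile is None

    def test_equal_mobile_counts(self):
        s = summarize_counts({"confined": 1, "diffusive": 1, "directed": 1})
        assert all(v == pytest.approx(1 / 3) for v in s.fractions_mobile.values())

    def test_flag_counting(self):
        cls = [
            MotionClassification(0, "diffusive", D=0.5, flags=["confined_fit_failed"]),
            MotionClassification(1, "stationary", D=0.0),
        ]
        assert summarize_fractions(cls).n_flagged == 1
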