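"""Time-averaged MSD curves and four-way motion-mode classification.

For a trajectory sampled at interval Δt, the time-averaged mean squared
displacement at lag n is

    MSD(n·Δt) = Σ_i [(x_{i+n} − x_i)² + (y_{i+n} − y_i)²] / (#pairs)

computed over a fixed analysis window (55 lags, i.e. the first 56 points of
the track) so that MSD statistics are comparable across tracks of different
lengths and line up with the 2.8-s duration filter.

Each track is then classified by a fixed decision tree:

1. A diffusion coefficient D is estimated from lags 2–11 by a least-squares
   fit of MSD = 4·D·t. Tracks with D ≤ 0.01 μm²/s are *stationary*
   ("immobile"); the rest are mobile. The fit goes through the origin: an
   intercept-free fit maps a confinement plateau to a positive effective D,
   which is what separates genuinely immobile tracks from confined ones
   (a free-intercept variant is available; see the methods note).
2. Mobile tracks' MSD over lags 2–30 is fitted with the confined-diffusion
   model MSD(t) = (4·R_conf²/3)·(1 − e^{−t/τ}) with t in frames (starting
   values R_conf = 0.3 μm, τ = 20 frames). Tracks with τ ≤ 30 frames are
   *confined*.
3. The remainder are fitted with MSD = a·t² (starting value a = 0.2) and
   called *directed* if a > 4·D·1.2, else *diffusive*. The comparison uses
   t in seconds (a in μm²/s², D in μm²/s); a frames-unit variant exists
   because the criterion mixes dimensions and the original unit convention
   is not on record.

Fit failures are flagged, never dropped: a failed confined fit falls
through to the quadratic branch with a warning recorded on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .tracks import Trajectory

LABELS = ("stationary", "confined", "diffusive", "directed")
MOBILE_LABELS = ("confined", "diffusive", "directed")


@dataclass
class MSDCurve:
    """Lag-indexed mean squared displacements of one track."""

    dt: float  # s
    lags: np.ndarray  # integer lags n = 1..max_lag
    msd: np.ndarray  # μm²
    counts: np.ndarray  # averaged pairs per lag
    window: int  # number of lags of the analysis window

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.int64)
        self.msd = np.asarray(self.msd, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)

    def times(self, unit: str = "seconds") -> np.ndarray:
        """Lag times in seconds or frames."""
        return self.lags * self.dt if unit == "seconds" else self.lags.astype(float)

    def select(self, lag_range: tuple) -> np.ndarray:
        lo, hi = lag_range
        if lo < self.lags[0] or hi > self.lags[-1]:
            raise ValueError(f"lag range {lag_range} outside curve lags")
        return (self.lags >= lo) & (self.lags <= hi)


@dataclass
class ClassifierConfig:
    d_immobile: float = 0.01  # μm²/s
    d_fit_lags: tuple = (2, 11)
    model_fit_lags: tuple = (2, 30)
    tau_confined_max: float = 30.0  # frames
    directed_factor: float = 1.2
    init_R_conf: float = 0.3  # μm
    init_tau: float = 20.0  # frames
    init_a: float = 0.2
    msd_window: int = 55
    msd_truncate: bool = False  # True: average only the first window+1 points
    d_intercept: str = "zero"  # "zero" or "free"
    directed_time_unit: str = "seconds"  # or "frames"

    def __post_init__(self) -> None:
        for name in ("d_immobile", "tau_confined_max", "directed_factor", "init_R_conf", "init_tau", "init_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.msd_window < self.model_fit_lags[1]:
            raise ValueError("fit lag ranges must lie within the MSD window")


@dataclass
class MotionClassification:
    track_id: object
    label: str
    D: float  # μm²/s
    R_conf: float | None = None  # μm
    tau: float | None = None  # frames
    a: float | None = None  # μm²/s² (or μm²/frame² in the frames variant)
    flags: list = field(default_factory=list)
    fit_diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# MSD and per-curve fits


def compute_msd(
    track: Trajectory,
    window: int = 55,
    max_lag: int | None = None,
    truncate: bool = False,
) -> MSDCurve:
    """Time-averaged MSD of a track, lags 1..``window``.

    The analysis window caps the maximum lag at 55 frames; by default every
    available displacement pair in the track is averaged, so longer tracks
    yield smoother curves. ``truncate=True`` restricts the average to the
    first ``window + 1`` points, which makes the per-lag pair counts — and
    hence the MSD noise level — identical across tracks of different
    lengths at the cost of discarding data.
    """
    if max_lag is None:
        max_lag = window
    if max_lag > window:
        raise ValueError("max_lag cannot exceed the window")
    if len(track) < window + 1:
        raise ValueError(f"track has {len(track)} points; needs {window + 1}")
    n_pts = window + 1 if truncate else len(track)
    frames = track.frames[:n_pts]
    if np.any(np.diff(frames) != 1):
        raise ValueError("MSD requires consecutive frames (no gaps)")
    pos = track.positions[:n_pts]
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    counts = np.empty(max_lag, dtype=np.int64)
    for n in lags:
        d = pos[n:] - pos[:-n]
        msd[n - 1] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
        counts[n - 1] = len(d)
    return MSDCurve(dt=track.dt, lags=lags, msd=msd, counts=counts, window=window)


def estimate_D(msd: MSDCurve, lag_range: tuple = (2, 11), intercept: str = "zero") -> float:
    """Diffusion coefficient from a linear MSD fit, MSD = 4·D·t (+ b).

    Negative slopes clamp to D = 0. ``intercept="free"`` adds an offset term
    that absorbs static localization error.
    """
    m = msd.select(lag_range)
    t = msd.times()[m]
    y = msd.msd[m]
    if m.sum() < 2:
        raise ValueError("need at least 2 lags to estimate D")
    if intercept == "free":
        slope = np.polyfit(t, y, 1)[0]
    elif intercept == "zero":
        slope = float(np.sum(y * t) / np.sum(t * t))
    else:
        raise ValueError("intercept must be 'zero' or 'free'")
    return max(slope / 4.0, 0.0)


@dataclass
class ConfinedFit:
    R_conf: float  # μm
    tau: float  # frames
    residual_norm: float
    converged: bool


def confined_model(t, R_conf, tau):
    """Confined-diffusion MSD: plateau 4·R_conf²/3 approached with rate 1/τ."""
    return 4.0 * R_conf**2 / 3.0 * (1.0 - np.exp(-t / tau))


def fit_confined(
    msd: MSDCurve, lag_range: tuple = (2, 30), init: tuple = (0.3, 20.0)
) -> ConfinedFit:
    """Nonlinear LS fit of the confined model with t in frames.

    τ is fitted in frame units because the classification threshold
    (30 frames) and starting value (20) are stated in frames; multiply by dt
    for seconds. Non-convergence is flagged on the result, not raised.
    """
    m = msd.select(lag_range)
    t = msd.times("frames")[m]
    y = msd.msd[m]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                confined_model,
                t,
                y,
                p0=init,
                bounds=([1e-6, 1e-6], [np.inf, np.inf]),
                maxfev=2000,
            )
        resid = confined_model(t, *popt) - y
        return ConfinedFit(
            R_conf=float(popt[0]),
            tau=float(popt[1]),
            residual_norm=float(np.linalg.norm(resid)),
            converged=True,
        )
    except (RuntimeError, ValueError):
        return ConfinedFit(R_conf=np.nan, tau=np.nan, residual_norm=np.nan, converged=False)


def fit_quadratic(
    msd: MSDCurve,
    lag_range: tuple = (2, 30),
    init_a: float = 0.2,
    time_unit: str = "seconds",
) -> float:
    """Least-squares fit of MSD = a·t²; the solution Σ msd·t²/Σ t⁴ in closed form.

    ``init_a`` is accepted for interface parity with the nonlinear fits; the
    pure-quadratic model is linear in a, so the starting value is moot.
    Negative a clamps to 0.
    """
    m = msd.select(lag_range)
    t = msd.times(time_unit)[m]
    y = msd.msd[m]
    a = float(np.sum(y * t**2) / np.sum(t**4))
    return max(a, 0.0)


# ---------------------------------------------------------------------------
# decision tree and summaries


def classify_trajectory(track: Trajectory, config: ClassifierConfig | None = None) -> MotionClassification:
    """Run the decision tree on one track and record every intermediate fit."""
    cfg = config or ClassifierConfig()
    msd = compute_msd(track, window=cfg.msd_window, truncate=cfg.msd_truncate)
    D = estimate_D(msd, cfg.d_fit_lags, intercept=cfg.d_intercept)
    diag = {"D": D}
    flags: list[str] = []

    if D <= cfg.d_immobile:
        return MotionClassification(track.id, "stationary", D=D, flags=flags, fit_diagnostics=diag)

    cfit = fit_confined(msd, cfg.model_fit_lags, init=(cfg.init_R_conf, cfg.init_tau))
    diag["confined_residual_norm"] = cfit.residual_norm
    if not cfit.converged:
        flags.append("confined_fit_failed")
        warnings.warn(f"track {track.id}: confined fit failed; falling through to quadratic test")
    elif cfit.tau <= cfg.tau_confined_max:
        return MotionClassification(
            track.id, "confined", D=D, R_conf=cfit.R_conf, tau=cfit.tau,
            flags=flags, fit_diagnostics=diag,
        )

    a = fit_quadratic(msd, cfg.model_fit_lags, cfg.init_a, time_unit=cfg.directed_time_unit)
    diag["a"] = a
    label = "directed" if a > 4.0 * D * cfg.directed_factor else "diffusive"
    return MotionClassification(
        track.id, label, D=D,
        R_conf=cfit.R_conf if cfit.converged else None,
        tau=cfit.tau if cfit.converged else None,
        a=a, flags=flags, fit_diagnostics=diag,
    )


@dataclass
class ModeSummary:
    counts: dict
    fractions_all: dict
    fractions_mobile: dict | None  # None when no mobile track exists
    n_tracks: int
    n_flagged: int = 0


def summarize_fractions(classifications: list) -> ModeSummary:
    """Mode counts and fractions over all tracks and over mobile tracks."""
    if not classifications:
        raise ValueError("no classifications to summarize")
    counts = {lab: 0 for lab in LABELS}
    n_flagged = 0
    for c in classifications:
        counts[c.label] += 1
        if c.flags:
            n_flagged += 1
    summary = summarize_counts(counts)
    summary.n_flagged = n_flagged
    return summary


def summarize_counts(counts: dict) -> ModeSummary:
    """Build the mode summary directly from per-label counts."""
    counts = {lab: int(counts.get(lab, 0)) for lab in LABELS}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no tracks counted")
    fractions_all = {lab: counts[lab] / total for lab in LABELS}
    n_mobile = sum(counts[lab] for lab in MOBILE_LABELS)
    fractions_mobile = (
        {lab: counts[lab] / n_mobile for lab in MOBILE_LABELS} if n_mobile else None
    )
    return ModeSummary(
        counts=counts,
        fractions_all=fractions_all,
        fractions_mobile=fractions_mobile,
        n_tracks=total,
    )
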