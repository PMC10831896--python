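"""Synthetic microscope: every pipeline input, with known ground truth.

The real experiment images fluorescently labeled pre-miRNA introduced into
living cells: HILO movies at 20 Hz for single-particle tracking, confocal
photon-count traces for FCS/FCCS, and two-color detection sets for
colocalization. No public raw data exists, so this module emulates each
modality with controllable ground truth:

* trajectories in four motion modes (stationary, confined, free, directed),
* movies rendered as integrated-Gaussian spots on Poisson background,
* two-channel FCS intensity traces from diffusers crossing a 3-D Gaussian
  observation volume, with a controllable double-labeled fraction,
* normalized cross-correlation amplitude time series decaying exponentially
  (the duplex-dissociation readout),
* two-channel detection sets with a planted colocalized fraction.

Every generator is deterministic under a fixed seed.

Default optics (pixel 0.16 μm, PSF σ 0.13 μm, 50 ms frames) correspond to a
100×/1.49 NA objective with an EMCCD running at 20 Hz; spot brightness and
background default to values at which detection is comfortable
(photons-per-frame ≫ background), since the real movies' SNR is not on
record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .correlation import AmplitudeSeries
from .images import ImageStack
from .tracks import Trajectory

MOTION_MODES = ("stationary", "confined", "free", "directed")


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class MotionParams:
    """Ground-truth motion model for one simulated particle.

    mode : one of "stationary", "confined", "free", "directed"
    D : diffusion coefficient, μm²/s
    v : drift velocity (vx, vy) in μm/s, used by mode="directed"
    R_conf : confinement radius in μm, used by mode="confined"
    dt : frame interval, s (the experiment's time resolution, 0.05 s)
    n_frames : number of positions to generate
    """

    mode: str
    D: float = 0.0
    v: tuple = (0.0, 0.0)
    R_conf: float | None = None
    dt: float = 0.05
    n_frames: int = 57

    def __post_init__(self) -> None:
        if self.mode not in MOTION_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        vals = [self.D, self.dt, *self.v] + ([self.R_conf] if self.R_conf is not None else [])
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite motion parameters")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.mode == "confined" and (self.R_conf is None or self.R_conf <= 0):
            raise ValueError("confined mode requires R_conf > 0")
        if self.mode == "directed" and math.hypot(*self.v) <= 0:
            raise ValueError("directed mode requires |v| > 0")


def _reflect_into_disc(pos: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect a point at a circular boundary until it lies inside."""
    delta = pos - center
    r = math.hypot(*delta)
    while r > radius:
        r_new = abs(2.0 * radius - r)
        # guard against pathological large steps bouncing forever
        if r_new >= r:
            r_new = radius * 0.999
        delta = delta * (r_new / r) if r > 0 else delta
        r = r_new
    return center + delta


def simulate_trajectory(
    params: MotionParams,
    origin: Sequence[float] = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
    track_id: object = 0,
) -> Trajectory:
    """Simulate one 2-D trajectory under the given motion model.

    Free motion uses Brownian increments with per-axis variance ``2·D·dt``;
    directed motion adds the drift ``v·dt`` per frame; confined motion
    reflects Brownian steps at the circular boundary of radius ``R_conf``
    around the origin, which preserves step-length statistics inside the
    domain. Stationary particles do not move at all.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    origin = np.asarray(origin, dtype=float)
    if not np.isfinite(origin).all():
        raise ValueError("non-finite origin")
    n = params.n_frames
    pos = np.empty((n, 2))
    pos[0] = origin
    if params.mode == "stationary":
        pos[:] = origin
    else:
        sigma = math.sqrt(2.0 * params.D * params.dt)
        steps = rng.normal(0.0, sigma, size=(n - 1, 2)) if sigma > 0 else np.zeros((n - 1, 2))
        if params.mode == "directed":
            steps = steps + np.asarray(params.v, dtype=float) * params.dt
        if params.mode == "confined":
            for i in range(1, n):
                pos[i] = _reflect_into_disc(pos[i - 1] + steps[i - 1], origin, params.R_conf)
        else:
            pos[1:] = origin + np.cumsum(steps, axis=0)
    return Trajectory(
        id=track_id,
        frames=np.arange(n),
        positions=pos,
        dt=params.dt,
        meta={"mode": params.mode, "params": params},
    )


# ---------------------------------------------------------------------------
# scene rendering


@dataclass
class SyntheticScene:
    """Ground-truth bundle: trajectories plus the optics used to render them.

    shape : image size (rows, cols) in pixels
    pixel_size : μm/pixel
    psf_sigma : μm, standard deviation of the Gaussian PSF
    photons_per_frame : expected photons emitted per spot per frame
    background : expected photons per pixel per frame
    """

    trajectories: list
    seed: int = 0
    shape: tuple = (64, 64)
    pixel_size: float = 0.16
    psf_sigma: float = 0.13
    photons_per_frame: float = 3000.0
    background: float = 10.0
    stack: ImageStack | None = None
    out_of_field: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")


def _integrated_gaussian_patch(x0, y0, sigma_px, cols, rows):
    """Expected per-pixel photon fraction of a unit-flux emitter.

    The PSF is integrated over each pixel with the error function (pixel
    centers at integer coordinates, pixel edges at half-integers), so the
    photometric centroid of the rendered spot is unbiased.
    """
    s = sigma_px * math.sqrt(2.0)
    fx = 0.5 * (erf((cols + 0.5 - x0) / s) - erf((cols - 0.5 - x0) / s))
    fy = 0.5 * (erf((rows + 0.5 - y0) / s) - erf((rows - 0.5 - y0) / s))
    return np.outer(fy, fx)


def render_image_stack(scene: SyntheticScene, seed: int | None = None) -> ImageStack:
    """Render the scene's trajectories into a Poisson-noise movie.

    Each emitter contributes an error-function-integrated 2-D Gaussian of
    width ``psf_sigma`` centered on its ground-truth position; pixel values
    are Poisson draws with mean = emitter contributions + background.
    Emitters whose center leaves the field of view are recorded in
    ``scene.out_of_field`` (and still rendered if partially visible).
    """
    if not scene.trajectories:
        n_frames = 1
    else:
        n_frames = 1 + max(int(t.frames.max()) for t in scene.trajectories)
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    ny, nx = scene.shape
    sigma_px = scene.psf_sigma / scene.pixel_size
    halfw = max(3, int(math.ceil(5 * sigma_px)))
    dt = scene.trajectories[0].dt if scene.trajectories else 0.05

    expected = np.full((n_frames, ny, nx), float(scene.background))
    scene.out_of_field = []
    for t in scene.trajectories:
        xs_px = t.positions[:, 0] / scene.pixel_size
        ys_px = t.positions[:, 1] / scene.pixel_size
        for f, x0, y0 in zip(t.frames, xs_px, ys_px):
            if not (0 <= x0 <= nx - 1 and 0 <= y0 <= ny - 1):
                scene.out_of_field.append((t.id, int(f)))
            c0, c1 = int(math.floor(x0)) - halfw, int(math.floor(x0)) + halfw + 1
            r0, r1 = int(math.floor(y0)) - halfw, int(math.floor(y0)) + halfw + 1
            c0c, c1c = max(c0, 0), min(c1, nx)
            r0c, r1c = max(r0, 0), min(r1, ny)
            if c0c >= c1c or r0c >= r1c:
                continue
            patch = _integrated_gaussian_patch(
                x0, y0, sigma_px, np.arange(c0c, c1c), np.arange(r0c, r1c)
            )
            expected[int(f), r0c:r1c, c0c:c1c] += scene.photons_per_frame * patch

    data = rng.poisson(expected).astype(np.uint16)
    stack = ImageStack(data=data, pixel_size=scene.pixel_size, dt=dt)
    scene.stack = stack
    return stack


# ---------------------------------------------------------------------------
# FCS traces


@dataclass
class FCSTraceConfig:
    """Configuration of the two-channel FCS trace simulator.

    n_particles : mean occupancy of the effective observation volume
        ``V_eff = π^{3/2}·w_xy²·w_z``
    D : diffusion coefficient, μm²/s
    w_xy : lateral 1/e² waist of the Gaussian observation volume, μm
    kappa : structure parameter w_z/w_xy (axial elongation, 10–15 on the
        instrument emulated here)
    bin_time : photon-count binning, s
    duration : trace length, s (5 s recordings in the experiment)
    brightness : photons/s emitted per particle at the volume center
    double_labeled_fraction : fraction of particles emitting in both
        channels (intact duplexes); the rest split between single-channel
        species
    """

    n_particles: float = 10.0
    D: float = 15.0
    w_xy: float = 0.25
    kappa: float = 12.0
    bin_time: float = 1e-4
    duration: float = 5.0
    brightness: float = 60000.0
    double_labeled_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if not 0.0 <= self.double_labeled_fraction <= 1.0:
            raise ValueError("double_labeled_fraction must be in [0, 1]")
        if self.n_particles <= 0 or self.D <= 0 or self.w_xy <= 0:
            raise ValueError("n_particles, D, w_xy must be positive")
        if self.bin_time <= 0 or self.duration <= 0 or self.brightness <= 0:
            raise ValueError("bin_time, duration, brightness must be positive")

    @property
    def w_z(self) -> float:
        return self.kappa * self.w_xy

    @property
    def v_eff(self) -> float:
        return math.pi ** 1.5 * self.w_xy**2 * self.w_z


@dataclass
class FCSTraces:
    counts_a: np.ndarray
    counts_b: np.ndarray
    bin_time: float
    config: FCSTraceConfig


def simulate_fcs_traces(config: FCSTraceConfig) -> FCSTraces:
    """Simulate two-channel photon-count traces from diffusing particles.

    Particles perform Brownian motion in a periodic box (lateral side
    10·w_xy so occupancy stays stationary); each contributes
    ``brightness·bin_time`` photons weighted by the 3-D Gaussian detection
    profile ``exp(−2(x²+y²)/w_xy² − 2z²/w_z²)``. A ``double_labeled_fraction``
    of particles emit into both channels; the remainder are split between
    A-only and B-only species. Per-bin photon counts are Poisson draws.
    """
    n_bins = int(round(config.duration / config.bin_time))
    if n_bins < 1000:
        raise ValueError("duration/bin_time must give at least 1000 bins")
    rng = np.random.default_rng(config.seed)

    lx = ly = 10.0 * config.w_xy
    lz = max(10.0 * config.w_xy, 4.0 * config.w_z)
    box = np.array([lx, ly, lz])
    n_total = max(3, int(round(config.n_particles * lx * ly * lz / config.v_eff)))
    n_double = int(round(config.double_labeled_fraction * n_total))
    n_a_only = (n_total - n_double + 1) // 2
    # species order along the particle axis: [double | A-only | B-only]
    a_slice = slice(0, n_double + n_a_only)
    b_members = np.zeros(n_total, dtype=bool)
    b_members[:n_double] = True
    b_members[n_double + n_a_only :] = True

    pos = rng.uniform(0.0, 1.0, size=(n_total, 3)) * box
    sigma = math.sqrt(2.0 * config.D * config.bin_time)
    center = box / 2.0
    inv2w = np.array([2.0 / config.w_xy**2, 2.0 / config.w_xy**2, 2.0 / config.w_z**2])

    mean_a = np.empty(n_bins)
    mean_b = np.empty(n_bins)
    chunk = 4096
    start = 0
    while start < n_bins:
        m = min(chunk, n_bins - start)
        steps = rng.normal(0.0, sigma, size=(m, n_total, 3))
        steps[0] += pos
        walk = np.cumsum(steps, axis=0)
        walk %= box
        pos = walk[-1]
        d2 = (walk - center) ** 2
        w = np.exp(-(d2 @ inv2w))  # (m, n_total)
        mean_a[start : start + m] = w[:, a_slice].sum(axis=1)
        mean_b[start : start + m] = w[:, b_members].sum(axis=1)
        start += m

    flux = config.brightness * config.bin_time
    counts_a = rng.poisson(flux * mean_a)
    counts_b = rng.poisson(flux * mean_b)
    return FCSTraces(counts_a=counts_a, counts_b=counts_b, bin_time=config.bin_time, config=config)


# ---------------------------------------------------------------------------
# amplitude decay series (duplex dissociation readout)


def simulate_amplitude_series(
    tau_true: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> AmplitudeSeries:
    """Normalized cross-correlation amplitude decaying exponentially.

    Values are ``exp(−(t−t0)/tau_true)`` plus Gaussian noise of ``noise_sd``;
    the first value is forced to 1 (the series is normalized at the first
    observation). Times and ``tau_true`` are in minutes.
    """
    if tau_true <= 0:
        raise ValueError("tau_true must be positive")
    times = np.asarray(times, dtype=float)
    if len(times) < 2 or not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.exp(-(times - times[0]) / tau_true)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(times))
    values[0] = 1.0
    return AmplitudeSeries(times=times, values=values)


# ---------------------------------------------------------------------------
# two-channel detection sets


def simulate_two_channel_detections(
    n_frames: int,
    n_A: int,
    n_B: int,
    coloc_fraction: float,
    jitter_sd: float = 0.05,
    fov: tuple = (20.0, 20.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant a known colocalized fraction between two detection channels.

    Per frame, ``round(coloc_fraction·n_A)`` channel-A points receive a
    channel-B partner displaced by isotropic Gaussian jitter of ``jitter_sd``
    μm; all remaining points in both channels are uniform over the field.
    Returns two detection tables (frame, x_um, y_um, quality, channel).
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fov = np.asarray(fov, dtype=float)
    n_col = int(round(coloc_fraction * n_A))
    n_col = min(n_col, n_B)
    rows_a, rows_b = [], []
    for f in range(n_frames):
        pts_a = rng.uniform(0.0, 1.0, size=(n_A, 2)) * fov
        partners = pts_a[:n_col] + rng.normal(0.0, jitter_sd, size=(n_col, 2))
        extra_b = rng.uniform(0.0, 1.0, size=(n_B - n_col, 2)) * fov
        pts_b = np.vstack([partners, extra_b]) if n_B else np.empty((0, 2))
        rows_a.append(pd.DataFrame({"frame": f, "x_um": pts_a[:, 0], "y_um": pts_a[:, 1]}))
        rows_b.append(pd.DataFrame({"frame": f, "x_um": pts_b[:, 0], "y_um": pts_b[:, 1]}))
    det_a = pd.concat(rows_a, ignore_index=True)
    det_b = pd.concat(rows_b, ignore_index=True)
    for df, ch in ((det_a, "A"), (det_b, "B")):
        df["quality"] = 100.0
        df["channel"] = ch
    return det_a, det_b
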