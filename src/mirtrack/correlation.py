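"""Fluorescence (cross-)correlation spectroscopy.

Correlation curves are computed from binned photon-count traces as

    G(τ) − 1 = ⟨δF_A(t) · δF_B(t+τ)⟩ / (⟨F_A⟩ ⟨F_B⟩)

on a quasi-logarithmic lag grid (16 lags per octave, lag spacing doubling
each octave — the classic multiple-tau layout). Amplitudes are estimated at
full bin resolution by direct shifted products rather than by octave
rebinning, so the estimator is exactly reproducible by a brute-force
correlator; for the trace lengths involved (5-s recordings) the extra noise
at long lags is irrelevant to the 0.01–813 ms fit window used here.

The single-diffusing-species model fitted to the curves is

    G(τ) − 1 = (1/N) · 1/(1 + τ/τ₁) · [1 + (1/κ)²(τ/τ₁)]^(−1/2)

with N the mean number of fluorescent molecules in the observation volume,
τ₁ the diffusion time and κ the structure parameter (axial/lateral aspect
ratio of the Gaussian volume, 10–15 on the instrument emulated here; κ is
held fixed during fitting because it is not identifiable from a single
curve). A two-component variant shares N and κ and splits the amplitude
between two diffusion times.

The time-dependent FCCS readout — the normalized cross-correlation
amplitude, which decays as labeled duplexes dissociate — is fitted with a
single exponential fixed to 1 at the first observation, yielding the
dissociation time constant in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize

FIT_WINDOW_S = (1e-5, 0.813)  # 0.01–813 ms


@dataclass
class CorrelationCurve:
    lags: np.ndarray  # s, strictly increasing
    g_minus_1: np.ndarray
    kind: str = "auto"  # "auto" or "cross"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g_minus_1 = np.asarray(self.g_minus_1, dtype=float)
        if len(self.lags) != len(self.g_minus_1):
            raise ValueError("lags and values length mismatch")
        if len(self.lags) >= 2 and not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be strictly increasing")
        if not (np.isfinite(self.lags).all() and np.isfinite(self.g_minus_1).all()):
            raise ValueError("non-finite correlation curve")

    def restrict(self, tmin: float, tmax: float) -> "CorrelationCurve":
        m = (self.lags >= tmin) & (self.lags <= tmax)
        return CorrelationCurve(self.lags[m], self.g_minus_1[m], self.kind)


@dataclass
class FCSFit:
    N: float
    tau1: float  # s
    kappa: float
    tau2: float | None = None
    fraction: float | None = None  # amplitude fraction of component 1
    residual_norm: float = np.nan
    converged: bool = True

    @property
    def amplitude(self) -> float:
        """Zero-lag amplitude of the fitted model, G(0) − 1 = 1/N."""
        return 1.0 / self.N


@dataclass
class AmplitudeSeries:
    """Normalized FCCS amplitude vs time since probe introduction (minutes)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not math.isclose(self.values[0], 1.0, abs_tol=1e-9):
            raise ValueError("series must be normalized to 1 at the first time point")


@dataclass
class DecayFit:
    tau_decay: float  # minutes
    amplitude: float
    residual_norm: float
    non_decaying: bool = False


# ---------------------------------------------------------------------------
# correlator


def multiple_tau_lags(n_bins: int, m: int = 16) -> np.ndarray:
    """Quasi-logarithmic lag grid in units of bins.

    The first octave holds lags 1..m at unit spacing; every later octave
    doubles the spacing, mirroring a multiple-tau correlator's register
    layout. Lags reaching half the trace length are dropped (too few
    products to average).
    """
    lags = list(range(1, m + 1))
    spacing = 2
    last = lags[-1]
    while last + spacing < n_bins // 2:
        for _ in range(m // 2):
            last += spacing
            if last >= n_bins // 2:
                break
            lags.append(last)
        spacing *= 2
    return np.array(lags, dtype=np.int64)


def correlate(
    trace_a: np.ndarray,
    trace_b: np.ndarray | None = None,
    bin_time: float = 1e-4,
    lag_bins: np.ndarray | None = None,
) -> CorrelationCurve:
    """Correlation curve of two photon-count traces (auto if one trace).

    For each lag τ = k·bin_time the estimator uses the overlapping segments:

        G(k) − 1 = mean(A[:n−k] · B[k:]) / (mean(A[:n−k]) · mean(B[k:])) − 1
    """
    a = np.asarray(trace_a, dtype=float)
    kind = "auto" if trace_b is None else "cross"
    b = a if trace_b is None else np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-D and equal length")
    n = len(a)
    if n < 1000:
        raise ValueError("traces too short to correlate (< 1000 bins)")
    if a.mean() == 0 or b.mean() == 0:
        raise ValueError("zero-mean trace: correlation undefined")
    if lag_bins is None:
        lag_bins = multiple_tau_lags(n)
    g = np.empty(len(lag_bins))
    for i, k in enumerate(lag_bins):
        head, tail = a[: n - k], b[k:]
        g[i] = np.mean(head * tail) / (head.mean() * tail.mean()) - 1.0
    return CorrelationCurve(lags=lag_bins * bin_time, g_minus_1=g, kind=kind)


# ---------------------------------------------------------------------------
# model fitting


def fcs_model(tau: np.ndarray, N: float, tau1: float, kappa: float) -> np.ndarray:
    """One-component 3-D diffusion model for G(τ) − 1."""
    x = tau / tau1
    return (1.0 / N) / (1.0 + x) / np.sqrt(1.0 + (1.0 / kappa) ** 2 * x)


def fit_fcs_model(
    curve: CorrelationCurve,
    n_components: int = 1,
    kappa: float = 12.0,
    fit_window: tuple = FIT_WINDOW_S,
) -> FCSFit:
    """Fit the diffusion model to a correlation curve with κ held fixed.

    The two-component variant is the amplitude-weighted sum of two diffusion
    terms sharing N and κ:
    ``(1/N)·[f·g(τ/τ₁) + (1−f)·g(τ/τ₂)]``.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    sub = curve.restrict(*fit_window)
    if len(sub.lags) < 10:
        raise ValueError("curve covers fewer than 10 lags in the fit window")

    amp0 = max(float(np.mean(sub.g_minus_1[:3])), 1e-6)
    p = Parameters()
    p.add("N", value=1.0 / amp0, min=1e-4, max=1e8)
    p.add("tau1", value=float(np.median(sub.lags)), min=sub.lags[0] / 100, max=sub.lags[-1] * 100)
    if n_components == 2:
        p.add("tau2", value=float(sub.lags[-1] / 10), min=sub.lags[0] / 100, max=sub.lags[-1] * 100)
        p.add("fraction", value=0.5, min=0.0, max=1.0)

    def resid(p):
        if n_components == 1:
            model = fcs_model(sub.lags, p["N"].value, p["tau1"].value, kappa)
        else:
            g1 = fcs_model(sub.lags, 1.0, p["tau1"].value, kappa)
            g2 = fcs_model(sub.lags, 1.0, p["tau2"].value, kappa)
            model = (1.0 / p["N"].value) * (p["fraction"].value * g1 + (1 - p["fraction"].value) * g2)
        return model - sub.g_minus_1

    out = minimize(
        resid, p, method="leastsq", max_nfev=10000, xtol=2.3e-16, ftol=2.3e-16
    )
    # one polishing restart: resets the trust region near the solution
    out = minimize(resid, out.params, method="leastsq", max_nfev=10000, xtol=2.3e-16, ftol=2.3e-16)
    res = resid(out.params)
    return FCSFit(
        N=out.params["N"].value,
        tau1=out.params["tau1"].value,
        kappa=kappa,
        tau2=out.params["tau2"].value if n_components == 2 else None,
        fraction=out.params["fraction"].value if n_components == 2 else None,
        residual_norm=float(np.linalg.norm(res)),
        converged=bool(out.success),
    )


def relative_cc_amplitude(fit_cc: FCSFit, fit_ac_a: FCSFit, fit_ac_b: FCSFit) -> float:
    """Cross-correlation amplitude relative to the smaller autocorrelation.

    ``(1/N_cc) / min(1/N_A, 1/N_B)`` — the standard FCCS readout of the
    double-labeled (co-diffusing) fraction; ≈1 for a fully double-labeled
    sample and ≈0 when the two labels never co-diffuse.
    """
    amp_a, amp_b = fit_ac_a.amplitude, fit_ac_b.amplitude
    if amp_a <= 0 or amp_b <= 0:
        raise ValueError("degenerate autocorrelation amplitude")
    return fit_cc.amplitude / min(amp_a, amp_b)


def fit_amplitude_decay(series: AmplitudeSeries, fix_amplitude: bool = True) -> DecayFit:
    """Exponential fit of the normalized FCCS amplitude decay.

    Model: ``value = A·exp(−(t − t0)/tau_decay)`` with A fixed to 1 because
    the series is normalized at the first observation (a free-amplitude
    variant is available with ``fix_amplitude=False``). ``tau_decay`` is in
    minutes. A series that does not decay (best-fit rate ~0) is flagged.
    """
    if len(series.times) < 3:
        raise ValueError("need at least 3 time points")
    t = series.times - series.times[0]
    v = series.values
    tmax = t[-1]

    p = Parameters()
    p.add("rate", value=1.0 / max(tmax / 3.0, 1e-9), min=0.0, max=1e6)
    if not fix_amplitude:
        p.add("A", value=1.0, min=1e-6)

    def resid(p):
        amp = p["A"].value if "A" in p else 1.0
        return amp * np.exp(-p["rate"].value * t) - v

    out = minimize(resid, p, method="leastsq")
    rate = out.params["rate"].value
    amp = out.params["A"].value if "A" in out.params else 1.0
    non_decaying = rate <= 1.0 / (100.0 * tmax)
    tau = np.inf if non_decaying else 1.0 / rate
    return DecayFit(
        tau_decay=float(tau),
        amplitude=float(amp),
        residual_norm=float(np.linalg.norm(resid(out.params))),
        non_decaying=bool(non_decaying),
    )
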