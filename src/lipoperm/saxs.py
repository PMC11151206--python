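"""1D SAXS curves of liposome dispersions: simulation and peak analysis.

A vesicle dispersion scatters with a power-law background
``I(q) ~ q^−D`` (large particles beyond the resolution limit, no
Guinier plateau) plus weak, broad Bragg-like reflections from the
bilayer stacking at ``q₁ = 2π/d`` and its second order ``2q₁``.  A
1:2 position ratio indicates a lamellar (layered) structure; low, broad
peaks point to predominantly unilamellar vesicles, whereas multilamellar
stacks would give sharp intense ones.

Peaks are modelled as log-normal-shaped profiles in ``q`` (Gaussian in
``ln q``, maximum exactly at the center parameter) on top of the
power-law background; fitting is least squares on ``log I`` so the
decades-spanning background does not drown out the peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy.signal import find_peaks

__all__ = [
    "SAXSCurve",
    "PeakFit",
    "simulate_saxs",
    "fit_peaks",
    "lamellar_spacing",
]

#: default instrument q range, Å⁻¹
DEFAULT_Q_RANGE = (0.004, 0.65)


@dataclass(frozen=True)
class SAXSCurve:
    """One-dimensional scattering curve: q in Å⁻¹, intensity in a.u."""

    q: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.size < 2 or np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.asarray(self.I).shape != q.shape:
            raise ValueError("q and I must have the same shape")


@dataclass(frozen=True)
class PeakFit:
    """Fitted peak centers/widths/amplitudes plus the background power law.

    ``centers`` are sorted ascending (Å⁻¹); ``widths`` are the Gaussian
    sigmas in ln q; ``background_exponent`` is D of ``I ~ q^−D``.
    ``peakless`` flags fits whose peak amplitudes are negligible against
    the background.
    """

    centers: tuple[float, ...]
    widths: tuple[float, ...]
    amplitudes: tuple[float, ...]
    background_exponent: float
    background_scale: float
    rss_log: float
    peakless: bool = False

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths):
            raise ValueError("peak widths must be positive")


def _lognormal_peak(q: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * (np.log(q / center) / width) ** 2)


def lamellar_spacing(q1: float) -> float:
    """Lamellar repeat distance d = 2π/q₁, returned in nm for q₁ in Å⁻¹."""
    if not (q1 > 0):
        raise ValueError("first-order peak position must be positive")
    return 2.0 * np.pi / q1 / 10.0  # Å → nm


def simulate_saxs(
    d_spacing: float,
    D: float = 3.6,
    peak_params: tuple[tuple[float, float], ...] = ((0.25, 0.12), (0.10, 0.12)),
    background_scale: float = 1.0,
    q_range: tuple[float, float] = DEFAULT_Q_RANGE,
    n_q: int = 600,
    noise_frac: float = 0.0,
    seed: int | None = None,
) -> SAXSCurve:
    """Synthetic lamellar curve: power-law background plus peaks at
    q₁ = 2π/d and 2q₁.

    ``d_spacing`` in nm; ``peak_params`` gives per-order (relative
    amplitude, ln-q width) where amplitude is relative to the background
    intensity at that peak's position — broad, low peaks on a steep
    background, as unilamellar vesicles produce.  ``noise_frac`` adds
    proportional Gaussian noise.
    """
    if d_spacing <= 0:
        raise ValueError("d-spacing must be positive")
    q = np.geomspace(q_range[0], q_range[1], n_q)
    I = background_scale * q ** (-D)
    q1 = 2.0 * np.pi / (d_spacing * 10.0)  # nm → Å
    for order, (rel_amp, width) in enumerate(peak_params, start=1):
        center = order * q1
        amp = rel_amp * background_scale * center ** (-D)
        I = I + _lognormal_peak(q, center, width, amp)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        I = I * (1.0 + noise_frac * rng.standard_normal(I.shape))
        I = np.clip(I, np.min(I[I > 0]) if np.any(I > 0) else 1e-12, None)
    return SAXSCurve(q=q, I=I)


def fit_peaks(
    curve: SAXSCurve,
    n_peaks: int = 2,
    q_window: tuple[float, float] | None = None,
    peakless_threshold: float = 1e-3,
) -> PeakFit:
    """Fit a power-law background plus ``n_peaks`` log-normal peaks.

    Least squares on ``log I`` over ``q_window`` (default: the whole
    curve).  The background is initialized by a log-log line through the
    low- and high-q flanks; peak centers by prominence-ranked local
    maxima of the background-subtracted residual (equally spaced
    fallback).  Centers are returned sorted ascending.

    Raises
    ------
    RuntimeError
        If the optimizer fails outright.
    """
    if n_peaks < 1:
        raise ValueError("need at least one peak")
    q = np.asarray(curve.q, dtype=float)
    I = np.asarray(curve.I, dtype=float)
    if q_window is not None:
        mask = (q >= q_window[0]) & (q <= q_window[1])
        if np.count_nonzero(mask) < 5 * n_peaks:
            raise ValueError("q_window too narrow for the requested peak count")
        q, I = q[mask], I[mask]
    I = np.clip(I, np.min(I[I > 0]), None)
    logq, logI = np.log(q), np.log(I)

    # background init: line through the outer 15% flanks in log-log space
    n = q.size
    flank = max(3, n * 15 // 100)
    idx = np.r_[0:flank, n - flank: n]
    slope, intercept = np.polyfit(logq[idx], logI[idx], 1)
    D0 = -slope
    c0 = np.exp(intercept)

    resid = logI - (intercept + slope * logq)
    found, props = find_peaks(resid, prominence=0.0)
    if found.size:
        order = np.argsort(props["prominences"])[::-1]
        centers0 = sorted(q[found[order[:n_peaks]]])
    else:
        centers0 = []
    while len(centers0) < n_peaks:
        centers0 = list(centers0) + [float(np.exp(np.median(logq)))]

    params = Parameters()
    params.add("logc", value=np.log(c0))
    params.add("D", value=max(D0, 0.1), min=0.0, max=8.0)
    for i, c in enumerate(centers0):
        amp0 = float(np.interp(c, q, I)) * max(
            np.exp(np.interp(np.log(c), logq, resid)) - 1.0, 0.05
        )
        params.add(f"center{i}", value=c, min=q[0], max=q[-1])
        params.add(f"width{i}", value=0.12, min=1e-3, max=2.0)
        params.add(f"amp{i}", value=max(amp0, 1e-12 * I.max()), min=0.0)

    def model(p) -> np.ndarray:
        out = np.exp(p["logc"].value) * q ** (-p["D"].value)
        for i in range(n_peaks):
            out = out + _lognormal_peak(
                q, p[f"center{i}"].value, p[f"width{i}"].value, p[f"amp{i}"].value
            )
        return out

    def residual(p):
        return np.log(np.clip(model(p), 1e-300, None)) - logI

    res = minimize(residual, params, method="leastsq")
    if not res.success:
        raise RuntimeError(f"SAXS peak fit did not converge: {res.message}")
    p = res.params
    order = np.argsort([p[f"center{i}"].value for i in range(n_peaks)])
    centers = tuple(float(p[f"center{i}"].value) for i in order)
    widths = tuple(float(p[f"width{i}"].value) for i in order)
    amps = tuple(float(p[f"amp{i}"].value) for i in order)
    bg_at_centers = [
        float(np.exp(p["logc"].value) * c ** (-p["D"].value)) for c in centers
    ]
    peakless = all(a < peakless_threshold * b for a, b in zip(amps, bg_at_centers))
    return PeakFit(
        centers=centers,
        widths=widths,
        amplitudes=amps,
        background_exponent=float(p["D"].value),
        background_scale=float(np.exp(p["logc"].value)),
        rss_log=float(np.sum(np.asarray(res.residual) ** 2)),
        peakless=peakless,
    )
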