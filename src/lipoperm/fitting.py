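"""Analysis chain: intensity → concentration → stage segmentation →
exponential regression → permeability and partition coefficient.

The measured observable is the exterior dye concentration.  The chain
mirrors how release experiments are evaluated:

1. convert intensity to concentration with the linear calibration;
2. segment the trace into baseline, release (from the inflection point
   onward), plateau and post-Triton stages;
3. regress ``c(t) = c_fin − a·exp(−b·(t − t_infl))`` on the release
   window — ``b`` is the first-order efflux rate constant;
4. permeability ``P = b·V_in·V_out/(A·(V_in + V_out))`` (the exact
   inverse of the forward rate constant);
5. partition coefficient from the plateau mass balance
   ``K = (c_triton − c_fin)/c_fin · V_aq/V_lip``;
6. aggregate replicates to mean ± sample SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from lmfit import Model

from .geometry import AssayGeometry, GeometryError
from .simulate import CalibrationCurve, FluorescenceTrace

__all__ = [
    "FitError",
    "SegmentationError",
    "ReleaseFit",
    "ExponentialFit",
    "StageMarkers",
    "ConditionSummary",
    "intensity_to_concentration",
    "segment_stages",
    "relative_release",
    "fit_exponential",
    "permeability_from_fit",
    "partition_from_plateau",
    "fit_release",
    "fit_condition",
]

_UL_TO_CM3 = 1e-3


class FitError(RuntimeError):
    """Raised when a regression cannot produce a usable result."""


class SegmentationError(ValueError):
    """Raised when a trace cannot be split into assay stages."""


@dataclass(frozen=True)
class StageMarkers:
    """Index ranges of the four assay stages within one trace.

    ``baseline`` and ``plateau`` are (start, stop) half-open index
    windows; ``inflection`` is the sample where release kinetics begin
    (fit window start) and ``triton`` the first post-micellization
    sample.  ``release_absent`` flags traces with no detectable efflux
    (plateau at the baseline level).
    """

    baseline: tuple[int, int]
    inflection: int
    plateau: tuple[int, int]
    triton: int
    release_absent: bool = False


@dataclass(frozen=True)
class ReleaseFit:
    """Full fit result for one trace.

    Concentrations in μg/mL, ``b`` in 1/s, ``P`` in cm/s, ``K``
    dimensionless.  ``a``/``b`` are the regression amplitude and rate;
    ``rss`` is the residual sum of squares in concentration units².
    """

    c0: float
    c_fin: float
    c_triton: float
    a: float
    b: float
    P: float
    K: float
    fit_window: tuple[float, float]
    rss: float
    converged: bool
    saturated_samples: int = 0

    @property
    def relative_plateau(self) -> float:
        """Plateau fraction c_fin/c_triton."""
        return self.c_fin / self.c_triton


@dataclass(frozen=True)
class ConditionSummary:
    """Replicate-aggregated transport parameters for one condition."""

    condition_label: str
    P_mean: float
    P_sd: float
    K_mean: float
    K_sd: float
    n: int
    statuses: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("summary needs at least one successful replicate")


def intensity_to_concentration(
    trace: FluorescenceTrace, calib: CalibrationCurve
) -> np.ndarray:
    """Convert intensity to concentration, c = (F − intercept)/slope.

    Negative excursions from noise are clipped at zero.  Samples above
    the calibration's linear range are converted linearly anyway but a
    trace that is saturated everywhere is unusable.
    """
    c = calib.concentration(trace.F)
    n_sat = int(np.sum(c > calib.linear_max))
    if n_sat == c.size:
        raise FitError("every sample exceeds the calibration linear range")
    if n_sat:
        warnings.warn(
            f"{n_sat} samples above the calibration linear range", stacklevel=2
        )
    return c


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; width forced odd."""
    width = max(1, int(width) | 1)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def segment_stages(
    trace: FluorescenceTrace, smooth_width: int = 11
) -> StageMarkers:
    """Locate the four assay stages on a fluorescence trace.

    Baseline = samples before the heat onset (first 10% of pre-Triton
    samples if no onset marker is recorded).  The Triton index comes
    from the recorded event or, failing that, from the largest positive
    single-sample jump after the plateau (latest maximal jump wins).
    The inflection point is the maximum of the smoothed first difference
    between heat onset and Triton; the plateau window is the last 10% of
    pre-Triton samples.
    """
    t = np.asarray(trace.t, dtype=float)
    F = np.asarray(trace.F, dtype=float)
    n = t.size
    if n < 10:
        raise SegmentationError("trace too short to segment")

    # --- Triton index ---
    if trace.triton_time is not None:
        triton = int(np.searchsorted(t, trace.triton_time))
        if triton >= n:
            raise SegmentationError("Triton marker beyond the end of the trace")
    else:
        d = np.diff(F)
        scale = np.median(np.abs(d)) + 1e-12 * (np.max(np.abs(F)) + 1.0)
        jmax = np.max(d)
        if jmax <= 10.0 * scale:
            raise SegmentationError("no Triton event marker and no detectable jump")
        # latest maximal jump wins
        candidates = np.flatnonzero(d >= jmax * (1.0 - 1e-9))
        triton = int(candidates[-1]) + 1

    # --- baseline window ---
    if trace.heat_onset is not None:
        onset = int(np.searchsorted(t, trace.heat_onset))
        onset = max(onset, 1)
    else:
        onset = max(1, triton // 10)
    baseline = (0, onset)

    # --- plateau: last 10% of pre-Triton samples (excluding the jump) ---
    pre = triton
    p0 = max(onset, pre - max(1, pre // 10))
    plateau = (p0, pre)

    # --- inflection: max smoothed first difference in (onset, triton) ---
    # Smooth the pre-Triton segment only, so the detergent jump cannot
    # bleed into the window through the convolution kernel.  Under noise
    # the narrow-kernel derivative is flat-plateau dominated, so first
    # localize the steep rise with a wide central-mean difference, then
    # refine with the narrow smoothed difference inside that region.
    d = np.diff(F)
    lo, hi = onset, max(onset + 1, triton - 1)
    seg = _smooth(d[lo:hi], smooth_width) if hi > lo else np.empty(0)
    if seg.size:
        h = max(3 * smooth_width, (hi - lo) // 8)
        wide = _smooth(d[lo:hi], 2 * h + 1)
        # earliest index whose wide derivative is close to the maximum:
        # for peaked derivatives this sits just before the peak, for
        # near-linear rises (slow efflux) it keeps the whole window
        wmax = float(np.max(wide))
        if wmax > 0:
            crude = int(np.flatnonzero(wide >= 0.75 * wmax)[0])
        else:
            crude = int(np.argmax(wide))
        w0, w1 = max(0, crude - h), min(seg.size, crude + h + 1)
        inflection = lo + w0 + int(np.argmax(seg[w0:w1]))
    else:
        inflection = onset

    # --- release-absent detection ---
    base_mean = float(np.mean(F[baseline[0]: baseline[1]]))
    base_sd = float(np.std(F[baseline[0]: baseline[1]]))
    plat_mean = float(np.mean(F[plateau[0]: plateau[1]]))
    rise = plat_mean - base_mean
    tiny = 1e-9 * (abs(base_mean) + 1.0)
    release_absent = bool(
        (seg.size == 0 or np.max(seg) <= 0) or rise <= 3.0 * base_sd + tiny
    )

    return StageMarkers(
        baseline=baseline,
        inflection=inflection,
        plateau=plateau,
        triton=triton,
        release_absent=release_absent,
    )


def relative_release(
    c: np.ndarray, c0: float, c_triton: float
) -> np.ndarray:
    """Released fraction rel(t) = (c(t) − c0)/(c_triton − c0)."""
    if not (c_triton > c0):
        raise ValueError("degenerate trace: c_triton must exceed c0")
    return (np.asarray(c, dtype=float) - c0) / (c_triton - c0)


def _exp_model(t, c_inf, a, b, t0=0.0):
    return c_inf - a * np.exp(-b * (t - t0))


class ExponentialFit(NamedTuple):
    """Regression result: amplitude ``a``, rate ``b`` (1/s), residual sum
    of squares, convergence flag, and the fitted asymptote ``c_inf``."""

    a: float
    b: float
    rss: float
    converged: bool
    c_inf: float


def fit_exponential(
    t: np.ndarray,
    c: np.ndarray,
    window: tuple[float, float] | None = None,
) -> ExponentialFit:
    """Nonlinear least squares of c(t) = c_inf − a·exp(−b·(t − t_start)).

    The rate is initialized from the log-linearized derivative (exact
    for clean exponentials) with a log-spaced restart grid as fallback.

    Raises
    ------
    FitError
        For constant input (rate unidentifiable) or if no restart
        converges.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, c = t[mask], c[mask]
    if t.size < 5:
        raise FitError("fit window must contain at least 5 samples")
    if np.ptp(c) == 0.0:
        raise FitError("constant concentration: rate constant unidentifiable")

    t0 = t[0]
    span = t[-1] - t0
    amp = float(c[-1] - c[0])

    # initial rate from the derivative's log-slope (exact when noise-free)
    b_candidates: list[float] = []
    d = np.diff(c) / np.diff(t)
    pos = d > 0
    if np.count_nonzero(pos) >= max(5, d.size // 4):
        tm = 0.5 * (t[:-1] + t[1:])[pos]
        with np.errstate(divide="ignore"):
            logd = np.log(d[pos])
        good = np.isfinite(logd)
        if np.count_nonzero(good) >= 3:
            slope = np.polyfit(tm[good], logd[good], 1)[0]
            if slope < 0:
                b_candidates.append(-slope)
    b_candidates += list(np.logspace(np.log10(0.05 / span), np.log10(50.0 / span), 9))

    model = Model(_exp_model, independent_vars=["t"])
    best = None
    for b0 in b_candidates:
        params = model.make_params(
            c_inf={"value": float(c[-1]) + abs(amp) * np.exp(-b0 * span), "min": -np.inf},
            a={"value": max(abs(amp), 1e-30) / max(1e-12, 1 - np.exp(-b0 * span)),
               "min": 0.0},
            b={"value": b0, "min": 1e-12},
            t0={"value": t0, "vary": False},
        )
        try:
            res = model.fit(c, params, t=t, method="leastsq",
                            fit_kws={"xtol": 1e-14, "ftol": 1e-14})
        except Exception:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[0]:
            best = (rss, res)
        # clean data: stop as soon as the fit is essentially exact
        if rss <= 1e-20 * max(1.0, float(np.sum(c**2))):
            break
    if best is None:
        raise FitError("exponential regression failed to converge on every restart")
    rss, res = best
    a = float(res.params["a"].value)
    b = float(res.params["b"].value)
    c_inf = float(res.params["c_inf"].value)
    converged = bool(res.success) and b > 0
    if not converged:
        raise FitError("exponential regression did not converge")
    return ExponentialFit(a=a, b=b, rss=rss, converged=converged, c_inf=c_inf)


def permeability_from_fit(b: float, geom: AssayGeometry) -> float:
    """Permeability from the fitted rate: P = b·V_in·V_out/(A·(V_in+V_out)).

    Exact inverse of the forward rate constant; for monodisperse
    thin-shell vesicles with V_out ≫ V_in this is ≈ b·d_Sauter/6
    corrected by V_out/(V_in + V_out).
    """
    if not (b > 0):
        raise FitError("rate constant must be positive")
    if geom.A <= 0 or geom.V_in <= 0 or geom.V_out <= 0:
        raise GeometryError("geometry with empty compartments or zero area")
    v_in = geom.V_in * _UL_TO_CM3
    v_out = geom.V_out * _UL_TO_CM3
    return b * v_in * v_out / (geom.A * (v_in + v_out))


def partition_from_plateau(
    c_fin: float, c_triton: float, geom: AssayGeometry
) -> float:
    """Apparent partition coefficient from the plateau mass balance.

    K = (c_triton − c_fin)/c_fin · V_aq/V_lip.  The dye unaccounted for
    by the thermal-release plateau but freed by Triton must have been in
    the membrane; normalizing by the membrane/aqueous volume ratio turns
    that mass into a concentration ratio.
    """
    if c_fin <= 0:
        raise FitError("partition coefficient undefined for c_fin <= 0")
    if geom.V_lip <= 0:
        raise GeometryError("partition coefficient undefined without lipid")
    K = (c_triton - c_fin) / c_fin * (geom.V_aq / geom.V_lip)
    return max(K, 0.0)


def fit_release(
    trace: FluorescenceTrace,
    calib: CalibrationCurve,
    geom: AssayGeometry,
    smooth_width: int = 11,
) -> ReleaseFit:
    """Run the full chain on one trace: convert, segment, regress, derive.

    ``c0`` is the mean baseline concentration (captures the ~10%
    unencapsulated dye); it is subtracted before the regression and the
    asymptote re-offset, so the reported ``c_fin`` is on the raw scale
    used by the plateau mass balance.  ``c_fin`` is the fitted
    asymptote, not the last raw sample, which makes truncated plateaus
    usable.
    """
    c = intensity_to_concentration(trace, calib)
    n_sat = int(np.sum(c > calib.linear_max))
    marks = segment_stages(trace, smooth_width=smooth_width)
    t = np.asarray(trace.t, dtype=float)

    c0 = float(np.mean(c[marks.baseline[0]: marks.baseline[1]]))
    post = c[marks.triton + 1:]
    if post.size == 0:
        post = c[marks.triton:]
    c_triton = float(np.mean(post))

    if marks.release_absent:
        raise FitError("no detectable release: rate constant unidentifiable")

    i0, i1 = marks.inflection, marks.triton
    window = (t[i0], t[i1 - 1])
    exp_fit = fit_exponential(t[i0:i1], c[i0:i1] - c0, window=None)
    a, b, rss, converged = exp_fit.a, exp_fit.b, exp_fit.rss, exp_fit.converged
    c_fin = exp_fit.c_inf + c0

    P = permeability_from_fit(b, geom)
    K = partition_from_plateau(c_fin, c_triton, geom)
    return ReleaseFit(
        c0=c0,
        c_fin=c_fin,
        c_triton=c_triton,
        a=a,
        b=b,
        P=P,
        K=K,
        fit_window=window,
        rss=rss,
        converged=converged,
        saturated_samples=n_sat,
    )


def fit_condition(
    traces: list[FluorescenceTrace],
    calib: CalibrationCurve,
    geom: AssayGeometry,
    condition_label: str | None = None,
    smooth_width: int = 11,
) -> ConditionSummary:
    """Fit every replicate of a condition and aggregate mean ± sample SD.

    Replicates that fail (degenerate or non-convergent) are recorded in
    ``statuses`` and excluded from the aggregate; if all fail a
    :class:`FitError` is raised.
    """
    if not traces:
        raise ValueError("no replicates supplied")
    label = condition_label or traces[0].condition_label
    Ps, Ks, statuses = [], [], []
    for tr in traces:
        try:
            fit = fit_release(tr, calib, geom, smooth_width=smooth_width)
        except (FitError, SegmentationError) as exc:
            statuses.append(f"failed: {exc}")
            continue
        Ps.append(fit.P)
        Ks.append(fit.K)
        statuses.append("ok")
    if not Ps:
        raise FitError(f"all {len(traces)} replicates of '{label}' failed")
    if len(Ps) < len(traces):
        warnings.warn(
            f"condition '{label}': {len(traces) - len(Ps)} of {len(traces)} "
            "replicates failed and were excluded",
            stacklevel=2,
        )
    Ps_arr = np.asarray(Ps)
    Ks_arr = np.asarray(Ks)
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return ConditionSummary(
        condition_label=label,
        P_mean=float(np.mean(Ps_arr)),
        P_sd=sd(Ps_arr),
        K_mean=float(np.mean(Ks_arr)),
        K_sd=sd(Ks_arr),
        n=len(Ps),
        statuses=tuple(statuses),
    )
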