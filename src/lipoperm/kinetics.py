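"""Forward kinetic model of thermally induced dye efflux from liposomes.

The assay observable is the externally dissolved, dequenched fraction of
an encapsulated self-quenching dye (carboxyfluorescein, CF).  The model
is a two-compartment aqueous mass balance across a single bilayer:

    V_in  dc_in/dt  = −P(T)·A·(c_in − c_out)
    V_out dc_out/dt = +P(T)·A·(c_in − c_out)

with permeability ``P`` switching between a near-impermeable gel-phase
value and a permeable fluid-phase value across the bilayer melting
temperature ``T_m`` (logistic interpolation).  A third, membrane-bound
dye pool ``m_mem`` is static: it neither permeates nor fluoresces and is
released only when Triton micellizes the bilayer, at which point all
remaining dye mixes into the single aqueous phase ``V_aq = V_in + V_out``.

On an isothermal segment the balance integrates in closed form to

    c_out(t) = c_eq − (c_eq − c_out(0))·exp(−k·t),
    k = P·A·(V_in + V_out)/(V_in·V_out),
    c_eq = (V_in·c_in(0) + V_out·c_out(0))/(V_in + V_out),

which is the exponential the fitting chain regresses against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import AssayGeometry, GeometryError

__all__ = [
    "KineticParams",
    "SystemState",
    "TemperatureSchedule",
    "Timecourse",
    "four_stage_schedule",
    "permeability_at",
    "rate_constant",
    "closed_form_release",
    "simulate_timecourse",
    "equilibrium_plateau",
]

_UL_TO_CM3 = 1e-3

#: melting temperature of the DPPC:DPPG:cholesterol (75:10:15) bilayer, °C
DEFAULT_TM_C = 41.5
#: width of the logistic gel→fluid interpolation, °C
DEFAULT_T_WIDTH_C = 1.5


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth transport parameters of one liposome sample.

    ``P_fluid``/``P_gel`` are the fluid- and gel-phase permeabilities in
    cm/s, ``T_m`` and ``T_width`` the midpoint and width (°C) of the
    logistic phase-transition interpolation, and ``K_app`` the apparent
    membrane/water partition coefficient inferred from the release
    plateau (dimensionless; can exceed octanol/water expectations
    because surface adsorption and dimerization count toward it).
    """

    P_fluid: float
    P_gel: float = 0.0
    T_m: float = DEFAULT_TM_C
    T_width: float = DEFAULT_T_WIDTH_C
    K_app: float = 0.0

    def __post_init__(self) -> None:
        if not (self.P_fluid >= self.P_gel >= 0.0):
            raise ValueError("require P_fluid >= P_gel >= 0")
        if not (self.T_width > 0):
            raise ValueError("T_width must be positive")
        if self.K_app < 0:
            raise ValueError("K_app must be non-negative")

    @classmethod
    def from_measured(
        cls,
        P_at: float,
        T_measured: float,
        K_app: float = 0.0,
        P_gel: float = 0.0,
        T_m: float = DEFAULT_TM_C,
        T_width: float = DEFAULT_T_WIDTH_C,
    ) -> "KineticParams":
        """Build params whose logistic P(T) equals ``P_at`` at ``T_measured``.

        Release experiments report the permeability at the hold
        temperature (e.g. 40 °C, just below ``T_m``); this inverts the
        logistic so that ``permeability_at(params, T_measured) == P_at``.
        """
        w = 1.0 / (1.0 + math.exp(-(T_measured - T_m) / T_width))
        if w <= 0:
            raise ValueError("T_measured too far below T_m to invert the logistic")
        P_fluid = P_gel + (P_at - P_gel) / w
        return cls(P_fluid=P_fluid, P_gel=P_gel, T_m=T_m, T_width=T_width, K_app=K_app)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state: aqueous concentrations (μg/mL), membrane-bound
    mass (μg), time (s) and temperature (°C)."""

    c_in: float
    c_out: float
    m_mem: float = 0.0
    t: float = 0.0
    T: float = 25.0

    def __post_init__(self) -> None:
        if min(self.c_in, self.c_out, self.m_mem) < 0:
            raise ValueError("state quantities must be non-negative")


@dataclass(frozen=True)
class TemperatureSchedule:
    """Piecewise-linear temperature program with an optional Triton event.

    ``times``/``temps`` are the breakpoints (s, °C); temperature is held
    constant beyond the last breakpoint.  ``heat_onset`` marks the start
    of the heating step (metadata for segmentation), ``triton_time`` the
    detergent addition that micellizes the bilayer.
    """

    times: tuple[float, ...]
    temps: tuple[float, ...]
    heat_onset: float | None = None
    triton_time: float | None = None
    t_end: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.size < 1 or np.any(np.diff(times) <= 0):
            raise ValueError("schedule times must be strictly increasing")
        if times[0] < 0:
            raise ValueError("schedule events before t = 0 are not allowed")
        if len(self.times) != len(self.temps):
            raise ValueError("times and temps must have equal length")
        if self.triton_time is not None and self.triton_time < 0:
            raise ValueError("Triton event before t = 0 is not allowed")

    @property
    def end(self) -> float:
        t_last = self.times[-1]
        if self.triton_time is not None:
            t_last = max(t_last, self.triton_time)
        if self.t_end is not None:
            t_last = max(t_last, self.t_end)
        return t_last

    def temperature(self, t):
        """Temperature at time(s) ``t`` (linear interpolation, flat ends)."""
        return np.interp(t, self.times, self.temps)

    def is_ramp(self, t0: float, t1: float) -> bool:
        """True if temperature varies anywhere on [t0, t1]."""
        ts = np.asarray(self.times)
        Ts = np.asarray(self.temps)
        inside = (ts > t0) & (ts < t1)
        grid = np.unique(np.concatenate([[t0, t1], ts[inside]]))
        Tvals = np.interp(grid, ts, Ts)
        return bool(np.ptp(Tvals) > 1e-12)


def four_stage_schedule(
    baseline_s: float = 120.0,
    release_s: float = 780.0,
    post_triton_s: float = 60.0,
    T_start: float = 25.0,
    T_hold: float = 40.0,
    ramp_s: float = 60.0,
) -> TemperatureSchedule:
    """Standard four-stage program: ambient baseline, heating ramp to the
    hold temperature, isothermal release + plateau, Triton dequench."""
    t_heat = baseline_s
    t_triton = baseline_s + release_s
    return TemperatureSchedule(
        times=(0.0, t_heat, t_heat + ramp_s),
        temps=(T_start, T_start, T_hold),
        heat_onset=t_heat,
        triton_time=t_triton,
        t_end=t_triton + post_triton_s,
    )


def permeability_at(params: KineticParams, T) -> float | np.ndarray:
    """Logistic gel→fluid interpolation of permeability at temperature ``T``.

    P(T) = P_gel + (P_fluid − P_gel) / (1 + exp(−(T − T_m)/T_width));
    strictly increasing in T whenever P_fluid > P_gel.
    """
    x = (np.asarray(T, dtype=float) - params.T_m) / params.T_width
    out = params.P_gel + (params.P_fluid - params.P_gel) / (1.0 + np.exp(-x))
    return float(out) if out.ndim == 0 else out


def rate_constant(P: float, geom: AssayGeometry) -> float:
    """First-order efflux rate k = P·A·(V_in + V_out)/(V_in·V_out), 1/s.

    ``P`` in cm/s, area in cm², volumes converted to cm³.  In the
    thin-shell monodisperse limit with V_out ≫ V_in this approaches
    6·P/d_Sauter.
    """
    if P < 0:
        raise ValueError("permeability must be non-negative")
    if geom.V_in <= 0 or geom.V_out <= 0:
        raise GeometryError("rate constant undefined for empty compartments")
    v_in = geom.V_in * _UL_TO_CM3
    v_out = geom.V_out * _UL_TO_CM3
    return P * geom.A * (v_in + v_out) / (v_in * v_out)


def closed_form_release(
    k: float,
    geom: AssayGeometry,
    c_in0: float,
    c_out0: float,
    t: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Isothermal exterior concentration c_out(t) = c_eq − (c_eq − c_out0)·e^(−k·t).

    ``c_eq`` is the aqueous-phase equilibrium concentration set by mass
    conservation.  Identifying with the regression form used on measured
    curves, the amplitude ``a = c_eq − c_out0`` and rate ``b = k``.
    """
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times are not allowed")
    c_eq = (geom.V_in * c_in0 + geom.V_out * c_out0) / (geom.V_in + geom.V_out)
    return c_eq - (c_eq - c_out0) * np.exp(-k * t)


@dataclass(frozen=True)
class Timecourse:
    """Simulated state series: arrays over the output grid plus markers."""

    t: np.ndarray
    c_in: np.ndarray
    c_out: np.ndarray
    m_mem: np.ndarray
    T: np.ndarray
    schedule: TemperatureSchedule

    def states(self) -> list[SystemState]:
        return [
            SystemState(
                c_in=float(ci), c_out=float(co), m_mem=float(m), t=float(ti), T=float(Ti)
            )
            for ti, ci, co, m, Ti in zip(self.t, self.c_in, self.c_out, self.m_mem, self.T)
        ]

    def total_mass(self, geom: AssayGeometry) -> np.ndarray:
        """Total dye mass (μg) at every sample — conserved throughout."""
        return (
            geom.V_in * _UL_TO_CM3 * self.c_in
            + geom.V_out * _UL_TO_CM3 * self.c_out
            + self.m_mem
        )


def simulate_timecourse(
    params: KineticParams,
    geom: AssayGeometry,
    schedule: TemperatureSchedule,
    init: SystemState,
    t_eval: Sequence[float] | np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
    ramp_max_step: float = 1.0,
) -> Timecourse:
    """Integrate the efflux balance under a temperature/event schedule.

    The membrane pool ``init.m_mem`` is carried unchanged until the
    Triton event, at which point all membrane-bound and interior dye
    mixes into a single aqueous phase of volume ``V_aq`` and the
    concentrations are pinned at the common post-micellization value.
    Total dye mass is conserved throughout.

    Integration is adaptive (RK45) with the step capped at
    ``ramp_max_step`` seconds on segments where temperature varies, so
    the logistic P(T) is resolved through the transition.
    """
    t_end = schedule.end
    if t_eval is None:
        t_eval = np.arange(0.0, t_end + 0.5, 1.0)
    t_eval = np.asarray(t_eval, dtype=float)
    if np.any(t_eval < 0) or np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be non-negative and strictly increasing")

    v_in = geom.V_in * _UL_TO_CM3
    v_out = geom.V_out * _UL_TO_CM3
    v_aq = v_in + v_out

    def rhs(t, y):
        P = permeability_at(params, schedule.temperature(t))
        flux = P * geom.A * (y[0] - y[1])  # μg/s
        return (-flux / v_in, flux / v_out)

    t_triton = schedule.triton_time
    # integration breakpoints: schedule knots + triton + end
    knots = [tt for tt in schedule.times if 0.0 < tt < t_end]
    if t_triton is not None and 0.0 < t_triton < t_end:
        knots.append(t_triton)
    seg_edges = np.unique(np.concatenate([[0.0], knots, [t_end]]))

    c_in_out = np.empty_like(t_eval)
    c_out_arr = np.empty_like(t_eval)
    m_mem_arr = np.empty_like(t_eval)

    y = np.array([init.c_in, init.c_out], dtype=float)
    m_mem = init.m_mem
    tritoned = False

    last_edge = seg_edges[-1]
    for t0, t1 in zip(seg_edges[:-1], seg_edges[1:]):
        if t1 == last_edge:
            mask = (t_eval >= t0) & (t_eval <= t1)
        else:
            mask = (t_eval >= t0) & (t_eval < t1)
        seg_pts = t_eval[mask]
        if tritoned:
            c_in_out[mask] = y[0]
            c_out_arr[mask] = y[1]
            m_mem_arr[mask] = m_mem
            continue
        # solve to the segment end; append t1 so the endpoint state is exact
        pts = np.unique(np.concatenate([seg_pts, [t1]]))
        max_step = ramp_max_step if schedule.is_ramp(t0, t1) else np.inf
        sol = solve_ivp(
            rhs, (t0, t1), y, method="RK45", t_eval=pts, rtol=rtol, atol=atol,
            max_step=max_step,
        )
        if not sol.success:  # pragma: no cover - RK45 on smooth rhs
            raise RuntimeError(f"integration failed: {sol.message}")
        if seg_pts.size:
            c_in_out[mask] = sol.y[0][: seg_pts.size]
            c_out_arr[mask] = sol.y[1][: seg_pts.size]
            m_mem_arr[mask] = m_mem
        y = sol.y[:, -1].copy()
        if t_triton is not None and abs(t1 - t_triton) < 1e-12:
            total = v_in * y[0] + v_out * y[1] + m_mem
            c_mix = total / v_aq
            y = np.array([c_mix, c_mix])
            m_mem = 0.0
            tritoned = True

    return Timecourse(
        t=t_eval,
        c_in=c_in_out,
        c_out=c_out_arr,
        m_mem=m_mem_arr,
        T=np.asarray(schedule.temperature(t_eval), dtype=float),
        schedule=schedule,
    )


def equilibrium_plateau(
    params: KineticParams,
    geom: AssayGeometry,
    c_in0: float,
    c_out0: float = 0.0,
) -> float:
    """Plateau fraction c_fin/c_triton for a thermal-release run.

    With a static membrane pool loaded self-consistently so that the
    plateau mass balance returns ``K_app`` exactly
    (``m_mem = K_app·c_fin·V_lip``), the aqueous plateau is
    ``c_fin = m_aq/V_aq`` independent of the membrane load, and

        c_fin/c_triton = 1/(1 + K_app·V_lip/V_aq).

    Strictly decreasing in ``K_app``; equal to 1 when the membrane
    retains nothing.
    """
    v_in = geom.V_in * _UL_TO_CM3
    v_out = geom.V_out * _UL_TO_CM3
    m_aq = v_in * c_in0 + v_out * c_out0
    c_fin = m_aq / (v_in + v_out)
    m_mem = params.K_app * c_fin * geom.V_lip * _UL_TO_CM3
    c_triton = (m_aq + m_mem) / (v_in + v_out)
    if c_triton == 0.0:
        return 1.0
    return c_fin / c_triton
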