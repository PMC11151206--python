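"""Synthetic assay data with known ground truth.

Generates every experiment type the dye-release assay produces —
four-stage thermal release traces, copermeation condition sets,
ethanol/oleic-acid enhancer runs, liposome titrations and temperature
scans — as fluorescence time series in instrument units, so the fitting
chain can be exercised end to end without measured data.

The fluorescence model is the one the analysis itself assumes: interior
(self-quenched) and membrane-bound dye are dark; only the dilute
exterior concentration fluoresces, linearly below ``linear_max``.  The
membrane-bound pool is loaded self-consistently, ``m_mem =
K_app·c_fin·V_lip``, so that the plateau mass balance applied to the
simulated trace returns ``K_app`` exactly — ground truth and recovered
value live on the same scale by construction.

Randomness is fully seeded: replicate ``j`` of condition ``i`` draws its
noise from ``numpy.random.SeedSequence([master_seed, i, j])``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import AssayGeometry, LiposomePopulation, MixingProtocol, assay_geometry
from .kinetics import (
    KineticParams,
    SystemState,
    TemperatureSchedule,
    four_stage_schedule,
    permeability_at,
    rate_constant,
    simulate_timecourse,
)

__all__ = [
    "CalibrationCurve",
    "ExperimentRecipe",
    "FluorescenceTrace",
    "REFERENCE_PANEL",
    "REFERENCE_CONDITION",
    "panel_recipes",
    "reference_kinetics",
    "generate_trace",
    "generate_condition_set",
    "generate_ethanol_steps",
    "generate_oleic_acid",
    "generate_titration",
    "generate_temperature_scan",
]

_UL_TO_CM3 = 1e-3

#: CF concentration of the hydration medium, μg/mL (7.5 mg/mL)
CF_HYDRATION_CONC_UG_ML = 7500.0

#: measured assay panel: permeability at 40 °C (cm/s) and apparent
#: partition coefficient for CF alone and in binary copermeation.
REFERENCE_CONDITION = "CF alone"
REFERENCE_PANEL: dict[str, dict[str, float]] = {
    "CF alone":     {"P": 1.4e-8, "P_sd": 0.4e-8, "K": 2.9e4, "K_sd": 0.2e4},
    "CF-ASC_aq":    {"P": 2.4e-8, "P_sd": 0.7e-8, "K": 2.5e4, "K_sd": 0.3e4},
    "CF-HCTZ_aq":   {"P": 1.5e-8, "P_sd": 0.3e-8, "K": 6.3e4, "K_sd": 0.9e4},
    "CF-KM_aq":     {"P": 1.2e-8, "P_sd": 0.3e-8, "K": 7.0e4, "K_sd": 0.2e4},
    "CF-NX_aq":     {"P": 2.3e-8, "P_sd": 0.5e-8, "K": 1.7e4, "K_sd": 0.1e4},
    "CF-CC_lip":    {"P": 2.2e-8, "P_sd": 0.7e-8, "K": 1.1e4, "K_sd": 0.3e4},
    "CF-APIX_lip":  {"P": 3.1e-9, "P_sd": 0.4e-9, "K": 3.1e4, "K_sd": 0.2e4},
    "CF-HCTZ_lip":  {"P": 1.1e-8, "P_sd": 0.1e-8, "K": 4.9e4, "K_sd": 0.5e4},
    "CF-NX_lip":    {"P": 2.2e-8, "P_sd": 0.2e-8, "K": 3.8e4, "K_sd": 0.5e4},
}


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear fluorescence calibration F = slope·c + intercept.

    Valid below ``linear_max`` (μg/mL); above it the dye begins to
    self-quench and the instrument response flattens.  Defaults keep the
    Triton level of every panel condition under the 1000 a.u.
    instrument ceiling.
    """

    slope: float = 5.0  # a.u. per μg/mL
    intercept: float = 2.0  # a.u.
    linear_max: float = 200.0  # μg/mL

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise ValueError("calibration slope must be positive")
        if not (self.linear_max > 0):
            raise ValueError("linear_max must be positive")

    def intensity(self, c) -> np.ndarray:
        return self.slope * np.asarray(c, dtype=float) + self.intercept

    def concentration(self, F) -> np.ndarray:
        return np.clip((np.asarray(F, dtype=float) - self.intercept) / self.slope, 0.0, None)


@dataclass(frozen=True)
class ExperimentRecipe:
    """One assay condition: multipliers on the reference kinetics plus
    acquisition settings.

    ``fP``/``fK`` scale the reference permeability and partition
    coefficient (1, 1 is the probe-alone reference).  ``noise_sd`` is the
    Gaussian intensity noise in a.u.; ``None`` means 0.5% of the
    condition's Triton-level intensity.  ``stage_durations`` are the
    baseline / release / plateau / post-Triton lengths in seconds
    (release and plateau are both at ``T_hold``; the split is
    bookkeeping only).
    """

    condition_label: str
    fP: float = 1.0
    fK: float = 1.0
    replicates: int = 3
    noise_sd: float | None = None
    dt: float = 1.0
    stage_durations: tuple[float, float, float, float] = (120.0, 600.0, 180.0, 60.0)
    T_hold: float = 40.0
    T_start: float = 25.0
    ramp_s: float = 60.0
    free_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (self.fP > 0 and self.fK > 0):
            raise ValueError("fP and fK must be positive")
        if not (0.0 <= self.free_fraction < 1.0):
            raise ValueError("free_fraction must be in [0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class FluorescenceTrace:
    """Time-resolved fluorescence with event markers and ground truth.

    ``F`` is in instrument units (a.u.), ``T`` in °C.  ``true_P`` is the
    permeability at the hold temperature and ``true_K`` the apparent
    partition coefficient used to generate the trace (NaN for measured
    data).  ``saturated`` flags samples whose underlying concentration
    exceeded the calibration's linear range.
    """

    t: np.ndarray
    F: np.ndarray
    T: np.ndarray
    heat_onset: float | None = None
    triton_time: float | None = None
    addition_times: tuple[float, ...] = ()
    replicate_id: int = 0
    condition_label: str = ""
    true_P: float = float("nan")
    true_K: float = float("nan")
    saturated: bool = False
    extra_events: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if (
            self.triton_time is not None
            and self.heat_onset is not None
            and self.triton_time <= self.heat_onset
        ):
            raise ValueError("Triton addition must follow the heat onset")

    @property
    def n(self) -> int:
        return int(np.asarray(self.t).size)


def reference_kinetics(
    P_measured: float = REFERENCE_PANEL[REFERENCE_CONDITION]["P"],
    K_app: float = REFERENCE_PANEL[REFERENCE_CONDITION]["K"],
    T_measured: float = 40.0,
    T_m: float = 41.5,
    T_width: float = 1.5,
) -> KineticParams:
    """Kinetic parameters whose P(T) matches the measured permeability at
    the measurement temperature (default: the probe-alone panel row)."""
    return KineticParams.from_measured(
        P_at=P_measured, T_measured=T_measured, K_app=K_app, T_m=T_m, T_width=T_width
    )


def panel_recipes(
    replicates: int = 3,
    noise_sd: float | None = None,
    **recipe_kwargs,
) -> list[ExperimentRecipe]:
    """Recipes for the full measured panel, as multipliers on the
    probe-alone reference row (which gets fP = fK = 1)."""
    ref = REFERENCE_PANEL[REFERENCE_CONDITION]
    return [
        ExperimentRecipe(
            condition_label=label,
            fP=row["P"] / ref["P"],
            fK=row["K"] / ref["K"],
            replicates=replicates,
            noise_sd=noise_sd,
            **recipe_kwargs,
        )
        for label, row in REFERENCE_PANEL.items()
    ]


def _loaded_initial_state(
    params: KineticParams,
    geom: AssayGeometry,
    c_interior: float,
    free_fraction: float,
) -> tuple[SystemState, float, float]:
    """Initial state plus (c_fin, c_triton) for a thermal-release run.

    The interior concentration is fixed at the hydration value; the free
    exterior dye is ``free_fraction`` of the total aqueous dye mass; the
    membrane pool is ``K_app·c_fin·V_lip`` so the plateau mass balance
    returns ``K_app`` exactly.
    """
    v_in = geom.V_in * _UL_TO_CM3
    v_out = geom.V_out * _UL_TO_CM3
    v_aq = v_in + v_out
    m_enc = v_in * c_interior
    m_aq = m_enc / (1.0 - free_fraction)
    c_out0 = free_fraction * m_aq / v_out
    c_fin = m_aq / v_aq
    m_mem = params.K_app * c_fin * geom.V_lip * _UL_TO_CM3
    c_triton = (m_aq + m_mem) / v_aq
    state = SystemState(c_in=c_interior, c_out=c_out0, m_mem=m_mem, t=0.0, T=25.0)
    return state, c_fin, c_triton


def _scaled_params(reference: KineticParams, fP: float, fK: float) -> KineticParams:
    return replace(
        reference,
        P_fluid=reference.P_fluid * fP,
        P_gel=reference.P_gel * fP,
        K_app=reference.K_app * fK,
    )


def _apply_calibration(
    c_out: np.ndarray,
    calib: CalibrationCurve,
    noise_sd: float,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, bool]:
    saturated = bool(np.any(c_out > calib.linear_max))
    F = calib.intensity(c_out)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        F = F + rng.normal(0.0, noise_sd, size=F.shape)
    return np.clip(F, 0.0, None), saturated


def generate_trace(
    recipe: ExperimentRecipe,
    params: KineticParams,
    pop: LiposomePopulation,
    protocol: MixingProtocol,
    calib: CalibrationCurve,
    rng: np.random.Generator | None = None,
    replicate_id: int = 0,
    c_interior: float = CF_HYDRATION_CONC_UG_ML,
) -> FluorescenceTrace:
    """Simulate one four-stage release trace under a recipe.

    The reference ``params`` are scaled by ``(fP, fK)`` before
    simulation.  Returns intensity in a.u. with Gaussian noise; the
    draw comes from ``rng`` (or a generator seeded with ``recipe.seed``
    when ``rng`` is None), so a fixed seed reproduces the trace bit for
    bit.
    """
    scaled = _scaled_params(params, recipe.fP, recipe.fK)
    geom = assay_geometry(pop, protocol)
    state, c_fin, c_triton = _loaded_initial_state(
        scaled, geom, c_interior, recipe.free_fraction
    )
    baseline_s, release_s, plateau_s, post_s = recipe.stage_durations
    schedule = four_stage_schedule(
        baseline_s=baseline_s,
        release_s=release_s + plateau_s,
        post_triton_s=post_s,
        T_start=recipe.T_start,
        T_hold=recipe.T_hold,
        ramp_s=recipe.ramp_s,
    )
    t_eval = np.arange(0.0, schedule.end + recipe.dt / 2, recipe.dt)
    course = simulate_timecourse(scaled, geom, schedule, state, t_eval=t_eval)

    noise_sd = recipe.noise_sd
    if noise_sd is None:
        noise_sd = 0.005 * float(calib.intensity(c_triton))
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([recipe.seed, replicate_id]))
    F, saturated = _apply_calibration(course.c_out, calib, noise_sd, rng)

    return FluorescenceTrace(
        t=course.t,
        F=F,
        T=course.T,
        heat_onset=schedule.heat_onset,
        triton_time=schedule.triton_time,
        replicate_id=replicate_id,
        condition_label=recipe.condition_label,
        true_P=float(permeability_at(scaled, recipe.T_hold)),
        true_K=scaled.K_app,
        saturated=saturated,
    )


def generate_condition_set(
    reference: KineticParams,
    conditions: list[ExperimentRecipe],
    pop: LiposomePopulation,
    protocol: MixingProtocol,
    calib: CalibrationCurve,
    master_seed: int = 0,
) -> list[FluorescenceTrace]:
    """Traces for all conditions × replicates with reproducible seeds.

    Exactly one condition must be the reference (fP = fK = 1); duplicate
    labels are rejected.  Replicate ``j`` of condition ``i`` uses
    ``SeedSequence([master_seed, i, j])``.
    """
    labels = [r.condition_label for r in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    if not any(r.fP == 1.0 and r.fK == 1.0 for r in conditions):
        raise ValueError("one condition must be the reference with fP = fK = 1")
    traces: list[FluorescenceTrace] = []
    for i, recipe in enumerate(conditions):
        for j in range(recipe.replicates):
            rng = np.random.default_rng(np.random.SeedSequence([master_seed, i, j]))
            traces.append(
                generate_trace(
                    recipe, reference, pop, protocol, calib, rng=rng, replicate_id=j
                )
            )
    return traces


def _staircase_trace(
    t: np.ndarray,
    c: np.ndarray,
    T_hold: float,
    addition_times: tuple[float, ...],
    triton_time: float | None,
    calib: CalibrationCurve,
    noise_sd: float,
    rng: np.random.Generator | None,
    label: str,
    true_P: float = float("nan"),
    true_K: float = float("nan"),
    heat_onset: float | None = None,
) -> FluorescenceTrace:
    F, saturated = _apply_calibration(c, calib, noise_sd, rng)
    return FluorescenceTrace(
        t=t,
        F=F,
        T=np.full_like(t, T_hold),
        heat_onset=heat_onset,
        triton_time=triton_time,
        addition_times=addition_times,
        condition_label=label,
        true_P=true_P,
        true_K=true_K,
        saturated=saturated,
    )


def generate_ethanol_steps(
    n_steps: int,
    lysis_fraction: float,
    params: KineticParams,
    pop: LiposomePopulation,
    protocol: MixingProtocol,
    calib: CalibrationCurve,
    step_interval_s: float = 300.0,
    baseline_s: float = 120.0,
    post_triton_s: float = 60.0,
    dt: float = 1.0,
    free_fraction: float = 0.10,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    c_interior: float = CF_HYDRATION_CONC_UG_ML,
) -> FluorescenceTrace:
    """Stepwise ethanol lysis at 30 °C: a non-decreasing staircase.

    Each addition instantly lyses ``lysis_fraction`` of the still-intact
    vesicles, dumping their interior and membrane-bound dye into the
    aqueous phase; after ``n`` additions the released fraction of
    encapsulated dye is ``1 − (1 − lysis_fraction)^n``.  There is no
    background permeation at 30 °C.  A final Triton event releases the
    remainder.
    """
    if not (0.0 < lysis_fraction <= 1.0):
        raise ValueError("lysis_fraction must be in (0, 1]")
    if n_steps < 1:
        raise ValueError("need at least one addition")
    geom = assay_geometry(pop, protocol)
    state, _, c_triton = _loaded_initial_state(params, geom, c_interior, free_fraction)
    v_in = geom.V_in * _UL_TO_CM3
    v_out = geom.V_out * _UL_TO_CM3
    v_aq = v_in + v_out
    m_free = v_out * state.c_out
    m_releasable = v_in * state.c_in + state.m_mem

    additions = tuple(baseline_s + k * step_interval_s for k in range(n_steps))
    triton_time = additions[-1] + step_interval_s
    t_end = triton_time + post_triton_s
    t = np.arange(0.0, t_end + dt / 2, dt)

    # number of additions that have occurred at each sample
    n_occurred = np.sum(t[None, :] >= np.asarray(additions)[:, None], axis=0)
    released = (1.0 - (1.0 - lysis_fraction) ** n_occurred) * m_releasable
    c = (m_free + released) / v_aq
    c[t >= triton_time] = c_triton

    return _staircase_trace(
        t, c, 30.0, additions, triton_time, calib, noise_sd, rng,
        label="ethanol_steps", true_K=params.K_app,
    )


def generate_oleic_acid(
    P_enhanced: float,
    params: KineticParams,
    pop: LiposomePopulation,
    protocol: MixingProtocol,
    calib: CalibrationCurve,
    duration_s: float = 600.0 * 60.0,
    addition_s: float = 120.0,
    post_triton_s: float = 300.0,
    dt: float = 10.0,
    free_fraction: float = 0.10,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    c_interior: float = CF_HYDRATION_CONC_UG_ML,
) -> FluorescenceTrace:
    """Oleic-acid enhancement at 30 °C: permeability steps from ~0 to
    ``P_enhanced`` at the addition time and the slow efflux runs for
    ``duration_s`` (10 h by default)."""
    if P_enhanced < 0:
        raise ValueError("enhanced permeability must be non-negative")
    geom = assay_geometry(pop, protocol)
    state, _, c_triton = _loaded_initial_state(params, geom, c_interior, free_fraction)
    triton_time = addition_s + duration_s
    t_end = triton_time + post_triton_s
    t = np.arange(0.0, t_end + dt / 2, dt)

    k = rate_constant(P_enhanced, geom)
    c_eq = (geom.V_in * state.c_in + geom.V_out * state.c_out) / (geom.V_in + geom.V_out)
    c = np.full_like(t, state.c_out)
    after = t >= addition_s
    c[after] = c_eq - (c_eq - state.c_out) * np.exp(-k * (t[after] - addition_s))
    c[t >= triton_time] = c_triton

    return _staircase_trace(
        t, c, 30.0, (addition_s,), triton_time, calib, noise_sd, rng,
        label="oleic_acid", true_P=P_enhanced, true_K=params.K_app,
        heat_onset=addition_s,
    )


def generate_titration(
    aliquots: tuple[float, ...] | list[float],
    cf_solution: float,
    K_app: float,
    pop: LiposomePopulation,
    calib: CalibrationCurve,
    V_solution: float = 1200.0,
    step_interval_s: float = 120.0,
    baseline_s: float = 120.0,
    post_triton_s: float = 60.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    dilution_correction: bool = False,
) -> FluorescenceTrace:
    """Add empty-liposome aliquots (μL of stock) to a dilute dye solution.

    After each aliquot the fluorescent (free) fraction of the dye is
    ``V_aq/(V_aq + K_app·V_lip,cum)`` — successive drops of decreasing
    magnitude.  The final Triton event micellizes the membranes and
    restores the original pure-solution intensity (dilution by the added
    aliquot volume is neglected unless ``dilution_correction``).
    """
    if len(aliquots) == 0:
        raise ValueError("need at least one aliquot")
    additions = tuple(baseline_s + k * step_interval_s for k in range(len(aliquots)))
    triton_time = additions[-1] + step_interval_s
    t_end = triton_time + post_triton_s
    t = np.arange(0.0, t_end + dt / 2, dt)

    V_lip_per = [v * pop.lipid_conc_stock * 1e-3 / pop.lipid_density for v in aliquots]
    c = np.full_like(t, float(cf_solution))
    V_lip_cum = 0.0
    V_added = 0.0
    for t_add, v_lip, v_aliquot in zip(additions, V_lip_per, aliquots):
        V_lip_cum += v_lip
        V_added += v_aliquot
        v_aq = V_solution + (V_added - V_lip_cum if dilution_correction else 0.0)
        c_total = cf_solution * (V_solution / v_aq if dilution_correction else 1.0)
        free = v_aq / (v_aq + K_app * V_lip_cum)
        c[t >= t_add] = c_total * free
    # Triton restores the full (possibly dilution-corrected) concentration
    v_aq_end = V_solution + (V_added if dilution_correction else 0.0)
    c[t >= triton_time] = cf_solution * (V_solution / v_aq_end if dilution_correction else 1.0)

    return _staircase_trace(
        t, c, 25.0, additions, triton_time, calib, noise_sd, rng,
        label="liposome_titration", true_K=K_app,
    )


def generate_temperature_scan(
    params: KineticParams,
    pop: LiposomePopulation,
    protocol: MixingProtocol,
    calib: CalibrationCurve,
    ramp_rate: float = 2.0,
    T_range: tuple[float, float] = (25.0, 60.0),
    dt: float = 1.0,
    free_fraction: float = 0.10,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    c_interior: float = CF_HYDRATION_CONC_UG_ML,
) -> FluorescenceTrace:
    """Linear temperature ramp (°C/min); output normalized to its maximum.

    Reveals the bilayer phase transition as the steepest rise of the
    release curve; a copermeant that rigidifies the membrane shifts the
    half-release temperature upward.
    """
    if ramp_rate <= 0:
        raise ValueError("ramp rate must be positive")
    T0, T1 = T_range
    if T1 <= T0:
        raise ValueError("T_range must be increasing")
    geom = assay_geometry(pop, protocol)
    state, _, _ = _loaded_initial_state(params, geom, c_interior, free_fraction)
    ramp_s = (T1 - T0) / (ramp_rate / 60.0)
    schedule = TemperatureSchedule(times=(0.0, ramp_s), temps=(T0, T1), heat_onset=0.0)
    t_eval = np.arange(0.0, ramp_s + dt / 2, dt)
    course = simulate_timecourse(params, geom, schedule, state, t_eval=t_eval)
    F, saturated = _apply_calibration(course.c_out, calib, noise_sd, rng)
    F = F / F.max()
    return FluorescenceTrace(
        t=course.t,
        F=F,
        T=course.T,
        heat_onset=0.0,
        condition_label="temperature_scan",
        true_K=params.K_app,
        saturated=saturated,
    )
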