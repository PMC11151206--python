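"""File formats, configuration and the batch pipeline.

Everything tabular is CSV (human-diffable): traces as
``time_s,intensity_au,temperature_C,event`` with a small ``# key: value``
comment header, a manifest tying each trace file to its condition,
replicate, seed and ground truth, per-condition results mirroring the
assay's summary-table layout, and a comparison table.  Run
configurations are YAML with schema validation; all randomness flows
from the config's master seed.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .copermeation import compare_conditions, max_fold_change
from .fitting import fit_condition
from .geometry import LiposomePopulation, MixingProtocol, assay_geometry
from .saxs import SAXSCurve, fit_peaks, lamellar_spacing
from .simulate import (
    CalibrationCurve,
    ExperimentRecipe,
    FluorescenceTrace,
    generate_condition_set,
    reference_kinetics,
)

__all__ = [
    "FormatError",
    "RunConfig",
    "read_trace_csv",
    "write_trace_csv",
    "read_saxs_csv",
    "write_saxs_csv",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger("lipoperm")

_TRACE_COLUMNS = ["time_s", "intensity_au", "temperature_C", "event"]
_KNOWN_EVENTS = {"", "heat", "addition", "triton"}


class FormatError(ValueError):
    """Raised for malformed input files (message carries the location)."""


# ---------------------------------------------------------------------------
# trace CSV


def write_trace_csv(trace: FluorescenceTrace, path: str | Path) -> None:
    """Write a trace with per-row event markers and a metadata header."""
    path = Path(path)
    t = np.asarray(trace.t, dtype=float)
    events = [""] * t.size
    if trace.heat_onset is not None:
        events[int(np.searchsorted(t, trace.heat_onset))] = "heat"
    for t_add in trace.addition_times:
        events[int(np.searchsorted(t, t_add))] = "addition"
    if trace.triton_time is not None:
        events[int(np.searchsorted(t, trace.triton_time))] = "triton"
    for idx, token in trace.extra_events:
        events[idx] = token
    df = pd.DataFrame(
        {
            "time_s": t,
            "intensity_au": np.asarray(trace.F, dtype=float),
            "temperature_C": np.asarray(trace.T, dtype=float),
            "event": events,
        }
    )
    header = [
        f"# condition: {trace.condition_label}",
        f"# replicate: {trace.replicate_id}",
        f"# true_P_cm_s: {trace.true_P!r}",
        f"# true_K: {trace.true_K!r}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trace_csv(path: str | Path) -> FluorescenceTrace:
    """Read a trace CSV; event markers are reconstructed from the event
    column and unknown tokens preserved (with a warning)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(
            path,
            comment="#",
            keep_default_na=False,
            dtype={"event": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # pandas parse failure
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2: header row plus 1-based indexing of the second row of the pair
        raise FormatError(
            f"{path}: non-monotonic time at data row {int(bad[0]) + 2}"
        )

    heat_onset = triton_time = None
    additions: list[float] = []
    extra: list[tuple[int, str]] = []
    for i, token in enumerate(df["event"].tolist()):
        if token == "heat":
            heat_onset = float(t[i])
        elif token == "triton":
            triton_time = float(t[i])
        elif token == "addition":
            additions.append(float(t[i]))
        elif token not in _KNOWN_EVENTS:
            warnings.warn(f"{path}: unknown event token '{token}' preserved")
            extra.append((i, token))

    def _float(key: str) -> float:
        try:
            return float(meta.get(key, "nan"))
        except ValueError:
            return float("nan")

    return FluorescenceTrace(
        t=t,
        F=df["intensity_au"].to_numpy(dtype=float),
        T=df["temperature_C"].to_numpy(dtype=float),
        heat_onset=heat_onset,
        triton_time=triton_time,
        addition_times=tuple(additions),
        replicate_id=int(float(meta.get("replicate", "0") or 0)),
        condition_label=meta.get("condition", path.stem),
        true_P=_float("true_P_cm_s"),
        true_K=_float("true_K"),
        extra_events=tuple(extra),
    )


# ---------------------------------------------------------------------------
# SAXS CSV


def write_saxs_csv(curve: SAXSCurve, path: str | Path) -> None:
    pd.DataFrame({"q_A^-1": curve.q, "intensity_au": curve.I}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_saxs_csv(path: str | Path) -> SAXSCurve:
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need two columns (q, intensity)")
    return SAXSCurve(
        q=df.iloc[:, 0].to_numpy(dtype=float), I=df.iloc[:, 1].to_numpy(dtype=float)
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: population, protocol, reference
    kinetics, calibration, recipes, output directory and master seed."""

    population: LiposomePopulation = LiposomePopulation()
    protocol: MixingProtocol = MixingProtocol()
    kinetics: dict = field(
        default_factory=lambda: {"P_measured": 1.4e-8, "K_app": 2.9e4, "T_measured": 40.0}
    )
    calibration: CalibrationCurve = CalibrationCurve()
    recipes: tuple[ExperimentRecipe, ...] = ()
    out_dir: str = "."
    seed: int = 0
    verbosity: str = "INFO"
    digest: str = ""


_SECTION_KEYS = {
    "population": LiposomePopulation,
    "protocol": MixingProtocol,
    "kinetics": None,
    "calibration": CalibrationCurve,
    "recipes": None,
    "seed": None,
    "out_dir": None,
    "verbosity": None,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown top-level sections and unknown keys inside typed sections
    are rejected with the offending names in the message.
    """
    path = Path(path)
    raw = path.read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    unknown = set(data) - set(_SECTION_KEYS)
    if unknown:
        raise FormatError(f"{path}: unknown config sections {sorted(unknown)}")

    def _coerce(val):
        # YAML 1.1 reads "2.9e4" (no sign after e) as a string; repair
        if isinstance(val, str):
            try:
                return float(val)
            except ValueError:
                return val
        return val

    def build(cls, section):
        kwargs = {k: _coerce(v) for k, v in (data.get(section, {}) or {}).items()}
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise FormatError(f"{path}: section '{section}': {exc}") from exc
        except ValueError as exc:
            raise FormatError(f"{path}: section '{section}': {exc}") from exc

    recipes = []
    for i, entry in enumerate(data.get("recipes", []) or []):
        try:
            entry = {
                k: (v if k == "condition_label" else _coerce(v))
                for k, v in dict(entry).items()
            }
            if "stage_durations" in entry:
                entry["stage_durations"] = tuple(entry["stage_durations"])
            for int_key in ("replicates", "seed"):
                if int_key in entry:
                    entry[int_key] = int(entry[int_key])
            recipes.append(ExperimentRecipe(**entry))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: recipe #{i}: {exc}") from exc

    kin = {k: _coerce(v) for k, v in (data.get("kinetics", {}) or {}).items()}
    allowed_kin = {"P_measured", "K_app", "T_measured", "T_m", "T_width", "P_gel"}
    bad = set(kin) - allowed_kin
    if bad:
        raise FormatError(f"{path}: kinetics keys {sorted(bad)} not recognized")

    return RunConfig(
        population=build(LiposomePopulation, "population"),
        protocol=build(MixingProtocol, "protocol"),
        kinetics={"P_measured": 1.4e-8, "K_app": 2.9e4, "T_measured": 40.0, **kin},
        calibration=build(CalibrationCurve, "calibration"),
        recipes=tuple(recipes),
        out_dir=str(data.get("out_dir", ".")),
        seed=int(data.get("seed", 0)),
        verbosity=str(data.get("verbosity", "INFO")),
        digest=hashlib.sha256(raw.encode()).hexdigest()[:16],
    )


# ---------------------------------------------------------------------------
# pipeline


def _log_run(config: RunConfig, command: str) -> None:
    from . import __version__

    logger.info(
        "command=%s seed=%d config_digest=%s lipoperm=%s",
        command,
        config.seed,
        config.digest or "(in-memory)",
        __version__,
    )


def run_pipeline(
    config: RunConfig,
    command: str,
    out_dir: str | Path | None = None,
    traces_dir: str | Path | None = None,
    reference_label: str | None = None,
) -> dict:
    """Execute one batch command: 'simulate', 'fit' or 'compare'.

    simulate → trace CSVs plus a manifest; fit → per-condition results
    CSV (summary-table layout); compare → comparison CSV against the
    reference condition.  Returns a dict of artifact paths / objects.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _log_run(config, command)
    kin = reference_kinetics(
        P_measured=config.kinetics["P_measured"],
        K_app=config.kinetics["K_app"],
        T_measured=config.kinetics.get("T_measured", 40.0),
        T_m=config.kinetics.get("T_m", 41.5),
        T_width=config.kinetics.get("T_width", 1.5),
    )

    if command == "simulate":
        if not config.recipes:
            raise ValueError("simulate: config defines no recipes")
        traces = generate_condition_set(
            kin,
            list(config.recipes),
            config.population,
            config.protocol,
            config.calibration,
            master_seed=config.seed,
        )
        rows = []
        for tr in traces:
            safe = tr.condition_label.replace("/", "_").replace(" ", "_")
            fname = f"trace_{safe}_r{tr.replicate_id}.csv"
            write_trace_csv(tr, out / fname)
            rows.append(
                {
                    "condition": tr.condition_label,
                    "replicate": tr.replicate_id,
                    "file": fname,
                    "seed": config.seed,
                    "true_P_cm_s": tr.true_P,
                    "true_K": tr.true_K,
                }
            )
        manifest = out / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return {"manifest": manifest, "n_traces": len(traces)}

    if command == "fit":
        src = Path(traces_dir or out)
        files = sorted(src.glob("trace_*.csv"))
        if not files:
            raise FileNotFoundError(f"fit: no trace_*.csv files in {src}")
        geom = assay_geometry(config.population, config.protocol)
        by_condition: dict[str, list[FluorescenceTrace]] = {}
        for f in files:
            tr = read_trace_csv(f)
            by_condition.setdefault(tr.condition_label, []).append(tr)
        rows = []
        for label, trs in by_condition.items():
            summary = fit_condition(trs, config.calibration, geom)
            rows.append(
                {
                    "sample": label,
                    "permeability_cm_s": summary.P_mean,
                    "permeability_sd": summary.P_sd,
                    "partition_coefficient": summary.K_mean,
                    "partition_sd": summary.K_sd,
                    "n": summary.n,
                }
            )
        results = out / "results.csv"
        pd.DataFrame(rows).to_csv(results, index=False)
        return {"results": results, "n_conditions": len(rows)}

    if command == "compare":
        results_csv = Path(traces_dir or out) / "results.csv"
        if not results_csv.exists():
            raise FileNotFoundError(f"compare: {results_csv} not found")
        df = pd.read_csv(results_csv)
        from .fitting import ConditionSummary

        summaries = [
            ConditionSummary(
                condition_label=r["sample"],
                P_mean=r["permeability_cm_s"],
                P_sd=r["permeability_sd"],
                K_mean=r["partition_coefficient"],
                K_sd=r["partition_sd"],
                n=int(r["n"]),
            )
            for r in df.to_dict("records")
        ]
        ref = reference_label or "CF alone"
        comparisons = compare_conditions(summaries, ref)
        comp_df = pd.DataFrame(
            [
                {
                    "condition": c.condition_label,
                    "fold_P": c.fold_P,
                    "fold_K": c.fold_K,
                    "direction_P": c.direction_P,
                    "direction_K": c.direction_K,
                }
                for c in comparisons
            ]
        )
        comp_csv = out / "comparison.csv"
        comp_df.to_csv(comp_csv, index=False)
        return {
            "comparison": comp_csv,
            "max_fold_P": max_fold_change(comparisons, "P"),
            "max_fold_K": max_fold_change(comparisons, "K"),
        }

    raise ValueError(f"unknown pipeline command '{command}'")


def saxs_report(curve: SAXSCurve, n_peaks: int = 2) -> dict:
    """Fit a SAXS curve and report peak positions, spacing and lamellarity
    cues (width/amplitude, not a hard classifier)."""
    fit = fit_peaks(curve, n_peaks=n_peaks)
    report = {
        "centers_A^-1": fit.centers,
        "widths_lnq": fit.widths,
        "amplitudes": fit.amplitudes,
        "background_exponent": fit.background_exponent,
        "lamellar_spacing_nm": lamellar_spacing(fit.centers[0]),
        "peakless": fit.peakless,
    }
    if len(fit.centers) >= 2:
        report["center_ratio"] = fit.centers[1] / fit.centers[0]
    return report
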