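"""Equilibrium sweeps, extinction-threshold detection and shape diagnostics.

These routines reproduce the structure of the theoretical analysis: grids of
long-run (t = t_max) SR-male and SRSR-female frequencies over pesticide dose
crossed with one varied female brood size, plus a bisection search for the
lowest dose that drives the population extinct and a descriptive curvature
summary of the dose-frequency relationship.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io_config
from .drive_model import ModelParams, Trajectory, default_model_params, simulate
from .parametrize import (
    build_dose_response,
    build_fecundity_params,
    fit_fecundity_mixed,
    fit_mortality_glm,
)
from .synthetic_data import (
    generate_fecundity_dataset,
    generate_mortality_dataset,
)

VARIABLE_PARAMS = ("b_SRSR", "b_SRST", "b_STST")

DEFAULT_DOSE_GRID = np.linspace(0.0, 2.5, 26)


@dataclass(frozen=True)
class SweepSpec:
    """A dose grid crossed with values of one varied brood-size parameter."""

    dose_grid: Sequence[float]
    vary: str
    fecundity_values: Sequence[float]

    def __post_init__(self):
        doses = np.asarray(list(self.dose_grid), float)
        fec = np.asarray(list(self.fecundity_values), float)
        if doses.size == 0 or fec.size == 0:
            raise ValueError("grids must be non-empty")
        if np.any(np.diff(doses) <= 0) or np.any(np.diff(fec) <= 0):
            raise ValueError("grids must be strictly increasing")
        if self.vary not in VARIABLE_PARAMS:
            raise ValueError(f"vary must be one of {VARIABLE_PARAMS}")
        if np.any(fec < 0):
            raise ValueError("fecundity values must be >= 0")

    @classmethod
    def from_params(cls, params: ModelParams, vary: str,
                    dose_grid: Sequence[float] = DEFAULT_DOSE_GRID,
                    n_fecundity: int = 5) -> "SweepSpec":
        """Fecundity grid spanning the parameter's sweep range (median +/- half-width),
        floored at zero."""
        lo, hi = params.fecundity.sweep_range(vary.removeprefix("b_"))
        lo = max(lo, 0.0)
        return cls(dose_grid=tuple(dose_grid), vary=vary,
                   fecundity_values=tuple(np.linspace(lo, hi, n_fecundity)))


def run_sweep(spec: SweepSpec, params: ModelParams) -> pd.DataFrame:
    """Simulate every (dose, fecundity value) cell to t_max.

    Returns a long-format frame with one row per cell: ``dose_ml,
    varied_param, varied_value, sr_male_freq, srsr_female_freq, extinct,
    t_final``.  Frequencies are NaN for extinct cells.
    """
    rows = []
    for value in spec.fecundity_values:
        cell_params = params.with_fecundity(**{spec.vary: float(value)})
        for dose in spec.dose_grid:
            traj = simulate(cell_params, float(dose))
            extinct = traj.extinct
            rows.append({
                "dose_ml": float(dose),
                "varied_param": spec.vary,
                "varied_value": float(value),
                "sr_male_freq": np.nan if extinct else float(traj.sr_male_freq[-1]),
                "srsr_female_freq": np.nan if extinct else float(traj.srsr_female_freq[-1]),
                "extinct": extinct,
                "t_final": traj.t_final,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    found: bool
    dose: float  # NaN when not found
    bracket: tuple[float, float] | None = None


def find_extinction_threshold(
    params: ModelParams,
    dose_grid: Sequence[float] = DEFAULT_DOSE_GRID,
    tol: float = 1e-3,
    refine: bool = True,
) -> ThresholdResult:
    """Lowest dose whose simulation ends extinct, refined by bisection.

    Scans the grid for the first extinct dose, then (with ``refine``)
    bisects between the last persistent and first extinct grid points down
    to ``tol``.  Returns an explicit not-found result when no grid dose
    causes extinction.
    """
    doses = np.asarray(list(dose_grid), float)
    if doses.size == 0:
        raise ValueError("dose grid must be non-empty")
    extinct_flags = [simulate(params, float(d)).extinct for d in doses]
    if not any(extinct_flags):
        return ThresholdResult(found=False, dose=float("nan"))
    first = int(np.argmax(extinct_flags))
    if first == 0:
        return ThresholdResult(found=True, dose=float(doses[0]), bracket=(float(doses[0]), float(doses[0])))
    lo, hi = float(doses[first - 1]), float(doses[first])
    if not refine:
        return ThresholdResult(found=True, dose=hi, bracket=(lo, hi))
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if simulate(params, mid).extinct:
            hi = mid
        else:
            lo = mid
    return ThresholdResult(found=True, dose=0.5 * (lo + hi), bracket=(lo, hi))


@dataclass(frozen=True)
class ShapeDiagnostic:
    """Descriptive curvature summary of a dose-indexed frequency series."""

    mean_second_difference: float
    interior_extremum: str | None     # "min", "max" or None
    extremum_dose: float              # NaN when no interior extremum
    interior_minus_chord: float       # mean deviation of interior points from
                                      # the endpoint-to-endpoint straight line
    n_points: int


def shape_diagnostic(result: pd.DataFrame, fecundity_value: float) -> ShapeDiagnostic:
    """Summarize the shape of SR-male frequency vs dose at one fecundity value."""
    sub = result.loc[
        np.isclose(result["varied_value"], fecundity_value) & ~result["extinct"]
    ].sort_values("dose_ml")
    doses = sub["dose_ml"].to_numpy(float)
    freqs = sub["sr_male_freq"].to_numpy(float)
    if doses.size < 3:
        raise ValueError("need at least 3 non-extinct doses for a shape diagnostic")
    d2 = np.diff(freqs, 2)
    chord = freqs[0] + (freqs[-1] - freqs[0]) * (doses - doses[0]) / (doses[-1] - doses[0])
    interior_dev = float(np.mean((freqs - chord)[1:-1]))
    extremum = None
    ext_dose = float("nan")
    interior = freqs[1:-1]
    if interior.size:
        i_min, i_max = int(np.argmin(interior)) + 1, int(np.argmax(interior)) + 1
        if freqs[i_min] < min(freqs[0], freqs[-1]):
            extremum, ext_dose = "min", float(doses[i_min])
        if freqs[i_max] > max(freqs[0], freqs[-1]):
            # a dominant interior maximum overrides a shallower minimum
            if extremum is None or (freqs[i_max] - max(freqs[0], freqs[-1])) > (
                min(freqs[0], freqs[-1]) - freqs[i_min]
            ):
                extremum, ext_dose = "max", float(doses[i_max])
    return ShapeDiagnostic(
        mean_second_difference=float(d2.mean()) if d2.size else 0.0,
        interior_extremum=extremum,
        extremum_dose=ext_dose,
        interior_minus_chord=interior_dev,
        n_points=int(doses.size),
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    outdir: Path
    params: ModelParams
    artifacts: dict = field(default_factory=dict)


def run_pipeline(config: "io_config.RunConfig", outdir: str | Path) -> PipelineResult:
    """Generate (or read) data, fit, parametrize, sweep, and write artifacts.

    Artifacts: the two data CSVs (when generated), the parametrization file,
    one sweep CSV per varied brood-size parameter, a threshold/diagnostic
    JSON, and a run log with seed, config hash, resolved parameters and
    per-stage timings.  All data artifacts are deterministic under a fixed
    seed; the run log records wall-clock timings and is excluded from
    byte-level reproducibility.
    """
    config = io_config.validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    timings = {}
    artifacts = {}

    def stage(name):
        log_lines.append(f"stage: {name}")
        return time.perf_counter()

    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(2)

    try:
        t0 = stage("data")
        if config.mortality_csv is not None:
            mortality = io_config.read_vial_csv(config.mortality_csv)
            log_lines.append(f"  read mortality table from {config.mortality_csv}")
        else:
            mortality = generate_mortality_dataset(
                params=config.true_mortality,
                n_vials_per_genotype=config.n_vials_per_genotype,
                seed=seeds[0],
            )
            path = outdir / "mortality.csv"
            io_config.write_vial_csv(mortality, path)
            # re-read so in-memory and file-based runs fit bit-identical inputs
            mortality = io_config.read_vial_csv(path)
            artifacts["mortality_csv"] = path
        if config.fecundity_csv is not None:
            fecundity_tbl = io_config.read_fecundity_csv(config.fecundity_csv)
            log_lines.append(f"  read fecundity table from {config.fecundity_csv}")
        else:
            fecundity_tbl = generate_fecundity_dataset(
                params=config.true_fecundity,
                n_females_per_genotype=config.n_females_per_genotype,
                seed=seeds[1],
            )
            path = outdir / "fecundity.csv"
            io_config.write_fecundity_csv(fecundity_tbl, path)
            fecundity_tbl = io_config.read_fecundity_csv(path)
            artifacts["fecundity_csv"] = path
        timings["data"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'data' failed: {exc}") from exc

    try:
        t0 = stage("fit")
        glm = fit_mortality_glm(mortality, formula=config.mortality_formula)
        mixed = fit_fecundity_mixed(fecundity_tbl, random_spec=config.fecundity_random_spec)
        log_lines.append(f"  mortality logLik={glm.llf:.4f}")
        log_lines.append(
            f"  fecundity logLik={mixed.llf:.4f} "
            f"random={mixed.random_structure} singular={mixed.singular}"
        )
        timings["fit"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    try:
        t0 = stage("parametrize")
        curves = build_dose_response(glm)
        fec = build_fecundity_params(fecundity_tbl, half_width=config.fecundity_half_width)
        initial = config.initial_state()
        model_params = default_model_params(
            curves, fec, theta=config.theta, initial_state=initial,
            t_max=config.t_max, efficacy=config.efficacy,
        )
        params_path = outdir / "params.yaml"
        io_config.write_params_file(model_params, params_path)
        artifacts["params"] = params_path
        timings["parametrize"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'parametrize' failed: {exc}") from exc

    try:
        t0 = stage("sweeps")
        dose_grid = np.linspace(config.sweep_dose_min, config.sweep_dose_max, config.sweep_dose_points)
        for vary in VARIABLE_PARAMS:
            spec = SweepSpec.from_params(model_params, vary, dose_grid=dose_grid,
                                         n_fecundity=config.sweep_fecundity_points)
            sweep = run_sweep(spec, model_params)
            path = outdir / f"sweep_{vary}.csv"
            sweep.to_csv(path, index=False)
            artifacts[f"sweep_{vary}"] = path
        timings["sweeps"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'sweeps' failed: {exc}") from exc

    try:
        t0 = stage("diagnostics")
        threshold = find_extinction_threshold(model_params, dose_grid)
        diag = {
            "extinction_threshold_found": threshold.found,
            "extinction_threshold_dose_ml": None if not threshold.found else threshold.dose,
        }
        diag_path = outdir / "diagnostics.json"
        diag_path.write_text(json.dumps(diag, indent=2, sort_keys=True) + "\n")
        artifacts["diagnostics"] = diag_path
        timings["diagnostics"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'diagnostics' failed: {exc}") from exc

    log = {
        "seed": config.seed,
        "config_hash": io_config.config_hash(config),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "resolved_theta": model_params.theta,
        "resolved_fecundity": {tok: fec.value(tok) for tok in ("SRSR", "SRST", "STST")},
        "resolved_curves": {
            tok: {"intercept": c.intercept, "slope": c.slope}
            for tok, c in curves.items()
        },
        "timings_s": timings,
    }
    log_path = outdir / "run_log.txt"
    log_path.write_text(
        "\n".join(log_lines) + "\n" + json.dumps(log, indent=2, sort_keys=True) + "\n"
    )
    artifacts["run_log"] = log_path
    return PipelineResult(outdir=outdir, params=model_params, artifacts=artifacts)
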