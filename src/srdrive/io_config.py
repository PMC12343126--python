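"""Readers, writers, configuration schema and validation shared by all stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._genotypes import FEMALE_TOKENS, GENOTYPE_TOKENS, Genotype
from .synthetic_data import (
    DEFAULT_FECUNDITY_PARAMS,
    DEFAULT_MORTALITY_PARAMS,
    FECUNDITY_COLUMNS,
    TrueFecundityParams,
    TrueMortalityParams,
    VIAL_COLUMNS,
)

_SEX_OF = {g.token: g.sex.value for g in Genotype}


class CsvValidationError(ValueError):
    """Raised with every violated row-level constraint, not just the first."""

    def __init__(self, path, problems):
        self.problems = list(problems)
        msg = f"{path}: {len(self.problems)} validation problem(s):\n" + "\n".join(
            f"  - {p}" for p in self.problems
        )
        super().__init__(msg)


class ConfigError(ValueError):
    """Raised with every violated configuration constraint."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _read_checked(path, expected_columns) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != expected_columns:
        raise CsvValidationError(
            path, [f"header mismatch: expected {expected_columns}, got {list(df.columns)}"]
        )
    return df


def read_vial_csv(path) -> pd.DataFrame:
    """Read and validate a mortality table (one row per vial).

    Data rows are numbered from 2 (line 1 is the header) in error messages.
    """
    df = _read_checked(path, VIAL_COLUMNS)
    problems = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        if row.genotype not in GENOTYPE_TOKENS:
            problems.append(f"line {pos}: unknown genotype token {row.genotype!r}")
            continue
        if row.sex != _SEX_OF[row.genotype]:
            problems.append(f"line {pos}: sex {row.sex!r} inconsistent with genotype {row.genotype}")
        if not (row.dose_ml >= 0):
            problems.append(f"line {pos}: dose_ml must be >= 0 (got {row.dose_ml})")
        if not (0 <= row.n_dead <= row.n_exposed):
            problems.append(
                f"line {pos}: need 0 <= n_dead <= n_exposed (got n_dead={row.n_dead}, "
                f"n_exposed={row.n_exposed})"
            )
    if problems:
        raise CsvValidationError(path, problems)
    return df


def read_fecundity_csv(path) -> pd.DataFrame:
    """Read and validate a fecundity table (one row per retained measurement)."""
    df = _read_checked(path, FECUNDITY_COLUMNS)
    problems = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        if row.genotype not in FEMALE_TOKENS:
            problems.append(f"line {pos}: genotype {row.genotype!r} is not a female genotype")
        if not (row.dose_ml >= 0):
            problems.append(f"line {pos}: dose_ml must be >= 0 (got {row.dose_ml})")
        if row.measure not in (1, 2):
            problems.append(f"line {pos}: measure must be 1 or 2 (got {row.measure})")
        if not (row.offspring >= 1):
            problems.append(f"line {pos}: offspring must be >= 1 after exclusion (got {row.offspring})")
    counts = df.groupby(["female_id", "measure"]).size()
    for (female, measure), k in counts.items():
        if k > 1:
            problems.append(f"female {female}: duplicate measure {measure}")
    if problems:
        raise CsvValidationError(path, problems)
    return df


def write_vial_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=VIAL_COLUMNS)


def write_fecundity_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=FECUNDITY_COLUMNS)


# ---------------------------------------------------------------------------
# parametrization file (consumed verbatim by the drive model)
# ---------------------------------------------------------------------------

def write_params_file(params, path) -> None:
    """Write a ModelParams as a human-editable YAML file."""
    doc = {
        "curves": {
            tok: {
                "intercept": float(c.intercept),
                "slope": float(c.slope),
                "dose_min": float(c.dose_min),
                "dose_max": float(c.dose_max),
            }
            for tok, c in params.curves.items()
        },
        "fecundity": {
            "b_SRSR": float(params.fecundity.b_SRSR),
            "b_SRST": float(params.fecundity.b_SRST),
            "b_STST": float(params.fecundity.b_STST),
            "half_width": float(params.fecundity.half_width),
        },
        "theta": float(params.theta),
        "efficacy": float(params.efficacy),
        "t_max": int(params.t_max),
        "extinction_threshold": float(params.extinction_threshold),
        "density_form": params.density_form,
        "initial_abundance": {
            tok: float(v) for tok, v in params.initial_state.as_dict().items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_params_file(path):
    """Read a parametrization file back into a ModelParams."""
    from .drive_model import ModelParams, PopulationState
    from .parametrize import DoseResponseCurve, FecundityParams

    doc = yaml.safe_load(Path(path).read_text())
    curves = {
        tok: DoseResponseCurve(genotype=tok, **spec) for tok, spec in doc["curves"].items()
    }
    fec = FecundityParams(**doc["fecundity"])
    initial = PopulationState.from_mapping(doc["initial_abundance"])
    return ModelParams(
        curves=curves,
        fecundity=fec,
        theta=doc["theta"],
        efficacy=doc.get("efficacy", 1.0),
        t_max=doc.get("t_max", 1000),
        extinction_threshold=doc.get("extinction_threshold"),
        density_form=doc.get("density_form", "beverton_holt"),
        initial_state=initial,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration for an end-to-end pipeline run."""

    seed: int = 0
    profile: str = "production"              # test profiles may relax efficacy
    # data stage
    mortality_csv: str | None = None         # when set, generation is skipped
    fecundity_csv: str | None = None
    n_vials_per_genotype: int = 35
    n_females_per_genotype: int = 150
    true_mortality: TrueMortalityParams = field(default_factory=lambda: DEFAULT_MORTALITY_PARAMS)
    true_fecundity: TrueFecundityParams = field(default_factory=lambda: DEFAULT_FECUNDITY_PARAMS)
    # fitting stage
    mortality_formula: str = "per_class"
    fecundity_random_spec: str = "individual_in_vial"
    fecundity_half_width: float = 10.0
    # model stage
    theta: float | None = None               # None: derived from brood sizes
    efficacy: float = 1.0
    t_max: int = 1000
    initial_total: float = 1000.0
    initial_sr_male_freq: float = 0.1
    initial_srsr_female_freq: float = 0.01
    initial_srst_female_freq: float = 0.18
    # sweep stage
    sweep_dose_min: float = 0.0
    sweep_dose_max: float = 2.5
    sweep_dose_points: int = 26
    sweep_fecundity_points: int = 5

    def initial_state(self):
        from .drive_model import PopulationState

        return PopulationState.from_frequencies(
            total=self.initial_total,
            sr_male_freq=self.initial_sr_male_freq,
            srsr_female_freq=self.initial_srsr_female_freq,
            srst_female_freq=self.initial_srst_female_freq,
        )


def validate_config(config: RunConfig) -> RunConfig:
    """Check every constraint and return the (already-defaulted) config."""
    problems = []
    if not isinstance(config.seed, (int, np.integer)):
        problems.append(f"seed must be an integer (got {config.seed!r})")
    if config.profile not in ("production", "test"):
        problems.append(f"profile must be 'production' or 'test' (got {config.profile!r})")
    if config.profile == "production" and config.efficacy != 1.0:
        problems.append("drive efficacy must be 1.0 in a production profile")
    if not (0.0 <= config.efficacy <= 1.0):
        problems.append("efficacy must be in [0, 1]")
    if config.theta is not None and config.theta <= 0:
        problems.append("theta must be > 0")
    if config.t_max < 1:
        problems.append("t_max must be >= 1")
    if config.n_vials_per_genotype <= 0:
        problems.append("n_vials_per_genotype must be > 0")
    if config.n_females_per_genotype < 0:
        problems.append("n_females_per_genotype must be >= 0")
    if config.initial_total <= 0:
        problems.append("initial_total must be > 0")
    for name in ("initial_sr_male_freq", "initial_srsr_female_freq", "initial_srst_female_freq"):
        v = getattr(config, name)
        if not (0.0 <= v <= 1.0):
            problems.append(f"{name} must be in [0, 1]")
    if config.initial_srsr_female_freq + config.initial_srst_female_freq > 1.0:
        problems.append("initial SRSR + SRST female frequencies must not exceed 1")
    if not (0 <= config.sweep_dose_min < config.sweep_dose_max):
        problems.append("need 0 <= sweep_dose_min < sweep_dose_max")
    if config.sweep_dose_points < 2:
        problems.append("sweep_dose_points must be >= 2")
    if config.sweep_fecundity_points < 1:
        problems.append("sweep_fecundity_points must be >= 1")
    if config.fecundity_half_width < 0:
        problems.append("fecundity_half_width must be >= 0")
    for name in ("mortality_csv", "fecundity_csv"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name} path does not exist: {p}")
    if problems:
        raise ConfigError(problems)
    return config


_NESTED_KEYS = {"true_mortality", "true_fecundity"}


def load_config(path) -> RunConfig:
    """Load a YAML config file, rejecting unknown keys, and validate it."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, Mapping):
        raise ConfigError([f"config root must be a mapping, got {type(doc).__name__}"])
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ConfigError([f"unknown config key {k!r}" for k in unknown])
    kwargs = dict(doc)
    if "true_mortality" in kwargs:
        kwargs["true_mortality"] = TrueMortalityParams(**kwargs["true_mortality"])
    if "true_fecundity" in kwargs:
        kwargs["true_fecundity"] = TrueFecundityParams(**kwargs["true_fecundity"])
    return validate_config(RunConfig(**kwargs))


def config_hash(config: RunConfig) -> str:
    """Stable hash of the fully resolved configuration."""
    def default(o):
        if isinstance(o, (TrueMortalityParams, TrueFecundityParams)):
            d = asdict(o)
            # mappings inside frozen dataclasses may be arbitrary Mapping types
            return json.loads(json.dumps(d, sort_keys=True, default=dict))
        if isinstance(o, Mapping):
            return dict(o)
        raise TypeError(f"unserializable config value: {o!r}")

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()
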