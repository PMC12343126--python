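"""Synthetic mortality and fecundity experiments with known ground truth.

Two generators mimic the structure of a vial-based pesticide assay:

* a mortality assay — per vial, a known number of flies of one genotype is
  exposed to a dose of pesticide solution and deaths are counted after a
  fixed interval; deaths are binomial with a logit-linear dose-response; and
* a fecundity assay — exposed females (nested in vials) each contribute up
  to two weekly offspring counts, Poisson on a log-linear scale with vial
  (and optionally individual) random intercepts; zero counts are discarded
  because a zero cannot be distinguished from a failed mating.

Because the generating parameters are known, every downstream fitting stage
can be tested by parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._genotypes import (
    FEMALE_TOKENS,
    GENOTYPE_ORDER,
    GENOTYPE_TOKENS,
    Genotype,
)

VIAL_COLUMNS = ["vial_id", "genotype", "sex", "dose_ml", "n_exposed", "n_dead"]
FECUNDITY_COLUMNS = ["female_id", "vial_id", "genotype", "dose_ml", "measure", "offspring"]

DEFAULT_DOSE_MIN = 0.0
DEFAULT_DOSE_MAX = 1.8


@dataclass(frozen=True)
class TrueMortalityParams:
    """Generating logit-linear dose-response parameters, one curve per genotype.

    ``intercepts`` and ``slopes`` are keyed by genotype token; death
    probability at dose ``x`` (ml of solution) is ``expit(a + b * x)``.
    """

    intercepts: Mapping[str, float]
    slopes: Mapping[str, float]
    dose_min: float = DEFAULT_DOSE_MIN
    dose_max: float = DEFAULT_DOSE_MAX

    def __post_init__(self) -> None:
        for token in GENOTYPE_TOKENS:
            if token not in self.intercepts or token not in self.slopes:
                raise ValueError(f"missing mortality parameters for genotype {token}")
        for name, mapping in (("intercept", self.intercepts), ("slope", self.slopes)):
            for token, value in mapping.items():
                if not np.isfinite(value):
                    raise ValueError(f"non-finite {name} for genotype {token}: {value}")
        if not (self.dose_min >= 0 and self.dose_max > self.dose_min):
            raise ValueError("dose bounds must satisfy 0 <= dose_min < dose_max")

    def death_probability(self, genotype: str, dose) -> np.ndarray:
        return expit(self.intercepts[genotype] + self.slopes[genotype] * np.asarray(dose, float))


@dataclass(frozen=True)
class TrueFecundityParams:
    """Generating Poisson log-linear fecundity parameters for female genotypes.

    ``log_means`` holds the log-scale mean offspring count at dose zero per
    female genotype; ``dose_effect`` is the shared log-linear dose slope.
    ``sigma_vial`` and ``sigma_individual`` are random-intercept standard
    deviations (individual defaults to zero so the default generator matches
    a vial-only random-effect structure).
    """

    log_means: Mapping[str, float]
    dose_effect: float = -0.3
    sigma_vial: float = 0.2
    sigma_individual: float = 0.0

    def __post_init__(self) -> None:
        for token in FEMALE_TOKENS:
            if token not in self.log_means:
                raise ValueError(f"missing fecundity log-mean for genotype {token}")
        for token, value in self.log_means.items():
            if not np.isfinite(np.exp(value)):
                raise ValueError(f"exp(log-mean) not finite for genotype {token}")
        if self.sigma_vial < 0 or self.sigma_individual < 0:
            raise ValueError("random-effect standard deviations must be >= 0")
        if not np.isfinite(self.dose_effect):
            raise ValueError("dose_effect must be finite")


#: Calibrated defaults: drive-carrying males and drive-homozygous females
#: have elevated baseline mortality, male curves converge at high dose, and
#: heterozygous females are the most fecund (b_SRST > b_STST > b_SRSR).
DEFAULT_MORTALITY_PARAMS = TrueMortalityParams(
    intercepts={"SR": -1.8, "ST": -3.0, "SRSR": -2.3, "SRST": -3.5, "STST": -3.5},
    slopes={"SR": 2.3, "ST": 2.8, "SRSR": 2.5, "SRST": 2.5, "STST": 2.5},
)

DEFAULT_FECUNDITY_PARAMS = TrueFecundityParams(
    log_means={"SRSR": float(np.log(10.0)), "SRST": float(np.log(30.0)), "STST": float(np.log(20.0))},
    dose_effect=-0.3,
    sigma_vial=0.2,
    sigma_individual=0.0,
)


def true_dose_response_curves(params: TrueMortalityParams = DEFAULT_MORTALITY_PARAMS):
    """The generating curves as fit-compatible dose-response objects."""
    from .parametrize import DoseResponseCurve

    return {
        token: DoseResponseCurve(
            genotype=token,
            intercept=float(params.intercepts[token]),
            slope=float(params.slopes[token]),
            dose_min=params.dose_min,
            dose_max=params.dose_max,
        )
        for token in GENOTYPE_TOKENS
    }


def default_dose_grid(n: int, dose_min: float = DEFAULT_DOSE_MIN, dose_max: float = DEFAULT_DOSE_MAX) -> np.ndarray:
    """Evenly spaced doses over the assay range (the spacing is a free choice)."""
    if n < 1:
        raise ValueError("need at least one dose")
    if n == 1:
        return np.array([dose_min])
    return np.linspace(dose_min, dose_max, n)


def _check_doses(dose_values: Sequence[float], params_min: float, params_max: float) -> np.ndarray:
    doses = np.asarray(list(dose_values), dtype=float)
    if doses.size == 0:
        raise ValueError("dose_values must be non-empty")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if np.any(doses < params_min - 1e-12) or np.any(doses > params_max + 1e-12):
        raise ValueError(
            f"doses outside the configured range [{params_min}, {params_max}]"
        )
    return doses


def generate_mortality_dataset(
    params: TrueMortalityParams = DEFAULT_MORTALITY_PARAMS,
    n_vials_per_genotype: int = 35,
    dose_values: Sequence[float] | None = None,
    flies_per_vial_range: tuple[int, int] = (7, 11),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the vial-level mortality assay.

    Returns one row per vial with columns ``vial_id, genotype, sex, dose_ml,
    n_exposed, n_dead``; exactly ``n_vials_per_genotype`` rows per genotype,
    doses cycled over ``dose_values`` (default: an evenly spaced grid with one
    point per vial), and ``n_dead ~ Binomial(n_exposed, expit(a + b*dose))``.
    """
    if n_vials_per_genotype <= 0:
        raise ValueError("n_vials_per_genotype must be positive")
    lo, hi = flies_per_vial_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid flies_per_vial_range")
    if dose_values is None:
        doses = default_dose_grid(n_vials_per_genotype, params.dose_min, params.dose_max)
    else:
        doses = _check_doses(dose_values, params.dose_min, params.dose_max)

    rng = np.random.default_rng(seed)
    rows = []
    vial_counter = 0
    for genotype in GENOTYPE_ORDER:
        for i in range(n_vials_per_genotype):
            vial_counter += 1
            dose = float(doses[i % doses.size])
            n_exposed = int(rng.integers(lo, hi + 1))
            p_death = float(params.death_probability(genotype.token, dose))
            n_dead = int(rng.binomial(n_exposed, p_death))
            rows.append(
                {
                    "vial_id": f"MV{vial_counter:04d}",
                    "genotype": genotype.token,
                    "sex": genotype.sex.value,
                    "dose_ml": dose,
                    "n_exposed": n_exposed,
                    "n_dead": n_dead,
                }
            )
    return pd.DataFrame(rows, columns=VIAL_COLUMNS)


def generate_fecundity_dataset(
    params: TrueFecundityParams = DEFAULT_FECUNDITY_PARAMS,
    n_females_per_genotype: int = 150,
    dose_values: Sequence[float] | None = None,
    females_per_vial: int = 4,
    n_measures: int = 2,
    survival_thinning: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the per-female fecundity assay.

    Females of each genotype are assigned round-robin to doses and grouped
    into vials; each contributes up to ``n_measures`` weekly offspring
    counts, Poisson with log-mean ``log_mean[g] + dose_effect*dose + u_vial
    (+ u_individual)``.  Rows with a zero count are removed (a zero cannot be
    told apart from an unmated female), so females whose counts are all zero
    vanish entirely.  Realized per-genotype female counts are attached as
    ``df.attrs["n_females_realized"]``.

    ``survival_thinning`` optionally maps genotype token -> probability that
    an exposed female survives to be measured at a given dose fraction of
    the range, emulating genotype-imbalanced sample sizes; default off.
    """
    if n_females_per_genotype < 0:
        raise ValueError("n_females_per_genotype must be >= 0")
    if females_per_vial < 1:
        raise ValueError("females_per_vial must be >= 1")
    if dose_values is None:
        doses = default_dose_grid(8)
    else:
        doses = _check_doses(dose_values, 0.0, np.inf)

    rng = np.random.default_rng(seed)
    rows = []
    vial_counter = 0
    female_counter = 0
    for token in FEMALE_TOKENS:
        eta0 = params.log_means[token]
        # females grouped by dose, then chunked into vials
        per_dose = [[] for _ in range(doses.size)]
        for i in range(n_females_per_genotype):
            per_dose[i % doses.size].append(i)
        for d_idx, females in enumerate(per_dose):
            dose = float(doses[d_idx])
            if survival_thinning is not None and females:
                keep_p = float(survival_thinning.get(token, 1.0))
                females = [f for f in females if rng.random() < keep_p]
            for start in range(0, len(females), females_per_vial):
                chunk = females[start : start + females_per_vial]
                vial_counter += 1
                vial_id = f"FV{vial_counter:04d}"
                u_vial = rng.normal(0.0, params.sigma_vial) if params.sigma_vial > 0 else 0.0
                for _ in chunk:
                    female_counter += 1
                    female_id = f"F{female_counter:05d}"
                    u_ind = (
                        rng.normal(0.0, params.sigma_individual)
                        if params.sigma_individual > 0
                        else 0.0
                    )
                    lam = np.exp(eta0 + params.dose_effect * dose + u_vial + u_ind)
                    for measure in range(1, n_measures + 1):
                        count = int(rng.poisson(lam))
                        if count == 0:
                            continue  # zero-count exclusion
                        rows.append(
                            {
                                "female_id": female_id,
                                "vial_id": vial_id,
                                "genotype": token,
                                "dose_ml": dose,
                                "measure": measure,
                                "offspring": count,
                            }
                        )
    df = pd.DataFrame(rows, columns=FECUNDITY_COLUMNS)
    realized = {
        token: int(df.loc[df["genotype"] == token, "female_id"].nunique())
        for token in FEMALE_TOKENS
    }
    df.attrs["n_females_realized"] = realized
    return df
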