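"""Deterministic dynamics of an X-linked sex-ratio drive allele.

A class-structured model with non-overlapping generations tracks continuous
abundances of the five genotypes.  Each generation: dose-dependent mortality
removes a genotype-specific fraction of adults before mating; surviving
females each mate once, with sires drawn in proportion to male abundance,
and produce a brood whose size depends only on the dam's genotype; drive
acts in SR sires with 100% efficacy (all-daughter broods); offspring are
then density-regulated (Beverton-Holt by default) and replace the adults.

Populations are absorbed to zero below a quasi-extinction cutoff, so the
classic driving-X outcome — fixation followed by extinction through loss of
males — is reachable despite the deterministic, continuous state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._genotypes import (
    FEMALE_GENOTYPES,
    GENOTYPE_INDEX,
    GENOTYPE_ORDER,
    GENOTYPE_TOKENS,
    MALE_GENOTYPES,
    Genotype,
    Sex,
)
from .parametrize import DoseResponseCurve, FecundityParams

_IDX_SR = GENOTYPE_INDEX[Genotype.SR]
_IDX_ST = GENOTYPE_INDEX[Genotype.ST]
_IDX_SRSR = GENOTYPE_INDEX[Genotype.SRSR]
_MALE_SLICE = slice(0, 2)
_FEMALE_SLICE = slice(2, 5)

DENSITY_FORMS = ("beverton_holt", "ricker")


@dataclass
class PopulationState:
    """Abundance per genotype (canonical order SR, ST, SRSR, SRST, STST)."""

    abundance: np.ndarray
    t: int = 0

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, float)
        if self.abundance.shape != (5,):
            raise ValueError("abundance must be a length-5 vector")
        if not np.all(np.isfinite(self.abundance)) or np.any(self.abundance < 0):
            raise ValueError("abundances must be finite and non-negative")
        if self.t < 0:
            raise ValueError("generation index must be >= 0")

    @classmethod
    def from_mapping(cls, values: Mapping[str, float], t: int = 0) -> "PopulationState":
        return cls(np.array([values.get(tok, 0.0) for tok in GENOTYPE_TOKENS]), t=t)

    @classmethod
    def from_frequencies(
        cls,
        total: float = 1000.0,
        sr_male_freq: float = 0.1,
        srsr_female_freq: float = 0.01,
        srst_female_freq: float = 0.18,
        female_fraction: float = 0.5,
    ) -> "PopulationState":
        """Initial state at a given total density and class frequencies."""
        males = total * (1.0 - female_fraction)
        females = total * female_fraction
        return cls(np.array([
            males * sr_male_freq,
            males * (1.0 - sr_male_freq),
            females * srsr_female_freq,
            females * srst_female_freq,
            females * (1.0 - srsr_female_freq - srst_female_freq),
        ]))

    @property
    def total(self) -> float:
        return float(self.abundance.sum())

    @property
    def males(self) -> float:
        return float(self.abundance[_MALE_SLICE].sum())

    @property
    def females(self) -> float:
        return float(self.abundance[_FEMALE_SLICE].sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(GENOTYPE_TOKENS, map(float, self.abundance)))


@dataclass(frozen=True)
class CrossOutcome:
    """Offspring genotype distribution for one sire x dam pairing."""

    sire: Genotype
    dam: Genotype
    probs: dict

    def __post_init__(self):
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"offspring probabilities sum to {total}, not 1")


def cross_offspring(sire: Genotype, dam: Genotype, efficacy: float = 1.0) -> CrossOutcome:
    """Offspring distribution for one mating under X-linked drive.

    ``efficacy`` is the fraction of Y-bearing sperm destroyed in SR sires
    (production value 1.0: SR-sired broods are all daughters).  Daughters
    combine the sire's X allele with one maternal allele; sons carry a
    maternal allele only.
    """
    if sire.sex != Sex.MALE or dam.sex != Sex.FEMALE:
        raise ValueError("cross_offspring requires a male sire and a female dam")
    if not (0.0 <= efficacy <= 1.0):
        raise ValueError("efficacy must be in [0, 1]")
    if sire is Genotype.SR:
        p_daughter = 1.0 / (2.0 - efficacy)
    else:
        p_daughter = 0.5
    sire_allele = sire.alleles[0]
    probs: dict[Genotype, float] = {}
    for maternal in dam.alleles:  # each maternal allele drawn w.p. 1/2
        daughter = Genotype.from_token("".join(sorted((sire_allele, maternal))))
        probs[daughter] = probs.get(daughter, 0.0) + 0.5 * p_daughter
        son = Genotype.from_token(maternal)
        probs[son] = probs.get(son, 0.0) + 0.5 * (1.0 - p_daughter)
    probs = {g: p for g, p in probs.items() if p > 0.0}
    return CrossOutcome(sire=sire, dam=dam, probs=probs)


def _cross_tensor(efficacy: float = 1.0) -> np.ndarray:
    """(dam, sire, offspring) probability tensor over canonical indices."""
    T = np.zeros((3, 2, 5))
    for di, dam in enumerate(FEMALE_GENOTYPES):
        for si, sire in enumerate(MALE_GENOTYPES):
            for g, p in cross_offspring(sire, dam, efficacy).probs.items():
                T[di, si, GENOTYPE_INDEX[g]] = p
    return T


@dataclass
class ModelParams:
    """Everything needed to iterate the drive recursion at one dose."""

    curves: Mapping[str, DoseResponseCurve]
    fecundity: FecundityParams
    theta: float
    initial_state: PopulationState
    efficacy: float = 1.0
    t_max: int = 1000
    extinction_threshold: float = field(default=None)
    density_form: str = "beverton_holt"

    def __post_init__(self):
        missing = [tok for tok in GENOTYPE_TOKENS if tok not in self.curves]
        if missing:
            raise ValueError(f"missing dose-response curves for {missing}")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not (0.0 <= self.efficacy <= 1.0):
            raise ValueError("efficacy must be in [0, 1]")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.extinction_threshold is None:
            self.extinction_threshold = 1e-6 * self.initial_state.total
        if self.extinction_threshold <= 0:
            raise ValueError("extinction threshold must be > 0")
        if self.density_form not in DENSITY_FORMS:
            raise ValueError(f"density_form must be one of {DENSITY_FORMS}")

    def with_fecundity(self, **changes) -> "ModelParams":
        return replace(self, fecundity=replace(self.fecundity, **changes))

    def brood_sizes(self) -> np.ndarray:
        return np.array([self.fecundity.value(g.token) for g in FEMALE_GENOTYPES])

    def survival(self, dose: float) -> np.ndarray:
        if dose < 0:
            raise ValueError("dose must be >= 0")
        return np.array([
            1.0 - float(self.curves[tok].death_probability(dose))
            for tok in GENOTYPE_TOKENS
        ])


def default_theta(fecundity: FecundityParams, initial_total: float) -> float:
    """Pick theta so the pesticide-free wild-type equilibrium sits near the
    initial density: under Beverton-Holt, N* = (b/2 - 1)/theta."""
    b_mean = np.mean([fecundity.value(tok) for tok in ("SRSR", "SRST", "STST")])
    if b_mean <= 2.0:
        raise ValueError("mean brood size must exceed 2 for a positive equilibrium")
    return (b_mean / 2.0 - 1.0) / initial_total


def default_model_params(
    curves: Mapping[str, DoseResponseCurve],
    fecundity: FecundityParams,
    theta: float | None = None,
    initial_state: PopulationState | None = None,
    **kwargs,
) -> ModelParams:
    if initial_state is None:
        initial_state = PopulationState.from_frequencies()
    if theta is None:
        theta = default_theta(fecundity, initial_state.total)
    return ModelParams(
        curves=curves, fecundity=fecundity, theta=theta,
        initial_state=initial_state, **kwargs,
    )


# ---------------------------------------------------------------------------
# one-generation operators
# ---------------------------------------------------------------------------

def apply_mortality(state: PopulationState, dose: float, curves: Mapping[str, DoseResponseCurve]) -> PopulationState:
    """Remove the dose- and genotype-specific fraction of each class."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    missing = [tok for tok in GENOTYPE_TOKENS if tok not in curves]
    if missing:
        raise ValueError(f"missing dose-response curves for {missing}")
    survival = np.array([
        1.0 - float(curves[tok].death_probability(dose)) for tok in GENOTYPE_TOKENS
    ])
    return PopulationState(state.abundance * survival, t=state.t)


def mate_and_reproduce(state: PopulationState, fecundity: FecundityParams, efficacy: float = 1.0) -> np.ndarray:
    """Offspring abundances from random once-mating of all surviving females.

    Every female mates (with a sire drawn proportionally to male abundance)
    as long as total male abundance is positive; a dam of genotype ``j``
    contributes ``b_j`` offspring split over genotypes by the mating table.
    """
    n = state.abundance
    if np.any(n < 0):
        raise ValueError("abundances must be non-negative")
    males = n[_MALE_SLICE]
    m_total = males.sum()
    if m_total <= 0.0:
        return np.zeros(5)
    sire_freq = males / m_total
    b = np.array([fecundity.value(g.token) for g in FEMALE_GENOTYPES])
    dams = n[_FEMALE_SLICE] * b
    T = _cross_tensor(efficacy)
    return np.einsum("d,s,dsg->g", dams, sire_freq, T)


def density_regulate(offspring: np.ndarray, theta: float, form: str = "beverton_holt") -> np.ndarray:
    """Scale all genotypes by a common density-dependent recruitment factor."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    offspring = np.asarray(offspring, float)
    total = offspring.sum()
    if form == "beverton_holt":
        factor = 1.0 / (1.0 + theta * total)
    elif form == "ricker":
        factor = np.exp(-theta * total)
    else:
        raise ValueError(f"density_form must be one of {DENSITY_FORMS}")
    return offspring * factor


def step(state: PopulationState, dose: float, params: ModelParams) -> PopulationState:
    """One non-overlapping generation: mortality, mating, recruitment."""
    survivors = apply_mortality(state, dose, params.curves)
    offspring = mate_and_reproduce(survivors, params.fecundity, params.efficacy)
    recruits = density_regulate(offspring, params.theta, params.density_form)
    return PopulationState(recruits, t=state.t + 1)


def sr_male_frequency(state: PopulationState) -> float:
    """SR males / all males; NaN when there are no males."""
    males = state.abundance[_MALE_SLICE].sum()
    if males <= 0.0:
        return float("nan")
    return float(state.abundance[_IDX_SR] / males)


def srsr_female_frequency(state: PopulationState) -> float:
    """SRSR females / all females; NaN when there are no females."""
    females = state.abundance[_FEMALE_SLICE].sum()
    if females <= 0.0:
        return float("nan")
    return float(state.abundance[_IDX_SRSR] / females)


@dataclass
class Trajectory:
    """Per-generation record of a simulation run."""

    t: np.ndarray
    abundance: np.ndarray  # (n, 5)
    sr_male_freq: np.ndarray
    srsr_female_freq: np.ndarray
    extinct: bool
    dose: float

    @property
    def total(self) -> np.ndarray:
        return self.abundance.sum(axis=1)

    @property
    def t_final(self) -> int:
        return int(self.t[-1])

    def final_state(self) -> PopulationState:
        return PopulationState(self.abundance[-1], t=self.t_final)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.abundance, columns=[f"n_{tok}" for tok in GENOTYPE_TOKENS])
        df.insert(0, "t", self.t)
        df["total"] = self.total
        df["sr_male_freq"] = self.sr_male_freq
        df["srsr_female_freq"] = self.srsr_female_freq
        df["extinct"] = self.extinct
        df["dose_ml"] = self.dose
        return df


def simulate(params: ModelParams, dose: float) -> Trajectory:
    """Iterate the recursion for ``t_max`` generations (or until extinction).

    Genotype abundances that fall below the quasi-extinction cutoff are
    absorbed to zero each generation; the run is flagged extinct and
    truncated once total abundance drops below the cutoff.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    eps = params.extinction_threshold
    survival = params.survival(dose)
    b = params.brood_sizes()
    T = _cross_tensor(params.efficacy)
    theta = params.density_form
    theta_val = params.theta

    n = params.initial_state.abundance.astype(float).copy()
    n[n < eps] = 0.0
    ts = [0]
    traj = [n.copy()]
    extinct = n.sum() < eps
    if not extinct:
        for t in range(1, params.t_max + 1):
            n = n * survival
            m_total = n[0] + n[1]
            if m_total > 0.0:
                sire_freq = n[_MALE_SLICE] / m_total
                dams = n[_FEMALE_SLICE] * b
                offspring = np.einsum("d,s,dsg->g", dams, sire_freq, T)
            else:
                offspring = np.zeros(5)
            total_off = offspring.sum()
            if theta == "beverton_holt":
                n = offspring / (1.0 + theta_val * total_off)
            else:
                n = offspring * np.exp(-theta_val * total_off)
            n[n < eps] = 0.0
            ts.append(t)
            traj.append(n.copy())
            if n.sum() < eps:
                extinct = True
                break
    abundance = np.asarray(traj)
    males = abundance[:, _MALE_SLICE].sum(axis=1)
    females = abundance[:, _FEMALE_SLICE].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        srm = np.where(males > 0, abundance[:, _IDX_SR] / np.where(males > 0, males, 1.0), np.nan)
        srf = np.where(females > 0, abundance[:, _IDX_SRSR] / np.where(females > 0, females, 1.0), np.nan)
    return Trajectory(
        t=np.asarray(ts),
        abundance=abundance,
        sr_male_freq=srm,
        srsr_female_freq=srf,
        extinct=bool(extinct),
        dose=float(dose),
    )
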