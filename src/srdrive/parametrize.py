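"""Fitting the assay data and exporting model-ready parameters.

The mortality assay is fit with a binomial GLM (logit link) on per-vial
(dead, survived) counts; the fecundity assay with a Poisson random-intercept
model (individual nested in vial, with an automatic fallback to a vial-only
intercept when the individual variance component collapses to zero).  Model
selection uses likelihood-ratio tests, genotype comparisons use z-tests on
link-scale marginal means with a multivariate-normal ("Tukey") multiplicity
adjustment, and the fitted mortality model is exported as per-genotype
logit-linear dose-response curves that reproduce its predictions exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, norm

from ._genotypes import FEMALE_TOKENS, GENOTYPE_ORDER, GENOTYPE_TOKENS
from ._poisson_mixed import NestedPoissonMixed, VialOnlyPoissonMixed, numerical_hessian

__all__ = [
    "GlmFit",
    "MixedFit",
    "LrtResult",
    "ContrastResult",
    "DoseResponseCurve",
    "FecundityParams",
    "SeparationError",
    "fit_mortality_glm",
    "fit_fecundity_mixed",
    "lrt_drop",
    "genotype_contrasts",
    "build_dose_response",
    "build_fecundity_params",
]


class SeparationError(ValueError):
    """Raised when a binomial fit shows signs of complete separation."""


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _drive_class(token: str) -> str:
    if token in ("SR", "SRSR"):
        return "SR"
    if token == "SRST":
        return "HET"
    return "ST"


def _mortality_design(df: pd.DataFrame, formula: str, levels: tuple[str, ...] | None = None):
    """Design matrix and column names for the mortality model.

    Formulas:

    * ``per_class`` (default) — one intercept and one dose slope per
      genotype class (cell-means; sex is absorbed by the class factor).
    * ``per_class_treatment`` — same model space in treatment coding
      (reference class intercept/slope plus per-class offsets).
    * ``per_class_additive_dose`` — per-class intercepts, one shared slope.
    * ``per_class_treatment_additive_dose`` — treatment coding of the same.
    * ``per_class_intercept`` — per-class intercepts only (no dose term).
    * ``drive_class_additive`` — intercept, male indicator, drive-class
      factor (SR reference, HET/ST dummies), dose, and dose:drive-class.

    ``levels`` fixes the genotype levels (canonical order); rows with a
    genotype outside ``levels`` are rejected, which surfaces missing-level
    prediction requests.
    """
    g = df["genotype"].to_numpy()
    dose = df["dose_ml"].to_numpy(float)
    if levels is None:
        levels = tuple(t for t in GENOTYPE_TOKENS if t in set(g))
    extra = sorted(set(g) - set(levels))
    if extra:
        raise ValueError(f"genotype level(s) {extra} absent from the fitted model")
    cols, names = [], []
    if formula in ("per_class", "per_class_additive_dose", "per_class_intercept"):
        for token in levels:
            cols.append((g == token).astype(float))
            names.append(f"g[{token}]")
        if formula == "per_class":
            for token in levels:
                cols.append((g == token) * dose)
                names.append(f"g[{token}]:dose")
        elif formula == "per_class_additive_dose":
            cols.append(dose)
            names.append("dose")
    elif formula in ("per_class_treatment", "per_class_treatment_additive_dose"):
        cols.append(np.ones(len(df)))
        names.append("const")
        for token in levels[1:]:
            cols.append((g == token).astype(float))
            names.append(f"g[{token}]")
        cols.append(dose)
        names.append("dose")
        if formula == "per_class_treatment":
            for token in levels[1:]:
                cols.append((g == token) * dose)
                names.append(f"g[{token}]:dose")
    elif formula == "drive_class_additive":
        dc = np.array([_drive_class(t) for t in g])
        male = df["sex"].to_numpy() == "male"
        cols.append(np.ones(len(df)))
        names.append("const")
        cols.append(male.astype(float))
        names.append("sex[male]")
        dc_levels = tuple(l for l in ("HET", "ST") if l in set(dc))
        for level in dc_levels:
            cols.append((dc == level).astype(float))
            names.append(f"dc[{level}]")
        cols.append(dose)
        names.append("dose")
        for level in dc_levels:
            cols.append((dc == level) * dose)
            names.append(f"dc[{level}]:dose")
    else:
        raise ValueError(f"unknown mortality formula {formula!r}")
    return np.column_stack(cols), names, levels


def _fecundity_design(df: pd.DataFrame, formula: str, levels: tuple[str, ...] | None = None):
    """Design for the fecundity model; the first observed female genotype
    (canonical order, so normally SRSR) is the reference level.

    Formulas: ``genotype*dose`` (maximal), ``genotype+dose``, ``genotype``,
    ``dose``, ``1``.
    """
    g = df["genotype"].to_numpy()
    dose = df["dose_ml"].to_numpy(float)
    if levels is None:
        levels = tuple(t for t in FEMALE_TOKENS if t in set(g))
    extra = sorted(set(g) - set(levels))
    if extra:
        raise ValueError(f"genotype level(s) {extra} absent from the fitted model")
    cols = [np.ones(len(df))]
    names = ["const"]
    if formula in ("genotype*dose", "genotype+dose", "genotype"):
        for token in levels[1:]:
            cols.append((g == token).astype(float))
            names.append(f"g[{token}]")
    if formula in ("genotype*dose", "genotype+dose", "dose"):
        cols.append(dose)
        names.append("dose")
    if formula == "genotype*dose":
        for token in levels[1:]:
            cols.append((g == token) * dose)
            names.append(f"g[{token}]:dose")
    if formula not in ("genotype*dose", "genotype+dose", "genotype", "dose", "1"):
        raise ValueError(f"unknown fecundity formula {formula!r}")
    return np.column_stack(cols), names, levels


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    """A fitted binomial GLM on per-vial death counts."""

    formula: str
    terms: tuple[str, ...]
    params: np.ndarray
    cov: np.ndarray
    llf: float
    df_resid: int
    n_obs: int
    link: str = "logit"
    design_builder: Callable[[pd.DataFrame], np.ndarray] = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.terms)

    def predict_linear(self, df: pd.DataFrame) -> np.ndarray:
        return self.design_builder(df) @ self.params

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted death probabilities."""
        return expit(self.predict_linear(df))


@dataclass
class MixedFit:
    """A fitted Poisson mixed model on per-measure offspring counts."""

    formula: str
    terms: tuple[str, ...]
    params: np.ndarray
    cov: np.ndarray
    llf: float
    df_resid: int
    n_obs: int
    random_structure: str
    variance_components: dict
    singular: bool
    converged: bool
    link: str = "log"
    design_builder: Callable[[pd.DataFrame], np.ndarray] = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.terms) + len(self.variance_components)

    def predict_linear(self, df: pd.DataFrame) -> np.ndarray:
        return self.design_builder(df) @ self.params

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted mean counts at random effects = 0."""
        return np.exp(self.predict_linear(df))


@dataclass(frozen=True)
class LrtResult:
    dropped: str
    df: int
    chi2: float
    pvalue: float


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple[str, str]
    estimate: float
    se: float
    z: float
    pvalue: float
    pvalue_adjusted: float
    adjustment: str = "mvn"


@dataclass(frozen=True)
class DoseResponseCurve:
    """Logit-linear death-probability curve for one genotype class."""

    genotype: str
    intercept: float
    slope: float
    dose_min: float = 0.0
    dose_max: float = 1.8

    def death_probability(self, dose):
        dose = np.asarray(dose, float)
        if np.any(dose < 0):
            raise ValueError("dose must be >= 0")
        return expit(self.intercept + self.slope * dose)


@dataclass(frozen=True)
class FecundityParams:
    """Per-genotype brood sizes (offspring per brood) with a sweep half-width."""

    b_SRSR: float
    b_SRST: float
    b_STST: float
    half_width: float = 10.0

    def __post_init__(self):
        for token in FEMALE_TOKENS:
            if self.value(token) < 0:
                raise ValueError(f"brood size for {token} must be >= 0")

    def value(self, token: str) -> float:
        return {"SRSR": self.b_SRSR, "SRST": self.b_SRST, "STST": self.b_STST}[token]

    def sweep_range(self, token: str) -> tuple[float, float]:
        b = self.value(token)
        return (b - self.half_width, b + self.half_width)


# ---------------------------------------------------------------------------
# mortality GLM
# ---------------------------------------------------------------------------

def fit_mortality_glm(records: pd.DataFrame, formula: str = "per_class") -> GlmFit:
    """Fit a binomial GLM (logit link) to per-vial (dead, survived) counts."""
    if len(records) == 0:
        raise ValueError("empty mortality table")
    if records["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes to fit the mortality model")
    if formula != "per_class_intercept" and records["dose_ml"].nunique() < 2:
        raise ValueError("doses must not all be identical for a dose-response fit")

    X, names, levels = _mortality_design(records, formula)
    endog = np.column_stack([
        records["n_dead"].to_numpy(float),
        (records["n_exposed"] - records["n_dead"]).to_numpy(float),
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=200)
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    if (not np.all(np.isfinite(params))) or (not np.all(np.isfinite(cov))) \
            or np.any(np.abs(params) > 25):
        raise SeparationError(
            "binomial fit appears separated (diverging coefficients); check for "
            "covariate classes that are all-dead or all-alive"
        )
    return GlmFit(
        formula=formula,
        terms=tuple(names),
        params=params,
        cov=cov,
        llf=float(res.llf),
        df_resid=int(res.df_resid),
        n_obs=len(records),
        design_builder=lambda df, _f=formula, _l=levels: _mortality_design(df, _f, _l)[0],
    )


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

def lrt_drop(full, reduced, assume_nested: bool = False) -> LrtResult:
    """Likelihood-ratio test comparing nested fits (full vs reduced)."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits were not estimated on the same observations")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than full model")
    nested_by_name = set(reduced.terms) <= set(full.terms)
    if not nested_by_name and not assume_nested:
        raise ValueError(
            "reduced terms are not a subset of full terms; pass "
            "assume_nested=True if the models are nested under a different coding"
        )
    stat = 2.0 * (full.llf - reduced.llf)
    if stat < -1e-6:
        warnings.warn(
            f"negative LRT statistic ({stat:.3g}): the 'full' fit has lower "
            "likelihood than the reduced one; refit with better starting values",
            RuntimeWarning,
        )
    stat = max(stat, 0.0)
    dropped = ",".join(sorted(set(full.terms) - set(reduced.terms))) or "(reparametrization)"
    p = 1.0 if df == 0 else float(chi2.sf(stat, df))
    return LrtResult(dropped=dropped, df=df, chi2=float(stat), pvalue=p)


# ---------------------------------------------------------------------------
# fecundity mixed model
# ---------------------------------------------------------------------------

def fit_fecundity_mixed(
    records: pd.DataFrame,
    random_spec: str = "individual_in_vial",
    formula: str = "genotype*dose",
    singular_tol: float = 1e-4,
) -> MixedFit:
    """Fit the Poisson random-intercept model to per-measure offspring counts.

    With ``random_spec='individual_in_vial'`` the individual variance
    component is estimated; if it collapses below ``singular_tol`` the fit
    is flagged singular and automatically refit with a vial-only random
    intercept (the returned fit is the fallback, with ``singular=True``).
    """
    if len(records) == 0:
        raise ValueError("empty fecundity table")
    if records["vial_id"].nunique() < 2:
        raise ValueError("need at least 2 vials")
    y = records["offspring"].to_numpy(float)
    if np.any(y < 1):
        raise ValueError("offspring counts must be >= 1 (zero counts are excluded upstream)")
    if np.all(y == y[0]):
        raise ValueError("all counts identical: variance estimation is degenerate")

    X, names, levels = _fecundity_design(records, formula)
    vial_codes = pd.factorize(records["vial_id"])[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta0 = np.asarray(sm.GLM(y, X, family=sm.families.Poisson()).fit().params)

    if random_spec == "individual_in_vial":
        ind_codes = pd.factorize(records["female_id"])[0]
        model = NestedPoissonMixed(y, X, vial_codes, ind_codes)
        res = model.fit(beta0)
        sigma_v, sigma_id = res.x[-2], res.x[-1]
        if sigma_id < singular_tol:
            fallback = _fit_vial_only(records, y, X, names, vial_codes, beta0, formula, levels)
            return replace(fallback, singular=True)
        cov = _cov_from_hessian(model.loglik, res.x, model.n_fixed)
        return MixedFit(
            formula=formula,
            terms=tuple(names),
            params=res.x[: model.n_fixed],
            cov=cov,
            llf=float(-res.fun),
            df_resid=model.n_obs - model.n_fixed - 2,
            n_obs=model.n_obs,
            random_structure="individual_in_vial",
            variance_components={"vial_sd": float(sigma_v), "individual_sd": float(sigma_id)},
            singular=False,
            converged=bool(res.success),
            design_builder=lambda df, _f=formula, _l=levels: _fecundity_design(df, _f, _l)[0],
        )
    if random_spec == "vial":
        return _fit_vial_only(records, y, X, names, vial_codes, beta0, formula, levels)
    raise ValueError(f"unknown random_spec {random_spec!r}")


def _fit_vial_only(records, y, X, names, vial_codes, beta0, formula, levels) -> MixedFit:
    model = VialOnlyPoissonMixed(y, X, vial_codes)
    res = model.fit(beta0)
    cov = _cov_from_hessian(model.loglik, res.x, model.n_fixed)
    return MixedFit(
        formula=formula,
        terms=tuple(names),
        params=res.x[: model.n_fixed],
        cov=cov,
        llf=float(-res.fun),
        df_resid=model.n_obs - model.n_fixed - 1,
        n_obs=model.n_obs,
        random_structure="vial",
        variance_components={"vial_sd": float(res.x[-1])},
        singular=False,
        converged=bool(res.success),
        design_builder=lambda df, _f=formula, _l=levels: _fecundity_design(df, _f, _l)[0],
    )


def _cov_from_hessian(loglik, x_opt, n_fixed):
    """Fixed-effect covariance from the observed information at the optimum."""
    H = numerical_hessian(lambda x: -loglik(x), x_opt)
    try:
        cov_all = np.linalg.inv(H)
        cov = cov_all[:n_fixed, :n_fixed]
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H[:n_fixed, :n_fixed])
    # symmetrize against finite-difference noise
    return 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# marginal-mean contrasts
# ---------------------------------------------------------------------------

def genotype_contrasts(
    fit: MixedFit,
    dose_values: Sequence[float],
    genotypes: Sequence[str] = FEMALE_TOKENS,
    n_mc: int = 200_000,
    mc_seed: int = 20240901,
) -> list[ContrastResult]:
    """Pairwise genotype differences of link-scale marginal means.

    Marginal means average the linear predictor over ``dose_values``;
    z-tests on all pairwise differences are adjusted with the multivariate-
    normal analogue of the Tukey method, estimated from a deterministic
    Monte-Carlo sample of the joint max-|z| distribution (so adjusted
    p-values are exactly monotone in |z| within one call).
    """
    genotypes = list(genotypes)
    if len(genotypes) < 2:
        raise ValueError("need at least 2 genotype levels")
    doses = np.asarray(list(dose_values), float)
    if doses.size == 0:
        raise ValueError("dose_values must be non-empty")
    # link-scale marginal mean rows, one per genotype
    L = np.stack([
        fit.design_builder(pd.DataFrame({"genotype": g, "dose_ml": doses})).mean(axis=0)
        for g in genotypes
    ])
    means = L @ fit.params
    cov_m = L @ fit.cov @ L.T
    if not np.all(np.isfinite(cov_m)):
        raise ValueError("singular or non-finite covariance for marginal means")
    pairs = list(combinations(range(len(genotypes)), 2))
    C = np.zeros((len(pairs), len(genotypes)))
    for k, (i, j) in enumerate(pairs):
        C[k, i], C[k, j] = 1.0, -1.0
    est = C @ means
    var = np.einsum("ki,ij,kj->k", C, cov_m, C)
    se = np.sqrt(np.maximum(var, 1e-300))
    zstat = est / se
    p_raw = 2.0 * norm.sf(np.abs(zstat))
    # joint null sample of the standardized contrast vector
    rng = np.random.default_rng(mc_seed)
    vals, vecs = np.linalg.eigh(cov_m)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    draws = rng.standard_normal((n_mc, len(genotypes))) @ root.T
    zmax = np.max(np.abs(draws @ C.T) / se, axis=1)
    p_adj = np.array([np.mean(zmax >= abs(z)) for z in zstat])
    p_adj = np.clip(np.maximum(p_adj, p_raw), 0.0, 1.0)
    return [
        ContrastResult(
            pair=(genotypes[i], genotypes[j]),
            estimate=float(est[k]),
            se=float(se[k]),
            z=float(zstat[k]),
            pvalue=float(p_raw[k]),
            pvalue_adjusted=float(p_adj[k]),
        )
        for k, (i, j) in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# parameter export
# ---------------------------------------------------------------------------

def build_dose_response(fit: GlmFit, dose_min: float = 0.0, dose_max: float = 1.8) -> dict[str, DoseResponseCurve]:
    """Per-genotype logit-linear curves that replicate the fit's predictions.

    The curve intercept/slope are the fitted linear predictor at dose 0 and
    its per-ml increment, so ``curve.death_probability(d)`` equals the
    model's predicted mortality for that genotype class at dose ``d``.
    """
    curves = {}
    for g in GENOTYPE_ORDER:
        probe = pd.DataFrame(
            {"genotype": [g.token] * 2, "sex": [g.sex.value] * 2, "dose_ml": [0.0, 1.0]}
        )
        lin = fit.predict_linear(probe)
        curves[g.token] = DoseResponseCurve(
            genotype=g.token,
            intercept=float(lin[0]),
            slope=float(lin[1] - lin[0]),
            dose_min=dose_min,
            dose_max=dose_max,
        )
    return curves


def build_fecundity_params(records: pd.DataFrame, half_width: float = 10.0) -> FecundityParams:
    """Arithmetic mean offspring count per female genotype, with sweep ranges."""
    values = {}
    for token in FEMALE_TOKENS:
        sub = records.loc[records["genotype"] == token, "offspring"]
        if len(sub) == 0:
            raise ValueError(f"no fecundity records for genotype {token}")
        values[token] = float(sub.mean())
    return FecundityParams(
        b_SRSR=values["SRSR"],
        b_SRST=values["SRST"],
        b_STST=values["STST"],
        half_width=half_width,
    )
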