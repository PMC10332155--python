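"""Factorial lethality comparison across exposure set-ups or species.

Lethality proportions from well-level counts are modeled with a binomial
GLM (logit link) in a full factorial of the named factors — concentration
(ordered categorical), developmental stage (adult vs regenerating) and an
exposure-type or species grouping factor.  The significance of each model
term is assessed by dropping it and comparing twice the log-likelihood
difference to a chi-square with the difference in parameters
(likelihood-ratio / analysis-of-deviance).

Complete separation (a cell with deterministic 0% or 100% mortality) leaves
ordinary ML estimates unbounded; it is detected and a Firth (Jeffreys-prior
penalized) fit is supplied as a bias-reduced fallback, with the flag carried
on the result.  A Poisson log-linear contingency parameterization is
available as an alternative via ``family="poisson"``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LethalityFit",
    "factorial_terms",
    "fit_lethality_model",
    "term_drop_anova",
    "simulate_lethality_records",
]


def factorial_terms(factors: Sequence[str]) -> List[str]:
    """All main effects and interactions of a full factorial, as patsy terms."""
    terms = []
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            terms.append(":".join(f"C({f})" for f in combo))
    return terms


def _design(records: pd.DataFrame, terms: Sequence[str]):
    rhs = " + ".join(terms) if terms else "1"
    return patsy.dmatrix(rhs, records, return_type="dataframe")


@dataclass
class LethalityFit:
    """Fitted factorial lethality model."""

    result: object                       # statsmodels GLMResults
    terms: List[str]
    family: str
    separation: bool
    firth_params: Optional[pd.Series] = None

    @property
    def deviance(self) -> float:
        return float(self.result.deviance)

    @property
    def df_resid(self) -> float:
        return float(self.result.df_resid)

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def params(self) -> pd.Series:
        return self.result.params


def _firth_binomial(X: np.ndarray, dead: np.ndarray, total: np.ndarray,
                    max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Firth-penalized binomial-logit coefficients (Jeffreys prior).

    Newton iterations on the penalized score
    U*(b) = X' (y - n*pi + h (1/2 - pi)), h the hat-matrix diagonal.
    Finite even under complete separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = total * pi * (1 - pi)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (dead - total * pi + h * (0.5 - pi))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_lethality_model(
    records: pd.DataFrame,
    factors: Sequence[str] = ("concentration_uM", "worm_type", "exposure_type"),
    terms: Optional[Sequence[str]] = None,
    family: str = "binomial",
) -> LethalityFit:
    """Fit the factorial lethality GLM on well-level (n_dead, n_total) counts.

    ``records`` needs one row per replicate well with columns ``n_dead``,
    ``n_total`` and the factor columns.  ``terms`` defaults to the full
    factorial of ``factors``.  Each factor must have >= 2 observed levels.
    """
    records = records.copy()
    if (records["n_dead"] > records["n_total"]).any() or (
        records["n_dead"] < 0
    ).any():
        raise ValueError("need 0 <= n_dead <= n_total")
    for f in factors:
        if records[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    terms = list(terms) if terms is not None else factorial_terms(factors)
    X = _design(records, terms)
    dead = records["n_dead"].to_numpy(float)
    total = records["n_total"].to_numpy(float)

    if family == "binomial":
        endog = np.column_stack([dead, total - dead])
        model = sm.GLM(endog, X, family=sm.families.Binomial())
    elif family == "poisson":
        model = sm.GLM(dead, X, family=sm.families.Poisson(),
                       exposure=np.maximum(total, 1e-12))
    else:
        raise ValueError(f"unknown family {family!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(maxiter=200)

    separation = False
    firth = None
    if family == "binomial":
        mu = result.fittedvalues
        pinned = (mu < 1e-6) | (mu > 1 - 1e-6)
        separation = bool(pinned.any() and np.abs(result.params).max() > 12)
        if separation:
            warnings.warn(
                "complete separation detected; Firth bias-reduced estimates "
                "supplied in firth_params",
                stacklevel=2,
            )
            beta = _firth_binomial(X.to_numpy(), dead, total)
            firth = pd.Series(beta, index=X.columns)
    return LethalityFit(result, terms, family, separation, firth)


def term_drop_anova(
    records: pd.DataFrame,
    factors: Sequence[str],
    term: str,
    family: str = "binomial",
) -> Tuple[float, int, float]:
    """Likelihood-ratio test for one term of the full factorial model.

    Refits without ``term`` (a patsy term string as produced by
    :func:`factorial_terms`, e.g. ``"C(worm_type)"`` or
    ``"C(concentration_uM):C(worm_type)"``) and returns
    (LRT statistic, df, p) with p from the chi-square.  The drop is
    *hierarchical*: every higher-order interaction containing the term goes
    with it — removing a main effect while keeping its interactions would
    leave the design span unchanged and the test vacuous.  The reduced model
    is nested by construction; an unknown term raises.
    """
    full_terms = factorial_terms(factors)
    if term not in full_terms:
        raise ValueError(
            f"term {term!r} is not part of the full factorial {full_terms}"
        )

    def term_factors(t: str) -> frozenset:
        return frozenset(t.split(":"))

    dropped = term_factors(term)
    reduced_terms = [
        t for t in full_terms if not dropped <= term_factors(t)
    ]
    full = fit_lethality_model(records, factors, full_terms, family)
    reduced = fit_lethality_model(records, factors, reduced_terms, family)
    lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = int(round(full.result.df_model - reduced.result.df_model))
    if df == 0:
        return (0.0, 0, 1.0) if lrt < 1e-8 else (lrt, 0, 0.0)
    p = float(stats.chi2.sf(lrt, df))
    return float(lrt), df, p


def simulate_lethality_records(
    concentrations: Sequence[float] = (31.6, 100.0, 316.0),
    worm_types: Sequence[str] = ("adult", "regenerating"),
    exposure_types: Sequence[str] = ("96well", "bulk"),
    n_wells: int = 3,
    n_per_well: int = 6,
    base_logit: float = -2.0,
    conc_slope: float = 1.0,
    worm_effect: float = 0.0,
    exposure_effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic well-level lethality counts on a known logit-linear truth.

    Death probability: logit p = base + slope * z(log10 conc)
    + worm_effect * 1[regenerating] + exposure_effect * 1[bulk].  Used for
    calibration and power checks of the factorial GLM.
    """
    rng = np.random.default_rng(seed)
    logc = np.log10(np.asarray(concentrations, float))
    z = (logc - logc.mean()) / (logc.std() if logc.std() > 0 else 1.0)
    rows = []
    for (ci, conc), worm, expo in itertools.product(
        enumerate(concentrations), worm_types, exposure_types
    ):
        eta = (
            base_logit
            + conc_slope * z[ci]
            + worm_effect * (worm == worm_types[-1])
            + exposure_effect * (expo == exposure_types[-1])
        )
        p = 1.0 / (1.0 + np.exp(-eta))
        for well in range(n_wells):
            rows.append(
                {
                    "concentration_uM": conc,
                    "worm_type": worm,
                    "exposure_type": expo,
                    "well": well,
                    "n_total": n_per_well,
                    "n_dead": int(rng.binomial(n_per_well, p)),
                }
            )
    return pd.DataFrame(rows)
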