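"""Logistic growth-mortality models with information-theoretic selection.

Survival (alive = 1, dead = 0) is modelled by fixed-effects logistic
regression on tree size, age, competition and windowed BAI metrics:

    logit Pr(Y_i = 1) = a0 + sum_k b_k x_ik

Candidate models are every non-empty predictor subset up to ``max_terms``
variables. Ranking uses AIC (-2 logL + 2k, k including the intercept),
the AIC difference to the best model, and Akaike weights
W_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2); discrimination is the
rank-based AUC (ties get half credit) and fit quality the McFadden
pseudo-R^2 = 1 - logL_model / logL_null. Mortality probability, where
reported, is 1 - fitted survival probability.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class FitError(ValueError):
    """The logistic fit is impossible for this input."""


@dataclass
class ModelFitResult:
    terms: tuple[str, ...]
    params: dict[str, float]
    bse: dict[str, float]
    log_likelihood: float
    aic: float
    auc: float
    mcfadden_r2: float
    converged: bool
    separation: bool
    n: int
    delta_aic: float = np.nan
    akaike_weight: float = np.nan

    @property
    def label(self) -> str:
        return " + ".join(self.terms) if self.terms else "(intercept only)"


def auc(response, fitted_prob) -> float:
    """Rank-based AUC: P(score of a survivor > score of a dead tree).

    Equivalent to the Mann-Whitney U statistic scaled to [0, 1]; tied
    scores receive half credit.
    """
    y = np.asarray(response, dtype=int)
    s = np.asarray(fitted_prob, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise FitError("AUC undefined with a single response class")
    ranks = stats.rankdata(s)
    u = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _null_loglik(y: np.ndarray) -> float:
    p = float(np.mean(y))
    if p in (0.0, 1.0):
        return 0.0
    n1 = int(np.sum(y))
    n0 = y.size - n1
    return n1 * np.log(p) + n0 * np.log(1 - p)


def fit_logistic(
    response, predictors: pd.DataFrame, min_trees: int = 10
) -> ModelFitResult:
    """Maximum-likelihood logistic fit of survival on the given predictors.

    ``response`` is 1 for living, 0 for dead trees. Complete or
    quasi-complete separation is flagged (detected as perfect in-sample
    discrimination); non-convergent fits are flagged and later excluded
    from model ranking.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    if y.size < min_trees:
        raise FitError(f"need >= {min_trees} trees, got {y.size}")
    if y.size != len(X):
        raise FitError("response/predictor length mismatch")
    classes = np.unique(y)
    if not np.array_equal(np.union1d(classes, [0.0, 1.0]), [0.0, 1.0]):
        raise FitError("response must be coded 0/1")
    if classes.size < 2:
        raise FitError("both classes must be present")
    if not np.all(np.isfinite(X.to_numpy())) or not np.all(np.isfinite(y)):
        raise FitError("predictors and response must be finite")

    exog = sm.add_constant(X, has_constant="add")
    converged = True
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            params = res.params
            bse = res.bse
            llf = float(res.llf)
            fitted = np.asarray(res.predict(exog))
        except Exception:  # perfect separation can abort the Newton solver
            converged = False
            separation = True
            params = pd.Series(np.nan, index=exog.columns)
            bse = pd.Series(np.nan, index=exog.columns)
            llf = np.nan
            fitted = np.full(y.size, np.nan)

    if np.all(np.isfinite(fitted)):
        auc_value = auc(y, fitted)
        if auc_value == 1.0:  # fitted score perfectly separates the classes
            separation = True
    else:
        auc_value = np.nan

    k = exog.shape[1]
    llnull = _null_loglik(y)
    return ModelFitResult(
        terms=tuple(X.columns),
        params={c: float(params[c]) for c in exog.columns},
        bse={c: float(bse[c]) for c in exog.columns},
        log_likelihood=llf,
        aic=float(-2 * llf + 2 * k) if np.isfinite(llf) else np.nan,
        auc=auc_value,
        mcfadden_r2=float(1 - llf / llnull) if llnull != 0 and np.isfinite(llf) else np.nan,
        converged=converged,
        separation=separation,
        n=int(y.size),
    )


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights over a set of AIC values (sum to 1)."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - np.nanmin(aics)
    raw = np.exp(-delta / 2.0)
    return raw / np.nansum(raw)


def enumerate_and_rank(
    data: pd.DataFrame,
    response_col: str,
    predictors: list[str],
    max_terms: int = 4,
    collinearity_bar: float | None = None,
    min_trees: int = 10,
) -> list[ModelFitResult]:
    """Fit every predictor subset up to ``max_terms`` and rank by support.

    Non-convergent fits are excluded from the ranking; separated fits are
    kept but flagged. When ``collinearity_bar`` is set, predictor pairs
    with |r| above it may not co-occur in a model (a warning is logged for
    each barred pair).
    """
    if not predictors:
        raise FitError("empty candidate pool")
    missing = [p for p in predictors if p not in data.columns]
    if missing:
        raise FitError(f"predictors absent from data: {missing}")
    y = data[response_col].to_numpy()

    barred: set[frozenset[str]] = set()
    if collinearity_bar is not None:
        corr = data[predictors].corr().abs()
        for a, b in itertools.combinations(predictors, 2):
            if corr.loc[a, b] > collinearity_bar:
                barred.add(frozenset((a, b)))
                warnings.warn(
                    f"collinear pair barred from co-occurring: {a}, {b} "
                    f"(|r| = {corr.loc[a, b]:.2f})",
                    stacklevel=2,
                )

    results: list[ModelFitResult] = []
    max_terms = min(max_terms, len(predictors))
    for size in range(1, max_terms + 1):
        for combo in itertools.combinations(predictors, size):
            if any(frozenset(p) <= set(combo) for p in barred):
                continue
            fit = fit_logistic(y, data[list(combo)], min_trees=min_trees)
            if fit.converged:
                results.append(fit)
    if not results:
        raise FitError("no candidate model converged")

    aics = np.array([r.aic for r in results])
    weights = akaike_weights(aics)
    best = float(np.min(aics))
    for r, w in zip(results, weights):
        r.delta_aic = float(r.aic - best)
        r.akaike_weight = float(w)
    results.sort(key=lambda r: (-r.akaike_weight, len(r.terms)))
    return results


def ranking_table(results: list[ModelFitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.label,
                "n_terms": len(r.terms),
                "aic": r.aic,
                "delta_aic": r.delta_aic,
                "akaike_weight": r.akaike_weight,
                "auc": r.auc,
                "mcfadden_r2": r.mcfadden_r2,
                "separation": r.separation,
            }
            for r in results
        ]
    )


def top_table(results: list[ModelFitResult], k: int = 3) -> pd.DataFrame:
    """Top-k model report: weights for all, AUC/pseudo-R^2 for the best."""
    rows = []
    for i, r in enumerate(results[:k]):
        rows.append(
            {
                "model": r.label,
                "delta_aic": r.delta_aic,
                "akaike_weight": r.akaike_weight,
                "auc": r.auc if i == 0 else np.nan,
                "mcfadden_r2": r.mcfadden_r2 if i == 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
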