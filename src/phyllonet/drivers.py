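"""Attribution of community and network variation to host, space, climate.

Two complementary engines mirror the study's Table 1 / Table 2 logic:

* :func:`rf_importance` — a regression random forest per response (a
  network metric per plant), with permutation-increase-in-MSE predictor
  importance and a response-permutation significance test for each
  predictor.
* :func:`multispecies_glm` — per-OTU negative-binomial regressions
  whose per-term likelihood-ratio statistics are summed over OTUs into
  a community-level statistic TS, tested by permuting response rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .community import OtuTable

__all__ = ["ImportanceResult", "MultispeciesGlmResult", "rf_importance", "multispecies_glm"]


@dataclass
class ImportanceResult:
    """Per-predictor permutation importance (increase in MSE) and
    response-permutation p-value."""

    table: pd.DataFrame  # index predictor; columns importance, p
    n_perm: int


@dataclass
class MultispeciesGlmResult:
    """Per-term deviance-sum statistic TS (sum over OTUs of
    likelihood-ratio statistics) and permutation p-value."""

    table: pd.DataFrame  # index term; columns TS, p
    n_perm: int


# ---------------------------------------------------------------------------
# random forest importance
# ---------------------------------------------------------------------------


def _forest_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator,
    n_repeats: int = 10,
) -> np.ndarray:
    seed_fit, seed_perm = rng.integers(2**31, size=2)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=1.0 / 3, random_state=int(seed_fit)
    ).fit(X, y)
    imp = permutation_importance(
        forest,
        X,
        y,
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats,
        random_state=int(seed_perm),
    )
    return imp.importances_mean


def rf_importance(
    X: pd.DataFrame,
    y: Sequence[float],
    n_trees: int = 500,
    n_perm: int = 100,
    seed: int | None = None,
) -> ImportanceResult:
    """Random-forest predictor importance with permutation significance.

    A regression forest (mtry = p/3) is fitted to the response;
    importance is the mean increase in squared error when a predictor's
    values are permuted. Significance per predictor: the forest is
    refitted on ``n_perm`` response-permuted datasets and
    ``p = (1 + #{null importance >= observed}) / (n_perm + 1)``.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    if X.shape[0] != y.size:
        raise ValueError("predictor rows must align with the response")
    rng = np.random.default_rng(seed)
    x_arr = X.to_numpy(float)
    observed = _forest_importance(x_arr, y, n_trees, rng)
    exceed = np.zeros(X.shape[1])
    for _ in range(n_perm):
        y_perm = y[rng.permutation(y.size)]
        null = _forest_importance(x_arr, y_perm, n_trees, rng, n_repeats=5)
        exceed += null >= observed
    pvals = (1 + exceed) / (1 + n_perm)
    table = pd.DataFrame(
        {"importance": observed, "p": pvals}, index=list(X.columns)
    ).sort_values("importance", ascending=False)
    return ImportanceResult(table, n_perm)


# ---------------------------------------------------------------------------
# multispecies GLM
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """Maximum log-likelihood of a negative-binomial (NB2) regression
    with log link; dispersion by ML (statsmodels), Poisson fallback when
    the NB optimizer fails."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.NegativeBinomial(y, X).fit(disp=0, method="bfgs", maxiter=200)
            if np.isfinite(res.llf):
                return float(res.llf)
        except Exception:
            pass
        try:
            res = sm.NegativeBinomial(y, X).fit(disp=0, method="nm", maxiter=2000)
            if np.isfinite(res.llf):
                return float(res.llf)
        except Exception:
            pass
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        return float(res.llf)


def _as_matrix(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def multispecies_glm(
    table: OtuTable | pd.DataFrame,
    terms: Mapping[str, np.ndarray],
    n_perm: int = 999,
    seed: int | None = None,
) -> MultispeciesGlmResult:
    """Community-level GLM test summing per-OTU likelihood ratios.

    For each OTU a negative-binomial regression with log link is fitted
    under the sequential designs implied by the ordered ``terms``; the
    term statistic ``TS`` is the sum over OTUs of the likelihood-ratio
    statistics between the designs with and without the term. p-values
    permute the rows of the response matrix (all OTUs jointly).
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
        raise ValueError("responses must be nonnegative integer counts")
    arr = arr.astype(int)
    n = arr.shape[0]
    designs = [np.ones((n, 1))]
    names = []
    for name, x in terms.items():
        x = _as_matrix(x)
        if x.shape[0] != n:
            raise ValueError(f"term {name!r} is not aligned with the count table")
        designs.append(np.hstack([designs[-1], x]))
        names.append(name)

    # the intercept-only log-likelihood is invariant under row permutation
    ll0 = np.array([_nb_loglik(arr[:, j], designs[0]) for j in range(arr.shape[1])])

    def ts_all(rows: np.ndarray) -> np.ndarray:
        y_mat = arr[rows]
        ll = np.empty((len(designs), arr.shape[1]))
        ll[0] = ll0
        for d, X in enumerate(designs[1:], start=1):
            for j in range(arr.shape[1]):
                ll[d, j] = _nb_loglik(y_mat[:, j], X)
        lr = np.maximum(0.0, 2.0 * np.diff(ll, axis=0))
        return lr.sum(axis=1)

    ts_obs = ts_all(np.arange(n))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += ts_all(perm) >= ts_obs
    pvals = (1 + exceed) / (1 + n_perm)
    tbl = pd.DataFrame({"TS": ts_obs, "p": pvals}, index=names)
    return MultispeciesGlmResult(tbl, n_perm)
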