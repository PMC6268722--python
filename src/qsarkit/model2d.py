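"""2D-QSAR: descriptor filtering, beam forward selection, MLR with LOO.

The fitting procedure mirrors the classical multistep MLR workflow:

1. drop descriptors that are zero for more than 20% of the compounds,
2. prune pairs with |Pearson intercorrelation| > 0.8 (keeping, of each
   offending pair, the member better correlated with the response),
3. modified forward selection — a beam search that keeps several best
   subsets at each step and scores candidates by leave-one-out q², with a
   Topliss-style cap on the descriptor count,
4. final multiple linear regression with F-/t-test p-values, fitted R²,
   SE, and LOO q²/SE.

All of this is wrapped as the scikit-learn estimator
:class:`ForwardSelectionMLR`; the module functions expose the individual
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .pls import ols_loo_residuals, press_q2

__all__ = ["MLRModel", "filter_sparse", "filter_correlated", "forward_select",
           "fit_mlr", "loo_q2", "ForwardSelectionMLR"]


@dataclass
class MLRModel:
    descriptors: list
    coefficients: np.ndarray
    intercept: float
    r2: float
    se_train: float
    q2: float
    se_loo: float
    model_pvalue: float
    descriptor_pvalues: dict = field(default_factory=dict)

    @property
    def max_descriptor_pvalue(self) -> float:
        return max(self.descriptor_pvalues.values()) if self.descriptor_pvalues else np.nan

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (np.asarray(X[self.descriptors], dtype=float) @ self.coefficients
                + self.intercept)


def filter_sparse(X: pd.DataFrame, zero_fraction: float = 0.20
                  ) -> tuple[pd.DataFrame, list]:
    """Remove columns with more than ``zero_fraction`` exact zeros.

    The rule is strict: a column with exactly 20% zeros survives at the
    default threshold.  Returns the reduced matrix and the removed names.
    """
    if X.shape[1] == 0:
        raise ValueError("empty descriptor matrix")
    zero_frac = (X == 0).mean(axis=0)
    removed = X.columns[zero_frac > zero_fraction].tolist()
    kept = X.drop(columns=removed)
    if kept.shape[1] == 0:
        raise ValueError(
            f"all {X.shape[1]} columns exceed the {zero_fraction:.0%} zero "
            "fraction; raise the threshold")
    return kept, removed


def filter_correlated(X: pd.DataFrame, y, r_threshold: float = 0.8
                      ) -> tuple[pd.DataFrame, list]:
    """Greedy intercorrelation pruning.

    Constant columns (undefined correlation) are removed first.  Then,
    while any pair has |Pearson r| > threshold, the most correlated pair is
    resolved by dropping its member with the weaker |correlation to y|
    (tie → the later column).  No surviving pair exceeds the threshold.
    """
    if X.shape[1] < 2:
        return X, []
    y = np.asarray(y, dtype=float)
    removed = []
    const = X.columns[X.std(axis=0, ddof=0) == 0].tolist()
    removed += const
    Xw = X.drop(columns=const)
    cols = list(Xw.columns)
    if len(cols) < 2:
        return Xw, removed
    M = np.asarray(Xw, dtype=float)
    C = np.corrcoef(M, rowvar=False)
    ry = np.abs(np.array([np.corrcoef(M[:, j], y)[0, 1] for j in range(M.shape[1])]))
    alive = np.ones(len(cols), dtype=bool)
    while True:
        A = np.abs(C.copy())
        np.fill_diagonal(A, 0)
        A[~alive, :] = 0
        A[:, ~alive] = 0
        i, j = np.unravel_index(np.argmax(A), A.shape)
        if A[i, j] <= r_threshold:
            break
        if ry[i] > ry[j]:
            drop = j
        elif ry[j] > ry[i]:
            drop = i
        else:
            drop = max(i, j)
        alive[drop] = False
        removed.append(cols[drop])
    kept = [c for c, a in zip(cols, alive) if a]
    return Xw[kept], removed


def loo_q2(X, y) -> tuple[float, float]:
    """LOO q² and SE for least squares with intercept (hat-matrix form)."""
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    loo_resid = ols_loo_residuals(np.asarray(X, dtype=float), y)
    return press_q2(y, y - loo_resid)


def forward_select(X: pd.DataFrame, y, max_descriptors: int,
                   n_subsets_kept: int = 3, seed: int | None = None,
                   stop: str = "plateau") -> list[tuple[tuple, float]]:
    """Beam forward selection scored by LOO q².

    Each of the kept subsets is extended by every remaining descriptor; the
    ``n_subsets_kept`` best extensions (by q²) survive to the next round.
    ``stop="plateau"`` halts when no extension improves the best q²;
    ``stop="fixed"`` always grows to ``max_descriptors``.  Returns the kept
    subsets with their q², best first.  ``seed`` only breaks exact score
    ties reproducibly.
    """
    if max_descriptors < 1:
        raise ValueError("max_descriptors must be at least 1")
    if stop not in ("plateau", "fixed"):
        raise ValueError("stop must be 'plateau' or 'fixed'")
    n = len(y)
    cap = min(max_descriptors, max(1, n // 5))
    cols = list(X.columns)
    y = np.asarray(y, dtype=float).ravel()
    M = {c: np.asarray(X[c], dtype=float) for c in cols}

    beam: list[tuple[tuple, float]] = [((), -np.inf)]
    best_overall: list[tuple[tuple, float]] = []
    for _step in range(cap):
        candidates: dict[tuple, float] = {}
        for subset, _q in beam:
            for c in cols:
                if c in subset:
                    continue
                new = tuple(sorted(subset + (c,)))
                if new in candidates:
                    continue
                Xs = np.column_stack([M[cc] for cc in new])
                try:
                    q2, _ = loo_q2(Xs, y)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                candidates[new] = q2
        if not candidates:
            break
        ranked = sorted(candidates.items(), key=lambda kv: -kv[1])
        new_beam = ranked[:n_subsets_kept]
        prev_best = beam[0][1]
        beam = new_beam
        best_overall = _merge_best(best_overall, new_beam, n_subsets_kept)
        if stop == "plateau" and new_beam[0][1] <= prev_best:
            break
    if not best_overall:
        raise ValueError("forward selection found no usable descriptor subset")
    # fixed mode returns the final (full-size) beam; plateau mode the best
    # subsets seen at any size
    return beam if stop == "fixed" else best_overall


def _merge_best(acc, new, k):
    pool = {s: q for s, q in acc}
    for s, q in new:
        pool[s] = max(q, pool.get(s, -np.inf))
    return sorted(pool.items(), key=lambda kv: -kv[1])[:k]


def fit_mlr(X: pd.DataFrame, y) -> MLRModel:
    """Ordinary least squares with the full training-statistics block."""
    names = list(X.columns)
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} descriptors")
    A = sm.add_constant(Xa, has_constant="add")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j in range(p):
            others = np.delete(Xa, j, axis=1)
            B = sm.add_constant(others, has_constant="add")
            if np.linalg.matrix_rank(B) == np.linalg.matrix_rank(A):
                bad.append(names[j])
        raise ValueError(f"rank-deficient descriptor matrix; collinear "
                         f"columns include {bad or names}")
    res = sm.OLS(y, A).fit()
    rss = float(np.sum(res.resid ** 2))
    q2, se_loo = loo_q2(Xa, y)
    return MLRModel(
        descriptors=names,
        coefficients=np.asarray(res.params[1:]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        se_train=float(np.sqrt(rss / (n - p - 1))),
        q2=q2,
        se_loo=se_loo,
        model_pvalue=float(res.f_pvalue),
        descriptor_pvalues=dict(zip(names, np.asarray(res.pvalues[1:]))),
    )


class ForwardSelectionMLR(RegressorMixin, BaseEstimator):
    """Filter → prune → beam-select → MLR, as one scikit-learn regressor.

    Parameters
    ----------
    zero_fraction : sparse-column threshold (default 0.20, strict ``>``).
    r_threshold : intercorrelation limit (default 0.8).
    max_descriptors : beam-search depth cap; additionally capped at n/5.
    n_subsets_kept : beam width (several best subsets are retained).
    stop : "plateau" (stop when LOO q² stops improving) or "fixed".

    Fitted attributes
    -----------------
    model_ : the final :class:`MLRModel`.
    selected_ : chosen descriptor names.
    candidates_ : ranked (subset, q²) list from the beam search.
    stage_log_ : per-stage column counts and removals.
    """

    def __init__(self, zero_fraction: float = 0.20, r_threshold: float = 0.8,
                 max_descriptors: int = 10, n_subsets_kept: int = 3,
                 stop: str = "plateau", seed: int | None = None):
        self.zero_fraction = zero_fraction
        self.r_threshold = r_threshold
        self.max_descriptors = max_descriptors
        self.n_subsets_kept = n_subsets_kept
        self.stop = stop
        self.seed = seed

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float).ravel()
        log = {"n_in": X.shape[1]}
        X1, removed_sparse = filter_sparse(X, self.zero_fraction)
        log["sparse_removed"] = removed_sparse
        X2, removed_corr = filter_correlated(X1, y, self.r_threshold)
        log["correlated_removed"] = removed_corr
        log["n_after_filters"] = X2.shape[1]
        subsets = forward_select(X2, y, self.max_descriptors,
                                 self.n_subsets_kept, seed=self.seed,
                                 stop=self.stop)
        self.candidates_ = subsets
        self.selected_ = list(subsets[0][0])
        self.model_ = fit_mlr(X2[self.selected_], y)
        log["n_selected"] = len(self.selected_)
        self.stage_log_ = log
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame):
        check_is_fitted(self, "model_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=self.feature_names_in_)
        return self.model_.predict(X)
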