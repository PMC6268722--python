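"""Model assessment: δ confidence bands, rm²-family metrics, Y-scrambling.

The central diagnostic is the δ band.  In predicted-vs-observed space the
ideal model lies on y = x; δ is the half-width of the band y = x ± δ chosen
so that a stated fraction (default 95%) of the *training* compounds fall
inside it.  A model generalizes when roughly the same fraction of an
external set falls inside the same band; an overfit model shrinks its
training residuals, producing a narrow band that the external set escapes.

The rm² family (Roy and co-workers) penalizes divergence between the
ordinary squared correlation r² of observed vs predicted values and the
squared correlation constrained through the origin:

    rm²  = r² · (1 − sqrt(r² − r0²))      (observed regressed on predicted)
    rm′² = r² · (1 − sqrt(r² − r0′²))     (axes exchanged)
    r̄m²  = (rm² + rm′²) / 2,   Δrm² = |rm² − rm′²|

Accepted quality thresholds: r̄m² > 0.5 and Δrm² < 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_LEVEL = 0.95
#: reporting grid for δ; printed values conventionally lie on steps of 0.05
DELTA_GRID = 0.05
RM_BAR_THRESHOLD = 0.5
RM_DELTA_THRESHOLD = 0.2


# --------------------------------------------------------------------------
# δ band

def compute_delta(y_obs, y_pred, level: float = DEFAULT_LEVEL,
                  grid: float | None = None) -> float:
    """Smallest δ with |y_obs − y_pred| ≤ δ for at least ceil(level·n) points.

    This is the ceil(level·n)-th order statistic of the absolute residuals.
    With ``grid`` set (e.g. 0.05) the result is rounded *up* to that grid,
    matching how δ is conventionally reported; the default returns the raw
    order statistic.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape:
        raise ValueError("observed and predicted vectors differ in length")
    n = len(y_obs)
    if n < 5:
        raise ValueError("need at least 5 points to place a confidence band")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    resid = np.sort(np.abs(y_obs - y_pred))
    k = int(np.ceil(level * n))
    delta = float(resid[k - 1])
    if grid:
        delta = float(np.ceil(delta / grid - 1e-12) * grid)
    return delta


def band_coverage(y_obs, y_pred, delta: float) -> float:
    """Fraction of points with |y_obs − y_pred| ≤ δ."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape:
        raise ValueError("observed and predicted vectors differ in length")
    return float(np.mean(np.abs(y_obs - y_pred) <= delta + 1e-12))


@dataclass
class BandAssessment:
    """δ-band assessment of a model against an external set.

    ``sign`` summarizes whether the external coverage is consistent with the
    confidence level: "+" (coverage ≥ level − tolerance), "−" (coverage <
    level − 2·tolerance), "+/−" in between.  ``delta`` is the raw order
    statistic; ``delta_reported`` is rounded up to the 0.05 reporting grid.
    """

    delta: float
    delta_reported: float
    level: float
    train_coverage: float
    external_coverage: float
    sign: str
    prediction_range: tuple[float, float]


def assess(train_pairs, test_pairs, level: float = DEFAULT_LEVEL,
           tolerance: float = 0.10) -> BandAssessment:
    """Full δ-band assessment: δ from training, sign from the external set.

    Parameters are (observed, predicted) pairs for the training and external
    sets.  The prediction range is the span of the training predictions.
    """
    y_tr, p_tr = (np.asarray(a, dtype=float).ravel() for a in train_pairs)
    y_te, p_te = (np.asarray(a, dtype=float).ravel() for a in test_pairs)
    if len(y_te) == 0 or len(y_tr) == 0:
        raise ValueError("training and external sets must be non-empty")
    delta = compute_delta(y_tr, p_tr, level=level)
    cov_tr = band_coverage(y_tr, p_tr, delta)
    cov_te = band_coverage(y_te, p_te, delta)
    if cov_te >= level - tolerance:
        sign = "+"
    elif cov_te < level - 2 * tolerance:
        sign = "-"
    else:
        sign = "+/-"
    return BandAssessment(
        delta=delta,
        delta_reported=float(np.ceil(delta / DELTA_GRID - 1e-12) * DELTA_GRID),
        level=level,
        train_coverage=cov_tr,
        external_coverage=cov_te,
        sign=sign,
        prediction_range=(float(p_tr.min()), float(p_tr.max())),
    )


# --------------------------------------------------------------------------
# rm² family

def _r2_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _r02(y: np.ndarray, x: np.ndarray) -> float:
    """Squared correlation of the least-squares line through the origin.

    Regress y on x without intercept (slope k = Σxy/Σx²) and measure
    1 − Σ(y − kx)² / Σ(y − ȳ)², the through-origin analogue of R².
    """
    k = float(x @ y) / float(x @ x)
    ss_res = float(np.sum((y - k * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class RmMetrics:
    r2: float
    r02: float
    r02_prime: float
    rm2: float
    rm2_prime: float
    rm2_bar: float
    rm2_delta: float
    good: bool = field(init=False)

    def __post_init__(self):
        self.good = (self.rm2_bar > RM_BAR_THRESHOLD
                     and self.rm2_delta < RM_DELTA_THRESHOLD)


def rm_metrics(y_obs, y_pred) -> RmMetrics:
    """rm², rm′², r̄m² and Δrm² of an (observed, predicted) pair."""
    y = np.asarray(y_obs, dtype=float).ravel()
    x = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != x.shape:
        raise ValueError("observed and predicted vectors differ in length")
    if len(y) < 3:
        raise ValueError("need at least 3 points")
    r2 = _r2_pearson(y, x)
    r02 = _r02(y, x)          # observed on predicted, through origin
    r02p = _r02(x, y)         # predicted on observed, through origin
    rm2 = r2 * (1.0 - np.sqrt(max(r2 - r02, 0.0)))
    rm2p = r2 * (1.0 - np.sqrt(max(r2 - r02p, 0.0)))
    bar, delta = combine_rm(rm2, rm2p)
    return RmMetrics(r2=r2, r02=r02, r02_prime=r02p, rm2=float(rm2),
                     rm2_prime=float(rm2p), rm2_bar=bar, rm2_delta=delta)


def combine_rm(rm2: float, rm2_prime: float) -> tuple[float, float]:
    """(r̄m², Δrm²) from an (rm², rm′²) pair: the mean and |difference|."""
    return (rm2 + rm2_prime) / 2.0, abs(rm2 - rm2_prime)


# --------------------------------------------------------------------------
# external predictivity

def predictive_r2(y_obs_test, y_pred_test) -> tuple[float, float]:
    """External-set r_t² (squared Pearson correlation) and Q²F1.

    The Pearson form is insensitive to scale and shift of the predictions,
    so the predicted-variance form Q²F1 = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² is reported
    alongside it; a model can score r_t² ≈ 1 with useless predictions (e.g.
    anti-correlated), which Q²F1 exposes.
    """
    y = np.asarray(y_obs_test, dtype=float).ravel()
    p = np.asarray(y_pred_test, dtype=float).ravel()
    if len(y) < 3:
        raise ValueError("need at least 3 points")
    r2 = _r2_pearson(y, p)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2f1 = 1.0 - float(np.sum((y - p) ** 2)) / ss_tot
    return r2, q2f1


# --------------------------------------------------------------------------
# Y-scrambling

def y_scramble(X, y, n_permutations: int, model_fitter, seed: int = 0):
    """Chance-correlation reference distribution by response permutation.

    ``model_fitter(X, y_perm)`` must return a ``(R², q²)`` pair for a full
    refit of the modeling pipeline on the permuted response.  The identity
    permutation is excluded (it would leak the unscrambled model into the
    null distribution).  Returns a dict with the raw draws and the mean and
    95th percentile of each statistic.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be at least 10")
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    r2s, q2s = [], []
    for _ in range(n_permutations):
        perm = rng.permutation(len(y))
        while np.all(perm == np.arange(len(y))):
            perm = rng.permutation(len(y))
        r2, q2 = model_fitter(X, y[perm])
        r2s.append(r2)
        q2s.append(q2)
    r2s, q2s = np.asarray(r2s), np.asarray(q2s)
    return {
        "r2": r2s, "q2": q2s,
        "r2_mean": float(r2s.mean()), "q2_mean": float(q2s.mean()),
        "r2_p95": float(np.percentile(r2s, 95)),
        "q2_p95": float(np.percentile(q2s, 95)),
    }


def plot_band(y_obs_train, y_pred_train, y_obs_test, y_pred_test,
              assessment: BandAssessment, ax=None):
    """Observed-vs-predicted scatter with the y = x ± δ confidence band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lo = min(np.min(y_pred_train), np.min(y_obs_train)) - 0.5
    hi = max(np.max(y_pred_train), np.max(y_obs_train)) + 0.5
    xs = np.array([lo, hi])
    ax.plot(xs, xs, "k-", lw=0.8)
    d = assessment.delta
    ax.plot(xs, xs + d, "k--", lw=0.8)
    ax.plot(xs, xs - d, "k--", lw=0.8)
    ax.scatter(y_pred_train, y_obs_train, c="tab:blue", s=18, label="training")
    ax.scatter(y_pred_test, y_obs_test, c="tab:red", marker="^", s=22,
               label="external")
    ax.set_xlabel("predicted")
    ax.set_ylabel("observed")
    ax.legend()
    return ax
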