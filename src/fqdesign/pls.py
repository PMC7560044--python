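"""Partial-least-squares QSAR fitting and cross-validation statistics.

The activity (log f_b, the base-10 log of the percent of drug bound to
plasma protein) is regressed on the filtered, block-scaled similarity-index
descriptor matrix with PLS. Model quality is reported as the leave-one-out
cross-validated determination coefficient q^2, the non-cross-validated r^2,
the standard error of estimate SEE and the F statistic; the relative
importance of the five fields is summarized as |coefficient x column-sd|
mass fractions.

The PLS core is the deterministic NIPALS implementation of scikit-learn
(no randomness; bit-reproducible predictions for identical inputs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls",
    "predict",
    "loo_q2",
    "select_components",
    "model_stats",
    "field_contributions",
]


@dataclass
class PLSModel:
    """Fitted PLS regression with training statistics.

    ``coef``/``intercept`` act on the descriptor matrix exactly as passed to
    :func:`fit_pls` (i.e. after any column filtering and block scaling):
    ``y_hat = X @ coef + intercept``.
    """

    n_components: int
    coef: np.ndarray
    intercept: float
    q2: float | None = None
    r2: float | None = None
    see: float | None = None
    f_stat: float | None = None
    field_contributions: dict[str, float] | None = None
    metadata: dict | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.coef + self.intercept

    def to_json(self) -> str:
        d = asdict(self)
        d["coef"] = self.coef.tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        d = json.loads(text)
        d["coef"] = np.asarray(d["coef"], dtype=float)
        return cls(**d)


@dataclass
class CVResult:
    """q^2 per candidate component count; chosen n maximizes q^2 (ties -> smaller n)."""

    q2_by_n: dict[int, float]
    chosen_n: int


def _check_xy(X: np.ndarray, y: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X rows must match len(y)")
    if n < 1:
        raise ValueError("need at least one component")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to fit")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n > rank:
        raise ValueError(f"n_components={n} exceeds centered-X rank {rank}")
    return X, y


def fit_pls(X: np.ndarray, y: np.ndarray, n: int) -> PLSModel:
    """Deterministic NIPALS PLS fit of y on X with ``n`` latent components."""
    X, y = _check_xy(X, y, n)
    pls = PLSRegression(n_components=n, scale=False, max_iter=1000, tol=1e-12)
    with warnings.catch_warnings():
        # expected on exact fits: later components see a constant y residual
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls.fit(X, y)
    coef = pls.coef_.ravel()
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return PLSModel(n_components=n, coef=coef, intercept=intercept)


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def loo_q2(X: np.ndarray, y: np.ndarray, n: int) -> float:
    """Leave-one-out cross-validated determination coefficient.

    q2 = 1 - sum (y_i - yhat_(-i))^2 / sum (y_i - ybar)^2  with ybar the mean
    of all training responses; may be negative for models worse than the mean.
    """
    X, y = _check_xy(X, y, n)
    if y.size < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    press = 0.0
    idx = np.arange(y.size)
    for i in idx:
        keep = idx != i
        m = fit_pls(X[keep], y[keep], n)
        press += float((y[i] - m.predict(X[i][None, :])[0]) ** 2)
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss


def select_components(X: np.ndarray, y: np.ndarray, max_n: int) -> CVResult:
    """Scan 1..max_n components by LOO q^2; smallest n wins ties."""
    X, y = _check_xy(X, y, max_n)
    q2s: dict[int, float] = {}
    for n in range(1, max_n + 1):
        q2s[n] = loo_q2(X, y, n)
    best = max(q2s, key=lambda n: (q2s[n], -n))
    return CVResult(q2_by_n=q2s, chosen_n=best)


def model_stats(y: np.ndarray, y_hat: np.ndarray, n: int) -> dict[str, float]:
    """Non-cross-validated fit statistics r^2, SEE and F.

    r^2 = 1 - RSS/TSS; SEE = sqrt(RSS / (N - n - 1));
    F = (r^2 / n) / ((1 - r^2) / (N - n - 1)); a perfect fit returns F = inf.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("y and y_hat must have equal length")
    N = y.size
    if N <= n + 1:
        raise ValueError(f"need N > n + 1 (got N={N}, n={n})")
    rss = float(np.sum((y - y_hat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero variance in y")
    r2 = 1.0 - rss / tss
    see = float(np.sqrt(rss / (N - n - 1)))
    if rss == 0.0 or r2 == 1.0:  # perfect fit to float precision
        f = float("inf")
    else:
        f = (r2 / n) / ((1.0 - r2) / (N - n - 1))
    return {"r2": r2, "see": see, "f_stat": float(f)}


def field_contributions(
    coef: np.ndarray, column_sds: np.ndarray, column_fields: np.ndarray
) -> dict[str, float]:
    """Per-field |coef_j * sd_j| mass fractions (sum to 1).

    ``column_fields`` labels each descriptor column with its field kind; the
    coefficient and sd must be on the same (scaled or unscaled) column scale,
    in which case the fractions are identical either way.
    """
    coef = np.asarray(coef, dtype=float)
    mass = np.abs(coef * np.asarray(column_sds, dtype=float))
    total = mass.sum()
    if total == 0:
        raise ValueError("all coefficients are zero; contributions undefined")
    fields = np.asarray(column_fields)
    return {
        k: float(mass[fields == k].sum() / total) for k in dict.fromkeys(fields)
    }
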