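"""Feature denoising and dimensionality reduction.

Two stages sit between raw feature series and the classifier:

1. **FFT smoothing** — a zero-phase moving average of odd span (default 5
   samples) realised as FFT-based circular convolution after reflection
   padding, so edges are handled symmetrically and the output keeps the
   input length.

2. **Factor analysis** — columns are standardized, the correlation matrix
   eigendecomposed (so eigenvalues sum to the number of variables and
   per-component variance shares are eigenvalue / p * 100), the smallest
   number of components whose cumulative share reaches the threshold
   (default 95%) is retained, the retained loadings are varimax-rotated,
   and factor-score weights follow the regression method
   W = R^{-1} Lambda.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

__all__ = [
    "fft_smooth",
    "smooth_columns",
    "FactorModel",
    "fit_factor_model",
    "factor_scores",
    "explained_variance_table",
    "cumulative_variance",
    "varimax",
]


def fft_smooth(series, window: int = 5) -> np.ndarray:
    """Zero-phase moving average of odd length via FFT convolution.

    ``window=1`` is the identity; a constant series passes through
    unchanged (unit DC gain); a unit impulse becomes a centred boxcar of
    height ``1/window``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("fft_smooth expects a 1-D series")
    m = len(x)
    if m < 1 or not np.all(np.isfinite(x)):
        raise ValueError("series must be non-empty and finite")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > m:
        raise ValueError(f"window {window} exceeds series length {m}")
    if window == 1:
        return x.copy()
    half = window // 2
    padded = np.concatenate([x[half:0:-1], x, x[-2 : -half - 2 : -1]])
    kernel = np.full(window, 1.0 / window)
    out = fftconvolve(padded, kernel, mode="same")
    return out[half : half + m]


def smooth_columns(df: pd.DataFrame, columns, window: int = 5) -> pd.DataFrame:
    """Apply :func:`fft_smooth` to the named columns of a feature table."""
    out = df.copy()
    for c in columns:
        out[c] = fft_smooth(df[c].to_numpy(float), window)
    return out


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation of a loadings matrix (variables x factors).

    Maximises the variance of squared loadings within each factor; being
    orthogonal it leaves each variable's communality (row sum of squared
    loadings) untouched.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy()
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        )
        R = u @ vt
        d = np.sum(s)
        if d_old != 0 and (d - d_old) < tol * d:
            break
        d_old = d
    rotated = L @ R
    # deterministic sign: make each factor's largest-magnitude loading positive
    signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(rotated.shape[1])])
    signs[signs == 0] = 1.0
    return rotated * signs


@dataclass
class FactorModel:
    """A fitted correlation-matrix factor model with rotation.

    ``eigenvalues`` are all p component variances (non-increasing, summing
    to p); ``percent``/``cumulative`` are the variance shares in percent;
    the rotated loadings and regression score weights cover the ``k``
    retained factors; ``means``/``sds`` are the standardization constants.
    """

    eigenvalues: np.ndarray
    percent: np.ndarray
    cumulative: np.ndarray
    loadings_rotated: np.ndarray
    score_weights: np.ndarray
    k: int
    means: np.ndarray
    sds: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return len(self.eigenvalues)

    def to_json(self, path) -> None:
        payload = {
            "eigenvalues": self.eigenvalues.tolist(),
            "percent": self.percent.tolist(),
            "cumulative": self.cumulative.tolist(),
            "loadings_rotated": self.loadings_rotated.tolist(),
            "score_weights": self.score_weights.tolist(),
            "k": self.k,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "feature_names": list(self.feature_names),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FactorModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            eigenvalues=np.array(d["eigenvalues"]),
            percent=np.array(d["percent"]),
            cumulative=np.array(d["cumulative"]),
            loadings_rotated=np.array(d["loadings_rotated"]),
            score_weights=np.array(d["score_weights"]),
            k=int(d["k"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            feature_names=list(d.get("feature_names", [])),
        )


def fit_factor_model(
    feature_table,
    variance_threshold: float = 95.0,
    feature_names: list[str] | None = None,
) -> FactorModel:
    """Fit the rotated factor model to a samples x variables table.

    Retains the smallest k whose cumulative variance share reaches
    ``variance_threshold`` percent (set 90 for the looser convention).
    """
    if isinstance(feature_table, pd.DataFrame):
        feature_names = feature_names or list(feature_table.columns)
        X = feature_table.to_numpy(float)
    else:
        X = np.asarray(feature_table, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature table must be 2-D")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite entries")
    names = feature_names or [f"x{i}" for i in range(p)]
    sds = X.std(axis=0, ddof=1)
    means = X.mean(axis=0)
    # constant columns can carry float dust, so test variance relative to scale
    zero = np.flatnonzero(sds <= 1e-12 * np.maximum(np.abs(means), 1.0))
    if zero.size:
        raise ValueError(f"zero-variance column(s): {[names[i] for i in zero]}")

    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    percent = eigval / p * 100.0
    cumulative = np.cumsum(percent)

    k = int(np.searchsorted(cumulative, variance_threshold) + 1)
    k = min(k, p)
    loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
    rotated = varimax(loadings)
    # regression method W = R^{-1} Lambda; pinv covers singular correlation
    # matrices (perfectly collinear variables)
    score_weights = np.linalg.pinv(R) @ rotated

    return FactorModel(
        eigenvalues=eigval,
        percent=percent,
        cumulative=cumulative,
        loadings_rotated=rotated,
        score_weights=score_weights,
        k=k,
        means=means,
        sds=sds,
        feature_names=names,
    )


def factor_scores(model: FactorModel, feature_rows) -> np.ndarray:
    """Regression-method factor scores: standardized rows times the score
    weights.  Columns are centred (mean ~0) on the fitting table."""
    if isinstance(feature_rows, pd.DataFrame):
        feature_rows = feature_rows.to_numpy(float)
    X = np.atleast_2d(np.asarray(feature_rows, dtype=float))
    if X.shape[1] != model.n_variables:
        raise ValueError(
            f"expected {model.n_variables} columns, got {X.shape[1]}"
        )
    Z = (X - model.means) / model.sds
    return Z @ model.score_weights


def cumulative_variance(percent) -> np.ndarray:
    """Running total of per-factor variance shares (percent)."""
    return np.cumsum(np.asarray(percent, dtype=float))


def explained_variance_table(eigenvalues, n_variables: int | None = None) -> pd.DataFrame:
    """Total-explained-variance table from component eigenvalues.

    Per-component share = eigenvalue / n_variables * 100 and the cumulative
    column is its running sum — the convention under which a
    correlation-matrix extraction's shares total exactly 100%.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    p = n_variables or len(eig)
    percent = eig / p * 100.0
    return pd.DataFrame(
        {
            "component": np.arange(1, len(eig) + 1),
            "eigenvalue": eig,
            "percent": percent,
            "cumulative": cumulative_variance(percent),
        }
    )
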