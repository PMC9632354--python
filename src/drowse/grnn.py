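"""Generalized regression neural network (GRNN) over windowed samples.

The GRNN is Specht's one-pass kernel estimator: a query's output is the
Gaussian-kernel-weighted average of the stored training labels,

    y(x) = sum_i Y_i exp(-|x - X_i|^2 / (2 sigma^2))
           / sum_i exp(-|x - X_i|^2 / (2 sigma^2)),

with a single smoothing factor sigma controlling the kernel bandwidth.
With binary labels the output is a fatigue score in [0, 1], thresholded at
0.5 (boundary classified as fatigue — the conservative call for a safety
system).  The training signal for tuning sigma is the leave-one-out mean
squared error, which unlike the resubstitution error does not collapse to
zero as sigma -> 0.

Frame-level factor scores are grouped into sliding windows (default 900
frames with step 80, i.e. one minute of context at 15 fps) whose features
are per-column means and whose label is the majority frame label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRNNModel",
    "WindowSample",
    "make_windows",
    "windows_to_arrays",
    "grnn_predict",
    "classify",
    "loo_mse",
    "pairwise_sq_dists",
]


@dataclass
class GRNNModel:
    """Stored training patterns, binary labels and the smoothing factor."""

    patterns: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) in {0, 1}
    sigma: float
    decision_threshold: float = 0.5
    feature_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        self.labels = np.asarray(self.labels, dtype=float).ravel()
        if len(self.patterns) < 1:
            raise ValueError("model needs at least one pattern")
        if len(self.labels) != len(self.patterns):
            raise ValueError("patterns and labels must align")
        if not set(np.unique(self.labels)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary (0/1)")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "patterns": self.patterns.tolist(),
                    "labels": self.labels.tolist(),
                    "sigma": self.sigma,
                    "decision_threshold": self.decision_threshold,
                    "feature_order": list(self.feature_order),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GRNNModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            patterns=np.array(d["patterns"]),
            labels=np.array(d["labels"]),
            sigma=float(d["sigma"]),
            decision_threshold=float(d.get("decision_threshold", 0.5)),
            feature_order=list(d.get("feature_order", [])),
        )


@dataclass(frozen=True)
class WindowSample:
    """One sliding-window aggregate: mean feature vector plus majority label."""

    features: np.ndarray
    label: int
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("window features must be finite")


def make_windows(
    score_rows,
    labels,
    window: int = 900,
    step: int = 80,
    t=None,
) -> list[WindowSample]:
    """Slice frame-level rows into overlapping windows.

    Windows start at 0, step, 2*step, ...; there are
    ``floor((n - window) / step) + 1`` of them.  Features are per-column
    means; the label is the majority of frame labels with ties going to
    fatigue (1).  ``t`` optionally supplies timestamps, otherwise frame
    indices are used.
    """
    X = np.atleast_2d(np.asarray(score_rows, dtype=float))
    y = np.asarray(labels).ravel()
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    n = len(X)
    if len(y) != n:
        raise ValueError("rows and labels must align")
    if n < window:
        raise ValueError(f"need at least {window} frames, got {n}")
    tt = np.asarray(t, dtype=float) if t is not None else np.arange(n, dtype=float)
    samples = []
    for start in range(0, n - window + 1, step):
        end = start + window
        frac = float(np.mean(y[start:end]))
        label = 1 if frac >= 0.5 else 0
        samples.append(
            WindowSample(
                features=X[start:end].mean(axis=0),
                label=label,
                t_start=float(tt[start]),
                t_end=float(tt[end - 1]) + (float(tt[1] - tt[0]) if n > 1 else 1.0),
            )
        )
    return samples


def windows_to_arrays(samples: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([s.features for s in samples])
    y = np.array([s.label for s in samples], dtype=float)
    return X, y


def _check_query(model: GRNNModel, query) -> tuple[np.ndarray, bool]:
    q = np.asarray(query, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[1] != model.patterns.shape[1]:
        raise ValueError(
            f"query dimension {q.shape[1]} != pattern dimension {model.patterns.shape[1]}"
        )
    return q, single


def grnn_predict(model: GRNNModel, query):
    """Kernel-weighted label average for one query or a batch.

    When every kernel weight underflows to zero (query far outside the
    training support at small sigma), falls back to the nearest pattern's
    label.
    """
    q, single = _check_query(model, query)
    d2 = (
        np.sum(q**2, axis=1)[:, None]
        + np.sum(model.patterns**2, axis=1)[None, :]
        - 2.0 * q @ model.patterns.T
    )
    d2 = np.maximum(d2, 0.0)
    with np.errstate(under="ignore"):
        w = np.exp(-d2 / (2.0 * model.sigma**2))
    denom = w.sum(axis=1)
    out = np.empty(len(q))
    ok = denom > 0
    out[ok] = (w[ok] @ model.labels) / denom[ok]
    if np.any(~ok):
        nearest = np.argmin(d2[~ok], axis=1)
        out[~ok] = model.labels[nearest]
    return float(out[0]) if single else out


def classify(model: GRNNModel, query):
    """Threshold the fatigue score: fatigue iff score >= decision threshold."""
    score = grnn_predict(model, query)
    if np.isscalar(score):
        return "fatigue" if score >= model.decision_threshold else "non_fatigue"
    return np.where(score >= model.decision_threshold, "fatigue", "non_fatigue")


def pairwise_sq_dists(patterns) -> np.ndarray:
    """Squared Euclidean distances between all training patterns; compute
    once and reuse across the sigma search."""
    X = np.atleast_2d(np.asarray(patterns, dtype=float))
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    return np.maximum(d2, 0.0)


def loo_mse(patterns, labels, sigma: float, d2: np.ndarray | None = None) -> float:
    """Leave-one-out mean squared error of the GRNN at a given sigma.

    Each sample is predicted with itself removed from both kernel sums; a
    sample whose remaining weights all underflow takes its nearest other
    pattern's label.
    """
    X = np.atleast_2d(np.asarray(patterns, dtype=float))
    y = np.asarray(labels, dtype=float).ravel()
    n = len(X)
    if n < 2:
        raise ValueError("leave-one-out needs at least two samples")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if d2 is None:
        d2 = pairwise_sq_dists(X)
    with np.errstate(under="ignore"):
        w = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(w, 0.0)
    denom = w.sum(axis=1)
    preds = np.empty(n)
    ok = denom > 0
    preds[ok] = (w[ok] @ y) / denom[ok]
    if np.any(~ok):
        d2_loo = d2.copy()
        np.fill_diagonal(d2_loo, np.inf)
        nearest = np.argmin(d2_loo[~ok], axis=1)
        preds[~ok] = y[nearest]
    return float(np.mean((preds - y) ** 2))
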