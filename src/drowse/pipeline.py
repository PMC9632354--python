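"""End-to-end harness: landmarks -> features -> scores -> GA-GRNN -> metrics.

The stages mirror the deployment data path.  Landmark streams (simulated
or ingested from CSV) are turned into the 11-feature table, denoised with
the 5-point FFT moving average, reduced to common-factor scores, sliced
into 900-frame windows stepped by 80, and classified by a GRNN whose
smoothing factor is tuned by the genetic algorithm on the training split's
leave-one-out MSE.  Splits are chronological per session
(train/test/validate, default 55/20/25), so windows never straddle a split
boundary and evaluation windows are disjoint in time from training ones.

Everything stochastic draws from seeds derived from the single config
seed, making a run reproducible from (config, seed) alone.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import features as feat
from . import preprocess as prep
from .ga import GAConfig, GAResult, optimize
from .grnn import (
    GRNNModel,
    grnn_predict,
    loo_mse,
    make_windows,
    pairwise_sq_dists,
    windows_to_arrays,
)
from .metrics import ConfusionMatrix, MetricsReport, confusion, metrics
from .synth import Session, SubjectProfile, simulate_session

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "compare_baselines",
    "KNNClassifier",
    "RandomForestBaseline",
    "GRNNClassifier",
]


@dataclass(frozen=True)
class PipelineConfig:
    profile: SubjectProfile = field(default_factory=SubjectProfile)
    duration: float = 7200.0  # seconds simulated per driver state
    fps: float = 15.0
    landmark_files: tuple[str, ...] | None = None  # bypasses the simulator
    smoothing_window: int = 5
    variance_threshold: float = 95.0
    window: int = 900
    step: int = 80
    splits: tuple[float, float, float] = (0.55, 0.20, 0.25)
    ga: GAConfig = field(default_factory=GAConfig)
    positive_class: int = 0  # 0 = normal driving
    rounding: str = "round_first"
    estimate_pose: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "profile" in kwargs:
            kwargs["profile"] = SubjectProfile.from_dict(kwargs["profile"])
        if "ga" in kwargs:
            kwargs["ga"] = GAConfig(**kwargs["ga"])
        for key in ("splits", "landmark_files"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    report: MetricsReport  # validation split
    test_report: MetricsReport | None
    cm: ConfusionMatrix
    sigma: float
    ga_result: GAResult
    factor_model: prep.FactorModel
    model: GRNNModel
    n_windows: dict
    timings: dict
    log: list[str]


def _derived_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def _chronological_split(df: pd.DataFrame, fractions) -> list[pd.DataFrame]:
    n = len(df)
    cut1 = int(round(fractions[0] * n))
    cut2 = cut1 + int(round(fractions[1] * n))
    return [df.iloc[:cut1], df.iloc[cut1:cut2], df.iloc[cut2:]]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full identification pipeline and score the held-out split."""
    t0 = time.perf_counter()
    log: list[str] = []
    timings: dict[str, float] = {}

    def tick(stage: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        timings[stage] = now - t0
        log.append(f"{stage}: {now - t0:.2f}s")
        t0 = now

    # 1. landmark streams -------------------------------------------------
    if config.landmark_files is not None:
        sessions = [Session.read_csv(p) for p in config.landmark_files]
    else:
        seeds = _derived_seeds(config.seed, 2)
        log.append(f"simulator seeds: awake={seeds[0]} fatigued={seeds[1]}")
        sessions = [
            simulate_session(config.profile, "awake", config.duration, config.fps, seeds[0]),
            simulate_session(config.profile, "fatigued", config.duration, config.fps, seeds[1]),
        ]
    tick("simulate")

    # 2. features, smoothed per session -----------------------------------
    tables = []
    for s in sessions:
        df = feat.extract_features(s, estimate_pose=config.estimate_pose)
        df = prep.smooth_columns(df, feat.FEATURE_ORDER, config.smoothing_window)
        tables.append(df)
    tick("features")

    # 3. chronological splits per session ---------------------------------
    split_tables: list[list[pd.DataFrame]] = [[], [], []]
    for df in tables:
        for i, part in enumerate(_chronological_split(df, config.splits)):
            split_tables[i].append(part)

    # 4. factor model on the training frames ------------------------------
    train_frames = pd.concat(split_tables[0], ignore_index=True)
    fa = prep.fit_factor_model(
        train_frames[list(feat.FEATURE_ORDER)], config.variance_threshold
    )
    log.append(f"factor model: k={fa.k}, cumulative={fa.cumulative[fa.k - 1]:.2f}%")
    tick("factor_analysis")

    # 5. windows per split segment ----------------------------------------
    windows = [[], [], []]
    for i, parts in enumerate(split_tables):
        for part in parts:
            if len(part) < config.window:
                continue
            scores = prep.factor_scores(fa, part[list(feat.FEATURE_ORDER)])
            windows[i].extend(
                make_windows(
                    scores,
                    part["label"].to_numpy(),
                    config.window,
                    config.step,
                    t=part["t"].to_numpy(),
                )
            )
    n_windows = {"train": len(windows[0]), "test": len(windows[1]), "validate": len(windows[2])}
    if min(n_windows.values()) == 0:
        raise ValueError(f"a split has no complete window: {n_windows}")
    tick("windows")

    # 6. GA-tuned GRNN on the training windows ----------------------------
    Xtr, ytr = windows_to_arrays(windows[0])
    d2 = pairwise_sq_dists(Xtr)
    ga_result = optimize(
        lambda sigma: loo_mse(Xtr, ytr, sigma, d2=d2),
        replace(config.ga, seed=_derived_seeds(config.seed, 3)[2]),
    )
    model = GRNNModel(
        patterns=Xtr,
        labels=ytr,
        sigma=ga_result.best_sigma,
        feature_order=[f"factor_{i + 1}" for i in range(fa.k)],
    )
    log.append(
        f"GA: sigma={ga_result.best_sigma:.4f}, loo_mse={ga_result.best_fitness:.4f}, "
        f"generations={ga_result.generations_run}"
    )
    tick("train")

    # 7. evaluation --------------------------------------------------------
    def evaluate(samples) -> tuple[MetricsReport, ConfusionMatrix]:
        X, y = windows_to_arrays(samples)
        pred = (np.atleast_1d(grnn_predict(model, X)) >= model.decision_threshold).astype(int)
        cm = confusion(pred.tolist(), y.astype(int).tolist(), positive=config.positive_class)
        return metrics(cm, rounding=config.rounding), cm

    test_report = evaluate(windows[1])[0] if windows[1] else None
    report, cm = evaluate(windows[2])
    tick("evaluate")
    log.append(f"validation: {report.as_dict()}")

    return PipelineResult(
        report=report,
        test_report=test_report,
        cm=cm,
        sigma=ga_result.best_sigma,
        ga_result=ga_result,
        factor_model=fa,
        model=model,
        n_windows=n_windows,
        timings=timings,
        log=log,
    )


# ---------------------------------------------------------------------------
# baseline models


class KNNClassifier:
    """Plain k-nearest-neighbour majority vote with Euclidean distance."""

    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X, y) -> "KNNClassifier":
        self._X = np.atleast_2d(np.asarray(X, dtype=float))
        self._y = np.asarray(y, dtype=int).ravel()
        return self

    def predict(self, X) -> np.ndarray:
        if self._X is None:
            raise RuntimeError("fit before predict")
        Q = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = (
            np.sum(Q**2, axis=1)[:, None]
            + np.sum(self._X**2, axis=1)[None, :]
            - 2.0 * Q @ self._X.T
        )
        k = min(self.k, len(self._X))
        nearest = np.argpartition(d2, k - 1, axis=1)[:, :k]
        votes = self._y[nearest].mean(axis=1)
        return (votes >= 0.5).astype(int)  # ties go to fatigue


class RandomForestBaseline:
    """Tree-ensemble baseline behind the same fit/predict surface."""

    def __init__(self, n_estimators: int = 100, seed: int = 0):
        from sklearn.ensemble import RandomForestClassifier

        self._rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)

    def fit(self, X, y):
        self._rf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def predict(self, X):
        return self._rf.predict(np.asarray(X, dtype=float))


class GRNNClassifier:
    """GRNN behind the baseline surface; sigma fixed, or GA-tuned per fit."""

    def __init__(self, sigma: float | None = 0.1, ga: GAConfig | None = None):
        self.sigma = sigma
        self.ga = ga
        self._model: GRNNModel | None = None

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        sigma = self.sigma
        if sigma is None:
            d2 = pairwise_sq_dists(X)
            sigma = optimize(
                lambda s: loo_mse(X, y, s, d2=d2), self.ga or GAConfig()
            ).best_sigma
        self._model = GRNNModel(patterns=X, labels=y, sigma=sigma)
        return self

    def predict(self, X):
        if self._model is None:
            raise RuntimeError("fit before predict")
        scores = np.atleast_1d(grnn_predict(self._model, X))
        return (scores >= self._model.decision_threshold).astype(int)


def compare_baselines(
    X,
    y,
    models: dict | None = None,
    folds: int = 5,
    rounds: int = 10,
    seed: int = 0,
    positive: int = 0,
    rounding: str = "round_first",
) -> pd.DataFrame:
    """Repeated stratified k-fold comparison on identical folds.

    Every model sees the same ``rounds x folds`` train/test partitions
    (so ``folds * rounds`` evaluations per model); returns one row per
    (model, round, fold) with the four percentage metrics.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes for a stratified comparison")
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]} has {counts.min()} samples, "
            f"fewer than {folds} folds"
        )
    if models is None:
        models = {
            "knn": KNNClassifier(),
            "rf": RandomForestBaseline(seed=seed),
            "ga_grnn": GRNNClassifier(sigma=None),
        }
    round_seeds = _derived_seeds(seed, rounds)
    rows = []
    for r in range(rounds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=round_seeds[r])
        for f, (tr, te) in enumerate(skf.split(X, y)):
            for name, mdl in models.items():
                mdl.fit(X[tr], y[tr])
                pred = np.asarray(mdl.predict(X[te]))
                rep = metrics(
                    confusion(pred.tolist(), y[te].tolist(), positive=positive),
                    rounding=rounding,
                )
                rows.append({"model": name, "round": r, "fold": f, **rep.as_dict()})
    return pd.DataFrame(rows)
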