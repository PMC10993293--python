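"""Composition-based predictive models of the rarity index.

Two regressor families mirror the analysis design: ridge regression
(alpha = 0.01, intercept unpenalized) for linear signal and coefficient
inspection, and a seeded random forest for nonlinear signal and
impurity-based feature importances.  Feature spaces are either the mono-
plus di-unit counts of each k-mer (4 + 16 columns for DNA, 20 + 400 for
protein) or the eight physicochemical descriptors of a peptide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold, train_test_split

from .kmers import alphabet_for


@dataclass
class ModelConfig:
    model: str = "ridge"  # "ridge" | "random_forest"
    alpha: float = 0.01
    n_trees: int = 100
    cv_folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ModelReport:
    model: str
    r2_test: float
    mae_test: float
    cv_r2: list[float]
    feature_scores: pd.Series  # ridge: signed coefficients; forest: importances
    intercept: float | None
    config: ModelConfig

    @property
    def cv_r2_mean(self) -> float:
        return float(np.mean(self.cv_r2))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "r2_test": self.r2_test,
            "mae_test": self.mae_test,
            "cv_r2": self.cv_r2,
            "cv_r2_mean": self.cv_r2_mean,
            "intercept": self.intercept,
            "feature_scores": self.feature_scores.to_dict(),
            "config": vars(self.config).copy(),
        }


def feature_columns(seq_type: str) -> list[str]:
    """Deterministic column order: monomers then dimers, lexicographic in each block."""
    alphabet = alphabet_for(seq_type)
    monomers = sorted(alphabet)
    dimers = sorted("".join(p) for p in itertools.product(alphabet, repeat=2))
    return monomers + dimers


def build_sequence_features(kmers: list[str], seq_type: str) -> pd.DataFrame:
    """Mono- and di-unit count matrix of a list of same-length k-mers.

    Monomer counts per row sum to k and dimer counts to k - 1.
    """
    if not kmers:
        raise ValueError("no k-mers given")
    lengths = {len(km) for km in kmers}
    if len(lengths) != 1:
        raise ValueError(f"k-mers must share one length, got lengths {sorted(lengths)}")
    columns = feature_columns(seq_type)
    col_index = {c: i for i, c in enumerate(columns)}
    data = np.zeros((len(kmers), len(columns)), dtype=np.float64)
    for row, kmer in enumerate(kmers):
        for ch in kmer:
            data[row, col_index[ch]] += 1
        for i in range(len(kmer) - 1):
            data[row, col_index[kmer[i : i + 2]]] += 1
    return pd.DataFrame(data, index=pd.Index(kmers, name="kmer"), columns=columns)


def _check_xy(X: pd.DataFrame, y: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)} values")
    if len(y) < cfg.cv_folds:
        raise ValueError(f"{len(y)} rows cannot support {cfg.cv_folds}-fold validation")
    return y


def _make_estimator(cfg: ModelConfig):
    if cfg.model == "ridge":
        return Ridge(alpha=cfg.alpha)
    if cfg.model == "random_forest":
        return RandomForestRegressor(n_estimators=cfg.n_trees, random_state=cfg.seed, n_jobs=1)
    raise ValueError(f"unknown model {cfg.model!r}")


def _fit(X: pd.DataFrame, y: np.ndarray, cfg: ModelConfig) -> ModelReport:
    y = _check_xy(X, y, cfg)
    X_train, X_test, y_train, y_test = train_test_split(
        X.to_numpy(), y, test_size=cfg.test_fraction, random_state=cfg.seed
    )
    est = _make_estimator(cfg)
    est.fit(X_train, y_train)
    pred = est.predict(X_test)
    cv = cross_validate(X, y, cfg)
    if cfg.model == "ridge":
        scores = pd.Series(est.coef_, index=X.columns)
        intercept = float(est.intercept_)
    else:
        scores = pd.Series(est.feature_importances_, index=X.columns)
        intercept = None
    return ModelReport(
        model=cfg.model,
        r2_test=float(r2_score(y_test, pred)),
        mae_test=float(mean_absolute_error(y_test, pred)),
        cv_r2=cv,
        feature_scores=scores,
        intercept=intercept,
        config=cfg,
    )


def fit_ridge(X: pd.DataFrame, y: np.ndarray, cfg: ModelConfig | None = None) -> ModelReport:
    """L2-penalized linear regression of rarity on the feature matrix."""
    cfg = cfg or ModelConfig()
    cfg.model = "ridge"
    return _fit(X, y, cfg)


def fit_random_forest(X: pd.DataFrame, y: np.ndarray, cfg: ModelConfig | None = None) -> ModelReport:
    """Seeded random-forest regression; importances are impurity-based and sum to 1."""
    cfg = cfg or ModelConfig(model="random_forest")
    cfg.model = "random_forest"
    return _fit(X, y, cfg)


def cross_validate(X: pd.DataFrame, y: np.ndarray, cfg: ModelConfig) -> list[float]:
    """Per-fold test R^2 under a seeded shuffled k-fold split."""
    y = _check_xy(X, y, cfg)
    folds = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    Xa = X.to_numpy()
    scores = []
    for train_idx, test_idx in folds.split(Xa):
        est = _make_estimator(cfg)
        est.fit(Xa[train_idx], y[train_idx])
        scores.append(float(r2_score(y[test_idx], est.predict(Xa[test_idx]))))
    return scores


def top_features(report: ModelReport, m: int | None = None) -> list[tuple[str, float]]:
    """Features ranked by |coefficient| (ridge) or importance (forest), ties lexicographic."""
    scores = report.feature_scores
    ranked = sorted(scores.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return ranked if m is None else ranked[: max(m, 0)]
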