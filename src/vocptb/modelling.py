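"""Class-balanced tenfold CV with in-fold rank-sum feature selection.

The analysis core: samples are first balanced (majority class randomly
subsampled to the minority count), then split into stratified folds.
*Within each fold* the training 90% alone ranks every feature by a
two-sided Mann–Whitney rank-sum p-value, the top-k features are kept,
a classifier (random forest or Gaussian process) is fitted on them, and
out-of-fold probabilities are produced for the held-out 10%.  After all
folds every sample carries exactly one test probability.

Selecting features inside the fold is the whole point — selection on
the full data before splitting leaks the test labels into the feature
ranking and inflates apparent performance; :func:`run_cv_leaky`
implements that broken variant deliberately so the inflation can be
demonstrated and guarded against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from ._util import subseed
from .preprocess import FeatureMatrix

__all__ = [
    "ModelConfig",
    "CVResult",
    "ConfigError",
    "balance_classes",
    "ranksum_pvalues",
    "ranksum_select",
    "train_classifier",
    "predict_proba",
    "run_cv",
    "run_cv_leaky",
]

#: largest per-group size for which the exact permutation rank-sum is used
_EXACT_MAX_GROUP = 8


class ConfigError(ValueError):
    """Invalid model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Cross-validation and classifier settings.

    ``n_features`` is the per-fold rank-sum selection size (the study
    carried 100 lowest-p features into classification).  Random-forest
    and Gaussian-process hyperparameters are exposed; the global
    ``seed`` expands into named sub-seeds for balancing, fold shuffling
    and classifier training.
    """

    n_folds: int = 10
    n_features: int = 100
    classifier: str = "random_forest"
    seed: int = 0
    n_trees: int = 1000
    gp_length_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        if self.classifier not in ("random_forest", "gaussian_process"):
            raise ConfigError(
                f"unknown classifier {self.classifier!r}; "
                "expected 'random_forest' or 'gaussian_process'"
            )


@dataclass
class CVResult:
    """Out-of-fold test probabilities for every retained sample."""

    sample_ids: list[str]
    labels: np.ndarray
    probabilities: np.ndarray
    fold_of: np.ndarray
    selected_features: list[list[int]] = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.fold_of = np.asarray(self.fold_of, dtype=int)
        n = len(self.sample_ids)
        if not (self.labels.shape == self.probabilities.shape == self.fold_of.shape == (n,)):
            raise ValueError("CVResult fields misaligned")
        if np.any(~np.isfinite(self.probabilities)) or (
            (self.probabilities < 0) | (self.probabilities > 1)
        ).any():
            raise ValueError("probabilities must be finite and within [0, 1]")

    def to_dict(self) -> dict:
        return {
            "sample_ids": list(self.sample_ids),
            "labels": self.labels.tolist(),
            "probabilities": self.probabilities.tolist(),
            "fold_of": self.fold_of.tolist(),
            "selected_features": [list(f) for f in self.selected_features],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CVResult":
        return cls(
            sample_ids=list(d["sample_ids"]),
            labels=np.asarray(d["labels"]),
            probabilities=np.asarray(d["probabilities"]),
            fold_of=np.asarray(d["fold_of"]),
            selected_features=[list(f) for f in d["selected_features"]],
        )


def balance_classes(matrix: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Equalise class counts by random subsampling of the majority class.

    The minority class is kept in full; majority samples are drawn
    uniformly without replacement.  Original sample order is preserved,
    so an already balanced matrix comes back identical.
    """
    labels = matrix.labels
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    if pos.size > neg.size:
        pos = rng.choice(pos, size=neg.size, replace=False)
    elif neg.size > pos.size:
        neg = rng.choice(neg, size=pos.size, replace=False)
    keep = np.sort(np.concatenate([pos, neg]))
    return matrix.take(keep)


def _exact_ranksum_p(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Conditions on the observed (possibly tied) values: p is the
    fraction of the C(n, n1) label assignments whose U statistic is at
    least as far from its null mean as the observed one.  A feature
    constant across samples has every permuted U equal to the observed
    U, hence p = 1.
    """
    n, n_feat = values.shape
    n1 = int((labels == 1).sum())
    ranks = stats.rankdata(values, axis=0)
    mu = n1 * (n - n1) / 2.0
    obs_u = ranks[labels == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    n_comb = comb(n, n1)
    hits = np.zeros(n_feat)
    for subset in combinations(range(n), n1):
        u = ranks[list(subset)].sum(axis=0) - n1 * (n1 + 1) / 2.0
        hits += np.abs(u - mu) >= np.abs(obs_u - mu) - 1e-9
    return hits / n_comb


def ranksum_pvalues(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Mann–Whitney p and rank-biserial effect per feature.

    Exact enumeration for group sizes up to 8 (conditioning on ties),
    tie-corrected normal approximation otherwise.  Features constant
    across all samples get p = 1 and effect 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = values[labels == 1], values[labels == 0]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values, axis=0)
    u = ranks[labels == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    effect = 2.0 * u / (n1 * n0) - 1.0  # rank-biserial correlation
    if max(n1, n0) <= _EXACT_MAX_GROUP:
        p = _exact_ranksum_p(values, labels)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(pos, neg, axis=0, method="asymptotic")
        p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
        p[~np.isfinite(p)] = 1.0  # zero-variance (constant) features
    constant = np.all(values == values[0], axis=0)
    p = np.where(constant, 1.0, p)
    return p, np.where(constant, 0.0, effect)


def ranksum_select(values: np.ndarray, labels: np.ndarray, k: int) -> list[int]:
    """Indices of the k features with the smallest rank-sum p-value.

    Ties in p are broken by larger absolute rank-biserial effect, then
    by lower feature index, so selection is fully deterministic.
    """
    values = np.asarray(values, dtype=float)
    if k > values.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {values.shape[1]}")
    p, effect = ranksum_pvalues(values, labels)
    order = np.lexsort((np.arange(values.shape[1]), -np.abs(effect), p))
    return [int(i) for i in order[:k]]


def train_classifier(values: np.ndarray, labels: np.ndarray, config: ModelConfig):
    """Fit the configured classifier; returns a handle with predict_proba.

    Random forest: ``n_trees`` trees with sqrt-feature subsampling.
    Gaussian process: RBF kernel (initial length-scale from config,
    optimised by marginal likelihood) on standardised features.  Both
    are deterministic given the config seed.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in training data")
    rs = subseed(config.seed, "classifier", config.classifier)
    if config.classifier == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features="sqrt",
            random_state=rs,
            n_jobs=1,
        )
    else:
        clf = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "gp",
                    GaussianProcessClassifier(
                        kernel=1.0 * RBF(length_scale=config.gp_length_scale),
                        random_state=rs,
                    ),
                ),
            ]
        )
    with warnings.catch_warnings():
        # GP marginal-likelihood optimisation can brush parameter bounds
        warnings.simplefilter("ignore")
        clf.fit(values, labels)
    return clf


def predict_proba(handle, values: np.ndarray) -> np.ndarray:
    """Probability of the positive class for each row of ``values``."""
    values = np.asarray(values, dtype=float)
    expected = handle.n_features_in_ if hasattr(handle, "n_features_in_") else handle[0].n_features_in_
    if values.ndim != 2 or values.shape[1] != expected:
        raise ValueError(
            f"test matrix has {values.shape[-1] if values.ndim else 0} features; "
            f"classifier was trained on {expected}"
        )
    classes = list(handle.classes_)
    proba = handle.predict_proba(values)[:, classes.index(1)]
    return np.clip(proba, 0.0, 1.0)


def _cv_over_folds(matrix: FeatureMatrix, config: ModelConfig, preselected) -> CVResult:
    labels = matrix.labels
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if min(n_pos, n_neg) < config.n_folds:
        raise ConfigError(
            f"smallest class has {min(n_pos, n_neg)} samples, fewer than "
            f"n_folds={config.n_folds}; use a smaller n_folds"
        )
    if config.n_features > matrix.n_features:
        raise ConfigError(
            f"n_features={config.n_features} exceeds available features "
            f"({matrix.n_features})"
        )
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=subseed(config.seed, "folds")
    )
    probs = np.full(matrix.n_samples, np.nan)
    fold_of = np.full(matrix.n_samples, -1)
    selected_per_fold: list[list[int]] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(matrix.values, labels)):
        x_train, y_train = matrix.values[train_idx], labels[train_idx]
        if preselected is None:
            selected = ranksum_select(x_train, y_train, config.n_features)
        else:
            selected = list(preselected)
        fold_config = ModelConfig(
            n_folds=config.n_folds,
            n_features=config.n_features,
            classifier=config.classifier,
            seed=subseed(config.seed, "fold", fold),
            n_trees=config.n_trees,
            gp_length_scale=config.gp_length_scale,
        )
        handle = train_classifier(x_train[:, selected], y_train, fold_config)
        probs[test_idx] = predict_proba(handle, matrix.values[np.ix_(test_idx, selected)])
        fold_of[test_idx] = fold
        selected_per_fold.append(selected)
    return CVResult(
        sample_ids=list(matrix.sample_ids),
        labels=labels,
        probabilities=probs,
        fold_of=fold_of,
        selected_features=selected_per_fold,
    )


def run_cv(matrix: FeatureMatrix, config: ModelConfig) -> CVResult:
    """Stratified k-fold CV with rank-sum selection done inside each fold.

    Expects a balanced matrix (use :func:`balance_classes` first, or the
    pipeline wrapper which does).  Fully deterministic given the config
    seed; every sample receives exactly one out-of-fold probability.
    """
    return _cv_over_folds(matrix, config, preselected=None)


def run_cv_leaky(matrix: FeatureMatrix, config: ModelConfig) -> CVResult:
    """Deliberately broken variant: features selected on the FULL data.

    Selecting before splitting lets the held-out labels steer the
    feature ranking; on null data with many features and few samples
    this inflates apparent AUC well above chance.  Exists only to
    demonstrate and test that leakage — never use it for analysis.
    """
    selected = ranksum_select(matrix.values, matrix.labels, config.n_features)
    return _cv_over_folds(matrix, config, preselected=selected)
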