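"""Downstream evaluation: repeated random splits, random-forest AUROC.

Quantifies what the wrapper stage buys over the differential-methylation
screen alone: the same stratified train/test splits are applied to both
feature sets (paired design), a random forest is trained per split and
feature set, and the test-set AUROC distribution is summarised per strategy.

Note the protocol mirrors the study design: the feature panels are selected
once on the full data set and the repeated splits evaluate classification
only. This is optimistic about generalisation, because the test samples
participated in feature selection; the documentation discusses the bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .io import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    n_repeats: int = 100
    test_fraction: float = 0.3
    rf_n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class EvalResult:
    """Per-repeat AUROCs (long format) plus per-strategy summary."""

    per_repeat: pd.DataFrame  # columns: repeat, strategy, auroc
    summary: pd.DataFrame  # index: strategy; columns: median, q25, q75

    def median(self, strategy: str) -> float:
        return float(self.summary.loc[strategy, "median"])


def auroc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation:
    (concordant pairs + half the tied pairs) / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def stratified_splits(
    labels: np.ndarray, cfg: EvalConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic list of (train, test) index pairs, stratified by class.

    Each class contributes ``round(n_class * test_fraction)`` test samples
    (at least one, leaving at least one for training).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need both classes to build stratified splits")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    splits = []
    for _ in range(cfg.n_repeats):
        test_idx, train_idx = [], []
        for c in classes:
            members = np.flatnonzero(labels == c)
            rng.shuffle(members)
            n_test = int(round(members.size * cfg.test_fraction))
            n_test = min(max(n_test, 1), members.size - 1)
            test_idx.append(members[:n_test])
            train_idx.append(members[n_test:])
        splits.append(
            (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))
        )
    return splits


def _fit_score(
    X_train, y_train, X_test, n_trees: int, seed: int
) -> np.ndarray:
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X_train, y_train)
    pos = list(rf.classes_).index(rf.classes_.max())
    return rf.predict_proba(X_test)[:, pos]


def compare_strategies(
    matrix: pd.DataFrame,
    labels,
    strategy_probes: dict[str, list[str]],
    cfg: EvalConfig,
) -> EvalResult:
    """Paired comparison of feature strategies over repeated random splits.

    ``strategy_probes`` maps a strategy name (e.g. ``dmr_only``,
    ``three_step``) to its probe list; every strategy is evaluated on the
    identical split sequence and with the identical per-repeat forest seed, so
    differences are attributable to the feature sets alone.
    """
    labels = np.asarray(labels)
    if matrix.shape[1] != labels.size:
        raise ValueError("labels length must match matrix sample count")
    for name, probes in strategy_probes.items():
        if not probes:
            raise ConfigurationError(f"strategy {name!r} has an empty probe set")
        missing = [p for p in probes if p not in matrix.index]
        if missing:
            raise ConfigurationError(
                f"strategy {name!r}: probes absent from matrix: {missing[:5]}"
            )
    splits = stratified_splits(labels, cfg)
    rf_seeds = np.random.default_rng(cfg.seed + 1).integers(
        0, 2**31 - 1, size=cfg.n_repeats
    )
    rows = []
    for name, probes in strategy_probes.items():
        X = matrix.loc[probes].to_numpy(dtype=float).T
        for r, (train, test) in enumerate(splits):
            scores = _fit_score(
                X[train], labels[train], X[test], cfg.rf_n_trees, int(rf_seeds[r])
            )
            rows.append(
                {
                    "repeat": r,
                    "strategy": name,
                    "auroc": auroc(scores, labels[test] == labels.max()),
                }
            )
    per_repeat = pd.DataFrame(rows)
    summary = (
        per_repeat.groupby("strategy")["auroc"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
        )
    )
    return EvalResult(per_repeat=per_repeat, summary=summary)
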