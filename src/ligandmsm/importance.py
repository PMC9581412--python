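"""Per-residue importance profiles that distinguish macrostates.

Given residue-pair inverse-distance features and core-state labels, a binary
classifier is trained per macrostate in one-versus-the-rest fashion and asked
which features drove its decisions.  Two attribution routes:

* **random forest** — per-feature Gini importance, averaged over
  cross-validation folds (100 trees, unlimited depth, √d features per split,
  seeded), with held-out accuracy logged per fold;
* **KL divergence** — symmetrized Kullback-Leibler divergence between the
  in-state and rest histograms of each feature (shared bin edges,
  pseudo-count regularization), a model-free baseline.

Per-feature importances are aggregated per residue by summing over every pair
the residue participates in, then min-max normalized to [0, 1] per state.
Transition frames (core label −1) are always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold

from ._exceptions import DataError, ParameterError
from .featurization import FeatureSet

__all__ = [
    "ImportanceProfile",
    "rf_importance",
    "kl_importance",
    "aggregate_per_residue",
]


@dataclass
class ImportanceProfile:
    """Importance per feature and per residue, per macrostate.

    per_feature / per_feature_std: ``(n_states, n_features)`` fold means/stds.
    per_residue: ``(n_states, n_residues)`` aggregated, min-max normalized.
    accuracies: held-out accuracy per (state, fold) for the RF route.
    """

    states: np.ndarray
    per_feature: np.ndarray
    per_feature_std: np.ndarray
    residues: np.ndarray
    per_residue: np.ndarray
    method: str
    folds: int
    seed: int
    accuracies: np.ndarray | None = None

    def residue_table(self):
        import pandas as pd

        df = pd.DataFrame(self.per_residue.T, columns=[f"state_{s}" for s in self.states])
        df.insert(0, "residue", self.residues)
        return df


def _gather(features, labels) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    if isinstance(features, FeatureSet):
        X = features.concatenated()
        pair_labels = features.labels
    else:
        mats = [features] if isinstance(features, np.ndarray) else list(features)
        X = np.concatenate([np.atleast_2d(m) for m in mats], axis=0)
        pair_labels = [("f", j) for j in range(X.shape[1])]
    y = np.concatenate(
        [labels] if isinstance(labels, np.ndarray) else [np.asarray(l) for l in labels]
    ).astype(np.int64)
    if y.size != X.shape[0]:
        raise ParameterError(f"{y.size} labels for {X.shape[0]} frames")
    core = y >= 0
    X, y = X[core], y[core]
    if np.unique(y).size < 2:
        raise DataError("need at least two distinct macrostate labels among core frames")
    return X, y, pair_labels


def rf_importance(
    features,
    labels,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 100,
) -> ImportanceProfile:
    """One-vs-rest random-forest Gini importance per macrostate.

    Transition frames are dropped; each state needs at least ``folds`` frames.
    The forests use 100 trees, unlimited depth and √d features per split.
    """
    X, y, pair_labels = _gather(features, labels)
    states = np.unique(y)
    for s in states:
        if (y == s).sum() < folds:
            raise DataError(f"macrostate {s} has fewer than {folds} core frames")
    n_feat = X.shape[1]
    per_feat = np.zeros((states.size, n_feat))
    per_std = np.zeros((states.size, n_feat))
    acc = np.zeros((states.size, folds))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    split_ix = list(kf.split(X))
    for si, s in enumerate(states):
        yb = (y == s).astype(int)
        fold_imp = np.zeros((folds, n_feat))
        for f, (tr, te) in enumerate(split_ix):
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                max_depth=None,
                max_features="sqrt",
                random_state=seed + 1000 * f + si,
                n_jobs=1,
            )
            clf.fit(X[tr], yb[tr])
            fold_imp[f] = clf.feature_importances_
            acc[si, f] = clf.score(X[te], yb[te])
        per_feat[si] = fold_imp.mean(axis=0)
        per_std[si] = fold_imp.std(axis=0)
    residues, per_res = aggregate_per_residue(per_feat, pair_labels)
    return ImportanceProfile(
        states, per_feat, per_std, residues, per_res,
        method="random_forest", folds=folds, seed=seed, accuracies=acc,
    )


def symmetric_kl(p_samples: np.ndarray, q_samples: np.ndarray,
                 bins: int = 50, pseudocount: float = 1.0) -> float:
    """Symmetrized histogram KL divergence (KL(P‖Q)+KL(Q‖P))/2 in nats.

    Shared bin edges over the pooled range; ``pseudocount`` is added to every
    bin before normalization, so identical or constant inputs give exactly 0.
    """
    lo = min(p_samples.min(), q_samples.min())
    hi = max(p_samples.max(), q_samples.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(p_samples, bins=edges)
    q, _ = np.histogram(q_samples, bins=edges)
    p = p + pseudocount
    q = q + pseudocount
    p = p / p.sum()
    q = q / q.sum()
    return float(0.5 * (np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))))


def kl_importance(
    features,
    labels,
    bins: int = 50,
    pseudocount: float = 1.0,
) -> ImportanceProfile:
    """Per-feature symmetrized KL divergence between each state and the rest."""
    X, y, pair_labels = _gather(features, labels)
    states = np.unique(y)
    n_feat = X.shape[1]
    per_feat = np.zeros((states.size, n_feat))
    for si, s in enumerate(states):
        ins = X[y == s]
        rest = X[y != s]
        for j in range(n_feat):
            per_feat[si, j] = symmetric_kl(ins[:, j], rest[:, j], bins, pseudocount)
    residues, per_res = aggregate_per_residue(per_feat, pair_labels)
    return ImportanceProfile(
        states, per_feat, np.zeros_like(per_feat), residues, per_res,
        method="kl_divergence", folds=1, seed=0,
    )


def aggregate_per_residue(
    per_feature: np.ndarray, pair_labels: list[tuple]
) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-feature importances onto residues and min-max normalize per state.

    Every feature must map to exactly two residue identifiers.  The returned
    per-state profiles lie in [0, 1] with the maximum exactly 1 whenever any
    importance is positive.
    """
    per_feature = np.atleast_2d(np.asarray(per_feature, dtype=float))
    if len(pair_labels) != per_feature.shape[1]:
        raise ParameterError("one pair label required per feature column")
    for lab in pair_labels:
        if len(lab) != 2:
            raise ParameterError(f"feature label {lab!r} does not name exactly two residues")
    residues = np.array(sorted({r for lab in pair_labels for r in lab}, key=str))
    index = {r: i for i, r in enumerate(residues)}
    agg = np.zeros((per_feature.shape[0], residues.size))
    for j, (r1, r2) in enumerate(pair_labels):
        agg[:, index[r1]] += per_feature[:, j]
        agg[:, index[r2]] += per_feature[:, j]
    lo = agg.min(axis=1, keepdims=True)
    hi = agg.max(axis=1, keepdims=True)
    span = hi - lo
    # flat-but-positive profiles normalize to all ones (every residue maximal)
    flat = np.where(hi > 0, 1.0, 0.0)
    norm = np.where(span > 0, (agg - lo) / np.where(span == 0, 1, span), flat)
    return residues, norm
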