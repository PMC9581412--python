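"""Time-lagged independent component analysis and VAMP2 feature scoring.

tICA solves the generalized symmetric eigenproblem C(τ)·v = λ·C(0)·v where
C(0) and C(τ) are the instantaneous and time-lagged covariance matrices of the
feature time series.  The leading eigenvectors span the slowest linearly
resolvable degrees of freedom; eigenvalues approximate autocorrelations of the
underlying slow processes at the chosen lag.

Covariances are estimated with the symmetrized (reversible) convention: every
(t, t+τ) pair contributes both as (head, tail) and (tail, head), which makes
C(τ) symmetric and guarantees C(0) ± C(τ) ⪰ 0 — eigenvalues therefore lie in
[−1, 1] up to regularization.  Cross-trajectory pairs are never counted.

The VAMP2 score ranks candidate feature sets by the kinetic variance their
leading singular functions capture: score = 1 + Σ squared generalized singular
values (the constant function contributes the 1).  Cross-validation is by
whole trajectory, falling back to contiguous block splits when there are fewer
trajectories than folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from ._exceptions import DataError, ParameterError
from .featurization import FeatureSet

__all__ = [
    "TICAModel",
    "VAMP2Report",
    "estimate_lagged_covariances",
    "fit_tica",
    "tica",
    "project",
    "vamp2_score_cv",
    "score_feature_sets",
]


class LaggedCovariances(NamedTuple):
    mean: np.ndarray
    C0: np.ndarray
    Ctau: np.ndarray
    n_pairs: int


def _as_matrices(features) -> list[np.ndarray]:
    if isinstance(features, FeatureSet):
        return features.matrices
    if isinstance(features, np.ndarray):
        return [features]
    return [np.asarray(m, dtype=float) for m in features]


def estimate_lagged_covariances(features, lag: int) -> LaggedCovariances:
    """Pooled symmetrized instantaneous and time-lagged covariances.

    Every trajectory must be longer than ``lag``; pairs never straddle a
    trajectory boundary.  The mean is taken over heads and tails jointly so
    that the estimators are exactly mean-free under the pair measure.
    """
    if lag < 1:
        raise ParameterError("lag must be ≥ 1")
    mats = _as_matrices(features)
    for i, m in enumerate(mats):
        if m.shape[0] <= lag:
            raise ParameterError(
                f"trajectory {i} has {m.shape[0]} frames, not longer than lag {lag}"
            )
    dim = mats[0].shape[1]
    n_pairs = 0
    s = np.zeros(dim)
    for m in mats:
        head, tail = m[:-lag], m[lag:]
        s += head.sum(axis=0) + tail.sum(axis=0)
        n_pairs += head.shape[0]
    mean = s / (2 * n_pairs)

    C0 = np.zeros((dim, dim))
    Ct = np.zeros((dim, dim))
    for m in mats:
        head = m[:-lag] - mean
        tail = m[lag:] - mean
        C0 += head.T @ head + tail.T @ tail
        Ct += head.T @ tail
    C0 /= 2 * n_pairs
    Ct = (Ct + Ct.T) / (2 * n_pairs)
    return LaggedCovariances(mean, C0, Ct, n_pairs)


@dataclass
class TICAModel:
    """A fitted tICA transform.

    components are the generalized eigenvectors (columns), C0-orthonormal
    after regularization; eigenvalues are sorted descending and clipped to 1.
    """

    mean: np.ndarray
    C0: np.ndarray
    Ctau: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    lag: int
    regularization: float

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def timescales(self, frame_spacing_ns: float = 1.0) -> np.ndarray:
        """Implied timescales −τ/ln λ in ns (NaN where λ ≤ 0)."""
        lam = self.eigenvalues
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                lam > 0, -self.lag * frame_spacing_ns / np.log(np.clip(lam, 1e-300, 1)), np.nan
            )


def default_regularization(C0: np.ndarray) -> float:
    return 1e-6 * np.trace(C0) / C0.shape[0]


def fit_tica(
    C0: np.ndarray,
    Ctau: np.ndarray,
    n_components: int | None = None,
    regularization: float | None = None,
    mean: np.ndarray | None = None,
    lag: int = 1,
) -> TICAModel:
    """Solve the regularized generalized eigenproblem Ctau·v = λ·(C0 + εI)·v."""
    C0 = np.asarray(C0, dtype=float)
    Ctau = np.asarray(Ctau, dtype=float)
    eps = default_regularization(C0) if regularization is None else float(regularization)
    C0r = C0 + eps * np.eye(C0.shape[0])
    try:
        vals, vecs = scipy.linalg.eigh(Ctau, C0r)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise scipy.linalg.LinAlgError(
            f"generalized eigenproblem failed ({exc}); try a larger regularization"
        ) from exc
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.any(vals > 1.0 + 1e-10):
        warnings.warn(
            f"tICA eigenvalues exceed 1 (max {vals.max():.6f}); clipping", stacklevel=2
        )
    vals = np.minimum(vals, 1.0)
    if n_components is not None:
        vals, vecs = vals[:n_components], vecs[:, :n_components]
    # deterministic sign: largest-magnitude entry positive
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    if mean is None:
        mean = np.zeros(C0.shape[0])
    return TICAModel(np.asarray(mean, float), C0, Ctau, vals, vecs, lag, eps)


def tica(
    features,
    lag: int,
    n_components: int | None = None,
    regularization: float | None = None,
) -> TICAModel:
    """Estimate covariances and fit tICA in one call."""
    mean, C0, Ct, _ = estimate_lagged_covariances(features, lag)
    return fit_tica(C0, Ct, n_components, regularization, mean=mean, lag=lag)


def project(model: TICAModel, features):
    """Project features onto the tICA components.

    Accepts a FeatureSet or list of matrices (returns a list of coordinate
    tables), a single 2-D matrix, or a single 1-D vector (e.g. an external
    structure) — the return type mirrors the input.
    """
    def _one(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != model.mean.size:
            raise ParameterError(
                f"feature dimension {x.shape[-1]} does not match model ({model.mean.size})"
            )
        return (x - model.mean) @ model.components

    if isinstance(features, FeatureSet):
        return [_one(m) for m in features.matrices]
    if isinstance(features, np.ndarray):
        return _one(features)
    return [_one(m) for m in features]


# ---------------------------------------------------------------------------
# VAMP2 cross-validated scoring
# ---------------------------------------------------------------------------

@dataclass
class VAMP2Report:
    """Cross-validated VAMP2 scores as a tidy table.

    scores has columns feature_type, lag, fold, score; ``summary()``
    aggregates to mean ± std per (feature_type, lag).
    """

    scores: pd.DataFrame
    n_eigenvalues: int
    folds: int

    def summary(self) -> pd.DataFrame:
        g = self.scores.groupby(["feature_type", "lag"])["score"]
        out = g.agg(["mean", "std"]).reset_index()
        out["std"] = out["std"].fillna(0.0)
        return out

    def best_feature_type(self) -> str:
        """Feature type with the highest lag-averaged mean score."""
        s = self.summary().groupby("feature_type")["mean"].mean()
        return str(s.idxmax())


def _cv_units(mats: list[np.ndarray], folds: int, min_len: int) -> list[list[np.ndarray]]:
    """Split trajectories into ≥ folds units, block-splitting when too few."""
    units: list[np.ndarray] = list(mats)
    if len(units) < folds:
        per = int(np.ceil(folds / len(units)))
        split: list[np.ndarray] = []
        for m in units:
            n_blocks = min(per, max(1, m.shape[0] // max(min_len, 2)))
            split.extend(np.array_split(m, n_blocks))
        units = split
    if len(units) < folds:
        raise ParameterError(
            f"cannot form {folds} cross-validation units from the data"
        )
    return units


def _vamp2_score(train: LaggedCovariances, test: LaggedCovariances, k: int) -> float:
    """VAMP2 of the train model's top-k singular functions on test covariances.

    Test covariances are taken about the test mean, i.e. the singular
    functions are re-centred on the held-out data; the constant function then
    contributes exactly 1 and is added separately.
    """
    eps = default_regularization(train.C0)
    C0r = train.C0 + eps * np.eye(train.C0.shape[0])
    vals, vecs = scipy.linalg.eigh(train.Ctau, C0r)
    order = np.argsort(vals)[::-1]
    V = vecs[:, order[:k]]
    A = V.T @ test.C0 @ V
    B = V.T @ test.Ctau @ V
    # whiten by A
    w, U = scipy.linalg.eigh(A)
    w = np.clip(w, 1e-12, None)
    Ainv_half = U @ np.diag(w**-0.5) @ U.T
    M = Ainv_half @ B @ Ainv_half
    sv = scipy.linalg.svdvals(M)
    sv = np.minimum(sv, 1.0)
    return 1.0 + float(np.sum(sv**2))


def vamp2_score_cv(
    features,
    lags: Sequence[int],
    n_eigenvalues: int = 10,
    folds: int = 5,
    seed: int = 0,
    feature_type: str = "features",
) -> VAMP2Report:
    """Cross-validated VAMP2 scores of one feature set at several lags.

    Per fold, the leading (n_eigenvalues − 1) non-constant singular functions
    are estimated from the training covariances and scored on the held-out
    covariances; the constant function contributes a fixed 1, so a feature set
    carrying no dynamics scores ≈ 1.
    """
    mats = _as_matrices(features)
    k = n_eigenvalues - 1
    rows = []
    max_lag = max(lags)
    units = _cv_units(mats, folds, min_len=2 * (max_lag + 1))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    fold_ids = np.array_split(order, folds)
    for lag in lags:
        for f, test_ids in enumerate(fold_ids):
            test_set = set(int(i) for i in test_ids)
            train = [units[i] for i in range(len(units)) if i not in test_set]
            test = [units[i] for i in sorted(test_set)]
            try:
                cov_tr = estimate_lagged_covariances(train, lag)
                cov_te = estimate_lagged_covariances(test, lag)
            except ParameterError as exc:
                raise ParameterError(
                    f"insufficient frames for lag {lag} in fold {f}: {exc}"
                ) from exc
            rows.append(
                {"feature_type": feature_type, "lag": lag, "fold": f,
                 "score": _vamp2_score(cov_tr, cov_te, k)}
            )
    return VAMP2Report(pd.DataFrame(rows), n_eigenvalues, folds)


def score_feature_sets(
    feature_sets: dict[str, FeatureSet],
    lags: Sequence[int],
    n_eigenvalues: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> VAMP2Report:
    """Score several candidate feature sets and allow argmax selection.

    The selection rule mirrors standard practice: the winning feature type is
    the one with the highest mean VAMP2 score averaged across lag times
    (``VAMP2Report.best_feature_type``).
    """
    frames = []
    for name, fs in feature_sets.items():
        rep = vamp2_score_cv(fs, lags, n_eigenvalues, folds, seed, feature_type=name)
        frames.append(rep.scores)
    return VAMP2Report(pd.concat(frames, ignore_index=True), n_eigenvalues, folds)
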