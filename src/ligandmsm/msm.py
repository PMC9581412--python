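"""Microstate clustering, reversible MSM estimation, validation and weights.

The estimation chain is: k-means microstates in tIC space → sliding-window
transition counts at a lag τ → restriction to the largest mutually connected
set → maximum-likelihood reversible transition matrix via the detailed-balance
fixed point → spectral decomposition with π-orthonormal eigenvectors.

Validation tools: implied timescales across lags (with trajectory bootstrap
confidence intervals), GMRQ cross-validation for hyperparameter selection, and
the Chapman-Kolmogorov test.  Frame weights π_state/count_state turn the MSM
into an equilibrium reweighting of the raw frames for any observable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from ._exceptions import ConnectivityError, DataError, ParameterError

__all__ = [
    "MicrostateModel",
    "MSMModel",
    "FrameWeights",
    "cluster_microstates",
    "count_transitions",
    "estimate_reversible_msm",
    "estimate_msm_from_assignments",
    "compute_frame_weights",
    "implied_timescales",
    "gmrq_cv",
    "ck_test",
    "weighted_mean",
    "weighted_percentile",
    "free_energy_surface",
    "weighted_statistics",
]


# ---------------------------------------------------------------------------
# Microstate clustering
# ---------------------------------------------------------------------------

@dataclass
class MicrostateModel:
    centers: np.ndarray
    assignments: list[np.ndarray]
    k: int
    seed: int
    inertia: float = float("nan")

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.assignments)


def _as_coord_list(tic_coords) -> list[np.ndarray]:
    if isinstance(tic_coords, np.ndarray):
        return [np.atleast_2d(tic_coords)]
    return [np.atleast_2d(np.asarray(c, dtype=float)) for c in tic_coords]


def cluster_microstates(
    tic_coords,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    n_init: int = 5,
) -> MicrostateModel:
    """k-means microstates (k-means++ seeding, deterministic given seed)."""
    coords = _as_coord_list(tic_coords)
    X = np.concatenate(coords, axis=0)
    if k > X.shape[0]:
        raise ParameterError(f"k={k} exceeds the {X.shape[0]} available frames")
    km = KMeans(n_clusters=k, random_state=seed, max_iter=max_iter, n_init=n_init)
    km.fit(X)
    lengths = [c.shape[0] for c in coords]
    labels = np.split(km.labels_.astype(np.int64), np.cumsum(lengths)[:-1])
    return MicrostateModel(km.cluster_centers_, list(labels), k, seed, float(km.inertia_))


def assign_to_centers(tic_coords, centers: np.ndarray) -> list[np.ndarray]:
    """Nearest-center (Euclidean) assignment of new data."""
    out = []
    for c in _as_coord_list(tic_coords):
        d = ((c[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        out.append(np.argmin(d, axis=1).astype(np.int64))
    return out


# ---------------------------------------------------------------------------
# Counting and reversible estimation
# ---------------------------------------------------------------------------

def count_transitions(
    assignments, lag: int, n_states: int | None = None
) -> np.ndarray:
    """Sliding-window transition counts at the given lag.

    Every (t, t+lag) pair inside each trajectory contributes one count; pairs
    never cross trajectory boundaries.  Trajectories shorter than lag+1
    contribute nothing (with a warning).
    """
    if lag < 1:
        raise ParameterError("lag must be ≥ 1")
    seqs = [np.asarray(a, dtype=np.int64) for a in (
        [assignments] if isinstance(assignments, np.ndarray) else assignments
    )]
    if n_states is None:
        n_states = int(max(s.max() for s in seqs if s.size)) + 1
    C = np.zeros((n_states, n_states), dtype=np.int64)
    for i, s in enumerate(seqs):
        if s.size <= lag:
            warnings.warn(
                f"trajectory {i} ({s.size} frames) shorter than lag {lag}; skipped",
                stacklevel=2,
            )
            continue
        np.add.at(C, (s[:-lag], s[lag:]), 1)
    return C


@dataclass
class MSMModel:
    """A reversible Markov state model on the active (connected) set.

    ``T``, ``pi`` and the spectral quantities live on ``active_set`` indices;
    ``count_matrix`` is the full matrix on the original microstate labels.
    Eigenvectors are π-orthonormal: left φ_i = π ψ_i and Σ_s π_s ψ_i ψ_j = δ_ij.
    """

    count_matrix: np.ndarray
    active_set: np.ndarray
    T: np.ndarray
    pi: np.ndarray
    eigenvalues: np.ndarray
    right_eigenvectors: np.ndarray
    left_eigenvectors: np.ndarray
    lag_frames: int
    frame_spacing_ns: float = 1.0

    @property
    def lag_ns(self) -> float:
        return self.lag_frames * self.frame_spacing_ns

    @property
    def n_states(self) -> int:
        return self.active_set.size

    def timescales(self, n: int | None = None, in_ns: bool = True) -> np.ndarray:
        """Implied timescales −τ/ln λ_i, skipping the unit eigenvalue."""
        lam = self.eigenvalues[1:]
        unit = self.lag_ns if in_ns else self.lag_frames
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = np.where(lam > 0, -unit / np.log(np.clip(lam, 1e-300, 1)), np.nan)
        return ts[:n] if n is not None else ts

    def full_index(self) -> np.ndarray:
        """Map original microstate label → active-set index (−1 if excluded)."""
        idx = np.full(self.count_matrix.shape[0], -1, dtype=np.int64)
        idx[self.active_set] = np.arange(self.active_set.size)
        return idx


def _largest_connected_set(C: np.ndarray) -> np.ndarray:
    """Largest set mutually connected by bidirectional counts, by total counts."""
    mutual = (C > 0) & (C.T > 0)
    np.fill_diagonal(mutual, True)
    n_comp, labels = connected_components(mutual, directed=False)
    if n_comp == 1:
        return np.arange(C.shape[0])
    best, best_weight = None, -1.0
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        weight = C[np.ix_(members, members)].sum()
        if weight > best_weight:
            best, best_weight = members, weight
    return best


def reversible_mle(C: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood reversible transition matrix from a count matrix.

    Self-consistent iteration on the symmetric pair weights x_ij:
    x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j), the stationary point of the
    reversible likelihood; T_ij = x_ij/x_i and π_i = x_i/Σx at convergence.
    """
    C = np.asarray(C, dtype=float)
    c_row = C.sum(axis=1)
    if np.any(c_row == 0):
        raise ConnectivityError("count matrix has empty rows; restrict to the connected set")
    Csym = C + C.T
    x = Csym.copy()
    x_row = x.sum(axis=1)
    for _ in range(max_iter):
        q = c_row / x_row
        denom = q[:, None] + q[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(Csym > 0, Csym / denom, 0.0)
        x_row_new = x_new.sum(axis=1)
        delta = np.max(np.abs(x_row_new / x_row_new.sum() - x_row / x_row.sum()))
        x, x_row = x_new, x_row_new
        if delta < tol:
            break
    pi = x_row / x_row.sum()
    T = x / x_row[:, None]
    return T, pi


def estimate_reversible_msm(
    count_matrix: np.ndarray,
    lag: int,
    frame_spacing_ns: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> MSMModel:
    """Reversible MSM restricted to the largest mutually connected set."""
    C = np.asarray(count_matrix)
    if np.any(C < 0):
        raise DataError("counts must be non-negative")
    active = _largest_connected_set(C)
    Ca = C[np.ix_(active, active)].astype(float)
    if Ca.sum() == 0:
        raise ConnectivityError("no transition counts in the connected set")
    T, pi = reversible_mle(Ca, tol=tol, max_iter=max_iter)

    # spectral decomposition through the π-symmetrized matrix
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] / sqrt_pi[None, :]) * T
    S = (S + S.T) / 2
    vals, U = scipy.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals, U = vals[order], U[:, order]
    psi = U / sqrt_pi[:, None]      # right eigenvectors
    phi = U * sqrt_pi[:, None]      # left eigenvectors
    for j in range(psi.shape[1]):   # deterministic sign convention
        k = np.argmax(np.abs(psi[:, j]))
        if psi[k, j] < 0:
            psi[:, j] = -psi[:, j]
            phi[:, j] = -phi[:, j]
    vals = np.clip(vals, -1.0, 1.0)
    return MSMModel(
        count_matrix=np.asarray(count_matrix),
        active_set=active,
        T=T,
        pi=pi,
        eigenvalues=vals,
        right_eigenvectors=psi,
        left_eigenvectors=phi,
        lag_frames=int(lag),
        frame_spacing_ns=frame_spacing_ns,
    )


def msm_from_transition_matrix(
    T: np.ndarray, lag: int = 1, frame_spacing_ns: float = 1.0
) -> MSMModel:
    """Wrap an exact reversible row-stochastic matrix as an MSMModel.

    π comes from the dominant left eigenvector; detailed balance is required
    (checked).  Useful when the transition matrix is known analytically.
    """
    T = np.asarray(T, dtype=float)
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise DataError("T rows must sum to 1")
    vals, vecs = scipy.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(np.real(vecs[:, i]))
    pi = pi / pi.sum()
    flux = pi[:, None] * T
    if not np.allclose(flux, flux.T, atol=1e-8):
        raise DataError("T does not satisfy detailed balance")
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] / sqrt_pi[None, :]) * T
    S = (S + S.T) / 2
    ev, U = scipy.linalg.eigh(S)
    order = np.argsort(ev)[::-1]
    ev, U = ev[order], U[:, order]
    psi = U / sqrt_pi[:, None]
    phi = U * sqrt_pi[:, None]
    for j in range(psi.shape[1]):
        k = np.argmax(np.abs(psi[:, j]))
        if psi[k, j] < 0:
            psi[:, j] = -psi[:, j]
            phi[:, j] = -phi[:, j]
    n = T.shape[0]
    return MSMModel(np.zeros((n, n), dtype=np.int64), np.arange(n), T, pi,
                    np.clip(ev, -1.0, 1.0), psi, phi, int(lag), frame_spacing_ns)


def estimate_msm_from_assignments(
    assignments, lag: int, frame_spacing_ns: float = 1.0, n_states: int | None = None
) -> MSMModel:
    C = count_transitions(assignments, lag, n_states)
    return estimate_reversible_msm(C, lag, frame_spacing_ns)


# ---------------------------------------------------------------------------
# Frame weights and weighted statistics
# ---------------------------------------------------------------------------

@dataclass
class FrameWeights:
    """Per-frame equilibrium weights π_state / count_state.

    Frames whose microstate fell outside the MSM's active set carry weight 0
    and are flagged in ``included``; weights sum to 1 over included frames.
    """

    weights: list[np.ndarray]
    included: list[np.ndarray]

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.weights)

    def included_mask(self) -> np.ndarray:
        return np.concatenate(self.included)


def compute_frame_weights(msm: MSMModel, assignments) -> FrameWeights:
    seqs = [np.asarray(a, dtype=np.int64) for a in (
        [assignments] if isinstance(assignments, np.ndarray) else assignments
    )]
    idx = msm.full_index()
    counts = np.zeros(msm.n_states, dtype=np.int64)
    for s in seqs:
        mapped = idx[s]
        counts += np.bincount(mapped[mapped >= 0], minlength=msm.n_states)
    if counts.sum() == 0:
        raise DataError("no frames fall inside the MSM active set")
    per_state = np.where(counts > 0, msm.pi / np.maximum(counts, 1), 0.0)
    weights, included = [], []
    for s in seqs:
        mapped = idx[s]
        inc = mapped >= 0
        w = np.where(inc, per_state[np.clip(mapped, 0, None)], 0.0)
        weights.append(w)
        included.append(inc)
    total = sum(w.sum() for w in weights)
    weights = [w / total for w in weights]
    return FrameWeights(weights, included)


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise DataError("weights sum to zero")
    return float(np.dot(np.asarray(values, float), w) / w.sum())


def weighted_percentile(
    values: np.ndarray, weights: np.ndarray, q: float | Sequence[float]
):
    """Weighted percentile by linear interpolation of the weighted empirical CDF.

    Uses the left-continuous convention: order statistic x_(i) sits at
    cumulative position (S_i − w_i/2)/S_n; uniform weights reproduce numpy's
    default percentile interpolation in the large-n limit.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    v, w = v[keep], w[keep]
    if v.size == 0:
        raise DataError("weights sum to zero")
    order = np.argsort(v)
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    positions = (cw - 0.5 * w) / cw[-1]
    qs = np.atleast_1d(np.asarray(q, dtype=float)) / 100.0
    out = np.interp(qs, positions, v)
    return float(out[0]) if np.isscalar(q) else out


def free_energy_surface(
    coords: np.ndarray,
    weights: np.ndarray,
    bins: int = 60,
    extent=None,
) -> dict:
    """Free energy F = −ln(weight mass) per bin, shifted so min F = 0 (k_BT units).

    1-D or 2-D coordinates; empty bins get +inf (unbounded free energy).
    """
    x = np.atleast_2d(np.asarray(coords, dtype=float))
    if x.shape[0] in (1, 2) and x.shape[1] > 2:
        x = x.T
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise DataError("weights sum to zero")
    if x.shape[1] == 1:
        rng1d = extent[0] if (extent is not None and np.ndim(extent) == 2) else extent
        hist, edges = np.histogram(x[:, 0], bins=bins, range=rng1d, weights=w)
        edges = (edges,)
    elif x.shape[1] == 2:
        hist, ex, ey = np.histogram2d(x[:, 0], x[:, 1], bins=bins, range=extent, weights=w)
        edges = (ex, ey)
    else:
        raise ParameterError("free-energy surfaces support 1-D or 2-D coordinates")
    with np.errstate(divide="ignore"):
        F = -np.log(hist / hist.sum())
    F -= np.nanmin(F[np.isfinite(F)])
    return {"free_energy": F, "edges": edges}


def weighted_statistics(values, weights, kind: str = "mean", **kw):
    """Dispatcher over the weighted summaries: mean, percentile, free_energy."""
    if isinstance(weights, FrameWeights):
        weights = weights.concatenated()
    if kind == "mean":
        return weighted_mean(values, weights)
    if kind == "percentile":
        return weighted_percentile(values, weights, kw.pop("p"))
    if kind in ("free_energy", "histogram"):
        return free_energy_surface(values, weights, **kw)
    raise ParameterError(f"unknown statistic kind {kind!r}")


# ---------------------------------------------------------------------------
# Implied timescales
# ---------------------------------------------------------------------------

def implied_timescales(
    assignments,
    lags: Sequence[int],
    n_timescales: int = 5,
    frame_spacing_ns: float = 1.0,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Implied timescales t_i(τ) = −τ/ln λ_i(τ) across lag times.

    Returns a tidy table with columns lag_frames, lag_ns, process (2 = slowest
    non-stationary), timescale_ns, ci_low, ci_high and a ``below_lag`` flag
    marking the unresolved region t_i < τ.  Non-positive eigenvalues yield NaN
    timescales rather than an exception.  Confidence intervals (2.5/97.5
    percentiles) come from a trajectory-level bootstrap.
    """
    seqs = [np.asarray(a, dtype=np.int64) for a in (
        [assignments] if isinstance(assignments, np.ndarray) else assignments
    )]
    n_states = int(max(s.max() for s in seqs)) + 1
    rng = np.random.default_rng(seed)
    rows = []
    for lag in lags:
        msm = estimate_msm_from_assignments(seqs, lag, frame_spacing_ns, n_states)
        ts = msm.timescales(n_timescales)
        boots = np.full((n_bootstrap, n_timescales), np.nan)
        for b in range(n_bootstrap):
            pick = rng.integers(0, len(seqs), size=len(seqs))
            try:
                m = estimate_msm_from_assignments(
                    [seqs[i] for i in pick], lag, frame_spacing_ns, n_states
                )
                t = m.timescales(n_timescales)
                boots[b, : t.size] = t[:n_timescales]
            except (ConnectivityError, DataError):
                continue
        for i in range(min(n_timescales, ts.size)):
            if n_bootstrap and np.isfinite(boots[:, i]).any():
                lo, hi = np.nanpercentile(boots[:, i], [2.5, 97.5])
            else:
                lo = hi = np.nan
            rows.append(
                {
                    "lag_frames": lag,
                    "lag_ns": lag * frame_spacing_ns,
                    "process": i + 2,
                    "timescale_ns": ts[i],
                    "ci_low": lo,
                    "ci_high": hi,
                    "below_lag": bool(np.isnan(ts[i]) or ts[i] < lag * frame_spacing_ns),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GMRQ cross-validation
# ---------------------------------------------------------------------------

def _gmrq_score(
    train_msm: MSMModel, test_assignments: list[np.ndarray], n_processes: int, lag: int
) -> float:
    """Rayleigh-quotient trace of the train model's eigenfunctions on test data.

    Eigenfunctions (constant included) are evaluated along the test
    trajectories; pair-symmetrized second-moment matrices keep every
    generalized eigenvalue in [−1, 1], so the score is bounded by n_processes.
    """
    idx = train_msm.full_index()
    psi = train_msm.right_eigenvectors[:, :n_processes]
    C00 = np.zeros((n_processes, n_processes))
    C0t = np.zeros((n_processes, n_processes))
    n_pairs = 0
    dropped = 0
    for s in test_assignments:
        if s.size <= lag:
            continue
        m = idx[s]
        a, b = m[:-lag], m[lag:]
        ok = (a >= 0) & (b >= 0)
        dropped += int((~ok).sum())
        a, b = a[ok], b[ok]
        if a.size == 0:
            continue
        F, G = psi[a], psi[b]
        C00 += F.T @ F + G.T @ G
        C0t += F.T @ G + G.T @ F
        n_pairs += a.size
    if n_pairs == 0:
        raise DataError("no test pairs overlap the training model's active set")
    if dropped:
        warnings.warn(
            f"{dropped} test pairs dropped (microstates unseen in training)", stacklevel=2
        )
    C00 /= 2 * n_pairs
    C0t /= 2 * n_pairs
    C00 += 1e-10 * np.eye(n_processes)
    return float(np.trace(scipy.linalg.solve(C00, C0t, assume_a="sym")))


def gmrq_cv(
    tic_coords,
    k_values: Sequence[int],
    n_processes: int = 5,
    folds: int = 5,
    lag: int = 1,
    seed: int = 0,
    frame_spacing_ns: float = 1.0,
) -> pd.DataFrame:
    """GMRQ cross-validation over microstate counts.

    For each fold: cluster and estimate the MSM on the training trajectories,
    then score the top ``n_processes`` eigenfunctions (constant included) on
    the held-out trajectories.  Returns mean ± std per k.
    """
    coords = _as_coord_list(tic_coords)
    units = coords
    if len(units) < folds:
        per = int(np.ceil(folds / len(units)))
        units = [blk for c in units for blk in np.array_split(c, per)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    fold_ids = np.array_split(order, folds)
    rows = []
    for k in k_values:
        for f, test_ids in enumerate(fold_ids):
            test_set = set(int(i) for i in test_ids)
            train = [units[i] for i in range(len(units)) if i not in test_set]
            test = [units[i] for i in sorted(test_set)]
            micro = cluster_microstates(train, k, seed=seed + f)
            msm = estimate_msm_from_assignments(
                micro.assignments, lag, frame_spacing_ns, n_states=k
            )
            test_assign = assign_to_centers(test, micro.centers)
            score = _gmrq_score(msm, test_assign, n_processes, lag)
            rows.append({"k": k, "fold": f, "score": score})
    df = pd.DataFrame(rows)
    out = df.groupby("k")["score"].agg(["mean", "std"]).reset_index()
    out["std"] = out["std"].fillna(0.0)
    return out


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

def _set_transition_probability(
    msm: MSMModel, Tk: np.ndarray, sets: list[np.ndarray]
) -> np.ndarray:
    """π-weighted set-to-set transition probabilities under a propagator."""
    idx = msm.full_index()
    n = len(sets)
    P = np.zeros((n, n))
    for a, A in enumerate(sets):
        ia = idx[A]
        ia = ia[ia >= 0]
        wa = msm.pi[ia]
        if wa.sum() == 0:
            P[a] = np.nan
            continue
        for b, B in enumerate(sets):
            ib = idx[B]
            ib = ib[ib >= 0]
            P[a, b] = float(wa @ Tk[np.ix_(ia, ib)].sum(axis=1) / wa.sum())
    return P


def ck_test(
    assignments,
    macrostate_sets: Sequence[Sequence[int]],
    lag: int,
    k_multiples: Sequence[int] = (1, 2, 3, 4, 5),
    frame_spacing_ns: float = 1.0,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Chapman-Kolmogorov test on macrostate sets.

    Predicted: set-to-set transition probabilities under T(τ)^k.  Estimated:
    the same quantity from an MSM re-estimated at lag k·τ.  Agreement across
    k is the Markovianity check; bootstrap CIs are on the estimated curve.
    """
    seqs = [np.asarray(a, dtype=np.int64) for a in (
        [assignments] if isinstance(assignments, np.ndarray) else assignments
    )]
    n_states = int(max(s.max() for s in seqs)) + 1
    sets = [np.asarray(sorted(S), dtype=np.int64) for S in macrostate_sets]
    base = estimate_msm_from_assignments(seqs, lag, frame_spacing_ns, n_states)
    min_len = min(s.size for s in seqs)
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_multiples:
        if lag * k >= min_len:
            warnings.warn(f"k={k} exceeds the data length; truncating", stacklevel=2)
            break
        predicted = _set_transition_probability(
            base, np.linalg.matrix_power(base.T, k), sets
        )
        est_msm = estimate_msm_from_assignments(seqs, lag * k, frame_spacing_ns, n_states)
        estimated = _set_transition_probability(est_msm, est_msm.T, sets)
        boots = np.full((n_bootstrap, len(sets), len(sets)), np.nan)
        for b in range(n_bootstrap):
            pick = rng.integers(0, len(seqs), size=len(seqs))
            try:
                m = estimate_msm_from_assignments(
                    [seqs[i] for i in pick], lag * k, frame_spacing_ns, n_states
                )
                boots[b] = _set_transition_probability(m, m.T, sets)
            except (ConnectivityError, DataError):
                continue
        for a in range(len(sets)):
            for bset in range(len(sets)):
                if n_bootstrap and np.isfinite(boots[:, a, bset]).any():
                    lo, hi = np.nanpercentile(boots[:, a, bset], [2.5, 97.5])
                else:
                    lo = hi = np.nan
                rows.append(
                    {"k": k, "lag_frames": lag * k, "from_set": a, "to_set": bset,
                     "predicted": predicted[a, bset], "estimated": estimated[a, bset],
                     "ci_low": lo, "ci_high": hi}
                )
    return pd.DataFrame(rows)
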