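"""Metastable macrostates: spectral-gap selection, PCCA+ memberships, cores, MFPTs.

PCCA+ exploits the simplex structure of the leading right eigenvectors of a
reversible transition matrix: rows of the eigenvector matrix lie (up to noise)
inside a simplex whose vertices correspond to maximally pure microstates.  A
vertex search followed by the inverse linear transform yields fuzzy membership
vectors; negative entries are clipped and rows renormalized (the feasibility-
repaired variant without the final crispness optimization — deterministic and
adequate for gapped systems).

Core states re-express memberships at frame level: a frame belongs to a
macrostate only when its membership exceeds a threshold (default 0.8);
everything else is a transition frame.  MFPTs between macrostates are computed
from microstate hitting times (exact dense linear solve) aggregated with
stationary weights over the source set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from ._exceptions import ConnectivityError, DataError, ParameterError
from .msm import MSMModel, estimate_msm_from_assignments
from .synthetic import hitting_times

__all__ = [
    "SpectralGapReport",
    "MacrostateModel",
    "select_n_macrostates",
    "pcca_memberships",
    "frame_memberships",
    "assign_cores",
    "macrostate_stationary",
    "mfpt_between_macrostates",
    "crisp_sets",
    "build_macrostate_model",
]

TRANSITION = -1  # core-assignment code for unassigned (transition) frames


@dataclass
class SpectralGapReport:
    timescales: np.ndarray
    gap_ratios: np.ndarray      # gap_ratios[i] = t_{i+2} / t_{i+3}
    recommended_n: int
    confident: bool


def select_n_macrostates(
    msm: MSMModel, max_n: int | None = None, confidence_ratio: float = 2.0
) -> SpectralGapReport:
    """Recommend a macrostate count from the relaxation-timescale spectrum.

    The gap after the (n−1)-th slowest relaxation timescale separates n
    metastable sets; the recommendation is the n maximizing t_{n}/t_{n+1}.
    A flat spectrum (best ratio below ``confidence_ratio``) is flagged
    low-confidence, and the user may override the recommendation.
    """
    ts = msm.timescales()
    ts = ts[np.isfinite(ts)]
    if max_n is not None:
        ts = ts[: max_n]
    if ts.size < 2:
        raise ParameterError("need at least 3 eigenvalues to look for a spectral gap")
    ratios = ts[:-1] / ts[1:]
    best = int(np.argmax(ratios))
    # ratios[i] is the gap after timescale i+2 → recommends i+2 macrostates
    return SpectralGapReport(
        timescales=ts,
        gap_ratios=ratios,
        recommended_n=best + 2,
        confident=bool(ratios[best] >= confidence_ratio),
    )


def pcca_memberships(msm: MSMModel, n_macro: int) -> np.ndarray:
    """PCCA+ fuzzy memberships of the active microstates.

    Returns an ``(n_states, n_macro)`` row-stochastic matrix.  Requires a
    reversible model (real eigenvalues) with at least n_macro positive
    eigenvalues.
    """
    if n_macro < 1:
        raise ParameterError("n_macro must be ≥ 1")
    n = msm.n_states
    if n_macro == 1:
        return np.ones((n, 1))
    if n_macro > n:
        raise ParameterError("n_macro exceeds the number of microstates")
    if np.iscomplexobj(msm.eigenvalues):
        raise ParameterError("complex eigenvalues: the model is not reversible")
    if (msm.eigenvalues[:n_macro] <= 0).any():
        raise ParameterError(
            f"need {n_macro} positive eigenvalues, spectrum has "
            f"{int((msm.eigenvalues > 0).sum())}"
        )
    X = msm.right_eigenvectors[:, :n_macro].copy()
    X[:, 0] = 1.0  # exact constant eigenfunction

    vertices = _inner_simplex_vertices(X)
    A = scipy.linalg.inv(X[vertices])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    rows = chi.sum(axis=1)
    rows[rows == 0] = 1.0
    return chi / rows[:, None]


def _inner_simplex_vertices(X: np.ndarray) -> np.ndarray:
    """Greedy vertex search: the most mutually spread rows of X."""
    n, m = X.shape
    # first vertex: farthest row from the centroid
    d = np.linalg.norm(X - X.mean(axis=0), axis=1)
    verts = [int(np.argmax(d))]
    basis = np.zeros((m, 0))
    for _ in range(1, m):
        diff = X - X[verts[0]]
        if basis.shape[1]:
            diff = diff - (diff @ basis) @ basis.T
        norms = np.linalg.norm(diff, axis=1)
        norms[verts] = -np.inf
        nxt = int(np.argmax(norms))
        verts.append(nxt)
        v = X[nxt] - X[verts[0]]
        if basis.shape[1]:
            v = v - basis @ (basis.T @ v)
        nv = np.linalg.norm(v)
        if nv > 0:
            basis = np.column_stack([basis, v / nv])
    return np.asarray(verts)


def frame_memberships(
    memberships: np.ndarray, msm: MSMModel, assignments
) -> list[np.ndarray]:
    """Per-frame macrostate membership rows (NaN rows outside the active set)."""
    seqs = [np.asarray(a, dtype=np.int64) for a in (
        [assignments] if isinstance(assignments, np.ndarray) else assignments
    )]
    idx = msm.full_index()
    out = []
    for s in seqs:
        mapped = idx[s]
        rows = np.full((s.size, memberships.shape[1]), np.nan)
        ok = mapped >= 0
        rows[ok] = memberships[mapped[ok]]
        out.append(rows)
    return out


def assign_cores(
    frame_membership_rows, core_threshold: float = 0.8
) -> list[np.ndarray]:
    """Core assignment: argmax macrostate where max membership > threshold.

    Frames below the threshold (or outside the active set) get the sentinel
    ``TRANSITION`` (−1).  Ties break toward the lower macrostate index.
    """
    if not (0.5 <= core_threshold <= 1.0):
        raise ParameterError("core_threshold must lie in [0.5, 1]")
    blocks = (
        [frame_membership_rows]
        if isinstance(frame_membership_rows, np.ndarray) and frame_membership_rows.ndim == 2
        else list(frame_membership_rows)
    )
    out = []
    for rows in blocks:
        rows = np.asarray(rows, dtype=float)
        best = np.nanmax(rows, axis=1, initial=-np.inf)
        arg = np.argmax(np.nan_to_num(rows, nan=-np.inf), axis=1)
        assigned = np.where(best > core_threshold, arg, TRANSITION)
        out.append(assigned.astype(np.int64))
    return out


def macrostate_stationary(
    msm: MSMModel,
    memberships: np.ndarray,
    assignments=None,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Macrostate stationary probabilities macro_π_A = Σ_i π_i χ_iA.

    With ``assignments`` given, uncertainties are estimated by re-estimating
    the MSM on trajectory bootstrap resamples (memberships held fixed).
    """
    macro_pi = memberships.T @ msm.pi
    std = np.zeros_like(macro_pi)
    if n_bootstrap and assignments is not None:
        seqs = [np.asarray(a, dtype=np.int64) for a in (
            [assignments] if isinstance(assignments, np.ndarray) else assignments
        )]
        rng = np.random.default_rng(seed)
        samples = []
        for _ in range(n_bootstrap):
            pick = rng.integers(0, len(seqs), size=len(seqs))
            try:
                m = estimate_msm_from_assignments(
                    [seqs[i] for i in pick], msm.lag_frames, msm.frame_spacing_ns,
                    n_states=msm.count_matrix.shape[0],
                )
            except (ConnectivityError, DataError):
                continue
            if not np.array_equal(m.active_set, msm.active_set):
                # map π back onto the reference active set
                pi_full = np.zeros(msm.count_matrix.shape[0])
                pi_full[m.active_set] = m.pi
                pi_b = pi_full[msm.active_set]
                if pi_b.sum() == 0:
                    continue
                pi_b = pi_b / pi_b.sum()
            else:
                pi_b = m.pi
            samples.append(memberships.T @ pi_b)
        if samples:
            std = np.std(np.asarray(samples), axis=0)
    return macro_pi, std


def crisp_sets(memberships: np.ndarray, active_set: np.ndarray | None = None
               ) -> list[np.ndarray]:
    """Crisp macrostate sets by argmax membership (lower index wins ties)."""
    arg = np.argmax(memberships, axis=1)
    n_macro = memberships.shape[1]
    states = np.arange(memberships.shape[0]) if active_set is None else np.asarray(active_set)
    return [states[arg == a] for a in range(n_macro)]


def mfpt_between_macrostates(
    msm: MSMModel,
    macrostate_sets: Sequence[Sequence[int]],
    assignments=None,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean first passage times between macrostate sets, in ns.

    Sets are given in original microstate labels, must be disjoint, non-empty
    and inside the active set.  MFPT(A→B) averages the exact microstate
    hitting times over the source set with stationary weights; an unreachable
    target yields +inf.  Returns (mfpt, std) with std from trajectory
    bootstrap when assignments are provided.
    """
    idx = msm.full_index()
    sets = []
    seen: set[int] = set()
    for S in macrostate_sets:
        S = sorted(int(s) for s in S)
        if not S:
            raise ParameterError("macrostate sets must be non-empty")
        if seen & set(S):
            raise ParameterError("macrostate sets must be disjoint")
        seen |= set(S)
        mapped = idx[np.asarray(S)]
        if (mapped < 0).any():
            raise ParameterError("macrostate sets must lie inside the active set")
        sets.append(mapped)

    def _mfpt(model: MSMModel, mapped_sets) -> np.ndarray:
        n = len(mapped_sets)
        out = np.zeros((n, n))
        for b, B in enumerate(mapped_sets):
            h = hitting_times(model.T, B, lag=model.lag_ns)
            for a, A in enumerate(mapped_sets):
                if a == b:
                    continue
                w = model.pi[A]
                out[a, b] = float(w @ h[A] / w.sum())
        return out

    mfpt = _mfpt(msm, sets)
    std = np.zeros_like(mfpt)
    if n_bootstrap and assignments is not None:
        seqs = [np.asarray(a, dtype=np.int64) for a in (
            [assignments] if isinstance(assignments, np.ndarray) else assignments
        )]
        rng = np.random.default_rng(seed)
        samples = []
        full_sets = [np.asarray(sorted(int(s) for s in S)) for S in macrostate_sets]
        for _ in range(n_bootstrap):
            pick = rng.integers(0, len(seqs), size=len(seqs))
            try:
                m = estimate_msm_from_assignments(
                    [seqs[i] for i in pick], msm.lag_frames, msm.frame_spacing_ns,
                    n_states=msm.count_matrix.shape[0],
                )
                midx = m.full_index()
                msets = []
                for S in full_sets:
                    mm = midx[S]
                    mm = mm[mm >= 0]
                    if mm.size == 0:
                        raise DataError("set outside bootstrap active set")
                    msets.append(mm)
                samples.append(_mfpt(m, msets))
            except (ConnectivityError, DataError):
                continue
        if samples:
            std = np.std(np.asarray(samples), axis=0)
    return mfpt, std


@dataclass
class MacrostateModel:
    """Bundle of the macrostate-level description of an MSM."""

    n_macro: int
    memberships: np.ndarray                 # microstate-level, rows on the simplex
    frame_membership_rows: list[np.ndarray]
    core_threshold: float
    core_assignment: list[np.ndarray]       # −1 = transition frame
    macro_pi: np.ndarray
    macro_pi_std: np.ndarray
    mfpt: np.ndarray                        # ns
    mfpt_std: np.ndarray
    sets: list[np.ndarray]                  # crisp microstate sets (original labels)


def build_macrostate_model(
    msm: MSMModel,
    assignments,
    n_macro: int,
    core_threshold: float = 0.8,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> MacrostateModel:
    """PCCA+ memberships, cores, populations and MFPTs in one pass."""
    chi = pcca_memberships(msm, n_macro)
    rows = frame_memberships(chi, msm, assignments)
    cores = assign_cores(rows, core_threshold)
    macro_pi, macro_std = macrostate_stationary(
        msm, chi, assignments, n_bootstrap=n_bootstrap, seed=seed
    )
    sets = crisp_sets(chi, msm.active_set)
    mfpt, mfpt_std = mfpt_between_macrostates(
        msm, [s for s in sets if s.size], assignments,
        n_bootstrap=n_bootstrap, seed=seed,
    )
    return MacrostateModel(
        n_macro, chi, rows, core_threshold, cores,
        macro_pi, macro_std, mfpt, mfpt_std, sets,
    )
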