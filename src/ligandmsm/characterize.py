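"""Structural summaries of macrostates.

For each macrostate core ensemble this module provides: a representative frame
(the one with the lowest mean ligand RMSD to all other frames after protein
superposition), contact-frequency maps and their between-state deltas,
equilibrium-weighted distance distribution summaries (median and 5th/95th
percentiles), and per-residue secondary-structure class frequencies.  All
ensemble averages are weighted by the MSM stationary frame weights so they are
equilibrium expectations rather than raw trajectory averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import DataError, ParameterError
from .msm import FrameWeights, weighted_percentile

__all__ = [
    "kabsch_align",
    "apply_alignment",
    "representative_frame",
    "contact_frequency",
    "contact_frequency_delta",
    "distance_distribution_summary",
    "ss_frequency",
]

SS_CLASSES = ("H", "E", "C")


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------

def kabsch_align(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch algorithm).

    Returns (rotation, translation, rmsd) such that ``mobile @ R + t`` best
    superposes onto the reference over the selected atoms.  Reflections are
    excluded by the determinant correction; degenerate (collinear) selections
    raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise ParameterError("need at least 3 atoms for superposition")
    P = mobile[sel]
    Q = reference[sel]
    if P.shape != Q.shape:
        raise ParameterError("mobile and reference selections differ in size")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear selections leave the rotation about the axis undetermined
    if S[1] <= 1e-12 * max(S[0], 1.0):
        raise ParameterError("degenerate (collinear) atom selection")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = cq - cp @ R
    diff = P0 @ R - Q0
    rmsd = float(np.sqrt((diff**2).sum() / sel.size))
    return R, t, rmsd


def apply_alignment(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R + t


# ---------------------------------------------------------------------------
# Representative frames
# ---------------------------------------------------------------------------

def representative_frame(
    frames: np.ndarray,
    protein_selection: np.ndarray,
    ligand_selection: np.ndarray,
    max_frames: int = 2000,
    seed: int = 0,
) -> tuple[int, float]:
    """Frame with the lowest mean ligand RMSD to every other frame.

    All frames are superposed on the protein selection against the ensemble
    mean structure (two alignment passes, which makes the result independent
    of frame ordering up to noise); ligand RMSDs are then plain coordinate
    RMSDs.  For ensembles larger than ``max_frames`` a seeded uniform
    subsample bounds the O(n²) cost; the returned index refers to the
    original frame ordering.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ParameterError("frames must be (n_frames, n_atoms, 3)")
    n = frames.shape[0]
    if n == 0:
        raise DataError("empty macrostate: no frames to summarize")
    if n > max_frames:
        rng = np.random.default_rng(seed)
        subsample = np.sort(rng.choice(n, size=max_frames, replace=False))
    else:
        subsample = np.arange(n)
    sub = frames[subsample]
    m = sub.shape[0]

    # reference: order-independent start (mean of protein-centred frames),
    # then two rounds of align-to-mean
    prot = np.asarray(protein_selection)
    ref = sub.mean(axis=0)
    for _ in range(2):
        aligned = np.empty_like(sub)
        for i, xyz in enumerate(sub):
            R, t, _ = kabsch_align(xyz, ref, prot)
            aligned[i] = apply_alignment(xyz, R, t)
        ref = aligned.mean(axis=0)
    lig = aligned[:, np.asarray(ligand_selection)]

    mean_rmsd = np.empty(m)
    chunk = max(1, int(2e6 // max(m, 1)))
    for start in range(0, m, chunk):
        block = lig[start : start + chunk]
        d2 = ((block[:, None, :, :] - lig[None, :, :, :]) ** 2).sum(axis=(2, 3))
        mean_rmsd[start : start + chunk] = (
            np.sqrt(d2 / lig.shape[1]).sum(axis=1) / max(m - 1, 1)
        )
    best = int(np.argmin(mean_rmsd))
    return int(subsample[best]), float(mean_rmsd[best])


# ---------------------------------------------------------------------------
# Contact frequencies
# ---------------------------------------------------------------------------

def _concat(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x
    return np.concatenate([np.asarray(b) for b in x], axis=0)


def _weights_of(weights) -> np.ndarray:
    if isinstance(weights, FrameWeights):
        return weights.concatenated()
    return np.asarray(weights, dtype=float)


def contact_frequency(
    distances,
    core_assignment,
    weights,
    state: int,
    cutoff: float = 6.0,
) -> np.ndarray:
    """Weighted fraction of a state's frames in contact, per pair.

    ``distances`` are per-frame distance tables (frames first axis); a contact
    is a distance below the cutoff.  Weights are renormalized inside the state.
    """
    d = _concat(distances)
    labels = _concat(core_assignment)
    w = _weights_of(weights)
    mask = labels == state
    if not mask.any():
        raise DataError(f"macrostate {state} has no core frames")
    ws = w[mask]
    if ws.sum() == 0:
        ws = np.ones(mask.sum())
    ws = ws / ws.sum()
    contact = (d[mask] < cutoff).astype(float)
    return np.clip(np.tensordot(ws, contact, axes=(0, 0)), 0.0, 1.0)


def contact_frequency_delta(
    distances,
    core_assignment,
    weights,
    state_a: int,
    state_b: int,
    cutoff: float = 6.0,
) -> dict:
    """Contact-frequency maps of two states and their A − B delta in [−1, 1]."""
    fa = contact_frequency(distances, core_assignment, weights, state_a, cutoff)
    fb = contact_frequency(distances, core_assignment, weights, state_b, cutoff)
    return {"freq_a": fa, "freq_b": fb, "delta": fa - fb}


# ---------------------------------------------------------------------------
# Distance distributions
# ---------------------------------------------------------------------------

def distance_distribution_summary(
    pair_distances,
    core_assignment,
    weights,
    pair_labels: list[tuple] | None = None,
    states: list[int] | None = None,
    references: dict | None = None,
) -> pd.DataFrame:
    """Per-state weighted median and 5th/95th percentiles of pair distances.

    ``references`` may attach annotation distances (e.g. measured on external
    structures) per pair label; they are merged in as extra columns.
    """
    d = _concat(pair_distances)
    labels = _concat(core_assignment)
    w = _weights_of(weights)
    if states is None:
        states = sorted(int(s) for s in np.unique(labels) if s >= 0)
    if pair_labels is None:
        pair_labels = [("p", j) for j in range(d.shape[1])]
    rows = []
    for s in states:
        mask = labels == s
        if not mask.any():
            continue
        ws = w[mask]
        if ws.sum() == 0:
            ws = np.ones(mask.sum())
        for j, lab in enumerate(pair_labels):
            p5, med, p95 = weighted_percentile(d[mask, j], ws, [5.0, 50.0, 95.0])
            row = {"state": s, "pair": lab, "p5": p5, "median": med, "p95": p95}
            if references and lab in references:
                row["reference"] = references[lab]
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Secondary-structure frequencies
# ---------------------------------------------------------------------------

def ss_frequency(
    ss_labels,
    core_assignment,
    weights,
    states: list[int] | None = None,
) -> dict[int, np.ndarray]:
    """Weighted per-residue secondary-structure class frequencies per state.

    ``ss_labels`` are per-frame per-residue characters in {H, E, C} (helix,
    sheet, coil), typically produced by an external secondary-structure
    assignment run.  Returns, per state, an ``(n_residues, 3)`` array whose
    rows sum to 1 in the class order (H, E, C).
    """
    lab = _concat(ss_labels)
    lab = np.asarray(lab)
    if lab.dtype.kind in "SU":
        sym = np.char.upper(lab.astype(str))
    else:
        raise ParameterError("secondary-structure labels must be characters")
    unknown = set(np.unique(sym)) - set(SS_CLASSES)
    if unknown:
        raise DataError(f"unknown secondary-structure symbols: {sorted(unknown)}")
    assign = _concat(core_assignment)
    w = _weights_of(weights)
    if states is None:
        states = sorted(int(s) for s in np.unique(assign) if s >= 0)
    out = {}
    for s in states:
        mask = assign == s
        if not mask.any():
            raise DataError(f"macrostate {s} has no core frames")
        ws = w[mask]
        if ws.sum() == 0:
            ws = np.ones(mask.sum())
        ws = ws / ws.sum()
        freq = np.stack(
            [np.tensordot(ws, (sym[mask] == c).astype(float), axes=(0, 0))
             for c in SS_CLASSES], axis=1
        )
        out[s] = freq
    return out


def ss_frequency_delta(freq_a: np.ndarray, freq_b: np.ndarray) -> np.ndarray:
    """Per-residue per-class frequency difference between two ensembles."""
    return np.asarray(freq_a) - np.asarray(freq_b)
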