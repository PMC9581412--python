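"""Seed selection for adaptive sampling rounds.

Two rules for picking the frames from which new simulations are launched:

* **tIC-grid seeding** — lay a uniform grid over the rectangular extent of the
  first two tICs and pick, for each grid target, the nearest data frame.  This
  spreads seeds across free-energy basins *and* barriers with equal weight,
  the strategy used to start the first unbiased round from enhanced-sampling
  data.

* **inverse-π selection** — draw microstates with probability proportional to
  1/π_i so that rarely visited regions are preferentially re-seeded; a member
  frame of each drawn microstate is then chosen uniformly.  Sampling is with
  replacement.  An inverse-counts variant is available as a flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._exceptions import DataError, ParameterError
from .msm import MSMModel

__all__ = ["SeedSelection", "tic_grid_seeds", "inverse_pi_selection",
           "inverse_pi_probabilities"]


@dataclass
class SeedSelection:
    """Frames (trajectory, frame index) selected for re-seeding."""

    selected_frames: list[tuple[int, int]]
    rule: str
    seed: int
    selected_states: np.ndarray | None = None
    targets: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "rule": self.rule,
                "seed": self.seed,
                "selected_frames": [list(f) for f in self.selected_frames],
                "selected_states": None
                if self.selected_states is None
                else self.selected_states.tolist(),
            },
            indent=1,
        )


def _grid_targets(low: np.ndarray, high: np.ndarray, n_points: int) -> np.ndarray:
    nx = int(np.ceil(np.sqrt(n_points)))
    ny = int(np.ceil(n_points / nx))
    gx = np.linspace(low[0], high[0], nx) if nx > 1 else np.array([(low[0] + high[0]) / 2])
    gy = np.linspace(low[1], high[1], ny) if ny > 1 else np.array([(low[1] + high[1]) / 2])
    grid = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    return grid[:n_points]


def tic_grid_seeds(tic_coords, n_points: int, seed: int = 0) -> SeedSelection:
    """Uniform-grid seeds over the (tIC1, tIC2) extent.

    For each of ``n_points`` grid targets the nearest data frame (Euclidean in
    the 2-D projection) is selected; a frame already taken is replaced by the
    next-nearest.  If the data collapse to a point, the single frame is
    returned once with a warning.
    """
    coords = (
        [np.atleast_2d(tic_coords)] if isinstance(tic_coords, np.ndarray)
        else [np.atleast_2d(np.asarray(c, float)) for c in tic_coords]
    )
    X = np.concatenate(coords, axis=0)[:, :2]
    if n_points > X.shape[0]:
        raise ParameterError(f"n_points={n_points} exceeds the {X.shape[0]} frames")
    refs = []
    offset = 0
    for t, c in enumerate(coords):
        refs.extend((t, i) for i in range(c.shape[0]))
        offset += c.shape[0]
    low, high = X.min(axis=0), X.max(axis=0)
    targets = _grid_targets(low, high, n_points)
    tree = cKDTree(X)
    chosen: list[int] = []
    degenerate = bool(np.allclose(low, high))
    for tgt in targets:
        k = 1
        while True:
            _, idx = tree.query(tgt, k=k)
            cand = np.atleast_1d(idx)
            new = [int(i) for i in cand if int(i) not in chosen]
            if new:
                chosen.append(new[0])
                break
            if k >= X.shape[0]:
                break  # all frames taken (duplicate-point data)
            k = min(2 * k, X.shape[0])
    if degenerate:
        warnings.warn("all frames identical: returning the single frame once", stacklevel=2)
        chosen = chosen[:1]
    return SeedSelection(
        [refs[i] for i in chosen], rule="tic_grid", seed=seed, targets=targets
    )


def inverse_pi_probabilities(pi: np.ndarray) -> np.ndarray:
    """Selection probabilities ∝ 1/π_i, normalized."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise DataError("stationary probabilities must be strictly positive")
    inv = 1.0 / pi
    return inv / inv.sum()


def inverse_pi_selection(
    msm: MSMModel,
    n_seeds: int,
    seed: int = 0,
    assignments=None,
    use_counts: bool = False,
) -> SeedSelection:
    """Microstate seeds drawn inversely proportional to stationary probability.

    With ``use_counts`` the weighting is 1/(visit counts) instead of 1/π.
    When assignments are provided, a member frame of each drawn microstate is
    chosen uniformly at random; otherwise only microstate indices are
    returned.  Drawing is with replacement.
    """
    if msm.n_states == 0:
        raise DataError("empty active set")
    rng = np.random.default_rng(seed)
    if use_counts:
        counts = msm.count_matrix[np.ix_(msm.active_set, msm.active_set)].sum(axis=1)
        p = inverse_pi_probabilities(counts / counts.sum())
    else:
        p = inverse_pi_probabilities(msm.pi)
    states_local = rng.choice(msm.n_states, size=n_seeds, p=p)
    states = msm.active_set[states_local]

    frames: list[tuple[int, int]] = []
    if assignments is not None:
        seqs = [np.asarray(a, dtype=np.int64) for a in (
            [assignments] if isinstance(assignments, np.ndarray) else assignments
        )]
        pools = {}
        for s in np.unique(states):
            pool = [
                (t, int(i))
                for t, seq in enumerate(seqs)
                for i in np.flatnonzero(seq == s)
            ]
            if not pool:
                raise DataError(f"no frames assigned to microstate {s}")
            pools[int(s)] = pool
        for s in states:
            pool = pools[int(s)]
            frames.append(pool[rng.integers(len(pool))])
    return SeedSelection(frames, rule="inverse_pi", seed=seed, selected_states=states)
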