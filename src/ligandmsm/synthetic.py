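"""Synthetic trajectory data with analytic kinetic ground truth.

Two surrogates are generated:

1. **Metastable Markov chains** — block-structured, reversible-by-construction
   transition matrices with known stationary distribution, implied timescales
   and mean first passage times, plus state trajectories sampled from them and
   Gaussian feature emissions conditioned on the hidden state.

2. **Toy bead complexes** — a ring of "protein" beads (one bead per residue)
   with a small "ligand" whose placement switches between a few designed
   binding modes, each with a distinct residue-contact pattern.  This mimics
   the geometry of a small ligand exploring discrete poses inside a protein
   pocket while keeping the true mode kinetics exactly known.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from ._exceptions import ConnectivityError, ParameterError
from .featurization import FeatureSet, Topology, TrajectoryEnsemble

__all__ = [
    "MetastableChainSpec",
    "SyntheticGroundTruth",
    "ToyComplexSpec",
    "build_metastable_chain",
    "analytic_ground_truth",
    "sample_discrete_trajectories",
    "emit_feature_trajectories",
    "generate_toy_complex_trajectories",
    "default_toy_spec",
]


# ---------------------------------------------------------------------------
# Specs and ground-truth container
# ---------------------------------------------------------------------------

@dataclass
class MetastableChainSpec:
    """Parameters of a block-structured metastable chain.

    intra_rate / inter_rate: expected probability mass, per step, of leaving a
    microstate towards states of the same / of other blocks.  weight_spread
    controls how non-uniform the stationary distribution is (0 = uniform).
    """

    n_micro: int
    n_macro: int
    intra_rate: float = 0.3
    inter_rate: float = 0.01
    seed: int = 0
    weight_spread: float = 0.5

    def __post_init__(self) -> None:
        if self.n_micro < 1 or self.n_macro < 1:
            raise ParameterError("state counts must be positive")
        if self.n_macro > self.n_micro:
            raise ParameterError("n_macro cannot exceed n_micro")
        if not (0 <= self.intra_rate and 0 <= self.inter_rate):
            raise ParameterError("rates must be non-negative")
        if self.intra_rate + self.inter_rate >= 1:
            raise ParameterError("intra_rate + inter_rate must be < 1")
        if not (0 <= self.weight_spread < 1):
            raise ParameterError("weight_spread must be in [0, 1)")
        if self.n_macro > 1 and self.inter_rate == 0:
            raise ConnectivityError("inter_rate = 0 with several blocks gives a reducible chain")


@dataclass
class SyntheticGroundTruth:
    """Exact reference quantities of a generated chain.

    mfpt_true is the block-to-block mean first passage time matrix in the same
    time unit as ``lag`` (diagonal zero); timescales_true are the implied
    relaxation timescales −lag/ln λ_i for the non-unit eigenvalues.
    """

    T_true: np.ndarray
    pi_true: np.ndarray
    timescales_true: np.ndarray
    mfpt_true: np.ndarray
    block_assignment: np.ndarray
    lag: float = 1.0
    labels: list[np.ndarray] | None = None
    contact_sets: list[set] | None = None

    def to_json(self) -> dict:
        return {
            "T_true": self.T_true.tolist(),
            "pi_true": self.pi_true.tolist(),
            "timescales_true": self.timescales_true.tolist(),
            "mfpt_true": self.mfpt_true.tolist(),
            "block_assignment": self.block_assignment.tolist(),
            "lag": self.lag,
            "labels": None if self.labels is None else [l.tolist() for l in self.labels],
        }


@dataclass
class ToyComplexSpec:
    """Geometry of the toy bead complex.

    pose_offsets: per-mode ligand centroid placements (Å).  The invariant
    that offsets differ by at least 3×jitter_sd between modes keeps the
    designed contact patterns separable.
    """

    n_residues: int = 16
    n_ligand_atoms: int = 3
    pose_offsets: np.ndarray = field(default_factory=lambda: np.zeros((1, 3)))
    jitter_sd: float = 0.3
    mode_chain: MetastableChainSpec | None = None
    induced_shift: float = 1.0  # Å; pocket residues move toward the bound pose

    @property
    def n_modes(self) -> int:
        return len(self.pose_offsets)

    def __post_init__(self) -> None:
        self.pose_offsets = np.asarray(self.pose_offsets, dtype=float).reshape(-1, 3)
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be non-negative")
        if self.jitter_sd > 0:
            for i in range(self.n_modes):
                for j in range(i + 1, self.n_modes):
                    sep = np.linalg.norm(self.pose_offsets[i] - self.pose_offsets[j])
                    if sep < 3 * self.jitter_sd:
                        raise ParameterError(
                            f"pose offsets {i} and {j} separated by {sep:.2f} Å, "
                            f"below 3×jitter_sd = {3 * self.jitter_sd:.2f} Å"
                        )
        if self.mode_chain is None:
            self.mode_chain = MetastableChainSpec(
                n_micro=self.n_modes, n_macro=self.n_modes,
                intra_rate=0.0, inter_rate=0.02, seed=0, weight_spread=0.0,
            ) if self.n_modes > 1 else MetastableChainSpec(1, 1, 0.0, 0.0, 0, 0.0)
        if self.mode_chain.n_micro != self.n_modes:
            raise ParameterError("mode_chain.n_micro must equal the number of modes")


# ---------------------------------------------------------------------------
# Chain construction and exact reference quantities
# ---------------------------------------------------------------------------

def build_metastable_chain(spec: MetastableChainSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build a reversible block-structured transition matrix.

    Construction: microstates get positive weights w_i (the unnormalized
    stationary distribution); the off-diagonal transition probability is
    ``T_ij = base_b * w_j`` with one base rate per pair class (same block /
    different block).  The flux ``w_i T_ij = base_b w_i w_j`` is symmetric, so
    detailed balance holds exactly with π ∝ w.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_micro, spec.n_macro
    blocks = np.concatenate(
        [np.full(len(ix), b) for b, ix in enumerate(np.array_split(np.arange(n), m))]
    )
    w = 1.0 + spec.weight_spread * (2.0 * rng.random(n) - 1.0)

    same = blocks[:, None] == blocks[None, :]
    off = ~np.eye(n, dtype=bool)
    T = np.zeros((n, n))

    mean_w = w.mean()
    sizes = np.bincount(blocks, minlength=m)
    # expected number of intra / inter partners per row
    if n > m:  # blocks with >1 state exist
        intra_partners = max((sizes[blocks] - 1).mean(), 1e-12)
        base_intra = spec.intra_rate / (intra_partners * mean_w)
    else:
        base_intra = 0.0
    if m > 1:
        inter_partners = (n - sizes[blocks]).mean()
        base_inter = spec.inter_rate / (inter_partners * mean_w)
    else:
        base_inter = 0.0

    T[same & off] = (base_intra * np.broadcast_to(w, (n, n)))[same & off]
    T[~same] = (base_inter * np.broadcast_to(w, (n, n)))[~same]
    row_leave = T.sum(axis=1)
    if np.any(row_leave >= 1.0):
        raise ParameterError(
            f"requested rates give a leaving mass ≥ 1 (max {row_leave.max():.3f}); lower them"
        )
    np.fill_diagonal(T, 1.0 - row_leave)

    if n > m and m > 1:
        intra_mass = np.where(same & off, T, 0.0).sum(axis=1)
        inter_mass = np.where(~same, T, 0.0).sum(axis=1)
        if np.any(intra_mass <= inter_mass):
            raise ParameterError("within-block mass does not exceed between-block mass")
    _require_irreducible(T)
    return T, blocks


def _require_irreducible(T: np.ndarray) -> None:
    n_comp, _ = connected_components(T > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise ConnectivityError("transition matrix is reducible")


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Dominant left eigenvector of a row-stochastic matrix, normalized to 1."""
    vals, vecs = scipy.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def hitting_times(T: np.ndarray, target: Sequence[int], lag: float = 1.0) -> np.ndarray:
    """Expected first-passage time to the target set from every state.

    Solves ``h = 0`` on the target and ``(I − T) h = lag·1`` elsewhere; the
    exact dense linear-solve reference used throughout.
    """
    n = T.shape[0]
    target = np.asarray(sorted(set(int(t) for t in target)))
    rest = np.setdiff1d(np.arange(n), target)
    h = np.zeros(n)
    if rest.size:
        A = np.eye(rest.size) - T[np.ix_(rest, rest)]
        try:
            h[rest] = scipy.linalg.solve(A, np.full(rest.size, lag))
        except scipy.linalg.LinAlgError:
            h[rest] = np.inf
    return h


def analytic_ground_truth(
    T_true: np.ndarray,
    block_assignment: Sequence[int],
    lag: float = 1.0,
) -> SyntheticGroundTruth:
    """Exact π, implied timescales and block-to-block MFPTs of a chain."""
    T_true = np.asarray(T_true, dtype=float)
    if not np.allclose(T_true.sum(axis=1), 1.0, atol=1e-10):
        raise ParameterError("T_true rows must sum to 1")
    _require_irreducible(T_true)
    blocks = np.asarray(block_assignment, dtype=int)
    pi = stationary_distribution(T_true)

    vals = np.real(scipy.linalg.eigvals(T_true))
    vals = np.sort(vals)[::-1]
    sub = vals[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(sub > 0, -lag / np.log(np.clip(sub, 1e-300, None)), np.nan)

    n_blocks = blocks.max() + 1
    mfpt = np.zeros((n_blocks, n_blocks))
    for b in range(n_blocks):
        h = hitting_times(T_true, np.flatnonzero(blocks == b), lag)
        for a in range(n_blocks):
            if a == b:
                continue
            src = np.flatnonzero(blocks == a)
            mfpt[a, b] = float(np.dot(pi[src], h[src]) / pi[src].sum())
    return SyntheticGroundTruth(T_true, pi, ts, mfpt, blocks, lag)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_discrete_trajectories(
    T: np.ndarray,
    n_trajs: int,
    n_steps: int,
    seed: int = 0,
    initial_states: Sequence[int] | None = None,
) -> list[np.ndarray]:
    """Sample hidden-state trajectories from a row-stochastic matrix.

    Initial states are drawn from the stationary distribution unless given
    explicitly.  Bit-reproducible for a fixed seed.
    """
    T = np.asarray(T, dtype=float)
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ParameterError("T rows must sum to 1")
    rng = np.random.default_rng(seed)
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    if initial_states is None:
        pi = stationary_distribution(T)
        states = rng.choice(n, size=n_trajs, p=pi)
    else:
        states = np.asarray(initial_states, dtype=int).copy()
        if states.size != n_trajs:
            raise ParameterError("initial_states length must equal n_trajs")
    out = np.empty((n_trajs, n_steps), dtype=np.int64)
    out[:, 0] = states
    for t in range(1, n_steps):
        u = rng.random(n_trajs)
        states = (cum[states] < u[:, None]).sum(axis=1)
        out[:, t] = states
    return [out[i] for i in range(n_trajs)]


def emit_feature_trajectories(
    labels: Sequence[np.ndarray],
    emission_means: np.ndarray,
    emission_sd: float,
    seed: int = 0,
    frame_spacing_ns: float = 1.0,
) -> FeatureSet:
    """Gaussian feature emissions conditioned on the hidden state.

    Frame t of a trajectory is drawn from N(emission_means[label_t],
    emission_sd²·I).
    """
    means = np.atleast_2d(np.asarray(emission_means, dtype=float))
    n_states = int(max(l.max() for l in labels)) + 1
    if means.shape[0] != n_states:
        raise ParameterError(
            f"{means.shape[0]} mean vectors for {n_states} hidden states"
        )
    rng = np.random.default_rng(seed)
    mats = []
    for lab in labels:
        base = means[np.asarray(lab, dtype=int)]
        noise = rng.standard_normal(base.shape) * emission_sd if emission_sd > 0 else 0.0
        mats.append(base + noise)
    feat_labels = [("f", j) for j in range(means.shape[1])]
    return FeatureSet(mats, feat_labels, None, frame_spacing_ns)


# ---------------------------------------------------------------------------
# Toy bead complex
# ---------------------------------------------------------------------------

def default_toy_spec(
    n_modes: int = 3,
    n_residues: int = 16,
    n_ligand_atoms: int = 3,
    jitter_sd: float = 0.3,
    switch_rate: float = 0.02,
    seed: int = 0,
) -> ToyComplexSpec:
    """A ready-made toy complex: a bead ring with ligand poses in distinct sectors."""
    radius = n_residues * 3.8 / (2 * np.pi)
    angles = 2 * np.pi * np.arange(n_modes) / n_modes
    offsets = np.stack(
        [np.array([np.cos(a), np.sin(a), 0.0]) * (radius - 2.5) for a in angles]
    )
    chain = MetastableChainSpec(
        n_micro=n_modes, n_macro=n_modes, intra_rate=0.0,
        inter_rate=switch_rate, seed=seed, weight_spread=0.3,
    ) if n_modes > 1 else MetastableChainSpec(1, 1, 0.0, 0.0, seed, 0.0)
    return ToyComplexSpec(n_residues, n_ligand_atoms, offsets, jitter_sd, chain)


def generate_toy_complex_trajectories(
    spec: ToyComplexSpec,
    n_steps: int,
    seed: int = 0,
    n_trajs: int = 1,
    contact_cutoff: float = 6.0,
    frame_spacing_ns: float = 1.0,
) -> tuple[TrajectoryEnsemble, SyntheticGroundTruth]:
    """Generate bead "protein + ligand" trajectories with designed binding modes.

    Protein beads sit on a ring (one bead per residue, ~3.8 Å spacing) and
    jitter isotropically; ligand beads form a short rigid chain placed at the
    active mode's pose offset plus jitter.  Residues in contact with the
    active pose are additionally displaced by ``induced_shift`` Å toward the
    pose centre — a minimal induced-fit response that makes the protein's
    internal geometry mode-dependent, the way a real pocket deforms around
    different binding poses.  The returned ground truth carries the true
    mode-switching matrix, per-frame mode labels, and the designed per-mode
    contact sets (residue/ligand-atom pairs within ``contact_cutoff`` Å of
    the noiseless shifted pose).
    """
    rng = np.random.default_rng(seed)
    n_res, n_lig = spec.n_residues, spec.n_ligand_atoms

    radius = n_res * 3.8 / (2 * np.pi)
    theta = 2 * np.pi * np.arange(n_res) / n_res
    protein_sites = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n_res)], axis=1
    )
    ligand_local = np.stack(
        [np.linspace(-(n_lig - 1) * 0.75, (n_lig - 1) * 0.75, n_lig),
         np.zeros(n_lig), np.zeros(n_lig)], axis=1
    )

    T_mode, mode_blocks = build_metastable_chain(spec.mode_chain)
    labels = sample_discrete_trajectories(
        T_mode, n_trajs, n_steps, seed=rng.integers(2**31)
    )

    # induced fit: residues near the noiseless pose relax toward its centre
    lig_names = [f"C{a+1}" for a in range(n_lig)]
    mode_sites = np.empty((spec.n_modes, n_res, 3))
    contact_sets: list[set] = []
    for mode in range(spec.n_modes):
        center = spec.pose_offsets[mode]
        lig = ligand_local + center
        d0 = np.linalg.norm(protein_sites[:, None, :] - lig[None, :, :], axis=-1)
        pocket = d0.min(axis=1) < contact_cutoff
        sites = protein_sites.copy()
        if spec.induced_shift and pocket.any():
            vec = center - protein_sites[pocket]
            vec /= np.linalg.norm(vec, axis=1, keepdims=True)
            sites[pocket] += spec.induced_shift * vec
        mode_sites[mode] = sites
        d = np.linalg.norm(sites[:, None, :] - lig[None, :, :], axis=-1)
        contact_sets.append(
            {(int(r), lig_names[a]) for r, a in zip(*np.where(d < contact_cutoff))}
        )

    blocks = []
    for lab in labels:
        xyz = np.empty((n_steps, n_res + n_lig, 3))
        xyz[:, :n_res] = mode_sites[lab] + rng.normal(
            0.0, spec.jitter_sd, size=(n_steps, n_res, 3)
        )
        centers = spec.pose_offsets[lab]  # (T, 3)
        xyz[:, n_res:] = (
            centers[:, None, :] + ligand_local[None]
            + rng.normal(0.0, spec.jitter_sd, size=(n_steps, n_lig, 3))
        )
        blocks.append(xyz)

    top = Topology(
        atom_names=[f"CA" for _ in range(n_res)] + lig_names,
        residue_ids=np.concatenate([np.arange(n_res), np.full(n_lig, n_res)]),
        is_ligand=np.concatenate([np.zeros(n_res, bool), np.ones(n_lig, bool)]),
        residue_names=["BEA"] * n_res + ["LIG"] * n_lig,
    )
    traj = TrajectoryEnsemble(top, blocks, frame_spacing_ns)

    gt = analytic_ground_truth(T_mode, mode_blocks, lag=frame_spacing_ns)
    gt.labels = labels
    gt.contact_sets = contact_sets
    return traj, gt
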