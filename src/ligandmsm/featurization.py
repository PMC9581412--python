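"""Distance-based featurization of protein–ligand trajectories.

Coordinates are carried in a lightweight :class:`TrajectoryEnsemble` container
(one coordinate block per independent trajectory, Å units throughout).  Two
feature families are produced:

* *ligand contacts* — minimum distances between each protein residue and a
  small set of named ligand atoms, transformed into quasi-binary contact
  features (indicator or inverse distance below a cutoff).  These drive the
  kinetic model.
* *residue pairs* — inverse distances between protein residue pairs whose
  minimum distance crosses a filter cutoff at least once in the data.  These
  feed the per-residue importance stage.

External structures (PDB topology plus XTC/DCD/multi-model-PDB coordinates)
are read through :mod:`mdtraj` when it is installed; the in-memory container
is the canonical interchange object either way.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._exceptions import DataError, EmptyFeatureError, ParameterError, TopologyError

__all__ = [
    "Topology",
    "TrajectoryEnsemble",
    "FeatureSpec",
    "FeatureSet",
    "min_distance_matrix",
    "transform_quasibinary",
    "build_residue_pair_features",
    "featurize_external_structure",
    "load_trajectory",
]


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Minimal topology: per-atom name, residue id and ligand flag.

    Residue ids are the author-assigned residue numbers (not necessarily
    zero-based or contiguous), mirroring how residues are addressed in
    structural biology (e.g. the C-terminal calmodulin domain residues
    88–147).
    """

    atom_names: list[str]
    residue_ids: np.ndarray  # (n_atoms,) int
    is_ligand: np.ndarray  # (n_atoms,) bool
    residue_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.is_ligand = np.asarray(self.is_ligand, dtype=bool)
        if not (len(self.atom_names) == self.residue_ids.size == self.is_ligand.size):
            raise ParameterError("atom_names, residue_ids and is_ligand must align")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def protein_residues(self) -> np.ndarray:
        """Sorted unique residue ids of the protein part."""
        return np.unique(self.residue_ids[~self.is_ligand])

    def residue_atoms(self, resid: int, heavy_only: bool = False) -> np.ndarray:
        """Atom indices belonging to protein residue ``resid``."""
        mask = (self.residue_ids == resid) & ~self.is_ligand
        if heavy_only:
            names = np.array([n.strip().upper().startswith("H") for n in self.atom_names])
            mask &= ~names
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise TopologyError(f"residue {resid} not found in topology")
        return idx

    def ligand_atom(self, name: str) -> int:
        """Atom index of the ligand atom called ``name``."""
        for i in np.flatnonzero(self.is_ligand):
            if self.atom_names[i] == name:
                return int(i)
        raise TopologyError(f"ligand atom {name!r} not found in topology")


@dataclass
class TrajectoryEnsemble:
    """A set of independent trajectories sharing one topology.

    coords: one ``(n_frames, n_atoms, 3)`` float array per trajectory, in Å.
    frame_spacing_ns: the time between consecutive frames.
    """

    topology: Topology
    coords: list[np.ndarray]
    frame_spacing_ns: float = 1.0

    def __post_init__(self) -> None:
        self.coords = [np.asarray(c, dtype=float) for c in self.coords]
        for c in self.coords:
            if c.ndim != 3 or c.shape[1] != self.topology.n_atoms or c.shape[2] != 3:
                raise ParameterError(
                    f"coordinate block of shape {c.shape} does not match topology "
                    f"({self.topology.n_atoms} atoms)"
                )

    @property
    def n_trajs(self) -> int:
        return len(self.coords)

    @property
    def n_frames(self) -> list[int]:
        return [c.shape[0] for c in self.coords]

    def frame(self, traj: int, index: int) -> "TrajectoryEnsemble":
        """A single frame as a one-trajectory, one-frame ensemble."""
        return TrajectoryEnsemble(
            self.topology, [self.coords[traj][index : index + 1]], self.frame_spacing_ns
        )

    # -- plain-text serialization -------------------------------------------

    def write_pdb(self, path: str, traj: int = 0) -> None:
        """Write one trajectory as a multi-model PDB file."""
        top = self.topology
        with open(path, "w") as fh:
            for m, xyz in enumerate(self.coords[traj], start=1):
                fh.write(f"MODEL     {m:4d}\n")
                for a in range(top.n_atoms):
                    resname = (
                        top.residue_names[a] if top.residue_names else ("LIG" if top.is_ligand[a] else "BEA")
                    )
                    chain = "L" if top.is_ligand[a] else "A"
                    x, y, z = xyz[a]
                    fh.write(
                        "ATOM  {serial:5d} {name:<4s}{res:>4s} {chain}{resid:4d}    "
                        "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n".format(
                            serial=a + 1,
                            name=top.atom_names[a][:4],
                            res=resname[:4],
                            chain=chain,
                            resid=int(top.residue_ids[a]),
                            x=x,
                            y=y,
                            z=z,
                        )
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")


def load_trajectory(
    coord_files: str | Sequence[str],
    topology_file: str | None = None,
    frame_spacing_ns: float = 1.0,
    ligand_resnames: Sequence[str] = ("LIG", "TFP"),
) -> TrajectoryEnsemble:
    """Read external trajectories (PDB/XTC/DCD) into a :class:`TrajectoryEnsemble`.

    Requires :mod:`mdtraj`.  Ligand atoms are identified by residue name.
    mdtraj reports nm; coordinates are converted to Å.
    """
    import mdtraj  # deferred import: optional dependency

    if isinstance(coord_files, str):
        coord_files = [coord_files]
    blocks = []
    top = None
    for f in coord_files:
        t = mdtraj.load(f, top=topology_file) if topology_file else mdtraj.load(f)
        blocks.append(np.asarray(t.xyz, dtype=float) * 10.0)
        top = t.topology
    atom_names = [a.name for a in top.atoms]
    residue_ids = np.array([a.residue.resSeq for a in top.atoms])
    resnames = [a.residue.name for a in top.atoms]
    is_ligand = np.array([rn in set(ligand_resnames) for rn in resnames])
    return TrajectoryEnsemble(
        Topology(atom_names, residue_ids, is_ligand, resnames), blocks, frame_spacing_ns
    )


# ---------------------------------------------------------------------------
# Feature specification and container
# ---------------------------------------------------------------------------

VALID_MODES = ("ligand_contacts", "residue_pairs")
VALID_TRANSFORMS = ("binary", "inverse")


@dataclass
class FeatureSpec:
    """How to turn distances into features.

    mode: ``ligand_contacts`` (residue ↔ ligand-atom minimum distances) or
        ``residue_pairs`` (residue ↔ residue inverse distances).
    transform: ``binary`` (indicator ``d < cutoff``) or ``inverse``
        (``1/d`` when ``d < cutoff`` else 0).
    cutoff: contact cutoff in Å.
    """

    mode: str = "ligand_contacts"
    transform: str = "inverse"
    cutoff: float = 6.0
    ligand_atoms: list[str] = field(default_factory=list)
    residue_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ParameterError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if self.transform not in VALID_TRANSFORMS:
            raise ParameterError(
                f"transform must be one of {VALID_TRANSFORMS}, got {self.transform!r}"
            )
        if not self.cutoff > 0:
            raise ParameterError("cutoff must be positive")
        if self.mode == "ligand_contacts" and not self.ligand_atoms:
            raise ParameterError("ligand_contacts mode requires a non-empty ligand_atoms list")


@dataclass
class FeatureSet:
    """Per-trajectory feature matrices with shared labels.

    matrices: one ``(n_frames, n_features)`` array per trajectory.
    labels: one ``(residue, ligand-atom)`` or ``(residue, residue)`` tuple per
        feature column.
    """

    matrices: list[np.ndarray]
    labels: list[tuple]
    spec: FeatureSpec | None = None
    frame_spacing_ns: float = 1.0

    def __post_init__(self) -> None:
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        n_feat = len(self.labels)
        for m in self.matrices:
            if m.ndim != 2 or m.shape[1] != n_feat:
                raise ParameterError(
                    f"feature matrix of shape {m.shape} does not match {n_feat} labels"
                )

    @property
    def n_features(self) -> int:
        return len(self.labels)

    @property
    def n_trajs(self) -> int:
        return len(self.matrices)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.matrices, axis=0)

    def save(self, prefix: str) -> None:
        """Write matrices as an .npz array container plus a JSON label sidecar."""
        np.savez(prefix + ".npz", **{f"traj_{i}": m for i, m in enumerate(self.matrices)})
        meta = {
            "labels": [list(l) for l in self.labels],
            "frame_spacing_ns": self.frame_spacing_ns,
            "spec": None if self.spec is None else vars(self.spec).copy(),
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)

    @classmethod
    def load(cls, prefix: str) -> "FeatureSet":
        data = np.load(prefix + ".npz")
        mats = [data[f"traj_{i}"] for i in range(len(data.files))]
        with open(prefix + ".json") as fh:
            meta = json.load(fh)
        spec = None
        if meta.get("spec"):
            d = meta["spec"]
            d["residue_range"] = tuple(d["residue_range"]) if d.get("residue_range") else None
            spec = FeatureSpec(**d)
        return cls(mats, [tuple(l) for l in meta["labels"]], spec, meta["frame_spacing_ns"])


# ---------------------------------------------------------------------------
# Distance computations
# ---------------------------------------------------------------------------

def min_distance_matrix(
    traj: TrajectoryEnsemble,
    residue_range: tuple[int, int] | None = None,
    ligand_atoms: Sequence[str] | None = None,
) -> list[np.ndarray]:
    """Per-frame minimum residue↔ligand-atom distances.

    Returns one ``(n_frames, n_residues, n_ligand_atoms)`` array per
    trajectory; entry ``(t, r, a)`` is the minimum over the atoms of residue
    ``r`` of the Euclidean distance to ligand atom ``a`` at frame ``t``, in Å.
    """
    top = traj.topology
    residues = _resolve_residues(top, residue_range)
    if ligand_atoms is None:
        ligand_atoms = [top.atom_names[i] for i in np.flatnonzero(top.is_ligand)]
    lig_idx = np.array([top.ligand_atom(a) for a in ligand_atoms])
    res_atoms = [top.residue_atoms(r) for r in residues]

    out = []
    for xyz in traj.coords:
        lig = xyz[:, lig_idx]  # (T, L, 3)
        dmat = np.empty((xyz.shape[0], len(residues), len(lig_idx)))
        for ri, idx in enumerate(res_atoms):
            # (T, n_atoms_r, L)
            d = np.linalg.norm(xyz[:, idx, None, :] - lig[:, None, :, :], axis=-1)
            dmat[:, ri, :] = d.min(axis=1)
        out.append(dmat)
    return out


def residue_min_distances(
    traj: TrajectoryEnsemble,
    residue_range: tuple[int, int] | None = None,
    heavy_only: bool = True,
    exclude_neighbors: int = 1,
) -> tuple[list[np.ndarray], list[tuple[int, int]]]:
    """Per-frame minimum residue↔residue distances for all retained pairs.

    Pairs closer in sequence than ``exclude_neighbors`` (|i - j| ≤ value, on
    the ordered residue list) are dropped; hydrogens are excluded when
    ``heavy_only``.  Returns per-trajectory ``(n_frames, n_pairs)`` arrays and
    the pair labels as residue-id tuples.
    """
    top = traj.topology
    residues = _resolve_residues(top, residue_range)
    res_atoms = [top.residue_atoms(r, heavy_only=heavy_only) for r in residues]
    pairs = [
        (i, j)
        for i, j in itertools.combinations(range(len(residues)), 2)
        if j - i > exclude_neighbors
    ]
    labels = [(int(residues[i]), int(residues[j])) for i, j in pairs]
    out = []
    for xyz in traj.coords:
        dmat = np.empty((xyz.shape[0], len(pairs)))
        for p, (i, j) in enumerate(pairs):
            d = np.linalg.norm(
                xyz[:, res_atoms[i], None, :] - xyz[:, None, res_atoms[j], :], axis=-1
            )
            dmat[:, p] = d.min(axis=(1, 2))
        out.append(dmat)
    return out, labels


def _resolve_residues(top: Topology, residue_range: tuple[int, int] | None) -> np.ndarray:
    residues = top.protein_residues
    if residue_range is not None:
        lo, hi = residue_range
        residues = residues[(residues >= lo) & (residues <= hi)]
        expected = np.arange(lo, hi + 1)
        missing = np.setdiff1d(expected, residues)
        if missing.size:
            raise TopologyError(f"residues missing from topology: {missing.tolist()}")
    return residues


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def transform_quasibinary(
    distances: list[np.ndarray],
    spec: FeatureSpec,
    labels: list[tuple] | None = None,
    frame_spacing_ns: float = 1.0,
) -> FeatureSet:
    """Quasi-binary contact transform of residue↔ligand distance tables.

    ``binary``: 1 if d < cutoff else 0.  ``inverse``: 1/d if d < cutoff else 0.
    Distances must be strictly positive.
    """
    mats = []
    for d in distances:
        d = np.asarray(d, dtype=float)
        if np.any(d <= 0):
            raise DataError("distances must be strictly positive")
        flat = d.reshape(d.shape[0], -1)
        below = flat < spec.cutoff
        if spec.transform == "binary":
            mats.append(below.astype(float))
        else:
            mats.append(np.where(below, 1.0 / flat, 0.0))
    if labels is None:
        n_res, n_lig = np.asarray(distances[0]).shape[1:]
        lig_names = spec.ligand_atoms or [f"L{a}" for a in range(n_lig)]
        labels = [(r, lig_names[a]) for r in range(n_res) for a in range(n_lig)]
    return FeatureSet(mats, labels, spec, frame_spacing_ns)


def featurize_ligand_contacts(traj: TrajectoryEnsemble, spec: FeatureSpec) -> FeatureSet:
    """Convenience path: minimum distances then the quasi-binary transform."""
    dists = min_distance_matrix(traj, spec.residue_range, spec.ligand_atoms)
    residues = _resolve_residues(traj.topology, spec.residue_range)
    labels = [(int(r), a) for r in residues for a in spec.ligand_atoms]
    return transform_quasibinary(dists, spec, labels, traj.frame_spacing_ns)


def build_residue_pair_features(
    traj: TrajectoryEnsemble | None = None,
    distances: list[np.ndarray] | None = None,
    pair_labels: list[tuple[int, int]] | None = None,
    cutoff_filter: float = 6.5,
    residue_range: tuple[int, int] | None = None,
    frame_spacing_ns: float | None = None,
) -> FeatureSet:
    """Inverse residue–residue distances for pairs that cross the filter cutoff.

    A pair is retained iff its minimum distance is below ``cutoff_filter`` in
    at least one frame AND above it in at least one frame, i.e. the contact
    actually forms and breaks somewhere in the data.  Retained values are
    plain inverse distances (no cutoff zeroing).
    """
    if distances is None:
        if traj is None:
            raise ParameterError("provide either a trajectory or precomputed distances")
        distances, pair_labels = residue_min_distances(traj, residue_range)
        frame_spacing_ns = traj.frame_spacing_ns
    if pair_labels is None:
        raise ParameterError("pair_labels required with precomputed distances")
    stacked = np.concatenate([np.asarray(d, dtype=float) for d in distances], axis=0)
    if np.any(stacked <= 0):
        raise DataError("distances must be strictly positive")
    below = (stacked < cutoff_filter).any(axis=0)
    above = (stacked > cutoff_filter).any(axis=0)
    keep = np.flatnonzero(below & above)
    if keep.size == 0:
        raise EmptyFeatureError(
            f"no residue pair crosses the {cutoff_filter} Å filter cutoff"
        )
    spec = FeatureSpec(
        mode="residue_pairs",
        transform="inverse",
        cutoff=cutoff_filter,
        residue_range=residue_range,
    )
    mats = [1.0 / np.asarray(d, dtype=float)[:, keep] for d in distances]
    labels = [tuple(pair_labels[i]) for i in keep]
    return FeatureSet(mats, labels, spec, frame_spacing_ns or 1.0)


def featurize_external_structure(
    structure: TrajectoryEnsemble, spec: FeatureSpec
) -> np.ndarray:
    """Featurize one external structure with the trajectory transform.

    ``structure`` must hold exactly one frame whose topology resolves every
    residue and ligand atom of the spec; the returned vector can be projected
    through a fitted tICA model alongside trajectory data (e.g. to place
    crystal structures on a free-energy surface).
    """
    total = sum(c.shape[0] for c in structure.coords)
    if total != 1:
        raise ParameterError(f"expected exactly one frame, got {total}")
    fs = featurize_ligand_contacts(structure, spec)
    return fs.matrices[0][0]
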