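"""Per-residue flexibility from coordinate trajectories.

Implements least-squares rigid-body (Kabsch) superposition and the
root-mean-square fluctuation of C-alpha atoms about a reference
structure,

    RMSF_i = sqrt( mean_t |r_i(t) - r_i,ref|^2 ),

computed after optionally superposing every frame onto the reference so
that global rigid motion does not inflate the per-residue fluctuation.
Coordinates are angstroms on input; RMSF is reported in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PreconditionError

__all__ = [
    "Trajectory",
    "RMSFProfile",
    "kabsch_superpose",
    "apply_transform",
    "rmsf_per_residue",
]


@dataclass
class Trajectory:
    """An ordered stack of coordinate frames with shared atom metadata.

    coords : (n_frames, n_atoms, 3) angstrom
    atom_names / residue_indices : per-atom metadata; C-alphas are the
    atoms named "CA".
    """

    coords: np.ndarray
    atom_names: np.ndarray
    residue_indices: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise PreconditionError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 2:
            raise PreconditionError("a trajectory needs >= 2 frames")
        self.atom_names = np.asarray(self.atom_names)
        self.residue_indices = np.asarray(self.residue_indices)
        if (self.atom_names.size != self.coords.shape[1]
                or self.residue_indices.size != self.coords.shape[1]):
            raise PreconditionError("atom metadata must match the atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def ca_mask(self) -> np.ndarray:
        return self.atom_names == "CA"

    @classmethod
    def from_multimodel_pdb(cls, path) -> "Trajectory":
        """Read every MODEL of a multi-model PDB as one frame (Bio.PDB)."""
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("traj", str(path))
        frames, names, resids = [], None, None
        for model in structure:
            c, nm, ri = [], [], []
            for chain in model:
                for residue in chain:
                    for atom in residue:
                        c.append(atom.get_coord())
                        nm.append(atom.get_name())
                        ri.append(residue.id[1])
            frames.append(np.array(c))
            if names is None:
                names, resids = np.array(nm), np.array(ri)
        return cls(coords=np.stack(frames), atom_names=names,
                   residue_indices=resids)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: np.ndarray | None = None):
    """Optimal least-squares rigid superposition of ``mobile`` onto
    ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches the reference; the
    RMSD (angstrom) is evaluated over the selection used for the fit.
    The rotation is proper (det = +1, SVD sign-corrected).
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise PreconditionError("mobile and reference must have equal shape")
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection)
    m, r = mobile[sel], reference[sel]
    if m.shape[0] < 3:
        raise PreconditionError("superposition needs >= 3 selected atoms")
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    m0, r0 = m - mc, r - rc
    if np.linalg.matrix_rank(m0, tol=1e-9) < 2:
        raise PreconditionError("degenerate (collinear) selection")
    h = m0.T @ r0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ np.asarray(rotation).T + np.asarray(translation)


@dataclass
class RMSFProfile:
    """Per-residue C-alpha RMSF in nm."""

    residue_indices: np.ndarray
    rmsf_nm: np.ndarray

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices)
        self.rmsf_nm = np.asarray(self.rmsf_nm, dtype=float)
        if np.any(self.rmsf_nm < 0):
            raise PreconditionError("RMSF values must be >= 0")


def rmsf_per_residue(traj: Trajectory, reference: np.ndarray | str = "first",
                     fit: bool = True) -> RMSFProfile:
    """C-alpha RMSF of every residue about a reference structure.

    Parameters
    ----------
    reference : "first", "mean", or an (n_atoms, 3) coordinate array
        The structure deviations are measured against.  "first" uses
        frame 0 (e.g. the equilibrated starting structure); "mean" uses
        the trajectory average (computed after superposing all frames on
        frame 0, then re-fitting) and gives the variance-minimising RMSF.
    fit : bool
        Superpose each frame onto the reference over the C-alpha atoms
        before measuring deviations (removes global rigid motion).
    """
    ca = traj.ca_mask
    if not ca.any():
        raise PreconditionError("trajectory has no C-alpha atoms")
    sel = np.flatnonzero(ca)

    def fitted_stack(ref_coords):
        frames = np.empty_like(traj.coords)
        for f in range(traj.n_frames):
            if fit:
                rot, trans, _ = kabsch_superpose(traj.coords[f], ref_coords, sel)
                frames[f] = apply_transform(traj.coords[f], rot, trans)
            else:
                frames[f] = traj.coords[f]
        return frames

    if isinstance(reference, str):
        if reference == "first":
            ref = traj.coords[0]
        elif reference == "mean":
            ref = fitted_stack(traj.coords[0]).mean(axis=0)
        else:
            raise PreconditionError(f"unknown reference {reference!r}")
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != traj.coords[0].shape:
            raise PreconditionError("reference shape does not match trajectory")

    frames = fitted_stack(ref)
    dev = frames[:, sel, :] - ref[sel]
    rmsf_a = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return RMSFProfile(residue_indices=traj.residue_indices[sel],
                       rmsf_nm=rmsf_a / 10.0)
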