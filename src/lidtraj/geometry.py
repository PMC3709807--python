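"""Superposition and distance primitives.

Everything downstream (MSD decomposition, contact traces, proximity
factors) reduces to these four operations: a least-squares rigid fit
(Kabsch, optionally mass-weighted), the minimal inter-residue distance,
per-atom RMSF, and mass-weighted centre-of-mass separation.

Defaults follow the analysis conventions of the rest of the toolkit:
distances use heavy atoms (crystal structures carry no hydrogens, so
heavy-atom distances make crystal and simulation analyses commensurable),
and deviation analyses fit on the backbone of the rigid sub-domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .core import Frame, Topology, Trajectory
from .errors import DegenerateFitError, SelectionError

__all__ = [
    "RigidTransform",
    "kabsch_fit",
    "min_residue_distance",
    "min_distance",
    "rmsf",
    "com_distance",
    "check_chain_continuity",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1, no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


def kabsch_fit(
    mobile: Frame,
    reference: Frame,
    selection: np.ndarray,
    masses: np.ndarray | None = None,
    mass_weighted: bool = False,
) -> tuple[RigidTransform, Frame]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The transform minimises the (optionally mass-weighted) squared
    deviation over ``selection`` (atom indices, identical correspondence in
    both frames); the returned frame is the transform applied to *all*
    mobile atoms.

    Raises :class:`DegenerateFitError` for fewer than 3 atoms or a
    collinear selection, where the rotation is underdetermined.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise DegenerateFitError("superposition needs at least 3 atoms")
    X = mobile.coordinates[sel]
    Y = reference.coordinates[sel]
    if mass_weighted:
        if masses is None:
            raise ValueError("mass_weighted fit requires masses")
        w = np.asarray(masses, dtype=float)[sel]
    else:
        w = np.ones(sel.size)
    wsum = w.sum()
    xc = (w[:, None] * X).sum(0) / wsum
    yc = (w[:, None] * Y).sum(0) / wsum
    Xc, Yc = X - xc, Y - yc
    # collinear (rank < 2) centered cloud -> rotation about the line is free
    if np.linalg.matrix_rank(Xc, tol=1e-8) < 2:
        raise DegenerateFitError("selection is collinear; fit is degenerate")
    rot, _ = Rotation.align_vectors(Yc, Xc, weights=w)
    R = rot.as_matrix()
    transform = RigidTransform(R, yc - R @ xc)
    fitted = Frame(transform.apply(mobile.coordinates), time=mobile.time)
    return transform, fitted


def min_distance(
    frame: Frame, indices_a: np.ndarray, indices_b: np.ndarray
) -> float:
    """Minimum Euclidean distance over all cross pairs of two atom sets."""
    a = np.asarray(indices_a, dtype=int)
    b = np.asarray(indices_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise SelectionError("min_distance: empty atom selection")
    return float(cdist(frame.coordinates[a], frame.coordinates[b]).min())


def min_residue_distance(
    frame: Frame,
    topology: Topology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    atom_subset: str = "heavy",
) -> float:
    """Minimal atom-atom distance between two residue selections.

    ``group_a``/``group_b`` are atom index arrays (e.g. from
    :meth:`RegionSet.resolve`); ``atom_subset`` restricts them to
    ``heavy`` (default), ``all`` or ``backbone`` atoms.
    """
    a = topology.apply_subset(np.asarray(group_a, dtype=int), atom_subset)
    b = topology.apply_subset(np.asarray(group_b, dtype=int), atom_subset)
    return min_distance(frame, a, b)


def rmsf(
    trajectory: Trajectory,
    selection: np.ndarray,
    fit: tuple[Frame, np.ndarray] | None = None,
    mass_weighted_fit: bool = False,
) -> tuple[np.ndarray, float]:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    With ``fit=(reference, fit_selection)`` every frame is first superposed
    onto the reference over the fit selection, so rigid-body motion does
    not count as fluctuation.  Returns (per-atom RMSF, selection mean).
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF is undefined for a single-frame trajectory")
    sel = np.asarray(selection, dtype=int)
    coords = []
    for fr in trajectory.frames:
        if fit is not None:
            ref, fitsel = fit
            _, fr = kabsch_fit(
                fr, ref, fitsel,
                masses=trajectory.topology.masses,
                mass_weighted=mass_weighted_fit,
            )
        coords.append(fr.coordinates[sel])
    arr = np.stack(coords)                      # (n_frames, n_sel, 3)
    mean = arr.mean(axis=0)
    per_atom = np.sqrt(((arr - mean) ** 2).sum(axis=2).mean(axis=0))
    return per_atom, float(per_atom.mean())


def com_distance(
    trajectory: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Per-frame distance between mass-weighted centroids of two groups.

    Returns (series, mean, standard deviation).
    """
    m = trajectory.topology.masses
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    for g in (a, b):
        if g.size == 0:
            raise SelectionError("com_distance: empty selection")
        if m[g].sum() <= 0:
            raise ValueError("com_distance: zero total mass")
    out = np.empty(trajectory.n_frames)
    for k, fr in enumerate(trajectory.frames):
        ca = (m[a][:, None] * fr.coordinates[a]).sum(0) / m[a].sum()
        cb = (m[b][:, None] * fr.coordinates[b]).sum(0) / m[b].sum()
        out[k] = np.linalg.norm(ca - cb)
    return out, float(out.mean()), float(out.std())


def check_chain_continuity(
    topology: Topology, frame: Frame, bond_cutoff: float = 3.0,
    ca_cutoff: float = 4.5,
) -> list[str]:
    """Warn about broken molecules (no periodic-boundary imaging is done).

    For consecutive residues on a chain the C(i)-N(i+1) peptide bond should
    not exceed ``bond_cutoff``; for one-atom-per-residue models the
    pseudo-atom spacing should not exceed ``ca_cutoff``.  Returns the list
    of warning messages (also emitted via :mod:`warnings`).
    """
    msgs: list[str] = []
    residues = [r for r in topology.residues()
                if r.name not in ("HOH", "WAT", "SOL")]
    by_chain: dict[str, list] = {}
    for r in residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    for chain, rs in by_chain.items():
        for r1, r2 in zip(rs, rs[1:]):
            if r2.number != r1.number + 1:
                continue
            names1 = {topology.names[i]: i for i in r1.atom_indices}
            names2 = {topology.names[i]: i for i in r2.atom_indices}
            if "C" in names1 and "N" in names2:
                d = np.linalg.norm(
                    frame.coordinates[names1["C"]] - frame.coordinates[names2["N"]]
                )
                cutoff = bond_cutoff
            else:
                d = cdist(
                    frame.coordinates[list(r1.atom_indices)],
                    frame.coordinates[list(r2.atom_indices)],
                ).min()
                cutoff = ca_cutoff
            if d > cutoff:
                msg = (
                    f"chain {chain}: residues {r1.number}-{r2.number} are "
                    f"{d:.2f} A apart (> {cutoff} A); molecule may be broken"
                )
                msgs.append(msg)
                warnings.warn(msg, stacklevel=2)
    return msgs
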