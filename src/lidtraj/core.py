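"""Core containers: atoms, topology, frames, trajectories and region sets.

These are deliberately thin, array-backed records.  Coordinates are always
float64 ndarrays in Angstrom; times are picoseconds; masses are atomic mass
units looked up from the element symbol (overridable per atom).  Author
(source-file) residue numbering is preserved everywhere -- analyses refer to
residues by the numbers a crystallographer would use, with no internal
renumbering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import PartitionError, RegionError, SelectionError

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "Residue",
    "RegionSet",
    "atomic_mass",
    "BACKBONE_NAMES",
]

#: Atom names treated as protein backbone for subset filtering.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: Residue names excluded from protein analysis selections by default.
SOLVENT_NAMES = frozenset({"HOH", "WAT", "SOL", "NA", "CL", "K", "MG", "CA2", "ZN"})


def atomic_mass(element: str) -> float:
    """Standard atomic mass (amu) for an element symbol.

    Raises ``ValueError`` for symbols the periodic table does not know,
    rather than guessing.
    """
    el = gemmi.Element(element.strip().capitalize() or "X")
    if el.name == "X" and element.strip().upper() not in ("X",):
        raise ValueError(f"unknown element symbol: {element!r}")
    if el.weight <= 0:
        raise ValueError(f"element {element!r} has no tabulated mass")
    return float(el.weight)


@dataclass(frozen=True)
class AtomRecord:
    """One atom as read from a coordinate file.

    ``residue_number`` is the author numbering from the source file,
    preserved exactly.  ``mass`` defaults to the element's standard atomic
    mass but may be overridden (e.g. united-atom or coarse-grained models).
    """

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    mass: float = -1.0
    is_hetero: bool = False

    def __post_init__(self):
        if self.mass < 0:
            object.__setattr__(self, "mass", atomic_mass(self.element))
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    number: int
    name: str
    atom_indices: tuple[int, ...]


class Topology:
    """Ordered atom list with cached per-atom arrays and residue grouping.

    Atom order is stable and identical across every frame of an associated
    trajectory; all index-based selections refer to this order.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.elements = np.array([a.element.upper() for a in self.atoms])
        self.names = np.array([a.name for a in self.atoms])
        self.chain_ids = np.array([a.chain_id for a in self.atoms])
        self.residue_numbers = np.array(
            [a.residue_number for a in self.atoms], dtype=int
        )
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.chains: set[str] = set(self.chain_ids.tolist())
        self._residues: tuple[Residue, ...] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def residues(self) -> tuple[Residue, ...]:
        """Residues in file order, grouped by (chain, number, name)."""
        if self._residues is None:
            groups: dict[tuple[str, int, str], list[int]] = {}
            order: list[tuple[str, int, str]] = []
            for i, a in enumerate(self.atoms):
                key = (a.chain_id, a.residue_number, a.residue_name)
                if key not in groups:
                    groups[key] = []
                    order.append(key)
                groups[key].append(i)
            self._residues = tuple(
                Residue(c, n, r, tuple(groups[(c, n, r)])) for (c, n, r) in order
            )
        return self._residues

    # -- selections ------------------------------------------------------

    def select_interval(
        self, chain_id: str, start: int, end: int
    ) -> np.ndarray:
        """Atom indices of residues ``start``..``end`` (inclusive) on a chain."""
        mask = (
            (self.chain_ids == chain_id)
            & (self.residue_numbers >= start)
            & (self.residue_numbers <= end)
        )
        return np.flatnonzero(mask)

    def select_residue(self, chain_id: str, number: int) -> np.ndarray:
        return self.select_interval(chain_id, number, number)

    def subset_mask(self, which: str = "heavy") -> np.ndarray:
        """Boolean mask for an atom subset: ``heavy``, ``all`` or ``backbone``."""
        if which == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if which == "heavy":
            return self.elements != "H"
        if which == "backbone":
            return np.isin(self.names, sorted(BACKBONE_NAMES))
        raise ValueError(f"unknown atom subset {which!r}")

    def apply_subset(self, indices: np.ndarray, which: str) -> np.ndarray:
        out = indices[self.subset_mask(which)[indices]]
        if out.size == 0:
            raise SelectionError(
                f"selection empty after applying atom subset {which!r}"
            )
        return out

    def protein_mask(self) -> np.ndarray:
        """Atoms belonging to polymer residues (waters/ions excluded)."""
        return ~np.isin(self.residue_names, sorted(SOLVENT_NAMES))


@dataclass
class Frame:
    """One coordinate snapshot: per-atom 3-vectors in Angstrom, time in ps."""

    coordinates: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.time)


class Trajectory:
    """Ordered frames over a fixed topology.

    Construction asserts the frame/topology consistency invariant: every
    frame carries exactly ``topology.n_atoms`` coordinates and frame times
    are strictly increasing.
    """

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        for k, fr in enumerate(frames):
            if fr.n_atoms != topology.n_atoms:
                from .errors import TopologyMismatchError

                raise TopologyMismatchError(
                    f"frame {k}: {fr.n_atoms} atoms, topology has "
                    f"{topology.n_atoms}"
                )
        times = np.array([fr.time for fr in frames], dtype=float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames: list[Frame] = frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames], dtype=float)

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([fr.coordinates for fr in self.frames])

    def __getitem__(self, k: int) -> Frame:
        return self.frames[k]

    def __len__(self) -> int:
        return len(self.frames)


Interval = tuple[str, int, int]


class RegionSet:
    """Named residue-interval selections.

    Each region is a list of inclusive ``(chain_id, start, end)`` intervals
    in author numbering.  Regions used for MSD decomposition must be
    pairwise disjoint and jointly cover the analysis selection; that is
    checked at use time by :func:`lidtraj.msd.msd_profile`.
    """

    def __init__(self, regions: dict[str, list[Interval]]):
        self.regions: dict[str, list[Interval]] = {
            name: [tuple(iv) for iv in ivs] for name, ivs in regions.items()
        }

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def names(self) -> list[str]:
        return list(self.regions)

    def resolve(self, name: str, topology: Topology) -> np.ndarray:
        """Atom indices for a named region; every interval must hit >=1 atom."""
        if name not in self.regions:
            raise RegionError(f"unknown region {name!r}")
        chunks = []
        for chain, start, end in self.regions[name]:
            idx = topology.select_interval(chain, start, end)
            if idx.size == 0:
                raise RegionError(
                    f"region {name!r}: interval {chain}:{start}-{end} "
                    "resolves to no atoms in the topology"
                )
            chunks.append(idx)
        return np.unique(np.concatenate(chunks))

    def validate(
        self,
        topology: Topology,
        decomposition: Sequence[str] | None = None,
        allow_overlap: bool = False,
    ) -> None:
        """Resolve every region; optionally enforce disjointness.

        With ``decomposition`` given, those regions must be pairwise
        disjoint (required for the additive MSD split).  Overlap among
        other regions is tolerated only when ``allow_overlap`` is set.
        """
        resolved = {name: self.resolve(name, topology) for name in self.regions}
        names = list(decomposition) if decomposition else (
            [] if allow_overlap else list(self.regions)
        )
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.intersect1d(resolved[a], resolved[b]).size:
                    raise PartitionError(
                        f"regions {a!r} and {b!r} overlap; decomposition "
                        "regions must be pairwise disjoint"
                    )

    def residues_in(self, name: str, topology: Topology) -> list[Residue]:
        """Residues of the topology whose atoms fall inside a region."""
        idx = set(self.resolve(name, topology).tolist())
        return [
            r for r in topology.residues() if any(i in idx for i in r.atom_indices)
        ]

    def to_dict(self) -> dict[str, list[str]]:
        return {
            name: [f"{c}:{s}-{e}" for c, s, e in ivs]
            for name, ivs in self.regions.items()
        }
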