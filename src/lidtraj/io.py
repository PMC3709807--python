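"""Structure, trajectory and region-definition input/output.

PDB v3 coordinate files are the portable dialect (gemmi does the heavy
lifting); multi-model PDB serves as the text trajectory format, and the
usual binary trajectory formats (XTC/DCD/TRR) are available through the
MDAnalysis coordinate readers when that package is installed.

Policies (applied on read):

* author residue numbering preserved exactly;
* hydrogens retained if present;
* alternate locations resolved to the highest-occupancy conformer
  (ties: first listed);
* waters, ions and heteroatoms are parsed and retained but flagged, so
  analysis selections can exclude them.
"""

from __future__ import annotations

import re
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .core import AtomRecord, Frame, RegionSet, Topology, Trajectory, atomic_mass
from .errors import EmptyInputError, ParseError, RegionError, TopologyMismatchError

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "parse_regions",
    "read_regions",
    "DEFAULT_REGIONS",
]

#: Default region definitions for the DnaK substrate-binding domain:
#: rigid beta sandwich, five-helix lid, the central lid span used for
#: interconnectivity analysis, and the bound hepta-peptide (chain B in the
#: crystal structure of the complex).
DEFAULT_REGIONS = {
    "beta": ["A:389-507"],
    "lid": ["A:508-607"],
    "lid_circle": ["A:522-595"],
    "peptide": ["B:1-7"],
}

_COORD_RE = re.compile(r"^[\s\-+]*\d*\.?\d+\s*$")


def _validate_coordinate_records(path: Path) -> None:
    """Reject garbled ATOM/HETATM records, naming the offending line.

    gemmi tolerates some malformed fixed-column records; this pre-pass
    enforces that the three coordinate fields are numeric.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(
                    f"{path}, line {lineno}: ATOM record too short"
                )
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                if not _COORD_RE.match(line[lo:hi]):
                    raise ParseError(
                        f"{path}, line {lineno}: non-numeric coordinate "
                        f"field {line[lo:hi]!r}"
                    )


def _model_to_records_coords(
    model: gemmi.Model,
) -> tuple[list[AtomRecord], np.ndarray]:
    records: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            # altloc: keep the highest-occupancy variant per atom name,
            # ties resolved to the first listed.
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                if atom.name not in best:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > best[atom.name].occ:
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                el = atom.element.name
                try:
                    mass = atomic_mass(el)
                except ValueError:
                    raise ParseError(
                        f"atom {atom.serial} ({name}): unknown element {el!r}"
                    )
                records.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=name,
                        element=el,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                        mass=mass,
                        is_hetero=res.het_flag == "H",
                    )
                )
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    return records, np.array(coords, dtype=float).reshape(-1, 3)


def read_structure(path: str | Path, format: str = "pdb") -> tuple[Topology, Frame]:
    """Read a single-model structure into a (Topology, Frame) pair."""
    path = Path(path)
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_coordinate_records(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise EmptyInputError(f"{path}: no coordinate records")
    records, coords = _model_to_records_coords(st[0])
    return Topology(records), Frame(coords, time=0.0)


def write_structure(
    path: str | Path, topology: Topology, frame: Frame
) -> None:
    """Write a (Topology, Frame) pair as a PDB file (3-decimal precision)."""
    write_trajectory(path, Trajectory(topology, [frame]))


def _build_gemmi_structure(trajectory: Trajectory) -> gemmi.Structure:
    st = gemmi.Structure()
    for k, fr in enumerate(trajectory.frames):
        model = gemmi.Model(k + 1)
        chain = None
        residue = None
        prev_key = None
        for i, a in enumerate(trajectory.topology.atoms):
            if chain is None or chain.name != a.chain_id:
                chain = gemmi.Chain(a.chain_id)
                model.add_chain(chain)
                chain = model[len(model) - 1]
                prev_key = None
            key = (a.residue_number, a.residue_name)
            if key != prev_key:
                residue = gemmi.Residue()
                residue.name = a.residue_name
                residue.seqid = gemmi.SeqId(a.residue_number, " ")
                chain.add_residue(residue)
                residue = chain[len(chain) - 1]
                prev_key = key
            atom = gemmi.Atom()
            atom.name = a.name
            atom.serial = a.serial
            atom.element = gemmi.Element(a.element)
            x, y, z = fr.coordinates[i]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            residue.add_atom(atom)
        st.add_model(model)
    st.setup_entities()
    return st


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB.

    PDB carries no time stamps; readers reassign times from a declared
    stride (see :func:`read_trajectory`).
    """
    st = _build_gemmi_structure(trajectory)
    st.write_pdb(str(path))


def read_trajectory(
    path: str | Path,
    topology: Topology,
    format: str = "auto",
    dt_ps: float = 1.0,
    t0_ps: float = 0.0,
) -> Trajectory:
    """Read a trajectory against a known topology.

    ``format='auto'`` dispatches on the file extension: ``.pdb`` is read as
    a multi-model PDB; anything else goes through the MDAnalysis coordinate
    readers (XTC/DCD/TRR/...), an optional dependency.  Frames missing time
    stamps are assigned ``t0_ps + k * dt_ps``.
    """
    path = Path(path)
    if format == "auto":
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "binary"
    if format == "pdb":
        _validate_coordinate_records(path)
        st = gemmi.read_pdb(str(path))
        if len(st) == 0 or st[0].count_atom_sites() == 0:
            raise EmptyInputError(f"{path}: no coordinate records")
        frames = []
        for k, model in enumerate(st):
            _, coords = _model_to_records_coords(model)
            if coords.shape[0] != topology.n_atoms:
                raise TopologyMismatchError(
                    f"{path}: frame {k} has {coords.shape[0]} atoms, "
                    f"topology has {topology.n_atoms}"
                )
            frames.append(Frame(coords, time=t0_ps + k * dt_ps))
        return Trajectory(topology, frames)
    if format == "binary":
        try:
            import MDAnalysis as mda
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "binary trajectory formats require the 'mdanalysis' extra"
            ) from exc
        reader = mda.coordinates.core.reader(str(path), n_atoms=topology.n_atoms)
        frames = []
        for k, ts in enumerate(reader):
            if ts.positions.shape[0] != topology.n_atoms:
                raise TopologyMismatchError(
                    f"{path}: frame {k} has {ts.positions.shape[0]} atoms, "
                    f"topology has {topology.n_atoms}"
                )
            t = float(ts.time) if ts.time is not None else t0_ps + k * dt_ps
            frames.append(Frame(ts.positions.astype(float), time=t))
        return Trajectory(topology, frames)
    raise ValueError(f"unsupported trajectory format {format!r}")


_INTERVAL_RE = re.compile(r"^\s*([A-Za-z0-9])\s*:\s*(-?\d+)\s*-\s*(-?\d+)\s*$")


def parse_regions(
    config: dict | str,
    topology: Topology | None = None,
    decomposition: list[str] | None = None,
    allow_overlap: bool = True,
) -> RegionSet:
    """Build a RegionSet from a mapping of name -> "chain:start-end" strings.

    ``config`` may be a dict or a YAML document.  With a topology given,
    every interval is checked to resolve to at least one atom, and regions
    named in ``decomposition`` are checked for pairwise disjointness
    (overlap elsewhere is flagged unless ``allow_overlap``).
    """
    if isinstance(config, str):
        config = yaml.safe_load(config)
    if not isinstance(config, dict) or not config:
        raise RegionError("region config must be a non-empty mapping")
    regions: dict[str, list[tuple[str, int, int]]] = {}
    for name, spec in config.items():
        if isinstance(spec, str):
            spec = [spec]
        intervals = []
        for item in spec:
            m = _INTERVAL_RE.match(str(item))
            if not m:
                raise RegionError(
                    f"region {name!r}: cannot parse interval {item!r} "
                    "(expected 'CHAIN:START-END')"
                )
            chain, start, end = m.group(1), int(m.group(2)), int(m.group(3))
            if end < start:
                raise RegionError(
                    f"region {name!r}: interval end {end} precedes start {start}"
                )
            intervals.append((chain, start, end))
        regions[str(name)] = intervals
    rs = RegionSet(regions)
    if topology is not None:
        rs.validate(topology, decomposition=decomposition, allow_overlap=allow_overlap)
    return rs


def read_regions(path: str | Path, topology: Topology | None = None, **kw) -> RegionSet:
    """Read a region config file (YAML mapping of name -> intervals)."""
    return parse_regions(Path(path).read_text(), topology=topology, **kw)


#: Conventional region names for single-chain regions, keyed by chain id.
_CHAIN_ROLE = {"A": "core", "B": "lid", "P": "peptide"}


def auto_regions(topology: Topology) -> RegionSet:
    """Derive one region per chain from the topology itself.

    Chains A/B/P get the conventional names core/lid/peptide (the layout
    of the synthetic complexes); any other chain becomes ``chain_<id>``.
    Used as a fallback when no region config is given and the default
    DnaK numbering does not resolve.
    """
    regions: dict[str, list[tuple[str, int, int]]] = {}
    for chain in sorted(topology.chains):
        mask = topology.chain_ids == chain
        nums = topology.residue_numbers[mask]
        name = _CHAIN_ROLE.get(chain, f"chain_{chain}")
        regions[name] = [(chain, int(nums.min()), int(nums.max()))]
    return RegionSet(regions)


def default_or_auto_regions(topology: Topology) -> RegionSet:
    """DEFAULT_REGIONS when they resolve against the topology, else
    chain-derived auto regions."""
    try:
        return parse_regions(DEFAULT_REGIONS, topology=topology)
    except RegionError:
        return auto_regions(topology)
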