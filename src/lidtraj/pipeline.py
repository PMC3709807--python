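"""Run configuration, stage orchestration and report generation.

A :class:`RunConfig` is a fully serializable description of one analysis
run; ``run_pipeline`` executes any subset of the stages {msd, contacts,
proximity, network, report} over an input trajectory (read from disk or
synthesised from a preset), writing tidy TSV artifacts plus a manifest
recording inputs, the effective configuration, and every file produced.
Stages are independent: each reads only the trajectory and its own
configuration, except ``report``, which requires the ``network`` stage's
output in the same invocation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as _contacts
from . import geometry as _geometry
from . import io as _io
from . import msd as _msd
from . import proximity as _proximity
from . import synthetic as _synthetic
from .core import RegionSet, Trajectory
from .errors import DependencyError, RegionError

__all__ = ["RunConfig", "run_pipeline", "contact_report"]

log = logging.getLogger("lidtraj")

ALL_STAGES = ("msd", "contacts", "proximity", "network", "report")


@dataclass
class RunConfig:
    """Serializable description of a pipeline run.

    Either ``structure``+``trajectory`` paths or a synthetic ``preset``
    must be given.  Saved and re-loaded configs re-execute to identical
    outputs for the deterministic stages (the synthetic stage is
    deterministic given ``seed``).
    """

    structure: str | None = None
    trajectory: str | None = None
    regions: str | None = None              # region config path
    preset: str | None = None               # synthetic preset name
    seed: int = 0
    n_frames: int = 250
    dt_ps: float = 10.0
    atom_subset: str = "heavy"
    fit_region: str | None = None           # region fitted before MSD
    lid_region: str = "lid"
    probe_region: str = "peptide"
    msd_regions: list[str] = field(default_factory=lambda: ["core", "lid"])
    stride: int = 1
    persistence: int = 10
    window: str = "last:0.2"
    cutoff: float = 4.0
    report_cutoff: float = 3.5
    min_sequence_separation: int = 4
    outdir: str = "lidtraj_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _load_inputs(config: RunConfig):
    """Materialise (trajectory, region set) from paths or a preset."""
    if config.preset:
        topo, frame, regions = _synthetic.generate_toy_complex()
        spec = _synthetic.preset_spec(
            config.preset, regions, seed=config.seed,
            n_frames=config.n_frames, dt_ps=config.dt_ps,
        )
        traj, truth = _synthetic.generate_trajectory(spec, (topo, frame))
        return traj, regions, truth
    if not config.structure or not config.trajectory:
        raise RegionError(
            "config needs either a synthetic preset or structure+trajectory paths"
        )
    topo, frame = _io.read_structure(config.structure)
    traj = _io.read_trajectory(
        config.trajectory, topo, dt_ps=config.dt_ps
    )
    if config.regions:
        regions = _io.read_regions(config.regions, topology=topo)
    else:
        regions = _io.default_or_auto_regions(topo)
    return traj, regions, None


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages; return the manifest (also written).

    Raises :class:`DependencyError` when a requested stage is missing its
    upstream artifact (``report`` without ``network``).
    """
    stages = list(stages) if stages else list(ALL_STAGES)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")
    if "report" in stages and "network" not in stages:
        raise DependencyError("stage 'report' requires stage 'network'")
    if "network" in stages and "proximity" not in stages:
        raise DependencyError("stage 'network' requires stage 'proximity'")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj, regions, truth = _load_inputs(config)
    topo = traj.topology

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_frames": traj.n_frames,
        "n_atoms": topo.n_atoms,
        "stages": {},
        "files": [],
        "warnings": [],
    }
    manifest["warnings"].extend(
        _geometry.check_chain_continuity(topo, traj.frames[0])
    )
    if truth is not None:
        tpath = outdir / "ground_truth.json"
        _synthetic.write_ground_truth(tpath, truth)
        manifest["files"].append(str(tpath))

    network = None

    for stage in [s for s in ALL_STAGES if s in stages]:
        t0 = _time.perf_counter()
        files: list[str] = []

        if stage == "msd":
            fit = None
            if config.fit_region:
                fit = _msd.FitSpec(
                    selection=regions.resolve(config.fit_region, topo),
                    label=config.fit_region,
                )
            profile = _msd.msd_profile(
                traj, traj.frames[0], regions, config.msd_regions, fit=fit
            )
            p = outdir / "msd.tsv"
            profile.to_frame().to_csv(p, sep="\t", index=False)
            files.append(str(p))

        elif stage == "contacts":
            lid_res = regions.residues_in(config.lid_region, topo)
            probe_idx = regions.resolve(config.probe_region, topo)
            trace = _contacts.nearest_residue_trace(
                traj, lid_res, probe_idx,
                atom_subset=config.atom_subset, stride=config.stride,
            )
            p = outdir / "contact_trace.tsv"
            trace.to_tsv(p)
            files.append(str(p))
            tform = _contacts.contact_formation_time(
                trace, persistence=config.persistence
            )
            meta = outdir / "contact_formation.json"
            meta.write_text(json.dumps({"formation_time_ps": tform}))
            files.append(str(meta))
            try:
                rp = outdir / "contact_raster.png"
                _contacts.plot_raster(trace, rp)
                files.append(str(rp))
            except Exception as exc:  # plotting is best-effort
                manifest["warnings"].append(f"raster plot failed: {exc}")

        elif stage == "proximity":
            lid_res = regions.residues_in(config.lid_region, topo)
            matrix = _proximity.proximity_matrix(
                traj, lid_res, window=config.window,
                atom_subset=config.atom_subset,
            )
            p = outdir / "proximity.tsv"
            matrix.to_frame().to_csv(p, sep="\t", index=False)
            files.append(str(p))
            manifest["stages"].setdefault("proximity", {})
            manifest["_matrix"] = matrix          # in-memory handoff

        elif stage == "network":
            matrix = manifest.pop("_matrix", None)
            if matrix is None:
                raise DependencyError("stage 'network' has no proximity matrix")
            network = _proximity.build_network(
                matrix, cutoff=config.cutoff,
                min_sequence_separation=config.min_sequence_separation,
            )
            p = outdir / "network_edges.tsv"
            network.to_frame().to_csv(p, sep="\t", index=False)
            files.append(str(p))
            import networkx as nx

            gp = outdir / "network.graphml"
            nx.write_graphml(network.to_graph(), gp)
            files.append(str(gp))

        elif stage == "report":
            if network is None:
                raise DependencyError("stage 'report' has no network artifact")
            refs = _proximity.load_reference_contact_sets()
            table = contact_report(
                {"run": network, **refs}, report_cutoff=config.report_cutoff
            )
            p = outdir / "contact_report.tsv"
            table.to_csv(p, sep="\t", index=False)
            files.append(str(p))

        dt = _time.perf_counter() - t0
        log.info("stage %s: %d frames, %.2f s", stage, traj.n_frames, dt)
        manifest["stages"][stage] = {"seconds": round(dt, 3), "files": files}
        manifest["files"].extend(files)

    manifest.pop("_matrix", None)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=str))
    manifest["files"].append(str(mpath))
    return manifest


def contact_report(
    networks: dict[str, "_proximity.InteractionNetwork"],
    report_cutoff: float = 3.5,
    k: int | None = None,
) -> pd.DataFrame:
    """Per-condition sorted pair list at the report cutoff, with pairs
    common to at least k conditions flagged (default: all but one)."""
    if not networks:
        raise ValueError("contact_report needs at least one network")
    if len(networks) >= 2:
        common = _proximity.common_contacts(list(networks.values()), k=k)
    else:
        common = set()
    rows = []
    for cond, net in networks.items():
        for i, j, p in net.edges:
            if p <= report_cutoff:
                rows.append((cond, i, j, round(p, 2), (i, j) in common))
    return pd.DataFrame(
        rows, columns=["condition", "res_i", "res_j", "P_A", "common"]
    )
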