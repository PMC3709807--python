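"""Spatiotemporal nearest-contact tracing.

At each sampled frame the analysis finds the lid residue whose minimal
heavy-atom distance to a probe group (the bound peptide, or just its
N-terminal residue) is smallest, and classifies that distance into three
bins: close (< 3 A), mid (3-6 A) and far (>= 6 A).  Plotted as residue
index versus time this gives the familiar three-colour contact raster;
reduced along time it yields a contact-formation time -- the first moment
from which the nearest contact stays at or below a bin threshold for a
required number of consecutive records (a persistence criterion, because a
single-frame excursion is noise, not a formed contact).

Bin boundaries are half-open with the boundary assigned upward:
[0, 3) close, [3, 6) mid, [6, inf) far.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Residue, Topology, Trajectory
from .errors import SelectionError

__all__ = [
    "CLOSE_CUTOFF",
    "MID_CUTOFF",
    "bin_distance",
    "ContactTrace",
    "nearest_residue_trace",
    "contact_formation_time",
]

CLOSE_CUTOFF = 3.0
MID_CUTOFF = 6.0

_BIN_RANK = {"close": 0, "mid": 1, "far": 2}


def bin_distance(
    d: float, close: float = CLOSE_CUTOFF, mid: float = MID_CUTOFF
) -> str:
    """Classify a distance: [0, close) -> 'close', [close, mid) -> 'mid',
    [mid, inf) -> 'far'."""
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if d < close:
        return "close"
    if d < mid:
        return "mid"
    return "far"


@dataclass
class ContactTrace:
    """Per-frame nearest lid residue to the probe, with binned distance."""

    records: pd.DataFrame          # frame, time_ps, nearest_residue, distance_A, bin
    lid_region: str
    probe_region: str
    atom_subset: str
    stride: int

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def close_records(self) -> pd.DataFrame:
        return self.records[self.records["bin"] == "close"]

    def raster_table(self) -> pd.DataFrame:
        """Raster-ready view: one row per record, residue id vs time with bin."""
        return self.records[["time_ps", "nearest_residue", "bin"]]


def _residue_min_distances(
    frame_coords: np.ndarray,
    residue_atoms: list[np.ndarray],
    probe_idx: np.ndarray,
) -> np.ndarray:
    """Min heavy-atom distance of each residue's atom set to the probe."""
    probe = frame_coords[probe_idx]
    out = np.empty(len(residue_atoms))
    for r, idx in enumerate(residue_atoms):
        out[r] = cdist(frame_coords[idx], probe).min()
    return out


def nearest_residue_trace(
    trajectory: Trajectory,
    lid_residues: list[Residue],
    probe_indices: np.ndarray,
    atom_subset: str = "heavy",
    stride: int = 1,
) -> ContactTrace:
    """Trace the lid residue nearest to the probe through a trajectory.

    ``lid_residues`` come from :meth:`RegionSet.residues_in`;
    ``probe_indices`` is the probe's atom index array.  Ties between lid
    residues are broken toward the lower residue number.  ``stride``
    subsamples frames (records are exactly the stride-1 records
    subsampled).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not lid_residues:
        raise SelectionError("nearest_residue_trace: empty lid region")
    topo = trajectory.topology
    probe = topo.apply_subset(np.asarray(probe_indices, dtype=int), atom_subset)
    res_atoms = []
    res_numbers = []
    for r in sorted(lid_residues, key=lambda r: (r.chain_id, r.number)):
        idx = topo.apply_subset(np.array(r.atom_indices, dtype=int), atom_subset)
        res_atoms.append(idx)
        res_numbers.append(r.number)
    res_numbers = np.array(res_numbers)

    rows = []
    for k in range(0, trajectory.n_frames, stride):
        fr = trajectory.frames[k]
        dists = _residue_min_distances(fr.coordinates, res_atoms, probe)
        best = int(np.argmin(dists))  # argmin takes the first (lowest resid) on ties
        d = float(dists[best])
        rows.append((k, fr.time, int(res_numbers[best]), d, bin_distance(d)))
    records = pd.DataFrame(
        rows, columns=["frame", "time_ps", "nearest_residue", "distance_A", "bin"]
    )
    return ContactTrace(records, "lid", "probe", atom_subset, stride)


def contact_formation_time(
    trace: ContactTrace,
    bin_threshold: str = "close",
    persistence: int = 10,
) -> float | None:
    """Earliest time from which the contact bin stays at or below a
    threshold for at least ``persistence`` consecutive records.

    Returns the time (ps) of the first record of that run, or ``None`` if
    no such run exists.  A trailing run shorter than ``persistence`` does
    not qualify.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    if bin_threshold not in _BIN_RANK:
        raise ValueError(f"unknown bin {bin_threshold!r}")
    ranks = trace.records["bin"].map(_BIN_RANK).to_numpy()
    ok = ranks <= _BIN_RANK[bin_threshold]
    # first index i such that ok[i .. i+persistence-1] are all true
    count = 0
    for i in range(len(ok)):
        count = count + 1 if ok[i] else 0
        if count >= persistence:
            start = i - persistence + 1
            return float(trace.records["time_ps"].iloc[start])
    return None


def plot_raster(trace: ContactTrace, path) -> None:
    """Three-colour residue-vs-time raster of the nearest-contact trace."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"close": "#d62728", "mid": "#e6c700", "far": "#7b2d8b"}
    fig, ax = plt.subplots(figsize=(8, 4))
    for name, sub in trace.records.groupby("bin"):
        ax.scatter(
            sub["time_ps"], sub["nearest_residue"],
            s=8, c=colors[name], label=f"{name}", linewidths=0,
        )
    ax.set_xlabel("time (ps)")
    ax.set_ylabel("nearest residue")
    ax.legend(frameon=False, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
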