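"""Salt-bridge contact occupancy from MD distance series.

A frame is "in contact" with an acceptor residue when the minimum distance
from the donor atom to that residue's carboxylate oxygens is at or below a
cutoff (4.5 angstroms by default, the conventional salt-bridge criterion).
Occupancy is reported per run, per residue, for either-residue contact, and
cumulatively across runs weighted by frame count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panels import DistanceSeries

__all__ = [
    "min_distance_per_frame",
    "running_average",
    "contact_occupancy",
    "OccupancyResult",
    "distances_from_pdb",
]

DEFAULT_CUTOFF_A = 4.5


def min_distance_per_frame(series: DistanceSeries, residue: str) -> np.ndarray:
    """Per-frame minimum over a residue's carboxylate-oxygen distances."""
    if residue not in series.distances:
        raise KeyError(f"residue {residue!r} not in run {series.run_id!r}")
    return series.distances[residue].min(axis=1)


def running_average(values, window_frames: int) -> np.ndarray:
    """Centered moving mean of fixed width.

    Interior points average a window centred on the frame; near the edges
    the window is shifted inward so it always spans exactly
    ``window_frames`` frames (so a window as long as the series returns the
    global mean everywhere).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    w = int(window_frames)
    if w < 1 or w > n:
        raise ValueError("window must be between 1 and the series length")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(n)
    lo = np.clip(idx - (w - 1) // 2, 0, n - w)
    return (csum[lo + w] - csum[lo]) / w


@dataclass
class OccupancyResult:
    """Contact fractions at a distance cutoff.

    ``per_run[run][residue]`` and ``per_run[run]["either"]`` are fractions in
    [0, 1]; ``cumulative`` is the frame-weighted pool over runs, identical to
    total contact frames / total frames.
    """

    cutoff_A: float
    per_run: dict[str, dict[str, float]]
    cumulative: dict[str, float]
    frame_counts: dict[str, int]
    residues: list[str] = field(default_factory=list)

    @property
    def total_frames(self) -> int:
        return sum(self.frame_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for run, occ in self.per_run.items():
            for key, frac in occ.items():
                rows.append({"run": run, "contact": key, "occupancy": frac,
                             "n_frames": self.frame_counts[run],
                             "cutoff_A": self.cutoff_A})
        for key, frac in self.cumulative.items():
            rows.append({"run": "cumulative", "contact": key, "occupancy": frac,
                         "n_frames": self.total_frames, "cutoff_A": self.cutoff_A})
        return pd.DataFrame.from_records(rows)

    def summary(self) -> str:
        lines = [f"Contact occupancy at cutoff {self.cutoff_A:.2f} A "
                 f"({self.total_frames} frames over {len(self.per_run)} runs)"]
        for run, occ in self.per_run.items():
            parts = ", ".join(f"{k}: {v:.3f}" for k, v in occ.items())
            lines.append(f"  {run}: {parts}")
        parts = ", ".join(f"{k}: {v:.3f}" for k, v in self.cumulative.items())
        lines.append(f"  cumulative: {parts}")
        return "\n".join(lines)


def contact_occupancy(runs: Sequence[DistanceSeries],
                      cutoff_A: float = DEFAULT_CUTOFF_A) -> OccupancyResult:
    """Per-run and cumulative contact fractions at ``cutoff_A``.

    Either-residue contact counts a frame in which *any* residue is within
    the cutoff (the ligand can switch between acceptor residues while
    remaining salt-bridged throughout).
    """
    runs = list(runs)
    if not runs:
        raise ValueError("need at least one run")
    residues = runs[0].residues
    for r in runs:
        if r.residues != residues:
            raise ValueError("runs disagree on residue set")
    per_run: dict[str, dict[str, float]] = {}
    frame_counts: dict[str, int] = {}
    pooled = {res: 0 for res in residues}
    pooled_either = 0
    total = 0
    for run in runs:
        n = run.n_frames
        frame_counts[run.run_id] = n
        total += n
        occ: dict[str, float] = {}
        either = np.zeros(n, dtype=bool)
        for res in residues:
            contact = min_distance_per_frame(run, res) <= cutoff_A
            occ[res] = float(contact.mean())
            pooled[res] += int(contact.sum())
            either |= contact
        occ["either"] = float(either.mean())
        pooled_either += int(either.sum())
        per_run[run.run_id] = occ
    cumulative = {res: pooled[res] / total for res in residues}
    cumulative["either"] = pooled_either / total
    return OccupancyResult(float(cutoff_A), per_run, cumulative, frame_counts,
                           list(residues))


def distances_from_pdb(path: str, donor_selection: str,
                       acceptor_selections: dict[str, str],
                       dt_ns: float = 1.0, run_id: str = "run1") -> DistanceSeries:
    """Donor-acceptor distances from a multi-model PDB trajectory.

    ``donor_selection`` picks a single atom (e.g. the ligand's methylamine
    nitrogen); each entry of ``acceptor_selections`` maps a residue label to
    a selection of its carboxylate oxygens.  Selections use MDAnalysis
    syntax; MDAnalysis must be installed for this reader.
    """
    import MDAnalysis as mda

    u = mda.Universe(path)
    donor = u.select_atoms(donor_selection)
    if len(donor) != 1:
        raise ValueError(f"donor selection matched {len(donor)} atoms, expected 1")
    acceptors = {}
    for res, sel in acceptor_selections.items():
        ag = u.select_atoms(sel)
        if len(ag) == 0:
            raise ValueError(f"acceptor selection for {res!r} matched no atoms")
        acceptors[res] = ag
    frames = {res: [] for res in acceptors}
    times = []
    for i, _ in enumerate(u.trajectory):
        times.append(i * dt_ns)
        dpos = donor.positions[0]
        for res, ag in acceptors.items():
            d = np.linalg.norm(ag.positions - dpos, axis=1)
            frames[res].append(d)
    return DistanceSeries(run_id, np.asarray(times),
                          {res: np.asarray(v) for res, v in frames.items()})
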