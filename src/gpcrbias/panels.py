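"""Tabular data containers shared across the fitting modules.

Containers are thin, validated wrappers around :class:`pandas.DataFrame`
holding the long-format schemas the CLI reads and writes.  Concentrations
are stored in molar throughout; responses are percent of the reference
agonist's maximal effect once normalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

GPROTEIN = "gprotein"
ARRESTIN = "arrestin"

#: Column order of the concentration-response CSV schema.
CURVE_COLUMNS = [
    "ligand",
    "receptor",
    "pathway",
    "experiment",
    "replicate",
    "concentration_M",
    "response",
]

BINDING_COLUMNS = ["target", "competitor_conc_M", "signal", "well_type"]

LATENCY_COLUMNS = [
    "mouse",
    "dose",
    "dose_unit",
    "route",
    "time_min",
    "baseline_s",
    "test_s",
]


class SchemaError(ValueError):
    """A table does not match the expected file schema."""


@dataclass
class ConcResponsePanel:
    """Concentration-response data for one ligand/receptor/pathway.

    Parameters
    ----------
    ligand, receptor, pathway : str
        Identity of the curve.  ``pathway`` is typically ``"gprotein"`` or
        ``"arrestin"``.
    data : pandas.DataFrame
        Long-format table with columns ``experiment``, ``replicate``,
        ``concentration_M`` (molar, > 0) and ``response``.
    reference_ligand : str
        Ligand whose fitted maximum defines 100% after normalisation.
    truth : dict, optional
        Generating parameters when the panel is synthetic (``em``, ``tau``,
        ``ka``, ``n_hill``, ``log_r``); used only by recovery tests.
    normalized : bool
        Whether responses are on the percent-of-reference scale.
    """

    ligand: str
    receptor: str
    pathway: str
    data: pd.DataFrame
    reference_ligand: str = ""
    truth: dict | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        required = {"experiment", "replicate", "concentration_M", "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"panel missing columns: {sorted(missing)}")
        conc = np.asarray(self.data["concentration_M"], dtype=float)
        if not np.all(conc > 0):
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.isfinite(np.asarray(self.data["response"], dtype=float))):
            raise ValueError("responses must be finite")

    @property
    def concentrations(self) -> np.ndarray:
        """Sorted distinct concentrations (molar)."""
        return np.sort(self.data["concentration_M"].unique())

    @property
    def n_concentrations(self) -> int:
        return len(self.concentrations)

    @property
    def experiments(self) -> list:
        return sorted(self.data["experiment"].unique())

    def mean_by_concentration(self) -> pd.Series:
        """Mean response at each distinct concentration, ascending."""
        return self.data.groupby("concentration_M")["response"].mean().sort_index()

    def pooled_replicate_sd(self) -> float:
        """Pooled within-concentration SD; NaN when nothing replicates."""
        g = self.data.groupby("concentration_M")["response"]
        counts = g.count()
        if (counts < 2).all():
            return float("nan")
        var = g.var(ddof=1)
        w = counts - 1
        mask = w > 0
        return float(np.sqrt(np.average(var[mask], weights=w[mask])))

    def subset_experiment(self, experiment) -> "ConcResponsePanel":
        sub = self.data[self.data["experiment"] == experiment].reset_index(drop=True)
        return ConcResponsePanel(
            self.ligand, self.receptor, self.pathway, sub,
            self.reference_ligand, self.truth, self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format rows in the curves CSV schema."""
        out = self.data.copy()
        out.insert(0, "ligand", self.ligand)
        out.insert(1, "receptor", self.receptor)
        out.insert(2, "pathway", self.pathway)
        return out[CURVE_COLUMNS]


def panels_from_frame(frame: pd.DataFrame, reference_by_receptor: Mapping[str, str] | None = None,
                      normalized: bool = False) -> list[ConcResponsePanel]:
    """Split a curves-schema table into one panel per (ligand, receptor, pathway)."""
    missing = set(CURVE_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"curves table missing columns: {sorted(missing)}")
    panels = []
    for (lig, rec, path), sub in frame.groupby(["ligand", "receptor", "pathway"], sort=True):
        ref = reference_by_receptor.get(rec, "") if reference_by_receptor else ""
        panels.append(
            ConcResponsePanel(
                lig, rec, path,
                sub[["experiment", "replicate", "concentration_M", "response"]].reset_index(drop=True),
                reference_ligand=ref, normalized=normalized,
            )
        )
    return panels


@dataclass
class BindingPanel:
    """Competition radioligand binding data for one competitor/target.

    ``data`` columns: ``competitor_conc_M`` (NaN allowed on total/nonspecific
    wells), ``signal`` (counts), ``well_type`` in {"competition", "total",
    "nonspecific"}.  The hot (radio)ligand concentration and its dissociation
    constant are carried for the Cheng–Prusoff correction.
    """

    target: str
    data: pd.DataFrame
    hot_conc_M: float
    hot_kd_M: float
    competitor: str = ""
    truth: dict | None = None

    def __post_init__(self) -> None:
        required = {"competitor_conc_M", "signal", "well_type"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"binding panel missing columns: {sorted(missing)}")
        if self.hot_conc_M <= 0 or self.hot_kd_M <= 0:
            raise ValueError("hot-ligand concentration and Kd must be positive")
        comp = self.data[self.data["well_type"] == "competition"]
        if not np.all(np.asarray(comp["competitor_conc_M"], dtype=float) > 0):
            raise ValueError("competitor concentrations must be strictly positive")

    def nonspecific_mean(self) -> float:
        ns = self.data.loc[self.data["well_type"] == "nonspecific", "signal"]
        if len(ns) == 0:
            raise ValueError("no nonspecific wells present")
        return float(ns.mean())


@dataclass
class LatencyTable:
    """Tail-withdrawal latencies: one row per mouse/dose/time point.

    Columns: ``mouse``, ``dose``, ``dose_unit``, ``route``, ``time_min``,
    ``baseline_s``, ``test_s``.  Test latencies are right-censored at
    ``cutoff_s`` (15 s by default, chosen to prevent tissue damage).
    """

    data: pd.DataFrame
    cutoff_s: float = 15.0
    truth: dict | None = None

    def __post_init__(self) -> None:
        missing = set(LATENCY_COLUMNS) - set(self.data.columns)
        if missing:
            raise SchemaError(f"latency table missing columns: {sorted(missing)}")
        base = np.asarray(self.data["baseline_s"], dtype=float)
        test = np.asarray(self.data["test_s"], dtype=float)
        if not np.all((base > 0) & (base < self.cutoff_s)):
            raise ValueError("baselines must lie strictly between 0 and the cutoff")
        if np.any(test > self.cutoff_s + 1e-12):
            raise ValueError("test latencies exceed the censoring cutoff")

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.data["dose"].unique())


@dataclass
class DistanceSeries:
    """Per-frame donor-acceptor distances for one MD run.

    ``distances`` maps an acceptor residue label (e.g. ``"E209"``) to an
    (n_frames, n_oxygens) array of donor-to-carboxylate-oxygen distances in
    angstroms.  All residues in a run share the time axis.
    """

    run_id: str
    time_ns: np.ndarray
    distances: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ns, dtype=float)
        if len(t) == 0:
            raise ValueError(f"run {self.run_id!r} is empty")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time axis must be strictly increasing")
        self.time_ns = t
        for res, arr in self.distances.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape[0] != len(t):
                arr = arr.T
            if arr.shape[0] != len(t):
                raise ValueError(f"residue {res}: frame count mismatch with time axis")
            if not np.all(arr > 0):
                raise ValueError(f"residue {res}: distances must be positive")
            self.distances[res] = arr

    @property
    def n_frames(self) -> int:
        return len(self.time_ns)

    @property
    def residues(self) -> list[str]:
        return sorted(self.distances)
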