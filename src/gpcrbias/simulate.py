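"""Seeded synthetic-data generators with embedded ground truth.

Every generator emulates one of the pipeline's inputs — concentration-
response panels, competition binding, tail-withdrawal latencies, MD distance
series — at the level of the normalised/derived signal the analysis actually
consumes, with additive Gaussian noise and a known generating truth attached
for recovery testing.  All generators are pure functions of their parameters
and seed: the same seed reproduces the tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .doseresponse import operational_response
from .panels import (
    ARRESTIN,
    GPROTEIN,
    BindingPanel,
    ConcResponsePanel,
    DistanceSeries,
    LatencyTable,
)

__all__ = [
    "AssayDesign",
    "TruthRecord",
    "half_log_concentrations",
    "BIAS_PANEL_CONCENTRATIONS",
    "gen_conc_response",
    "make_biased_truths",
    "gen_bias_panel",
    "gen_competition_binding",
    "gen_tailflick",
    "gen_distance_trajectory",
]


def half_log_concentrations(lo_M: float, hi_M: float) -> np.ndarray:
    """Half-log (sqrt-10) spaced concentrations from ``lo_M`` to ``hi_M``."""
    if lo_M <= 0 or hi_M <= lo_M:
        raise ValueError("need 0 < lo < hi")
    n = int(round(2.0 * np.log10(hi_M / lo_M))) + 1
    return 10.0 ** np.linspace(np.log10(lo_M), np.log10(hi_M), n)


#: default agonist grid: ~1 pM to 10 uM in half-log steps
DEFAULT_CONCENTRATIONS = half_log_concentrations(1e-12, 1e-5)

#: grid used for two-pathway bias panels: 8 half-log points placed so that a
#: ~1 nM reference EC50 and arrestin curves attenuated up to ~100-fold both
#: stay inside the sampled range
BIAS_PANEL_CONCENTRATIONS = half_log_concentrations(10 ** -9.5, 1e-6)


@dataclass
class AssayDesign:
    """Plate structure of a simulated concentration-response assay.

    noise_sd is the additive Gaussian well noise in percent of the reference
    maximum (constant variance; the assays report only mean +/- SEM, so
    nothing richer is assumed).  ``tau_gsd``, when set above 1, applies a
    lognormal day-effect multiplier to tau per experiment (geometric SD,
    e.g. 1.2); it is off (1.0) by default.
    """

    concentrations: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONCENTRATIONS.copy())
    replicates_per_conc: int = 3
    n_experiments: int = 3
    noise_sd: float = 5.0
    seed: int = 0
    tau_gsd: float = 1.0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates_per_conc < 1 or self.n_experiments < 1:
            raise ValueError("replicates and experiments must be >= 1")
        if self.tau_gsd < 1.0:
            raise ValueError("tau_gsd is a geometric SD and must be >= 1")
        self.concentrations = conc

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthRecord:
    """Generating operational-model parameters for one ligand/pathway."""

    ligand: str
    pathway: str
    tau: float
    ka: float
    em: float = 100.0
    n_hill: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.ka <= 0 or self.em <= 0:
            raise ValueError("tau, K_A and Em must be positive")

    @property
    def log_r(self) -> float:
        """log10(tau/K_A), the generating transduction coefficient."""
        return float(np.log10(self.tau) - np.log10(self.ka))

    @property
    def emax_obs(self) -> float:
        t = self.tau ** self.n_hill
        return self.em * t / (1.0 + t)

    @property
    def ec50_obs(self) -> float:
        return self.ka / (1.0 + self.tau) if self.n_hill == 1 else float("nan")

    def as_dict(self) -> dict:
        return {"ligand": self.ligand, "pathway": self.pathway,
                "em": float(self.em), "tau": float(self.tau),
                "ka": float(self.ka), "n_hill": float(self.n_hill),
                "log_r": float(self.log_r)}


def gen_conc_response(truth: TruthRecord, design: AssayDesign,
                      receptor: str = "REC",
                      rng: np.random.Generator | None = None) -> ConcResponsePanel:
    """Simulate one ligand/pathway panel from operational-model means.

    Each well's response is the operational-model value at its concentration
    plus i.i.d. Gaussian noise of SD ``design.noise_sd``; experiment and
    replicate labels follow the plate structure.  The generating truth is
    embedded on the returned panel.
    """
    rng = rng if rng is not None else design.rng()
    rows = []
    for exp in range(1, design.n_experiments + 1):
        tau = truth.tau
        if design.tau_gsd > 1.0:
            tau = tau * rng.lognormal(0.0, np.log(design.tau_gsd))
        for conc in design.concentrations:
            mean = operational_response(conc, truth.em, tau, truth.ka, truth.n_hill)
            for rep in range(1, design.replicates_per_conc + 1):
                resp = mean + (rng.normal(0.0, design.noise_sd)
                               if design.noise_sd > 0 else 0.0)
                rows.append((exp, rep, conc, resp))
    data = pd.DataFrame(rows, columns=["experiment", "replicate",
                                       "concentration_M", "response"])
    return ConcResponsePanel(truth.ligand, receptor, truth.pathway, data,
                             truth=truth.as_dict())


def make_biased_truths(reference: dict[str, TruthRecord], bias_factor: float,
                       ligand: str, arrestin_emax_frac: float = 0.4,
                       pathway_pair: tuple[str, str] = (GPROTEIN, ARRESTIN),
                       ) -> dict[str, TruthRecord]:
    """Construct test-ligand truths realising a requested true bias factor.

    The test ligand keeps the reference's G-protein parameters (biased
    ligands in this class retain G-protein activity) and the whole
    transduction-coefficient gap ``log10(bias_factor)`` is placed in the
    arrestin pathway.  For G-protein-biased ligands (factor > 1) arrestin
    recruitment is attenuated: arrestin Emax is pinned at
    ``arrestin_emax_frac`` of the system maximum (default 40%, a clearly
    measurable partial curve) and K_A absorbs the remainder.  For
    arrestin-biased ligands (factor < 1) recruitment stays full (tau as the
    reference, matching how arrestin-preferring opioids recruit robustly)
    and the gain goes into functional affinity.  The embedded ddlog equals
    ``log10(bias_factor)`` exactly (to float round-off).
    """
    if bias_factor <= 0:
        raise ValueError("bias factor must be positive")
    if not 0 < arrestin_emax_frac < 1:
        raise ValueError("arrestin_emax_frac must be in (0, 1)")
    path_g, path_a = pathway_pair
    ref_g, ref_a = reference[path_g], reference[path_a]
    target_log_r = ref_a.log_r - np.log10(bias_factor)
    if bias_factor >= 1.0:
        tau_a = arrestin_emax_frac / (1.0 - arrestin_emax_frac)
    else:
        tau_a = ref_a.tau
    ka_a = tau_a * 10.0 ** (-target_log_r)
    return {
        path_g: replace(ref_g, ligand=ligand),
        path_a: TruthRecord(ligand, path_a, tau_a, ka_a, em=ref_a.em,
                            n_hill=ref_a.n_hill),
    }


def gen_bias_panel(reference_truth, test_truths, pathways=(GPROTEIN, ARRESTIN),
                   design: AssayDesign | None = None, receptor: str = "REC",
                   ) -> list[ConcResponsePanel]:
    """Simulate a reference plus test ligands across two (or more) pathways.

    Parameters
    ----------
    reference_truth : TruthRecord or mapping pathway -> TruthRecord
        A single record is reused (relabelled) for every pathway; the
        reference must be a high-efficacy full agonist.
    test_truths : mapping ligand -> (mapping pathway -> TruthRecord | float)
        A float is interpreted as a requested *true bias factor* and expanded
        with :func:`make_biased_truths`.
    """
    pathways = tuple(pathways)
    if len(pathways) < 2:
        raise ValueError("need at least two pathways for a bias panel")
    if design is None:
        design = AssayDesign(concentrations=BIAS_PANEL_CONCENTRATIONS.copy())
    if isinstance(reference_truth, TruthRecord):
        reference = {p: replace(reference_truth, pathway=p) for p in pathways}
    else:
        reference = dict(reference_truth)
    rng = design.rng()
    panels = [gen_conc_response(reference[p], design, receptor, rng)
              for p in pathways]
    for ligand, spec_t in test_truths.items():
        if isinstance(spec_t, (int, float)):
            truths = make_biased_truths(reference, float(spec_t), ligand,
                                        pathway_pair=pathways[:2])
        else:
            truths = dict(spec_t)
        for p in pathways:
            panels.append(gen_conc_response(truths[p], design, receptor, rng))
    return panels


def gen_competition_binding(ki_true: float, kd_hot: float, l_hot: float,
                            design: AssayDesign, target: str = "REC",
                            total_signal: float = 1000.0,
                            nonspecific_signal: float = 100.0,
                            n_control_wells: int = 3) -> BindingPanel:
    """Simulate one-site competition binding against a hot radioligand.

    Total binding = nonspecific + specific mass-action component with
    IC50 = Ki_true * (1 + [hot]/Kd_hot), plus Gaussian noise whose SD is
    ``design.noise_sd`` percent of the specific window.  Total-binding and
    nonspecific control wells are included.
    """
    if ki_true <= 0 or kd_hot <= 0:
        raise ValueError("Ki and hot-ligand Kd must be positive")
    if l_hot <= 0:
        raise ValueError("hot-ligand concentration must be positive")
    rng = design.rng()
    ic50 = ki_true * (1.0 + l_hot / kd_hot)
    window = total_signal - nonspecific_signal
    sd = design.noise_sd / 100.0 * window
    rows = []
    for conc in design.concentrations:
        mean = nonspecific_signal + window / (1.0 + conc / ic50)
        for _ in range(design.replicates_per_conc):
            noise = rng.normal(0.0, sd) if sd > 0 else 0.0
            rows.append((conc, mean + noise, "competition"))
    for _ in range(n_control_wells):
        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
        rows.append((np.nan, total_signal + noise, "total"))
    for _ in range(n_control_wells):
        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
        rows.append((np.nan, nonspecific_signal + noise, "nonspecific"))
    data = pd.DataFrame(rows, columns=["competitor_conc_M", "signal", "well_type"])
    truth = {"ki": ki_true, "ic50": ic50, "kd_hot": kd_hot, "l_hot": l_hot}
    return BindingPanel(target, data, l_hot, kd_hot, truth=truth)


def gen_tailflick(ed50_true: float, hill: float, doses, n_mice: int,
                  baseline_mean_s: float = 3.0, baseline_sd_s: float = 0.5,
                  mpe_noise_sd: float = 15.0, cutoff_s: float = 15.0,
                  seed: int = 0, time_min: float = 10.0,
                  dose_unit: str = "nmol", route: str = "icv") -> LatencyTable:
    """Simulate per-mouse tail-withdrawal latencies for a dose-response study.

    The mean %MPE at dose d follows a logistic in log dose with floor 0 and
    ceiling 100 (50% at the generating ED50); per-mouse Gaussian noise
    (``mpe_noise_sd``, %MPE units) is added, the score is converted back to a
    latency through each mouse's own baseline, and the latency is
    right-censored at ``cutoff_s`` (and floored at 0).
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if n_mice < 2:
        raise ValueError("need at least 2 mice per dose")
    if cutoff_s <= baseline_mean_s:
        raise ValueError("cutoff must exceed the mean baseline")
    if ed50_true <= 0 or hill <= 0:
        raise ValueError("ED50 and Hill slope must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    mouse = 0
    for dose in doses:
        mean_mpe = 100.0 / (1.0 + (ed50_true / dose) ** hill)
        for _ in range(n_mice):
            mouse += 1
            base = float(np.clip(rng.normal(baseline_mean_s, baseline_sd_s),
                                 0.5, cutoff_s - 2.0))
            mpe = mean_mpe + (rng.normal(0.0, mpe_noise_sd)
                              if mpe_noise_sd > 0 else 0.0)
            latency = base + mpe / 100.0 * (cutoff_s - base)
            latency = float(np.clip(latency, 0.0, cutoff_s))
            rows.append((f"m{mouse}", dose, dose_unit, route, time_min, base, latency))
    data = pd.DataFrame(rows, columns=["mouse", "dose", "dose_unit", "route",
                                       "time_min", "baseline_s", "test_s"])
    truth = {"ed50": ed50_true, "hill": hill, "cutoff_s": cutoff_s,
             "mpe_noise_sd": mpe_noise_sd}
    return LatencyTable(data, cutoff_s=cutoff_s, truth=truth)


def gen_distance_trajectory(p_contact_target: float, n_frames: int,
                            n_runs: int = 2, seed: int = 0,
                            mean_in_A: float = 3.0, mean_out_A: float = 8.0,
                            sd_in_A: float = 0.4, sd_out_A: float = 1.0,
                            switch_rate: float = 0.1, dt_ns: float = 1.0,
                            residues: tuple[str, ...] = ("E209", "D223"),
                            n_oxygens: int = 2,
                            floor_A: float = 1.5) -> list[DistanceSeries]:
    """Simulate two-state (bridged/unbridged) donor-acceptor distance runs.

    Contact dynamics follow a two-state Markov chain whose stationary
    probability of the bridged state is ``p_contact_target``; ``switch_rate``
    sets the overall transition propensity (mean bridged dwell about
    ``1/(switch_rate*(1-p))`` frames).  While bridged, the donor partners
    with one acceptor residue at a time (chosen at random each frame, giving
    the fluctuating switch between residues); that residue's oxygen
    distances are drawn around ``mean_in_A``, all others around
    ``mean_out_A``.  Distances are floored at 1.5 A (van der Waals contact
    lower bound).
    """
    if not 0.0 <= p_contact_target <= 1.0:
        raise ValueError("contact probability must be in [0, 1]")
    if n_frames < 10:
        raise ValueError("need at least 10 frames per run")
    if not 0.0 < switch_rate <= 1.0:
        raise ValueError("switch_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p = p_contact_target
    a_in = switch_rate * p          # out -> in
    a_out = switch_rate * (1.0 - p)  # in -> out
    runs = []
    for irun in range(1, n_runs + 1):
        state = rng.random() < p
        dists = {res: np.empty((n_frames, n_oxygens)) for res in residues}
        for f in range(n_frames):
            if f > 0:
                u = rng.random()
                state = (u >= a_out) if state else (u < a_in)
            partner = rng.integers(len(residues)) if state else -1
            for k, res in enumerate(residues):
                mean, sd = ((mean_in_A, sd_in_A) if (state and k == partner)
                            else (mean_out_A, sd_out_A))
                dists[res][f] = np.maximum(rng.normal(mean, sd, n_oxygens), floor_A)
        runs.append(DistanceSeries(f"run{irun}", np.arange(n_frames) * dt_ns, dists))
    return runs
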