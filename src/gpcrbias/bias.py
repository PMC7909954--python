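"""Ligand-bias quantification from transduction coefficients.

Within each pathway the reference agonist's ``log10(tau/K_A)`` is subtracted
(``dlog``), cancelling system and assay amplification; the between-pathway
difference ``ddlog = dlog(G protein) - dlog(arrestin)`` is the log bias, and
its antilog ``10**ddlog`` the bias factor.  A bias factor above 1 means
G-protein preference relative to the reference, below 1 arrestin preference,
and a factor whose confidence interval covers 1 is called unbiased.  Ligands
whose signal in a pathway is too weak to fit are reported as
``not_determined`` rather than forced to a number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .doseresponse import (
    LogisticCurve,
    LowSignalVerdict,
    OperationalModel,
    low_signal_check,
    mask_biphasic,
    normalize_to_reference,
)
from .panels import ARRESTIN, GPROTEIN, ConcResponsePanel

__all__ = [
    "Estimate",
    "BiasFactor",
    "BiasResult",
    "BiasOptions",
    "BiasAnalysis",
    "BiasResults",
    "delta_log",
    "delta_delta_log",
    "bias_factor",
    "run_bias_pipeline",
]

G_BIASED = "g_biased"
ARRESTIN_BIASED = "arrestin_biased"
UNBIASED = "unbiased"
NOT_DETERMINED = "not_determined"


@dataclass
class Estimate:
    """A point estimate with its standard error and experiment count."""

    value: float
    se: float
    n: int = 1


def delta_log(ligand: Estimate | None, reference: Estimate | None) -> Estimate | None:
    """Within-pathway normalised coefficient: logR(ligand) - logR(reference).

    SEs combine in quadrature.  ``None`` (not determined) propagates.
    """
    if ligand is None or reference is None:
        return None
    return Estimate(
        ligand.value - reference.value,
        float(np.sqrt(ligand.se**2 + reference.se**2)),
        ligand.n + reference.n,
    )


def delta_delta_log(dlog_g: Estimate | None, dlog_arrestin: Estimate | None) -> Estimate | None:
    """Between-pathway log bias: dlog(G protein) - dlog(arrestin)."""
    if dlog_g is None or dlog_arrestin is None:
        return None
    return Estimate(
        dlog_g.value - dlog_arrestin.value,
        float(np.sqrt(dlog_g.se**2 + dlog_arrestin.se**2)),
        dlog_g.n + dlog_arrestin.n,
    )


@dataclass
class BiasFactor:
    value: float
    ci_lo: float
    ci_hi: float
    label: str
    alpha: float = 0.05


def bias_factor(ddlog: float, se: float, df: float, alpha: float = 0.05) -> BiasFactor:
    """Antilog the log bias and classify against 1.

    The confidence interval is ``10**(ddlog +/- t(df)*se)``; the class is
    ``g_biased`` when the whole interval exceeds 1, ``arrestin_biased`` when
    it lies entirely below 1, otherwise ``unbiased``.  With fewer than one
    degree of freedom no interval (and no class) can be stated.
    """
    if not np.isfinite(ddlog):
        return BiasFactor(float("nan"), float("nan"), float("nan"), NOT_DETERMINED, alpha)
    bf = 10.0**ddlog
    if df < 1:
        return BiasFactor(bf, float("nan"), float("nan"), NOT_DETERMINED, alpha)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    lo = 10.0 ** (ddlog - tcrit * se)
    hi = 10.0 ** (ddlog + tcrit * se)
    if lo > 1.0:
        label = G_BIASED
    elif hi < 1.0:
        label = ARRESTIN_BIASED
    else:
        label = UNBIASED
    return BiasFactor(bf, float(lo), float(hi), label, alpha)


@dataclass
class BiasResult:
    """One ligand's bias outcome at one receptor (one row of the bias table)."""

    ligand: str
    receptor: str
    reference_ligand: str
    pathway_pair: tuple[str, str]
    dlog_g: Estimate | None
    dlog_arrestin: Estimate | None
    ddlog: Estimate | None
    factor: BiasFactor
    flags: list[str] = field(default_factory=list)
    verdicts: dict[str, LowSignalVerdict] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.factor.label


@dataclass
class BiasOptions:
    """Fitting policy for the bias pipeline.

    per_experiment
        Fit each independent experiment separately and use the SEM of the
        per-experiment transduction coefficients (default, matching the
        N-independent-experiments structure of the assays); ``False`` pools
        all wells into one fit with asymptotic SEs.
    biphasic_policy
        ``"mask"`` drops top-concentration points rising above the first
        plateau before fitting; ``"fit-all"`` uses every point.
    """

    pathway_pair: tuple[str, str] = (GPROTEIN, ARRESTIN)
    per_experiment: bool = True
    n_hill: float = 1.0
    min_span_pct: float = 10.0
    min_snr: float = 3.0
    biphasic_policy: str = "mask"
    alpha: float = 0.05
    parameterization: str = "composite"
    normalize: bool = True


class BiasAnalysis:
    """End-to-end bias pipeline over a set of concentration-response panels.

    Parameters
    ----------
    panels : sequence of ConcResponsePanel
        Raw (or pre-normalised) curves covering, per receptor, the reference
        agonist and any test ligands in both pathways of
        ``options.pathway_pair``.
    references : mapping receptor -> ligand
        The balanced reference agonist per receptor (e.g. DAMGO for MOR,
        U50,488h for KOR); must be present in both pathways.

    ``fit()`` returns :class:`BiasResults`.
    """

    def __init__(self, panels: Sequence[ConcResponsePanel],
                 references: Mapping[str, str],
                 options: BiasOptions | None = None):
        self.panels = list(panels)
        self.references = dict(references)
        self.options = options or BiasOptions()
        self._index: dict[tuple[str, str, str], ConcResponsePanel] = {}
        for p in self.panels:
            self._index[(p.receptor, p.ligand, p.pathway)] = p

    # -- per-curve transduction coefficient --------------------------------

    def _log_r(self, panel: ConcResponsePanel, em: float) -> tuple[Estimate | None, list[str]]:
        opt = self.options
        flags: list[str] = []
        if opt.biphasic_policy == "mask":
            panel, masked = mask_biphasic(panel)
            if masked:
                flags.append("masked_biphasic:" + ",".join(f"{c:.3g}" for c in masked))
        if opt.per_experiment:
            values = []
            for exp in panel.experiments:
                sub = panel.subset_experiment(exp)
                res = OperationalModel.from_panel(
                    sub, em, n_hill=opt.n_hill, parameterization=opt.parameterization
                ).fit()
                if res.converged:
                    values.append(res.log_r)
                else:
                    flags.append(f"experiment_{exp}_unconverged")
            if len(values) == 0:
                return None, flags + ["no_converged_experiments"]
            values = np.asarray(values)
            se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
            return Estimate(float(values.mean()), se, len(values)), flags
        res = OperationalModel.from_panel(
            panel, em, n_hill=opt.n_hill, parameterization=opt.parameterization
        ).fit()
        if not res.converged:
            return None, flags + ["pooled_fit_unconverged"]
        return Estimate(res.log_r, res.se_log_r, len(panel.experiments)), flags

    # -- pipeline ----------------------------------------------------------

    def fit(self) -> "BiasResults":
        opt = self.options
        path_g, path_a = opt.pathway_pair
        rows: list[BiasResult] = []
        fits: dict[tuple[str, str, str], Estimate | None] = {}
        norm_panels: dict[tuple[str, str, str], ConcResponsePanel] = {}

        receptors = sorted({p.receptor for p in self.panels})
        for rec in receptors:
            if rec not in self.references:
                raise ValueError(f"no reference ligand configured for receptor {rec!r}")
            ref = self.references[rec]
            ref_panels = {}
            for path in (path_g, path_a):
                key = (rec, ref, path)
                if key not in self._index:
                    raise ValueError(
                        f"reference ligand {ref!r} missing in pathway {path!r} "
                        f"for receptor {rec!r}"
                    )
                ref_panels[path] = self._index[key]

            em: dict[str, float] = {}
            ref_logr: dict[str, Estimate | None] = {}
            for path in (path_g, path_a):
                raw_ref = ref_panels[path]
                ref_norm = (normalize_to_reference(raw_ref, raw_ref)
                            if opt.normalize else raw_ref)
                norm_panels[(rec, ref, path)] = ref_norm
                em[path] = LogisticCurve.from_panel(ref_norm).fit().top
                est, _ = self._log_r(ref_norm, em[path])
                if est is None:
                    raise ValueError(
                        f"reference {ref!r} transduction fit failed in {path!r} at {rec!r}"
                    )
                ref_logr[path] = est
                fits[(rec, ref, path)] = est

            ligands = sorted({p.ligand for p in self.panels if p.receptor == rec})
            for lig in ligands:
                flags: list[str] = []
                verdicts: dict[str, LowSignalVerdict] = {}
                if lig == ref:
                    # the reference against itself is exactly unbiased
                    se_g = ref_logr[path_g].se * np.sqrt(2.0)
                    se_a = ref_logr[path_a].se * np.sqrt(2.0)
                    n2 = ref_logr[path_g].n * 2
                    dg = Estimate(0.0, float(se_g), n2)
                    da = Estimate(0.0, float(se_a), ref_logr[path_a].n * 2)
                    rows.append(BiasResult(
                        lig, rec, ref, (path_g, path_a), dg, da,
                        Estimate(0.0, 0.0, dg.n + da.n),
                        BiasFactor(1.0, 1.0, 1.0, UNBIASED, opt.alpha),
                        ["reference"], {},
                    ))
                    continue

                lig_logr: dict[str, Estimate | None] = {}
                for path in (path_g, path_a):
                    key = (rec, lig, path)
                    if key not in self._index:
                        lig_logr[path] = None
                        flags.append(f"missing_panel:{path}")
                        continue
                    panel = (normalize_to_reference(self._index[key], ref_panels[path])
                             if opt.normalize else self._index[key])
                    norm_panels[key] = panel
                    verdict = low_signal_check(panel, opt.min_span_pct, opt.min_snr)
                    verdicts[path] = verdict
                    if verdict.too_low:
                        lig_logr[path] = None
                        flags.append(f"low_signal:{path}")
                        continue
                    est, f = self._log_r(panel, em[path])
                    lig_logr[path] = est
                    flags.extend(f)
                    fits[key] = est

                dg = delta_log(lig_logr[path_g], ref_logr[path_g])
                da = delta_log(lig_logr[path_a], ref_logr[path_a])
                dd = delta_delta_log(dg, da)
                if dd is None:
                    bf = BiasFactor(float("nan"), float("nan"), float("nan"),
                                    NOT_DETERMINED, opt.alpha)
                else:
                    df = dd.n - 2
                    bf = bias_factor(dd.value, dd.se, df, opt.alpha)
                rows.append(BiasResult(lig, rec, ref, (path_g, path_a),
                                       dg, da, dd, bf, flags, verdicts))

        return BiasResults(rows, fits, norm_panels, self.options)


class BiasResults:
    """Fitted bias table plus per-curve diagnostics.

    Attributes
    ----------
    rows : list of BiasResult
    log_r : dict (receptor, ligand, pathway) -> Estimate
        Per-curve transduction-coefficient estimates.
    panels : dict (receptor, ligand, pathway) -> ConcResponsePanel
        Normalised panels as fitted.
    """

    def __init__(self, rows, log_r, panels, options):
        self.rows = rows
        self.log_r = log_r
        self.panels = panels
        self.options = options

    @property
    def table(self) -> pd.DataFrame:
        """The bias CSV schema: one row per ligand x receptor."""
        recs = []
        for r in self.rows:
            recs.append({
                "ligand": r.ligand,
                "receptor": r.receptor,
                "reference": r.reference_ligand,
                "dlog_g": r.dlog_g.value if r.dlog_g else np.nan,
                "dlog_g_se": r.dlog_g.se if r.dlog_g else np.nan,
                "dlog_arrestin": r.dlog_arrestin.value if r.dlog_arrestin else np.nan,
                "dlog_arrestin_se": r.dlog_arrestin.se if r.dlog_arrestin else np.nan,
                "ddlog": r.ddlog.value if r.ddlog else np.nan,
                "ddlog_se": r.ddlog.se if r.ddlog else np.nan,
                "bias_factor": r.factor.value,
                "ci_lo": r.factor.ci_lo,
                "ci_hi": r.factor.ci_hi,
                "class": r.label,
                "flags": ";".join(r.flags),
            })
        return pd.DataFrame.from_records(recs)

    def __getitem__(self, key) -> BiasResult:
        ligand, receptor = key
        for r in self.rows:
            if r.ligand == ligand and r.receptor == receptor:
                return r
        raise KeyError(key)

    def summary(self) -> str:
        t = self.table
        lines = ["Ligand bias (operational model, ddlog(tau/K_A))", ""]
        with pd.option_context("display.width", 120, "display.float_format",
                               lambda v: f"{v:.3f}"):
            lines.append(t.drop(columns="flags").to_string(index=False))
        return "\n".join(lines)

    def plot(self, receptor: str, ax=None):
        """Diagnostic overlay of normalised curves for one receptor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for (rec, lig, path), panel in sorted(self.panels.items()):
            if rec != receptor:
                continue
            means = panel.mean_by_concentration()
            ax.semilogx(means.index, means.values, "o--", ms=4,
                        label=f"{lig} / {path}")
        ax.set_xlabel("[A] (M)")
        ax.set_ylabel("response (% reference max)")
        ax.set_title(f"{receptor}: normalised concentration-response")
        ax.legend(fontsize=7)
        return ax


def run_bias_pipeline(panels, references, options: BiasOptions | None = None) -> BiasResults:
    """normalise -> low-signal screen -> operational fits -> ddlog -> bias table."""
    return BiasAnalysis(panels, references, options).fit()
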