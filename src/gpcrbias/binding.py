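"""Competition radioligand binding: specific binding, one-site IC50 fit,
Cheng-Prusoff conversion to Ki, and fold-selectivity summaries.

Concentrations are molar internally; reports convert to nM at the boundary.
The hot ligand is assumed non-depleted (classical Cheng-Prusoff conditions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doseresponse import _covariance, _multistart_least_squares
from .panels import BindingPanel

__all__ = [
    "specific_binding",
    "CompetitionBinding",
    "KiResult",
    "cheng_prusoff",
    "pki",
    "ki_from_pki_nM",
    "fold_selectivity",
    "min_fold_selectivity",
]


def specific_binding(panel: BindingPanel) -> BindingPanel:
    """Subtract mean nonspecific binding from every well.

    Specific = signal - mean(nonspecific wells), floored at zero; floored
    wells are marked in a ``floored`` column.  Refused when the panel has no
    nonspecific wells.
    """
    ns = panel.nonspecific_mean()
    out = panel.data.copy()
    corrected = out["signal"].astype(float) - ns
    out["floored"] = corrected < 0
    out["signal"] = corrected.clip(lower=0.0)
    return BindingPanel(panel.target, out, panel.hot_conc_M, panel.hot_kd_M,
                        panel.competitor, panel.truth)


@dataclass
class KiResult:
    """One-site competition fit with the Cheng-Prusoff corrected affinity."""

    ic50: float
    se_ic50: float
    ki: float
    pki: float
    se_pki: float
    top: float
    bottom: float
    converged: bool
    n_points: int

    @property
    def ki_nM(self) -> float:
        return self.ki * 1e9

    def summary(self) -> str:
        return "\n".join([
            "One-site competition binding fit",
            f"  IC50      : {self.ic50:.4g} M (SE {self.se_ic50:.2g})",
            f"  Ki        : {self.ki_nM:.4g} nM",
            f"  pKi       : {self.pki:.3f} (SE {self.se_pki:.3f})",
            f"  converged : {self.converged}",
        ])


class CompetitionBinding:
    """One-site competition model fitted to specific binding vs competitor.

    The curve is a decreasing logistic in log10 concentration with the Hill
    slope fixed at -1 (single class of sites)::

        B(x) = bottom + (top - bottom) / (1 + 10**(x - logIC50))

    ``fit()`` returns :class:`KiResult`; the Ki applies the Cheng-Prusoff
    correction with the panel's hot-ligand concentration and Kd.  Flat data
    yield an unconverged flag rather than an exception.
    """

    def __init__(self, panel: BindingPanel, subtract_nonspecific: bool = True):
        work = specific_binding(panel) if subtract_nonspecific else panel
        comp = work.data[work.data["well_type"] == "competition"]
        conc = np.asarray(comp["competitor_conc_M"], dtype=float)
        if len(np.unique(conc)) < 4:
            raise ValueError("need at least 4 competitor concentrations")
        self.x = np.log10(conc)
        self.y = np.asarray(comp["signal"], dtype=float)
        self.hot_conc_M = work.hot_conc_M
        self.hot_kd_M = work.hot_kd_M

    def fit(self) -> KiResult:
        x, y = self.x, self.y

        def residuals(p):
            bottom, span, logic50 = p
            return bottom + span / (1.0 + 10.0 ** (x - logic50)) - y

        ymin, ymax = float(y.min()), float(y.max())
        spread = max(ymax - ymin, 1e-9)
        lo = np.array([ymin - spread, 0.0, x.min() - 3.0])
        hi = np.array([ymax + spread, 2.0 * spread + 1e-9, x.max() + 3.0])
        starts = [(ymin, spread, x0) for x0 in (x.min(), np.median(x), x.max())]
        best = _multistart_least_squares(residuals, starts, (lo, hi))
        nan = float("nan")
        if best is None:
            return KiResult(nan, nan, nan, nan, nan, nan, nan, False, len(y))
        bottom, span, logic50 = best.x
        cov = _covariance(best, len(y))
        se_log = float(np.sqrt(max(cov[2, 2], 0)))
        ic50 = 10.0**logic50
        se_ic50 = ic50 * np.log(10.0) * se_log
        spread_ok = span > 1e-6 * max(abs(ymax), 1.0)
        in_range = x.min() - 2.9 < logic50 < x.max() + 2.9
        converged = bool(spread_ok and in_range and np.isfinite(se_log))
        ki = cheng_prusoff(ic50, self.hot_conc_M, self.hot_kd_M)
        return KiResult(
            float(ic50), float(se_ic50), float(ki), pki(ki), se_log,
            float(bottom + span), float(bottom), converged, len(y),
        )


def cheng_prusoff(ic50: float, hot_conc: float, hot_kd: float) -> float:
    """Ki = IC50 / (1 + [hot]/Kd_hot); all quantities molar."""
    if hot_kd <= 0:
        raise ValueError("hot-ligand Kd must be positive")
    if hot_conc < 0 or ic50 <= 0:
        raise ValueError("IC50 and hot-ligand concentration must be positive")
    return ic50 / (1.0 + hot_conc / hot_kd)


def pki(ki_M: float) -> float:
    """pKi = -log10(Ki in molar)."""
    if ki_M <= 0:
        raise ValueError("Ki must be positive")
    return float(-np.log10(ki_M))


def ki_from_pki_nM(pki_value: float) -> float:
    """Inverse conversion at the reporting boundary: Ki in nM from pKi."""
    return float(10.0 ** (9.0 - pki_value))


def fold_selectivity(ki_by_target: Mapping[str, float], anchor: str | None = None) -> pd.DataFrame:
    """Fold selectivity of every target relative to an anchor.

    fold(target) = Ki(target) / Ki(anchor); the anchor defaults to the
    highest-affinity (lowest-Ki) target.  Scale-invariant by construction.
    """
    if len(ki_by_target) < 2:
        raise ValueError("need Ki for at least two targets")
    for t, k in ki_by_target.items():
        if not np.isfinite(k) or k <= 0:
            raise ValueError(f"Ki for {t!r} must be finite and positive")
    if anchor is None:
        anchor = min(ki_by_target, key=ki_by_target.get)
    if anchor not in ki_by_target:
        raise KeyError(anchor)
    ka = ki_by_target[anchor]
    rows = [
        {"target": t, "anchor": anchor, "ki": k, "fold": k / ka}
        for t, k in sorted(ki_by_target.items(), key=lambda kv: kv[1])
    ]
    return pd.DataFrame.from_records(rows)


def min_fold_selectivity(ki_by_target: Mapping[str, float], anchors: Sequence[str],
                         others: Sequence[str] | None = None) -> float:
    """Worst-case selectivity of an anchor set over competing targets.

    min over others of Ki(other) / max over anchors of Ki(anchor) - i.e. the
    closest competitor measured against the weakest primary target.
    """
    if others is None:
        others = [t for t in ki_by_target if t not in set(anchors)]
    if not anchors or not others:
        raise ValueError("need at least one anchor and one competing target")
    worst_anchor = max(ki_by_target[a] for a in anchors)
    nearest_other = min(ki_by_target[o] for o in others)
    return nearest_other / worst_anchor
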