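"""Dose-response models: three-parameter logistic and the Black–Leff
operational model, plus the normalisation contracts that precede them.

The operational model links agonist concentration ``A`` to response through
an efficacy parameter ``tau`` (receptor density x coupling) and a functional
affinity ``K_A``::

    E(A) = Em * (tau*A)**n / ((A + K_A)**n + (tau*A)**n)

For a transducer-slope of ``n = 1`` this is algebraically a logistic with
observed maximum ``Em*tau/(1+tau)`` and EC50 ``K_A/(1+tau)``; the composite
transduction coefficient ``log10(tau/K_A)`` is identifiable even when
``tau`` and ``K_A`` separately are not (full agonists).  Both the joint
(tau, K_A) and the composite parameterisations are provided and agree on
noise-free data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .panels import ConcResponsePanel

__all__ = [
    "logistic3",
    "operational_response",
    "logistic_to_logR",
    "LogisticCurve",
    "LogisticResults",
    "OperationalModel",
    "OperationalResults",
    "LowSignalVerdict",
    "low_signal_check",
    "normalize_to_reference",
    "bret_ratio",
    "mask_biphasic",
]

FULL_AGONIST_FRACTION = 0.95


def logistic3(x, bottom, top, logec50, slope=1.0):
    """Three-parameter logistic in x = log10(concentration), Hill slope fixed."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logec50 - np.asarray(x, float))))


def operational_response(conc, em, tau, ka, n_hill=1.0):
    """Operational-model response at concentration(s) ``conc`` (molar).

    Returns 0 at ``conc = 0`` and approaches ``Em*tau^n/(1+tau^n)`` as
    ``conc`` grows; always strictly below ``Em``.
    """
    a = np.asarray(conc, dtype=float)
    if np.any(a < 0):
        raise ValueError("concentration must be non-negative")
    num = (tau * a) ** n_hill
    den = (a + ka) ** n_hill + num
    with np.errstate(invalid="ignore"):
        out = em * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out if out.shape else float(out)


def logistic_to_logR(emax_obs, ec50_obs, em):
    """Closed-form log10(tau/K_A) from observed logistic parameters (n = 1).

    From ``tau/(1+tau) = Emax_obs/Em`` and ``EC50_obs = K_A/(1+tau)``::

        log10(tau/K_A) = log10(Emax_obs/Em) - log10(EC50_obs)
    """
    if ec50_obs <= 0:
        raise ValueError("EC50 must be positive")
    if emax_obs <= 0:
        raise ValueError("observed Emax must be positive (degenerate curve)")
    if emax_obs > em * (1 + 1e-9):
        raise ValueError("observed Emax exceeds the system maximum Em")
    return float(np.log10(emax_obs / em) - np.log10(ec50_obs))


def _multistart_least_squares(residuals, starts, bounds):
    """Bounded least squares from several starts; lowest-cost solution wins."""
    best = None
    lo, hi = bounds
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, float), lo, hi)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.least_squares(residuals, x0, bounds=bounds, method="trf")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost - 1e-12):
            best = res
    return best


def _covariance(res, n_obs):
    """Asymptotic parameter covariance from the final Jacobian."""
    _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
    s = np.where(s > np.finfo(float).eps * max(res.jac.shape) * s.max(), s, np.inf)
    jtj_inv = vt.T @ np.diag(1.0 / s**2) @ vt
    dof = max(n_obs - len(res.x), 1)
    s2 = 2.0 * res.cost / dof
    return jtj_inv * s2


@dataclass
class LogisticResults:
    """Fitted three-parameter logistic curve."""

    bottom: float
    top: float
    logec50: float
    se_bottom: float
    se_top: float
    se_logec50: float
    slope: float
    converged: bool
    n_points: int
    rss: float = float("nan")

    @property
    def ec50(self) -> float:
        return 10.0 ** self.logec50

    @property
    def span(self) -> float:
        return self.top - self.bottom

    def predict(self, conc):
        return logistic3(np.log10(np.asarray(conc, float)), self.bottom, self.top,
                         self.logec50, self.slope)

    def summary(self) -> str:
        lines = [
            "Three-parameter logistic fit",
            f"  n points    : {self.n_points}",
            f"  bottom      : {self.bottom:10.3f} (SE {self.se_bottom:.3f})",
            f"  top         : {self.top:10.3f} (SE {self.se_top:.3f})",
            f"  logEC50 (M) : {self.logec50:10.3f} (SE {self.se_logec50:.3f})",
            f"  EC50        : {self.ec50:.3e} M",
            f"  converged   : {self.converged}",
        ]
        return "\n".join(lines)


class LogisticCurve:
    """Three-parameter logistic dose-response model, Hill slope fixed at 1.

    Parameters
    ----------
    concentration : array-like, molar (strictly positive)
    response : array-like, same length
    slope : float
        Hill slope, fixed (not estimated); default 1.

    ``fit()`` returns :class:`LogisticResults`.  Non-convergence is reported
    through the ``converged`` flag rather than an exception; fewer than four
    distinct concentrations is refused outright.
    """

    def __init__(self, concentration, response, slope: float = 1.0):
        conc = np.asarray(concentration, dtype=float)
        resp = np.asarray(response, dtype=float)
        if conc.shape != resp.shape:
            raise ValueError("concentration and response lengths differ")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(conc)) < 4:
            raise ValueError("need at least 4 distinct concentrations to fit")
        self.x = np.log10(conc)
        self.y = resp
        self.slope = float(slope)

    @classmethod
    def from_panel(cls, panel: ConcResponsePanel, slope: float = 1.0) -> "LogisticCurve":
        return cls(panel.data["concentration_M"], panel.data["response"], slope=slope)

    def fit(self) -> LogisticResults:
        x, y, slope = self.x, self.y, self.slope

        def residuals(p):
            bottom, span, logec50 = p
            return logistic3(x, bottom, bottom + span, logec50, slope) - y

        ymin, ymax = float(y.min()), float(y.max())
        spread = max(ymax - ymin, 1e-9)
        lo = np.array([ymin - spread, 0.0, x.min() - 3.0])
        hi = np.array([ymax + spread, 2.0 * spread + 1e-9, x.max() + 3.0])
        starts = [
            (ymin, spread, x0) for x0 in (x.min(), np.median(x), x.max())
        ]
        best = _multistart_least_squares(residuals, starts, (lo, hi))
        nan = float("nan")
        if best is None:
            return LogisticResults(nan, nan, nan, nan, nan, nan, slope, False, len(y))
        bottom, span, logec50 = best.x
        cov = _covariance(best, len(y))
        se_b = float(np.sqrt(max(cov[0, 0], 0)))
        se_span = cov[1, 1]
        se_top = float(np.sqrt(max(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1], 0)))
        se_l = float(np.sqrt(max(cov[2, 2], 0)))
        # a fit pinned to the logEC50 bound has not located a transition
        converged = bool(x.min() - 2.9 < logec50 < x.max() + 2.9 and np.isfinite(se_l))
        return LogisticResults(
            float(bottom), float(bottom + span), float(logec50),
            se_b, se_top, se_l, slope, converged, len(y), rss=float(2 * best.cost),
        )


@dataclass
class OperationalResults:
    """Fitted operational model for one concentration-response curve."""

    em: float
    tau: float
    ka: float
    n_hill: float
    log_r: float          # log10(tau/K_A), the transduction coefficient
    se_log_r: float
    converged: bool
    full_agonist: bool
    n_points: int
    identifiability_note: str = ""
    rss: float = float("nan")

    @property
    def emax_obs(self) -> float:
        t = self.tau ** self.n_hill
        return self.em * t / (1.0 + t)

    def predict(self, conc):
        return operational_response(conc, self.em, self.tau, self.ka, self.n_hill)

    def summary(self) -> str:
        lines = [
            "Operational (Black-Leff) model fit",
            f"  Em (fixed)       : {self.em:.3f}",
            f"  tau              : {self.tau:.4g}",
            f"  K_A              : {self.ka:.4g} M",
            f"  log10(tau/K_A)   : {self.log_r:.4f} (SE {self.se_log_r:.4f})",
            f"  full agonist     : {self.full_agonist}",
            f"  converged        : {self.converged}",
        ]
        if self.identifiability_note:
            lines.append(f"  note             : {self.identifiability_note}")
        return "\n".join(lines)


class OperationalModel:
    """Operational-model fit with the system maximum ``Em`` held fixed.

    ``Em`` comes from the reference agonist's fitted top in the same pathway
    (100 on the normalised scale).  The default composite parameterisation
    estimates ``(log10(tau/K_A), log10 tau)`` so the transduction
    coefficient's standard error is read directly off the covariance; the
    alternative ``parameterization="tau_ka"`` estimates ``(log10 tau,
    log10 K_A)`` jointly and propagates the SE of the difference.
    """

    def __init__(self, concentration, response, em, n_hill: float = 1.0,
                 parameterization: str = "composite"):
        conc = np.asarray(concentration, dtype=float)
        resp = np.asarray(response, dtype=float)
        if conc.shape != resp.shape:
            raise ValueError("concentration and response lengths differ")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(conc)) < 4:
            raise ValueError("need at least 4 distinct concentrations to fit")
        if em <= 0:
            raise ValueError("Em must be positive")
        if parameterization not in ("composite", "tau_ka"):
            raise ValueError("parameterization must be 'composite' or 'tau_ka'")
        self.conc = conc
        self.y = resp
        self.em = float(em)
        self.n_hill = float(n_hill)
        self.parameterization = parameterization

    @classmethod
    def from_panel(cls, panel: ConcResponsePanel, em, **kw) -> "OperationalModel":
        return cls(panel.data["concentration_M"], panel.data["response"], em, **kw)

    # -- internals ---------------------------------------------------------

    def _fit_composite(self):
        conc, y, em, n = self.conc, self.y, self.em, self.n_hill

        def residuals(p):
            log_r, log_tau = p
            tau = 10.0 ** log_tau
            ka = tau * 10.0 ** (-log_r)
            return operational_response(conc, em, tau, ka, n) - y

        lx = np.log10(conc)
        lo = np.array([-lx.max() - 6.0, -4.0])
        hi = np.array([-lx.min() + 6.0, 6.0])
        starts = [(-x0, 0.5) for x0 in (lx.min(), np.median(lx), lx.max())]
        best = _multistart_least_squares(residuals, starts, (lo, hi))
        if best is None:
            return None
        log_r, log_tau = best.x
        cov = _covariance(best, len(y))
        return best, float(log_r), float(log_tau), float(np.sqrt(max(cov[0, 0], 0)))

    def _fit_tau_ka(self):
        conc, y, em, n = self.conc, self.y, self.em, self.n_hill

        def residuals(p):
            log_tau, log_ka = p
            return operational_response(conc, em, 10.0 ** log_tau, 10.0 ** log_ka, n) - y

        lx = np.log10(conc)
        lo = np.array([-4.0, lx.min() - 6.0])
        hi = np.array([6.0, lx.max() + 6.0])
        starts = [(0.5, k0) for k0 in (lx.min(), np.median(lx), lx.max())]
        best = _multistart_least_squares(residuals, starts, (lo, hi))
        if best is None:
            return None
        log_tau, log_ka = best.x
        cov = _covariance(best, len(y))
        var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
        return best, float(log_tau - log_ka), float(log_tau), float(np.sqrt(max(var, 0)))

    def fit(self) -> OperationalResults:
        out = self._fit_composite() if self.parameterization == "composite" else self._fit_tau_ka()
        nan = float("nan")
        if out is None:
            return OperationalResults(self.em, nan, nan, self.n_hill, nan, nan,
                                      False, False, len(self.y))
        best, log_r, log_tau, se_log_r = out
        tau = 10.0 ** log_tau
        ka = tau * 10.0 ** (-log_r)
        full = tau ** self.n_hill / (1.0 + tau ** self.n_hill) >= FULL_AGONIST_FRACTION
        note = ("full-agonist limit: tau and K_A not separately identifiable; "
                "log10(tau/K_A) remains well determined") if full else ""
        return OperationalResults(
            self.em, float(tau), float(ka), self.n_hill, log_r, se_log_r,
            converged=bool(np.isfinite(log_r)), full_agonist=bool(full),
            n_points=len(self.y), identifiability_note=note, rss=float(2 * best.cost),
        )


@dataclass
class LowSignalVerdict:
    """Outcome of the minimum-signal screen applied before operational fits.

    A panel whose response span is a small fraction of the reference maximum,
    or indistinguishable from well noise, cannot support a transduction
    coefficient; the pipeline reports such ligands as not determined instead
    of forcing a number.
    """

    too_low: bool
    span: float
    max_mean_response: float
    snr: float
    min_span_pct: float
    min_snr: float


def low_signal_check(panel: ConcResponsePanel, min_span_pct: float = 10.0,
                     min_snr: float = 3.0, noise_sd: float | None = None) -> LowSignalVerdict:
    """Screen a normalised panel for a fittable signal.

    ``too_low`` when the concentration-mean span is below ``min_span_pct``
    (percent of the reference maximum, i.e. of 100 on the normalised scale)
    or the span-to-noise ratio falls below ``min_snr``.  Noise is the pooled
    within-concentration replicate SD unless supplied.
    """
    means = panel.mean_by_concentration()
    span = float(means.max() - means.min())
    sd = noise_sd if noise_sd is not None else panel.pooled_replicate_sd()
    snr = span / sd if (sd is not None and np.isfinite(sd) and sd > 0) else float("inf")
    too_low = span < min_span_pct or snr < min_snr
    return LowSignalVerdict(bool(too_low), span, float(means.max()), float(snr),
                            min_span_pct, min_snr)


def normalize_to_reference(panel: ConcResponsePanel,
                           reference_panel: ConcResponsePanel) -> ConcResponsePanel:
    """Rescale responses so the reference agonist's fitted top is 100.

    The reference panel (same receptor/pathway/assay grouping) is fitted with
    the three-parameter logistic; responses of ``panel`` are mapped through
    ``100 * (r - bottom_ref) / (top_ref - bottom_ref)``.  Refused when the
    reference fit does not converge.
    """
    ref_fit = LogisticCurve.from_panel(reference_panel).fit()
    if not ref_fit.converged:
        raise ValueError(
            f"reference fit for {reference_panel.ligand!r} did not converge; "
            "normalization refused"
        )
    if ref_fit.span <= 0:
        raise ValueError("reference curve has no span; normalization refused")
    out = panel.data.copy()
    out["response"] = 100.0 * (out["response"] - ref_fit.bottom) / ref_fit.span
    return ConcResponsePanel(
        panel.ligand, panel.receptor, panel.pathway, out,
        reference_ligand=reference_panel.ligand, truth=panel.truth, normalized=True,
    )


def bret_ratio(acceptor_counts, donor_counts, vehicle_ratio=None):
    """Per-well BRET ratio: acceptor emission over donor emission.

    Wells with non-positive donor counts are flagged and excluded (NaN).
    When ``vehicle_ratio`` is given (scalar or array of vehicle-well ratios),
    its mean is subtracted to yield the drug-induced net BRET signal.

    Returns ``(ratio, flagged)`` arrays of equal length.
    """
    acc = np.asarray(acceptor_counts, dtype=float)
    don = np.asarray(donor_counts, dtype=float)
    if acc.shape != don.shape:
        raise ValueError("acceptor and donor series differ in length")
    flagged = ~(don > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(flagged, np.nan, acc / np.where(flagged, 1.0, don))
    if vehicle_ratio is not None:
        ratio = ratio - np.nanmean(np.asarray(vehicle_ratio, dtype=float))
    return ratio, flagged


def mask_biphasic(panel: ConcResponsePanel, n_se: float = 3.0,
                  max_masked: int = 3) -> tuple[ConcResponsePanel, list[float]]:
    """Mask a high-concentration upturn before monophasic fitting.

    Some arrestin-recruitment curves rise again at the highest
    concentrations (a second signalling wave).  Working down from the top
    concentration, a point is masked when its mean response exceeds the
    plateau of a logistic fitted to the remaining data by more than ``n_se``
    residual standard errors.  Returns the (possibly) reduced panel and the
    list of masked concentrations, highest first.
    """
    masked: list[float] = []
    current = panel
    for _ in range(max_masked):
        concs = current.concentrations
        if len(concs) <= 4:
            break
        top_conc = concs[-1]
        keep = current.data[current.data["concentration_M"] < top_conc]
        reduced = ConcResponsePanel(panel.ligand, panel.receptor, panel.pathway,
                                    keep.reset_index(drop=True),
                                    panel.reference_ligand, panel.truth, panel.normalized)
        fit = LogisticCurve.from_panel(reduced).fit()
        if not fit.converged:
            break
        resid_sd = np.sqrt(fit.rss / max(fit.n_points - 3, 1))
        top_mean = current.mean_by_concentration().loc[top_conc]
        n_top = (current.data["concentration_M"] == top_conc).sum()
        if top_mean > fit.top + n_se * resid_sd / np.sqrt(n_top):
            masked.append(float(top_conc))
            current = reduced
        else:
            break
    return current, masked
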