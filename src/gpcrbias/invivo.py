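"""In-vivo endpoint analysis: warm-water tail-withdrawal antinociception
(%MPE, ED50 with asymmetric 95% CI), conditioned-place-preference difference
scores with a Welch t test, and vehicle-normalised 20-minute binning of
respiratory/locomotor minute counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .doseresponse import _covariance, _multistart_least_squares
from .panels import LatencyTable

__all__ = [
    "percent_mpe",
    "mpe_table",
    "Ed50Model",
    "Ed50Result",
    "fit_ed50",
    "cpp_score",
    "CppResult",
    "welch_t",
    "normalize_to_vehicle",
]

DEFAULT_CUTOFF_S = 15.0
#: antinociception peaked at this time point after injection
DEFAULT_PEAK_TIME_MIN = 10.0


def percent_mpe(test_s, baseline_s, cutoff_s: float = DEFAULT_CUTOFF_S,
                return_flags: bool = False):
    """Percent of maximum possible antinociceptive effect.

    %MPE = 100 * (test - baseline) / (cutoff - baseline).  A test latency at
    or beyond the cutoff scores the maximum of 100 (the tail is removed from
    the water at the cutoff, so longer latencies are unobservable).
    Hyperalgesic (sub-baseline) latencies are clamped at -100 and flagged.
    The score is invariant to any common linear rescaling of the three
    latencies (e.g. a change of time unit).
    """
    test = np.asarray(test_s, dtype=float)
    base = np.asarray(baseline_s, dtype=float)
    if np.any(base >= cutoff_s):
        raise ValueError("baseline latency must lie below the cutoff")
    raw = 100.0 * (test - base) / (cutoff_s - base)
    raw = np.where(test >= cutoff_s, 100.0, raw)
    clamped = raw < -100.0
    out = np.clip(raw, -100.0, 100.0)
    if out.ndim == 0:
        out = float(out)
        clamped = bool(clamped)
    if return_flags:
        return out, clamped
    return out


def mpe_table(latencies: LatencyTable, time_min: float | None = DEFAULT_PEAK_TIME_MIN) -> pd.DataFrame:
    """Per-mouse %MPE at one time point (default: the 10-min peak effect)."""
    df = latencies.data
    if time_min is not None and "time_min" in df.columns:
        sel = df[df["time_min"] == time_min]
        if len(sel) == 0:
            raise ValueError(f"no rows at time_min={time_min}")
        df = sel
    out = df[["mouse", "dose", "dose_unit"]].copy()
    out["mpe"] = percent_mpe(df["test_s"].to_numpy(), df["baseline_s"].to_numpy(),
                             latencies.cutoff_s)
    return out.reset_index(drop=True)


@dataclass
class Ed50Result:
    """Median effective dose from a logistic fit in log10(dose).

    The 95% CI is computed on the log scale and antilogged, so it is
    symmetric in log dose and asymmetric on the dose axis (matching how
    such intervals are conventionally reported).
    """

    ed50: float
    hill: float
    log_ed50: float
    se_log_ed50: float
    ci_lo: float
    ci_hi: float
    converged: bool
    extrapolated: bool
    n_points: int
    dose_unit: str = "nmol"

    def summary(self) -> str:
        return "\n".join([
            "ED50 fit (logistic in log dose, 0-100% MPE)",
            f"  ED50      : {self.ed50:.3g} {self.dose_unit} "
            f"(95% CI {self.ci_lo:.3g}-{self.ci_hi:.3g})",
            f"  Hill slope: {self.hill:.3f}",
            f"  converged : {self.converged}"
            + ("  [extrapolated: responses do not bracket 50%]" if self.extrapolated else ""),
        ])


class Ed50Model:
    """Dose-response model for %MPE: bottom fixed at 0, top fixed at 100.

    %MPE(d) = 100 / (1 + 10**(h * (logED50 - log10 d))); the ED50 and Hill
    slope ``h`` are estimated by least squares, and the CI uses a t critical
    value with n - 2 degrees of freedom on logED50.
    """

    def __init__(self, dose, mpe, dose_unit: str = "nmol", alpha: float = 0.05):
        d = np.asarray(dose, dtype=float)
        y = np.asarray(mpe, dtype=float)
        if np.any(d <= 0):
            raise ValueError("doses must be strictly positive")
        if len(np.unique(d)) < 3:
            raise ValueError("need at least 3 distinct doses")
        self.logd = np.log10(d)
        self.y = y
        self.dose_unit = dose_unit
        self.alpha = alpha

    @classmethod
    def from_latencies(cls, latencies: LatencyTable,
                       time_min: float | None = DEFAULT_PEAK_TIME_MIN, **kw) -> "Ed50Model":
        t = mpe_table(latencies, time_min)
        unit = t["dose_unit"].iloc[0] if len(t) else "nmol"
        return cls(t["dose"], t["mpe"], dose_unit=unit, **kw)

    def fit(self) -> Ed50Result:
        x, y = self.logd, self.y
        group_means = pd.Series(y).groupby(pd.Series(x)).mean()
        extrapolated = not (group_means.min() < 50.0 < group_means.max())
        flat = group_means.max() - group_means.min() < 1e-9

        def residuals(p):
            log_ed50, hill = p
            return 100.0 / (1.0 + 10.0 ** (hill * (log_ed50 - x))) - y

        lo = np.array([x.min() - 3.0, 0.05])
        hi = np.array([x.max() + 3.0, 10.0])
        starts = [(x0, h0) for x0 in (x.min(), np.median(x), x.max()) for h0 in (0.5, 1.0, 2.0)]
        best = _multistart_least_squares(residuals, starts, (lo, hi))
        nan = float("nan")
        if best is None or flat:
            return Ed50Result(nan, nan, nan, nan, nan, nan, False, extrapolated,
                              len(y), self.dose_unit)
        log_ed50, hill = best.x
        cov = _covariance(best, len(y))
        se = float(np.sqrt(max(cov[0, 0], 0)))
        df = max(len(y) - 2, 1)
        tcrit = stats.t.ppf(1.0 - self.alpha / 2.0, df)
        in_range = x.min() - 2.9 < log_ed50 < x.max() + 2.9
        return Ed50Result(
            float(10.0**log_ed50), float(hill), float(log_ed50), se,
            float(10.0 ** (log_ed50 - tcrit * se)), float(10.0 ** (log_ed50 + tcrit * se)),
            converged=bool(in_range and np.isfinite(se)),
            extrapolated=bool(extrapolated), n_points=len(y), dose_unit=self.dose_unit,
        )


def fit_ed50(dose, mpe, **kw) -> Ed50Result:
    """Functional wrapper around :class:`Ed50Model`."""
    return Ed50Model(dose, mpe, **kw).fit()


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, p, df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


@dataclass
class CppResult:
    """Conditioned place preference difference scores for one group."""

    deltas: np.ndarray
    mean: float
    sem: float
    t: float
    p: float
    df: float
    degenerate_variance: bool

    def summary(self) -> str:
        return (f"CPP difference score: {self.mean:.1f} +/- {self.sem:.1f} s "
                f"(Welch t = {self.t:.3f}, p = {self.p:.4g}, df = {self.df:.1f})"
                + ("  [degenerate variance]" if self.degenerate_variance else ""))


def cpp_score(pre_times_s, post_times_s) -> CppResult:
    """Drug-side time difference scores with a Welch t test of post vs pre.

    ``pre_times_s`` and ``post_times_s`` are per-animal times spent on the
    drug-paired side before and after conditioning, in seconds, paired by
    position.  Delta = post - pre per animal; the test compares the post and
    pre samples as independent groups (Welch correction), matching how such
    preference shifts are usually tested.
    """
    pre = np.asarray(pre_times_s, dtype=float)
    post = np.asarray(post_times_s, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post sessions have inconsistent animal counts")
    if len(pre) < 2:
        raise ValueError("need at least two animals")
    deltas = post - pre
    degenerate = bool(np.var(pre, ddof=1) == 0 and np.var(post, ddof=1) == 0)
    if degenerate:
        t = 0.0 if np.allclose(pre.mean(), post.mean()) else float("inf")
        p = 1.0 if t == 0.0 else 0.0
        df = float(len(pre) - 1)
    else:
        t, p, df = welch_t(post, pre)
    sem = float(deltas.std(ddof=1) / np.sqrt(len(deltas)))
    return CppResult(deltas, float(deltas.mean()), sem, t, p, df, degenerate)


def normalize_to_vehicle(series: pd.DataFrame, vehicle: pd.DataFrame,
                         bin_min: int = 20, value_col: str = "value") -> pd.DataFrame:
    """Express binned group means as percent of the vehicle group.

    Inputs are minute-resolution tables with columns ``minute`` and
    ``value_col`` (plus anything else, ignored).  Minutes are averaged in
    non-overlapping ``bin_min``-minute segments; each group bin mean is then
    divided by the matching vehicle bin mean (x100).  Bins where the vehicle
    mean is zero are flagged and reported as NaN.
    """
    def binned(df):
        d = df.copy()
        d["bin"] = (d["minute"].astype(int)) // bin_min
        return d.groupby("bin")[value_col].mean()

    g = binned(series)
    v = binned(vehicle)
    common = g.index.intersection(v.index)
    if len(common) == 0:
        raise ValueError("group and vehicle series share no time bins")
    out = pd.DataFrame({
        "bin": common,
        "bin_start_min": common * bin_min,
        "group_mean": g.loc[common].to_numpy(),
        "vehicle_mean": v.loc[common].to_numpy(),
    })
    zero = out["vehicle_mean"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_vehicle"] = np.where(zero, np.nan,
                                      100.0 * out["group_mean"] / out["vehicle_mean"])
    out["flagged"] = zero
    return out.reset_index(drop=True)
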