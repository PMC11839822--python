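"""Non-compartmental analysis of per-hen residue series.

Model-free summary of a concentration-time profile: observed Cmax/Tmax, the
terminal elimination rate constant (lambda_z) from a best-fit log-linear
regression over candidate terminal windows, the half-life t1/2 = ln2 /
lambda_z, and the AUC by the linear trapezoidal rule with exponential
extrapolation to infinity. Internal PK time unit is hours; series built from
the pipeline carry times in days and are converted on entry.

The best-fit rule mirrors the common NCA convention: among the candidate
sets formed by the last k post-peak points (k = 3 ... all, the peak itself
excluded unless too few points remain), pick the window maximising the
adjusted R^2 of the ln(concentration)-vs-time regression, preferring more
points on ties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import HOURS_PER_DAY, ResidueSeries

__all__ = [
    "TerminalFit",
    "NcaResult",
    "FlockNcaSummary",
    "observed_peak",
    "fit_terminal",
    "auc_linear",
    "run_nca",
    "summarize_flock",
    "geometric_mean",
]

#: adjusted-R^2 values within this of the best are tied; ties prefer the
#: larger candidate window (the conventional best-fit threshold)
_R2_TIE_TOL = 1e-4


class NcaError(ValueError):
    """Series unusable for the requested NCA step."""


@dataclass(frozen=True)
class TerminalFit:
    """Terminal log-linear regression: ln C = intercept - lambda_z * t (t in h)."""

    lambda_z: float  # 1/h
    intercept: float  # ln(ng/g)
    n_points: int
    adj_r_squared: float
    span: tuple[float, float]  # hours, first/last point used

    def __post_init__(self) -> None:
        if self.lambda_z <= 0:
            raise ValueError("lambda_z must be > 0")
        if self.n_points < 3:
            raise ValueError("terminal fit needs >= 3 points")


@dataclass(frozen=True)
class NcaResult:
    """Per-hen NCA parameter set (hours / ng/g units)."""

    hen_id: str
    cmax_obs: float  # ng/g
    tmax_obs: float  # h
    lambda_z: float  # 1/h
    t_half: float  # h
    auc_last: float  # h*ng/g
    auc_inf: float  # h*ng/g
    pct_extrapolated: float  # %
    terminal_fit: TerminalFit

    def __post_init__(self) -> None:
        if self.auc_inf < self.auc_last:
            raise ValueError("auc_inf must be >= auc_last")
        if not (0.0 <= self.pct_extrapolated < 100.0):
            raise ValueError("pct_extrapolated outside [0, 100)")


def observed_peak(series: ResidueSeries) -> tuple[float, float]:
    """(cmax_obs ng/g, tmax_obs days) straight from the data, ties to the
    earliest time."""
    if len(series) == 0:
        raise NcaError(f"empty series for hen {series.hen_id}")
    idx = int(np.argmax(series.concentrations))  # argmax takes the first max
    return series.concentrations[idx], series.times[idx]


def _ols_loglinear(
    t_h: np.ndarray, ln_c: np.ndarray
) -> tuple[float, float, float, float]:
    """Slope, intercept, adjusted R^2 and residual SD of ln C on time (h)."""
    n = len(t_h)
    slope, intercept = np.polyfit(t_h, ln_c, 1)
    resid = ln_c - (intercept + slope * t_h)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((ln_c - ln_c.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    s = math.sqrt(max(ss_res, 0.0) / (n - 2))
    return float(slope), float(intercept), adj, s


def fit_terminal(
    series: ResidueSeries,
    points: Sequence[int] | None = None,
) -> TerminalFit:
    """Best-fit terminal log-linear regression, or a manual point selection.

    ``points`` (indices into the series) overrides the automatic rule.
    Automatic rule: candidates are the last k points after Tmax (Tmax
    excluded unless fewer than 3 points would remain), k from 3 up; the
    candidate with the highest adjusted R^2 wins, with ties going to the
    larger window. Candidates with a non-negative slope are rejected; if all
    are, no terminal phase is identifiable. Windows spanning less than two
    of their own estimated half-lives are considered unreliable (the usual
    lambda_z acceptance criterion) and are only used if no candidate passes
    the span check.
    """
    t_h = np.asarray(series.times, dtype=float) * HOURS_PER_DAY
    ln_c = np.log(np.asarray(series.concentrations, dtype=float))
    if points is not None:
        idx = np.asarray(sorted(points), dtype=int)
        if len(idx) < 3:
            raise NcaError("manual terminal fit needs >= 3 points")
        slope, intercept, adj, _ = _ols_loglinear(t_h[idx], ln_c[idx])
        if slope >= 0:
            raise NcaError("manual point selection has non-negative slope")
        return TerminalFit(-slope, intercept, len(idx), adj,
                           (float(t_h[idx[0]]), float(t_h[idx[-1]])))

    peak_idx = int(np.argmax(series.concentrations))
    start = peak_idx + 1  # exclude Tmax from candidates
    if len(series) - start < 3:
        start = peak_idx  # too few points: allow Tmax in
    m = len(series) - start
    if m < 3:
        raise NcaError(
            f"hen {series.hen_id}: only {m} post-peak points, need >= 3"
        )
    candidates: list[tuple[float, float, float, float, int, bool]] = []
    for k in range(3, m + 1):
        lo = len(series) - k
        if lo < start:
            break
        slope, intercept, adj, s_res = _ols_loglinear(t_h[lo:], ln_c[lo:])
        if slope >= 0:
            continue
        span_h = t_h[-1] - t_h[lo]
        span_ok = span_h >= 2.0 * (math.log(2) / -slope)
        candidates.append((slope, intercept, adj, s_res, lo, span_ok))
    if not candidates:
        raise NcaError(
            f"hen {series.hen_id}: no candidate window with negative slope"
        )
    pool = [c for c in candidates if c[5]]
    if pool:
        best = max(pool, key=lambda c: c[2])
        # a longer window only counts as tied if it fits comparably well in
        # absolute terms too: adjusted R^2 alone is scale-dependent and, on
        # data spanning several decades, would wave through windows with
        # visible curvature
        tied = [
            c for c in pool
            if c[2] >= best[2] - _R2_TIE_TOL and c[3] <= 2.0 * best[3] + 1e-12
        ]
        best_fit = min(tied, key=lambda c: c[4])  # most points, earliest start
    else:
        # no window is reliable; take the one covering the most half-lives
        best_fit = max(
            candidates, key=lambda c: (t_h[-1] - t_h[c[4]]) * -c[0]
        )
    slope, intercept, adj, _, lo, _ = best_fit
    return TerminalFit(-slope, intercept, len(series) - lo, adj,
                       (float(t_h[lo]), float(t_h[-1])))


def auc_linear(
    series: ResidueSeries, fit: TerminalFit | None
) -> tuple[float, float, float]:
    """(auc_last, auc_inf, pct_extrapolated) by the linear trapezoidal rule.

    auc_last sums trapezoids over the observed points (h * ng/g); the tail
    beyond the last observation is C_last / lambda_z; pct_extrapolated is
    the tail's share of auc_inf in percent. With ``fit=None`` only auc_last
    is computed (auc_inf = auc_last, 0% extrapolated).
    """
    if len(series) < 2:
        raise NcaError("AUC needs at least 2 points")
    t_h = np.asarray(series.times, dtype=float) * HOURS_PER_DAY
    c = np.asarray(series.concentrations, dtype=float)
    auc_last = float(np.trapezoid(c, t_h))
    if fit is None:
        return auc_last, auc_last, 0.0
    tail = float(c[-1]) / fit.lambda_z
    auc_inf = auc_last + tail
    return auc_last, auc_inf, 100.0 * tail / auc_inf


def run_nca(series: ResidueSeries) -> NcaResult:
    """Full NCA of one hen's series (times in days on input)."""
    cmax, tmax_days = observed_peak(series)
    fit = fit_terminal(series)
    auc_last, auc_inf, pct = auc_linear(series, fit)
    return NcaResult(
        hen_id=series.hen_id,
        cmax_obs=cmax,
        tmax_obs=tmax_days * HOURS_PER_DAY,
        lambda_z=fit.lambda_z,
        t_half=math.log(2) / fit.lambda_z,
        auc_last=auc_last,
        auc_inf=auc_inf,
        pct_extrapolated=pct,
        terminal_fit=fit,
    )


def geometric_mean(values: Iterable[float]) -> float:
    """exp(mean(ln x)); the standard summary for lognormal PK parameters."""
    arr = np.asarray(list(values), dtype=float)
    if len(arr) == 0:
        raise NcaError("geometric mean of empty set")
    if np.any(arr <= 0):
        raise NcaError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))


_SUMMARY_PARAMS = (
    "cmax_obs",
    "tmax_obs",
    "lambda_z",
    "t_half",
    "auc_last",
    "auc_inf",
    "pct_extrapolated",
)


@dataclass(frozen=True)
class FlockNcaSummary:
    """Geometric mean and (min, max) range per NCA parameter over hens."""

    n_hens: int
    geometric_means: Mapping[str, float]
    ranges: Mapping[str, tuple[float, float]]


def summarize_flock(results: Sequence[NcaResult]) -> FlockNcaSummary:
    """Flock-level summary: geometric mean and range for each parameter,
    computed over hens with a valid terminal fit. Non-positive parameter
    values are excluded from that parameter's summary with a warning."""
    if not results:
        raise NcaError("no NCA results to summarize")
    gms: dict[str, float] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for name in _SUMMARY_PARAMS:
        vals = [getattr(r, name) for r in results]
        pos = [v for v in vals if v > 0]
        if len(pos) < len(vals):
            warnings.warn(
                f"{len(vals) - len(pos)} non-positive value(s) excluded from "
                f"{name} summary",
                stacklevel=2,
            )
        if not pos:
            continue
        gms[name] = geometric_mean(pos)
        ranges[name] = (min(pos), max(pos))
    return FlockNcaSummary(len(results), gms, ranges)
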