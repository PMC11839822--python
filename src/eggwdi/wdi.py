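"""Withdrawal-interval (WDI) estimators and the PAR calculator.

Three estimators of the time after which eggs from treated hens may enter
the food supply:

* **HLM** (half-life multiplier): ten terminal half-lives, the time for
  >99% depletion.
* **FDA-style tolerance limit**: the first time at which the upper one-sided
  tolerance limit for the 99th population percentile of ln(residue), at 95%
  confidence, falls to the permitted concentration. Uses all
  elimination-phase timepoints.
* **EMA-style tolerance limit**: the same construction for the 95th
  percentile at 95% confidence, restricted to the final seven timepoints
  (the window the EU tool accepts), with the EU substitution of 2 x LLOQ
  for a missing MRL.

The tolerance limit on a log-linear depletion regression uses the
noncentral-t formulation: with ln C = a + b t + e, e ~ N(0, sigma^2),
residual SD s on n - 2 df, and effective sample size
n*(t) = [1/n + (t - xbar)^2 / Sxx]^(-1), the upper (P, conf) limit is

    UTL(t) = a + b t + K(t) s,
    K(t)   = t_{n-2, z_P sqrt(n*(t))}^{-1}(conf) / sqrt(n*(t)),

where the inverse is the conf-quantile of the noncentral t distribution
with noncentrality z_P sqrt(n*(t)). Both regulatory WDIs are the first
crossing of UTL(t) below ln(limit), located on a 0.01-day grid and rounded
up to the next whole day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .augment import AugmentedTimepoint
from .data import HOURS_PER_DAY

__all__ = [
    "LimitBasis",
    "ResidueLimit",
    "ToleranceLimitFit",
    "WdiMethod",
    "WdiEstimate",
    "ParInputs",
    "wdi_hlm",
    "fit_depletion",
    "upper_tolerance_limit",
    "wdi_from_tolerance",
    "wdi_fda",
    "wdi_ema",
    "compute_par",
    "round_up_wdi",
]

DEFAULT_SEARCH_WINDOW = 365.0  # days
_GRID_STEP = 0.01  # days; raw WDIs are reported to 0.1 d precision
EMA_MAX_TIMEPOINTS = 7


class WdiError(ValueError):
    """WDI estimation failed (invalid input or no crossing)."""


class LimitBasis(str, Enum):
    """Where a residue limit comes from when no tolerance/MRL is approved."""

    EXPLICIT_MRL = "explicit_mrl"
    LOD = "lod"  # US practice: the assay LOD stands in for the tolerance
    TWO_TIMES_LLOQ = "two_times_lloq"  # EU practice: 2 x LLOQ stands in for the MRL


@dataclass(frozen=True)
class ResidueLimit:
    """Permitted residue concentration (ng/g) and its regulatory basis."""

    value: float
    basis: LimitBasis = LimitBasis.EXPLICIT_MRL

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("residue limit must be > 0")

    @classmethod
    def from_lod(cls, lod: float) -> "ResidueLimit":
        return cls(lod, LimitBasis.LOD)

    @classmethod
    def from_lloq(cls, lloq: float) -> "ResidueLimit":
        return cls(2.0 * lloq, LimitBasis.TWO_TIMES_LLOQ)


class WdiMethod(str, Enum):
    HLM = "hlm"
    FDA_TOLERANCE = "fda_tolerance"
    EMA_MRL = "ema_mrl"


@dataclass(frozen=True)
class WdiEstimate:
    """One method's withdrawal interval, raw and rounded up to whole days."""

    method: WdiMethod
    raw_wdi: float  # days
    rounded_wdi: int  # whole days
    limit: ResidueLimit | None = None
    diagnostics: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rounded_wdi < self.raw_wdi:
            raise ValueError("rounded_wdi must be >= raw_wdi")


def round_up_wdi(raw: float) -> int:
    """Round a raw WDI up to the nearest 24 h interval (whole days).

    Integers map to themselves; tiny floating overshoot beyond an integer is
    not forgiven — any fractional day costs a full extra day of withdrawal.
    """
    if raw < 0:
        raise WdiError(f"negative WDI {raw}")
    return int(math.ceil(raw))


def wdi_hlm(t_half_hours: float) -> WdiEstimate:
    """Half-life multiplier estimate: 10 terminal half-lives, in days.

    At ten half-lives less than 0.1% of the residue remains, the standard
    rule-of-thumb for >99% depletion.
    """
    if t_half_hours <= 0:
        raise WdiError("t_half must be > 0")
    raw = 10.0 * t_half_hours / HOURS_PER_DAY
    return WdiEstimate(
        method=WdiMethod.HLM,
        raw_wdi=raw,
        rounded_wdi=round_up_wdi(raw),
        limit=None,
        diagnostics={"t_half_hours": t_half_hours, "multiplier": 10},
    )


@dataclass(frozen=True)
class ToleranceLimitFit:
    """Log-linear depletion regression plus tolerance-limit machinery.

    Sufficient statistics of the OLS fit of ln(concentration in ng/g) on
    time (days): slope (1/day, expected negative), intercept (ln ng/g),
    residual SD ``s`` on ``n - 2`` df, mean time ``xbar`` and centred sum of
    squares ``sxx``. ``percentile`` and ``confidence`` select the (P, conf)
    upper tolerance limit.
    """

    n: int
    slope: float
    intercept: float
    s: float
    xbar: float
    sxx: float
    percentile: float
    confidence: float
    diagnostics: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("tolerance fit needs n >= 3")
        if self.s < 0 or self.sxx <= 0:
            raise ValueError("require s >= 0 and Sxx > 0")
        if not (0.0 < self.percentile < 1.0 and 0.0 < self.confidence < 1.0):
            raise ValueError("percentile and confidence must be in (0, 1)")

    @property
    def df(self) -> int:
        return self.n - 2

    def predicted(self, t) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def _lack_of_fit(times: np.ndarray, y: np.ndarray, fit_resid_ss: float
                 ) -> tuple[float, float]:
    """Lack-of-fit F test of the line against the per-timepoint-means model.

    Returns (F, p). Requires replicate values at some timepoints; if the
    pure-error SS is ~0 with a nonzero lack-of-fit SS the statistic is
    infinite (p = 0); a ~0 lack-of-fit SS gives F = 0, p = 1.
    """
    groups = {}
    for t, v in zip(times, y):
        groups.setdefault(t, []).append(v)
    k = len(groups)
    n = len(y)
    if k < 3 or n <= k:
        return math.nan, math.nan
    ss_pe = sum(
        float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in groups.values()
    )
    ss_lof = fit_resid_ss - ss_pe
    df_lof, df_pe = k - 2, n - k
    if ss_lof <= 1e-12:
        return 0.0, 1.0
    if ss_pe <= 1e-12:
        return math.inf, 0.0
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    return f, float(stats.f.sf(f, df_lof, df_pe))


def fit_depletion(
    points: Sequence[tuple[float, float]],
    percentile: float,
    confidence: float,
) -> ToleranceLimitFit:
    """OLS of ln(concentration) on time over pooled (time days, ng/g) points.

    Stores the sufficient statistics needed for pointwise tolerance limits.
    A non-negative slope is recorded as a diagnostic warning (depletion not
    evident) rather than an error; downstream crossing search requires a
    negative slope and will fail loudly.
    """
    if len(points) < 3:
        raise WdiError("depletion fit needs >= 3 points")
    t = np.asarray([p[0] for p in points], dtype=float)
    c = np.asarray([p[1] for p in points], dtype=float)
    if np.any(c <= 0):
        raise WdiError("all concentrations must be > 0 for a log-linear fit")
    if len(np.unique(t)) < 2:
        raise WdiError("singular design: need >= 2 distinct times")
    y = np.log(c)
    n = len(t)
    xbar = float(t.mean())
    sxx = float(np.sum((t - xbar) ** 2))
    slope = float(np.sum((t - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (intercept + slope * t)
    ss_res = float(np.dot(resid, resid))
    s = math.sqrt(ss_res / (n - 2)) if n > 2 else 0.0
    # guard against negative round-off under an exact fit
    if ss_res < 0:
        s = 0.0
    diagnostics: dict[str, object] = {}
    if slope >= 0:
        diagnostics["warning_positive_slope"] = slope
    f, p = _lack_of_fit(t, y, ss_res)
    if not math.isnan(f):
        diagnostics["lack_of_fit_F"] = f
        diagnostics["lack_of_fit_p"] = p
    return ToleranceLimitFit(
        n=n,
        slope=slope,
        intercept=intercept,
        s=s,
        xbar=xbar,
        sxx=sxx,
        percentile=percentile,
        confidence=confidence,
        diagnostics=diagnostics,
    )


def tolerance_factor(fit: ToleranceLimitFit, t) -> np.ndarray | float:
    """Pointwise one-sided tolerance factor K(t).

    K(t) = q_nct(conf; df = n - 2, nc = z_P sqrt(n*(t))) / sqrt(n*(t)) with
    the effective sample size n*(t) = [1/n + (t - xbar)^2 / Sxx]^(-1). At
    t = xbar and large n, K -> z_P.
    """
    if fit.df < 1:
        raise WdiError("tolerance factor needs df >= 1")
    tt = np.asarray(t, dtype=float)
    n_eff = 1.0 / (1.0 / fit.n + (tt - fit.xbar) ** 2 / fit.sxx)
    z_p = stats.norm.ppf(fit.percentile)
    k = stats.nct.ppf(fit.confidence, fit.df, z_p * np.sqrt(n_eff)) / np.sqrt(n_eff)
    return k


def upper_tolerance_limit(fit: ToleranceLimitFit, t) -> np.ndarray | float:
    """UTL(t) = predicted ln-concentration + K(t) * s, in ln(ng/g).

    With s = 0 this is the fitted mean line itself.
    """
    yhat = fit.predicted(t)
    if fit.s == 0.0:
        return yhat
    return yhat + tolerance_factor(fit, t) * fit.s


def wdi_from_tolerance(
    fit: ToleranceLimitFit,
    limit: ResidueLimit,
    method: WdiMethod = WdiMethod.FDA_TOLERANCE,
    search_window: float = DEFAULT_SEARCH_WINDOW,
) -> WdiEstimate:
    """Smallest t with UTL(t) <= ln(limit), on a 0.01-day grid.

    A coarse whole-day scan brackets the first crossing, then the bracketed
    day is refined at 0.01-day resolution; the raw WDI is the first fine
    grid point at or below the limit, rounded up to whole days for the
    recommended interval.
    """
    if fit.slope >= 0:
        raise WdiError("no depletion: fitted slope is non-negative")
    ln_limit = math.log(limit.value)
    coarse = np.arange(0.0, search_window + 1.0, 1.0)
    utl = np.atleast_1d(upper_tolerance_limit(fit, coarse))
    below = np.nonzero(utl <= ln_limit)[0]
    if len(below) == 0:
        raise WdiError(
            f"tolerance limit never reaches {limit.value} ng/g within "
            f"{search_window} days"
        )
    day = coarse[below[0]]
    if day == 0.0:
        raw = 0.0
    else:
        fine = np.arange(day - 1.0, day + _GRID_STEP / 2, _GRID_STEP)
        futl = np.atleast_1d(upper_tolerance_limit(fit, fine))
        fidx = np.nonzero(futl <= ln_limit)[0]
        raw = float(fine[fidx[0]])
    diagnostics = dict(fit.diagnostics)
    diagnostics.update(
        {
            "percentile": fit.percentile,
            "confidence": fit.confidence,
            "n": fit.n,
            "slope_per_day": fit.slope,
            "utl_at_raw": float(np.atleast_1d(upper_tolerance_limit(fit, raw))[0]),
        }
    )
    return WdiEstimate(
        method=method,
        raw_wdi=raw,
        rounded_wdi=round_up_wdi(raw),
        limit=limit,
        diagnostics=diagnostics,
    )


def _pool(timepoints: Sequence[AugmentedTimepoint]) -> list[tuple[float, float]]:
    return [(tp.time, v) for tp in timepoints for v in tp.values]


def wdi_fda(
    timepoints: Sequence[AugmentedTimepoint],
    limit: ResidueLimit,
    search_window: float = DEFAULT_SEARCH_WINDOW,
) -> WdiEstimate:
    """US-style WDI: 99th percentile, 95% confidence, over ALL
    elimination-phase timepoints (each with >= 10 values after
    augmentation)."""
    fit = fit_depletion(_pool(timepoints), percentile=0.99, confidence=0.95)
    est = wdi_from_tolerance(fit, limit, WdiMethod.FDA_TOLERANCE, search_window)
    return est


def wdi_ema(
    timepoints: Sequence[AugmentedTimepoint],
    limit: ResidueLimit,
    max_timepoints: int = EMA_MAX_TIMEPOINTS,
    search_window: float = DEFAULT_SEARCH_WINDOW,
    strict: bool = False,
) -> WdiEstimate:
    """EU-style WDI: 95th percentile, 95% confidence, restricted to the
    final ``max_timepoints`` timepoints (the EU tool's input limit).

    Data checks — lack-of-fit F test of linearity and Bartlett's test of
    variance homogeneity across timepoints (both at alpha = 0.05) — warn in
    the diagnostics by default; ``strict=True`` turns failures into errors.
    """
    window = sorted(timepoints, key=lambda tp: tp.time)[-max_timepoints:]
    if len(window) < 3:
        raise WdiError(
            f"EMA window has {len(window)} timepoints, need >= 3"
        )
    fit = fit_depletion(_pool(window), percentile=0.95, confidence=0.95)
    diagnostics = dict(fit.diagnostics)
    groups = [np.log(np.asarray(tp.values)) for tp in window
              if len(tp.values) >= 2
              and np.std(np.log(tp.values)) > 1e-10]
    if len(groups) >= 2:
        bart_stat, bart_p = stats.bartlett(*groups)
        diagnostics["bartlett_stat"] = float(bart_stat)
        diagnostics["bartlett_p"] = float(bart_p)
        if bart_p < 0.05:
            diagnostics["warning_heteroscedastic"] = True
    lof_p = diagnostics.get("lack_of_fit_p")
    if isinstance(lof_p, float) and lof_p < 0.05:
        diagnostics["warning_nonlinear"] = True
    if strict and any(k.startswith("warning_") for k in diagnostics):
        raise WdiError(f"EMA data checks failed: {sorted(diagnostics)}")
    fit = ToleranceLimitFit(
        n=fit.n, slope=fit.slope, intercept=fit.intercept, s=fit.s,
        xbar=fit.xbar, sxx=fit.sxx, percentile=fit.percentile,
        confidence=fit.confidence, diagnostics=diagnostics,
    )
    return wdi_from_tolerance(fit, limit, WdiMethod.EMA_MRL, search_window)


@dataclass(frozen=True)
class ParInputs:
    """Inputs of the provisionally-acceptable-residue calculation.

    ``adi`` in ug/kg bodyweight/day, ``bodyweight`` in kg,
    ``partition_fraction`` the share of the ADI allotted to this food, and
    ``consumption`` the daily intake of the food in kg/day.
    """

    adi: float
    bodyweight: float
    partition_fraction: float
    consumption: float

    def __post_init__(self) -> None:
        if min(self.adi, self.bodyweight, self.consumption) <= 0:
            raise ValueError("ADI, bodyweight and consumption must be > 0")
        if not (0.0 < self.partition_fraction <= 1.0):
            raise ValueError("partition_fraction must be in (0, 1]")


def compute_par(inputs: ParInputs) -> float:
    """Provisionally acceptable residue in ug/kg of food (= ppb).

    PAR = ADI x bodyweight x partition fraction / daily consumption: the
    residue concentration at which eating ``consumption`` kg/day delivers
    exactly the food's share of the acceptable daily intake.
    """
    return (
        inputs.adi * inputs.bodyweight * inputs.partition_fraction
        / inputs.consumption
    )
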